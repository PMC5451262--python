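# Methods

## The assembly-queue model

`iftsim` simulates the life cycle of fluorescently tagged IFT proteins in a
single biflagellate cell: cell-body supply → basal-body pool → anterograde
transit → ciliary tip → retrograde transit → recycling at the base or
release back into the cell body. The two flagella (labelled *experimental*
and *control*) share one cell body; photobleaching protocols target the
experimental structure only, which is what makes frame-by-frame
normalization to the control pool meaningful.

Trains depart each pool as a renewal process with mean rate
`departure_rate` (default 1/s) and inter-departure CV `departure_cv`
(default 0.3, gamma-distributed intervals; CV 0 gives clockwork release).
Train size alternates between bright (size factor 1.0) and dim
(`bright_dim_ratio` = 0.5) with `dim_fraction` = 0.5, independently per
train. Each protein joins a nascent train at
`departure − max(0, N(recruitment_lead, lead_sd))`; nascent trains occupy at
most `n_slots` = 9 assembly slots, and a recruitment stalls until the train
nine departures ahead has left (with the default leads this cap binds
rarely and shaves mean queue occupancy by ≈ 0.1 train; the Little's-law
property test therefore uses a configuration where the cap is slack).
Transit is deterministic: 12 µm at 2 µm/s anterograde, a 0.9 s tip dwell,
3 µm/s retrograde — 10.9 s base to base. Copies are integer counts per
(compartment, protein, bleach state); trains carry their own counts, so
copy number is conserved exactly and bleaching is irreversible by
construction.

Recycling (`recycle_enabled` proteins, the IFT-B recycling class): copies
returning at the base enter a recycling compartment with a truncated-normal
residence (~6 ± 1 s, one draw per train-and-protein batch), then move with
`reuse_prob` into a reuse-ready buffer or otherwise to the cell body. A
recruiting train draws each copy from the reuse buffer with probability
`buffer/(buffer + copies_per_train)` — reuse governed by supply — and the
remainder from the cell body. This per-copy mixing matters: a take-the-
whole-buffer rule produces unrealistic all-bright/all-dark trains under
FLIP, whereas real trains leave the depleted pool uniformly dimmed.

Integration is event-driven with every event time snapped to the `dt` =
0.01 s grid (integer ticks), which is exact for this piecewise-
deterministic process and makes runs byte-for-byte reproducible; a warm-up
of one transit plus the longest residence and lead is simulated before
t = 0 so all compartments start in steady state. Acquisition photobleaching
(`imaging_bleach_rate`, default 0.003/s for every copy in the evanescent
field of both structures) is applied once per 0.1 s frame, i.e. per
exposure. Experimental and control structures, the bleach protocol and the
imaging noise each use named substreams of a single master seed.

## Default calibration

Printed or directly anchored values: departure rate 1/s; nine assembly
slots; recruitment leads 7.0 s (IFT140, IFT43), 6.5 s (IFT54, IFT20),
5.5 s (IFT46, IFT27), 2.5 s (D1bLIC); recycling residence 6 ± 1 s; KAP
mostly dissociating at the tip (`tip_release_prob` 0.9); tubulin carried by
~45% of trains and fully incorporated at the tip.

The remaining recycling parameters are the solution of a flux balance
against four observables at once (per-departure pool drop, tip-FLIP pool
plateau, post-FLIP train-intensity deficit, retrograde-derived pool
fraction). With mean train size m = 0.75 and lead µ, the pool holds
λµm nascent + λm(1−q)·6 s recycling + reuse buffer + standing copies,
where q is the tip-release fraction; departing trains under FLIP carry a
bleached fraction r = reuse_prob·(1−q). Requiring r ≈ 0.4 and a pool of
~8 bright-train equivalents forces q ≈ 0.55 and reuse_prob ≈ 0.9 for the
recycling IFT-B proteins, with `standing_extra` ≈ 1 train. The constraint
set is over-determined: the printed ~52% pool decline within ~5.8 s after a
whole-flagellum bleach would need the directly flushable retrograde-derived
compartments to be half the pool, which contradicts the printed pool size
(from the 12.7% per-departure drop) and the 6 s residence. The shipped
calibration favours the drop/plateau/deficit set; the whole-flagellum-
bleach decline consequently bottoms at ~35% over ~10 s instead of 52% over
5.8 s, and the corresponding acceptance checks are expected to fail.

Two leads deviate from naive readings because the model couples them to
other printed quantities. KAP's lead is 3.0 s: pool FRAP recovery in this
model equals the recruitment lead plus a small estimator overhead, and the
KAP pool demonstrably recovers in under 4 s; a 5 s lead cannot do that.
Tubulin's lead is 0.5 s: with 45% carriage the thinned renewal wait alone
is ~1.8 s, so only a sub-second lead reproduces a ~1.9 s experimental gap
that is statistically indistinguishable from the control flagellum's.

Free rendering/supply choices: `copies_per_train` 40 (brightness and
granularity unit), `total_cell_copies` 8000 (≈ 95% of the protein outside
the pool; finite, so prolonged FLIP exhausts the cell), 20 photons per
copy, 0.16 µm pixels, 10 frames/s, PSF sigma 1.3 px, background 10
counts/px, read noise 2 counts.

## What the virtual microscope does and does not emulate

Rendering is one-dimensional along a layout axis holding both pools and
both flagella; trains and pools are Gaussian profiles whose amplitude is
proportional to unbleached copies, with Poisson shot noise and additive
read noise. Duty-cycled FLIP acquisition supports both real dialects —
frames during laser-on are dropped, or saturated and masked. Incorporated
axonemal tubulin accumulates as a static tip spot. Not emulated: focus
drift, cell autofluorescence structure, evanescent-depth effects, 2-D pool
substructure, or flagellar growth. Passing tests on this synthetic data
therefore validate the estimators' logic and calibration, not their
robustness to those real-world artefacts.

A consequence worth knowing: because recruitment is instantaneous per
train, the pool signal is granular — queue-occupancy fluctuations of one to
two trains (±15–30%) on a multi-second correlation time. This is the
dominant "noise" in all pool traces, far above shot noise, and it drives
the estimator design below. Real pools recruit continuously and are
smoother at short timescales, but the paper-style per-departure drops put a
lower bound on the real granularity too.

## Estimator design

* **Traces and normalization.** ROI sums per frame, background-subtracted
  with the temporal median of a dark layout region; saturated/dropped
  frames masked. Normalization is 100·experimental/control per frame, so
  any decay shared by the structures (acquisition bleaching, cell-body
  dilution) cancels — verified by paired simulations with different imaging
  bleach rates.
* **Two-line FRAP fit.** Window placement (post-bleach minimum, plateau,
  90%-of-plateau crossing) runs on a smoothed copy that never averages
  across the bleach instant; the plateau (median over 10 s from the first
  sustained flat stretch after the dip) and the rising line are then fit on
  raw values, making the estimator exact on piecewise-linear input. Fits
  with a rising slope under 2%/s are censored as degenerate. Because
  single-cell fits are heavy-tailed under occupancy noise, each FRAP assay
  also fits the replicate-averaged curve, and reports both the two-line
  recovery time and the time to reach 95% of the plateau ("maximum
  recovery").
* **FLIP fit.** The initial slope is a raw least-squares trendline over the
  first 10 s (exact on linear input); the 10 s loss is read off that
  trendline. The plateau level is a tail median and the plateau time the
  first sustained approach to within 10% of the full decline — level-based
  rather than slope-based, because occupancy-noise slopes are comparable to
  the true decline slope. For the whole-flagellum bleach the fit window
  ends at transit + residence after the bleach, where unbleached returns
  start refilling the pool, and pool recovery is the first sustained return
  to 90% of the pre-bleach level.
* **Trajectory detection.** Shear-and-sum line integration over a velocity
  grid (anterograde +1.0…+3.5, retrograde −4.5…−1.5 µm/s, 0.1 steps) on a
  rolling-low-quantile background (20th percentile over 10 s per position,
  robust to non-stationary traffic and to 50% line occupancy). Candidate
  peaks above a pixel-noise floor — or 8% of the brightest line, whichever
  is larger — are accepted greedily with matching pursuit: each accepted
  line's pixels are removed from a per-direction residual and later
  candidates are re-scored against it, which kills the wrong-velocity ghost
  responses of bright lines while keeping genuinely distinct dim trains.
  On noise-free renders recall and precision are 1 for lines separated by
  ≥ 0.4 s.
* **Gap measurement.** First post-bleach anterograde trajectory from the
  base whose mean intensity reaches 30% of the pre-bleach median; dimmer
  earlier trains are counted as early birds. A 0.15 s margin skips trains
  whose frame-quantized origin straddles the bleach. The ground-truth
  oracle applies the same criterion to unbleached copy numbers in the event
  log.
* **Train-intensity ratio (FLIP deficit).** Mean anterograde trajectory
  intensity, experimental / control, with both sides truncated to the
  brightest-N trajectories (N = smaller count) so the detection limit does
  not censor the dimmed side asymmetrically; under FLIP the intensities are
  measured proximal to the bleach window so pool-derived dimming is not
  conflated with en-route bleaching.
* **Departure drops.** 100·(mean over [t−0.4, t−0.1] − mean over
  [t+0.1, t+0.4])/pre-mean at ground-truth departure times, overlapping
  windows skipped. Note these windows integrate ~0.5 s of pool refill
  (~15 copies at default rates), so measured drops run ~60% of the
  instantaneous copy loss; the printed drop values should be compared with
  this in mind.

## Problem sizes

Default virtual experiments use one simulated cell per replicate (40 s for
FRAP and gap assays, 60 s for FLIP, 45 s for whole-flagellum bleach, 120 s
for traffic statistics) at 10 fps. The acceptance script runs 10–49
replicates per assay and finishes in about a minute on one CPU; the test
suite uses smaller replicate counts and runs in under a minute.

## Known limitations

* Pool granularity (instantaneous per-train recruitment) inflates
  single-replicate estimator variance; replicate means and mean-curve fits
  are the reliable outputs.
* The whole-flagellum-bleach decline is slower and shallower than the
  measured benchmark (see Calibration); the same flux-balance tension
  depresses the measured IFT54 per-departure drop.
* Retrograde trains re-use the anterograde composition minus tip-released
  copies; there is no mid-flagellum standing IFT, no U-turns, no diffusive
  motor return, and flagellar length is fixed.
* The queue occupancy implied by the default leads is ~7 trains; analyses
  that assume ~9 queueing trains will read the model's value as low.
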