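# iftsim

Stochastic simulation and kymograph quantification of **intraflagellar
transport (IFT) train assembly** at the ciliary base.

Cilia and flagella are built and maintained by IFT trains — multi-megadalton
assemblies of IFT-A, IFT-B and motor proteins that run from the basal body to
the ciliary tip (anterograde, kinesin-2) and back (retrograde, IFT dynein).
Around each basal body sits a pool of IFT material from which trains are
released roughly once per second. `iftsim` implements an *assembly-queue*
model of this pool: several trains in different stages of assembly queue for
sequential release, each protein class joins a nascent train with its own
recruitment lead time before departure, and returning IFT-B proteins are
partly reused at the base (a "semi-open" system) while IFT-A and motor
proteins disperse back into the cell body (an "open" system).

On top of the simulator sits a virtual TIRF microscope (kymograms and image
stacks with PSF blur, Poisson shot noise, read noise, and duty-cycled
bleach-laser acquisition artefacts) and the estimators used on real
recordings: frame-by-frame normalization of the bleached basal-body pool to
the unbleached control pool, two-line FRAP recovery fitting, FLIP loss
curves, straight-line trajectory detection with traffic statistics,
post-bleach traffic-gap measurement, and per-departure pool-drop
quantification. Because the simulator keeps exact ground truth (every copy's
compartment and bleach state, every train's composition), each estimator can
be validated against an oracle.

## The model in brief

For each protein *p* a train departing at time *t* recruits its copies at
*t − L_p*, with recruitment lead *L_p* ~ N(μ_p, σ_p) truncated at 0 (μ ≈ 7 s
for IFT-A, ≈ 6.5/5.5 s for IFT-B2/B1, ≈ 3 s for kinesin-2 KAP, ≈ 2.5 s for
IFT dynein, ≲ 1 s for tubulin cargo). Departures form a renewal process with
rate λ = 1/s and CV 0.3, bounded by `n_slots = 9` assembly slots, so by
Little's law the pool holds λ·μ_p nascent-train copies of protein *p*.
Trains transit a 12 µm flagellum at 2 µm/s out and 3 µm/s back with a 0.9 s
tip dwell (base→tip→base ≈ 10.9 s). At the tip a protein-specific fraction
of copies is released; returning copies of recycling IFT-B proteins dwell
~6 s in a basal recycling compartment and are then reused in nascent trains
with probability 0.9 or released to the cell body. Every copy carries an
irreversible bleach state; copy number is conserved exactly.

## Worked example

Simulate a cell expressing tagged IFT54, photobleach the experimental
basal-body pool at t = 10 s, render a kymogram, and measure the traffic gap:

```python
import numpy as np
import iftsim as m

config   = m.build_default_config(["IFT54"], duration=40.0, seed=7)
protocol = m.BleachProtocol([m.pool_pulse(10.0, efficiency=0.95)])
log, trace = m.run_simulation(config, protocol)

kym   = m.render_kymogram(trace, m.RenderConfig(),
                          np.random.default_rng(7), protocol=protocol)["IFT54"]
trajs = m.detect_trains(kym, "experimental")
stats = m.traffic_stats(trajs, "anterograde")
gap   = m.measure_gap(trajs, t_bleach=10.0)
print(f"anterograde frequency {stats['frequency']:.2f}/s, "
      f"velocity {stats['velocity_mean']:.2f} um/s")
print(f"post-bleach gap {gap.gap:.1f} s ({gap.n_early_birds} early birds)")
```

prints

```
anterograde frequency 0.90/s, velocity 2.01 um/s
post-bleach gap 5.7 s (0 early birds)
```

i.e. trains keep leaving about once per second at the anterograde speed, but
after the pool bleach no *bright* train departs for several seconds — the
recruitment lead time of the IFT54 material that was already queued in the
pool when the bleach hit (6.5 s on average for this protein; this replicate
drew 5.7 s).

The same pipeline drives replicate-level virtual experiments:

```python
from iftsim.experiments import run_flip_tip
flip = run_flip_tip("IFT54", n=14, seed=1)
print(flip.mean("plateau_level"))   # 42.8 — % of the pool fed by fresh supply
```

A command line mirrors the library: `iftsim simulate`, `iftsim render`,
`iftsim quantify`, `iftsim experiment --assay gap --protein IFT140`, and
`iftsim reproduce-all`.

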