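"""Replicate in-silico photobleaching assays, end to end.

Each replicate simulates one cell (experimental + control flagellum sharing
one cell body), renders kymograms with the virtual TIRF microscope, and
applies the kymograph estimators — so every summary statistic travels the
same pipeline a real measurement would.  Assays:

* ``run_frap_pool`` — focused pulse on the experimental basal-body pool,
  two-line recovery-time fit of the normalized pool trace.
* ``run_flip_tip`` — duty-cycled bleach near the tip, pool loss curve and
  plateau plus the train-intensity deficit of departing trains.
* ``run_full_flagellum_bleach`` — single bleach of the whole flagellum:
  pool decline amplitude/duration, first unbleached retrograde return and
  pool recovery time.
* ``run_gap`` / ``run_two_color_gap`` / ``run_tubulin_gap`` — pool bleach
  followed by the wait for the first bright anterograde train.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import kymo_quant as kq
from . import queue_model as qm
from . import tirf_render as tr

__all__ = [
    "ExperimentSpec", "ExperimentSummary", "run_frap_pool", "run_flip_tip",
    "run_full_flagellum_bleach", "run_gap", "run_two_color_gap",
    "run_tubulin_gap", "run_traffic", "run_departure_drops", "reproduce_all",
]

ASSAYS = ("frap_pool", "flip_tip", "full_flagellum_bleach", "gap",
          "two_color_gap", "tubulin_gap")


@dataclass
class ExperimentSpec:
    assay: str
    proteins: tuple[str, ...]
    n_replicates: int
    seed: int
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.assay not in ASSAYS:
            raise qm.ConfigError(f"unknown assay {self.assay!r}")
        if self.assay == "two_color_gap" and set(self.proteins) != {"KAP", "IFT140"}:
            raise qm.ConfigError("two_color_gap requires KAP and IFT140")
        if self.assay == "tubulin_gap" and "tubulin" not in self.proteins:
            raise qm.ConfigError("tubulin_gap requires tubulin")


@dataclass
class ExperimentSummary:
    """Per-replicate values plus summary moments for one assay."""

    assay: str
    protein: str
    per_replicate: pd.DataFrame      # one row per non-censored replicate
    censored: int = 0
    paired_t: dict | None = None     # {"metric_a", "metric_b", "t", "p"}
    mean_curve: dict | None = None   # fit of the replicate-averaged curve

    @property
    def n(self) -> int:
        return len(self.per_replicate)

    def mean(self, metric: str) -> float:
        return float(self.per_replicate[metric].mean())

    def sd(self, metric: str) -> float:
        return float(self.per_replicate[metric].std(ddof=1))

    def table(self) -> pd.DataFrame:
        rows = []
        for metric in self.per_replicate.columns:
            rows.append({
                "assay": self.assay, "protein": self.protein, "metric": metric,
                "mean": self.mean(metric), "sd": self.sd(metric),
                "n": self.n, "censored": self.censored})
        return pd.DataFrame(rows)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed & 0x7FFFFFFF)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def _replicate(proteins, seed, duration, protocol, overrides=None,
               shot_noise=True):
    """Simulate + render one cell; returns (config, log, trace, kyms)."""
    overrides = dict(overrides or {})
    cfg_overrides = {"duration": duration, "seed": seed}
    cfg_overrides.update(overrides.pop("config", {}))
    config = qm.build_default_config(proteins, **cfg_overrides)
    for pname, fields in overrides.pop("proteins", {}).items():
        idx = [i for i, p in enumerate(config.proteins) if p.name == pname][0]
        config.proteins[idx] = replace(config.proteins[idx], **fields)
    log, trace = qm.run_simulation(config, protocol)
    rcfg = tr.RenderConfig(shot_noise=shot_noise,
                           **overrides.pop("render", {}))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 0x2E5]))
    kyms = tr.render_kymogram(trace, rcfg, rng, protocol=protocol)
    return config, log, trace, kyms


def _norm_pool_trace(kym: tr.Kymogram) -> kq.IntensityTrace:
    exp = kq.extract_trace(kym, kym.pool_roi("experimental"))
    ctrl = kq.extract_trace(kym, kym.pool_roi("control"))
    return kq.normalize_trace(exp, ctrl)


def _time_to_level(trace: kq.IntensityTrace, t0: float, level: float,
                   sustain: float = 2.0) -> float:
    """First time after ``t0`` the smoothed trace sustainedly regains
    ``level``, relative to ``t0`` (nan if never)."""
    t, v, mk = trace.time, trace.value, trace.mask
    sm = kq._smooth(t, v, mk, 3.0, breaks=(t0,))
    post = (t >= t0) & mk
    idx = np.nonzero(post)[0]
    below = [i for i in idx if np.isfinite(sm[i]) and sm[i] < level]
    if not below:
        return np.nan                      # never lost the level
    for i in idx:
        if i <= below[0]:
            continue
        if not (np.isfinite(sm[i]) and sm[i] >= level):
            continue
        ahead = post & (t >= t[i]) & (t <= t[i] + sustain)
        vals = sm[ahead][np.isfinite(sm[ahead])]
        if len(vals) and np.all(vals >= level):
            return float(t[i] - t0)
    return np.nan


def _mean_trace(traces: list[kq.IntensityTrace]) -> kq.IntensityTrace:
    """Frame-wise mean of normalized traces over replicates (masked frames
    excluded per replicate)."""
    time = traces[0].time
    vals = np.stack([np.where(t.mask, t.value, np.nan) for t in traces])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vals, axis=0)
    mask = np.isfinite(mean)
    return kq.IntensityTrace(time.copy(), np.nan_to_num(mean), mask,
                             units="percent")


def run_frap_pool(protein: str, n: int = 10, seed: int = 0,
                  t_bleach: float = 10.0, duration: float = 40.0,
                  efficiency: float = 0.95, overrides=None) -> ExperimentSummary:
    """Pool FRAP: recovery time and plateau of the normalized pool signal."""
    rows, censored, traces = [], 0, []
    protocol = qm.BleachProtocol([qm.pool_pulse(t_bleach, efficiency)])
    for s in _spawn_seeds(seed, n):
        _, _, _, kyms = _replicate([protein], s, duration, protocol, overrides)
        kym = next(iter(kyms.values()))
        trace = _norm_pool_trace(kym)
        traces.append(trace)
        fit = kq.fit_frap(trace, t_bleach, fallback_tail=10.0)
        # a meaningful two-line construction needs a visibly rising line
        if (not fit.ok or not np.isfinite(fit.recovery_time)
                or fit.rising_slope < 2.0):
            censored += 1
            continue
        rows.append({"recovery_time": fit.recovery_time,
                     "plateau_level": fit.plateau_level,
                     "rising_slope": fit.rising_slope})
    summary = ExperimentSummary("frap_pool", protein, pd.DataFrame(rows), censored)
    # queue-occupancy noise makes single-cell two-line fits heavy-tailed, so
    # also fit the replicate-averaged recovery curve
    mt = _mean_trace(traces)
    mfit = kq.fit_frap(mt, t_bleach, fallback_tail=10.0)
    # the paper-style alternative readout: time to reach maximum recovery
    t_max = (np.nan if not mfit.ok else
             _time_to_level(mt, t_bleach, 0.95 * mfit.plateau_level))
    summary.mean_curve = {"recovery_time": mfit.recovery_time,
                          "plateau_level": mfit.plateau_level,
                          "time_to_max_recovery": t_max,
                          "ok": mfit.ok}
    return summary


def run_flip_tip(protein: str, n: int = 14, seed: int = 0,
                 t_start: float = 10.0, duration: float = 60.0,
                 overrides=None, measure_trains: bool = True) -> ExperimentSummary:
    """Tip FLIP: pool loss slope, plateau level/time, and the intensity of
    trains departing under FLIP relative to the control flagellum."""
    rows, censored = [], 0
    for s in _spawn_seeds(seed, n):
        protocol = qm.BleachProtocol([qm.tip_flip(t_start, duration)])
        _, _, _, kyms = _replicate([protein], s, duration, protocol, overrides)
        kym = next(iter(kyms.values()))
        trace = _norm_pool_trace(kym)
        fit = kq.fit_flip(trace, t_start, tail_window=25.0)
        row = {"initial_slope": fit.initial_slope, "loss_at_10s": fit.loss_at_10s}
        if fit.declined:
            if fit.plateau_time is None:
                censored += 1
                continue
            row["plateau_time"] = fit.plateau_time
            row["plateau_level"] = fit.plateau_level
        else:
            # open-system proteins never decline; report the level late in FLIP
            row["plateau_time"] = 0.0
            row["plateau_level"] = trace.window_mean(t_start + 20, duration)
        if measure_trains:
            t_lo = t_start + (fit.plateau_time or 10.0)
            try:
                # intensities are measured proximal to the FLIP window so
                # the pool-derived dimming is not conflated with en-route
                # bleaching inside the beam
                e = kq.detect_trains(kym, "experimental", threshold_k=3.5,
                                     exclude_tip_um=3.5
                                     ).filter("anterograde", t_lo)
                c = kq.detect_trains(kym, "control", threshold_k=3.5,
                                     exclude_tip_um=3.5
                                     ).filter("anterograde", t_lo)
                row["train_intensity_ratio"] = kq.train_intensity_ratio(e, c)
            except ValueError:
                row["train_intensity_ratio"] = np.nan
        rows.append(row)
    return ExperimentSummary("flip_tip", protein, pd.DataFrame(rows), censored)


def run_full_flagellum_bleach(protein: str, n: int = 6, seed: int = 0,
                              t_bleach: float = 10.0, duration: float = 45.0,
                              overrides=None) -> ExperimentSummary:
    """Whole-flagellum bleach: pool decline (amplitude + duration) as the
    bleached retrograde wave flushes through the recycling compartment,
    first unbleached retrograde return, and pool recovery time."""
    rows, censored, traces = [], 0, []
    protocol = qm.BleachProtocol([qm.whole_flagellum_bleach(t_bleach)])
    config = None
    for s in _spawn_seeds(seed, n):
        config, log, _, kyms = _replicate([protein], s, duration, protocol,
                                          overrides)
        kym = next(iter(kyms.values()))
        trace = _norm_pool_trace(kym)
        traces.append(trace)
        # the decline phase ends once unbleached retrograde returns have
        # flushed through the recycling compartment (transit + residence)
        residence = (config.protein(protein).residence_mean
                     if config.protein(protein).recycle_enabled else 0.0)
        t_cut = t_bleach + 0.95 * (config.transit_time + residence)
        flip = kq.fit_flip(trace, t_bleach, t_max=t_cut)
        pre = trace.window_mean(t_bleach - 5, t_bleach)
        row = {"decline_pct": pre - flip.plateau_level,
               "decline_duration": (flip.plateau_time
                                    if flip.declined and flip.plateau_time is not None
                                    else np.nan)}
        # pool recovery: first sustained return to ~the prebleach level
        pre_lvl = trace.window_mean(t_bleach - 5, t_bleach)
        row["pool_recovery_time"] = _time_to_level(trace, t_bleach,
                                                   0.9 * pre_lvl)
        # first retrograde trajectory carrying unbleached protein back to the
        # base; trains already in transit at the bleach carry bright
        # pre-bleach segments, so only lines starting after the bleach count
        trajs = kq.detect_trains(kym, "experimental")
        retro = [t for t in trajs if t.direction == "retrograde"]
        pre_med = np.median([t.mean_intensity for t in retro
                             if t.base_time < t_bleach] or [np.nan])
        ret = [t.base_time for t in retro
               if t.origin_time > t_bleach and t.base_time > t_bleach
               and t.mean_intensity >= 0.3 * pre_med]
        row["first_retro_return"] = (min(ret) - t_bleach) if ret else np.nan
        rows.append(row)
    summary = ExperimentSummary("full_flagellum_bleach", protein,
                                pd.DataFrame(rows), censored)
    # stable estimates from the replicate-averaged pool curve
    residence = (config.protein(protein).residence_mean
                 if config.protein(protein).recycle_enabled else 0.0)
    t_cut = t_bleach + 0.95 * (config.transit_time + residence)
    mt = _mean_trace(traces)
    mflip = kq.fit_flip(mt, t_bleach, t_max=t_cut)
    pre = mt.window_mean(t_bleach - 5, t_bleach)
    summary.mean_curve = {
        "decline_pct": pre - mflip.plateau_level,
        "decline_duration": mflip.plateau_time,
        "pool_recovery_time": _time_to_level(mt, t_bleach, 0.9 * pre),
    }
    return summary


def run_gap(protein: str, n: int = 20, seed: int = 0, t_bleach: float = 10.0,
            duration: float = 40.0, efficiency: float = 0.95,
            overrides=None) -> ExperimentSummary:
    """Post-bleach traffic gap: wait from the pool bleach to the first
    bright anterograde train."""
    rows, censored = [], 0
    protocol = qm.BleachProtocol([qm.pool_pulse(t_bleach, efficiency)])
    for s in _spawn_seeds(seed, n):
        _, log, _, kyms = _replicate([protein], s, duration, protocol, overrides)
        kym = next(iter(kyms.values()))
        trajs = kq.detect_trains(kym, "experimental")
        res = kq.measure_gap(trajs, t_bleach)
        if res.censored:
            censored += 1
            continue
        rows.append({"gap": res.gap, "n_early_birds": res.n_early_birds,
                     "oracle_gap": kq.gap_from_event_log(log, t_bleach, protein)})
    return ExperimentSummary("gap", protein, pd.DataFrame(rows), censored)


def run_two_color_gap(n: int = 49, seed: int = 0, t_bleach: float = 10.0,
                      duration: float = 40.0, efficiency: float = 0.95,
                      overrides=None) -> dict:
    """Simultaneous KAP (green) / IFT140 (red) gap assay.

    A replicate counts as 'KAP first' when the first qualifying KAP train
    precedes the first train qualifying in both channels (same simulated
    trains, two spectral channels)."""
    protocol = qm.BleachProtocol([qm.pool_pulse(t_bleach, efficiency)])
    rows, censored, kap_first = [], 0, 0
    for s in _spawn_seeds(seed, n):
        _, _, _, kyms = _replicate(["KAP", "IFT140"], s, duration, protocol,
                                   overrides)
        res = {}
        bad = False
        for channel, name in (("green", "KAP"), ("red", "IFT140")):
            trajs = kq.detect_trains(kyms[channel], "experimental")
            g = kq.measure_gap(trajs, t_bleach)
            if g.censored:
                bad = True
                break
            res[name] = g.gap
        if bad:
            censored += 1
            continue
        half_frame = 0.051
        if res["KAP"] < res["IFT140"] - half_frame:
            kap_first += 1
        rows.append({"gap_KAP": res["KAP"], "gap_IFT140": res["IFT140"]})
    df = pd.DataFrame(rows)
    return {"n_kap_first": kap_first, "n": len(df), "censored": censored,
            "summary": ExperimentSummary("two_color_gap", "KAP+IFT140", df,
                                         censored)}


def run_tubulin_gap(n: int = 25, seed: int = 0, t_bleach: float = 10.0,
                    duration: float = 30.0, efficiency: float = 0.95,
                    bleach_both: bool = False, overrides=None) -> ExperimentSummary:
    """Tubulin loading gap, paired experimental vs control flagellum.

    Incorporated axonemal tubulin starts pre-bleached; the pool pulse hits
    the experimental side (or both pools with ``bleach_both``).  The control
    gap is simply the wait for the next tubulin-carrying train."""
    region = "pool-both" if bleach_both else "pool-exp"
    protocol = qm.BleachProtocol([
        qm.pool_pulse(t_bleach, efficiency, region=region)])
    rows, censored = [], 0
    for s in _spawn_seeds(seed, n):
        _, _, _, kyms = _replicate(["tubulin"], s, duration, protocol, overrides)
        kym = next(iter(kyms.values()))
        row = {}
        bad = False
        for struct, key in (("experimental", "gap_exp"), ("control", "gap_ctrl")):
            trajs = kq.detect_trains(kym, struct, exclude_tip_um=1.6)
            try:
                g = kq.measure_gap(trajs, t_bleach)
            except ValueError:
                bad = True
                break
            if g.censored:
                bad = True
                break
            row[key] = g.gap
        if bad:
            censored += 1
            continue
        rows.append(row)
    df = pd.DataFrame(rows)
    paired = None
    if len(df) > 2:
        t, p = stats.ttest_rel(df["gap_exp"], df["gap_ctrl"])
        paired = {"metric_a": "gap_exp", "metric_b": "gap_ctrl",
                  "t": float(t), "p": float(p)}
    return ExperimentSummary("tubulin_gap", "tubulin", df, censored, paired)


def run_traffic(protein: str = "IFT54", n: int = 2, seed: int = 0,
                duration: float = 120.0, overrides=None) -> ExperimentSummary:
    """Unperturbed traffic statistics from detected trajectories."""
    rows = []
    for s in _spawn_seeds(seed, n):
        config, _, _, kyms = _replicate([protein], s, duration, None, overrides)
        kym = next(iter(kyms.values()))
        trajs = kq.detect_trains(kym, "experimental")
        st = kq.traffic_stats(trajs, "anterograde")
        rows.append({"frequency": st["frequency"],
                     "velocity_mean": st["velocity_mean"]})
    return ExperimentSummary("traffic", protein, pd.DataFrame(rows), 0)


def run_departure_drops(protein: str = "KAP", n: int = 3, seed: int = 0,
                        duration: float = 60.0, bright_only: bool = True,
                        overrides=None) -> ExperimentSummary:
    """Per-departure pool signal drops measured on the rendered pool trace
    at ground-truth departure times (bright trains by default, matching how
    drops are read off real kymograms)."""
    rows = []
    for s in _spawn_seeds(seed, n):
        _, log, _, kyms = _replicate([protein], s, duration, None, overrides)
        kym = next(iter(kyms.values()))
        exp = kq.extract_trace(kym, kym.pool_roi("experimental"))
        deps = [r for r in log.of_kind("departure", "experimental")
                if r["unbleached"] + r["bleached"] > 0]
        times = np.array([r["t"] for r in deps])
        bright = np.array([r["size_factor"] == 1.0 for r in deps])
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            drops = kq.departure_drops(exp, times)
        if bright_only:
            drops = drops[bright[np.argsort(times)]]
        for d in drops[np.isfinite(drops)]:
            rows.append({"drop_pct": float(d)})
    return ExperimentSummary("departure_drops", protein, pd.DataFrame(rows), 0)


# ---------------------------------------------------------------------------

def reproduce_all(seed: int = 1, n_scale: float = 1.0) -> dict:
    """Run every assay at its default replicate count and return the headline
    observables as a flat dict of {name: {"value", "n"}}.

    ``n_scale`` < 1 shrinks replicate counts proportionally (minimum 4) for
    quick smoke runs.
    """
    def ns(n):
        return max(4, int(round(n * n_scale)))

    seeds = _spawn_seeds(seed, 16)
    out: dict[str, dict] = {}

    def put(name, value, n):
        out[name] = {"value": (None if value is None or not np.isfinite(value)
                               else round(float(value), 3)), "n": int(n)}

    frap_kap = run_frap_pool("KAP", n=ns(10), seed=seeds[0])
    put("kap_frap_recovery_s", frap_kap.mean_curve["recovery_time"], ns(10))
    frap_54 = run_frap_pool("IFT54", n=ns(10), seed=seeds[1])
    put("ift54_frap_recovery_s", frap_54.mean_curve["recovery_time"], ns(10))
    frap_43 = run_frap_pool("IFT43", n=ns(10), seed=seeds[13])
    put("ift43_frap_recovery_s", frap_43.mean_curve["recovery_time"], ns(10))
    put("ift54_frap_time_to_max_recovery_s",
        frap_54.mean_curve["time_to_max_recovery"], ns(10))
    put("ift43_frap_time_to_max_recovery_s",
        frap_43.mean_curve["time_to_max_recovery"], ns(10))

    flip_54 = run_flip_tip("IFT54", n=ns(14), seed=seeds[2])
    put("ift54_flip_pool_plateau_pct", flip_54.mean("plateau_level"), flip_54.n)
    put("ift54_flip_plateau_time_s", flip_54.mean("plateau_time"), flip_54.n)
    ratio = flip_54.per_replicate["train_intensity_ratio"].dropna()
    put("ift54_flip_train_intensity_deficit_pct",
        100.0 * (1.0 - ratio.mean()), len(ratio))

    flip_43 = run_flip_tip("IFT43", n=ns(8), seed=seeds[3])
    put("ift43_flip_pool_loss_at_10s_pct", flip_43.mean("loss_at_10s"), flip_43.n)
    ratio43 = flip_43.per_replicate["train_intensity_ratio"].dropna()
    put("ift43_flip_train_intensity_deficit_pct",
        100.0 * (1.0 - ratio43.mean()), len(ratio43))

    full_54 = run_full_flagellum_bleach("IFT54", n=ns(12), seed=seeds[4])
    put("ift54_full_bleach_decline_pct",
        full_54.mean_curve["decline_pct"], full_54.n)
    put("ift54_full_bleach_decline_duration_s",
        full_54.mean_curve["decline_duration"], full_54.n)
    rets = full_54.per_replicate["first_retro_return"].dropna()
    put("ift54_full_bleach_first_retro_return_s", rets.mean(), len(rets))
    put("ift54_full_bleach_pool_recovery_s",
        full_54.mean_curve["pool_recovery_time"], full_54.n)
    put("ift54_retro_derived_pool_fraction_pct",
        full_54.mean_curve["decline_pct"], full_54.n)

    gap_140 = run_gap("IFT140", n=ns(20), seed=seeds[5])
    put("ift140_gap_s", gap_140.mean("gap"), gap_140.n)
    gap_dyn = run_gap("D1bLIC", n=ns(20), seed=seeds[6])
    put("d1blic_gap_s", gap_dyn.mean("gap"), gap_dyn.n)

    two = run_two_color_gap(n=ns(49), seed=seeds[7])
    put("kap_first_trains_of_49", two["n_kap_first"] * 49.0 / max(1, two["n"]),
        two["n"])

    tub = run_tubulin_gap(n=ns(25), seed=seeds[8])
    put("tubulin_gap_experimental_s", tub.mean("gap_exp"), tub.n)
    put("tubulin_gap_control_s", tub.mean("gap_ctrl"), tub.n)
    if tub.paired_t:
        put("tubulin_gap_paired_p", tub.paired_t["p"], tub.n)

    drops_kap = run_departure_drops("KAP", n=ns(3), seed=seeds[9])
    put("kap_pool_drop_per_departure_pct", drops_kap.mean("drop_pct"),
        drops_kap.n)
    drops_54 = run_departure_drops("IFT54", n=ns(3), seed=seeds[10])
    put("ift54_pool_drop_per_departure_pct", drops_54.mean("drop_pct"),
        drops_54.n)

    traffic = run_traffic("IFT54", n=ns(2), seed=seeds[11])
    put("anterograde_frequency_per_s", traffic.mean("frequency"), traffic.n)
    put("anterograde_velocity_um_s", traffic.mean("velocity_mean"), traffic.n)

    # queue occupancy: time-averaged number of nascent trains holding IFT140
    config = qm.build_default_config(["IFT140"], duration=120.0,
                                     seed=_spawn_seeds(seed, 13)[12])
    log, _ = qm.run_simulation(config, None)
    occ = _queue_occupancy(log, config, "IFT140")
    put("nascent_trains_in_pool", occ, 1)
    return out


def _queue_occupancy(log: qm.EventLog, config: qm.SimConfig, protein: str,
                     structure: str = "experimental") -> float:
    """Time-averaged number of nascent trains holding ``protein``, measured
    over a window that excludes edge effects at the start and end of the
    recording (recruitments without a logged departure count up to the
    window end)."""
    t0 = min(15.0, config.duration / 4)
    t1 = config.duration - 1.0
    departures = {d["train"]: d["t"] for d in log.of_kind("departure", structure)}
    total = 0.0
    for r in log.of_kind("recruit", structure):
        if r["protein"] != protein:
            continue
        t_rec = r["t"]
        t_dep = departures.get(r["train"], t1)
        total += max(0.0, min(t_dep, t1) - max(t_rec, t0))
    return total / (t1 - t0)
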