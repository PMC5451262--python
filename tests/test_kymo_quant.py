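"""Tests for the kymograph estimators, with ground-truth oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import iftsim as m
from iftsim.kymo_quant import IntensityTrace, gap_from_event_log
from iftsim.tirf_render import Kymogram, ROI, StructureLayout


def _trace(values, dt=0.1):
    v = np.asarray(values, dtype=float)
    return IntensityTrace(np.arange(len(v)) * dt, v,
                          np.ones(len(v), dtype=bool), units="percent")


def _toy_kymogram(data, dt=0.1, px=0.16):
    n = data.shape[1]
    layout = {"control": StructureLayout(5.0, 10.0),
              "experimental": StructureLayout(n // 2 - 5.0, float(n // 2))}
    return Kymogram(data=data.astype(float), frame_interval=dt, pixel_size=px,
                    channel="t", layout=layout,
                    valid_frames=np.ones(data.shape[0], dtype=bool),
                    flagellum_length=(n - n // 2 - 1) * px)


# ---------------------------------------------------------------------------
# traces and normalization
# ---------------------------------------------------------------------------

def test_extract_trace_uniform_grid_is_zero():
    data = np.full((50, 120), 7.0)
    kym = _toy_kymogram(data)
    tr = m.extract_trace(kym, kym.pool_roi("experimental"))
    assert len(tr.value) == 50
    assert np.allclose(tr.value, 0.0)


def test_extract_trace_rejects_empty_roi():
    kym = _toy_kymogram(np.zeros((10, 120)))
    with pytest.raises(ValueError):
        m.extract_trace(kym, ROI(5, 5))


def test_extract_trace_matches_ground_truth_pool(noise_free_run):
    cfg, log, trace, kym = noise_free_run
    tr = m.extract_trace(kym, kym.pool_roi("experimental"))
    gt = trace.pool_series("IFT54", "experimental")[:, 0].astype(float)
    keep = gt > 0
    ratio = tr.value[keep] / gt[keep]
    # proportional to unbleached pool copies (constant photons/copy factor)
    assert np.std(ratio) / np.mean(ratio) < 0.05


def test_normalize_trace_identity_and_scaling():
    e = _trace([50.0] * 20)
    n = m.normalize_trace(e, _trace([50.0] * 20))
    assert np.allclose(n.value[n.mask], 100.0)
    decay = np.exp(-0.05 * np.arange(20))
    n2 = m.normalize_trace(_trace(40.0 * decay), _trace(50.0 * decay))
    assert np.allclose(n2.value[n2.mask], 80.0)   # shared decay cancels


def test_normalize_trace_masks_dead_control():
    e = _trace([1.0] * 10)
    with pytest.raises(ValueError):
        m.normalize_trace(e, _trace([0.0] * 10))


def test_normalization_cancels_acquisition_bleaching():
    """Pool traces normalized to the control are insensitive to the imaging
    bleach rate (paired simulations, rate 0 vs 0.005/s)."""
    levels = {}
    for rate in (0.0, 0.005):
        cfg = m.build_default_config(["IFT54"], duration=40.0, seed=3,
                                     imaging_bleach_rate=rate)
        _, trace = m.run_simulation(cfg)
        kym = m.render_kymogram(trace, m.RenderConfig(shot_noise=False,
                                                      read_noise_sd=0.0),
                                np.random.default_rng(0))["IFT54"]
        e = m.extract_trace(kym, kym.pool_roi("experimental"))
        c = m.extract_trace(kym, kym.pool_roi("control"))
        n = m.normalize_trace(e, c)
        levels[rate] = n.value[n.mask][-100:].mean()
    assert levels[0.005] == pytest.approx(levels[0.0], rel=0.12)


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

def test_fit_frap_exact_on_piecewise_linear():
    t = np.arange(0, 30.0 + 1e-9, 0.1)
    v = np.where(t < 10.0, 100.0,
                 np.where(t < 15.0, 40.0 + 10.0 * (t - 10.0), 90.0))
    fit = m.fit_frap(IntensityTrace(t, v, np.ones(len(t), bool)), 10.0)
    assert fit.ok
    assert fit.recovery_time == pytest.approx(5.0, abs=0.05)
    assert fit.plateau_level == pytest.approx(90.0, abs=0.5)
    assert fit.rising_slope == pytest.approx(10.0, abs=0.2)


def test_fit_frap_reports_failure_without_plateau():
    t = np.arange(0, 8.0, 0.1)
    v = 10.0 + 5.0 * t                       # still rising at trace end
    fit = m.fit_frap(IntensityTrace(t, v, np.ones(len(t), bool)), 1.0)
    assert not fit.ok and "plateau" in fit.message


def test_fit_frap_breakpoint_recovery_under_noise():
    """Known two-line breakpoint recovered within 0.5 s on average under
    2% measurement noise."""
    rng = np.random.default_rng(42)
    t = np.arange(0, 30.0 + 1e-9, 0.1)
    clean = np.where(t < 10.0, 100.0,
                     np.where(t < 15.0, 40.0 + 10.0 * (t - 10.0), 90.0))
    errs = []
    for _ in range(100):
        v = clean + rng.normal(0, 2.0, len(t))
        fit = m.fit_frap(IntensityTrace(t, v, np.ones(len(t), bool)), 10.0)
        if fit.ok:
            errs.append(fit.recovery_time - 5.0)
    assert len(errs) > 90
    assert abs(np.mean(errs)) < 0.5


def test_fit_flip_exact_on_linear():
    t = np.arange(0, 10.1, 0.1)
    v = 100.0 - 3.0 * t
    fit = m.fit_flip(IntensityTrace(t, v, np.ones(len(t), bool)), 0.0)
    assert fit.initial_slope == pytest.approx(-3.0, abs=1e-9)
    assert fit.loss_at_10s == pytest.approx(30.0, abs=1e-9)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(slope=st.floats(-5.0, -0.5), intercept=st.floats(50.0, 150.0))
def test_fit_flip_slope_exact_on_random_linear(slope, intercept):
    t = np.arange(0, 12.0, 0.1)
    v = intercept + slope * t
    fit = m.fit_flip(IntensityTrace(t, v, np.ones(len(t), bool)), 0.0)
    assert fit.initial_slope == pytest.approx(slope, abs=1e-8)


def test_fit_flip_flags_constant_trace():
    t = np.arange(0, 20.0, 0.1)
    fit = m.fit_flip(IntensityTrace(t, np.full(len(t), 80.0),
                                    np.ones(len(t), bool)), 2.0)
    assert fit.initial_slope == pytest.approx(0.0, abs=1e-9)
    assert not fit.declined


# ---------------------------------------------------------------------------
# trajectory detection
# ---------------------------------------------------------------------------

def _line_kymogram(lines, n_frames=120, width=140, amp=400.0, bg=10.0):
    """Geometric fixture: straight lines of (velocity um/s, base time s)."""
    data = np.full((n_frames, width), bg)
    dt, px = 0.1, 0.16
    x0 = width // 2
    for v, t0 in lines:
        for f in range(n_frames):
            x = v * (f * dt - t0)
            if 0 <= x <= 12.0:
                j = x0 + int(round(x / px))
                if j < width:
                    data[f, j] += amp
    return _toy_kymogram(data)


def test_detect_single_anterograde_line():
    kym = _line_kymogram([(2.0, 1.0)])
    trajs = m.detect_trains(kym, "experimental")
    assert len(trajs) == 1
    tr = trajs.trajectories[0]
    assert tr.velocity == pytest.approx(2.0, abs=0.11)
    assert tr.base_time == pytest.approx(1.0, abs=0.15)


def test_detect_crossing_lines_signs_and_velocities():
    kym = _line_kymogram([(2.0, 1.0), (-3.0, 8.0)])
    trajs = m.detect_trains(kym, "experimental")
    vels = sorted(tr.velocity for tr in trajs)
    assert len(trajs) == 2
    assert vels[0] == pytest.approx(-3.0, abs=0.11)
    assert vels[1] == pytest.approx(2.0, abs=0.11)


def test_detection_recall_and_precision_on_noise_free_render(noise_free_run):
    cfg, log, trace, kym = noise_free_run
    trajs = m.detect_trains(kym, "experimental")
    det = [t.base_time for t in trajs if t.velocity > 0]
    true = log.departures("experimental")
    true = true[true < cfg.duration - 6.5]     # end-clipped lines excluded
    for t0 in true:
        assert min(abs(t0 - d) for d in det) < 0.3
    # no false positives: every detection within the record matches a train
    for d in det:
        if 0 <= d < cfg.duration - 6.5:
            assert min(abs(d - t0) for t0 in log.departures("experimental")) < 0.3


@pytest.mark.parametrize("photons", [5.0, 20.0, 80.0])
def test_detection_degrades_gracefully_with_brightness(photons):
    cfg = m.build_default_config(["IFT54"], duration=30.0, seed=9)
    log, trace = m.run_simulation(cfg)
    rcfg = m.RenderConfig(photons_per_copy=photons)
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(2))["IFT54"]
    trajs = m.detect_trains(kym, "experimental")
    freq = m.traffic_stats(trajs, "anterograde")["frequency"]
    if photons >= 20.0:
        assert freq == pytest.approx(1.0, abs=0.25)
    else:
        assert freq > 0.3                      # dimmer, but not blind


def test_traffic_stats_trivia():
    kym = _line_kymogram([(2.0, float(t)) for t in range(1, 11)],
                         n_frames=120)
    trajs = m.detect_trains(kym, "experimental")
    st_ = m.traffic_stats(trajs, "anterograde", interval=10.0)
    assert st_["frequency"] == pytest.approx(1.0, abs=0.2)
    empty = m.traffic_stats(m.TrajectorySet([], 10.0), "retrograde")
    assert empty["frequency"] == 0.0 and empty.get("empty")


def test_velocity_estimate_matches_config(default_kymogram):
    trajs = m.detect_trains(default_kymogram, "experimental")
    st_ = m.traffic_stats(trajs, "anterograde")
    assert st_["velocity_mean"] == pytest.approx(2.0, abs=0.11)
    st_r = m.traffic_stats(trajs, "retrograde")
    assert st_r["velocity_mean"] == pytest.approx(3.0, abs=0.15)


# ---------------------------------------------------------------------------
# gap, drops, ratios
# ---------------------------------------------------------------------------

def test_measure_gap_against_event_log_oracle():
    """Gap from the rendered kymogram equals the gap enumerated from the
    ground-truth event log, per replicate."""
    protocol = m.BleachProtocol([m.pool_pulse(10.0, 0.97)])
    for seed in (3, 5, 8):
        cfg = m.build_default_config(["IFT140"], duration=35.0, seed=seed)
        log, trace = m.run_simulation(cfg, protocol)
        kym = m.render_kymogram(trace, m.RenderConfig(),
                                np.random.default_rng(seed),
                                protocol=protocol)["red"]
        trajs = m.detect_trains(kym, "experimental")
        res = m.measure_gap(trajs, 10.0)
        oracle = gap_from_event_log(log, 10.0, "IFT140")
        assert not res.censored
        assert res.gap == pytest.approx(oracle, abs=0.35)


def test_gap_oracle_deterministic_schedule():
    """With cv 0 and no lead spread the gap is the lead plus the wait to
    the next scheduled slot."""
    from dataclasses import replace
    cfg = m.build_default_config(["IFT140"], duration=30.0, seed=1,
                                 departure_cv=0.0)
    cfg.proteins[0] = replace(cfg.proteins[0], lead_sd=0.0)
    protocol = m.BleachProtocol([m.pool_pulse(10.0, 1.0)])
    log, _ = m.run_simulation(cfg, protocol)
    oracle = gap_from_event_log(log, 10.0, "IFT140")
    lead = cfg.proteins[0].recruitment_lead
    assert lead <= oracle < lead + 1.0 + 2 * cfg.dt


def test_gap_without_bleach_is_next_train_wait():
    protocol = m.BleachProtocol([m.pool_pulse(10.0, 0.0)])
    cfg = m.build_default_config(["IFT140"], duration=30.0, seed=4)
    log, trace = m.run_simulation(cfg, protocol)
    kym = m.render_kymogram(trace, m.RenderConfig(),
                            np.random.default_rng(4))["red"]
    res = m.measure_gap(m.detect_trains(kym, "experimental"), 10.0)
    assert res.gap < 2.5                       # ~1/rate, not the 7 s lead


def test_departure_drops_forced_counts():
    t = np.arange(0, 20.0, 0.1)
    v = np.where(t < 10.0, 100.0, 84.0)        # pool of 100 loses 16 copies
    tr = IntensityTrace(t, v, np.ones(len(t), bool))
    drops = m.departure_drops(tr, np.array([10.0]))
    assert drops[0] == pytest.approx(16.0, abs=1e-9)


def test_departure_drops_constant_trace_and_overlap_warning():
    t = np.arange(0, 20.0, 0.1)
    tr = IntensityTrace(t, np.full(len(t), 100.0), np.ones(len(t), bool))
    assert m.departure_drops(tr, np.array([10.0]))[0] == pytest.approx(0.0)
    with warnings.catch_warnings(record=True) as w:
        warnings.simplefilter("always")
        drops = m.departure_drops(tr, np.array([10.0, 10.2]))
        assert np.isnan(drops).all()
        assert any("skipped" in str(x.message) for x in w)


def test_train_intensity_ratio_identity_and_guard():
    def make(vals):
        return m.TrajectorySet([
            m.Trajectory(origin_time=i, origin_position=0.0, velocity=2.0,
                         duration=5.0, mean_intensity=v, quality=10.0)
            for i, v in enumerate(vals)], duration=30.0)
    a = make([100, 120, 140, 90])
    assert m.train_intensity_ratio(a, make([100, 120, 140, 90])) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        m.train_intensity_ratio(a, make([100, 110]))
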