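"""Tests for the virtual TIRF renderer."""

import numpy as np
import pytest

import iftsim as m
from iftsim.tirf_render import default_layout, _expected_signal


def _single_train_trace(seed=0):
    cfg = m.build_default_config(["IFT54"], duration=10.0, seed=seed,
                                 departure_rate=0.12, departure_cv=0.0,
                                 imaging_bleach_rate=0.0)
    _, trace = m.run_simulation(cfg)
    return cfg, trace


def test_single_train_draws_straight_line_of_slope_v():
    cfg, trace = _single_train_trace()
    rcfg = m.RenderConfig(shot_noise=False, read_noise_sd=0.0)
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(0))["IFT54"]
    sub, pos = kym.flagellum_view("experimental")
    # follow the anterograde leg of one experimental train: the rendered
    # peak column must advance at v_antero
    tr = next(t for t in trace.trains.values()
              if t["structure"] == "experimental" and len(t["frames"]) > 30)
    rising = np.nonzero(np.diff(tr["positions"]) > 0)[0][2:-2]
    frames = tr["frames"][rising]
    peak_x = pos[np.argmax(sub[frames], axis=1)]
    slope = np.polyfit(frames * kym.frame_interval, peak_x, 1)[0]
    assert slope == pytest.approx(cfg.v_antero, abs=0.1)
    assert np.allclose(peak_x, tr["positions"][rising], atol=2 * kym.pixel_size)


def test_zero_photons_gives_pure_background():
    _, trace = _single_train_trace()
    rcfg = m.RenderConfig(photons_per_copy=0.0, shot_noise=False,
                          read_noise_sd=0.0)
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(0))["IFT54"]
    assert np.allclose(kym.data, rcfg.background)


def test_linearity_before_noise():
    """Doubling unbleached copies doubles the expected signal above background."""
    cfg, trace = _single_train_trace()
    rcfg = m.RenderConfig()
    layout, width = default_layout(cfg, rcfg)
    from dataclasses import replace
    rcfg = replace(rcfg, layout=layout, width=width)
    base = _expected_signal(trace, rcfg, "IFT54")
    doubled = _expected_signal(trace, replace(rcfg, photons_per_copy=40.0),
                               "IFT54")
    assert np.allclose(doubled, 2.0 * base)


def test_noise_statistics_poisson_plus_read():
    """Per-pixel variance of a static scene ~ expected photons + read sd^2."""
    cfg = m.build_default_config(["IFT54"], duration=0.2, seed=1,
                                 departure_rate=0.01)
    _, trace = m.run_simulation(cfg)
    rcfg = m.RenderConfig(read_noise_sd=2.0)
    rng = np.random.default_rng(3)
    samples = np.stack([
        m.render_kymogram(trace, rcfg, rng)["IFT54"].data[0] for _ in range(800)])
    mean, var = samples.mean(axis=0), samples.var(axis=0)
    bright = mean > 30
    assert bright.any()
    expected_var = mean + rcfg.read_noise_sd ** 2
    assert np.median(np.abs(var[bright] / expected_var[bright] - 1)) < 0.15


def test_seed_determinism():
    _, trace = _single_train_trace()
    rcfg = m.RenderConfig()
    a = m.render_kymogram(trace, rcfg, np.random.default_rng(9))["IFT54"]
    b = m.render_kymogram(trace, rcfg, np.random.default_rng(9))["IFT54"]
    assert np.array_equal(a.data, b.data)


def test_stack_center_row_equals_direct_kymogram():
    _, trace = _single_train_trace()
    rcfg = m.RenderConfig()
    stack, kym = m.render_frame_stack(trace, rcfg, np.random.default_rng(4))
    direct = m.render_kymogram(trace, rcfg, np.random.default_rng(4))["IFT54"]
    extracted = m.extract_kymogram_from_stack(stack, row=rcfg.stack_height // 2,
                                              width=1, mode="max")
    assert np.array_equal(extracted, direct.data)
    assert np.array_equal(kym.data, direct.data)


def test_single_frozen_train_is_a_gaussian_spot():
    cfg, trace = _single_train_trace()
    rcfg = m.RenderConfig(shot_noise=False, read_noise_sd=0.0)
    stack, kym = m.render_frame_stack(trace, rcfg, np.random.default_rng(0))
    # pick a frame where the train is mid-flagellum
    tr = next(iter(trace.trains.values()))
    f = int(tr["frames"][len(tr["frames"]) // 2])
    frame = stack[f] - rcfg.background
    r, c = np.unravel_index(np.argmax(frame), frame.shape)
    assert r == rcfg.stack_height // 2         # brightest at the focal row
    peak = frame[r, c]
    # one PSF sigma away the signal falls by ~exp(-1/2) in both axes
    assert frame[r + 1, c] < peak
    assert frame[r, min(c + 3, frame.shape[1] - 1)] < 0.3 * peak


def test_drop_frames_dialect_drops_laser_on_frames():
    cfg = m.build_default_config(["IFT54"], duration=20.0, seed=2)
    _, trace = m.run_simulation(cfg)
    protocol = m.BleachProtocol([m.tip_flip(5.0, 20.0)])
    rcfg = m.RenderConfig()
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(1),
                            protocol=protocol)["IFT54"]
    n_off = int(kym.valid_frames.sum())
    assert 0 < n_off < kym.n_frames
    stack, _ = m.render_frame_stack(trace, rcfg, np.random.default_rng(1),
                                    protocol=protocol)
    assert stack.shape[0] == n_off


def test_saturated_dialect_marks_frames():
    cfg = m.build_default_config(["IFT54"], duration=12.0, seed=2)
    _, trace = m.run_simulation(cfg)
    protocol = m.BleachProtocol([m.tip_flip(4.0, 12.0)])
    rcfg = m.RenderConfig(acquisition_dialect="saturated-frames")
    kym = m.render_kymogram(trace, rcfg, np.random.default_rng(1),
                            protocol=protocol)["IFT54"]
    on = ~kym.valid_frames
    assert on.any()
    assert np.all(kym.data[on] == rcfg.saturation_level)


def test_frame_interval_must_match_trace():
    _, trace = _single_train_trace()
    with pytest.raises(m.ConfigError):
        m.render_kymogram(trace, m.RenderConfig(frame_rate=25.0),
                          np.random.default_rng(0))
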