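"""Kymograph quantification: intensity traces, control normalization,
FRAP/FLIP curve fitting, trajectory detection and traffic statistics.

The estimators automate the manual procedures used on real TIRF recordings:
basal-body intensities are measured over line ROIs and normalized frame by
frame to the unbleached control pool (which cancels acquisition bleaching),
FRAP recovery times come from the intersection of a fitted rising line with
a fitted plateau line, FLIP curves are summarized by an initial-window
slope and a plateau, and trains are detected as straight lines in the
kymogram by shear-and-sum line integration over a velocity grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .queue_model import EventLog
from .tirf_render import Kymogram, ROI

__all__ = [
    "IntensityTrace", "Trajectory", "TrajectorySet", "RecoveryFit", "FlipFit",
    "GapResult", "extract_trace", "normalize_trace", "fit_frap", "fit_flip",
    "detect_trains", "traffic_stats", "measure_gap", "departure_drops",
    "train_intensity_ratio",
]


@dataclass
class IntensityTrace:
    """Per-frame intensity over an ROI; ``value`` is in counts, or percent of
    the control after :func:`normalize_trace`."""
    time: np.ndarray
    value: np.ndarray
    mask: np.ndarray            # True where the frame is usable
    units: str = "counts"

    def __post_init__(self):
        if not (len(self.time) == len(self.value) == len(self.mask)):
            raise ValueError("trace arrays must have equal length")

    def at(self, t: float) -> float:
        """Value at the nearest usable frame."""
        i = int(np.argmin(np.abs(self.time - t)))
        if not self.mask[i]:
            ok = np.nonzero(self.mask)[0]
            if len(ok) == 0:
                return np.nan
            i = ok[np.argmin(np.abs(self.time[ok] - t))]
        return float(self.value[i])

    def window_mean(self, t0: float, t1: float) -> float:
        sel = (self.time >= t0 - 1e-9) & (self.time <= t1 + 1e-9) & self.mask
        if not sel.any():
            return np.nan
        return float(self.value[sel].mean())


def extract_trace(kym: Kymogram, roi: ROI,
                  background_roi: ROI | None = None) -> IntensityTrace:
    """Per-frame sum over the ROI, background-subtracted using the temporal
    median of a background ROI; saturated/dropped frames are masked."""
    if roi.x1 <= roi.x0:
        raise ValueError("empty roi")
    if roi.x0 < 0 or roi.x1 > kym.data.shape[1]:
        raise ValueError("roi outside kymogram")
    if background_roi is None:
        background_roi = kym.background_roi()
    sat = (kym.data >= kym.saturation_level).any(axis=1)
    mask = kym.valid_frames & ~sat
    bg_block = kym.data[mask][:, background_roi.slice()]
    bg_per_px = float(np.median(bg_block)) if bg_block.size else 0.0
    width = roi.x1 - roi.x0
    value = kym.data[:, roi.slice()].sum(axis=1) - bg_per_px * width
    return IntensityTrace(kym.times.copy(), value, mask.copy())


def normalize_trace(exp: IntensityTrace, ctrl: IntensityTrace,
                    floor_frac: float = 0.1) -> IntensityTrace:
    """100 x experimental / control, frame by frame.  Any decay shared by the
    two structures (e.g. acquisition photobleaching) cancels.  Control frames
    below ``floor_frac`` of the control median are masked."""
    if len(exp.time) != len(ctrl.time) or np.any(np.abs(exp.time - ctrl.time) > 1e-9):
        raise ValueError("traces must share a time base")
    mask = exp.mask & ctrl.mask
    ctrl_med = np.median(ctrl.value[mask]) if mask.any() else 0.0
    floor = floor_frac * max(ctrl_med, 1e-12)
    good = mask & (ctrl.value > floor)
    if not good.any():
        raise ValueError("all frames masked: control signal below floor")
    value = np.zeros_like(exp.value, dtype=float)
    value[good] = 100.0 * exp.value[good] / ctrl.value[good]
    np.clip(value, 0.0, None, out=value)
    return IntensityTrace(exp.time.copy(), value, good, units="percent")


# ---------------------------------------------------------------------------
# curve fits
# ---------------------------------------------------------------------------

@dataclass
class RecoveryFit:
    t_bleach: float
    recovery_time: float
    plateau_level: float
    rising_slope: float
    rise_window: tuple[float, float]
    plateau_window: tuple[float, float]
    ok: bool = True
    message: str = ""


@dataclass
class FlipFit:
    initial_slope: float          # percent/s over the slope window
    loss_at_10s: float            # percent lost over the first 10 s
    plateau_time: float | None    # s after t_start when decline levels off
    plateau_level: float | None   # percent
    declined: bool = True
    message: str = ""


def _segment_of(t: np.ndarray, breaks: tuple[float, ...]) -> np.ndarray:
    seg = np.zeros(len(t), dtype=int)
    for b in breaks:
        seg += (t >= b - 1e-9).astype(int)
    return seg


def _smooth(t: np.ndarray, v: np.ndarray, m: np.ndarray, window: float,
            breaks: tuple[float, ...] = ()) -> np.ndarray:
    """Moving average that never mixes samples across the known
    discontinuities in ``breaks`` (e.g. the bleach instant).  The pool
    signal fluctuates by design — every train departure/arrival moves it —
    so window placement for the line fits works on this smoothed version
    while the fits themselves use raw values."""
    half = window / 2.0
    seg = _segment_of(t, breaks)
    out = np.full(len(t), np.nan)
    for i in range(len(t)):
        sel = (np.abs(t - t[i]) <= half + 1e-9) & m & (seg == seg[i])
        if sel.any():
            out[i] = v[sel].mean()
    return out


def _local_slopes(t: np.ndarray, v: np.ndarray, window: float) -> np.ndarray:
    """Centred rolling least-squares slope of (possibly smoothed) values;
    nan where the window has < 3 finite samples."""
    out = np.full(len(t), np.nan)
    half = window / 2.0
    fin = np.isfinite(v)
    for i in range(len(t)):
        sel = (np.abs(t - t[i]) <= half + 1e-9) & fin
        if sel.sum() >= 3:
            out[i] = np.polyfit(t[sel], v[sel], 1)[0]
    return out


def _flat_runs(t, slopes, candidates, tol, span):
    """Contiguous stretches (>= span) of candidate frames with |slope| < tol;
    returns list of (start_idx, end_idx)."""
    runs = []
    run_start = None
    prev = None
    for i in np.nonzero(candidates)[0]:
        flat = np.isfinite(slopes[i]) and abs(slopes[i]) < tol
        contiguous = prev is not None and i == prev + 1
        if flat:
            if run_start is not None and not contiguous:
                if t[prev] - t[run_start] >= span - 1e-9:
                    runs.append((run_start, prev))
                run_start = None
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and t[prev] - t[run_start] >= span - 1e-9:
                runs.append((run_start, prev))
            run_start = None
        prev = i
    if run_start is not None and t[prev] - t[run_start] >= span - 1e-9:
        runs.append((run_start, prev))
    return runs


def fit_frap(trace: IntensityTrace, t_bleach: float, delta: float = 0.3,
             plateau_slope_tol: float = 2.5, plateau_span: float = 3.0,
             slope_window: float = 8.0, smooth_window: float = 3.0,
             dip_search: float = 10.0,
             fallback_tail: float | None = None) -> RecoveryFit:
    """Two-line FRAP recovery fit.

    Window placement (post-bleach minimum, plateau region, 90%-of-plateau
    crossing) works on a smoothed copy of the trace that never averages
    across the bleach instant; the plateau level and the rising line are
    then fit on raw values, so the estimator is exact on piecewise-linear
    input.  The recovery time is the intersection of the rising line with
    the plateau line, minus ``t_bleach``.
    """
    t, v, m = trace.time, trace.value, trace.mask
    post = (t >= t_bleach) & m
    if post.sum() < 5:
        return RecoveryFit(t_bleach, np.nan, np.nan, np.nan, (np.nan,) * 2,
                           (np.nan,) * 2, ok=False, message="trace too short")
    sm = _smooth(t, v, m, smooth_window, breaks=(t_bleach,))
    slopes = _local_slopes(t, np.where(post, sm, np.nan), slope_window)
    ts = t[1] - t[0] if len(t) > 1 else 0.1
    # the dip: minimum of the smoothed post-bleach curve; the plateau must
    # lie after it (a slow decline before the dip is not the plateau)
    early = post & (t <= t_bleach + max(5 * ts, dip_search) + 1e-9)
    ei = np.nonzero(early)[0]
    i_min = ei[np.nanargmin(sm[ei])]
    runs = _flat_runs(t, slopes, post & (t >= t[i_min]),
                      plateau_slope_tol, plateau_span)
    if runs:
        # plateau = robust level over a 10 s window from the first sustained
        # flat stretch (not to trace end: late occupancy drift would bias it)
        best = runs[0]
        pl_sel = np.zeros(len(t), dtype=bool)
        pl_sel[best[0]:] = True
        pl_sel &= m & (t <= t[best[0]] + 10.0 + 1e-9)
    elif fallback_tail is not None:
        # no sustained flat stretch (queue noise): fall back to the trace tail
        t_end = t[post][-1]
        pl_sel = post & (t >= t_end - fallback_tail)
    else:
        return RecoveryFit(t_bleach, np.nan, np.nan, np.nan, (np.nan,) * 2,
                           (np.nan,) * 2, ok=False, message="no plateau detected")
    plateau = float(np.median(v[pl_sel]))
    tp = t[pl_sel]
    plateau_window = (float(tp[0]), float(tp[-1]))

    # rising window: from the post-bleach minimum to the 90%-of-plateau crossing
    t_rise0 = max(t_bleach + delta, t[i_min])
    crossing = None
    for i in np.nonzero(post)[0]:
        if t[i] >= t_rise0 and np.isfinite(sm[i]) and sm[i] >= 0.9 * plateau:
            crossing = t[i]
            break
    if crossing is None or crossing <= t_rise0 + ts:
        # already at plateau: no measurable dip / instant recovery
        return RecoveryFit(t_bleach, 0.0, plateau, np.inf,
                           (t_rise0, t_rise0), plateau_window, ok=True,
                           message="no dip below 90% of plateau")
    rise_sel = (t >= t_rise0 - 1e-9) & (t <= crossing + 1e-9) & m
    if rise_sel.sum() < 3:
        return RecoveryFit(t_bleach, np.nan, plateau, np.nan,
                           (t_rise0, crossing), plateau_window, ok=False,
                           message="rising window too short")
    a, b = np.polyfit(t[rise_sel], v[rise_sel], 1)
    if a <= 0:
        return RecoveryFit(t_bleach, np.nan, plateau, a, (t_rise0, crossing),
                           plateau_window, ok=False, message="non-rising recovery")
    t_star = (plateau - b) / a
    return RecoveryFit(t_bleach, max(0.0, t_star - t_bleach), plateau, a,
                       (float(t_rise0), float(crossing)), plateau_window)


def fit_flip(trace: IntensityTrace, t_start: float,
             slope_window: tuple[float, float] = (0.0, 10.0),
             tail_window: float = 15.0, reach_frac: float = 0.1,
             decline_threshold: float = 10.0, smooth_window: float = 3.0,
             sustain: float = 1.5, t_max: float | None = None) -> FlipFit:
    """FLIP loss curve summary.

    ``initial_slope`` is the least-squares trendline over the initial window
    on raw values (exact on linear input) and ``loss_at_10s`` the drop over
    the first 10 s.  The plateau is estimated level-wise, which is robust to
    the slope noise the queue's train-sized granularity puts on pool traces:
    the plateau level is the median over the final ``tail_window`` seconds
    (clipped to ``t_max`` if the curve recovers later, as after a
    whole-flagellum bleach), and the plateau time is the first moment the
    smoothed trace sustainedly comes within ``reach_frac`` of the full
    decline.  Curves whose total decline stays below ``decline_threshold``
    percent are flagged as not declining.
    """
    t, v, m = trace.time, trace.value, trace.mask
    w0, w1 = (t_start + slope_window[0], t_start + slope_window[1])
    sel = (t >= w0 - 1e-9) & (t <= w1 + 1e-9) & m
    if sel.sum() < 3:
        raise ValueError("slope window too short")
    slope = float(np.polyfit(t[sel], v[sel], 1)[0])
    # signal loss over the first 10 s, read off the fitted trendline (robust
    # to the train-sized granularity of single frames)
    loss = -slope * 10.0

    m_eff = m.copy()
    if t_max is not None:
        m_eff &= t <= t_max + 1e-9
    post = (t >= t_start) & m_eff
    if not post.any():
        raise ValueError("t_start beyond trace")
    t_end = t[post][-1]
    pre = (t >= t_start - 3.0) & (t < t_start) & m
    start_level = float(np.median(v[pre])) if pre.sum() >= 3 else float(
        np.median(v[post & (t <= t_start + 2.0)]))
    tail = min(tail_window, max(2.0, (t_end - t_start) / 3.0))
    tail_sel = post & (t >= t_end - tail)
    plateau_level = float(np.median(v[tail_sel]))
    declined = (start_level - plateau_level) >= decline_threshold
    plateau_time = None
    if declined:
        sm = _smooth(t, v, m_eff, smooth_window, breaks=(t_start,))
        reach = plateau_level + reach_frac * (start_level - plateau_level)
        idx = np.nonzero(post)[0]
        for i in idx:
            if not (np.isfinite(sm[i]) and sm[i] <= reach):
                continue
            ahead = post & (t >= t[i]) & (t <= t[i] + sustain)
            vals = sm[ahead]
            if np.all(vals[np.isfinite(vals)] <= reach):
                plateau_time = float(t[i] - t_start)
                break
    return FlipFit(initial_slope=slope, loss_at_10s=float(loss),
                   plateau_time=plateau_time,
                   plateau_level=plateau_level if declined else plateau_level,
                   declined=declined,
                   message="" if declined else "no decline beyond threshold")


# ---------------------------------------------------------------------------
# trajectory detection
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    origin_time: float          # s; base departure (anterograde) or tip start (retro)
    origin_position: float      # um
    velocity: float             # signed um/s, positive = anterograde
    duration: float             # s inside the field of view
    mean_intensity: float       # background-subtracted counts per pixel sample
    quality: float              # peak response / robust noise scale
    base_time: float = np.nan   # s at which the line crosses the flagellar base

    @property
    def direction(self) -> str:
        return "anterograde" if self.velocity > 0 else "retrograde"


@dataclass
class TrajectorySet:
    trajectories: list[Trajectory]
    duration: float
    structure: str = "experimental"

    def __iter__(self):
        return iter(self.trajectories)

    def __len__(self):
        return len(self.trajectories)

    def filter(self, direction: str | None = None, t0: float | None = None,
               t1: float | None = None) -> "TrajectorySet":
        out = list(self.trajectories)
        if direction is not None:
            out = [tr for tr in out if tr.direction == direction]
        if t0 is not None:
            out = [tr for tr in out if tr.origin_time >= t0]
        if t1 is not None:
            out = [tr for tr in out if tr.origin_time <= t1]
        return TrajectorySet(out, self.duration, self.structure)


def detect_trains(kym: Kymogram, structure: str = "experimental",
                  v_antero: tuple[float, float] = (1.0, 3.5),
                  v_retro: tuple[float, float] = (-4.5, -1.5),
                  v_step: float = 0.1, threshold_k: float = 5.0,
                  min_separation: float = 0.4,
                  exclude_tip_um: float = 0.0) -> TrajectorySet:
    """Detect IFT trains as straight lines by shear-and-sum integration.

    The flagellum band is background-subtracted with a per-position temporal
    median; for every candidate velocity the image is summed along lines of
    that slope, peaks above ``threshold_k`` robust noise scales become
    trajectories, and non-maximum suppression across (base-intercept,
    velocity) keeps the best line per train.
    """
    sub, pos = kym.flagellum_view(structure)
    if exclude_tip_um > 0:
        # mask out the distal end, e.g. when incorporated axonemal material
        # accumulates there and defeats the temporal-median background
        keep = pos <= pos[-1] - exclude_tip_um
        sub, pos = sub[:, keep], pos[keep]
    n_frames, n_cols = sub.shape
    dt_f = kym.frame_interval
    px = kym.pixel_size
    img = sub.astype(float).copy()
    img[~kym.valid_frames] = np.nan
    med = np.nanmedian(img, axis=0)
    for j in range(img.shape[1]):
        col = img[:, j]
        col[np.isnan(col)] = med[j]
    # rolling temporal low-quantile background: adapts to non-stationary
    # traffic brightness (e.g. before vs after a bleach step) and, unlike a
    # median, stays on the baseline even when moving trains occupy half the
    # frames of a column
    from scipy.ndimage import percentile_filter
    win = min(n_frames if n_frames % 2 else n_frames - 1,
              2 * int(5.0 / dt_f) + 1)
    bg = percentile_filter(img, percentile=20, size=(max(3, win), 1),
                           mode="nearest")
    img = img - bg

    velocities = np.concatenate([
        np.arange(v_retro[0], v_retro[1] + 1e-9, v_step),
        np.arange(v_antero[0], v_antero[1] + 1e-9, v_step),
    ])
    L_px = n_cols - 1
    pad = int(np.ceil(L_px / (min(abs(v_antero[0]), abs(v_retro[1])) * dt_f / px))) + 2

    # pass 1: shear-and-sum response per velocity
    # pixel-level robust noise (lower-half MAD): the response distribution
    # itself is contaminated by dense traffic, so line significance is
    # judged against shot/read noise averaged along the line, and the
    # structured rest is handled by matching pursuit below
    med_px = float(np.median(img))
    below_px = med_px - img[img <= med_px]
    sigma_px = max(1.4826 * float(np.median(below_px)), 1e-9)
    responses = []
    peak = -np.inf
    for v in velocities:
        v_pf = v * dt_f / px                      # px per frame
        offs = np.round(np.arange(n_cols) / v_pf).astype(int)
        # response over base-intercept frame n0
        lo, hi = -pad, n_frames + pad
        acc = np.zeros(hi - lo)
        cnt = np.zeros(hi - lo)
        for j in range(n_cols):
            o = offs[j]
            # img[n0 + o, j] contributes to acc[n0]
            n0_lo = max(lo, -o)
            n0_hi = min(hi, n_frames - o)
            if n0_hi <= n0_lo:
                continue
            acc[n0_lo - lo:n0_hi - lo] += img[n0_lo + o:n0_hi + o, j]
            cnt[n0_lo - lo:n0_hi - lo] += 1
        ok = cnt >= max(3, 0.5 * n_cols)
        resp = np.full(len(acc), -np.inf)
        resp[ok] = acc[ok] / cnt[ok]
        med_r = float(np.median(resp[ok])) if ok.any() else 0.0
        if ok.any():
            peak = max(peak, float(resp[ok].max()) - med_r)
        responses.append((float(v), lo, resp, med_r))

    # pass 2: candidate thresholding.  The floor proportional to the
    # brightest line rejects the weak ghost responses a bright line leaves
    # at wrong velocities; local maxima only, capped for speed.
    sigma_resp = sigma_px / np.sqrt(0.5 * n_cols)
    candidates = []
    ghost_floor = 0.08 * max(peak, 0.0)
    for v, lo, resp, med_r in responses:
        thr = med_r + max(threshold_k * sigma_resp, ghost_floor)
        above = np.nonzero(resp > thr)[0]
        for i in above:
            if resp[i] == -np.inf:
                continue
            left = resp[i - 1] if i > 0 else -np.inf
            right = resp[i + 1] if i < len(resp) - 1 else -np.inf
            if resp[i] >= left and resp[i] >= right:
                candidates.append(((resp[i] - med_r) / max(sigma_resp, 1e-9),
                                   resp[i], float(v), i + lo, thr))
    candidates.sort(key=lambda c: (-c[1], c[3]))
    candidates = candidates[:800]

    # pass 3: greedy matching pursuit.  Accept candidates brightest-first;
    # after each acceptance the accepted line's pixels are removed from a
    # residual image and every later candidate is re-scored against it, so
    # ghost responses (wrong-velocity shears through an accepted train) die
    # while genuinely distinct dim trains keep their support.
    band = max(1, int(round(min_separation / dt_f)) - 1)
    # one residual per direction: an anterograde acceptance must not erase
    # the pixels of retrograde lines that merely cross it (and vice versa)
    residual = {1: img.copy(), -1: img.copy()}
    col_idx = np.arange(n_cols)

    def line_frames(v, n0):
        v_pf = v * dt_f / px
        return n0 + np.round(col_idx / v_pf).astype(int)

    def rescore(v, n0):
        fr = line_frames(v, n0)
        ok = (fr >= 0) & (fr < n_frames)
        if ok.sum() < max(3, 0.5 * n_cols):
            return -np.inf
        return residual[int(np.sign(v))][fr[ok], col_idx[ok]].mean()

    accepted = []
    for q, r, v, n0, thr in candidates:
        r_now = rescore(v, n0)
        if r_now < thr:
            continue
        accepted.append((q, r_now, v, n0))
        fr = line_frames(v, n0)
        ok = (fr >= 0) & (fr < n_frames)
        res = residual[int(np.sign(v))]
        for j in col_idx[ok]:
            f = fr[j]
            res[max(0, f - band):f + band + 1, j] = 0.0

    trajectories = []
    T = (n_frames - 1) * dt_f
    L = pos[-1]
    for q, r, v, n0 in accepted:
        t_base = n0 * dt_f
        # the line x(t) = v (t - t_base) exists while 0 <= x <= L
        if v > 0:
            t_lo, t_hi = t_base, t_base + L / v
        else:
            t_lo, t_hi = t_base + L / v, t_base
        t_lo_c, t_hi_c = max(0.0, t_lo), min(T, t_hi)
        if t_hi_c <= t_lo_c:
            continue
        # mean intensity along the visible part of the line
        ts = np.arange(int(np.ceil(t_lo_c / dt_f)), int(t_hi_c / dt_f) + 1)
        xs = np.round(v * (ts * dt_f - t_base) / px).astype(int)
        keep = (xs >= 0) & (xs < n_cols) & kym.valid_frames[ts]
        inten = float(img[ts[keep], xs[keep]].mean()) if keep.any() else 0.0
        origin_x = min(L, max(0.0, v * (t_lo_c - t_base)))
        trajectories.append(Trajectory(
            origin_time=float(t_lo_c), origin_position=float(origin_x),
            velocity=float(v), duration=float(t_hi_c - t_lo_c),
            mean_intensity=inten, quality=float(q), base_time=float(t_base)))
    trajectories.sort(key=lambda tr: tr.origin_time)
    return TrajectorySet(trajectories, duration=T, structure=structure)


def traffic_stats(trajs: TrajectorySet, direction: str = "anterograde",
                  interval: float | None = None) -> dict:
    """Frequency (trains/s) and velocity moments for one direction."""
    if interval is None:
        interval = trajs.duration
    if interval <= 0:
        raise ValueError("interval must be > 0")
    sel = [tr for tr in trajs if tr.direction == direction]
    out = {"n": len(sel), "frequency": len(sel) / interval}
    if sel:
        v = np.array([abs(tr.velocity) for tr in sel])
        out["velocity_mean"] = float(v.mean())
        out["velocity_sd"] = float(v.std(ddof=1)) if len(v) > 1 else 0.0
    else:
        out["velocity_mean"] = None
        out["velocity_sd"] = None
        out["empty"] = True
    return out


@dataclass
class GapResult:
    gap: float | None
    first_train: float | None
    n_early_birds: int
    censored: bool = False
    prebleach_median: float = np.nan


def measure_gap(trajs: TrajectorySet, t_bleach: float,
                base_window: tuple[float, float] = (0.0, 2.0),
                intensity_floor: float = 0.3,
                t_margin: float = 0.15) -> GapResult:
    """Interval between the pool bleach and the first bright anterograde
    train departing from the base.  Post-bleach trains dimmer than
    ``intensity_floor`` x the prebleach median are 'early birds' (residual
    unbleached material) and are excluded from the gap call.  ``t_margin``
    skips trains whose frame-quantized origin straddles the bleach instant."""
    antero = [tr for tr in trajs if tr.direction == "anterograde"]
    pre = [tr.mean_intensity for tr in antero if tr.origin_time < t_bleach]
    if len(pre) < 2:
        raise ValueError("prebleach segment too short to estimate train intensity")
    med = float(np.median(pre))
    floor = intensity_floor * med
    post = [tr for tr in antero
            if tr.origin_time >= t_bleach + t_margin
            and base_window[0] <= tr.origin_position <= base_window[1]]
    post.sort(key=lambda tr: tr.origin_time)
    early = 0
    for tr in post:
        if tr.mean_intensity >= floor:
            return GapResult(gap=tr.origin_time - t_bleach,
                             first_train=tr.origin_time, n_early_birds=early,
                             prebleach_median=med)
        early += 1
    return GapResult(gap=None, first_train=None, n_early_birds=early,
                     censored=True, prebleach_median=med)


def departure_drops(trace: IntensityTrace, departure_times: np.ndarray,
                    w: float = 0.3, g: float = 0.1) -> np.ndarray:
    """Percent drop of the pool signal across each train departure:
    100 x (mean over [t-g-w, t-g] - mean over [t+g, t+g+w]) / pre-mean.
    Departures whose windows would overlap a neighbour's are skipped (nan)."""
    times = np.sort(np.asarray(departure_times, dtype=float))
    out = np.full(len(times), np.nan)
    skipped = 0
    for i, td in enumerate(times):
        if i > 0 and td - times[i - 1] < g + w:
            skipped += 1
            continue
        if i < len(times) - 1 and times[i + 1] - td < g + w:
            skipped += 1
            continue
        pre = trace.window_mean(td - g - w, td - g)
        post = trace.window_mean(td + g, td + g + w)
        if not np.isfinite(pre) or not np.isfinite(post) or pre <= 0:
            skipped += 1
            continue
        out[i] = 100.0 * (pre - post) / pre
    if skipped:
        warnings.warn(f"departure_drops: skipped {skipped} departures with "
                      "overlapping or unusable windows", stacklevel=2)
    return out


def train_intensity_ratio(exp: TrajectorySet, ctrl: TrajectorySet,
                          match_counts: bool = True) -> float:
    """Mean anterograde train intensity, experimental / control.

    With ``match_counts`` both sides are truncated to the brightest N
    trajectories (N = smaller count), which compares like with like when
    one flagellum's dimmer trains fall below the detection limit —
    otherwise the dimmed side would be represented only by its brightest
    trains and the ratio biased towards 1.
    """
    e = sorted((tr.mean_intensity for tr in exp
                if tr.direction == "anterograde"), reverse=True)
    c = sorted((tr.mean_intensity for tr in ctrl
                if tr.direction == "anterograde"), reverse=True)
    if len(e) < 3 or len(c) < 3:
        raise ValueError("need at least 3 anterograde trajectories per flagellum")
    if match_counts:
        n = min(len(e), len(c))
        e, c = e[:n], c[:n]
    return float(np.mean(e) / np.mean(c))


def gap_from_event_log(log: EventLog, t_bleach: float, protein: str,
                       floor: float = 0.3, t_margin: float = 0.15,
                       structure: str = "experimental") -> float | None:
    """Ground-truth gap oracle mirroring :func:`measure_gap`: the first
    departure after the bleach whose unbleached copy number of ``protein``
    reaches ``floor`` times the median unbleached copy number of prebleach
    trains (train brightness tracks unbleached copies, so this is the
    event-log analogue of the intensity criterion)."""
    pre = [d["composition"][protein][0]
           for d in log.of_kind("departure", structure)
           if d["t"] < t_bleach and d.get("composition", {}).get(protein)]
    if len(pre) < 2:
        return None
    med = float(np.median(pre))
    for d in log.of_kind("departure", structure):
        if d["t"] < t_bleach + t_margin:
            continue
        comp = d.get("composition", {}).get(protein)
        if not comp or sum(comp) == 0:
            continue
        if comp[0] >= floor * med:
            return d["t"] - t_bleach
    return None
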