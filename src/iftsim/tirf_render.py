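"""Virtual TIRF microscope: turn a :class:`~iftsim.queue_model.StateTrace`
into synthetic kymograms and time-lapse stacks.

Rendering is one-dimensional along a layout axis holding, in order, the
control flagellum, the control basal-body pool, the experimental pool and
the experimental flagellum.  Each train contributes a Gaussian line profile
centred at its position with amplitude proportional to its unbleached copy
number; each pool contributes a stationary Gaussian.  Expected photon counts
get Poisson shot noise and additive Gaussian read noise.  Duty-cycled FLIP
acquisition supports the two dialects seen in real recordings: frames taken
while the bleach laser is on are either dropped or saturated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .queue_model import (BleachProtocol, ConfigError, STRUCTURES, SimConfig,
                          StateTrace)

__all__ = ["StructureLayout", "RenderConfig", "Kymogram", "ROI",
           "default_layout", "render_kymogram", "render_frame_stack",
           "extract_kymogram_from_stack"]


@dataclass
class StructureLayout:
    """Pixel placement of one pool/flagellum pair along the layout axis."""
    pool_px: float
    flagellum_x0_px: float   # base of the flagellum
    direction: int = 1       # +1: tip towards larger pixel index


@dataclass
class ROI:
    """Pixel range on the layout axis, tagged with structure and channel."""
    x0: int
    x1: int            # exclusive
    structure: str = "experimental"
    channel: str = ""

    def slice(self) -> slice:
        return slice(self.x0, self.x1)


@dataclass
class RenderConfig:
    frame_rate: float = 10.0          # frames/s
    pixel_size: float = 0.16          # um/px
    psf_sigma: float = 1.3            # px
    photons_per_copy: float = 20.0
    background: float = 10.0          # counts/px
    read_noise_sd: float = 2.0        # counts
    shot_noise: bool = True
    layout: dict[str, StructureLayout] | None = None
    width: int = 0
    acquisition_dialect: str = "drop-frames"   # or "saturated-frames"
    saturation_level: float = 65535.0
    stack_height: int = 9

    def __post_init__(self) -> None:
        if self.acquisition_dialect not in ("drop-frames", "saturated-frames"):
            raise ConfigError(f"unknown dialect {self.acquisition_dialect!r}")

    @property
    def frame_dt(self) -> float:
        return 1.0 / self.frame_rate


def default_layout(sim_config: SimConfig, render_config: RenderConfig
                   ) -> tuple[dict[str, StructureLayout], int]:
    """Place both structures on one axis with a dark gap between them."""
    flag_px = int(np.ceil(sim_config.flagellum_length / render_config.pixel_size))
    layout = {
        "control": StructureLayout(pool_px=10.0, flagellum_x0_px=15.0),
        "experimental": StructureLayout(pool_px=float(flag_px + 35),
                                        flagellum_x0_px=float(flag_px + 40)),
    }
    width = 2 * flag_px + 45
    return layout, width


@dataclass
class Kymogram:
    """2-D intensity grid (time frames x layout pixels) for one channel."""

    data: np.ndarray                      # (n_frames, width) float counts
    frame_interval: float                 # s
    pixel_size: float                     # um/px
    channel: str
    layout: dict[str, StructureLayout]
    valid_frames: np.ndarray              # bool (n_frames,)
    flagellum_length: float               # um
    annotations: list = field(default_factory=list)   # bleach-event dicts
    saturation_level: float = 65535.0

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def pool_roi(self, structure: str = "experimental", half_width: int = 4) -> ROI:
        c = self.layout[structure].pool_px
        return ROI(int(round(c)) - half_width, int(round(c)) + half_width + 1,
                   structure, self.channel)

    def background_roi(self) -> ROI:
        """A dark stretch of the layout between the two structures."""
        ctrl = self.layout["control"]
        exp = self.layout["experimental"]
        flag_px = int(np.ceil(self.flagellum_length / self.pixel_size))
        lo = int(ctrl.flagellum_x0_px) + flag_px + 4
        hi = int(exp.pool_px) - 6
        if hi <= lo:
            lo, hi = 0, max(1, int(ctrl.pool_px) - 6)
        return ROI(lo, hi, "none", self.channel)

    def flagellum_view(self, structure: str = "experimental"
                       ) -> tuple[np.ndarray, np.ndarray]:
        """(sub-grid, positions-in-um-from-base) for one flagellum."""
        lay = self.layout[structure]
        flag_px = int(np.ceil(self.flagellum_length / self.pixel_size)) + 1
        x0 = int(round(lay.flagellum_x0_px))
        sub = self.data[:, x0:x0 + flag_px]
        pos = np.arange(sub.shape[1]) * self.pixel_size
        return sub, pos


def _gaussian_kernel(sigma: float) -> tuple[np.ndarray, int]:
    half = max(1, int(np.ceil(4 * sigma)))
    xs = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (xs / sigma) ** 2) / (sigma * np.sqrt(2 * np.pi))
    return k, half


def _expected_signal(trace: StateTrace, rcfg: RenderConfig, channel: str
                     ) -> np.ndarray:
    """Noise-free expected photon image above background, (n_frames, width)."""
    cfg = trace.config
    layout, width = (rcfg.layout, rcfg.width)
    if layout is None:
        layout, width = default_layout(cfg, rcfg)
    n_frames = len(trace.times)
    img = np.zeros((n_frames, width))
    kern, half = _gaussian_kernel(rcfg.psf_sigma)
    p_idx = [i for i, p in enumerate(cfg.proteins) if p.channel == channel]
    if not p_idx:
        raise ConfigError(f"no protein renders into channel {channel!r}")

    def add_spot(frame_rows, px, amp):
        c = int(round(px))
        lo, hi = c - half, c + half + 1
        klo, khi = 0, len(kern)
        if lo < 0:
            klo, lo = -lo, 0
        if hi > width:
            khi, hi = len(kern) - (hi - width), width
        if hi > lo:
            frame_rows[lo:hi] += amp * kern[klo:khi]

    ppc = rcfg.photons_per_copy
    for si, s in enumerate(STRUCTURES):
        lay = layout[s]
        pool_u = trace.pool[:, si][:, p_idx].sum(axis=2)[:, :, 0].sum(axis=1)
        inc_u = trace.incorporated[:, si][:, p_idx, 0].sum(axis=1)
        tip_px = lay.flagellum_x0_px + lay.direction * cfg.flagellum_length / rcfg.pixel_size
        for f in range(n_frames):
            if pool_u[f]:
                add_spot(img[f], lay.pool_px, pool_u[f] * ppc)
            if inc_u[f]:
                add_spot(img[f], tip_px, inc_u[f] * ppc)
        for tr in trace.train_frames(s):
            u = tr["u"][:, p_idx].sum(axis=1)
            px = lay.flagellum_x0_px + lay.direction * tr["positions"] / rcfg.pixel_size
            for i, f in enumerate(tr["frames"]):
                if u[i]:
                    add_spot(img[f], px[i], u[i] * ppc)
    return img


def _laser_on_frames(protocol: BleachProtocol | None, n_frames: int,
                     frame_dt: float) -> np.ndarray:
    """True for frames whose exposure overlaps a duty-cycle laser-on window."""
    on = np.zeros(n_frames, dtype=bool)
    if not protocol:
        return on
    for ev in protocol:
        if ev.mode != "duty":
            continue
        for (a, b) in ev.on_windows(frame_dt / 10):
            f0 = max(0, int(np.floor(a / frame_dt)))
            f1 = min(n_frames - 1, int(np.floor(b / frame_dt)))
            on[f0:f1 + 1] = True
    return on


def render_kymogram(trace: StateTrace, rcfg: RenderConfig,
                    rng: np.random.Generator,
                    protocol: BleachProtocol | None = None,
                    channels: list[str] | None = None) -> dict[str, Kymogram]:
    """Render one kymogram per channel (experimental + control share a grid)."""
    cfg = trace.config
    if abs(rcfg.frame_dt - trace.frame_dt) > 1e-9:
        raise ConfigError("render frame interval must match trace snapshot interval")
    layout, width = (rcfg.layout, rcfg.width)
    if layout is None:
        layout, width = default_layout(cfg, rcfg)
        rcfg = replace(rcfg, layout=layout, width=width)
    if channels is None:
        channels = sorted({p.channel for p in cfg.proteins})
    n_frames = len(trace.times)
    on_frames = _laser_on_frames(protocol, n_frames, rcfg.frame_dt)
    annotations = []
    if protocol:
        for ev in protocol:
            annotations.append({"t_start": ev.t_start, "t_stop": ev.t_stop,
                                "region": ev.region, "mode": ev.mode,
                                "efficiency": ev.efficiency})
    out = {}
    for channel in channels:
        expected = _expected_signal(trace, rcfg, channel) + rcfg.background
        if rcfg.shot_noise:
            data = rng.poisson(expected).astype(float)
        else:
            data = expected.copy()
        if rcfg.read_noise_sd > 0:
            data += rng.normal(0.0, rcfg.read_noise_sd, size=data.shape)
        np.clip(data, 0.0, None, out=data)
        valid = ~on_frames
        if on_frames.any():
            if rcfg.acquisition_dialect == "drop-frames":
                data[on_frames] = 0.0
            else:
                data[on_frames] = rcfg.saturation_level
        out[channel] = Kymogram(
            data=data, frame_interval=rcfg.frame_dt, pixel_size=rcfg.pixel_size,
            channel=channel, layout=layout, valid_frames=valid,
            flagellum_length=cfg.flagellum_length, annotations=annotations,
            saturation_level=rcfg.saturation_level)
    return out


def render_frame_stack(trace: StateTrace, rcfg: RenderConfig,
                       rng: np.random.Generator,
                       protocol: BleachProtocol | None = None,
                       channel: str | None = None
                       ) -> tuple[np.ndarray, Kymogram]:
    """Time-lapse 2-D frames whose centre line-scan equals the direct
    kymogram rendered with the same seed.

    Returns ``(stack, kymogram)`` with stack shape (n_kept_frames, height,
    width); under the drop-frames dialect the laser-on frames are absent
    from the stack.
    """
    cfg = trace.config
    if channel is None:
        chans = sorted({p.channel for p in cfg.proteins})
        if len(chans) != 1:
            raise ConfigError("specify a channel for multi-channel stacks")
        channel = chans[0]
    kyms = render_kymogram(trace, rcfg, rng, protocol=protocol, channels=[channel])
    kym = kyms[channel]
    h = rcfg.stack_height
    mid = h // 2
    expected = _expected_signal(trace, kym_rcfg(rcfg, kym), channel)
    frames_kept = (np.nonzero(kym.valid_frames)[0]
                   if rcfg.acquisition_dialect == "drop-frames" and
                   (~kym.valid_frames).any() else np.arange(kym.n_frames))
    stack = np.zeros((len(frames_kept), h, kym.data.shape[1]))
    for out_i, f in enumerate(frames_kept):
        for row in range(h):
            dy = row - mid
            if dy == 0:
                stack[out_i, row] = kym.data[f]
                continue
            e = expected[f] * np.exp(-0.5 * (dy / rcfg.psf_sigma) ** 2) + rcfg.background
            line = rng.poisson(e).astype(float) if rcfg.shot_noise else e.copy()
            if rcfg.read_noise_sd > 0:
                line += rng.normal(0.0, rcfg.read_noise_sd, size=line.shape)
            stack[out_i, row] = np.clip(line, 0.0, None)
    if rcfg.acquisition_dialect == "saturated-frames":
        stack[~kym.valid_frames[frames_kept]] = rcfg.saturation_level
    return stack, kym


def kym_rcfg(rcfg: RenderConfig, kym: Kymogram) -> RenderConfig:
    if rcfg.layout is None:
        return replace(rcfg, layout=kym.layout, width=kym.data.shape[1])
    return rcfg


def extract_kymogram_from_stack(stack: np.ndarray, row: int, width: int = 1,
                                mode: str = "max",
                                template: Kymogram | None = None) -> np.ndarray | Kymogram:
    """Line-scan a stack along the layout axis: per frame, take the max (or
    mean) across a band of ``width`` rows centred at ``row``."""
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, height, width)")
    half = (width - 1) // 2
    lo, hi = row - half, row + half + 1
    if lo < 0 or hi > stack.shape[1]:
        raise ValueError("band outside stack")
    band = stack[:, lo:hi, :]
    if mode == "max":
        data = band.max(axis=1)
    elif mode == "mean":
        data = band.mean(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if template is None:
        return data
    return replace(template, data=data,
                   valid_frames=np.ones(data.shape[0], dtype=bool))
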