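"""Stochastic queue model of IFT train assembly at the ciliary base.

Intraflagellar transport (IFT) proteins cycle through five stations: the
cell-body supply, the basal-body pool (where nascent trains are assembled in
an ordered queue), anterograde transit to the ciliary tip, retrograde transit
back to the base, and either direct reuse at the base (semi-open recycling,
IFT-B) or release into the cell body (open system, IFT-A and motors).  Every
copy of every protein carries a photobleach state, so the simulator is the
ground-truth generator for virtual FRAP / FLIP photobleaching experiments.

Copies are tracked as aggregate (compartment, protein, bleach-state) counts
except on trains, which carry their own per-protein counts.  All event times
are snapped to an integer tick grid of ``dt`` seconds, which makes runs
byte-for-byte reproducible for a given (config, protocol, seed).
"""

from __future__ import annotations

import heapq
import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfigError",
    "ProtocolError",
    "RegistryError",
    "ProteinSpec",
    "SimConfig",
    "TrainRecord",
    "BleachEvent",
    "BleachProtocol",
    "EventLog",
    "StateTrace",
    "PROTEIN_REGISTRY",
    "build_default_config",
    "sample_departure_times",
    "recruitment_time",
    "apply_bleach",
    "route_returning_train",
    "run_simulation",
    "pool_content",
    "pool_pulse",
    "tip_flip",
    "whole_flagellum_bleach",
    "axoneme_prebleach",
]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class ProtocolError(ValueError):
    """Invalid photobleaching protocol."""


class RegistryError(KeyError):
    """Unknown protein name requested from the default registry."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ProteinSpec:
    """Per-protein kinetic, recycling and rendering parameters.

    ``recruitment_lead`` is the mean time between recruitment of this protein
    into a nascent train and that train's departure — the protein's position
    in the sequential assembly programme.  ``tip_release_prob`` is the
    fraction of a train's copies that do not return to the base by retrograde
    IFT (dissociation / incorporation / undetected return at the tip).
    ``recycle_enabled`` proteins returning on retrograde trains dwell in a
    basal recycling compartment for ``residence_mean`` seconds and are then
    reused in nascent trains with probability ``reuse_prob``, otherwise
    released to the cell body.
    """

    name: str
    complex_class: str = "IFT-B1"
    recruitment_lead: float = 5.0
    lead_sd: float = 1.5
    copies_per_train: int = 40
    carry_prob: float = 1.0
    tip_release_prob: float = 0.0
    recycle_enabled: bool = False
    residence_mean: float = 0.0
    residence_sd: float = 0.0
    reuse_prob: float = 0.0
    standing_extra: float = 1.0
    total_cell_copies: int = 8000
    channel: str = ""

    _CLASSES = ("IFT-A", "IFT-B1", "IFT-B2", "motor-kinesin", "motor-dynein", "cargo")

    def __post_init__(self) -> None:
        if not self.channel:
            self.channel = self.name
        self.validate()

    def validate(self) -> None:
        if self.complex_class not in self._CLASSES:
            raise ConfigError(f"{self.name}: unknown complex_class {self.complex_class!r}")
        for key in ("carry_prob", "tip_release_prob", "reuse_prob"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{self.name}.{key} = {v} outside [0, 1]")
        if self.recruitment_lead < 0:
            raise ConfigError(f"{self.name}.recruitment_lead must be >= 0")
        if self.copies_per_train < 1:
            raise ConfigError(f"{self.name}.copies_per_train must be >= 1")
        if self.recycle_enabled and self.residence_mean < 0:
            raise ConfigError(f"{self.name}.residence_mean must be >= 0")
        if self.standing_extra < 0 or self.total_cell_copies < 1:
            raise ConfigError(f"{self.name}: invalid pool/supply sizes")


#: Default per-protein calibration.  Leads follow the recruitment order
#: IFT-A ~ IFT-B2 > IFT-B1 > kinesin > dynein > tubulin cargo; recycling
#: parameters of the IFT-B recycling class are the flux-balance solution that
#: jointly reproduces the printed per-departure pool drops, the tip-FLIP pool
#: plateau, the post-FLIP train-intensity deficit and the retrograde-derived
#: pool fraction (see docs/methods.md).
PROTEIN_REGISTRY: dict[str, ProteinSpec] = {
    s.name: s
    for s in [
        ProteinSpec("IFT140", "IFT-A", recruitment_lead=7.0, lead_sd=1.5,
                    standing_extra=2.0, channel="red"),
        ProteinSpec("IFT43", "IFT-A", recruitment_lead=7.0, lead_sd=1.5,
                    standing_extra=2.0),
        ProteinSpec("IFT54", "IFT-B2", recruitment_lead=6.5, lead_sd=1.5,
                    tip_release_prob=0.55, recycle_enabled=True,
                    residence_mean=6.0, residence_sd=1.0, reuse_prob=0.9,
                    standing_extra=1.0),
        ProteinSpec("IFT20", "IFT-B2", recruitment_lead=6.5, lead_sd=1.5,
                    tip_release_prob=0.55, recycle_enabled=True,
                    residence_mean=6.0, residence_sd=1.0, reuse_prob=0.9,
                    standing_extra=1.0),
        ProteinSpec("IFT46", "IFT-B1", recruitment_lead=5.5, lead_sd=1.5,
                    tip_release_prob=0.55, recycle_enabled=True,
                    residence_mean=6.0, residence_sd=1.0, reuse_prob=0.9,
                    standing_extra=1.0),
        ProteinSpec("IFT27", "IFT-B1", recruitment_lead=5.5, lead_sd=1.5,
                    standing_extra=1.5),
        ProteinSpec("KAP", "motor-kinesin", recruitment_lead=3.0, lead_sd=1.2,
                    tip_release_prob=0.9, standing_extra=2.5, channel="green"),
        ProteinSpec("D1bLIC", "motor-dynein", recruitment_lead=2.5, lead_sd=1.0,
                    standing_extra=1.5),
        ProteinSpec("tubulin", "cargo", recruitment_lead=0.5, lead_sd=0.5,
                    carry_prob=0.45, tip_release_prob=1.0, standing_extra=0.5),
    ]
}


@dataclass
class SimConfig:
    """Whole-cell simulation configuration (two flagella sharing one cell body)."""

    flagellum_length: float = 12.0      # um
    v_antero: float = 2.0               # um/s
    v_retro: float = 3.0                # um/s
    turnaround: float = 0.9             # s dwell at the tip
    departure_rate: float = 1.0         # trains/s out of each pool
    departure_cv: float = 0.3           # CV of inter-departure intervals
    n_slots: int = 9                    # assembly-queue capacity
    bright_dim_ratio: float = 0.5       # size factor of dim trains
    dim_fraction: float = 0.5
    imaging_bleach_rate: float = 0.003  # 1/s, copies in the evanescent field
    duration: float = 60.0              # s of recorded simulation
    dt: float = 0.01                    # s, event-time quantum
    seed: int = 0
    proteins: list[ProteinSpec] = field(default_factory=list)
    n_structures: int = 2

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.v_antero, self.v_retro) <= 0:
            raise ConfigError("velocities must be > 0")
        if self.departure_rate <= 0:
            raise ConfigError("departure_rate must be > 0")
        if self.departure_cv < 0:
            raise ConfigError("departure_cv must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ConfigError("dt and duration must be > 0")
        if self.n_structures != 2:
            raise ConfigError("exactly two structures (experimental + control) supported")
        if not 0.0 < self.bright_dim_ratio <= 1.0 or not 0.0 <= self.dim_fraction <= 1.0:
            raise ConfigError("invalid bright/dim train parameters")
        if self.proteins:
            max_lead = max(p.recruitment_lead for p in self.proteins)
            if self.departure_rate * max_lead > self.n_slots:
                raise ConfigError(
                    "assembly queue overflow: departure_rate x max recruitment_lead "
                    f"= {self.departure_rate * max_lead:.2f} exceeds n_slots = "
                    f"{self.n_slots}; increase n_slots or lower the rate/lead"
                )

    @property
    def transit_time(self) -> float:
        """Base -> tip -> base travel time of one train."""
        return (self.flagellum_length / self.v_antero + self.turnaround
                + self.flagellum_length / self.v_retro)

    def protein(self, name: str) -> ProteinSpec:
        for p in self.proteins:
            if p.name == name:
                return p
        raise RegistryError(name)


def build_default_config(protein_names: Sequence[str], **overrides) -> SimConfig:
    """Return the calibrated default configuration for the named proteins.

    Names must come from :data:`PROTEIN_REGISTRY`.  Keyword overrides are
    applied to the :class:`SimConfig` fields.
    """
    specs = []
    for name in protein_names:
        if name not in PROTEIN_REGISTRY:
            raise RegistryError(
                f"unknown protein {name!r}; known: {sorted(PROTEIN_REGISTRY)}")
        specs.append(replace(PROTEIN_REGISTRY[name]))
    return SimConfig(proteins=specs, **overrides)


STRUCTURES = ("experimental", "control")

PHASES = ("assembling", "anterograde", "turnaround", "retrograde", "returned")


@dataclass
class TrainRecord:
    """One IFT train: schedule, size, per-protein composition and geometry."""

    id: int
    structure: str
    departure_time: float
    tip_arrival: float
    base_return: float
    size_factor: float = 1.0
    # protein name -> [unbleached, bleached] counts (on-train only)
    composition: dict[str, np.ndarray] = field(default_factory=dict)
    recruit_times: dict[str, float] = field(default_factory=dict)
    config: SimConfig | None = None

    def phase(self, t: float) -> str:
        if t < self.departure_time:
            return "assembling"
        if t < self.tip_arrival:
            return "anterograde"
        c = self.config
        turn = c.turnaround if c is not None else 0.0
        if t < self.tip_arrival + turn:
            return "turnaround"
        if t < self.base_return:
            return "retrograde"
        return "returned"

    def position(self, t: float) -> float:
        """Position along the flagellum in um (0 at base) at time ``t``."""
        c = self.config
        if c is None:
            raise ValueError("train has no config attached")
        ph = self.phase(t)
        if ph == "assembling":
            return 0.0
        if ph == "anterograde":
            return min(c.flagellum_length, c.v_antero * (t - self.departure_time))
        if ph == "turnaround":
            return c.flagellum_length
        if ph == "retrograde":
            x = c.flagellum_length - c.v_retro * (t - self.tip_arrival - c.turnaround)
            return max(0.0, x)
        return 0.0


BLEACH_REGIONS = (
    "pool-exp", "pool-both", "tip-window", "whole-flagellum-exp", "axoneme-prebleach",
)


@dataclass
class BleachEvent:
    """One timed laser event of a photobleaching protocol."""

    t_start: float
    region: str
    mode: str = "pulse"                  # "pulse" | "duty"
    efficiency: float = 1.0
    t_stop: float | None = None
    duty_on: float | None = None         # s laser on per cycle
    duty_off: float | None = None        # s laser off per cycle
    window: tuple[float, float] | None = None   # um, for tip-window
    channels: tuple[str, ...] | None = None     # None = all channels

    def __post_init__(self) -> None:
        if self.region not in BLEACH_REGIONS:
            if "control" in self.region or self.region in ("pool-ctrl", "whole-flagellum-ctrl"):
                raise ProtocolError("bleach regions must target the experimental "
                                    "structure; the control must stay untouched")
            raise ProtocolError(f"unknown bleach region {self.region!r}")
        if not 0.0 <= self.efficiency <= 1.0:
            raise ProtocolError("efficiency outside [0, 1]")
        if self.mode == "duty":
            if self.duty_on is None or self.duty_off is None or self.t_stop is None:
                raise ProtocolError("duty mode requires duty_on, duty_off and t_stop")
            if min(self.duty_on, self.duty_off) <= 0:
                raise ProtocolError("duty_on/duty_off must be > 0")
        elif self.mode == "pulse":
            if self.duty_on is not None or self.duty_off is not None:
                raise ProtocolError("duty fields only valid in duty mode")
        else:
            raise ProtocolError(f"unknown bleach mode {self.mode!r}")
        if self.region == "tip-window" and self.window is None:
            raise ProtocolError("tip-window region requires a [x0, x1] window")

    def on_windows(self, dt: float) -> list[tuple[float, float]]:
        """Laser-on intervals of a duty-cycled event, snapped to ``dt``."""
        if self.mode == "pulse":
            return [(self.t_start, self.t_start)]
        out = []
        t = self.t_start
        while t < self.t_stop:
            a = round(t / dt) * dt
            b = round(min(t + self.duty_on, self.t_stop) / dt) * dt
            if b > a:
                out.append((a, b))
            t += self.duty_on + self.duty_off
        return out


class BleachProtocol(list):
    """A time-ordered list of :class:`BleachEvent`."""

    def __init__(self, events: Iterable[BleachEvent] = ()):
        super().__init__(sorted(events, key=lambda e: e.t_start))


def pool_pulse(t: float, efficiency: float = 0.95, region: str = "pool-exp",
               channels=None) -> BleachEvent:
    """Brief focused-beam pulse on the experimental basal-body pool (FRAP/gap)."""
    return BleachEvent(t_start=t, region=region, mode="pulse",
                       efficiency=efficiency, channels=channels)


def tip_flip(t_start: float, t_stop: float, window: tuple[float, float] = (9.0, 11.5),
             duty_on: float = 0.15, duty_off: float = 0.65,
             efficiency: float = 0.99, channels=None) -> BleachEvent:
    """Duty-cycled FLIP beam parked over a window near the tip of the
    experimental flagellum (default duty 150 ms on / 650 ms off)."""
    return BleachEvent(t_start=t_start, t_stop=t_stop, region="tip-window",
                       mode="duty", duty_on=duty_on, duty_off=duty_off,
                       efficiency=efficiency, window=window, channels=channels)


def whole_flagellum_bleach(t: float, efficiency: float = 0.98, channels=None) -> BleachEvent:
    """Single bleach of the entire experimental flagellum (pool untouched)."""
    return BleachEvent(t_start=t, region="whole-flagellum-exp", mode="pulse",
                       efficiency=efficiency, channels=channels)


def axoneme_prebleach(t: float = 0.0, efficiency: float = 1.0, channels=None) -> BleachEvent:
    """Bleach tubulin already incorporated into the experimental axoneme
    (plus anything currently in transit), emulating the pre-bleach step of
    the tubulin loading-gap assay."""
    return BleachEvent(t_start=t, region="axoneme-prebleach", mode="pulse",
                       efficiency=efficiency, channels=channels)


# ---------------------------------------------------------------------------
# standalone operations
# ---------------------------------------------------------------------------

def sample_departure_times(config: SimConfig, rng: np.random.Generator,
                           t_min: float = 0.0, t_max: float | None = None) -> np.ndarray:
    """Departure times of a renewal process with mean interval
    ``1/departure_rate`` and coefficient of variation ``departure_cv``,
    snapped to the dt grid.  ``cv == 0`` gives perfectly regular release."""
    if config.departure_rate <= 0:
        raise ConfigError("departure_rate must be > 0")
    if t_max is None:
        t_max = config.duration
    span = t_max - t_min
    if span <= 0:
        return np.array([])
    mean = 1.0 / config.departure_rate
    n_guess = int(span / mean * 1.5 + 30)
    times = []
    t = t_min
    done = False
    while not done:
        if config.departure_cv == 0:
            intervals = np.full(n_guess, mean)
        else:
            shape = 1.0 / config.departure_cv**2
            intervals = rng.gamma(shape, mean / shape, size=n_guess)
        for iv in intervals:
            t += iv
            if t > t_max + 1e-9:
                done = True
                break
            times.append(t)
    return np.round(np.asarray(times) / config.dt) * config.dt


def recruitment_time(departure_t: float, spec: ProteinSpec,
                     rng: np.random.Generator) -> float:
    """Time at which this protein's copies join the nascent train departing at
    ``departure_t``: the departure minus a normal lead truncated at zero,
    clamped so recruitment never precedes t = 0 of the schedule origin."""
    lead = max(0.0, rng.normal(spec.recruitment_lead, spec.lead_sd))
    return max(0.0, departure_t - lead)


def _bleach_counts(counts: np.ndarray, efficiency: float,
                   rng: np.random.Generator) -> int:
    """Convert unbleached -> bleached in-place with per-copy probability
    ``efficiency``; returns the number of copies converted."""
    u = int(counts[0])
    if u == 0 or efficiency <= 0.0:
        return 0
    k = u if efficiency >= 1.0 else int(rng.binomial(u, efficiency))
    counts[0] -= k
    counts[1] += k
    return k


# ---------------------------------------------------------------------------
# event log and state trace
# ---------------------------------------------------------------------------

class EventLog:
    """Time-ordered ground-truth record of simulation events."""

    def __init__(self) -> None:
        self.records: list[dict] = []

    def add(self, t: float, kind: str, **payload) -> None:
        rec = {"t": round(t, 6), "kind": kind}
        rec.update(payload)
        self.records.append(rec)

    def of_kind(self, kind: str, structure: str | None = None) -> list[dict]:
        out = [r for r in self.records if r["kind"] == kind]
        if structure is not None:
            out = [r for r in out if r.get("structure") == structure]
        return out

    def departures(self, structure: str = "experimental") -> np.ndarray:
        return np.array([r["t"] for r in self.of_kind("departure", structure)])

    def to_jsonl(self) -> str:
        return "\n".join(json.dumps(r, sort_keys=True) for r in self.records) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "EventLog":
        log = cls()
        for line in text.splitlines():
            if line.strip():
                log.records.append(json.loads(line))
        return log


POOL_COMPARTMENTS = ("nascent", "recycling", "reuse", "standing")


class StateTrace:
    """Per-frame snapshots of every compartment plus per-train tracks.

    Arrays: ``pool[frame, structure, protein, compartment, state]``,
    ``cell_body[frame, protein, state]``, ``incorporated[frame, structure,
    protein, state]`` with state 0 = unbleached, 1 = bleached.  Train tracks
    hold per-frame position and per-protein unbleached/bleached counts.
    """

    def __init__(self, config: SimConfig, frame_dt: float) -> None:
        self.config = config
        self.frame_dt = frame_dt
        self.protein_names = [p.name for p in config.proteins]
        n_frames = int(round(config.duration / frame_dt)) + 1
        n_p = len(self.protein_names)
        self.times = np.arange(n_frames) * frame_dt
        self.pool = np.zeros((n_frames, 2, n_p, len(POOL_COMPARTMENTS), 2), dtype=np.int64)
        self.cell_body = np.zeros((n_frames, n_p, 2), dtype=np.int64)
        self.incorporated = np.zeros((n_frames, 2, n_p, 2), dtype=np.int64)
        # train id -> dict(structure, frames [], positions [], u (n,p), b (n,p))
        self.trains: dict[int, dict] = {}

    # -- indexing helpers ---------------------------------------------------
    def protein_index(self, protein: str) -> int:
        try:
            return self.protein_names.index(protein)
        except ValueError:
            raise RegistryError(protein) from None

    def frame_index(self, t: float) -> int:
        i = int(round(t / self.frame_dt))
        if not 0 <= i < len(self.times):
            raise ValueError(f"t={t} outside trace")
        return i

    # -- queries ------------------------------------------------------------
    def pool_series(self, protein: str, structure: str = "experimental") -> np.ndarray:
        """(n_frames, 2) unbleached/bleached totals over all pool compartments."""
        s = STRUCTURES.index(structure)
        p = self.protein_index(protein)
        return self.pool[:, s, p].sum(axis=1)

    def train_frames(self, structure: str | None = None) -> list[dict]:
        out = list(self.trains.values())
        if structure is not None:
            out = [t for t in out if t["structure"] == structure]
        return out

    def total_per_frame(self, protein: str) -> np.ndarray:
        """(n_frames, 2) whole-cell totals; constant under conservation."""
        p = self.protein_index(protein)
        tot = (self.cell_body[:, p] + self.pool[:, :, p].sum(axis=(1, 2))
               + self.incorporated[:, :, p].sum(axis=1))
        for tr in self.trains.values():
            f = tr["frames"]
            tot[f, 0] += tr["u"][:, p]
            tot[f, 1] += tr["b"][:, p]
        return tot

    # -- serialization ------------------------------------------------------
    def to_frame(self):
        """Long-format DataFrame (frame, time, structure, compartment,
        protein, position_um, unbleached, bleached)."""
        import pandas as pd

        rows = []
        for f, t in enumerate(self.times):
            for p, name in enumerate(self.protein_names):
                rows.append((f, t, "", "cell_body", name, np.nan,
                             self.cell_body[f, p, 0], self.cell_body[f, p, 1]))
                for s, sname in enumerate(STRUCTURES):
                    for c, cname in enumerate(POOL_COMPARTMENTS):
                        rows.append((f, t, sname, cname, name, np.nan,
                                     self.pool[f, s, p, c, 0], self.pool[f, s, p, c, 1]))
                    rows.append((f, t, sname, "incorporated", name, np.nan,
                                 self.incorporated[f, s, p, 0], self.incorporated[f, s, p, 1]))
        for tid, tr in sorted(self.trains.items()):
            for i, f in enumerate(tr["frames"]):
                for p, name in enumerate(self.protein_names):
                    rows.append((int(f), self.times[f], tr["structure"], f"train:{tid}",
                                 name, tr["positions"][i], tr["u"][i, p], tr["b"][i, p]))
        return pd.DataFrame(rows, columns=[
            "frame", "time_s", "structure", "compartment", "protein",
            "position_um", "unbleached", "bleached"])


def pool_content(trace: StateTrace, protein: str, t: float,
                 structure: str = "experimental") -> tuple[int, int]:
    """(unbleached, bleached) copies of ``protein`` in the basal-body pool
    (nascent + recycling + reuse + standing compartments) at time ``t``."""
    f = trace.frame_index(t)
    s = STRUCTURES.index(structure)
    p = trace.protein_index(protein)
    u, b = trace.pool[f, s, p].sum(axis=0)
    return int(u), int(b)


# ---------------------------------------------------------------------------
# the simulator
# ---------------------------------------------------------------------------

class SimState:
    """Mutable whole-cell state; exposed so bleach events can be unit-tested
    on hand-built states."""

    def __init__(self, config: SimConfig, rng_pool: dict[str, np.random.Generator]):
        self.config = config
        self.rng = rng_pool
        n_p = len(config.proteins)
        self.n_p = n_p
        self.cell_body = np.zeros((n_p, 2), dtype=np.int64)
        self.standing = {s: np.zeros((n_p, 2), dtype=np.int64) for s in STRUCTURES}
        self.reuse = {s: np.zeros((n_p, 2), dtype=np.int64) for s in STRUCTURES}
        self.recycling_batches = {s: [] for s in STRUCTURES}  # [t_release, p_idx, counts]
        self.incorporated = {s: np.zeros((n_p, 2), dtype=np.int64) for s in STRUCTURES}
        self.nascent = {s: {} for s in STRUCTURES}   # id -> TrainRecord
        self.inflag = {s: {} for s in STRUCTURES}
        for p, spec in enumerate(config.proteins):
            st = int(round(spec.standing_extra * spec.copies_per_train))
            for s in STRUCTURES:
                self.standing[s][p, 0] = st
            self.cell_body[p, 0] = max(0, spec.total_cell_copies - 2 * st)

    def recycling_totals(self, structure: str) -> np.ndarray:
        out = np.zeros((self.n_p, 2), dtype=np.int64)
        for _, p, counts in self.recycling_batches[structure]:
            out[p] += counts
        return out

    def _pool_count_arrays(self, structure: str):
        """All count arrays that sit inside one basal-body pool."""
        arrays = [self.standing[structure], self.reuse[structure]]
        per_protein = []
        for _, p, counts in self.recycling_batches[structure]:
            per_protein.append((p, counts))
        for tr in self.nascent[structure].values():
            for name, counts in tr.composition.items():
                per_protein.append((self._p_index(name), counts))
        return arrays, per_protein

    def _p_index(self, name: str) -> int:
        for i, spec in enumerate(self.config.proteins):
            if spec.name == name:
                return i
        raise RegistryError(name)

    def _channel_mask(self, channels) -> np.ndarray:
        if channels is None:
            return np.ones(self.n_p, dtype=bool)
        return np.array([p.channel in channels for p in self.config.proteins])


def apply_bleach(state: SimState, event: BleachEvent, t: float | None = None,
                 rng: np.random.Generator | None = None) -> int:
    """Apply one instantaneous bleach event to ``state``; returns the number
    of copies converted.  Duty-cycled tip-window exposure of moving trains is
    handled by the simulation loop, not here."""
    if rng is None:
        rng = state.rng.get("bleach", np.random.default_rng(0))
    t = event.t_start if t is None else t
    mask = state._channel_mask(event.channels)
    converted = 0
    cfg = state.config

    def bleach_array(arr: np.ndarray) -> int:
        n = 0
        for p in range(state.n_p):
            if mask[p]:
                n += _bleach_counts(arr[p], event.efficiency, rng)
        return n

    if event.region in ("pool-exp", "pool-both"):
        targets = STRUCTURES if event.region == "pool-both" else ("experimental",)
        for s in targets:
            arrays, per_protein = state._pool_count_arrays(s)
            for arr in arrays:
                converted += bleach_array(arr)
            for p, counts in per_protein:
                if mask[p]:
                    converted += _bleach_counts(counts, event.efficiency, rng)
    elif event.region in ("whole-flagellum-exp", "axoneme-prebleach"):
        for tr in state.inflag["experimental"].values():
            if 0.0 <= tr.position(t) <= cfg.flagellum_length:
                for name, counts in tr.composition.items():
                    if mask[state._p_index(name)]:
                        converted += _bleach_counts(counts, event.efficiency, rng)
        converted += bleach_array(state.incorporated["experimental"])
    elif event.region == "tip-window":
        x0, x1 = event.window
        for tr in state.inflag["experimental"].values():
            if x0 <= tr.position(t) <= x1:
                for name, counts in tr.composition.items():
                    if mask[state._p_index(name)]:
                        converted += _bleach_counts(counts, event.efficiency, rng)
    else:  # pragma: no cover - guarded by BleachEvent validation
        raise ProtocolError(event.region)
    return converted


def route_returning_train(train: TrainRecord, specs: Sequence[ProteinSpec],
                          rng: np.random.Generator,
                          dt: float = 0.01) -> list[dict]:
    """Route the copies of a train that has reached base position 0.

    Recycle-enabled proteins enter the basal recycling compartment with a
    truncated-normal residence, after which each copy is reused in a nascent
    train with ``reuse_prob`` or released to the cell body; everything else
    disperses to the cell body immediately.  Returns one fate record per
    protein: ``{"protein", "fate", "counts", "release_delay"}``.
    """
    fates = []
    by_name = {s.name: s for s in specs}
    for name, counts in train.composition.items():
        spec = by_name[name]
        n = int(counts.sum())
        if n == 0:
            continue
        if spec.recycle_enabled:
            delay = max(0.0, rng.normal(spec.residence_mean, spec.residence_sd))
            delay = round(delay / dt) * dt
            fates.append({"protein": name, "fate": "recycling",
                          "counts": counts.copy(), "release_delay": delay})
        else:
            fates.append({"protein": name, "fate": "cell_body",
                          "counts": counts.copy(), "release_delay": 0.0})
    return fates


# event priorities at equal tick
_PRIO = {"bleach": 0, "flip": 1, "recycle_exit": 2, "recruit": 3,
         "depart": 4, "tip": 5, "return": 6, "imaging": 7, "snapshot": 8}


def _window_exposure(train: TrainRecord, a: float, b: float,
                     x0: float, x1: float) -> float:
    """Seconds during [a, b] that the train position lies inside [x0, x1]."""
    c = train.config
    total = 0.0
    segs = [
        (train.departure_time, train.tip_arrival,
         lambda t: c.v_antero * (t - train.departure_time)),
        (train.tip_arrival, train.tip_arrival + c.turnaround,
         lambda t: c.flagellum_length),
        (train.tip_arrival + c.turnaround, train.base_return,
         lambda t: c.flagellum_length - c.v_retro * (t - train.tip_arrival - c.turnaround)),
    ]
    for (t0, t1, _) in [segs[1]]:
        lo, hi = max(a, t0), min(b, t1)
        if hi > lo and x0 <= c.flagellum_length <= x1:
            total += hi - lo
    # anterograde leg
    t0, t1 = train.departure_time, train.tip_arrival
    lo = max(a, t0 + x0 / c.v_antero)
    hi = min(b, t0 + x1 / c.v_antero, t1)
    if hi > lo:
        total += hi - lo
    # retrograde leg
    t0 = train.tip_arrival + c.turnaround
    lo = max(a, t0 + (c.flagellum_length - x1) / c.v_retro)
    hi = min(b, t0 + (c.flagellum_length - x0) / c.v_retro, train.base_return)
    if hi > lo:
        total += hi - lo
    return total


def run_simulation(config: SimConfig, protocol: BleachProtocol | None = None,
                   frame_dt: float = 0.1) -> tuple[EventLog, StateTrace]:
    """Simulate the full protein life cycle of both flagella of one cell.

    The two structures use independent random substreams of ``config.seed``;
    the protocol applies to the experimental structure only.  A warm-up
    period of one transit time plus the longest residence and lead is
    simulated before t = 0 so that every compartment starts at steady state;
    the :class:`EventLog` and :class:`StateTrace` cover t in [0, duration].
    """
    if protocol is None:
        protocol = BleachProtocol()
    if not isinstance(protocol, (list, tuple)):
        raise ProtocolError("protocol must be a BleachProtocol or list of events")
    if frame_dt + 1e-12 < config.dt:
        raise ConfigError("frame_dt must be >= dt")
    dt = config.dt
    specs = config.proteins
    n_p = len(specs)

    ss = np.random.SeedSequence([config.seed & 0x7FFFFFFF, 0x1F7])
    children = ss.spawn(6)
    rng_pool = {
        "departures/experimental": np.random.default_rng(children[0]),
        "departures/control": np.random.default_rng(children[1]),
        "trains/experimental": np.random.default_rng(children[2]),
        "trains/control": np.random.default_rng(children[3]),
        "bleach": np.random.default_rng(children[4]),
        "imaging": np.random.default_rng(children[5]),
    }

    max_lead = max((p.recruitment_lead + 4 * p.lead_sd for p in specs), default=0.0)
    max_res = max((p.residence_mean + 4 * p.residence_sd
                   for p in specs if p.recycle_enabled), default=0.0)
    warmup = math.ceil(config.transit_time + max_res + max_lead + 2.0)
    horizon = config.duration + max_lead + 1.0

    state = SimState(config, rng_pool)
    log = EventLog()
    trace = StateTrace(config, frame_dt)
    heap: list[tuple[int, int, int, str, tuple]] = []
    seq = 0

    def tick(t: float) -> int:
        return int(round(t / dt))

    def push(t: float, kind: str, payload: tuple) -> None:
        nonlocal seq
        heapq.heappush(heap, (tick(t), _PRIO[kind], seq, kind, payload))
        seq += 1

    # --- schedule trains ----------------------------------------------------
    all_trains: dict[int, TrainRecord] = {}
    next_id = 0
    for s in STRUCTURES:
        rng_d = rng_pool[f"departures/{s}"]
        rng_t = rng_pool[f"trains/{s}"]
        deps = sample_departure_times(config, rng_d, t_min=-float(warmup), t_max=horizon)
        for i, t_dep in enumerate(deps):
            factor = 1.0 if rng_t.random() >= config.dim_fraction else config.bright_dim_ratio
            t_tip = round((t_dep + config.flagellum_length / config.v_antero) / dt) * dt
            t_ret = round((t_tip + config.turnaround
                           + config.flagellum_length / config.v_retro) / dt) * dt
            tr = TrainRecord(id=next_id, structure=s, departure_time=float(t_dep),
                             tip_arrival=float(t_tip), base_return=float(t_ret),
                             size_factor=factor, config=config)
            next_id += 1
            all_trains[tr.id] = tr
            # a slot opens when the train n_slots ahead departs
            slot_free = deps[i - config.n_slots] if i >= config.n_slots else -1e9
            for p, spec in enumerate(specs):
                if rng_t.random() >= spec.carry_prob:
                    continue
                t_rec = t_dep - max(0.0, rng_t.normal(spec.recruitment_lead, spec.lead_sd))
                t_rec = max(t_rec, slot_free, -float(warmup))
                t_rec = round(t_rec / dt) * dt
                n_copies = int(round(spec.copies_per_train * factor))
                tr.recruit_times[spec.name] = float(t_rec)
                push(t_rec, "recruit", (tr.id, p, n_copies))
            push(t_dep, "depart", (tr.id,))
            push(t_tip, "tip", (tr.id,))
            push(t_ret, "return", (tr.id,))

    # --- schedule protocol --------------------------------------------------
    flip_windows: list[tuple[float, float, BleachEvent]] = []
    for ev in protocol:
        if ev.mode == "pulse":
            push(ev.t_start, "bleach", (ev,))
        else:
            for (a, b) in ev.on_windows(dt):
                push(b, "flip", (a, b, ev))
                flip_windows.append((a, b, ev))

    # --- frames -------------------------------------------------------------
    n_frames = len(trace.times)
    p_img = 1.0 - math.exp(-config.imaging_bleach_rate * frame_dt)
    for f in range(n_frames):
        t = f * frame_dt
        if p_img > 0:
            push(t, "imaging", (f,))
        push(t, "snapshot", (f,))

    rng_img = rng_pool["imaging"]
    rng_bleach = rng_pool["bleach"]
    end_tick = tick(config.duration)

    def log_ok(t: float) -> bool:
        return t >= -1e-9

    # --- event loop ---------------------------------------------------------
    while heap:
        tk, _prio, _seq, kind, payload = heapq.heappop(heap)
        if tk > end_tick:
            continue
        t = tk * dt

        if kind == "recruit":
            tid, p, n_copies = payload
            tr = all_trains[tid]
            s = tr.structure
            spec = specs[p]
            counts = np.zeros(2, dtype=np.int64)
            rng_t = rng_pool[f"trains/{s}"]
            need = n_copies
            if spec.recycle_enabled:
                ru, rb = state.reuse[s][p]
                avail = int(ru + rb)
                if avail > 0 and need > 0:
                    # per-copy reuse with probability governed by supply:
                    # reuse-ready copies compete with roughly one train's
                    # worth of cell-body demand, so individual trains get a
                    # mixed (not all-or-nothing) recycled share
                    p_take = avail / (avail + spec.copies_per_train)
                    take = min(int(rng_t.binomial(need, p_take)), avail)
                    if take > 0:
                        ku = (int(rng_t.hypergeometric(ru, rb, take))
                              if take < avail else int(ru))
                        counts += (ku, take - ku)
                        state.reuse[s][p] -= (ku, take - ku)
                        need -= take
            if need > 0:
                cu, cb = state.cell_body[p]
                avail = int(cu + cb)
                take = min(need, avail)
                if take > 0:
                    ku = int(rng_t.hypergeometric(cu, cb, take)) if take < avail else int(cu)
                    counts += (ku, take - ku)
                    state.cell_body[p] -= (ku, take - ku)
            tr.composition[spec.name] = counts
            state.nascent[s][tid] = tr
            if log_ok(t):
                log.add(t, "recruit", structure=s, train=tid, protein=spec.name,
                        unbleached=int(counts[0]), bleached=int(counts[1]))

        elif kind == "depart":
            (tid,) = payload
            tr = all_trains[tid]
            s = tr.structure
            state.nascent[s].pop(tid, None)
            if tr.composition:
                state.inflag[s][tid] = tr
            if log_ok(t):
                u = int(sum(c[0] for c in tr.composition.values()))
                b = int(sum(c[1] for c in tr.composition.values()))
                comp = {name: [int(c[0]), int(c[1])]
                        for name, c in tr.composition.items()}
                log.add(t, "departure", structure=s, train=tid,
                        size_factor=tr.size_factor, unbleached=u, bleached=b,
                        composition=comp)

        elif kind == "tip":
            (tid,) = payload
            tr = all_trains[tid]
            s = tr.structure
            if tid not in state.inflag[s]:
                continue
            rng_t = rng_pool[f"trains/{s}"]
            for name, counts in tr.composition.items():
                p = state._p_index(name)
                spec = specs[p]
                if spec.tip_release_prob <= 0:
                    continue
                rel_u = int(rng_t.binomial(int(counts[0]), spec.tip_release_prob))
                rel_b = int(rng_t.binomial(int(counts[1]), spec.tip_release_prob))
                counts -= (rel_u, rel_b)
                if spec.complex_class == "cargo":
                    state.incorporated[s][p] += (rel_u, rel_b)
                else:
                    state.cell_body[p] += (rel_u, rel_b)
            if log_ok(t):
                log.add(t, "tip_arrival", structure=s, train=tid)

        elif kind == "return":
            (tid,) = payload
            tr = all_trains[tid]
            s = tr.structure
            if state.inflag[s].pop(tid, None) is None:
                continue
            rng_t = rng_pool[f"trains/{s}"]
            fates = route_returning_train(tr, specs, rng_t, dt=dt)
            for fate in fates:
                p = state._p_index(fate["protein"])
                counts = fate["counts"]
                if fate["fate"] == "recycling":
                    batch = [t + fate["release_delay"], p, counts.copy()]
                    state.recycling_batches[s].append(batch)
                    push(t + fate["release_delay"], "recycle_exit", (s, id(batch), batch))
                else:
                    state.cell_body[p] += counts
                if log_ok(t):
                    log.add(t, "recycle_routing", structure=s, train=tid,
                            protein=fate["protein"], fate=fate["fate"],
                            unbleached=int(counts[0]), bleached=int(counts[1]),
                            release_delay=fate["release_delay"])
            tr.composition = {}
            if log_ok(t):
                log.add(t, "base_return", structure=s, train=tid)

        elif kind == "recycle_exit":
            s, _bid, batch = payload
            try:
                state.recycling_batches[s].remove(batch)
            except ValueError:
                continue
            _, p, counts = batch
            spec = specs[p]
            rng_t = rng_pool[f"trains/{s}"]
            ku = int(rng_t.binomial(int(counts[0]), spec.reuse_prob))
            kb = int(rng_t.binomial(int(counts[1]), spec.reuse_prob))
            state.reuse[s][p] += (ku, kb)
            state.cell_body[p] += (int(counts[0]) - ku, int(counts[1]) - kb)

        elif kind == "bleach":
            (ev,) = payload
            n = apply_bleach(state, ev, t=t, rng=rng_bleach)
            if log_ok(t):
                log.add(t, "bleach", region=ev.region, efficiency=ev.efficiency,
                        converted=int(n))

        elif kind == "flip":
            a, b, ev = payload
            x0, x1 = ev.window
            beta = -math.log(max(1e-6, 1.0 - min(ev.efficiency, 0.999999))) / ev.duty_on
            mask = state._channel_mask(ev.channels)
            for tr in list(state.inflag["experimental"].values()):
                tau = _window_exposure(tr, a, b, x0, x1)
                if tau <= 0:
                    continue
                p_hit = 1.0 - math.exp(-beta * tau)
                for name, counts in tr.composition.items():
                    if mask[state._p_index(name)]:
                        _bleach_counts(counts, p_hit, rng_bleach)

        elif kind == "imaging":
            for s in STRUCTURES:
                arrays, per_protein = state._pool_count_arrays(s)
                for arr in arrays:
                    for p in range(n_p):
                        _bleach_counts(arr[p], p_img, rng_img)
                for p, counts in per_protein:
                    _bleach_counts(counts, p_img, rng_img)
                for tr in state.inflag[s].values():
                    for counts in tr.composition.values():
                        _bleach_counts(counts, p_img, rng_img)
                for p in range(n_p):
                    _bleach_counts(state.incorporated[s][p], p_img, rng_img)

        elif kind == "snapshot":
            (f,) = payload
            for si, s in enumerate(STRUCTURES):
                nas = np.zeros((n_p, 2), dtype=np.int64)
                for tr in state.nascent[s].values():
                    for name, counts in tr.composition.items():
                        nas[state._p_index(name)] += counts
                trace.pool[f, si, :, 0] = nas
                trace.pool[f, si, :, 1] = state.recycling_totals(s)
                trace.pool[f, si, :, 2] = state.reuse[s]
                trace.pool[f, si, :, 3] = state.standing[s]
                trace.incorporated[f, si] = state.incorporated[s]
                for tr in state.inflag[s].values():
                    rec = trace.trains.setdefault(tr.id, {
                        "structure": s, "size_factor": tr.size_factor,
                        "departure_time": tr.departure_time,
                        "frames": [], "positions": [], "u": [], "b": []})
                    rec["frames"].append(f)
                    rec["positions"].append(tr.position(f * frame_dt))
                    u = np.zeros(n_p, dtype=np.int64)
                    b = np.zeros(n_p, dtype=np.int64)
                    for name, counts in tr.composition.items():
                        p = state._p_index(name)
                        u[p], b[p] = counts
                    rec["u"].append(u)
                    rec["b"].append(b)
            trace.cell_body[f] = state.cell_body

    for rec in trace.trains.values():
        rec["frames"] = np.asarray(rec["frames"], dtype=int)
        rec["positions"] = np.asarray(rec["positions"], dtype=float)
        rec["u"] = np.asarray(rec["u"], dtype=np.int64).reshape(len(rec["frames"]), n_p)
        rec["b"] = np.asarray(rec["b"], dtype=np.int64).reshape(len(rec["frames"]), n_p)

    log.records.sort(key=lambda r: (r["t"],))
    return log, trace
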