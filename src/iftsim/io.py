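"""File formats and configuration loading.

Formats: YAML configuration (flat simulation keys plus per-protein blocks),
JSONL event logs, CSV state traces and summary tables, and 16-bit TIFF
kymograms with a JSON sidecar holding the render metadata and bleach
annotations.  A run manifest (config hash, seed, version, outputs) is
written alongside every output set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from . import queue_model as qm
from . import tirf_render as tr

__all__ = ["load_config", "save_config", "save_kymogram", "load_kymogram",
           "save_event_log", "load_event_log", "save_state_trace",
           "write_manifest", "write_fixture_suite"]


_SIM_KEYS = {f.name for f in dataclasses.fields(qm.SimConfig)} - {"proteins"}
_PROT_KEYS = {f.name for f in dataclasses.fields(qm.ProteinSpec)} - {"name"}
_RENDER_KEYS = {f.name for f in dataclasses.fields(tr.RenderConfig)}
_EVENT_KEYS = {f.name for f in dataclasses.fields(qm.BleachEvent)}
_EXP_KEYS = {"assay", "proteins", "n_replicates", "seed", "overrides"}


class ConfigFileError(qm.ConfigError):
    """Schema violation in a configuration file, naming the offending key."""


def _check_keys(mapping: dict, allowed: set, path: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigFileError(
            f"unknown key(s) {sorted(unknown)} under {path!r}; "
            f"allowed: {sorted(allowed)}")


def load_config(path: str | Path):
    """Parse a YAML configuration file into (SimConfig, RenderConfig,
    BleachProtocol, ExperimentSpec-or-None).

    Top-level sections: ``simulation`` (SimConfig fields plus a ``proteins``
    list of names or {name: overrides} blocks), ``render``, ``protocol``
    (list of bleach events) and ``experiment``.  An empty file yields all
    defaults.  Unknown keys are rejected with their path.
    """
    text = Path(path).read_text() if Path(path).exists() else ""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigFileError("top level of the config must be a mapping")
    _check_keys(raw, {"simulation", "render", "protocol", "experiment"}, "<root>")

    sim_raw = dict(raw.get("simulation") or {})
    protein_items = sim_raw.pop("proteins", [])
    _check_keys(sim_raw, _SIM_KEYS, "simulation")
    names, prot_overrides = [], {}
    for item in protein_items:
        if isinstance(item, str):
            names.append(item)
        elif isinstance(item, dict) and len(item) == 1:
            (name, fields), = item.items()
            fields = fields or {}
            _check_keys(fields, _PROT_KEYS, f"simulation.proteins.{name}")
            names.append(name)
            prot_overrides[name] = fields
        else:
            raise ConfigFileError("simulation.proteins entries must be names "
                                  "or single-key {name: {field: value}} blocks")
    try:
        sim = qm.build_default_config(names, **sim_raw)
        for name, fields in prot_overrides.items():
            idx = [i for i, p in enumerate(sim.proteins) if p.name == name][0]
            sim.proteins[idx] = dataclasses.replace(sim.proteins[idx], **fields)
        sim.validate()
    except (TypeError, qm.ConfigError) as e:
        raise ConfigFileError(f"simulation: {e}") from e

    render_raw = dict(raw.get("render") or {})
    _check_keys(render_raw, _RENDER_KEYS, "render")
    try:
        render = tr.RenderConfig(**render_raw)
    except (TypeError, qm.ConfigError) as e:
        raise ConfigFileError(f"render: {e}") from e

    events = []
    for i, ev_raw in enumerate(raw.get("protocol") or []):
        ev_raw = dict(ev_raw)
        _check_keys(ev_raw, _EVENT_KEYS, f"protocol[{i}]")
        if "window" in ev_raw and ev_raw["window"] is not None:
            ev_raw["window"] = tuple(ev_raw["window"])
        try:
            events.append(qm.BleachEvent(**ev_raw))
        except (TypeError, qm.ProtocolError) as e:
            raise ConfigFileError(f"protocol[{i}]: {e}") from e
    protocol = qm.BleachProtocol(events)

    experiment = None
    if raw.get("experiment"):
        exp_raw = dict(raw["experiment"])
        _check_keys(exp_raw, _EXP_KEYS, "experiment")
        from .experiments import ExperimentSpec
        exp_raw.setdefault("proteins", names)
        exp_raw["proteins"] = tuple(exp_raw["proteins"])
        try:
            experiment = ExperimentSpec(**exp_raw)
        except (TypeError, qm.ConfigError) as e:
            raise ConfigFileError(f"experiment: {e}") from e
    return sim, render, protocol, experiment


def save_config(path: str | Path, sim: qm.SimConfig,
                render: tr.RenderConfig | None = None,
                protocol=None) -> None:
    doc: dict = {"simulation": {}}
    for f in dataclasses.fields(qm.SimConfig):
        if f.name == "proteins":
            continue
        doc["simulation"][f.name] = getattr(sim, f.name)
    doc["simulation"]["proteins"] = [
        {p.name: {k: getattr(p, k) for k in sorted(_PROT_KEYS)}}
        for p in sim.proteins]
    if render is not None:
        doc["render"] = {f.name: getattr(render, f.name)
                         for f in dataclasses.fields(tr.RenderConfig)
                         if f.name not in ("layout",)}
    if protocol:
        doc["protocol"] = [
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in dataclasses.asdict(ev).items() if v is not None}
            for ev in protocol]
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# kymograms
# ---------------------------------------------------------------------------

def save_kymogram(path: str | Path, kym: tr.Kymogram) -> None:
    """16-bit TIFF plus a JSON sidecar with scale and metadata."""
    path = Path(path)
    peak = float(kym.data.max())
    scale = 1.0 if peak <= 0 else min(1.0, 65535.0 / peak)
    data16 = np.round(np.clip(kym.data * scale, 0, 65535)).astype(np.uint16)
    tifffile.imwrite(path, data16, metadata={"axes": "TX"})
    meta = {
        "scale": scale,
        "frame_interval_s": kym.frame_interval,
        "pixel_size_um": kym.pixel_size,
        "channel": kym.channel,
        "flagellum_length_um": kym.flagellum_length,
        "saturation_level": kym.saturation_level,
        "valid_frames": kym.valid_frames.astype(int).tolist(),
        "layout": {s: dataclasses.asdict(l) for s, l in kym.layout.items()},
        "annotations": kym.annotations,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def load_kymogram(path: str | Path) -> tr.Kymogram:
    path = Path(path)
    data16 = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    layout = {s: tr.StructureLayout(**d) for s, d in meta["layout"].items()}
    return tr.Kymogram(
        data=data16.astype(float) / meta["scale"],
        frame_interval=meta["frame_interval_s"], pixel_size=meta["pixel_size_um"],
        channel=meta["channel"], layout=layout,
        valid_frames=np.array(meta["valid_frames"], dtype=bool),
        flagellum_length=meta["flagellum_length_um"],
        annotations=meta["annotations"],
        saturation_level=meta["saturation_level"])


def save_event_log(path: str | Path, log: qm.EventLog) -> None:
    Path(path).write_text(log.to_jsonl())


def load_event_log(path: str | Path) -> qm.EventLog:
    return qm.EventLog.from_jsonl(Path(path).read_text())


def save_state_trace(path: str | Path, trace: qm.StateTrace) -> None:
    trace.to_frame().to_csv(path, index=False)


def write_manifest(outdir: str | Path, seed: int, config_doc: dict | str,
                   outputs: list[str]) -> Path:
    """Write run metadata (config hash, seed, version, outputs) atomically."""
    outdir = Path(outdir)
    text = (config_doc if isinstance(config_doc, str)
            else json.dumps(config_doc, sort_keys=True, default=str))
    manifest = {
        "config_sha256": hashlib.sha256(text.encode()).hexdigest(),
        "seed": seed,
        "version": __version__,
        "outputs": sorted(outputs),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    tmp = outdir / ".manifest.tmp"
    tmp.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    final = outdir / "manifest.json"
    tmp.replace(final)
    return final


# ---------------------------------------------------------------------------
# canonical test fixtures
# ---------------------------------------------------------------------------

def write_fixture_suite(outdir: str | Path, seed: int = 0) -> dict[str, Path]:
    """Emit the small canonical fixtures used by the test-suite, each with a
    ground-truth JSON: a noise-free single-train kymogram, a crossing-lines
    kymogram, an exact piecewise-linear FRAP trace and a 10 s default
    render with its event log."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}

    # 1) noise-free single anterograde train (no retrograde return)
    cfg = qm.build_default_config(["IFT54"], duration=7.0, seed=seed,
                                  departure_rate=0.12, departure_cv=0.0,
                                  imaging_bleach_rate=0.0)
    cfg.proteins[0] = dataclasses.replace(cfg.proteins[0],
                                          tip_release_prob=1.0, carry_prob=1.0)
    _, trace = qm.run_simulation(cfg)
    rcfg = tr.RenderConfig(shot_noise=False, read_noise_sd=0.0)
    rng = np.random.default_rng(seed)
    kym = tr.render_kymogram(trace, rcfg, rng)["IFT54"]
    save_kymogram(outdir / "single_train.tif", kym)
    (outdir / "single_train.groundtruth.json").write_text(json.dumps(
        {"v_antero_um_s": cfg.v_antero, "n_anterograde_max": 2}, indent=1))
    out["single_train"] = outdir / "single_train.tif"

    # 2) crossing anterograde/retrograde lines, built geometrically
    n_frames, width = 120, 140
    layout = {"control": tr.StructureLayout(5.0, 10.0),
              "experimental": tr.StructureLayout(55.0, 60.0)}
    data = np.full((n_frames, width), 10.0)
    dt_f, px = 0.1, 0.16
    for f in range(n_frames):
        for v, t0 in ((2.0, 1.0), (-3.0, 8.0)):
            x = v * (f * dt_f - t0)
            if 0 <= x <= 12.0:
                j = int(round(60 + x / px))
                if 60 <= j < width:
                    data[f, j] += 400.0
    kym2 = tr.Kymogram(data=data, frame_interval=dt_f, pixel_size=px,
                       channel="fixture", layout=layout,
                       valid_frames=np.ones(n_frames, dtype=bool),
                       flagellum_length=12.0)
    save_kymogram(outdir / "crossing_lines.tif", kym2)
    (outdir / "crossing_lines.groundtruth.json").write_text(json.dumps(
        {"velocities_um_s": [2.0, -3.0], "base_times_s": [1.0, 8.0]}, indent=1))
    out["crossing_lines"] = outdir / "crossing_lines.tif"

    # 3) exact piecewise-linear FRAP trace (40% at bleach, +10%/s to 90%)
    t = np.round(np.arange(0, 30.0 + 1e-9, 0.1), 3)
    v = np.where(t < 10.0, 100.0,
                 np.where(t < 15.0, 40.0 + 10.0 * (t - 10.0), 90.0))
    pd.DataFrame({"time_s": t, "percent": v}).to_csv(
        outdir / "frap_piecewise.csv", index=False)
    (outdir / "frap_piecewise.groundtruth.json").write_text(json.dumps(
        {"t_bleach": 10.0, "recovery_time": 5.0, "plateau": 90.0}, indent=1))
    out["frap_piecewise"] = outdir / "frap_piecewise.csv"

    # 4) 10 s default render with event log
    cfg4 = qm.build_default_config(["IFT54"], duration=10.0, seed=seed)
    log4, trace4 = qm.run_simulation(cfg4)
    kym4 = tr.render_kymogram(trace4, tr.RenderConfig(),
                              np.random.default_rng(seed))["IFT54"]
    save_kymogram(outdir / "default_render.tif", kym4)
    save_event_log(outdir / "default_render.events.jsonl", log4)
    spec54 = cfg4.protein("IFT54")
    (outdir / "default_render.groundtruth.json").write_text(json.dumps(
        {"total_cell_copies": spec54.total_cell_copies,
         "n_departures": len(log4.departures("experimental"))}, indent=1))
    out["default_render"] = outdir / "default_render.tif"

    write_manifest(outdir, seed, {"fixture_suite": True},
                   [str(p.name) for p in out.values()])
    return out
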