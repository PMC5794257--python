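"""File formats, run configuration and the reproducible pipeline runner.

Sweeps round-trip through HDF5 (datasets ``time``/``command_v``/``current``/
``ground_truth_cm`` with a mandatory ``sample_rate`` attribute) or two-column
CSV; event tables and Cm tracks are CSV with units embedded in the column
names.  A :class:`RunConfig` (preset name + explicit overrides + seed) fully
determines a run; ``run_pipeline`` executes simulate → estimate → analyze and
writes a manifest carrying the config hash and seed so reruns are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import audiogram as ag
from . import epsc as ep
from . import exo as xo
from .cmtrack import track_cm
from .synth import (
    abr_from_preset,
    cell_from_preset,
    dpoae_from_preset,
    epsc_from_preset,
    exo_from_preset,
    generate_epsc_train,
    load_preset,
    protocol_from_preset,
    simulate_voltage_clamp,
    synthesize_abr_series,
)
from .synth.cell import StimulusProtocol, SweepRecording

__all__ = [
    "SessionMeta", "RunConfig", "read_trace", "write_trace",
    "write_events", "read_events", "run_pipeline",
]


@dataclass
class SessionMeta:
    """Provenance of one recording; the genotype is a label only."""

    recording_id: str
    genotype: str = "synthetic"
    baseline_epoch: tuple = (0.0, 0.0)
    k_onset: float | None = None
    provenance: dict = field(default_factory=dict)


def write_trace(path, sweep: SweepRecording, dialect: str = "hdf5") -> None:
    path = Path(path)
    if dialect == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("time", data=sweep.times())
            f.create_dataset("command_v", data=sweep.command_mv)
            f.create_dataset("current", data=sweep.current_pa)
            if sweep.cm_true_pf is not None:
                f.create_dataset("ground_truth_cm", data=sweep.cm_true_pf)
            f.attrs["sample_rate"] = sweep.sample_rate
            if sweep.protocol is not None:
                f.attrs["protocol"] = yaml.safe_dump(
                    {k: v for k, v in asdict(sweep.protocol).items()})
    elif dialect == "csv":
        df = pd.DataFrame({"command_mV": sweep.command_mv, "current_pA": sweep.current_pa})
        with open(path, "w") as fh:
            fh.write(f"# sample_rate_Hz={sweep.sample_rate}\n")
            df.to_csv(fh, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_trace(path, dialect: str | None = None) -> SweepRecording:
    path = Path(path)
    if dialect is None:
        dialect = "hdf5" if path.suffix in (".h5", ".hdf5") else "csv"
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            if "sample_rate" not in f.attrs:
                raise ValueError("trace file missing sample_rate metadata")
            proto = None
            if "protocol" in f.attrs:
                proto = StimulusProtocol(**yaml.safe_load(f.attrs["protocol"]))
            current = f["current"][:]
            if np.isnan(current).any():
                raise ValueError("trace contains NaN samples")
            return SweepRecording(
                sample_rate=float(f.attrs["sample_rate"]),
                command_mv=f["command_v"][:], current_pa=current,
                cm_true_pf=f["ground_truth_cm"][:] if "ground_truth_cm" in f else None,
                protocol=proto,
            )
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# sample_rate_Hz="):
            raise ValueError("CSV trace missing sample_rate metadata line")
        fs = float(header.split("=", 1)[1])
        df = pd.read_csv(fh)
    if df.isna().any().any():
        raise ValueError("trace contains NaN samples")
    return SweepRecording(sample_rate=fs, command_mv=df["command_mV"].to_numpy(),
                          current_pa=df["current_pA"].to_numpy())


def write_events(path, events) -> None:
    df = ep.events_to_frame(events) if isinstance(events, list) else events
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    kind: str = "capacitance"      # capacitance | epsc | abr
    preset: str = "wt"
    seed: int = 0
    outdir: str = "results"
    overrides: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def run_pipeline(config: RunConfig) -> dict:
    """Execute one configured run and write results + manifest to outdir."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    preset = load_preset(config.preset)
    ov = config.overrides
    results: dict = {}

    try:
        if config.kind == "capacitance":
            cell = cell_from_preset(preset, **ov.get("cell", {}))
            proto = protocol_from_preset(preset, **ov.get("protocol", {}))
            exo = exo_from_preset(preset, **ov.get("exo", {}))
            sweep = simulate_voltage_clamp(
                cell, proto, exo=exo,
                noise_sd=config.options.get("noise_sd", 0.0), seed=config.seed)
            trace = track_cm(sweep, baseline_window=tuple(
                config.options.get("baseline_window", (0.05, proto.step_onset - 0.05))))
            trace.to_csv(out / "cmtrace.csv")
            comp = xo.segment_components(trace)
            if comp.super_onset_t is not None and comp.latency is not None:
                comp.efficiency = xo.compute_efficiency(trace, (comp.latency, comp.super_onset_t))
            endo = xo.fit_endocytosis(trace)
            comp.endo_tau = endo[0] if endo else None
            results = {f"{k}": v for k, v in asdict(comp).items()}
            (out / "components.json").write_text(json.dumps(_jsonable(results), indent=2))
        elif config.kind == "epsc":
            params = epsc_from_preset(preset, **ov.get("epsc", {}))
            duration = config.options.get("duration", 65.0)
            train = generate_epsc_train(params, duration, seed=config.seed)
            events = ep.detect_events(train.trace_pa, train.sample_rate)
            write_events(out / "events.csv", events)
            prof = ep.rate_profile(np.array([e.t_onset for e in events]), (0.0, duration),
                                   baseline_epoch=(0.0, params.k_onset))
            stats = ep.population_stats(ep.events_to_frame(events), profile=prof)
            results = asdict(stats)
            (out / "stats.json").write_text(json.dumps(_jsonable(results), indent=2))
        elif config.kind == "abr":
            params = abr_from_preset(preset, **ov.get("abr", {}))
            series = synthesize_abr_series(params, seed=config.seed)
            res = ag.abr_threshold(series)
            results = {"threshold_dB": res.threshold, "defaulted": res.defaulted,
                       "noise_floor_uV": res.noise_floor}
            pd.DataFrame({"freq_kHz": [series.freq_khz], "threshold_dB": [res.threshold],
                          "defaulted": [int(res.defaulted)]}).to_csv(
                out / "audiogram.csv", index=False)
        else:
            raise ValueError(f"unknown run kind {config.kind!r}")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{config.kind}' failed: {err}") from err

    manifest = {
        "config": asdict(config), "config_sha256": config.digest(),
        "seed": config.seed, "results": _jsonable(results),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
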