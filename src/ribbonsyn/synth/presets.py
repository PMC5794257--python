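"""Named parameter presets (WT / KO study conditions) shipped as YAML."""

from __future__ import annotations

from importlib import resources

import yaml

from .audio import AbrSynthParams, DpoaeSynthParams
from .cell import CellModelParams, ExoTrajectoryParams, StimulusProtocol, make_two_sine_protocol
from .epsc import EpscTrainParams

__all__ = [
    "available_presets", "load_preset", "cell_from_preset", "protocol_from_preset",
    "exo_from_preset", "epsc_from_preset", "abr_from_preset", "dpoae_from_preset",
]


def available_presets() -> list[str]:
    pkg = resources.files(__package__) / "presets"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a preset by name ('wt', 'ko') or from an explicit YAML path."""
    name = name.lower()
    pkg = resources.files(__package__) / "presets" / f"{name}.yaml"
    try:
        text = pkg.read_text()
    except FileNotFoundError:
        with open(name) as fh:  # treat as a path
            text = fh.read()
    return yaml.safe_load(text)


def _merged(block: dict, overrides: dict) -> dict:
    out = dict(block)
    out.update(overrides)
    return out


def cell_from_preset(preset: str | dict, **overrides) -> CellModelParams:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    return CellModelParams(**_merged(p["cell"], overrides))


def protocol_from_preset(preset: str | dict, **overrides) -> StimulusProtocol:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    return make_two_sine_protocol(**_merged(p["protocol"], overrides))


def exo_from_preset(preset: str | dict, **overrides) -> ExoTrajectoryParams:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    return ExoTrajectoryParams(**_merged(p["exo"], overrides))


def epsc_from_preset(preset: str | dict, **overrides) -> EpscTrainParams:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    kw = _merged(p["epsc"], overrides)
    if isinstance(kw.get("main_params"), list):
        kw["main_params"] = tuple(kw["main_params"])
    return EpscTrainParams(**kw)


def abr_from_preset(preset: str | dict, **overrides) -> AbrSynthParams:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    kw = _merged(p["abr"], overrides)
    for key in ("levels", "wave_latencies"):
        if isinstance(kw.get(key), list):
            kw[key] = tuple(kw[key])
    return AbrSynthParams(**kw)


def dpoae_from_preset(preset: str | dict, **overrides) -> DpoaeSynthParams:
    p = preset if isinstance(preset, dict) else load_preset(preset)
    kw = _merged(p["dpoae"], overrides)
    if isinstance(kw.get("levels"), list):
        kw["levels"] = tuple(kw["levels"])
    return DpoaeSynthParams(**kw)
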