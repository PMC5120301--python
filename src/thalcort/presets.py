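"""Named parameter presets shipped with the package."""

from __future__ import annotations

import importlib.resources

import numpy as np
import yaml

from .params import ModelParameters, SimulationConfig

__all__ = ["available_presets", "load_preset", "load_preset_raw"]


def _registry() -> dict:
    text = (
        importlib.resources.files("thalcort").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)["presets"]


def available_presets() -> list[str]:
    return sorted(_registry())


def load_preset_raw(name: str) -> dict:
    """The full nested preset document (model/simulation/stimulus)."""
    registry = _registry()
    if name not in registry:
        raise KeyError(
            f"unknown preset {name!r}; available: {', '.join(sorted(registry))}"
        )
    return registry[name]


def load_preset(name: str = "taylor2016-default"):
    """Load a preset as ``(ModelParameters, SimulationConfig)``."""
    doc = load_preset_raw(name)
    params = ModelParameters(**{k: float(v) for k, v in doc["model"].items()})
    sim = doc.get("simulation", {})
    config = SimulationConfig(
        dt=float(sim.get("dt", 0.001)),
        duration=float(sim.get("duration", 20.0)),
        transient_discard=float(sim.get("transient_discard", 5.0)),
        initial_state=np.asarray(
            sim.get("initial_state", SimulationConfig().initial_state), dtype=float
        ),
    )
    return params, config
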