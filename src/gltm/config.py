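"""YAML configuration loading for all pipeline stages."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .model import ModelConfig, TrainConfig
from .synthetic import DEFAULT_BACKGROUND, DEFAULT_TEMPLATES, MotifTemplate, SimulationConfig


def load_config(path: str | Path | None) -> dict:
    """Read a YAML config with optional ``model``, ``train`` and ``simulation``
    sections; unspecified keys fall back to dataclass defaults."""
    raw: dict = {}
    if path is not None:
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
    model = ModelConfig(**raw.get("model", {}))
    train = TrainConfig(**raw.get("train", {}))
    sim_raw = dict(raw.get("simulation", {}))
    if "motif_templates" in sim_raw:
        sim_raw["motif_templates"] = tuple(
            MotifTemplate(t["name"], t["pattern"]) for t in sim_raw["motif_templates"]
        )
    simulation = SimulationConfig(**sim_raw)
    return {"model": model, "train": train, "simulation": simulation}


def dump_config(config: dict, path: str | Path) -> None:
    out = {
        "model": asdict(config["model"]),
        "train": asdict(config["train"]),
        "simulation": {
            "n_positive": config["simulation"].n_positive,
            "n_negative": config["simulation"].n_negative,
            "fragment_length": config["simulation"].fragment_length,
            "seed": config["simulation"].seed,
            "background_distribution": config["simulation"].background_distribution,
            "motif_templates": [
                {"name": t.name, "pattern": t.pattern}
                for t in config["simulation"].motif_templates
            ],
        },
    }
    with open(path, "w") as handle:
        yaml.safe_dump(out, handle, sort_keys=False)
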