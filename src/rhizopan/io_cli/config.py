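"""Run configuration for the full pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Paths and parameters for a full analysis run.

    All input paths are optional: stages whose inputs are absent are
    skipped. ``pathway_alpha`` governs trait/pathway tests,
    ``group_alpha`` the compound-class bias tests.
    """

    output_dir: Path
    groups: Path | None = None
    labels: Path | None = None
    alignment: Path | None = None
    traits: Path | None = None
    utilization: Path | None = None
    compound_classes: Path | None = None
    predictions: Path | None = None
    reactions: Path | None = None
    pathway_alpha: float = 0.05
    group_alpha: float = 0.01
    permutations: int = 1000
    seed: int = 0
    top_k: int = 5

    def __post_init__(self):
        for alpha in (self.pathway_alpha, self.group_alpha):
            if not 0.0 < alpha < 1.0:
                raise ValueError(f"alpha {alpha} outside (0, 1)")
        if self.permutations < 0:
            raise ValueError("permutation count must be >= 0")
        if not isinstance(self.seed, int) or isinstance(self.seed, bool):
            raise ValueError("seed must be an integer")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        self.output_dir = Path(self.output_dir)
        for f in fields(self):
            if f.type == "Path | None":
                value = getattr(self, f.name)
                if value is not None:
                    setattr(self, f.name, Path(value))


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration file.

    Relative input paths are resolved against the config file's
    directory.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    base = path.parent
    path_keys = {
        "output_dir", "groups", "labels", "alignment", "traits",
        "utilization", "compound_classes", "predictions", "reactions",
    }
    for key in path_keys & set(raw):
        if raw[key] is not None:
            raw[key] = base / raw[key]
    if "output_dir" not in raw:
        raise ValueError(f"{path}: config must set output_dir")
    return RunConfig(**raw)
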