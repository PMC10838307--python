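"""Run configuration: every pipeline threshold in one place.

Defaults are the method's published operating points:

- ``n_per_class``: 10,000 cells per class in a training set
- ``tree_holdout`` / ``forest_holdout``: 0.3 / 0.5 holdout fractions
- ``forest_cutoff``: senescent iff probability > 0.5 (strict)
- ``toxicity_fraction``: wells below 40% of positive-control counts are toxic
- ``bscore_threshold`` / ``min_hit_replicates``: hit iff B > 15 in ≥ 2 replicates
- ``dab_threshold``: marker-positive iff DAB mean > 0.2 (strict)
- ``circularity_min``: hepatocyte filter keeps circularity > 0.7 (strict)
- ``min_cells_per_sample``: samples under 10,000 cells are excluded
- ``css_window``: TSS counts cells with CSS in [1, 5] (closed)
- ``pixel_size``: 0.5 μm/pixel
- ``marker_control_percentile``: marker threshold at the control 95th percentile
- ``top_k_positive``: ideal senescent reference from the top 100 positives
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """A configuration key failed validation."""


@dataclass
class RunConfig:
    seed: int = 0
    feature_set: str = "core7"
    n_per_class: int = 10_000
    tree_holdout: float = 0.3
    forest_holdout: float = 0.5
    forest_cutoff: float = 0.5
    forest_trees: int = 100
    toxicity_fraction: float = 0.40
    bscore_threshold: float = 15.0
    min_hit_replicates: int = 2
    dab_threshold: float = 0.2
    circularity_min: float = 0.7
    min_cells_per_sample: int = 10_000
    css_window: tuple[float, float] = (1.0, 5.0)
    pixel_size: float = 0.5
    marker_control_percentile: float = 95.0
    top_k_positive: int = 100
    output_dir: str = "results"

    _POSITIVE = (
        "n_per_class", "forest_trees", "min_hit_replicates", "min_cells_per_sample",
        "pixel_size", "top_k_positive",
    )
    _NONNEGATIVE = ("toxicity_fraction", "dab_threshold", "circularity_min")
    _FRACTIONS = ("tree_holdout", "forest_holdout", "forest_cutoff")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for key in self._POSITIVE:
            if getattr(self, key) <= 0:
                raise ConfigError(f"config key {key!r} must be > 0 (got {getattr(self, key)})")
        for key in self._NONNEGATIVE:
            if getattr(self, key) < 0:
                raise ConfigError(f"config key {key!r} must be >= 0 (got {getattr(self, key)})")
        for key in self._FRACTIONS:
            v = getattr(self, key)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"config key {key!r} must be in (0, 1) (got {v})")
        lo, hi = self.css_window
        if not lo < hi:
            raise ConfigError(f"config key 'css_window' must satisfy lo < hi (got {self.css_window})")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["css_window"] = list(self.css_window)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {unknown}")
        if "css_window" in data:
            data = {**data, "css_window": tuple(data["css_window"])}
        return cls(**data)

    def digest(self) -> str:
        """Stable content hash for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode("utf8")
        return hashlib.sha256(blob).hexdigest()[:16]
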