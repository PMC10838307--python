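"""Per-cell tissue detection tables with marker-correlated morphology.

Senescent cells draw larger area/caliper values and lower circularity;
a two-distribution marker model links the hidden status to the DAB
nuclear mean optical density, with overlap so marker calls are imperfect
(as they are on real slides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .._seeds import child_rng
from ..featuresets import TISSUE6, FeatureSchemaError, get_feature_set
from .populations import FeatureDistribution

__all__ = ["MarkerModel", "TissueSpec", "default_tissue_spec", "generate_tissue_table"]


@dataclass(frozen=True)
class MarkerModel:
    """Log-normal DAB OD distributions for marker-negative/-positive cells.

    Parameterized by median (must be > 0; DAB optical densities are
    non-negative) and log-scale sigma.
    """

    negative_median: float = 0.06
    negative_sigma: float = 0.55
    positive_median: float = 0.45
    positive_sigma: float = 0.40

    def __post_init__(self) -> None:
        for name in ("negative_median", "negative_sigma", "positive_median", "positive_sigma"):
            v = getattr(self, name)
            if v <= 0:
                raise ValueError(f"marker intensity parameter {name} must be > 0 (got {v})")

    def draw(self, rng: np.random.Generator, status: np.ndarray) -> np.ndarray:
        n = len(status)
        z = rng.standard_normal(n)
        neg = self.negative_median * np.exp(self.negative_sigma * z)
        pos = self.positive_median * np.exp(self.positive_sigma * z)
        return np.where(status == 1, pos, neg)


# Latent-scale defaults for hepatocyte-like nuclei (μm units).
_NORMAL_TISSUE = {
    "Area": FeatureDistribution("lognormal", np.log(42.0), 0.20),
    "Perimeter": FeatureDistribution("lognormal", np.log(24.0), 0.15),
    "Circularity": FeatureDistribution("logitnormal", 2.0, 0.50),
    "MaxCaliper": FeatureDistribution("lognormal", np.log(8.3), 0.15),
    "MinCaliper": FeatureDistribution("lognormal", np.log(6.5), 0.15),
    "Eccentricity": FeatureDistribution("logitnormal", 0.2, 0.50),
}
_SENESCENT_TISSUE = {
    "Area": FeatureDistribution("lognormal", np.log(105.0), 0.30),
    "Perimeter": FeatureDistribution("lognormal", np.log(40.0), 0.22),
    "Circularity": FeatureDistribution("logitnormal", 1.05, 0.55),
    "MaxCaliper": FeatureDistribution("lognormal", np.log(14.5), 0.22),
    "MinCaliper": FeatureDistribution("lognormal", np.log(9.3), 0.20),
    "Eccentricity": FeatureDistribution("logitnormal", 0.85, 0.55),
}


@dataclass(frozen=True)
class TissueSpec:
    """Spec for one simulated tissue sample."""

    n_cells: int
    senescent_fraction: float
    normal: Mapping[str, FeatureDistribution]
    senescent: Mapping[str, FeatureDistribution]
    marker: MarkerModel
    sample_id: str = "sample_0"
    field_size: float = 2000.0  # μm, square field for centroid placement
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be > 0 (got {self.n_cells})")
        if not 0.0 <= self.senescent_fraction <= 1.0:
            raise ValueError(
                f"senescent_fraction must be in [0, 1] (got {self.senescent_fraction})"
            )
        fs = TISSUE6
        for label, dists in (("normal", self.normal), ("senescent", self.senescent)):
            missing = fs.missing_columns(list(dists))
            if missing:
                raise FeatureSchemaError(
                    f"{label} tissue distributions missing features: {missing}"
                )


def default_tissue_spec(
    n_cells: int = 20_000,
    senescent_fraction: float = 0.1,
    seed: int = 0,
    sample_id: str = "sample_0",
) -> TissueSpec:
    return TissueSpec(
        n_cells=n_cells,
        senescent_fraction=senescent_fraction,
        normal=dict(_NORMAL_TISSUE),
        senescent=dict(_SENESCENT_TISSUE),
        marker=MarkerModel(),
        sample_id=sample_id,
        seed=seed,
    )


def generate_tissue_table(spec: TissueSpec) -> pd.DataFrame:
    """Draw the per-cell tissue table.

    Columns: ``sample_id``, ``cell_id``, centroids (μm), the tissue6
    features, ``dab_mean`` and the hidden ``true_status`` (1 senescent).
    Reproducible under ``spec.seed``.
    """
    fs = get_feature_set(TISSUE6)
    rng = child_rng(spec.seed, f"tissue/{spec.sample_id}")
    n = spec.n_cells
    n_sen = int(round(n * spec.senescent_fraction))
    status = np.zeros(n, dtype=int)
    status[:n_sen] = 1
    rng.shuffle(status)

    z = rng.standard_normal((n, len(fs)))
    data = {}
    for j, name in enumerate(fs.features):
        nd, sd = spec.normal[name], spec.senescent[name]
        vals = np.where(status == 1, sd.transform(z[:, j]), nd.transform(z[:, j]))
        data[name] = vals

    dab = spec.marker.draw(rng, status)
    table = pd.DataFrame(
        {
            "sample_id": spec.sample_id,
            "cell_id": [f"{spec.sample_id}:cell_{i:07d}" for i in range(n)],
            "centroid_x": rng.uniform(0.0, spec.field_size, n),
            "centroid_y": rng.uniform(0.0, spec.field_size, n),
            **data,
            "dab_mean": dab,
            "true_status": status,
        }
    )
    return table
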