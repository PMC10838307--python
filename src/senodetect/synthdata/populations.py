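"""Two-population (normal vs senescent) per-nucleus feature tables.

Each feature is drawn from a distribution chosen to respect its support:
log-normal for strictly positive features (area, radii), logit-normal for
ratio features bounded in (0, 1]. Locations/scales are parameters of the
latent Gaussian. An optional correlation matrix couples features through
a Gaussian copula. Class counts follow round-half-even bookkeeping so
tests can assert them exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .._seeds import child_rng
from ..featuresets import CORE7, FeatureSet, FeatureSchemaError, get_feature_set

__all__ = [
    "FeatureDistribution",
    "PopulationSpec",
    "default_population_spec",
    "with_effect",
    "generate_population_table",
]

_KINDS = ("lognormal", "logitnormal", "normal")


@dataclass(frozen=True)
class FeatureDistribution:
    """Latent-Gaussian marginal: loc/scale on log, logit or identity scale."""

    kind: str
    loc: float
    scale: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.scale <= 0:
            raise ValueError(f"scale must be > 0 (got {self.scale})")

    def transform(self, z: np.ndarray) -> np.ndarray:
        x = self.loc + self.scale * np.asarray(z)
        if self.kind == "lognormal":
            return np.exp(x)
        if self.kind == "logitnormal":
            return 1.0 / (1.0 + np.exp(-x))
        return x


@dataclass(frozen=True)
class PopulationSpec:
    """Spec for a mixed normal/senescent feature table."""

    feature_set: FeatureSet
    normal: Mapping[str, FeatureDistribution]
    senescent: Mapping[str, FeatureDistribution]
    senescent_fraction: float
    n_cells: int
    seed: int = 0
    correlation: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        fs = get_feature_set(self.feature_set)
        object.__setattr__(self, "feature_set", fs)
        if not 0.0 <= self.senescent_fraction <= 1.0:
            raise ValueError(
                f"senescent_fraction must be in [0, 1] (got {self.senescent_fraction})"
            )
        if self.n_cells <= 0:
            raise ValueError(f"n_cells must be > 0 (got {self.n_cells})")
        for label, dists in (("normal", self.normal), ("senescent", self.senescent)):
            unknown = sorted(set(dists) - set(fs.features))
            if unknown:
                raise FeatureSchemaError(
                    f"{label} distributions name features outside {fs.name!r}: {unknown}"
                )
            missing = fs.missing_columns(list(dists))
            if missing:
                raise FeatureSchemaError(
                    f"{label} distributions missing features of {fs.name!r}: {missing}"
                )
        if self.correlation is not None:
            corr = np.asarray(self.correlation, dtype=float)
            k = len(fs)
            if corr.shape != (k, k):
                raise ValueError(f"correlation must be {k}x{k}, got {corr.shape}")
            object.__setattr__(self, "correlation", corr)


# Default latent-scale parameters. Senescent nuclei are larger (area,
# gyration, compactness), less circular (form factor), and less regular
# (elongation, chord ratio) than normal nuclei; displacement increases.
_DEFAULT_NORMAL = {
    "Area": FeatureDistribution("lognormal", np.log(180.0), 0.25),
    "FormFactor": FeatureDistribution("logitnormal", 1.73, 0.45),
    "Elongation": FeatureDistribution("logitnormal", 1.10, 0.45),
    "Compactness": FeatureDistribution("lognormal", np.log(5.3), 0.18),
    "ChordRatio": FeatureDistribution("logitnormal", 1.39, 0.45),
    "GyrationRadius": FeatureDistribution("lognormal", np.log(6.0), 0.18),
    "Displacement": FeatureDistribution("lognormal", np.log(0.05), 0.40),
}
_DEFAULT_SENESCENT = {
    "Area": FeatureDistribution("lognormal", np.log(520.0), 0.35),
    "FormFactor": FeatureDistribution("logitnormal", 0.85, 0.55),
    "Elongation": FeatureDistribution("logitnormal", 0.40, 0.55),
    "Compactness": FeatureDistribution("lognormal", np.log(9.0), 0.25),
    "ChordRatio": FeatureDistribution("logitnormal", 0.62, 0.55),
    "GyrationRadius": FeatureDistribution("lognormal", np.log(10.2), 0.25),
    "Displacement": FeatureDistribution("lognormal", np.log(0.12), 0.50),
}


def default_population_spec(
    n_cells: int = 10_000,
    senescent_fraction: float = 0.5,
    seed: int = 0,
    effect: float = 1.0,
) -> PopulationSpec:
    """Core-7 spec with the default class shifts, scaled by *effect*.

    ``effect=1`` gives the full default separation; ``effect=0`` makes the
    two classes identically distributed (null).
    """
    spec = PopulationSpec(
        feature_set=CORE7,
        normal=dict(_DEFAULT_NORMAL),
        senescent=dict(_DEFAULT_SENESCENT),
        senescent_fraction=senescent_fraction,
        n_cells=n_cells,
        seed=seed,
    )
    return with_effect(spec, effect)


def with_effect(spec: PopulationSpec, effect: float) -> PopulationSpec:
    """Interpolate the senescent marginals toward the normal ones.

    The senescent latent loc/scale become
    ``normal + effect * (senescent - normal)``; ``effect=0`` collapses the
    two classes onto one distribution, ``effect=1`` is a no-op.
    """
    senescent = {
        name: FeatureDistribution(
            kind=sd.kind,
            loc=nd.loc + effect * (sd.loc - nd.loc),
            scale=nd.scale + effect * (sd.scale - nd.scale),
        )
        for name, (nd, sd) in (
            (f, (spec.normal[f], spec.senescent[f])) for f in spec.feature_set
        )
    }
    return replace(spec, senescent=senescent)


def senescent_count(n_cells: int, fraction: float) -> int:
    """Class-count bookkeeping: round-half-even of n·fraction."""
    return int(round(n_cells * fraction))


def _draw_class(
    rng: np.random.Generator,
    dists: Mapping[str, FeatureDistribution],
    fs: FeatureSet,
    n: int,
    correlation: np.ndarray | None,
) -> pd.DataFrame:
    k = len(fs)
    if correlation is None:
        z = rng.standard_normal((n, k))
    else:
        chol = np.linalg.cholesky(correlation)
        z = rng.standard_normal((n, k)) @ chol.T
    data = {
        name: dists[name].transform(z[:, j]) for j, name in enumerate(fs.features)
    }
    return pd.DataFrame(data, columns=list(fs.features))


def generate_population_table(spec: PopulationSpec) -> pd.DataFrame:
    """Draw the mixed feature table; hidden truth in column ``true_label``.

    Returns exactly ``spec.n_cells`` rows in randomized order with columns
    ``nucleus_id``, the schema features, and ``true_label`` (0 normal,
    1 senescent). The truth column is for evaluation only and must never
    be fed to a classifier.
    """
    fs = get_feature_set(spec.feature_set)
    n_sen = senescent_count(spec.n_cells, spec.senescent_fraction)
    n_norm = spec.n_cells - n_sen
    rng = child_rng(spec.seed, "population_table")

    normal = _draw_class(rng, spec.normal, fs, n_norm, spec.correlation)
    normal["true_label"] = 0
    senescent = _draw_class(rng, spec.senescent, fs, n_sen, spec.correlation)
    senescent["true_label"] = 1

    table = pd.concat([normal, senescent], ignore_index=True)
    order = rng.permutation(len(table))
    table = table.iloc[order].reset_index(drop=True)
    table.insert(0, "nucleus_id", [f"cell_{i:07d}" for i in range(len(table))])
    return table
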