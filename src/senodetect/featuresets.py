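"""Named nuclear-feature schemas.

Three schemas are supported:

``core7``
    Area, FormFactor, Elongation, Compactness, ChordRatio, GyrationRadius,
    Displacement — the compact high-content-analysis dialect.
``extended17``
    The open-source-style dialect with 17 standard shape descriptors.
``tissue6``
    Area, Perimeter, Circularity, MaxCaliper, MinCaliper, Eccentricity —
    the slide-analysis dialect used by the tissue scoring pipeline.

Each feature carries a length dimension (0 = dimensionless ratio,
1 = length in μm, 2 = area in μm²) used by unit conversion and by the
scale-equivariance checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

__all__ = [
    "FeatureSet",
    "CORE7",
    "EXTENDED17",
    "TISSUE6",
    "FEATURE_SETS",
    "get_feature_set",
    "FeatureSchemaError",
]


class FeatureSchemaError(ValueError):
    """A table or vector does not conform to the expected feature schema."""


@dataclass(frozen=True)
class FeatureSet:
    """An ordered, named collection of nuclear features.

    Parameters
    ----------
    name:
        Schema identifier (``core7``, ``extended17`` or ``tissue6``).
    features:
        Ordered feature names.
    dimensions:
        Length dimension per feature: 0 (ratio), 1 (μm) or 2 (μm²).
    """

    name: str
    features: tuple[str, ...]
    dimensions: Mapping[str, int] = field(repr=False)

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise FeatureSchemaError(f"duplicate feature names in {self.name!r}")
        missing = [f for f in self.features if f not in self.dimensions]
        if missing:
            raise FeatureSchemaError(f"features without dimension: {missing}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self) -> Iterator[str]:
        return iter(self.features)

    def __contains__(self, name: object) -> bool:
        return name in self.features

    @property
    def units(self) -> dict[str, str]:
        _u = {0: "", 1: "um", 2: "um2"}
        return {f: _u[self.dimensions[f]] for f in self.features}

    def missing_columns(self, columns: Sequence[str]) -> list[str]:
        """Features of this schema absent from *columns* (order preserved)."""
        cols = set(columns)
        return [f for f in self.features if f not in cols]

    def validate_columns(self, columns: Sequence[str]) -> None:
        missing = self.missing_columns(columns)
        if missing:
            raise FeatureSchemaError(
                f"table does not conform to feature set {self.name!r}; "
                f"missing columns: {missing}"
            )


CORE7 = FeatureSet(
    name="core7",
    features=(
        "Area",
        "FormFactor",
        "Elongation",
        "Compactness",
        "ChordRatio",
        "GyrationRadius",
        "Displacement",
    ),
    dimensions={
        "Area": 2,
        "FormFactor": 0,
        "Elongation": 0,
        "Compactness": 1,
        "ChordRatio": 0,
        "GyrationRadius": 1,
        "Displacement": 0,
    },
)

EXTENDED17 = FeatureSet(
    name="extended17",
    features=(
        "Area",
        "BoundingBoxArea",
        "Compactness",
        "ConvexArea",
        "Eccentricity",
        "EquivalentDiameter",
        "Extent",
        "FormFactor",
        "MajorAxisLength",
        "MaxFeretDiameter",
        "MaxRadius",
        "MeanRadius",
        "MedianRadius",
        "MinFeretDiameter",
        "MinorAxisLength",
        "Perimeter",
        "Solidity",
    ),
    dimensions={
        "Area": 2,
        "BoundingBoxArea": 2,
        "Compactness": 1,
        "ConvexArea": 2,
        "Eccentricity": 0,
        "EquivalentDiameter": 1,
        "Extent": 0,
        "FormFactor": 0,
        "MajorAxisLength": 1,
        "MaxFeretDiameter": 1,
        "MaxRadius": 1,
        "MeanRadius": 1,
        "MedianRadius": 1,
        "MinFeretDiameter": 1,
        "MinorAxisLength": 1,
        "Perimeter": 1,
        "Solidity": 0,
    },
)

TISSUE6 = FeatureSet(
    name="tissue6",
    features=(
        "Area",
        "Perimeter",
        "Circularity",
        "MaxCaliper",
        "MinCaliper",
        "Eccentricity",
    ),
    dimensions={
        "Area": 2,
        "Perimeter": 1,
        "Circularity": 0,
        "MaxCaliper": 1,
        "MinCaliper": 1,
        "Eccentricity": 0,
    },
)

FEATURE_SETS: dict[str, FeatureSet] = {
    fs.name: fs for fs in (CORE7, EXTENDED17, TISSUE6)
}

#: ratio-type features bounded in (0, 1] (within rasterization tolerance)
UNIT_INTERVAL_FEATURES = frozenset(
    {"FormFactor", "Elongation", "ChordRatio", "Circularity", "Extent", "Solidity"}
)


def get_feature_set(name: str | FeatureSet) -> FeatureSet:
    """Resolve a feature-set name (or pass an instance through)."""
    if isinstance(name, FeatureSet):
        return name
    try:
        return FEATURE_SETS[name]
    except KeyError:
        raise FeatureSchemaError(
            f"unknown feature set {name!r}; known: {sorted(FEATURE_SETS)}"
        ) from None
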