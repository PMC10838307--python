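"""Readers/writers and table-dialect mapping.

Feature tables arrive in one of four CSV/TSV dialects; columns are mapped
to the canonical feature names of :mod:`senodetect.featuresets`. Unknown
columns pass through untouched. Dialects can be auto-detected from the
header fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .featuresets import FeatureSet, get_feature_set

__all__ = [
    "TableDialect",
    "DIALECTS",
    "detect_dialect",
    "read_feature_table",
    "write_feature_table",
    "read_mask",
    "write_mask",
]


@dataclass(frozen=True)
class TableDialect:
    """Column-name mapping from an export dialect to canonical names."""

    dialect_id: str
    mapping: Mapping[str, str]  # source column -> canonical column
    separator: str = ","

    def canonicalize(self, table: pd.DataFrame) -> pd.DataFrame:
        return table.rename(columns=dict(self.mapping))


_NATIVE = TableDialect("native", {})

_INCARTA = TableDialect(
    "incarta_like",
    {
        "Nucleus Area": "Area",
        "Nucleus Form Factor": "FormFactor",
        "Nucleus Elongation": "Elongation",
        "Nucleus Compactness": "Compactness",
        "Nucleus Chord Ratio": "ChordRatio",
        "Nucleus Gyration Radius": "GyrationRadius",
        "Nucleus Displacement": "Displacement",
        "Well": "well",
        "DAPI Mean": "dapi_mean",
        "C12FDG Mean": "c12fdg_mean",
    },
)

_CELLPROFILER = TableDialect(
    "cellprofiler_like",
    {
        "AreaShape_Area": "Area",
        "AreaShape_BoundingBoxArea": "BoundingBoxArea",
        "AreaShape_Compactness": "Compactness",
        "AreaShape_ConvexArea": "ConvexArea",
        "AreaShape_Eccentricity": "Eccentricity",
        "AreaShape_EquivalentDiameter": "EquivalentDiameter",
        "AreaShape_Extent": "Extent",
        "AreaShape_FormFactor": "FormFactor",
        "AreaShape_MajorAxisLength": "MajorAxisLength",
        "AreaShape_MaxFeretDiameter": "MaxFeretDiameter",
        "AreaShape_MaximumRadius": "MaxRadius",
        "AreaShape_MeanRadius": "MeanRadius",
        "AreaShape_MedianRadius": "MedianRadius",
        "AreaShape_MinFeretDiameter": "MinFeretDiameter",
        "AreaShape_MinorAxisLength": "MinorAxisLength",
        "AreaShape_Perimeter": "Perimeter",
        "AreaShape_Solidity": "Solidity",
        "Metadata_Well": "well",
        "ObjectNumber": "nucleus_id",
    },
)

_QUPATH = TableDialect(
    "qupath_like",
    {
        "Nucleus: Area": "Area",
        "Nucleus: Perimeter": "Perimeter",
        "Nucleus: Circularity": "Circularity",
        "Nucleus: Max caliper": "MaxCaliper",
        "Nucleus: Min caliper": "MinCaliper",
        "Nucleus: Eccentricity": "Eccentricity",
        "Centroid X": "centroid_x",
        "Centroid Y": "centroid_y",
        "DAB: Nucleus: Mean": "dab_mean",
        "Image": "sample_id",
        "Object ID": "cell_id",
    },
    separator="\t",
)

DIALECTS: dict[str, TableDialect] = {
    d.dialect_id: d for d in (_NATIVE, _INCARTA, _CELLPROFILER, _QUPATH)
}


def detect_dialect(columns) -> TableDialect:
    """Pick the dialect whose mapped columns overlap the header the most."""
    cols = set(columns)
    best, best_hits = _NATIVE, 0
    for dialect in DIALECTS.values():
        hits = len(cols & set(dialect.mapping))
        if hits > best_hits:
            best, best_hits = dialect, hits
    return best


def read_feature_table(
    path,
    dialect: str | TableDialect | None = None,
    feature_set: str | FeatureSet | None = None,
) -> pd.DataFrame:
    """Read a feature CSV/TSV and map its columns to canonical names.

    Malformed rows are skipped with a warning carrying their line
    numbers. With *feature_set* given, missing mandatory columns raise a
    ``ValueError`` naming them.
    """
    path = Path(path)
    sep = None  # let pandas sniff , vs \t
    if isinstance(dialect, str):
        dialect = DIALECTS[dialect]
    bad_lines: list[int] = []

    def _on_bad(bad):  # pragma: no cover - depends on malformed input
        bad_lines.append(len(bad_lines))
        return None

    table = pd.read_csv(path, sep=sep, engine="python", on_bad_lines=_on_bad)
    if bad_lines:
        import warnings

        warnings.warn(f"{path}: skipped {len(bad_lines)} malformed row(s)")
    if dialect is None:
        dialect = detect_dialect(table.columns)
    table = dialect.canonicalize(table)
    if feature_set is not None:
        fs = get_feature_set(feature_set)
        missing = fs.missing_columns(table.columns)
        if missing:
            raise ValueError(
                f"{path}: missing mandatory columns for {fs.name!r}: {missing}"
            )
    return table


def write_feature_table(table: pd.DataFrame, path) -> None:
    """Write a canonical (native-dialect) feature table as CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Read an integer label mask from TIFF or PNG."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path))
    return np.asarray(iio.imread(path))


def write_mask(path, mask: np.ndarray) -> None:
    """Write an integer label mask as 16-bit TIFF or PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(mask).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
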