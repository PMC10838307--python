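"""Histology pipeline: marker calls, ideal reference derivation, the
per-cell senescence score (CSS) and the tissue senescence score (TSS).

The CSS maps a tissue6 feature vector onto a scalar anchored at the two
ideal references: 0 at the ideal normal cell and 1 at the ideal
senescent cell, unbounded beyond. Each feature contributes its
normalized position between the references, weighted by
w_i = |P^N_i / P^S_i| / Σ_j |P^N_j / P^S_j|. A literal-formula variant
(carrying the ΣT and 1/n factors of the original write-up, which breaks
the 0/1 anchoring) is available behind ``literal=True`` for comparison.

The TSS of a sample is the percentage of its cells with CSS inside the
closed scoring window (default [1, 5]).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .featuresets import TISSUE6, FeatureSet, get_feature_set

__all__ = [
    "IdealReferencePair",
    "TissueScoreReport",
    "DegenerateReferenceError",
    "classify_marker_status",
    "derive_ideal_reference",
    "cell_senescence_score",
    "tissue_senescence_score",
    "filter_tissue_sample",
    "score_sample",
]


class DegenerateReferenceError(ValueError):
    """Some feature has identical ideal normal and senescent values."""


@dataclass(frozen=True)
class IdealReferencePair:
    """Per-feature ideal normal (P^N) and senescent (P^S) values.

    Weights are derived on construction: w_i = |P^N_i/P^S_i| normalized
    to sum to 1.
    """

    feature_set: FeatureSet
    p_normal: dict[str, float]
    p_senescent: dict[str, float]
    weights: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        fs = get_feature_set(self.feature_set)
        object.__setattr__(self, "feature_set", fs)
        for name, vals in (("p_normal", self.p_normal), ("p_senescent", self.p_senescent)):
            missing = fs.missing_columns(list(vals))
            if missing:
                raise ValueError(f"{name} missing features: {missing}")
        degenerate = [
            f for f in fs.features if self.p_senescent[f] == self.p_normal[f]
        ]
        if degenerate:
            raise DegenerateReferenceError(
                f"P^S equals P^N for features {degenerate}; reference is degenerate"
            )
        raw = {f: abs(self.p_normal[f] / self.p_senescent[f]) for f in fs.features}
        total = sum(raw.values())
        object.__setattr__(self, "weights", {f: raw[f] / total for f in fs.features})

    @property
    def n(self) -> int:
        return len(self.feature_set)

    def to_json(self, path) -> None:
        payload = {
            "feature_set": self.feature_set.name,
            "p_normal": self.p_normal,
            "p_senescent": self.p_senescent,
        }
        with open(path, "w", encoding="utf8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "IdealReferencePair":
        with open(path, encoding="utf8") as fh:
            payload = json.load(fh)
        return cls(
            feature_set=get_feature_set(payload["feature_set"]),
            p_normal=payload["p_normal"],
            p_senescent=payload["p_senescent"],
        )


@dataclass
class TissueScoreReport:
    """Scores and bookkeeping for one scored sample."""

    sample_id: str
    css: pd.Series
    tss: float
    n_cells_before: int
    n_cells_after: int
    excluded_sample: bool
    exclusion_log: pd.DataFrame


def classify_marker_status(
    table: pd.DataFrame, threshold: float = 0.2, channel: str = "dab_mean"
) -> pd.Series:
    """Marker-positive iff DAB nuclear mean intensity is strictly > threshold."""
    if channel not in table.columns:
        raise ValueError(f"marker channel {channel!r} missing from table")
    intensities = table[channel]
    if intensities.isna().any():
        raise ValueError(f"marker channel {channel!r} contains missing intensities")
    return intensities > threshold


def derive_ideal_reference(
    table: pd.DataFrame,
    statuses: pd.Series | np.ndarray | None = None,
    top_k: int = 100,
    feature_set: str | FeatureSet = TISSUE6,
    intensity_col: str = "dab_mean",
    id_col: str = "cell_id",
    dab_threshold: float = 0.2,
) -> IdealReferencePair:
    """Derive (P^N, P^S) from a marker-stained cell table.

    P^N is the per-feature mean over all marker-negative cells; P^S the
    mean over the ``top_k`` marker-positive cells ranked by descending
    marker intensity (ties broken by cell id for determinism).
    """
    fs = get_feature_set(feature_set)
    fs.validate_columns(table.columns)
    if statuses is None:
        statuses = classify_marker_status(table, threshold=dab_threshold, channel=intensity_col)
    statuses = np.asarray(statuses).astype(bool)

    positives = table[statuses]
    negatives = table[~statuses]
    if len(positives) < top_k:
        raise ValueError(
            f"need at least top_k={top_k} marker-positive cells; found {len(positives)}"
        )
    if len(negatives) < 1:
        raise ValueError("need at least one marker-negative cell")

    if id_col in positives.columns:
        ranked = positives.sort_values(
            [intensity_col, id_col], ascending=[False, True], kind="mergesort"
        )
    else:
        ranked = positives.sort_values(intensity_col, ascending=False, kind="mergesort")
    top = ranked.head(top_k)

    p_normal = {f: float(negatives[f].mean()) for f in fs.features}
    p_senescent = {f: float(top[f].mean()) for f in fs.features}
    return IdealReferencePair(feature_set=fs, p_normal=p_normal, p_senescent=p_senescent)


def cell_senescence_score(
    features: pd.DataFrame | pd.Series | dict,
    reference: IdealReferencePair,
    literal: bool = False,
):
    """CSS for one feature vector or a whole table.

    Weight-normalized form (default):
    ``CSS = Σ_i w_i (p_i − P^N_i) / (P^S_i − P^N_i)`` with the reference's
    derived weights. It satisfies ``CSS(P^N) = 0`` and ``CSS(P^S) = 1``
    exactly and is affine in each feature.

    With ``literal=True`` the as-printed composition is used instead
    (per-feature terms divided by ΣT = Σ|p_j − P^N_j| and two 1/n
    factors); it does not honor the 0/1 anchoring and exists only for
    comparison.
    """
    fs = reference.feature_set
    single = not isinstance(features, pd.DataFrame)
    if isinstance(features, dict):
        features = pd.Series(features)
    if single:
        table = features.to_frame().T
    else:
        table = features
    missing = fs.missing_columns(table.columns)
    if missing:
        raise ValueError(f"feature vector missing features: {missing}")

    p = table[list(fs.features)].to_numpy(float)
    pn = np.array([reference.p_normal[f] for f in fs.features])
    ps = np.array([reference.p_senescent[f] for f in fs.features])
    unit = (p - pn) / (ps - pn)

    if literal:
        n = float(reference.n)
        ratio = np.abs(pn / ps)
        sum_t = np.abs(p - pn).sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            terms = unit * (ratio / sum_t) * (1.0 / n)
        css = terms.sum(axis=1) / n
    else:
        w = np.array([reference.weights[f] for f in fs.features])
        css = (unit * w).sum(axis=1)

    if single:
        return float(css[0])
    return pd.Series(css, index=table.index, name="css")


def tissue_senescence_score(
    css_values, window: tuple[float, float] = (1.0, 5.0)
) -> float:
    """TSS = percentage of cells with CSS inside the closed *window*."""
    css = np.asarray(css_values, dtype=float)
    if css.size == 0:
        raise ValueError("cannot compute a TSS from zero cells")
    lo, hi = window
    if not lo < hi:
        raise ValueError(f"invalid CSS window {window}")
    inside = np.sum((css >= lo) & (css <= hi))
    return 100.0 * float(inside) / css.size


def filter_tissue_sample(
    table: pd.DataFrame,
    circularity_min: float = 0.7,
    min_cells: int = 10_000,
    hepatocyte_filter: bool = False,
) -> tuple[pd.DataFrame, bool, pd.DataFrame]:
    """Sample-level QC; returns ``(filtered_table, excluded, log)``.

    With the hepatocyte filter on, cells whose circularity is not
    strictly greater than *circularity_min* are dropped. The sample as a
    whole is excluded (flag, not an error) when fewer than *min_cells*
    cells survive.
    """
    log_rows = []
    out = table
    if hepatocyte_filter:
        dropped = out[out["Circularity"] <= circularity_min]
        for cid in dropped.get("cell_id", dropped.index):
            log_rows.append({"cell_id": cid, "reason": "circularity"})
        out = out[out["Circularity"] > circularity_min]
    excluded = len(out) < min_cells
    if excluded:
        log_rows.append({"cell_id": None, "reason": "min_cells"})
    log = pd.DataFrame(log_rows, columns=["cell_id", "reason"])
    return out.reset_index(drop=True), excluded, log


def score_sample(
    table: pd.DataFrame,
    reference: IdealReferencePair,
    window: tuple[float, float] = (1.0, 5.0),
    circularity_min: float = 0.7,
    min_cells: int = 10_000,
    hepatocyte_filter: bool = False,
    sample_id: str | None = None,
) -> TissueScoreReport:
    """Filter a sample, score every cell and summarize into a TSS."""
    if sample_id is None:
        sample_id = str(table["sample_id"].iloc[0]) if "sample_id" in table.columns else ""
    filtered, excluded, log = filter_tissue_sample(
        table,
        circularity_min=circularity_min,
        min_cells=min_cells,
        hepatocyte_filter=hepatocyte_filter,
    )
    css = cell_senescence_score(filtered, reference)
    tss = tissue_senescence_score(css, window=window) if len(css) else float("nan")
    return TissueScoreReport(
        sample_id=sample_id,
        css=css,
        tss=tss,
        n_cells_before=len(table),
        n_cells_after=len(filtered),
        excluded_sample=excluded,
        exclusion_log=log,
    )
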