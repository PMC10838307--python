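"""Drug-screen analysis: toxicity exclusion, B-score normalization,
hit calling and between-line selectivity.

B-scores use the canonical two-way median-polish formulation: the plate
matrix is decomposed into overall + row + column effects by iterated
median sweeps; each residual is scaled by the plate's robust spread
(1.4826 × median absolute residual). Control wells participate in the
polish but are never hit-eligible. Thresholds default to the method's
printed values: wells with counts below 40% of the plate's positive-
control mean are toxic, a drug is a hit when at least 2 replicates have
B-score strictly greater than 15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PlateSet",
    "BScoreResult",
    "median_polish",
    "bscore_normalize",
    "toxicity_filter",
    "call_hits",
    "classify_selectivity",
    "analyze_screen",
    "ScreenResult",
]

WELL_COLUMNS = [
    "plate_id", "replicate", "row", "col", "drug_id", "role", "count", "pct_senescent",
]


@dataclass
class PlateSet:
    """Long-format well table plus plate geometry for one cell line."""

    wells: pd.DataFrame
    n_rows: int
    n_cols: int
    cell_line: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"well table missing columns: {missing}")
        for plate_id, grp in self.wells.groupby("plate_id"):
            if not (grp["role"] == "pos").any():
                raise ValueError(f"plate {plate_id!r} has no positive-control well")

    @property
    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    def plate_matrix(self, plate_id: str, value: str = "pct_senescent") -> np.ndarray:
        """Dense (n_rows × n_cols) matrix for one plate; absent wells are NaN."""
        mat = np.full((self.n_rows, self.n_cols), np.nan)
        grp = self.wells[self.wells["plate_id"] == plate_id]
        mat[grp["row"].to_numpy(int), grp["col"].to_numpy(int)] = grp[value].to_numpy(float)
        return mat


@dataclass
class BScoreResult:
    """Median-polish decomposition and B-scores for one plate."""

    residuals: np.ndarray
    bscores: np.ndarray
    scale: float  # 1.4826 × median |residual|
    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    converged: bool
    n_sweeps: int


def median_polish(
    matrix: np.ndarray, tol: float = 1e-11, max_sweeps: int = 1000
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray, bool, int]:
    """Two-way median polish; NaN cells are ignored by the medians.

    Returns ``(residuals, overall, row_effects, col_effects, converged,
    n_sweeps)``. Convergence is declared when a full sweep moves every
    row and column median by less than ``tol`` times the data scale; the
    tight default drives residual row/column medians below 1e-9 of the
    data scale (the convergence rate is geometric, so the sweep budget is
    rarely exhausted).
    """
    r = np.array(matrix, dtype=float)
    if r.ndim != 2 or r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError(f"plate matrix must be at least 2x2, got shape {r.shape}")
    data_scale = np.nanmax(np.abs(r)) if np.isfinite(r).any() else 1.0
    if data_scale == 0:
        data_scale = 1.0
    overall = 0.0
    row_eff = np.zeros(r.shape[0])
    col_eff = np.zeros(r.shape[1])
    converged = False
    sweeps = 0
    for sweeps in range(1, max_sweeps + 1):
        with np.errstate(all="ignore"):
            rmed = np.nanmedian(r, axis=1)
        rmed = np.where(np.isnan(rmed), 0.0, rmed)
        r -= rmed[:, None]
        row_eff += rmed
        # re-center: sweep the median of effects into the overall term
        re_med = np.median(row_eff)
        row_eff -= re_med
        overall += re_med

        with np.errstate(all="ignore"):
            cmed = np.nanmedian(r, axis=0)
        cmed = np.where(np.isnan(cmed), 0.0, cmed)
        r -= cmed[None, :]
        col_eff += cmed
        ce_med = np.median(col_eff)
        col_eff -= ce_med
        overall += ce_med

        if max(np.abs(rmed).max(), np.abs(cmed).max()) < tol * data_scale:
            converged = True
            break
    return r, overall, row_eff, col_eff, converged, sweeps


def bscore_normalize(matrix: np.ndarray, tol: float = 1e-11, max_sweeps: int = 1000) -> BScoreResult:
    """B-scores for one plate matrix: residual / (1.4826 × median |residual|).

    A zero robust scale (e.g. a constant plate) yields B-scores of 0.
    """
    residuals, overall, row_eff, col_eff, converged, sweeps = median_polish(
        matrix, tol=tol, max_sweeps=max_sweeps
    )
    finite = residuals[np.isfinite(residuals)]
    scale = 1.4826 * float(np.median(np.abs(finite))) if finite.size else 0.0
    if scale > 0:
        bscores = residuals / scale
    else:
        # degenerate robust spread (e.g. constant plate): zero residuals map
        # to 0, any outlying residual to +/-inf so it still tops the ranking
        tol = 1e-12 * max(1.0, float(np.nanmax(np.abs(matrix))) if np.isfinite(matrix).any() else 1.0)
        with np.errstate(invalid="ignore"):
            bscores = np.where(
                np.abs(residuals) <= tol, 0.0, np.sign(residuals) * np.inf
            )
            bscores = np.where(np.isfinite(residuals), bscores, np.nan)
    return BScoreResult(
        residuals=residuals,
        bscores=bscores,
        scale=scale,
        overall=overall,
        row_effects=row_eff,
        col_effects=col_eff,
        converged=converged,
        n_sweeps=sweeps,
    )


def toxicity_filter(
    plate_set: PlateSet, fraction: float = 0.40
) -> tuple[PlateSet, pd.DataFrame]:
    """Drop drug wells with counts strictly below *fraction* × the plate's
    positive-control mean count; returns the filtered set and the log.

    Exclusion is per well (i.e. per replicate) and evaluated per plate.
    """
    wells = plate_set.wells
    exclusions = []
    keep = np.ones(len(wells), dtype=bool)
    wells = wells.reset_index(drop=True)
    for plate_id, grp in wells.groupby("plate_id"):
        pos = grp[grp["role"] == "pos"]
        if pos.empty:
            raise ValueError(f"plate {plate_id!r} has no positive-control well")
        threshold = fraction * pos["count"].mean()
        bad = grp[(grp["role"] == "drug") & (grp["count"] < threshold)]
        for _, rec in bad.iterrows():
            exclusions.append(
                {
                    "plate_id": plate_id,
                    "replicate": rec["replicate"],
                    "row": rec["row"],
                    "col": rec["col"],
                    "drug_id": rec["drug_id"],
                    "count": rec["count"],
                    "threshold": threshold,
                    "reason": "toxicity",
                }
            )
        keep[bad.index] = False
    log = pd.DataFrame(
        exclusions,
        columns=["plate_id", "replicate", "row", "col", "drug_id", "count", "threshold", "reason"],
    )
    filtered = PlateSet(
        wells=wells[keep].reset_index(drop=True),
        n_rows=plate_set.n_rows,
        n_cols=plate_set.n_cols,
        cell_line=plate_set.cell_line,
    )
    return filtered, log


def call_hits(
    drug_bscores: pd.DataFrame,
    threshold: float = 15.0,
    min_replicates: int = 2,
) -> pd.DataFrame:
    """Hit flags from per-drug replicate B-scores.

    *drug_bscores* is long-format with columns ``drug_id`` and ``bscore``
    (one row per surviving replicate; toxicity-excluded replicates are
    simply absent). A drug is a hit when at least *min_replicates* of its
    B-scores exceed *threshold* strictly.
    """
    rows = []
    for drug_id, grp in drug_bscores.groupby("drug_id"):
        b = grp["bscore"].to_numpy(float)
        b = b[~np.isnan(b)]  # NaN = well absent/excluded; +/-inf still counts
        n_pos = int(np.sum(b > threshold))
        rows.append(
            {
                "drug_id": drug_id,
                "n_replicates": len(b),
                "n_above": n_pos,
                "hit": n_pos >= min_replicates,
            }
        )
    return pd.DataFrame(rows, columns=["drug_id", "n_replicates", "n_above", "hit"])


def classify_selectivity(hits_a: pd.DataFrame, hits_b: pd.DataFrame) -> pd.DataFrame:
    """Partition a shared drug library by per-line hit flags.

    Both inputs are ``call_hits`` outputs over the same drug universe;
    the result adds ``selectivity`` ∈ {lineA_only, lineB_only, both, none}.
    """
    a = hits_a.set_index("drug_id")["hit"]
    b = hits_b.set_index("drug_id")["hit"]
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))
        only_b = sorted(set(b.index) - set(a.index))
        raise ValueError(
            f"mismatched drug universes (only in A: {only_a[:5]}, only in B: {only_b[:5]})"
        )
    drugs = sorted(a.index)
    rows = []
    for d in drugs:
        ha, hb = bool(a[d]), bool(b[d])
        cls = {
            (True, False): "lineA_only",
            (False, True): "lineB_only",
            (True, True): "both",
            (False, False): "none",
        }[(ha, hb)]
        rows.append({"drug_id": d, "hit_a": ha, "hit_b": hb, "selectivity": cls})
    return pd.DataFrame(rows)


@dataclass
class ScreenResult:
    """Outputs of the single-line screen pipeline."""

    well_bscores: pd.DataFrame  # long format incl. role, bscore
    drug_bscores: pd.DataFrame  # drug_id, replicate, bscore
    hits: pd.DataFrame
    exclusions: pd.DataFrame
    plate_results: dict = field(default_factory=dict)


def analyze_screen(
    plate_set: PlateSet,
    toxicity_fraction: float = 0.40,
    b_threshold: float = 15.0,
    min_replicates: int = 2,
) -> ScreenResult:
    """Toxicity filter → per-plate B-scores → per-drug hit calls."""
    filtered, exclusions = toxicity_filter(plate_set, fraction=toxicity_fraction)
    records = []
    plate_results = {}
    for plate_id in filtered.plate_ids:
        mat = filtered.plate_matrix(plate_id)
        res = bscore_normalize(mat)
        plate_results[plate_id] = res
        grp = filtered.wells[filtered.wells["plate_id"] == plate_id]
        for _, rec in grp.iterrows():
            records.append(
                {
                    "plate_id": plate_id,
                    "replicate": rec["replicate"],
                    "row": rec["row"],
                    "col": rec["col"],
                    "drug_id": rec["drug_id"],
                    "role": rec["role"],
                    "bscore": res.bscores[int(rec["row"]), int(rec["col"])],
                }
            )
    well_bscores = pd.DataFrame(records)
    drug_rows = well_bscores[well_bscores["role"] == "drug"]
    drug_bscores = drug_rows[["drug_id", "replicate", "bscore"]].reset_index(drop=True)
    hits = call_hits(drug_bscores, threshold=b_threshold, min_replicates=min_replicates)
    return ScreenResult(
        well_bscores=well_bscores,
        drug_bscores=drug_bscores,
        hits=hits,
        exclusions=exclusions,
        plate_results=plate_results,
    )
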