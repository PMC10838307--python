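"""Simulated multi-plate drug screens with positional artifacts.

Plates carry two reserved control columns (positive inducer / vehicle),
drug wells filled row-major across as many plates as needed, additive
row/column artifacts (what B-score normalization removes), spiked active
drugs with elevated %-senescent, and spiked toxic drugs with cell counts
reduced by their kill fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .._seeds import child_rng
from ..screen import PlateSet

__all__ = ["ScreenSpec", "default_screen_spec", "generate_screen_plates"]


@dataclass(frozen=True)
class ScreenSpec:
    """Spec for a simulated screen of one cell line."""

    n_drugs: int
    n_replicates: int = 3
    n_rows: int = 16
    n_cols: int = 24
    n_plates: int | None = None  # per replicate; None → as many as needed
    pos_control_col: int = 0
    neg_control_col: int = 1
    active_effects: Mapping[str, float] = field(default_factory=dict)  # added pct
    toxic_kill: Mapping[str, float] = field(default_factory=dict)  # kill fraction
    baseline_pct: float = 5.0
    baseline_sd: float = 1.0
    pos_pct: float = 60.0
    noise_sd: float = 1.0
    control_count: float = 1000.0
    count_sd: float = 50.0
    row_artifact_sd: float = 0.0
    col_artifact_sd: float = 0.0
    cell_line: str = "lineA"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"n_replicates must be >= 1 (got {self.n_replicates})")
        if self.n_drugs < 1:
            raise ValueError(f"n_drugs must be >= 1 (got {self.n_drugs})")
        if self.pos_control_col == self.neg_control_col:
            raise ValueError("control columns must be disjoint")
        for d, kill in self.toxic_kill.items():
            if not 0.0 <= kill <= 1.0:
                raise ValueError(f"kill fraction for {d!r} must be in [0, 1]")

    @property
    def drug_ids(self) -> list[str]:
        return [f"drug_{i:04d}" for i in range(self.n_drugs)]

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * (self.n_cols - 2)  # two control columns reserved

    @property
    def plates_needed(self) -> int:
        return -(-self.n_drugs // self.wells_per_plate)


def default_screen_spec(
    n_drugs: int = 60,
    n_actives: int = 5,
    n_toxics: int = 3,
    effect: float = 55.0,
    kill_fraction: float = 0.8,
    seed: int = 0,
    **overrides,
) -> ScreenSpec:
    """Spec with the first *n_actives* drugs active and the next *n_toxics* toxic."""
    ids = [f"drug_{i:04d}" for i in range(n_drugs)]
    actives = {d: effect for d in ids[:n_actives]}
    toxics = {d: kill_fraction for d in ids[n_actives : n_actives + n_toxics]}
    return ScreenSpec(
        n_drugs=n_drugs,
        active_effects=actives,
        toxic_kill=toxics,
        seed=seed,
        **overrides,
    )


def generate_screen_plates(spec: ScreenSpec) -> tuple[PlateSet, pd.DataFrame]:
    """Simulate the screen; returns ``(plate_set, ground_truth)``.

    Ground truth is a per-drug table with ``is_active``, ``is_toxic`` and
    the spiked effect/kill values. Actives get their effect added to the
    well %-senescent before artifacts; toxic wells draw counts around
    ``control_count * (1 - kill)``.
    """
    drug_ids = spec.drug_ids
    unknown = sorted((set(spec.active_effects) | set(spec.toxic_kill)) - set(drug_ids))
    if unknown:
        raise ValueError(f"spiked drugs outside the library: {unknown}")

    n_plates = spec.plates_needed
    if spec.n_plates is not None:
        if spec.n_plates < n_plates:
            raise ValueError(
                f"layout error: {spec.n_drugs} drugs need {n_plates} plates of "
                f"{spec.wells_per_plate} drug wells, only {spec.n_plates} allowed"
            )
        n_plates = spec.n_plates

    control_cols = {spec.pos_control_col: "pos", spec.neg_control_col: "neg"}
    drug_cols = [c for c in range(spec.n_cols) if c not in control_cols]

    # randomized plate map (as real screens use), identical across replicates;
    # clustering all spikes in one row would defeat the row/column polish
    layout_rng = child_rng(spec.seed, f"screen/layout/{spec.cell_line}")
    shuffled = list(layout_rng.permutation(drug_ids))
    layout: dict[tuple[int, int, int], str] = {}
    idx = 0
    for p in range(n_plates):
        for r in range(spec.n_rows):
            for c in drug_cols:
                if idx < len(shuffled):
                    layout[(p, r, c)] = shuffled[idx]
                    idx += 1

    rng = child_rng(spec.seed, f"screen/{spec.cell_line}")
    rows = []
    for rep in range(spec.n_replicates):
        for p in range(n_plates):
            plate_id = f"{spec.cell_line}_rep{rep}_plate{p}"
            row_eff = rng.normal(0.0, spec.row_artifact_sd, spec.n_rows) \
                if spec.row_artifact_sd > 0 else np.zeros(spec.n_rows)
            col_eff = rng.normal(0.0, spec.col_artifact_sd, spec.n_cols) \
                if spec.col_artifact_sd > 0 else np.zeros(spec.n_cols)
            for r in range(spec.n_rows):
                for c in range(spec.n_cols):
                    role = control_cols.get(c, "drug")
                    drug = layout.get((p, r, c)) if role == "drug" else None
                    if role == "drug" and drug is None:
                        continue  # unused well on the last plate
                    if role == "pos":
                        pct = spec.pos_pct + rng.normal(0.0, spec.baseline_sd)
                    else:
                        pct = spec.baseline_pct + rng.normal(0.0, spec.baseline_sd)
                        if drug in spec.active_effects:
                            pct += spec.active_effects[drug]
                    pct += row_eff[r] + col_eff[c] + rng.normal(0.0, spec.noise_sd)
                    pct = float(np.clip(pct, 0.0, 100.0))

                    mean_count = spec.control_count
                    if drug in spec.toxic_kill:
                        mean_count *= 1.0 - spec.toxic_kill[drug]
                    count = max(0, int(round(rng.normal(mean_count, spec.count_sd))))

                    rows.append(
                        {
                            "plate_id": plate_id,
                            "replicate": rep,
                            "row": r,
                            "col": c,
                            "drug_id": drug,
                            "role": role,
                            "count": count,
                            "pct_senescent": pct,
                        }
                    )

    wells = pd.DataFrame(rows)
    plate_set = PlateSet(
        wells=wells, n_rows=spec.n_rows, n_cols=spec.n_cols, cell_line=spec.cell_line
    )
    truth = pd.DataFrame(
        {
            "drug_id": drug_ids,
            "is_active": [d in spec.active_effects for d in drug_ids],
            "is_toxic": [d in spec.toxic_kill for d in drug_ids],
            "effect": [spec.active_effects.get(d, 0.0) for d in drug_ids],
            "kill_fraction": [spec.toxic_kill.get(d, 0.0) for d in drug_ids],
        }
    )
    return plate_set, truth
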