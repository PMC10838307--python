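"""Training-set construction, tree/forest classifiers, consensus voting,
and per-well summarization.

Labels are binary: 0 = normal/growing, 1 = senescent. Training sets are
built either by assumption (every treated cell is labeled senescent) or
by marker (treated cells filtered to marker-positive, controls to
marker-negative) and subsample a fixed number of cells per class without
replacement. Classification trees are cost-complexity pruned with the
alpha maximizing holdout accuracy (ties favor the simpler tree); random
forests report a per-cell senescence probability equal to the fraction
of trees voting 1, with labels assigned by strict comparison against the
probability cutoff (default 0.5). Consensus ensembles use equal-weight
majority voting; an exact tie votes non-senescent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from ._seeds import child_rng
from .featuresets import FeatureSet, get_feature_set
from .metrics import roc_pr

__all__ = [
    "LabelingPolicy",
    "TrainingSet",
    "ClassifierModel",
    "ConsensusEnsemble",
    "SizingError",
    "SchemaMismatchError",
    "build_training_set",
    "train_tree",
    "train_forest",
    "fit_pruned_tree",
    "predict",
    "predict_proba",
    "summarize_wells",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class SizingError(ValueError):
    """A class pool is smaller than the requested per-class sample."""


class SchemaMismatchError(ValueError):
    """Prediction table does not carry the model's feature schema."""


@dataclass(frozen=True)
class LabelingPolicy:
    """How training rows acquire their binary label.

    ``assumption`` labels every treated cell senescent and every control
    cell normal. ``marker`` additionally filters the treated pool to
    marker-positive cells and the control pool to marker-negative cells;
    the threshold is either absolute or a percentile of the pooled
    control-channel values (default: the 95th).
    """

    mode: str = "assumption"
    marker_channel: str | None = None
    threshold: float | None = None
    control_percentile: float | None = 95.0

    def __post_init__(self) -> None:
        if self.mode not in ("assumption", "marker"):
            raise ValueError(f"mode must be 'assumption' or 'marker', got {self.mode!r}")
        if self.mode == "marker":
            if self.marker_channel is None:
                raise ValueError("marker mode requires marker_channel")
            if self.threshold is None and self.control_percentile is None:
                raise ValueError("marker mode requires a threshold or control percentile")


@dataclass
class TrainingSet:
    """Feature matrix + binary labels + per-row provenance."""

    X: pd.DataFrame
    y: np.ndarray
    feature_set: FeatureSet
    provenance: pd.DataFrame  # columns: condition, labeling_mode
    seed: int
    class_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.X.isna().any().any():
            raise ValueError("training features contain missing values")
        bad = set(np.unique(self.y)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be 0/1, found {sorted(bad)}")
        if not self.class_counts:
            vals, counts = np.unique(self.y, return_counts=True)
            self.class_counts = dict(zip(vals.tolist(), counts.tolist()))


def _as_condition_map(tables) -> dict[str, pd.DataFrame]:
    if isinstance(tables, pd.DataFrame):
        return {"condition_0": tables}
    return dict(tables)


def _marker_threshold(policy: LabelingPolicy, normal_tables: Mapping[str, pd.DataFrame]) -> float:
    if policy.threshold is not None:
        return float(policy.threshold)
    pooled = pd.concat(
        [t[policy.marker_channel] for t in normal_tables.values()], ignore_index=True
    )
    return float(np.percentile(pooled.to_numpy(float), policy.control_percentile))


def build_training_set(
    normal_tables,
    senescent_tables,
    policy: LabelingPolicy | None = None,
    n_per_class: int = 10_000,
    seed: int = 0,
    feature_set: str | FeatureSet = "core7",
    allow_smaller: bool = False,
) -> TrainingSet:
    """Subsample a balanced training set from per-condition feature tables.

    Each class draws ``n_per_class`` rows without replacement, split
    equally across its conditions (remainder assigned to the first
    conditions in sorted order). Under marker labeling, pools are first
    restricted by the marker rule. A pool deficit raises
    :class:`SizingError` naming the available counts unless
    ``allow_smaller`` is set.
    """
    fs = get_feature_set(feature_set)
    policy = policy or LabelingPolicy()
    normal_tables = _as_condition_map(normal_tables)
    senescent_tables = _as_condition_map(senescent_tables)

    if policy.mode == "marker":
        thr = _marker_threshold(policy, normal_tables)
        ch = policy.marker_channel
        senescent_tables = {k: t[t[ch] > thr] for k, t in senescent_tables.items()}
        normal_tables = {k: t[t[ch] <= thr] for k, t in normal_tables.items()}

    for name, t in {**normal_tables, **senescent_tables}.items():
        fs.validate_columns(t.columns)

    def sample_class(tables: Mapping[str, pd.DataFrame], label: int) -> tuple[pd.DataFrame, list[str]]:
        conditions = sorted(tables)
        k = len(conditions)
        base, rem = divmod(n_per_class, k)
        quotas = {c: base + (1 if i < rem else 0) for i, c in enumerate(conditions)}
        frames, prov = [], []
        for cond in conditions:
            pool = tables[cond]
            want = quotas[cond]
            if len(pool) < want:
                if not allow_smaller:
                    raise SizingError(
                        f"class {label} condition {cond!r} pool has {len(pool)} rows; "
                        f"{want} requested (n_per_class={n_per_class})"
                    )
                want = len(pool)
            rng = child_rng(seed, f"training/{label}/{cond}")
            idx = rng.choice(len(pool), size=want, replace=False)
            frames.append(pool.iloc[np.sort(idx)][list(fs.features)])
            prov.extend([cond] * want)
        return pd.concat(frames, ignore_index=True), prov

    X0, prov0 = sample_class(normal_tables, 0)
    X1, prov1 = sample_class(senescent_tables, 1)
    X = pd.concat([X0, X1], ignore_index=True)
    y = np.concatenate([np.zeros(len(X0), int), np.ones(len(X1), int)])
    provenance = pd.DataFrame(
        {"condition": prov0 + prov1, "labeling_mode": policy.mode}
    )
    return TrainingSet(X=X, y=y, feature_set=fs, provenance=provenance, seed=seed)


@dataclass
class ClassifierModel:
    """A fitted tree or forest together with its schema and decision rule."""

    kind: str  # "tree" | "forest"
    feature_set: FeatureSet
    estimator: object
    cutoff: float = 0.5  # forests: probability > cutoff → senescent
    alpha: float | None = None  # trees: chosen pruning alpha
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("tree", "forest"):
            raise ValueError(f"kind must be 'tree' or 'forest', got {self.kind!r}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError(f"cutoff must be in (0, 1), got {self.cutoff}")


@dataclass
class ConsensusEnsemble:
    """Equal-weight majority vote over member models (tie → non-senescent)."""

    members: Sequence[ClassifierModel]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a consensus ensemble needs at least 2 members")
        names = {m.feature_set.name for m in self.members}
        if len(names) > 1:
            raise ValueError(f"members mix feature sets: {sorted(names)}")

    @property
    def feature_set(self) -> FeatureSet:
        return self.members[0].feature_set


def _validate_table(fs: FeatureSet, table: pd.DataFrame) -> pd.DataFrame:
    missing = fs.missing_columns(table.columns)
    if missing:
        raise SchemaMismatchError(
            f"table missing features of {fs.name!r}: {missing}"
        )
    return table[list(fs.features)]


def fit_pruned_tree(
    X: pd.DataFrame | np.ndarray, y: np.ndarray, alpha: float
) -> DecisionTreeClassifier:
    """Deterministic tree fit at a fixed cost-complexity alpha.

    Split tie-breaking is deterministic (fixed random_state, best
    splitter), so the fitted structure is invariant to row duplication.
    """
    tree = DecisionTreeClassifier(random_state=0, ccp_alpha=float(alpha))
    tree.fit(X, y)
    return tree


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")


def train_tree(
    training_set: TrainingSet,
    holdout_fraction: float = 0.3,
    alpha_grid: Sequence[float] | None = None,
    seed: int = 0,
) -> ClassifierModel:
    """Cost-complexity-pruned classification tree.

    A stratified holdout (default 30%) scores each candidate alpha from
    the pruning path (or an explicit grid); the alpha with the highest
    holdout accuracy wins, ties going to the larger alpha (simpler tree).
    Accuracies within one standard error of the maximum are treated as
    ties, so label noise prunes toward the root instead of keeping an
    arbitrarily overfit tree.
    """
    _check_two_classes(training_set.y)
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        training_set.X,
        training_set.y,
        test_size=holdout_fraction,
        stratify=training_set.y,
        random_state=seed,
    )
    if alpha_grid is None:
        path = DecisionTreeClassifier(random_state=0).cost_complexity_pruning_path(X_tr, y_tr)
        alphas = np.unique(np.clip(path.ccp_alphas, 0.0, None))
    else:
        alphas = np.unique(np.asarray(alpha_grid, dtype=float))

    candidates = []
    for alpha in alphas:
        tree = fit_pruned_tree(X_tr, y_tr, alpha)
        candidates.append((float(alpha), tree.score(X_ho, y_ho), tree))
    top_acc = max(acc for _, acc, _ in candidates)
    # ties resolved toward the larger alpha (simpler tree); accuracies within
    # one standard error of the maximum count as ties (1-SE pruning rule)
    se = np.sqrt(top_acc * (1.0 - top_acc) / len(y_ho))
    best_alpha, best_acc, best_tree = max(
        (c for c in candidates if c[1] >= top_acc - se - 1e-12),
        key=lambda c: c[0],
    )

    scores = best_tree.predict_proba(X_ho)[:, 1]
    try:
        auc = roc_pr(scores, y_ho)["auc"]
    except ValueError:
        auc = float("nan")
    return ClassifierModel(
        kind="tree",
        feature_set=training_set.feature_set,
        estimator=best_tree,
        alpha=best_alpha,
        metadata={
            "seed": seed,
            "holdout_fraction": holdout_fraction,
            "holdout_accuracy": float(best_acc),
            "holdout_auc": float(auc),
            "class_counts": dict(training_set.class_counts),
            "n_leaves": int(best_tree.get_n_leaves()),
        },
    )


def train_forest(
    training_set: TrainingSet,
    holdout_fraction: float = 0.5,
    n_estimators: int = 100,
    max_depth: int | None = None,
    max_features: str | int | float = "sqrt",
    cutoff: float = 0.5,
    seed: int = 0,
) -> ClassifierModel:
    """Random forest with vote-fraction probabilities (default 100 trees,
    50% holdout)."""
    _check_two_classes(training_set.y)
    if not 0.0 < holdout_fraction < 1.0:
        raise ValueError(f"holdout_fraction must be in (0, 1), got {holdout_fraction}")
    X_tr, X_ho, y_tr, y_ho = train_test_split(
        training_set.X,
        training_set.y,
        test_size=holdout_fraction,
        stratify=training_set.y,
        random_state=seed,
    )
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        max_features=max_features,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X_tr, y_tr)
    model = ClassifierModel(
        kind="forest",
        feature_set=training_set.feature_set,
        estimator=forest,
        cutoff=cutoff,
        metadata={
            "seed": seed,
            "holdout_fraction": holdout_fraction,
            "n_estimators": n_estimators,
            "max_depth": max_depth,
            "max_features": max_features,
            "class_counts": dict(training_set.class_counts),
        },
    )
    proba = predict_proba(model, X_ho)
    labels = (proba > cutoff).astype(int)
    model.metadata["holdout_accuracy"] = float(np.mean(labels == y_ho))
    try:
        model.metadata["holdout_auc"] = roc_pr(proba, y_ho)["auc"]
    except ValueError:
        model.metadata["holdout_auc"] = float("nan")
    return model


def predict_proba(model: ClassifierModel, table: pd.DataFrame) -> np.ndarray:
    """Senescence probability per row.

    Trees expose the leaf class fraction; forests the fraction of member
    trees voting senescent.
    """
    X = _validate_table(model.feature_set, table)
    if model.kind == "tree":
        return model.estimator.predict_proba(X)[:, 1]
    votes = np.stack([est.predict(X.to_numpy()) for est in model.estimator.estimators_])
    return votes.mean(axis=0)


def predict(model, table: pd.DataFrame) -> np.ndarray:
    """Per-cell binary labels for a model or a consensus ensemble.

    Forest labels use strict ``probability > cutoff``. Ensemble labels
    are 1 iff strictly more than half of the members vote 1.
    """
    if isinstance(model, ConsensusEnsemble):
        votes = np.stack([predict(m, table) for m in model.members])
        return (votes.sum(axis=0) * 2 > len(model.members)).astype(int)
    X = _validate_table(model.feature_set, table)
    if model.kind == "tree":
        return model.estimator.predict(X).astype(int)
    return (predict_proba(model, table) > model.cutoff).astype(int)


def summarize_wells(
    labels: np.ndarray,
    wells: Sequence,
    all_wells: Sequence | None = None,
) -> pd.DataFrame:
    """Per-well cell counts and % predicted senescent.

    Wells listed in *all_wells* but receiving no cells are flagged empty
    with an undefined (NaN) percentage — never 0.
    """
    labels = np.asarray(labels, dtype=int)
    wells = np.asarray(wells)
    if len(labels) != len(wells):
        raise ValueError("labels and wells must have equal length")
    df = pd.DataFrame({"well": wells, "label": labels})
    grouped = df.groupby("well")["label"].agg(n_cells="size", n_senescent="sum")
    if all_wells is not None:
        grouped = grouped.reindex(pd.Index(all_wells, name="well"))
        grouped[["n_cells", "n_senescent"]] = (
            grouped[["n_cells", "n_senescent"]].fillna(0).astype(int)
        )
    out = grouped.reset_index()
    out["empty"] = out["n_cells"] == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        out["pct_senescent"] = np.where(
            out["n_cells"] > 0, 100.0 * out["n_senescent"] / out["n_cells"], np.nan
        )
    return out


def save_model(model, path) -> None:
    """Versioned single-file serialization (model or ensemble)."""
    if isinstance(model, ConsensusEnsemble):
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "type": "ensemble",
            "members": [_model_payload(m) for m in model.members],
        }
    else:
        payload = _model_payload(model)
    joblib.dump(payload, path)


def _model_payload(model: ClassifierModel) -> dict:
    return {
        "format_version": MODEL_FORMAT_VERSION,
        "type": "model",
        "kind": model.kind,
        "feature_set": model.feature_set.name,
        "estimator": model.estimator,
        "cutoff": model.cutoff,
        "alpha": model.alpha,
        "metadata": model.metadata,
    }


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    if payload["type"] == "ensemble":
        return ConsensusEnsemble([_payload_model(p) for p in payload["members"]])
    return _payload_model(payload)


def _payload_model(payload: dict) -> ClassifierModel:
    return ClassifierModel(
        kind=payload["kind"],
        feature_set=get_feature_set(payload["feature_set"]),
        estimator=payload["estimator"],
        cutoff=payload["cutoff"],
        alpha=payload["alpha"],
        metadata=payload["metadata"],
    )
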