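"""Treatment classification and explainable feature importance.

Single-cell temporal feature vectors (all timepoints of a tracked cell
concatenated) are classified with a random forest — 1000 trees, entropy
criterion, stratified 5-fold cross-validation scored by micro-F1 — after
greedy removal of correlated features (|Pearson r| >= 0.75 keeps only the
first of a correlated set, since collinearity distorts importance
estimates).  Feature importance is measured with Shapley attributions and
summarised per feature group (biological entity x morphological type, plus
the vesicle-number group) as cumulative (sum of mean |phi|) and average
(mean of mean |phi|) importance.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold

from .catalogue import FeatureSpec
from .treeshap import brute_force_shap_values, forest_shap_values

__all__ = [
    "ClassifierConfig",
    "EvalReport",
    "AttributionMatrix",
    "prune_correlated",
    "train_and_evaluate",
    "shapley_attribution",
    "group_importance",
    "timepoint_column",
    "strip_timepoint",
]

#: column naming for cell x (feature, timepoint) matrices
_TP_RE = re.compile(r"^(?P<feature>.+)__t(?P<time>[0-9.]+)$")


def timepoint_column(feature: str, time: float) -> str:
    return f"{feature}__t{time:g}"


def strip_timepoint(column: str) -> str:
    m = _TP_RE.match(column)
    return m.group("feature") if m else column


@dataclass(frozen=True)
class ClassifierConfig:
    """Random-forest configuration (defaults follow the profiling protocol)."""

    n_trees: int = 1000
    criterion: str = "entropy"
    folds: int = 5
    correlation_threshold: float = 0.75
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self):
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not 0 < self.correlation_threshold <= 1:
            raise ValueError("correlation_threshold must be in (0, 1]")


@dataclass
class EvalReport:
    """Cross-validation report: per-fold micro-F1, mean +/- SD, confusion."""

    fold_scores: list[float]
    mean_f1: float
    sd_f1: float
    confusion: np.ndarray
    classes: list[str]
    config: ClassifierConfig

    def __str__(self) -> str:
        return (
            f"micro-F1 = {self.mean_f1:.3f} +/- {self.sd_f1:.3f} over "
            f"{self.config.folds} folds ({self.config.n_trees} trees, "
            f"{self.config.criterion})"
        )


@dataclass
class AttributionMatrix:
    """Per sample x feature x class Shapley values with base values."""

    values: np.ndarray  # (n, d, c)
    base: np.ndarray  # (c,)
    feature_names: list[str]
    classes: list[str] = field(default_factory=list)

    def mean_abs(self) -> pd.Series:
        """Mean |phi| per feature, summed over classes."""
        return pd.Series(
            np.abs(self.values).mean(axis=0).sum(axis=1), index=self.feature_names
        )


def prune_correlated(
    table: pd.DataFrame, threshold: float = 0.75
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Greedy correlation pruning in column order.

    Zero-variance columns are dropped first; then each column is dropped if
    its |Pearson r| with any *retained* earlier column reaches the
    threshold ("except the first feature").  Returns the reduced table and a
    removal log of (column, reason) pairs.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 rows to estimate correlations")
    log: list[tuple[str, str]] = []
    X = table.to_numpy(dtype=float)
    sd = X.std(axis=0)
    cols = list(table.columns)
    keep_mask = sd > 0
    for c, ok in zip(cols, keep_mask):
        if not ok:
            log.append((c, "zero variance"))
    Xc = X[:, keep_mask]
    names = [c for c, ok in zip(cols, keep_mask) if ok]
    n = Xc.shape[0]
    Z = (Xc - Xc.mean(axis=0)) / (Xc.std(axis=0) * np.sqrt(n))
    retained_idx: list[int] = []
    for j in range(len(names)):
        if retained_idx:
            r = np.abs(Z[:, retained_idx].T @ Z[:, j])
            if (r >= threshold).any():
                partner = names[retained_idx[int(np.argmax(r >= threshold))]]
                log.append((names[j], f"|r| >= {threshold} with {partner}"))
                continue
        retained_idx.append(j)
    kept = [names[j] for j in retained_idx]
    return table[kept], log


def train_and_evaluate(
    X: pd.DataFrame, y, cfg: ClassifierConfig | None = None
) -> tuple[RandomForestClassifier, EvalReport]:
    """Stratified k-fold evaluation then a final refit on all data."""
    cfg = cfg or ClassifierConfig()
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.folds:
        raise ValueError(
            f"class {classes[counts.argmin()]!r} has fewer samples than folds"
        )
    Xv = np.asarray(X, dtype=float)
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    scores = []
    y_true_all, y_pred_all = [], []
    for train, test in skf.split(Xv, y):
        clf = RandomForestClassifier(
            n_estimators=cfg.n_trees,
            criterion=cfg.criterion,
            random_state=cfg.seed,
            n_jobs=cfg.n_jobs,
        )
        clf.fit(Xv[train], y[train])
        pred = clf.predict(Xv[test])
        scores.append(f1_score(y[test], pred, average="micro"))
        y_true_all.append(y[test])
        y_pred_all.append(pred)
    final = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        criterion=cfg.criterion,
        random_state=cfg.seed,
        n_jobs=cfg.n_jobs,
    )
    final.fit(Xv, y)
    report = EvalReport(
        fold_scores=[float(s) for s in scores],
        mean_f1=float(np.mean(scores)),
        sd_f1=float(np.std(scores)),
        confusion=confusion_matrix(
            np.concatenate(y_true_all), np.concatenate(y_pred_all), labels=classes
        ),
        classes=[str(c) for c in classes],
        config=cfg,
    )
    return final, report


def shapley_attribution(
    model: RandomForestClassifier,
    X: pd.DataFrame | np.ndarray,
    method: str = "tree",
) -> AttributionMatrix:
    """Shapley attributions for every sample and class.

    ``method="tree"`` uses the polynomial path-dependent algorithm;
    ``method="exact"`` enumerates all feature subsets (small models only).
    Local accuracy holds: base + sum over features = predicted probability.
    """
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xv = np.asarray(X, dtype=float)
    if Xv.shape[1] != model.n_features_in_:
        raise ValueError(
            f"X has {Xv.shape[1]} features but the model was trained on "
            f"{model.n_features_in_}"
        )
    if method == "tree":
        phi, base = forest_shap_values(model, Xv)
    elif method == "exact":
        phi, base = brute_force_shap_values(model, Xv)
    else:
        raise ValueError("method must be 'tree' or 'exact'")
    return AttributionMatrix(
        values=phi, base=base, feature_names=names,
        classes=[str(c) for c in model.classes_],
    )


def group_importance(
    attributions: AttributionMatrix,
    grouping: FeatureSpec | dict[str, str],
    top_k: int = 15,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative and average Shapley importance per feature group.

    Cumulative importance is the sum of mean |phi| over group members,
    average importance the mean; their ratio is the group size.  Feature
    columns may carry a ``__t<time>`` suffix, which is stripped before group
    lookup.  Also returns the ``top_k`` features by mean |phi|.
    """
    mean_abs = attributions.mean_abs()
    groups = {}
    for col in mean_abs.index:
        base = strip_timepoint(col)
        if isinstance(grouping, dict):
            if base not in grouping:
                raise KeyError(f"feature {base!r} is not assigned to any group")
            groups[col] = grouping[base]
        else:
            if base not in grouping:
                raise KeyError(f"feature {base!r} is not in the catalogue")
            groups[col] = grouping.group_of(base)
    df = pd.DataFrame({"mean_abs_shap": mean_abs, "group": pd.Series(groups)})
    agg = df.groupby("group")["mean_abs_shap"].agg(
        cumulative="sum", average="mean", size="count"
    )
    agg = agg.sort_values("cumulative", ascending=False)
    top = (
        df.sort_values("mean_abs_shap", ascending=False)
        .head(top_k)
        .rename_axis("feature")
        .reset_index()
    )
    return agg, top
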