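"""Nested cross-validated case-control discrimination.

Each phenotype is contrasted against the shared control pool with three
algorithms (L2 logistic regression, random forest, gradient-boosted trees)
over three feature sets (metabolites only, clinical only, combined). Hyper-
parameters are selected on inner folds, performance estimated on outer folds,
and generalization checked on the geographic hold-out regions. Class
imbalance is handled by inverse-prevalence class weights. Confidence
intervals come from stratified participant bootstrap (1,000 iterations by
default), and every result carries an events-per-variable (EPV) flag so that
high AUCs in low-EPV contrasts are marked as unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .assembly import PhenotypeFrame
from .preprocess import FoldPlan, FittedTransform, _stratified_split, fit_transform
from .synthetic import CohortTable

ALGORITHMS = ("logreg", "random_forest", "xgboost")
FEATURE_SETS = ("metabolites_only", "clinical_only", "combined")

DEFAULT_GRIDS: dict[str, list[dict]] = {
    "logreg": [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)],
    "random_forest": [
        {"n_estimators": 300, "max_depth": d} for d in (None, 8)
    ],
    "xgboost": [
        {"n_estimators": 200, "max_depth": d, "learning_rate": lr}
        for d, lr in product((3, 6), (0.05, 0.1))
    ],
}


class DiscriminationError(ValueError):
    pass


@dataclass
class ModelSpec:
    algorithm: str
    feature_set: str
    grid: list[dict] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise DiscriminationError(f"unknown algorithm {self.algorithm!r}")
        if self.feature_set not in FEATURE_SETS:
            raise DiscriminationError(f"unknown feature set {self.feature_set!r}")
        if not self.grid:
            self.grid = [dict(g) for g in DEFAULT_GRIDS[self.algorithm]]

    @property
    def spec_id(self) -> str:
        return f"{self.algorithm}/{self.feature_set}"


def build_estimator(algorithm: str, params: dict, seed: int, pos_weight: float):
    """Instantiate one classifier with inverse-prevalence class weighting."""
    if algorithm == "logreg":
        return LogisticRegression(
            C=params.get("C", 1.0),
            class_weight="balanced",
            max_iter=2000,
            solver="lbfgs",
        )
    if algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=params.get("n_estimators", 300),
            max_depth=params.get("max_depth"),
            class_weight="balanced",
            random_state=seed,
            n_jobs=1,
        )
    if algorithm == "xgboost":
        return XGBClassifier(
            n_estimators=params.get("n_estimators", 200),
            max_depth=params.get("max_depth", 3),
            learning_rate=params.get("learning_rate", 0.1),
            scale_pos_weight=pos_weight,
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    raise DiscriminationError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Probability a random case outscores a random control, ties counted 1/2."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise DiscriminationError("ROC AUC needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    scores, labels, B: int = 1000, seed: int = 0, alpha: float = 0.05
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC over participant resamples.

    Resampling is stratified by class so both classes persist in every
    replicate; deterministic under ``seed``.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)
    if len(pos) == 0 or len(neg) == 0:
        raise DiscriminationError("bootstrap CI needs both classes present")
    rng = np.random.default_rng(seed)
    aucs = np.empty(B)
    for b in range(B):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.concatenate([ip, ineg])
        aucs[b] = roc_auc_score(y[idx], s[idx])
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def threshold_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity, specificity, balanced accuracy at a probability cutoff."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "balanced_accuracy": (sens + spec) / 2.0,
    }


def epv_flag(n_cases: int, n_features: int, threshold: float = 5.0) -> tuple[float, bool]:
    """Events-per-variable and whether the contrast falls below the threshold."""
    epv = n_cases / n_features
    return epv, bool(epv < threshold)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """A fitted transform + classifier pair (train statistics frozen)."""

    transform: FittedTransform
    model: object
    algorithm: str

    def predict_scores(self, matrix: pd.DataFrame) -> np.ndarray:
        X = self.transform.apply(matrix).to_numpy()
        return self.model.predict_proba(X)[:, 1]


@dataclass
class DiscriminationResult:
    phenotype: str
    algorithm: str
    feature_set: str
    fold_aucs: list[float]
    pooled_auc: float
    ci: tuple[float, float]
    metrics: dict[str, float]
    holdout_auc: float | None
    holdout_ci: tuple[float, float] | None
    epv: float
    low_epv: bool
    n_cases: int
    n_features: int
    chosen_params: list[dict]
    final_params: dict
    final_pipeline: FittedPipeline | None = None
    pooled_scores: np.ndarray | None = None
    pooled_labels: np.ndarray | None = None

    def to_row(self) -> dict:
        return {
            "phenotype": self.phenotype,
            "algorithm": self.algorithm,
            "feature_set": self.feature_set,
            "pooled_auc": self.pooled_auc,
            "mean_fold_auc": float(np.mean(self.fold_aucs)),
            "ci_low": self.ci[0],
            "ci_high": self.ci[1],
            "holdout_auc": self.holdout_auc,
            "epv": self.epv,
            "low_epv_unstable": self.low_epv,
            **self.metrics,
        }


def _fit_scored(
    algorithm: str,
    params: dict,
    seed: int,
    matrix: pd.DataFrame,
    labels: pd.Series,
    train_ids: list[str],
    test_ids: list[str],
) -> tuple[FittedPipeline, np.ndarray]:
    transform = fit_transform(matrix, train_ids)
    X_train = transform.apply(matrix.loc[train_ids]).to_numpy()
    y_train = labels.loc[train_ids].to_numpy()
    n_pos = max(int(y_train.sum()), 1)
    pos_weight = (len(y_train) - n_pos) / n_pos
    model = build_estimator(algorithm, params, seed, pos_weight)
    model.fit(X_train, y_train)
    pipeline = FittedPipeline(transform=transform, model=model, algorithm=algorithm)
    return pipeline, pipeline.predict_scores(matrix.loc[test_ids])


def run_nested_cv(
    cohort: CohortTable,
    frame: PhenotypeFrame,
    phenotype: str,
    spec: ModelSpec,
    plan: FoldPlan,
    retained_features: list[str] | None = None,
    feature_subset: list[str] | None = None,
    bootstrap_B: int = 1000,
    epv_threshold: float = 5.0,
    fit_final: bool = True,
) -> DiscriminationResult:
    """Nested CV for one (phenotype, algorithm, feature-set) cell.

    Inner folds pick the grid point maximizing mean inner AUC (first grid
    point wins ties; a singleton grid skips the inner loop). Outer folds are
    scored by models refit on the outer-training set. All imputation/scaling
    statistics are fit within training folds only. The final pipeline is
    refit on the full discovery set with the most frequently selected
    hyperparameters and evaluated on the geographic hold-out.
    """
    matrix = cohort.feature_matrix(spec.feature_set)
    matrix = matrix.set_axis(cohort.data["participant_id"], axis=0)
    if retained_features is not None:
        keep = [c for c in matrix.columns if c in set(retained_features)]
        matrix = matrix[keep]
    if feature_subset is not None:
        if not feature_subset:
            raise DiscriminationError("feature subset is empty")
        missing = set(feature_subset) - set(matrix.columns)
        if missing:
            raise DiscriminationError(
                f"subset features not in the retained universe: {sorted(missing)[:5]}"
            )
        matrix = matrix[list(feature_subset)]

    case_set = set(frame.cases[phenotype])
    all_ids = plan.discovery_ids() + plan.holdout
    labels = pd.Series(
        [int(i in case_set) for i in all_ids], index=all_ids, dtype=int
    )
    matrix = matrix.loc[all_ids]

    rng = np.random.default_rng(plan.seed + 1)
    pooled_scores, pooled_labels, fold_aucs, chosen = [], [], [], []
    for i, test_fold in enumerate(plan.outer_folds):
        train_ids = sorted(
            pid
            for j, fold in enumerate(plan.outer_folds)
            if j != i
            for pid in fold
        )
        if labels.loc[test_fold].sum() < 1 or labels.loc[train_ids].sum() < 2:
            raise DiscriminationError(
                f"degenerate outer fold {i} for {phenotype}: too few cases"
            )
        if len(spec.grid) > 1:
            lab_map = labels.loc[train_ids].to_dict()
            inner_folds = _stratified_split(
                train_ids, lab_map, plan.n_inner, rng
            )
            best_params, best_score = None, -np.inf
            for params in spec.grid:
                inner_aucs = []
                for k, val_ids in enumerate(inner_folds):
                    fit_ids = sorted(
                        pid
                        for l, f in enumerate(inner_folds)
                        if l != k
                        for pid in f
                    )
                    _, s = _fit_scored(
                        spec.algorithm, params, spec.seed, matrix, labels,
                        fit_ids, val_ids,
                    )
                    inner_aucs.append(roc_auc(s, labels.loc[val_ids]))
                score = float(np.mean(inner_aucs))
                if score > best_score:
                    best_params, best_score = params, score
        else:
            best_params = spec.grid[0]
        chosen.append(dict(best_params))
        _, scores = _fit_scored(
            spec.algorithm, best_params, spec.seed, matrix, labels,
            train_ids, test_fold,
        )
        fold_aucs.append(roc_auc(scores, labels.loc[test_fold]))
        pooled_scores.append(scores)
        pooled_labels.append(labels.loc[test_fold].to_numpy())

    scores = np.concatenate(pooled_scores)
    y = np.concatenate(pooled_labels)
    pooled_auc = roc_auc(scores, y)
    ci = bootstrap_ci(scores, y, B=bootstrap_B, seed=plan.seed + 7)
    metrics = threshold_metrics(scores, y)

    n_cases_disc = int(y.sum())
    epv, low = epv_flag(n_cases_disc, matrix.shape[1], epv_threshold)

    # most frequently selected params across outer folds; ties -> grid order
    counts = [sum(c == g for c in chosen) for g in spec.grid]
    final_params = spec.grid[int(np.argmax(counts))]

    final_pipeline, holdout_auc, holdout_ci = None, None, None
    if fit_final:
        discovery = plan.discovery_ids()
        final_pipeline, holdout_scores = _fit_scored(
            spec.algorithm, final_params, spec.seed, matrix, labels,
            discovery, plan.holdout or discovery[:1],
        )
        if plan.holdout:
            holdout_auc, holdout_ci = evaluate_holdout(
                final_pipeline,
                matrix.loc[plan.holdout],
                labels.loc[plan.holdout],
                bootstrap_B=bootstrap_B,
                seed=plan.seed + 13,
            )

    return DiscriminationResult(
        phenotype=phenotype,
        algorithm=spec.algorithm,
        feature_set=spec.feature_set,
        fold_aucs=fold_aucs,
        pooled_auc=pooled_auc,
        ci=ci,
        metrics=metrics,
        holdout_auc=holdout_auc,
        holdout_ci=holdout_ci,
        epv=epv,
        low_epv=low,
        n_cases=n_cases_disc,
        n_features=matrix.shape[1],
        chosen_params=chosen,
        final_params=dict(final_params),
        final_pipeline=final_pipeline,
        pooled_scores=scores,
        pooled_labels=y,
    )


def evaluate_holdout(
    pipeline: FittedPipeline,
    holdout_matrix: pd.DataFrame,
    holdout_labels,
    bootstrap_B: int = 1000,
    seed: int = 0,
) -> tuple[float | None, tuple[float, float] | None]:
    """Score a discovery-trained pipeline on the geographic hold-out.

    The fitted transform is applied unchanged. A single-class or empty
    hold-out produces a structured warning and an omitted AUC.
    """
    y = np.asarray(holdout_labels).astype(int)
    if len(y) == 0:
        warnings.warn("empty hold-out set; AUC omitted", stacklevel=2)
        return None, None
    if len(np.unique(y)) < 2:
        warnings.warn("single-class hold-out; AUC omitted", stacklevel=2)
        return None, None
    scores = pipeline.predict_scores(holdout_matrix)
    return (
        roc_auc(scores, y),
        bootstrap_ci(scores, y, B=bootstrap_B, seed=seed),
    )


def evaluate_feature_subset(
    cohort: CohortTable,
    frame: PhenotypeFrame,
    subset: list[str],
    specs: list[ModelSpec],
    plans: dict[str, FoldPlan],
    full_results: dict[tuple[str, str], DiscriminationResult] | None = None,
    retained_features: list[str] | None = None,
    bootstrap_B: int = 1000,
) -> pd.DataFrame:
    """Re-run the harness restricted to a metabolite subset.

    Returns a long table with one row per (phenotype, algorithm) and, when
    the corresponding full metabolites-only results are supplied, the paired
    AUC difference (subset minus full).
    """
    if not subset:
        raise DiscriminationError("feature subset is empty")
    rows = []
    for phenotype, plan in plans.items():
        for spec in specs:
            res = run_nested_cv(
                cohort, frame, phenotype, spec, plan,
                retained_features=retained_features,
                feature_subset=subset,
                bootstrap_B=bootstrap_B,
            )
            row = res.to_row()
            key = (phenotype, spec.algorithm)
            if full_results and key in full_results:
                row["delta_auc_vs_full"] = (
                    res.pooled_auc - full_results[key].pooled_auc
                )
            rows.append(row)
    return pd.DataFrame(rows)
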