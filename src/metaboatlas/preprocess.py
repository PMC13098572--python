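"""Leakage-safe feature filtering, imputation, scaling, and fold plans.

Features with more than 20% missing values are excluded globally; median
imputation and z-score standardization statistics are fitted strictly on
training rows and then applied unchanged to validation/hold-out rows, as
required to avoid information leakage in cross-validated models.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import PhenotypeFrame
from .synthetic import CohortTable


class PreprocessError(ValueError):
    pass


def filter_missingness(
    matrix: pd.DataFrame, threshold: float = 0.20
) -> list[str]:
    """Features kept iff their missing fraction is <= threshold.

    Strictly more than ``threshold`` missing excludes the feature (a feature
    missing exactly 20% is retained at the default threshold).
    """
    if not 0.0 < threshold < 1.0:
        raise PreprocessError("threshold must lie in (0, 1)")
    frac = matrix.isna().mean(axis=0)
    return [c for c in matrix.columns if frac[c] <= threshold]


@dataclass
class FittedTransform:
    """Training-fold medians and standardization statistics.

    Fitted only on a training index set; zero-variance features are dropped
    and logged on ``dropped``.
    """

    features: list[str]
    medians: pd.Series
    means: pd.Series
    sds: pd.Series
    dropped: list[str] = field(default_factory=list)

    def apply(self, matrix: pd.DataFrame) -> pd.DataFrame:
        out = matrix[self.features].copy()
        out = out.fillna(self.medians)
        return (out - self.means) / self.sds


def fit_transform(
    matrix: pd.DataFrame, training_index
) -> FittedTransform:
    """Fit medians/means/SDs on the training rows only.

    Standardization statistics are computed after median imputation, so the
    transformed training columns have mean 0 and SD 1 on observed+imputed
    values. Features entirely missing or constant in training are dropped
    with a warning.
    """
    train = matrix.loc[training_index]
    if len(train) == 0:
        raise PreprocessError("training index is empty")
    medians = train.median(axis=0, skipna=True)
    imputed = train.fillna(medians)
    means = imputed.mean(axis=0)
    sds = imputed.std(axis=0, ddof=0)
    bad = [
        c
        for c in matrix.columns
        if not np.isfinite(medians[c]) or sds[c] <= 0 or not np.isfinite(sds[c])
    ]
    if bad:
        warnings.warn(
            f"dropping {len(bad)} all-missing/constant training features: "
            f"{bad[:5]}{'...' if len(bad) > 5 else ''}",
            stacklevel=2,
        )
    keep = [c for c in matrix.columns if c not in set(bad)]
    return FittedTransform(
        features=keep,
        medians=medians[keep],
        means=means[keep],
        sds=sds[keep],
        dropped=bad,
    )


def apply_transform(
    transform: FittedTransform, matrix: pd.DataFrame
) -> pd.DataFrame:
    return transform.apply(matrix)


@dataclass
class FoldPlan:
    """Stratified nested-CV plan over the discovery region.

    Outer folds partition the discovery participants exactly; the geographic
    hold-out (all participants from the hold-out regions) is disjoint from
    every fold. Inner folds are drawn per outer-training set at fit time
    using ``seed``.
    """

    outer_folds: list[list[str]]
    holdout: list[str]
    n_inner: int
    seed: int

    @property
    def n_outer(self) -> int:
        return len(self.outer_folds)

    def discovery_ids(self) -> list[str]:
        return sorted(pid for fold in self.outer_folds for pid in fold)

    def to_json(self) -> str:
        return json.dumps(
            {
                "outer_folds": self.outer_folds,
                "holdout": self.holdout,
                "n_inner": self.n_inner,
                "seed": self.seed,
            },
            indent=1,
        )

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _stratified_split(
    ids: list[str], labels: dict[str, int], n_folds: int, rng: np.random.Generator
) -> list[list[str]]:
    """Split ids into n_folds with per-fold case counts differing by <=1."""
    folds: list[list[str]] = [[] for _ in range(n_folds)]
    for value in (1, 0):
        group = sorted(i for i in ids if labels[i] == value)
        group = [group[k] for k in rng.permutation(len(group))]
        for k, pid in enumerate(group):
            folds[k % n_folds].append(pid)
    return [sorted(f) for f in folds]


def make_fold_plan(
    cohort: CohortTable,
    frame: PhenotypeFrame,
    phenotype: str,
    n_outer: int = 5,
    n_inner: int = 5,
    seed: int = 0,
) -> FoldPlan:
    """Build the outer-fold partition for one phenotype contrast.

    Only discovery-region participants enter the folds; hold-out regions form
    the geographic validation set. Participant order is sorted by id before
    the seeded shuffle, so the plan is deterministic.
    """
    region = dict(zip(cohort.data["participant_id"], cohort.data["region"]))
    contrast_ids = sorted(set(frame.cases[phenotype]) | set(frame.controls))
    discovery = [i for i in contrast_ids if region.get(i) == "discovery"]
    holdout = [i for i in contrast_ids if region.get(i, "discovery") != "discovery"]
    if not discovery:
        raise PreprocessError("discovery region is empty for this contrast")
    case_set = set(frame.cases[phenotype])
    labels = {i: int(i in case_set) for i in contrast_ids}
    n_cases_disc = sum(labels[i] for i in discovery)
    if n_cases_disc < 2 * n_outer:
        raise PreprocessError(
            f"only {n_cases_disc} discovery cases for {phenotype}; too few for "
            f"{n_outer}-fold stratification — use fewer folds"
        )
    rng = np.random.default_rng(seed)
    folds = _stratified_split(discovery, labels, n_outer, rng)
    return FoldPlan(outer_folds=folds, holdout=sorted(holdout), n_inner=n_inner, seed=seed)
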