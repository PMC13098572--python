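"""Additive per-feature attributions and cross-disease consensus selection.

Attributions are Shapley values of the model output with respect to a
baseline (background) sample: for every explained participant the baseline
value plus the feature attributions equals the model output exactly (local
accuracy). Three exact routes are provided — a closed form for linear
models, the gradient-boosting library's native per-feature contributions for
its own trees, and full coalition enumeration for small feature counts —
plus a permutation-sampling estimator for large feature spaces. The
permutation estimator remains exactly locally accurate (each permutation's
marginal contributions telescope to the full output difference); only the
per-feature split of the total is Monte-Carlo estimated.

Consensus selection mirrors recurrence analysis across disease models: a
feature is a cross-disease feature when it ranks in the top-k attributions of
at least ``n_min`` phenotypes with directionally consistent effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import factorial

import numpy as np
import pandas as pd
import xgboost
from sklearn.linear_model import LogisticRegression
from xgboost import XGBClassifier


class AttributionError(ValueError):
    pass


def margin_function(model):
    """Return (f, scale) where f maps a feature matrix to the model output.

    Linear and boosted-tree models are explained on the log-odds margin;
    other classifiers on the positive-class probability.
    """
    if isinstance(model, LogisticRegression):
        return model.decision_function, "margin"
    if isinstance(model, XGBClassifier):
        return (lambda X: model.predict(X, output_margin=True)), "margin"
    if hasattr(model, "predict_proba"):
        return (lambda X: model.predict_proba(X)[:, 1]), "probability"
    return model.predict, "output"


def _as64(f):
    """Average float32 model outputs in float64 (keeps telescoping exact)."""
    return lambda X: np.asarray(f(X), dtype=np.float64)


@dataclass
class AttributionTable:
    """Global importance summary plus per-sample attributions for one model."""

    phenotype: str
    mean_abs: pd.Series  # per-feature mean |attribution| over explained samples
    direction: pd.Series  # sign of corr(feature value, per-sample attribution)
    baseline_value: float
    per_sample: pd.DataFrame  # explained samples x features
    margins: np.ndarray  # model output on the explained samples
    method: str
    approximate: bool = False

    def local_accuracy_error(self) -> float:
        """max |baseline + sum(attributions) - model output| over samples."""
        totals = self.baseline_value + self.per_sample.sum(axis=1).to_numpy()
        return float(np.max(np.abs(totals - self.margins)))


def _directions(X: pd.DataFrame, phi: np.ndarray) -> pd.Series:
    vals = X.to_numpy(dtype=float)
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        x, p = vals[:, j], phi[:, j]
        if np.ptp(x) == 0 or np.ptp(p) == 0:
            continue
        out[j] = np.sign(np.corrcoef(x, p)[0, 1])
    return pd.Series(out, index=X.columns)


def _linear_attributions(model, X: pd.DataFrame, baseline: pd.DataFrame):
    w = np.asarray(model.coef_).ravel()
    mu = baseline.to_numpy(dtype=float).mean(axis=0)
    phi = (X.to_numpy(dtype=float) - mu) * w
    base_val = float(w @ mu + float(np.asarray(model.intercept_).ravel()[0]))
    return phi, base_val


def _xgb_attributions(model: XGBClassifier, X: pd.DataFrame):
    data = X if model.get_booster().feature_names else X.to_numpy(dtype=float)
    contribs = model.get_booster().predict(
        xgboost.DMatrix(data), pred_contribs=True
    )
    return contribs[:, :-1].astype(float), float(contribs[0, -1])


def _exact_attributions(f, X: pd.DataFrame, baseline: pd.DataFrame):
    """Interventional Shapley by full coalition enumeration (small d only)."""
    d = X.shape[1]
    if d > 16:
        raise AttributionError("exact enumeration limited to <= 16 features")
    B = baseline.to_numpy(dtype=float)
    nb = len(B)
    weights = np.array(
        [factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)]
    )
    phi = np.zeros((len(X), d))
    base_val = float(np.mean(f(B)))
    for i, x in enumerate(X.to_numpy(dtype=float)):
        stacked = np.empty((2**d * nb, d))
        for mask in range(2**d):
            block = B.copy()
            for j in range(d):
                if mask >> j & 1:
                    block[:, j] = x[j]
            stacked[mask * nb : (mask + 1) * nb] = block
        v = f(stacked).reshape(2**d, nb).mean(axis=1)
        for j in range(d):
            for mask in range(2**d):
                if mask >> j & 1:
                    continue
                s = bin(mask).count("1")
                phi[i, j] += weights[s] * (v[mask | (1 << j)] - v[mask])
    return phi, base_val


def _permutation_attributions(
    f, X: pd.DataFrame, baseline: pd.DataFrame, n_permutations: int, seed: int
):
    """Permutation-sampling Shapley estimate; exactly locally accurate."""
    d = X.shape[1]
    B = baseline.to_numpy(dtype=float)
    nb = len(B)
    rng = np.random.default_rng(seed)
    base_preds = f(B)
    base_val = float(np.mean(base_preds))
    phi = np.zeros((len(X), d))
    for i, x in enumerate(X.to_numpy(dtype=float)):
        acc = np.zeros(d)
        for _ in range(n_permutations):
            perm = rng.permutation(d)
            cur = B.copy()
            blocks = np.empty((d * nb, d))
            for t, j in enumerate(perm):
                cur[:, j] = x[j]
                blocks[t * nb : (t + 1) * nb] = cur
            means = f(blocks).reshape(d, nb).mean(axis=1)
            prev = base_val
            for t, j in enumerate(perm):
                acc[j] += means[t] - prev
                prev = means[t]
        phi[i] = acc / n_permutations
    return phi, base_val


def compute_attributions(
    model,
    X: pd.DataFrame,
    baseline: pd.DataFrame,
    phenotype: str = "",
    method: str = "auto",
    n_permutations: int = 8,
    seed: int = 0,
    max_explained: int | None = None,
) -> AttributionTable:
    """Shapley attributions of ``model`` on the rows of ``X``.

    ``baseline`` is background data (typically training rows); its expected
    output is the attribution baseline. ``method='auto'`` picks the exact
    route for linear and gradient-boosted models, exact enumeration when the
    feature count allows it, and the permutation estimator otherwise (the
    latter is flagged approximate: per-feature values are sampled, the local
    accuracy identity still holds exactly).
    """
    if len(baseline) == 0:
        raise AttributionError("baseline data must be non-empty")
    if max_explained is not None and len(X) > max_explained:
        X = X.iloc[:max_explained]
    f, _scale = margin_function(model)
    f = _as64(f)

    if method == "auto":
        if isinstance(model, LogisticRegression):
            method = "linear"
        elif isinstance(model, XGBClassifier):
            method = "tree_contribs"
        elif X.shape[1] <= 12:
            method = "exact"
        else:
            method = "permutation"

    approximate = False
    with warnings.catch_warnings():
        # masked baselines are passed as plain arrays; suppress sklearn's
        # fitted-with-feature-names chatter
        warnings.filterwarnings(
            "ignore", message="X does not have valid feature names"
        )
        if method == "linear":
            phi, base_val = _linear_attributions(model, X, baseline)
        elif method == "tree_contribs":
            phi, base_val = _xgb_attributions(model, X)
        elif method == "exact":
            phi, base_val = _exact_attributions(f, X, baseline)
        elif method == "permutation":
            approximate = True
            phi, base_val = _permutation_attributions(
                f, X, baseline, n_permutations, seed
            )
        else:
            raise AttributionError(f"unknown attribution method {method!r}")
        warnings.filterwarnings(
            "ignore", message="X has feature names"
        )
        try:
            margins = np.asarray(f(X), dtype=float)
        except (ValueError, TypeError):
            margins = np.asarray(f(X.to_numpy(dtype=float)), dtype=float)
    return AttributionTable(
        phenotype=phenotype,
        mean_abs=pd.Series(np.abs(phi).mean(axis=0), index=X.columns),
        direction=_directions(X, phi),
        baseline_value=base_val,
        per_sample=pd.DataFrame(phi, index=X.index, columns=X.columns),
        margins=margins,
        method=method,
        approximate=approximate,
    )


def top_k(table: AttributionTable, k: int = 30) -> list[str]:
    """Features ranked by descending mean |attribution|, ties lexicographic."""
    s = table.mean_abs
    ranked = sorted(s.index, key=lambda c: (-s[c], c))
    if k >= len(ranked):
        if k > len(ranked):
            warnings.warn(
                f"k={k} exceeds the {len(ranked)}-feature universe; returning all",
                stacklevel=2,
            )
        return ranked
    if len(ranked) > k and s[ranked[k - 1]] == s[ranked[k]]:
        warnings.warn(
            f"tie at rank {k} ({ranked[k - 1]} vs {ranked[k]}); "
            "lexicographic winner kept",
            stacklevel=2,
        )
    return ranked[:k]


@dataclass
class ConsensusFeatureSet:
    """Recurrence counts and the selected cross-disease feature panel."""

    counts: pd.Series  # phenotypes where the feature is top-k
    consistency: pd.Series  # max fraction of those sharing one direction
    selected: list[str]
    k: int
    n_min: int
    c_min: float
    n_phenotypes: int

    def write(self, path, seed: int | None = None) -> None:
        lines = [
            f"# k={self.k} n_min={self.n_min} c_min={self.c_min} "
            f"n_phenotypes={self.n_phenotypes}"
            + (f" seed={seed}" if seed is not None else "")
        ]
        lines += self.selected
        from pathlib import Path

        Path(path).write_text("\n".join(lines) + "\n")


def consensus_select(
    tables: dict[str, AttributionTable],
    k: int = 30,
    n_min: int = 10,
    c_min: float = 0.8,
) -> ConsensusFeatureSet:
    """Cross-disease features: top-k recurrence plus direction consistency.

    Recurrence counts top-k membership across phenotype tables; direction
    consistency is the largest fraction of those phenotypes sharing one sign.
    Selection requires ``count >= n_min`` and ``consistency >= c_min``. The
    result is invariant to phenotype ordering.
    """
    if len(tables) < n_min:
        raise AttributionError(
            f"need at least n_min={n_min} phenotype tables, got {len(tables)}"
        )
    counts: dict[str, int] = {}
    signs: dict[str, list[float]] = {}
    for p in sorted(tables):
        table = tables[p]
        for feat in top_k(table, k):
            counts[feat] = counts.get(feat, 0) + 1
            signs.setdefault(feat, []).append(float(table.direction[feat]))
    features = sorted(counts)
    consistency = {}
    for feat in features:
        s = np.asarray(signs[feat])
        n_pos = int((s > 0).sum())
        n_neg = int((s < 0).sum())
        consistency[feat] = max(n_pos, n_neg) / len(s)
    counts_s = pd.Series({f: counts[f] for f in features}, dtype=int)
    cons_s = pd.Series(consistency)
    selected = [
        f for f in features if counts_s[f] >= n_min and cons_s[f] >= c_min
    ]
    return ConsensusFeatureSet(
        counts=counts_s,
        consistency=cons_s,
        selected=selected,
        k=k,
        n_min=n_min,
        c_min=c_min,
        n_phenotypes=len(tables),
    )


def sankey_edges(
    tables: dict[str, AttributionTable],
    consensus: ConsensusFeatureSet,
    phenotype_category: dict[str, str] | None = None,
    feature_kind=None,
) -> pd.DataFrame:
    """Edge table (feature, phenotype, weight) for flow-diagram export.

    ``tables`` must come from combined (metabolites + clinical) models only;
    an edge exists when a consensus feature is in that phenotype's top-k, its
    weight being the source table's mean |attribution| (no renormalization).
    """
    if feature_kind is None:
        feature_kind = lambda f: "metabolite" if f.startswith("met_") else "clinical"
    rows = []
    for p in sorted(tables):
        table = tables[p]
        members = set(top_k(table, consensus.k))
        for feat in consensus.selected:
            if feat not in members:
                continue
            rows.append(
                {
                    "feature": feat,
                    "phenotype": p,
                    "weight": float(table.mean_abs[feat]),
                    "feature_kind": feature_kind(feat),
                    "phenotype_category": (phenotype_category or {}).get(p, ""),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["feature", "phenotype", "weight", "feature_kind", "phenotype_category"],
    )
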