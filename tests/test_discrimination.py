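"""ROC/AUC metrics, bootstrap CIs, nested CV contracts, EPV flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_manual_cohort
from metaboatlas.assembly import build_phenotype_frame
from metaboatlas.discrimination import (
    DiscriminationError,
    FittedPipeline,
    ModelSpec,
    bootstrap_ci,
    epv_flag,
    evaluate_holdout,
    roc_auc,
    run_nested_cv,
    threshold_metrics,
)
from metaboatlas.preprocess import make_fold_plan
from oracles import auc_paircount


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.1], [1, 1, 0, 0]) == 1.0

    def test_three_of_four_concordant(self):
        scores, labels = [0.9, 0.4, 0.7, 0.1], [1, 1, 0, 0]
        assert roc_auc(scores, labels) == 0.75 == auc_paircount(scores, labels)

    def test_all_ties_half(self):
        assert roc_auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(DiscriminationError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_antisymmetry_under_score_negation(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        labels[0], labels[1] = 0, 1
        assert roc_auc(-scores, labels) == pytest.approx(1 - roc_auc(scores, labels))

    def test_equals_normalized_mann_whitney_u(self):
        """Cross-module identity: AUC = U / (n1 * n0) on shared data."""
        rng = np.random.default_rng(1)
        cases = rng.normal(0.8, 1, 60)
        controls = rng.normal(0, 1, 90)
        u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
        scores = np.concatenate([cases, controls])
        labels = np.concatenate([np.ones(60), np.zeros(90)])
        assert roc_auc(scores, labels) == pytest.approx(u / (60 * 90))


class TestBootstrapCI:
    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=300)
        y = rng.integers(0, 2, 300)
        y[:5], y[5:10] = 1, 0
        assert bootstrap_ci(s, y, B=200, seed=7) == bootstrap_ci(s, y, B=200, seed=7)

    def test_degenerate_perfect_separation(self):
        n = 250
        s = np.concatenate([np.ones(n), np.zeros(n)])
        y = np.concatenate([np.ones(n), np.zeros(n)])
        lo, hi = bootstrap_ci(s, y, B=200, seed=0)
        assert hi - lo < 0.01
        assert (lo, hi) == (1.0, 1.0)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(3)
        s = np.concatenate([rng.normal(1, 1, 400), rng.normal(0, 1, 400)])
        y = np.concatenate([np.ones(400), np.zeros(400)])
        lo, hi = bootstrap_ci(s, y, B=300, seed=1)
        assert lo <= roc_auc(s, y) <= hi


class TestEpvFlag:
    @pytest.mark.parametrize(
        "cases,features,threshold,flagged",
        [(100, 325, 5.0, True), (5000, 21, 5.0, False), (100, 325, 0.0, False)],
    )
    def test_flagging(self, cases, features, threshold, flagged):
        epv, flag = epv_flag(cases, features, threshold)
        assert epv == pytest.approx(cases / features)
        assert flag is flagged


def _harness_cohort(seed=0, n=600, perfect_feature=False):
    """One phenotype (C01) vs controls; 15 metabolites, 3 clinical."""
    rng = np.random.default_rng(seed)
    hierarchy = pd.DataFrame([("C01", "")], columns=["class_code", "subclass_code"])
    labels = (rng.random(n) < 0.25).astype(int)
    labels[:60] = 1  # guarantee enough cases
    mets = pd.DataFrame(
        rng.lognormal(size=(n, 15)), columns=[f"met_{i:03d}" for i in range(1, 16)]
    )
    if perfect_feature:
        mets["met_001"] = labels.astype(float)
    clin = pd.DataFrame(
        rng.normal(size=(n, 3)), columns=[f"clin_{i:03d}" for i in range(1, 4)]
    )
    region = np.where(rng.random(n) < 0.75, "discovery", "holdout_A")
    codes = [("C01",) if l else () for l in labels]
    return make_manual_cohort(mets, codes, hierarchy, clinical=clin, region=list(region))


class TestNestedCV:
    @pytest.mark.parametrize("algorithm", ["logreg", "random_forest", "xgboost"])
    def test_perfect_feature_gives_auc_one(self, algorithm):
        cohort = _harness_cohort(seed=4, perfect_feature=True)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=0)
        grid = {
            "logreg": [{"C": 10.0}],
            "random_forest": [{"n_estimators": 50, "max_depth": None}],
            "xgboost": [{"n_estimators": 50, "max_depth": 3, "learning_rate": 0.3}],
        }[algorithm]
        spec = ModelSpec(algorithm, "metabolites_only", grid=grid, seed=0)
        res = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        assert res.pooled_auc == pytest.approx(1.0, abs=1e-6)

    def test_deterministic_results(self):
        cohort = _harness_cohort(seed=5)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=3)
        spec = ModelSpec("logreg", "combined", grid=[{"C": 1.0}, {"C": 0.1}], seed=0)
        a = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        b = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        assert a.pooled_auc == b.pooled_auc
        assert a.ci == b.ci
        assert a.chosen_params == b.chosen_params

    def test_leakage_sentinel_corrupt_holdout(self):
        """Corrupting hold-out rows changes nothing fit on discovery."""
        cohort = _harness_cohort(seed=6)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=1)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}, {"C": 0.01}], seed=0)
        clean = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        corrupted = _harness_cohort(seed=6)
        mask = corrupted.data["region"] != "discovery"
        corrupted.data.loc[mask, corrupted.metabolite_cols] = 1e6
        dirty = run_nested_cv(corrupted, frame, "C01", spec, plan, bootstrap_B=50)
        assert clean.pooled_auc == dirty.pooled_auc
        assert clean.chosen_params == dirty.chosen_params
        np.testing.assert_array_equal(clean.pooled_scores, dirty.pooled_scores)

    def test_subset_identity_with_all_features(self):
        cohort = _harness_cohort(seed=7)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=2)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}], seed=0)
        full = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        sub = run_nested_cv(
            cohort, frame, "C01", spec, plan,
            feature_subset=cohort.metabolite_cols, bootstrap_B=50,
        )
        assert sub.pooled_auc == full.pooled_auc

    def test_empty_subset_rejected(self):
        cohort = _harness_cohort(seed=8)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=2)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}], seed=0)
        with pytest.raises(DiscriminationError, match="empty"):
            run_nested_cv(
                cohort, frame, "C01", spec, plan, feature_subset=[], bootstrap_B=50
            )

    def test_irrelevant_subset_near_chance(self):
        """Features with no planted signal give AUC ~ 0.5."""
        cohort = _harness_cohort(seed=9, n=1200, perfect_feature=True)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=4)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}], seed=0)
        res = run_nested_cv(
            cohort, frame, "C01", spec, plan,
            feature_subset=[f"met_{i:03d}" for i in range(2, 16)],  # excludes the label feature
            bootstrap_B=50, fit_final=False,
        )
        assert 0.4 < res.pooled_auc < 0.6


class TestPlantedSignal:
    @staticmethod
    def _cohort(seed):
        from metaboatlas.synthetic import GeneratorConfig, generate_cohort

        return generate_cohort(GeneratorConfig(
            n_participants=3000, n_metabolites=30, n_clinical=6,
            n_classes=1, subclasses_per_class=1, n_lipid_classes=1,
            n_gradient_classes=0, case_fraction_per_phenotype=0.15,
            shared_signature_size=6, gradient_signature_size=0,
            n_specific_per_phenotype=0, shared_shift=0.5,
            clinical_signal_size=3, clinical_shift=0.8,
            region_weights=(0.5, 0.3, 0.2), seed=seed,
        ))

    def test_clinical_covariates_add_complementary_signal(self):
        """Combined models beat metabolites-only when clinical features
        carry independent case signal (averaged over seeds)."""
        deltas = []
        for seed in (0, 1, 2):
            cohort = self._cohort(seed)
            frame = build_phenotype_frame(cohort, min_cases=100)
            p = frame.phenotypes[0]
            plan = make_fold_plan(cohort, frame, p, seed=seed)
            aucs = {}
            for fs in ("metabolites_only", "combined"):
                spec = ModelSpec("logreg", fs, grid=[{"C": 1.0}], seed=seed)
                aucs[fs] = run_nested_cv(
                    cohort, frame, p, spec, plan, bootstrap_B=50, fit_final=False
                ).pooled_auc
            deltas.append(aucs["combined"] - aucs["metabolites_only"])
        assert np.mean(deltas) > 0

    def test_holdout_exchangeable_with_discovery(self):
        """Hold-out drawn from the same distribution: AUCs agree within 0.05."""
        cohort = self._cohort(seed=5)
        frame = build_phenotype_frame(cohort, min_cases=100)
        p = frame.phenotypes[0]
        plan = make_fold_plan(cohort, frame, p, seed=5)
        spec = ModelSpec("logreg", "combined", grid=[{"C": 1.0}], seed=5)
        res = run_nested_cv(cohort, frame, p, spec, plan, bootstrap_B=50)
        assert res.holdout_auc is not None
        assert abs(res.pooled_auc - res.holdout_auc) < 0.05


class TestHoldout:
    def test_single_class_holdout_warns_and_omits(self):
        cohort = _harness_cohort(seed=10)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=5)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}], seed=0)
        res = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        m = cohort.feature_matrix("metabolites_only").set_axis(
            cohort.data["participant_id"], axis=0
        )
        with pytest.warns(UserWarning, match="single-class"):
            auc, ci = evaluate_holdout(
                res.final_pipeline, m.loc[plan.holdout], np.zeros(len(plan.holdout))
            )
        assert auc is None and ci is None

    def test_empty_holdout_warns(self):
        cohort = _harness_cohort(seed=11)
        frame = build_phenotype_frame(cohort, min_cases=10)
        plan = make_fold_plan(cohort, frame, "C01", seed=5)
        spec = ModelSpec("logreg", "metabolites_only", grid=[{"C": 1.0}], seed=0)
        res = run_nested_cv(cohort, frame, "C01", spec, plan, bootstrap_B=50)
        m = cohort.feature_matrix("metabolites_only").set_axis(
            cohort.data["participant_id"], axis=0
        )
        with pytest.warns(UserWarning, match="empty"):
            auc, _ = evaluate_holdout(res.final_pipeline, m.iloc[:0], [])
        assert auc is None


class TestThresholdMetrics:
    def test_confusion_arithmetic(self):
        scores = [0.9, 0.6, 0.4, 0.1]
        labels = [1, 0, 1, 0]
        m = threshold_metrics(scores, labels)
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.5
        assert m["balanced_accuracy"] == 0.5


class TestModelSpec:
    def test_default_grid_filled(self):
        spec = ModelSpec("logreg", "combined")
        assert spec.grid == [{"C": c} for c in (0.01, 0.1, 1.0, 10.0)]

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(DiscriminationError):
            ModelSpec("svm", "combined")
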