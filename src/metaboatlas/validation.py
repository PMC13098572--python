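"""Canonical validation studies on synthetic cohorts.

These functions define the package's reference study conditions — the
planted-structure cohorts and the checks run against them — in one place, so
the test suite and the reproduction script exercise identical configurations.
Each study returns plain numbers computed from scratch at call time.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm

from .assembly import FlowLedger, build_phenotype_frame, validate_flow_arithmetic
from .atlas import (
    adjusted_rand_index,
    ari_sweep,
    composite_similarity,
    statin_residualize,
)
from .attribution import compute_attributions, consensus_select
from .discrimination import ModelSpec, bootstrap_ci, run_nested_cv
from .preprocess import filter_missingness, make_fold_plan
from .profiling import compute_all_profiles
from .synthetic import GeneratorConfig, generate_cohort

# ---------------------------------------------------------------------------
# Reference cohort flow (the counts of the biobank-scale design this
# package emulates, used as inputs to the ledger machinery)
# ---------------------------------------------------------------------------

REFERENCE_FLOW = {
    "enrolled": 502_131,
    "removed_no_metabolomics": 227_895,
    "removed_cancer_history": 29_669,
    "final_cohort": 244_567,
    "cvd_cases": 27_950,
    "cvd_free_controls": 216_617,
    "n_classes": 37,
    "n_subclasses": 50,
}


def reference_flow_report() -> dict:
    """Recompute the reference cohort flow through the ledger machinery."""
    ledger = FlowLedger(initial=REFERENCE_FLOW["enrolled"])
    ledger.record("missing_metabolomics", REFERENCE_FLOW["removed_no_metabolomics"])
    ledger.record("exclusion_flag", REFERENCE_FLOW["removed_cancer_history"])
    report = validate_flow_arithmetic(ledger)
    final = report["final"]
    controls = final - REFERENCE_FLOW["cvd_cases"]
    n_phenotypes = REFERENCE_FLOW["n_classes"] + REFERENCE_FLOW["n_subclasses"]
    return {
        "final_cohort_n": final,
        "cvd_free_controls_n": controls,
        "phenotype_contrasts_n": n_phenotypes,
    }


# ---------------------------------------------------------------------------
# Planted-structure atlas: three phenotype groups
# ---------------------------------------------------------------------------

def atlas_study_config(
    seed: int,
    n_participants: int = 8000,
    cases_per_phenotype: int = 300,
    shared_shift: float = 1.0,
    statin_effect: float = 0.0,
    statin_prevalence_cases: float = 0.0,
    statin_prevalence_controls: float = 0.0,
    statin_prevalence_cases_by_group: dict | None = None,
) -> GeneratorConfig:
    """Cohort with three planted phenotype groups.

    Six disease classes with two subclasses each: two classes carry the
    shared lipid signature, two form a graded second arm on a disjoint
    signature, and two are metabolically null. 300 cases per subclass
    phenotype at the default size.
    """
    return GeneratorConfig(
        n_participants=n_participants,
        n_classes=6,
        subclasses_per_class=2,
        n_lipid_classes=2,
        n_gradient_classes=2,
        case_fraction_per_phenotype=cases_per_phenotype / n_participants,
        shared_signature_size=20,
        gradient_signature_size=15,
        n_specific_per_phenotype=4,
        shared_shift=shared_shift,
        specific_shift=0.8,
        block_corr=0.4,
        statin_effect=statin_effect,
        statin_prevalence_cases=statin_prevalence_cases,
        statin_prevalence_controls=statin_prevalence_controls,
        statin_prevalence_cases_by_group=statin_prevalence_cases_by_group,
        missing_rate=0.02,
        region_weights=(1.0, 0.0, 0.0),
        seed=seed,
    )


def planted_partition(cohort, frame, level: str = "subclass") -> dict[str, int]:
    """Ground-truth phenotype grouping (lipid / gradient / null)."""
    group_id = {"lipid": 0, "gradient": 1, "null": 2}
    class_group = cohort.ground_truth["class_group"]
    return {
        p: group_id[class_group[p[:3]]]
        for p in frame.phenotypes
        if frame.level[p] == level
    }


def _profiles_and_atlas(cohort, frame, matrix=None, level="subclass", tau=0.5, omega=0.5):
    if matrix is None:
        mets = cohort.metabolites().set_axis(cohort.data["participant_id"], axis=0)
        retained = filter_missingness(mets, 0.20)
        matrix = mets[retained].fillna(mets[retained].median())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = compute_all_profiles(matrix, frame, tau=tau, level=level)
        return matrix, composite_similarity(profiles, omega=omega)


def atlas_recovery_study(seeds, min_cases: int = 100) -> pd.DataFrame:
    """ARI between the k=3 cut and the planted grouping, per seed."""
    rows = []
    for seed in seeds:
        cohort = generate_cohort(atlas_study_config(seed))
        frame = build_phenotype_frame(cohort, min_cases=min_cases)
        _, atl = _profiles_and_atlas(cohort, frame)
        truth = planted_partition(cohort, frame)
        ari = adjusted_rand_index(atl.cut(3).labels, truth)
        rows.append({"seed": seed, "ari": ari})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Consensus recovery (model fits at reduced n)
# ---------------------------------------------------------------------------

def consensus_recovery_study(
    seed: int,
    n_participants: int = 6000,
    cases_per_phenotype: int = 150,
    k: int = 30,
) -> dict:
    """Recall of the planted shared signature by consensus selection.

    Combined (metabolites + clinical) L2 logistic models are fitted for every
    phenotype contrast; exact linear attributions feed top-k recurrence with
    n_min equal to the number of lipid-group contrasts.
    """
    import dataclasses

    cfg = atlas_study_config(
        seed, n_participants=n_participants, cases_per_phenotype=cases_per_phenotype
    )
    cfg = dataclasses.replace(cfg, clinical_signal_size=3, clinical_shift=0.5)
    cohort = generate_cohort(cfg)
    frame = build_phenotype_frame(cohort, min_cases=100)
    truth = cohort.ground_truth
    lipid_phenos = [
        p for p in frame.phenotypes
        if truth["class_group"][p[:3]] == "lipid"
    ]
    n_min = len(lipid_phenos)
    matrix_all = cohort.feature_matrix("combined").set_axis(
        cohort.data["participant_id"], axis=0
    )
    spec = ModelSpec("logreg", "combined", grid=[{"C": 1.0}], seed=seed)
    rng = np.random.default_rng(seed + 17)
    tables = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for p in frame.phenotypes:
            plan = make_fold_plan(cohort, frame, p, seed=seed)
            res = run_nested_cv(
                cohort, frame, p, spec, plan, bootstrap_B=50, fit_final=True
            )
            discovery = plan.discovery_ids()
            X = res.final_pipeline.transform.apply(matrix_all.loc[discovery])
            case_set = set(frame.cases[p])
            is_case = np.array([i in case_set for i in discovery])
            pick = np.concatenate([
                np.flatnonzero(is_case)[:100],
                np.flatnonzero(~is_case)[:100],
            ])
            baseline = X.iloc[rng.choice(len(X), size=100, replace=False)]
            tables[p] = compute_attributions(
                res.final_pipeline.model, X.iloc[pick], baseline, phenotype=p
            )
        consensus = consensus_select(tables, k=k, n_min=n_min, c_min=0.8)
    planted = set(truth["shared_signature"])
    recovered = planted & set(consensus.selected)
    return {
        "recall": len(recovered) / len(planted),
        "n_planted": len(planted),
        "n_selected": len(consensus.selected),
        "n_min": n_min,
        "consensus": consensus,
    }


# ---------------------------------------------------------------------------
# Null-cohort leakage detector
# ---------------------------------------------------------------------------

def null_cohort_config(seed: int, n_participants: int = 2000) -> GeneratorConfig:
    """Balanced single-phenotype cohort with no planted signal anywhere."""
    return GeneratorConfig(
        n_participants=n_participants,
        n_classes=1,
        subclasses_per_class=0,
        n_lipid_classes=1,
        n_gradient_classes=0,
        case_fraction_per_phenotype=0.5,
        shared_shift=0.0,
        specific_shift=0.0,
        n_specific_per_phenotype=0,
        shared_signature_size=20,
        gradient_signature_size=0,
        missing_rate=0.02,
        region_weights=(1.0, 0.0, 0.0),
        seed=seed,
    )


def null_auc_study(seed: int, algorithms=("logreg", "random_forest", "xgboost")) -> dict:
    """Pooled nested-CV AUC per algorithm on a pure-noise cohort."""
    cohort = generate_cohort(null_cohort_config(seed))
    frame = build_phenotype_frame(cohort, min_cases=100)
    phenotype = frame.phenotypes[0]
    plan = make_fold_plan(cohort, frame, phenotype, seed=seed)
    grids = {
        "logreg": [{"C": 1.0}],
        "random_forest": [{"n_estimators": 300, "max_depth": 8}],
        "xgboost": [{"n_estimators": 200, "max_depth": 3, "learning_rate": 0.1}],
    }
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for algo in algorithms:
            spec = ModelSpec(algo, "metabolites_only", grid=grids[algo], seed=seed)
            res = run_nested_cv(
                cohort, frame, phenotype, spec, plan,
                bootstrap_B=50, fit_final=False,
            )
            out[algo] = res.pooled_auc
    return out


# ---------------------------------------------------------------------------
# Statin robustness
# ---------------------------------------------------------------------------

def statin_null_study(seed: int, ks=range(2, 11)) -> pd.DataFrame:
    """ARI between adjusted and unadjusted partitions when statins do nothing.

    The null condition is a flag that neither affects metabolites
    (``statin_effect = 0``) nor tracks disease status (equal prevalence in
    cases and controls). Under that null the residualization coefficient is
    pure noise orthogonal to case status, so the adjusted and unadjusted
    atlases cut to identical partitions at every k. (A flag that is
    *correlated* with case status removes a case-aligned noise component and
    can legitimately perturb noise-level merge orders even with zero effect.)
    """
    cohort = generate_cohort(
        atlas_study_config(
            seed,
            statin_effect=0.0,
            statin_prevalence_cases=0.3,
            statin_prevalence_controls=0.3,
        )
    )
    frame = build_phenotype_frame(cohort, min_cases=100)
    matrix, atl = _profiles_and_atlas(cohort, frame)
    flags = cohort.data.set_index("participant_id").loc[matrix.index, "statin_flag"]
    adjusted = statin_residualize(matrix, flags.to_numpy())
    _, atl_adj = _profiles_and_atlas(cohort, frame, matrix=adjusted)
    return ari_sweep(atl, atl_adj, ks)


def statin_confounding_study(seeds, statin_effect: float = -1.0) -> pd.DataFrame:
    """Does residualization move the partition closer to the planted truth?

    Strong confounding concentrated in lipid features, with prescription
    tracking the diagnosis (heavy statin use among lipid-group and null-group
    cases, rare elsewhere): flagged participants have every lipid feature
    lowered by one log-unit, smearing a spurious lipid signature across the
    heavily-medicated phenotypes. A uniform exposure would only compress
    contrasts without reordering them; differential exposure is what biases
    the clustering. Reported per seed: ARI of the k=3 cut against the planted
    grouping, for unadjusted and statin-residualized data.
    """
    rows = []
    for seed in seeds:
        cohort = generate_cohort(
            atlas_study_config(
                seed,
                statin_effect=statin_effect,
                statin_prevalence_cases=0.05,
                statin_prevalence_controls=0.05,
                statin_prevalence_cases_by_group={"lipid": 0.6, "null": 0.6},
            )
        )
        frame = build_phenotype_frame(cohort, min_cases=100)
        matrix, atl_raw = _profiles_and_atlas(cohort, frame)
        flags = cohort.data.set_index("participant_id").loc[matrix.index, "statin_flag"]
        adjusted = statin_residualize(matrix, flags.to_numpy())
        _, atl_adj = _profiles_and_atlas(cohort, frame, matrix=adjusted)
        truth = planted_partition(cohort, frame)
        rows.append({
            "seed": seed,
            "ari_unadjusted": adjusted_rand_index(atl_raw.cut(3).labels, truth),
            "ari_adjusted": adjusted_rand_index(atl_adj.cut(3).labels, truth),
        })
    df = pd.DataFrame(rows)
    df["adjusted_closer"] = df["ari_adjusted"] > df["ari_unadjusted"]
    return df


# ---------------------------------------------------------------------------
# Bootstrap coverage
# ---------------------------------------------------------------------------

def bootstrap_coverage_study(
    seed: int,
    n_replicates: int = 100,
    n_per_group: int = 1000,
    separation: float = 1.0,
    B: int = 1000,
) -> dict:
    """Coverage of the 95% bootstrap CI for a known two-Gaussian AUC.

    With case scores N(separation, 1) and control scores N(0, 1) the true
    AUC is Phi(separation / sqrt(2)) ~= 0.760 at the default separation.
    """
    true_auc = float(norm.cdf(separation / np.sqrt(2)))
    rng = np.random.default_rng(seed)
    hits = 0
    for r in range(n_replicates):
        scores = np.concatenate([
            rng.normal(separation, 1.0, n_per_group),
            rng.normal(0.0, 1.0, n_per_group),
        ])
        labels = np.concatenate([np.ones(n_per_group), np.zeros(n_per_group)])
        lo, hi = bootstrap_ci(scores, labels, B=B, seed=seed * 100_003 + r)
        hits += int(lo <= true_auc <= hi)
    return {"covered": hits, "n_replicates": n_replicates, "true_auc": true_auc}
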