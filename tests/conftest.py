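import warnings

import numpy as np
import pandas as pd
import pytest

from metaboatlas.synthetic import CohortTable, GeneratorConfig, generate_cohort


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=FutureWarning)
        yield


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """Two lipid + one gradient + one null class, two subclasses each."""
    return GeneratorConfig(
        n_participants=1200,
        n_metabolites=40,
        n_clinical=8,
        n_classes=4,
        subclasses_per_class=2,
        n_lipid_classes=2,
        n_gradient_classes=1,
        case_fraction_per_phenotype=0.04,
        shared_signature_size=8,
        gradient_signature_size=5,
        n_specific_per_phenotype=2,
        shared_shift=1.2,
        missing_rate=0.03,
        region_weights=(0.7, 0.2, 0.1),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> CohortTable:
    return generate_cohort(small_config)


def make_manual_cohort(
    metabolites: pd.DataFrame,
    codes: list[tuple[str, ...]],
    hierarchy: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    region: list[str] | None = None,
    statin: list[bool] | None = None,
    exclusion: list[bool] | None = None,
) -> CohortTable:
    """Hand-built cohort for exact-value tests."""
    n = len(metabolites)
    data = metabolites.reset_index(drop=True).copy()
    clin_cols = []
    if clinical is not None:
        for c in clinical.columns:
            data[c] = clinical[c].to_numpy()
        clin_cols = list(clinical.columns)
    data.insert(0, "participant_id", [f"P{i:04d}" for i in range(n)])
    data["phenotype_codes"] = list(codes)
    data["region"] = region if region is not None else ["discovery"] * n
    data["statin_flag"] = statin if statin is not None else [False] * n
    data["exclusion_flag"] = exclusion if exclusion is not None else [False] * n
    return CohortTable(
        data=data,
        metabolite_cols=list(metabolites.columns),
        clinical_cols=clin_cols,
        hierarchy=hierarchy,
        ground_truth=None,
    )


@pytest.fixture
def toy_hierarchy() -> pd.DataFrame:
    return pd.DataFrame(
        [("C01", "C01S1"), ("C01", "C01S2"), ("C02", "C02S1"), ("C03", "")],
        columns=["class_code", "subclass_code"],
    )
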