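"""Disease-wise mean z-score profiles and nonparametric group comparisons.

For each phenotype contrast, every metabolite is standardized by the control
mean and SD and averaged over cases, giving the meanZ profile; features with
|meanZ| above a threshold (0.5 by default, strict inequality) form the
phenotype's altered-metabolite set. Group comparisons use the two-sided
Mann-Whitney U test with Benjamini-Hochberg FDR adjustment across the whole
requested table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .assembly import PhenotypeFrame
from .synthetic import CohortTable


class ProfilingError(ValueError):
    pass


@dataclass
class DiseaseProfile:
    """One phenotype's mean control-standardized profile."""

    phenotype: str
    mean_z: pd.Series  # indexed by metabolite name
    tau: float
    n_cases: int
    n_controls: int
    skipped: list[str] = field(default_factory=list)

    @property
    def altered_set(self) -> frozenset[str]:
        return frozenset(self.mean_z.index[self.mean_z.abs() > self.tau])


def compute_profile(
    matrix: pd.DataFrame,
    case_ids,
    control_ids,
    phenotype: str = "",
    tau: float = 0.5,
    complete_case: bool = False,
) -> DiseaseProfile:
    """meanZ profile of one phenotype against the shared control pool.

    ``matrix`` is indexed by participant id (typically median-imputed values;
    pass ``complete_case=True`` to ignore missing entries instead). The
    z-score of each value is ``(value - control mean) / control SD``; meanZ is
    its mean over cases. Zero-variance control features are skipped and
    logged.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if not case_ids:
        raise ProfilingError(f"phenotype {phenotype!r} has no cases")
    if not control_ids:
        raise ProfilingError("control pool is empty")
    cases = matrix.loc[case_ids]
    controls = matrix.loc[control_ids]
    if not complete_case and (cases.isna().any().any() or controls.isna().any().any()):
        raise ProfilingError(
            "matrix contains missing values; impute first or pass complete_case=True"
        )
    mu = controls.mean(axis=0, skipna=True)
    sd = controls.std(axis=0, ddof=0, skipna=True)
    good = sd > 0
    skipped = [c for c in matrix.columns if not good[c]]
    if skipped:
        warnings.warn(
            f"{phenotype}: skipping {len(skipped)} zero-variance control features",
            stacklevel=2,
        )
    z = (cases.loc[:, good] - mu[good]) / sd[good]
    mean_z = z.mean(axis=0, skipna=True)
    if not np.isfinite(mean_z).all():
        raise ProfilingError(f"non-finite meanZ for phenotype {phenotype!r}")
    return DiseaseProfile(
        phenotype=phenotype,
        mean_z=mean_z,
        tau=tau,
        n_cases=len(case_ids),
        n_controls=len(control_ids),
        skipped=skipped,
    )


def compute_all_profiles(
    matrix: pd.DataFrame,
    frame: PhenotypeFrame,
    tau: float = 0.5,
    level: str | None = None,
) -> dict[str, DiseaseProfile]:
    """Profiles for every retained phenotype (optionally one hierarchy level)."""
    out = {}
    for p in frame.phenotypes:
        if level is not None and frame.level[p] != level:
            continue
        out[p] = compute_profile(
            matrix, frame.cases[p], frame.controls, phenotype=p, tau=tau
        )
    return out


def profiles_to_frame(profiles: dict[str, DiseaseProfile]) -> pd.DataFrame:
    """Wide phenotypes x metabolites meanZ table (export layout)."""
    return pd.DataFrame({p: prof.mean_z for p, prof in profiles.items()}).T


def _stars(p_adj: float) -> str:
    if p_adj < 0.001:
        return "***"
    if p_adj < 0.01:
        return "**"
    if p_adj < 0.05:
        return "*"
    return ""


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone-enforced, clipped to [0,1])."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def mann_whitney_bh(
    matrix: pd.DataFrame,
    frame: PhenotypeFrame,
    metabolites: list[str] | None = None,
    phenotypes: list[str] | None = None,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per (phenotype, metabolite), BH-adjusted.

    The BH family is every cell of the requested table in a single
    correction; the family scope is recorded on the result's ``attrs``.
    U uses the tie-corrected normal approximation; all-tied comparisons get
    p = 1 with a warning.
    """
    if metabolites is None:
        metabolites = list(matrix.columns)
    if phenotypes is None:
        phenotypes = frame.phenotypes
    rows = []
    controls = matrix.loc[frame.controls]
    for p in phenotypes:
        cases = matrix.loc[frame.cases[p]]
        for met in metabolites:
            x = cases[met].dropna().to_numpy()
            y = controls[met].dropna().to_numpy()
            if len(x) == 0 or len(y) == 0:
                raise ProfilingError(
                    f"no observed values for {p}/{met} in one group"
                )
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                warnings.warn(f"{p}/{met}: all values tied; p set to 1", stacklevel=2)
                u, pval = len(x) * len(y) / 2.0, 1.0
            else:
                res = stats.mannwhitneyu(
                    x, y, alternative="two-sided", method="asymptotic",
                    use_continuity=False,
                )
                u, pval = float(res.statistic), float(res.pvalue)
            rows.append((p, met, u, min(pval, 1.0)))
    table = pd.DataFrame(rows, columns=["phenotype", "metabolite", "U", "p"])
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table["stars"] = table["p_adj"].map(_stars)
    table.attrs["bh_family"] = (
        f"{len(phenotypes)} phenotypes x {len(metabolites)} metabolites "
        f"({len(table)} cells, one correction)"
    )
    return table
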