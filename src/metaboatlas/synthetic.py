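"""Synthetic case-control metabolomics cohorts with planted structure.

The generator emulates the statistical shape of a large NMR-metabolomics
case-control cohort: right-skewed (log-normal) metabolite distributions with
block-correlated lipid panels, a class/subclass disease hierarchy with planted
per-disease mean-shift profiles (including a shared cross-disease signature),
a statin-like medication flag that perturbs lipid features, completely-at-random
missingness, and three region labels (one discovery region, two hold-outs).

All planted effects are additive on the log scale, so the expected
control-standardized mean z-score of a shifted feature has the closed form
``shift / control log-scale SD`` — the ground truth stored on the returned
cohort is sufficient to recompute that target exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

REGIONS = ("discovery", "holdout_A", "holdout_B")

#: sentinel written to delimited files for a missing numeric value
MISSING_TOKEN = "NA"
#: sentinel for an empty phenotype-code set (participant is a control)
NO_CODES_TOKEN = "-"

PHENOTYPE_GROUPS = ("lipid", "gradient", "null")


class CohortError(ValueError):
    """Raised for invalid generator configs or malformed cohort files."""


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort generator.

    Shifts are expressed in control log-scale standard-deviation units
    multiplied by the per-feature log SD, i.e. a ``shared_shift`` of 1.0
    moves case means by one control SD on the log scale.
    """

    n_participants: int = 2000
    n_metabolites: int = 325
    n_clinical: int = 66
    n_classes: int = 6
    subclasses_per_class: int = 2
    case_fraction_per_phenotype: float = 0.02
    shared_signature_size: int = 20
    shared_shift: float = 1.0
    specific_shift: float = 0.8
    n_specific_per_phenotype: int = 4
    gradient_signature_size: int = 15
    block_corr: float = 0.4
    n_blocks: int = 9
    n_lipid_blocks: int = 5
    n_lipid_classes: int | None = None
    n_gradient_classes: int | None = None
    statin_effect: float = 0.0
    statin_prevalence_cases: float = 0.0
    statin_prevalence_controls: float = 0.0
    # optional per-phenotype-group case prevalence (keys: lipid/gradient/null),
    # emulating prescription patterns that track the diagnosis
    statin_prevalence_cases_by_group: dict | None = None
    missing_rate: float = 0.0
    missing_nmr_fraction: float = 0.0
    exclusion_flag_rate: float = 0.0
    clinical_signal_size: int = 0
    clinical_shift: float = 0.0
    direct_class_case_fraction: float = 0.0
    region_weights: tuple[float, float, float] = (0.90, 0.06, 0.04)
    seed: int = 0

    def __post_init__(self) -> None:
        props = {
            "case_fraction_per_phenotype": self.case_fraction_per_phenotype,
            "statin_prevalence_cases": self.statin_prevalence_cases,
            "statin_prevalence_controls": self.statin_prevalence_controls,
            "missing_rate": self.missing_rate,
            "missing_nmr_fraction": self.missing_nmr_fraction,
            "exclusion_flag_rate": self.exclusion_flag_rate,
            "direct_class_case_fraction": self.direct_class_case_fraction,
        }
        for name, value in props.items():
            if not 0.0 <= value <= 1.0:
                raise CohortError(f"{name} must lie in [0, 1], got {value}")
        for g, v in (self.statin_prevalence_cases_by_group or {}).items():
            if g not in PHENOTYPE_GROUPS:
                raise CohortError(f"unknown phenotype group {g!r}")
            if not 0.0 <= v <= 1.0:
                raise CohortError(f"group statin prevalence must lie in [0, 1]")
        if not 0.0 <= self.block_corr < 1.0:
            raise CohortError("block_corr must lie in [0, 1)")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise CohortError("region_weights must sum to 1 within 1e-9")
        if self.shared_signature_size > self.n_metabolites:
            raise CohortError("shared_signature_size exceeds n_metabolites")
        n_lipid, n_gradient = self._class_group_counts()
        if n_lipid + n_gradient > self.n_classes:
            raise CohortError("lipid + gradient class counts exceed n_classes")
        n_pheno = self.n_classes * max(self.subclasses_per_class, 1)
        planted = (
            self.shared_signature_size
            + self.gradient_signature_size
            + n_pheno * self.n_specific_per_phenotype
        )
        if planted > self.n_metabolites:
            raise CohortError(
                f"planted features ({planted}) exceed n_metabolites "
                f"({self.n_metabolites}); shrink signatures or specifics"
            )

    def _class_group_counts(self) -> tuple[int, int]:
        n_lipid = (
            self.n_lipid_classes
            if self.n_lipid_classes is not None
            else -(-self.n_classes // 3)
        )
        n_gradient = (
            self.n_gradient_classes
            if self.n_gradient_classes is not None
            else -(-self.n_classes // 3)
        )
        return n_lipid, n_gradient


@dataclass
class CohortTable:
    """A participants-by-features cohort plus labels and provenance.

    ``data`` holds one row per participant with metabolite columns,
    clinical columns, and the label columns ``participant_id``,
    ``phenotype_codes`` (sorted tuple of hierarchy codes; empty = control),
    ``region``, ``statin_flag`` and ``exclusion_flag``.
    """

    data: pd.DataFrame
    metabolite_cols: list[str]
    clinical_cols: list[str]
    hierarchy: pd.DataFrame  # columns: class_code, subclass_code
    ground_truth: dict | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    def metabolites(self) -> pd.DataFrame:
        return self.data[self.metabolite_cols]

    def clinical(self) -> pd.DataFrame:
        return self.data[self.clinical_cols]

    def feature_matrix(self, feature_set: str) -> pd.DataFrame:
        """Return the matrix for one of the study's three feature sets."""
        if feature_set == "metabolites_only":
            cols = self.metabolite_cols
        elif feature_set == "clinical_only":
            cols = self.clinical_cols
        elif feature_set == "combined":
            cols = self.metabolite_cols + self.clinical_cols
        else:
            raise ValueError(f"unknown feature set: {feature_set!r}")
        return self.data[cols]

    def known_codes(self) -> set[str]:
        codes = set(self.hierarchy["class_code"])
        codes.update(c for c in self.hierarchy["subclass_code"] if c)
        return codes

    def is_case(self) -> pd.Series:
        return self.data["phenotype_codes"].map(bool)


def _metabolite_names(n: int) -> list[str]:
    return [f"met_{i + 1:03d}" for i in range(n)]


def _clinical_names(n: int) -> list[str]:
    return [f"clin_{i + 1:03d}" for i in range(n)]


def _block_bounds(n_features: int, n_blocks: int) -> list[tuple[int, int]]:
    sizes = np.full(n_blocks, n_features // n_blocks)
    sizes[: n_features % n_blocks] += 1
    ends = np.cumsum(sizes)
    starts = np.concatenate([[0], ends[:-1]])
    return list(zip(starts.tolist(), ends.tolist()))


def _spread(pool: np.ndarray, size: int) -> np.ndarray:
    """Evenly spaced selection from an index pool (spans all its blocks)."""
    if size == 0:
        return pool[:0]
    picks = np.unique(np.linspace(0, len(pool) - 1, size).round().astype(int))
    if len(picks) < size:  # rounding collisions: pool barely larger than size
        picks = np.arange(size)
    return pool[picks]


def build_hierarchy(n_classes: int, subclasses_per_class: int) -> pd.DataFrame:
    """Toy class -> subclass code table (two-column delimited layout)."""
    rows = []
    for c in range(1, n_classes + 1):
        cls = f"C{c:02d}"
        if subclasses_per_class == 0:
            rows.append((cls, ""))
        for s in range(1, subclasses_per_class + 1):
            rows.append((cls, f"{cls}S{s}"))
    return pd.DataFrame(rows, columns=["class_code", "subclass_code"])


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a cohort with the configured planted structure.

    Metabolites are ``exp(multivariate normal)`` with constant within-block
    correlation. Cases of each phenotype receive, on the log scale, the
    group-shared signature shift (lipid group: ``shared_shift`` with a common
    sign; gradient group: a per-class graded multiple of ``shared_shift`` on a
    second signature; null group: nothing) plus ``specific_shift`` on
    phenotype-private features. Statin-flagged participants receive
    ``statin_effect`` additively on the designated lipid features. Everything
    is reproducible from ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_participants, cfg.n_metabolites
    met_names = _metabolite_names(m)
    clin_names = _clinical_names(cfg.n_clinical)
    hierarchy = build_hierarchy(cfg.n_classes, cfg.subclasses_per_class)

    # ---- feature geometry -------------------------------------------------
    bounds = _block_bounds(m, cfg.n_blocks)
    block_of = np.empty(m, dtype=int)
    for b, (lo, hi) in enumerate(bounds):
        block_of[lo:hi] = b
    lipid_mask = block_of < cfg.n_lipid_blocks
    lipid_idx = np.flatnonzero(lipid_mask)
    nonlipid_idx = np.flatnonzero(~lipid_mask)
    if cfg.shared_signature_size > lipid_idx.size:
        raise CohortError("shared signature larger than the lipid feature pool")
    if cfg.gradient_signature_size > nonlipid_idx.size:
        raise CohortError("gradient signature larger than the non-lipid pool")
    # signatures are spread across blocks (biomarker groups), mirroring how
    # cross-disease panels span several lipoprotein/metabolite classes
    shared_idx = _spread(lipid_idx, cfg.shared_signature_size)
    gradient_idx = _spread(nonlipid_idx, cfg.gradient_signature_size)
    reserved = set(shared_idx) | set(gradient_idx)
    free_pool = [j for j in range(m) if j not in reserved]

    # ---- phenotype structure ---------------------------------------------
    classes = sorted(hierarchy["class_code"].unique())
    n_lipid_cls, n_grad_cls = cfg._class_group_counts()
    class_group = {}
    for i, cls in enumerate(classes):
        if i < n_lipid_cls:
            class_group[cls] = "lipid"
        elif i < n_lipid_cls + n_grad_cls:
            class_group[cls] = "gradient"
        else:
            class_group[cls] = "null"
    grad_classes = [c for c in classes if class_group[c] == "gradient"]
    grad_level = {
        c: lvl
        for c, lvl in zip(
            grad_classes,
            np.linspace(0.6, 1.4, max(len(grad_classes), 1)),
        )
    }

    subclass_codes = [s for s in hierarchy["subclass_code"] if s]
    phenotypes = subclass_codes if subclass_codes else classes
    specific_features: dict[str, list[int]] = {}
    cursor = 0
    for p in phenotypes:
        cls = p[:3]
        if class_group[cls] == "null":
            specific_features[p] = []
            continue
        take = free_pool[cursor : cursor + cfg.n_specific_per_phenotype]
        cursor += cfg.n_specific_per_phenotype
        specific_features[p] = take

    # ---- log-scale population parameters ----------------------------------
    log_mu = rng.normal(1.0, 0.4, size=m)
    log_sigma = rng.uniform(0.3, 0.7, size=m)

    # per-phenotype log-scale shift matrix (subclass level)
    shift = pd.DataFrame(0.0, index=phenotypes, columns=met_names)
    for p in phenotypes:
        cls = p[:3]
        group = class_group[cls]
        if group == "lipid":
            shift.iloc[
                shift.index.get_loc(p), shared_idx
            ] = cfg.shared_shift * log_sigma[shared_idx]
        elif group == "gradient":
            shift.iloc[shift.index.get_loc(p), gradient_idx] = (
                grad_level[cls] * cfg.shared_shift * log_sigma[gradient_idx]
            )
        for j in specific_features[p]:
            sign = 1.0 if (j % 2 == 0) else -1.0
            shift.iloc[shift.index.get_loc(p), j] = (
                sign * cfg.specific_shift * log_sigma[j]
            )

    # ---- case assignment ---------------------------------------------------
    ids = np.array([f"P{i + 1:06d}" for i in range(n)])
    order = rng.permutation(n)
    n_cases_each = int(round(cfg.case_fraction_per_phenotype * n))
    codes: list[tuple[str, ...]] = [() for _ in range(n)]
    assigned_phenotype = np.full(n, "", dtype=object)
    pos = 0
    for p in phenotypes:
        take = order[pos : pos + n_cases_each]
        pos += n_cases_each
        if pos > n:
            raise CohortError("case fractions exceed the cohort size")
        n_direct = int(round(cfg.direct_class_case_fraction * len(take)))
        for k, i in enumerate(take):
            cls = p[:3]
            code = cls if (k < n_direct and p != cls) else p
            codes[i] = (code,)
            assigned_phenotype[i] = p

    # ---- draw metabolites --------------------------------------------------
    rho = cfg.block_corr
    latent = np.empty((n, m))
    for b, (lo, hi) in enumerate(bounds):
        shared_factor = rng.standard_normal((n, 1))
        eps = rng.standard_normal((n, hi - lo))
        latent[:, lo:hi] = np.sqrt(rho) * shared_factor + np.sqrt(1 - rho) * eps
    log_x = log_mu + log_sigma * latent
    for p in phenotypes:
        rows = np.flatnonzero(assigned_phenotype == p)
        if rows.size:
            log_x[rows] += shift.loc[p].to_numpy()

    # statin flag: additive perturbation of lipid features on the log scale
    is_case = assigned_phenotype != ""
    statin_p = np.where(
        is_case, cfg.statin_prevalence_cases, cfg.statin_prevalence_controls
    )
    if cfg.statin_prevalence_cases_by_group:
        for i in np.flatnonzero(is_case):
            group = class_group[assigned_phenotype[i][:3]]
            if group in cfg.statin_prevalence_cases_by_group:
                statin_p[i] = cfg.statin_prevalence_cases_by_group[group]
    statin_flag = rng.random(n) < statin_p
    statin_vec = np.zeros(m)
    statin_vec[lipid_idx] = cfg.statin_effect
    log_x[statin_flag] += statin_vec

    metabolites = np.exp(log_x)

    # ---- clinical features ---------------------------------------------------
    clinical = rng.standard_normal((n, cfg.n_clinical))
    if cfg.clinical_signal_size > 0:
        k = min(cfg.clinical_signal_size, cfg.n_clinical)
        clinical[is_case, :k] += cfg.clinical_shift

    # ---- labels, missingness --------------------------------------------------
    region = rng.choice(REGIONS, size=n, p=list(cfg.region_weights))
    exclusion_flag = rng.random(n) < cfg.exclusion_flag_rate
    no_nmr = rng.random(n) < cfg.missing_nmr_fraction
    if cfg.missing_rate > 0:
        metabolites[rng.random((n, m)) < cfg.missing_rate] = np.nan
        clinical[rng.random((n, cfg.n_clinical)) < cfg.missing_rate] = np.nan
    metabolites[no_nmr] = np.nan

    data = pd.DataFrame(metabolites, columns=met_names)
    data[clin_names] = clinical
    data.insert(0, "participant_id", ids)
    data["phenotype_codes"] = codes
    data["region"] = region
    data["statin_flag"] = statin_flag
    data["exclusion_flag"] = exclusion_flag

    ground_truth = {
        "shift": shift,
        "log_mu": pd.Series(log_mu, index=met_names),
        "log_sigma": pd.Series(log_sigma, index=met_names),
        "shared_signature": [met_names[j] for j in shared_idx],
        "gradient_signature": [met_names[j] for j in gradient_idx],
        "specific_features": {
            p: [met_names[j] for j in specific_features[p]] for p in phenotypes
        },
        "lipid_features": [met_names[j] for j in lipid_idx],
        "block_of": pd.Series(block_of, index=met_names),
        "class_group": class_group,
        "gradient_level": grad_level,
        "statin_effect": cfg.statin_effect,
        "config": asdict(cfg),
    }
    return CohortTable(
        data=data,
        metabolite_cols=met_names,
        clinical_cols=clin_names,
        hierarchy=hierarchy,
        ground_truth=ground_truth,
    )


# --------------------------------------------------------------------------
# File round-trip
# --------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    """Write a cohort as TSV (plus ``<stem>.hierarchy.tsv`` sidecar).

    Missing numeric values are written as the explicit token ``NA``; an empty
    phenotype-code set is written as ``-``.
    """
    path = Path(path)
    out = cohort.data.copy()
    out["phenotype_codes"] = [
        ";".join(c) if c else NO_CODES_TOKEN for c in out["phenotype_codes"]
    ]
    out.to_csv(path, sep="\t", index=False, na_rep=MISSING_TOKEN)
    cohort.hierarchy.to_csv(
        path.with_suffix(".hierarchy.tsv"), sep="\t", index=False
    )


def read_cohort(
    path: str | Path, hierarchy_path: str | Path | None = None
) -> CohortTable:
    """Read a cohort TSV written by :func:`write_cohort`.

    Raises :class:`CohortError` naming the offending row/column on duplicate
    participant ids, unknown phenotype codes, or a malformed header.
    """
    path = Path(path)
    if hierarchy_path is None:
        hierarchy_path = path.with_suffix(".hierarchy.tsv")
    hierarchy = pd.read_csv(hierarchy_path, sep="\t", dtype=str).fillna("")
    df = pd.read_csv(
        path, sep="\t", na_values=[MISSING_TOKEN], keep_default_na=False
    )
    required = {"participant_id", "phenotype_codes", "region", "statin_flag"}
    missing = required - set(df.columns)
    if missing:
        raise CohortError(f"malformed header: missing columns {sorted(missing)}")
    dupes = df["participant_id"][df["participant_id"].duplicated()]
    if len(dupes):
        raise CohortError(f"duplicate participant_id: {dupes.iloc[0]!r}")

    known = set(hierarchy["class_code"])
    known.update(c for c in hierarchy["subclass_code"] if c)
    parsed = []
    for row_i, raw in enumerate(df["phenotype_codes"]):
        if pd.isna(raw) or raw == NO_CODES_TOKEN or raw == "":
            parsed.append(())
            continue
        codes = tuple(sorted(str(raw).split(";")))
        for c in codes:
            if c not in known:
                raise CohortError(
                    f"unknown phenotype code {c!r} at row {row_i} "
                    f"(participant {df['participant_id'].iloc[row_i]})"
                )
        parsed.append(codes)
    df["phenotype_codes"] = parsed
    df["statin_flag"] = df["statin_flag"].astype(bool)
    if "exclusion_flag" in df.columns:
        df["exclusion_flag"] = df["exclusion_flag"].astype(bool)

    met_cols = [c for c in df.columns if c.startswith("met_")]
    clin_cols = [c for c in df.columns if c.startswith("clin_")]
    if len(set(met_cols)) != len(met_cols):
        raise CohortError("duplicate metabolite column names")
    return CohortTable(
        data=df,
        metabolite_cols=met_cols,
        clinical_cols=clin_cols,
        hierarchy=hierarchy,
        ground_truth=None,
    )


def write_hierarchy(hierarchy: pd.DataFrame, path: str | Path) -> None:
    hierarchy.to_csv(path, sep="\t", index=False)


def read_hierarchy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if list(df.columns[:2]) != ["class_code", "subclass_code"]:
        raise CohortError(
            "hierarchy file must have columns class_code, subclass_code"
        )
    return df
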