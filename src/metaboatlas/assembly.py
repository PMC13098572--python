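"""Cohort exclusions, phenotype case/control framing, and flow accounting.

Exclusions follow the study design of a prevalent-disease case-control
cohort: participants lacking metabolomics are removed first, then those with
the generic exclusion flag (a cancer-history stand-in), and every step is
recorded in an auditable flow ledger. Phenotype contrasts are built at both
hierarchy levels; a class's cases are the union of its subclass cases plus
directly-coded cases, and the control pool is the globally phenotype-free
participants, shared across all contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import CohortTable


class AssemblyError(ValueError):
    pass


@dataclass
class ExclusionCriteria:
    require_metabolomics: bool = True
    exclude_flagged: bool = True
    min_cases_per_phenotype: int = 100

    def __post_init__(self) -> None:
        if self.min_cases_per_phenotype < 1:
            raise AssemblyError("min_cases_per_phenotype must be >= 1")


@dataclass
class FlowLedger:
    """Ordered record of exclusion steps: (label, n_removed, n_remaining)."""

    initial: int
    steps: list[tuple[str, int, int]] = field(default_factory=list)

    def record(self, label: str, n_removed: int) -> None:
        remaining = self.remaining - n_removed
        self.steps.append((label, int(n_removed), int(remaining)))

    @property
    def remaining(self) -> int:
        return self.steps[-1][2] if self.steps else self.initial

    def check_balance(self) -> None:
        expected = self.initial
        for label, removed, remaining in self.steps:
            expected -= removed
            if remaining != expected:
                raise AssemblyError(
                    f"flow ledger imbalance at step {label!r}: "
                    f"recorded remaining {remaining}, expected {expected}"
                )
        if self.remaining > self.initial:
            raise AssemblyError("flow ledger remaining exceeds initial count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.steps, columns=["step", "n_removed", "n_remaining"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_exclusions(
    cohort: CohortTable, criteria: ExclusionCriteria
) -> tuple[CohortTable, FlowLedger]:
    """Apply exclusion steps in study order and return the trimmed cohort.

    A participant hit by several criteria is removed once, at the first
    applicable step. "Lacking metabolomics" means every metabolite field is
    missing; partial missingness is handled later by the 20% feature filter.
    """
    df = cohort.data
    ledger = FlowLedger(initial=len(df))
    keep = pd.Series(True, index=df.index)

    if criteria.require_metabolomics:
        lacking = df[cohort.metabolite_cols].isna().all(axis=1) & keep
        ledger.record("missing_metabolomics", int(lacking.sum()))
        keep &= ~lacking
    if criteria.exclude_flagged:
        if "exclusion_flag" not in df.columns:
            raise AssemblyError("cohort lacks an exclusion_flag column")
        flagged = df["exclusion_flag"].astype(bool) & keep
        ledger.record("exclusion_flag", int(flagged.sum()))
        keep &= ~flagged

    ledger.check_balance()
    if keep.sum() == 0:
        warnings.warn("all participants excluded", stacklevel=2)
    trimmed = CohortTable(
        data=df[keep].reset_index(drop=True),
        metabolite_cols=cohort.metabolite_cols,
        clinical_cols=cohort.clinical_cols,
        hierarchy=cohort.hierarchy,
        ground_truth=cohort.ground_truth,
    )
    return trimmed, ledger


@dataclass
class PhenotypeFrame:
    """Case/control contrasts per retained phenotype (class and subclass).

    ``cases`` maps phenotype code -> sorted participant ids; ``level`` maps
    phenotype code -> "class" or "subclass". ``controls`` is the shared pool
    of phenotype-free participants.
    """

    cases: dict[str, list[str]]
    controls: list[str]
    level: dict[str, str]
    dropped: list[tuple[str, int]] = field(default_factory=list)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.cases)

    def n_contrasts(self) -> int:
        return len(self.cases)

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.phenotypes:
            for pid in self.cases[p]:
                rows.append((p, self.level[p], pid, "case"))
        return pd.DataFrame(
            rows, columns=["phenotype", "level", "participant_id", "role"]
        )


def _validate_hierarchy(hierarchy: pd.DataFrame) -> dict[str, str]:
    """Return subclass -> class map; reject orphan or cyclic entries."""
    classes = set(hierarchy["class_code"])
    parent: dict[str, str] = {}
    for _, row in hierarchy.iterrows():
        sub = row["subclass_code"]
        if not sub:
            continue
        if sub in classes:
            raise AssemblyError(
                f"hierarchy code {sub!r} appears as both class and subclass"
            )
        if sub in parent and parent[sub] != row["class_code"]:
            raise AssemblyError(f"subclass {sub!r} has multiple parents")
        parent[sub] = row["class_code"]
    return parent


def build_phenotype_frame(
    cohort: CohortTable,
    hierarchy: pd.DataFrame | None = None,
    min_cases: int = 100,
) -> PhenotypeFrame:
    """One case/control contrast per retained class and subclass.

    A class's case set is the union of its subclass case sets plus
    participants coded directly at class level. Phenotypes with fewer than
    ``min_cases`` cases are dropped ("fewer than" is strict: exactly
    ``min_cases`` is retained). Controls are all phenotype-free participants.
    """
    if hierarchy is None:
        hierarchy = cohort.hierarchy
    parent = _validate_hierarchy(hierarchy)
    classes = sorted(set(hierarchy["class_code"]))
    subclasses = sorted(parent)

    df = cohort.data
    case_sets: dict[str, set[str]] = {p: set() for p in classes + subclasses}
    coded = df["phenotype_codes"].map(bool)
    for pid, codes in zip(df["participant_id"], df["phenotype_codes"]):
        for code in codes:
            if code in parent:  # subclass: also counts toward its class
                case_sets[code].add(pid)
                case_sets[parent[code]].add(pid)
            elif code in case_sets:
                case_sets[code].add(pid)
            else:
                raise AssemblyError(f"phenotype code {code!r} not in hierarchy")

    controls = sorted(df.loc[~coded, "participant_id"])
    cases, level, dropped = {}, {}, []
    for p in classes + subclasses:
        n_cases = len(case_sets[p])
        if n_cases < min_cases:
            dropped.append((p, n_cases))
            continue
        cases[p] = sorted(case_sets[p])
        level[p] = "subclass" if p in parent else "class"
    return PhenotypeFrame(cases=cases, controls=controls, level=level, dropped=dropped)


def validate_flow_arithmetic(
    ledger: FlowLedger,
    expected_final: int | None = None,
    expected_steps: list[int] | None = None,
) -> dict:
    """Assert ledger arithmetic balances; cross-check expected counts.

    Returns a report dict with the recomputed final count. Imbalance is a
    hard error.
    """
    ledger.check_balance()
    final = ledger.initial - sum(s[1] for s in ledger.steps)
    if final != ledger.remaining:
        raise AssemblyError("ledger remaining disagrees with recomputed final")
    if expected_steps is not None:
        recorded = [s[1] for s in ledger.steps]
        if recorded != list(expected_steps):
            raise AssemblyError(
                f"step removals {recorded} differ from expected {expected_steps}"
            )
    if expected_final is not None and final != expected_final:
        raise AssemblyError(
            f"final count {final} differs from expected {expected_final}"
        )
    return {
        "initial": ledger.initial,
        "removed": [s[1] for s in ledger.steps],
        "final": final,
        "balanced": True,
    }
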