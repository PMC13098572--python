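"""Config-driven end-to-end runs with caching, logging, and a run manifest.

Stage order: generate/ingest -> assembly -> preprocessing -> profiling ->
atlas -> discrimination -> consensus -> parsimonious re-evaluation ->
medication robustness. Each stage's in-memory outputs are cached on disk
keyed by a hash of the stages' configuration, so the expensive discrimination
stage is skippable while iterating on the atlas; all tabular artifacts are
TSV, dendrograms Newick, and the manifest JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assembly import (
    ExclusionCriteria,
    apply_exclusions,
    build_phenotype_frame,
    validate_flow_arithmetic,
)
from .atlas import SimilarityAtlas, ari_sweep, composite_similarity, statin_residualize
from .attribution import (
    compute_attributions,
    consensus_select,
    sankey_edges,
)
from .discrimination import ModelSpec, run_nested_cv
from .preprocess import filter_missingness, make_fold_plan
from .profiling import compute_all_profiles, mann_whitney_bh, profiles_to_frame
from .synthetic import CohortTable, GeneratorConfig, generate_cohort, read_cohort

log = logging.getLogger("metaboatlas")

STAGES = (
    "cohort",
    "assembly",
    "preprocess",
    "profile",
    "cluster",
    "discriminate",
    "consensus",
    "subset",
    "robustness",
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int
    output_dir: str
    generator: dict | None = None
    input_cohort: str | None = None
    input_hierarchy: str | None = None
    exclusions: dict = field(default_factory=dict)
    preprocessing: dict = field(default_factory=dict)
    profiling: dict = field(default_factory=dict)
    atlas: dict = field(default_factory=dict)
    discrimination: dict = field(default_factory=dict)
    consensus: dict = field(default_factory=dict)
    robustness: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        if "seed" not in raw:
            raise ConfigError("config must set an explicit top-level seed")
        if "output_dir" not in raw:
            raise ConfigError("config must set output_dir")
        if raw.get("generator") is None and raw.get("input_cohort") is None:
            raise ConfigError("config needs either a generator block or input_cohort")
        if raw.get("input_cohort") and not Path(raw["input_cohort"]).exists():
            raise ConfigError(f"input_cohort not found: {raw['input_cohort']}")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return {
            f: getattr(self, f) for f in self.__dataclass_fields__
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str]) -> None:
        self.stages[stage] = {
            "outputs": outputs,
            "timestamp": time.time(),
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {
                "config_hash": self.config_hash,
                "version": self.version,
                "stages": self.stages,
            },
            indent=1,
        ))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


class _Cache:
    def __init__(self, root: Path, config_hash: str):
        self.dir = root / "cache"
        self.dir.mkdir(parents=True, exist_ok=True)
        self.config_hash = config_hash

    def path(self, stage: str) -> Path:
        return self.dir / f"{stage}_{self.config_hash}.pkl"

    def load(self, stage: str):
        p = self.path(stage)
        if p.exists():
            log.info("stage %s: loaded from cache", stage)
            with open(p, "rb") as fh:
                return pickle.load(fh)
        return None

    def store(self, stage: str, obj) -> None:
        with open(self.path(stage), "wb") as fh:
            pickle.dump(obj, fh)


def _write_matrix(df: pd.DataFrame, path: Path) -> str:
    df.to_csv(path, sep="\t")
    return _checksum(path)


def run_pipeline(config: RunConfig, until: str = "robustness") -> tuple[RunManifest, dict]:
    """Execute the pipeline through ``until`` (inclusive).

    Returns the manifest plus a dict of in-memory stage results. Any stage
    failure propagates with the stage name prepended.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__)
    cache = _Cache(out, config.config_hash())
    results: dict = {}
    last = STAGES.index(until)

    for stage in STAGES[: last + 1]:
        try:
            _run_stage(stage, config, cache, manifest, results, out)
        except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest.write(out / "manifest.json")
    return manifest, results


def _run_stage(stage, config, cache, manifest, results, out: Path) -> None:
    cached = cache.load(stage)
    if cached is not None:
        results.update(cached)
        manifest.record(stage, cached.get("_outputs", {}))
        return
    produced: dict = {}
    outputs: dict[str, str] = {}

    if stage == "cohort":
        if config.generator is not None:
            gen = GeneratorConfig(**{**config.generator, "seed": config.seed})
            produced["cohort"] = generate_cohort(gen)
        else:
            produced["cohort"] = read_cohort(
                config.input_cohort, config.input_hierarchy
            )

    elif stage == "assembly":
        crit = ExclusionCriteria(**config.exclusions)
        cohort, ledger = apply_exclusions(results["cohort"], crit)
        validate_flow_arithmetic(ledger)
        frame = build_phenotype_frame(
            cohort, min_cases=crit.min_cases_per_phenotype
        )
        ledger.write(out / "flow_ledger.tsv")
        frame.to_long_frame().to_csv(out / "phenotype_frame.tsv", sep="\t", index=False)
        outputs["flow_ledger"] = _checksum(out / "flow_ledger.tsv")
        outputs["phenotype_frame"] = _checksum(out / "phenotype_frame.tsv")
        produced.update({"analysis_cohort": cohort, "ledger": ledger, "frame": frame})

    elif stage == "preprocess":
        cohort = results["analysis_cohort"]
        thr = config.preprocessing.get("missingness_threshold", 0.20)
        mets = cohort.metabolites().set_axis(cohort.data["participant_id"], axis=0)
        clin = cohort.clinical().set_axis(cohort.data["participant_id"], axis=0)
        retained_mets = filter_missingness(mets, thr)
        retained_clin = filter_missingness(clin, thr)
        # global-median imputation for the descriptive (non-CV) stages
        imputed = mets[retained_mets].fillna(mets[retained_mets].median())
        (out / "retained_features.tsv").write_text(
            "\n".join(retained_mets + retained_clin) + "\n"
        )
        outputs["retained_features"] = _checksum(out / "retained_features.tsv")
        produced.update(
            {
                "retained_metabolites": retained_mets,
                "retained_clinical": retained_clin,
                "imputed_metabolites": imputed,
            }
        )

    elif stage == "profile":
        tau = config.profiling.get("tau", 0.5)
        profiles = compute_all_profiles(
            results["imputed_metabolites"], results["frame"], tau=tau
        )
        wide = profiles_to_frame(profiles)
        outputs["profiles"] = _write_matrix(wide, out / "mean_z_profiles.tsv")
        produced["profiles"] = profiles

    elif stage == "cluster":
        omega = config.atlas.get("omega", 0.5)
        frame = results["frame"]
        atlases = {}
        for level in ("class", "subclass"):
            profs = {
                p: prof
                for p, prof in results["profiles"].items()
                if frame.level[p] == level
            }
            if len(profs) < 2:
                continue
            atl = composite_similarity(profs, omega=omega)
            atlases[level] = atl
            for name, mat in (("S", atl.S), ("J", atl.J), ("R", atl.R_rescaled), ("D", atl.D)):
                outputs[f"{level}_{name}"] = _write_matrix(
                    mat, out / f"atlas_{level}_{name}.tsv"
                )
            (out / f"atlas_{level}.nwk").write_text(atl.dendrogram.to_newick() + "\n")
            outputs[f"{level}_newick"] = _checksum(out / f"atlas_{level}.nwk")
            cuts = []
            for k in config.robustness.get("ks", range(2, 11)):
                if k > len(atl.phenotypes):
                    continue
                part = atl.cut(k)
                cuts += [(k, p, lab) for p, lab in sorted(part.labels.items())]
            pd.DataFrame(cuts, columns=["k", "phenotype", "cluster"]).to_csv(
                out / f"atlas_{level}_partitions.tsv", sep="\t", index=False
            )
            outputs[f"{level}_partitions"] = _checksum(
                out / f"atlas_{level}_partitions.tsv"
            )
        produced["atlases"] = atlases

    elif stage == "discriminate":
        produced.update(_discriminate(config, results))
        table = pd.DataFrame([r.to_row() for r in produced["disc_results"].values()])
        table.to_csv(out / "discrimination.tsv", sep="\t", index=False)
        outputs["discrimination"] = _checksum(out / "discrimination.tsv")

    elif stage == "consensus":
        produced.update(_consensus(config, results))
        cfs = produced["consensus_set"]
        cfs.write(out / "consensus_features.txt", seed=config.seed)
        produced["sankey"].to_csv(out / "sankey_edges.tsv", sep="\t", index=False)
        outputs["consensus"] = _checksum(out / "consensus_features.txt")
        outputs["sankey"] = _checksum(out / "sankey_edges.tsv")
        # nonparametric comparisons for the most recurrent consensus metabolites
        top_recurrent = sorted(
            (f for f in cfs.selected if f in set(results["retained_metabolites"])),
            key=lambda f: (-cfs.counts[f], f),
        )[: config.consensus.get("n_comparison_metabolites", 5)]
        if top_recurrent:
            comparison = mann_whitney_bh(
                results["imputed_metabolites"], results["frame"],
                metabolites=top_recurrent,
            )
            comparison.to_csv(out / "comparison_table.tsv", sep="\t", index=False)
            outputs["comparisons"] = _checksum(out / "comparison_table.tsv")
            produced["comparison_table"] = comparison

    elif stage == "subset":
        produced.update(_subset_eval(config, results))
        if produced.get("subset_results") is not None:
            produced["subset_results"].to_csv(
                out / "subset_discrimination.tsv", sep="\t", index=False
            )
            outputs["subset"] = _checksum(out / "subset_discrimination.tsv")

    elif stage == "robustness":
        produced.update(_robustness(config, results))
        produced["ari_table"].to_csv(out / "statin_ari.tsv", sep="\t", index=False)
        outputs["statin_ari"] = _checksum(out / "statin_ari.tsv")

    produced["_outputs"] = outputs
    results.update(produced)
    cache.store(stage, produced)
    manifest.record(stage, outputs)
    log.info("stage %s: done", stage)


def _specs_from_config(config: RunConfig) -> list[ModelSpec]:
    disc = config.discrimination
    algorithms = disc.get("algorithms", ["logreg", "random_forest", "xgboost"])
    feature_sets = disc.get(
        "feature_sets", ["metabolites_only", "clinical_only", "combined"]
    )
    grids = disc.get("grids", {})
    return [
        ModelSpec(
            algorithm=a,
            feature_set=fs,
            grid=[dict(g) for g in grids.get(a, [])],
            seed=config.seed,
        )
        for a in algorithms
        for fs in feature_sets
    ]


def _phenotype_list(config: RunConfig, frame) -> list[str]:
    disc = config.discrimination
    level = disc.get("phenotype_level")
    phenos = [
        p for p in frame.phenotypes if level is None or frame.level[p] == level
    ]
    limit = disc.get("max_phenotypes")
    return phenos[:limit] if limit else phenos


def _discriminate(config: RunConfig, results: dict) -> dict:
    cohort = results["analysis_cohort"]
    frame = results["frame"]
    disc = config.discrimination
    retained = results["retained_metabolites"] + results["retained_clinical"]
    specs = _specs_from_config(config)
    disc_results, plans = {}, {}
    for phenotype in _phenotype_list(config, frame):
        plan = make_fold_plan(
            cohort, frame, phenotype,
            n_outer=disc.get("n_outer", 5),
            n_inner=disc.get("n_inner", 5),
            seed=config.seed,
        )
        plans[phenotype] = plan
        for spec in specs:
            res = run_nested_cv(
                cohort, frame, phenotype, spec, plan,
                retained_features=retained,
                bootstrap_B=disc.get("bootstrap_B", 1000),
                epv_threshold=disc.get("epv_threshold", 5.0),
            )
            disc_results[(phenotype, spec.spec_id)] = res
    return {"disc_results": disc_results, "fold_plans": plans}


def _consensus(config: RunConfig, results: dict) -> dict:
    """Attributions from combined models (best algorithm per phenotype)."""
    cons = config.consensus
    cohort = results["analysis_cohort"]
    disc_results = results["disc_results"]
    rng = np.random.default_rng(config.seed + 3)
    max_explained = cons.get("max_explained", 200)
    tables = {}
    combined = {
        key: r for key, r in disc_results.items() if r.feature_set == "combined"
    }
    phenotypes = sorted({key[0] for key in combined})
    matrix_all = cohort.feature_matrix("combined").set_axis(
        cohort.data["participant_id"], axis=0
    )
    for phenotype in phenotypes:
        candidates = [r for key, r in combined.items() if key[0] == phenotype]
        best = max(candidates, key=lambda r: float(np.mean(r.fold_aucs)))
        pipeline = best.final_pipeline
        plan = results["fold_plans"][phenotype]
        discovery = plan.discovery_ids()
        X_all = pipeline.transform.apply(matrix_all.loc[discovery])
        case_set = set(results["frame"].cases[phenotype])
        is_case = np.array([i in case_set for i in discovery])
        expl_cases = np.flatnonzero(is_case)
        expl_ctrls = np.flatnonzero(~is_case)
        half = max_explained // 2
        pick = np.concatenate([
            rng.choice(expl_cases, size=min(half, len(expl_cases)), replace=False),
            rng.choice(expl_ctrls, size=min(half, len(expl_ctrls)), replace=False),
        ])
        baseline_idx = rng.choice(
            len(discovery), size=min(100, len(discovery)), replace=False
        )
        tables[phenotype] = compute_attributions(
            pipeline.model,
            X_all.iloc[np.sort(pick)],
            X_all.iloc[np.sort(baseline_idx)],
            phenotype=phenotype,
            seed=config.seed + 5,
        )
    cfs = consensus_select(
        tables,
        k=cons.get("k", 30),
        n_min=cons.get("n_min", 10),
        c_min=cons.get("c_min", 0.8),
    )
    frame = results["frame"]
    edges = sankey_edges(
        tables, cfs, phenotype_category={p: frame.level[p] for p in phenotypes}
    )
    return {"attribution_tables": tables, "consensus_set": cfs, "sankey": edges}


def _subset_eval(config: RunConfig, results: dict) -> dict:
    cfs = results["consensus_set"]
    subset = [f for f in cfs.selected if f in set(results["retained_metabolites"])]
    if not subset:
        log.warning("consensus set contains no metabolites; subset stage skipped")
        return {"subset_results": None}
    cohort = results["analysis_cohort"]
    frame = results["frame"]
    disc = config.discrimination
    rows = []
    specs = [
        s for s in _specs_from_config(config) if s.feature_set == "metabolites_only"
    ]
    for phenotype, plan in results["fold_plans"].items():
        for spec in specs:
            res = run_nested_cv(
                cohort, frame, phenotype, spec, plan,
                retained_features=results["retained_metabolites"],
                feature_subset=subset,
                bootstrap_B=disc.get("bootstrap_B", 1000),
                fit_final=False,
            )
            row = res.to_row()
            full = results["disc_results"].get((phenotype, spec.spec_id))
            if full is not None:
                row["delta_auc_vs_full"] = res.pooled_auc - full.pooled_auc
            rows.append(row)
    return {"subset_results": pd.DataFrame(rows)}


def _robustness(config: RunConfig, results: dict) -> dict:
    cohort = results["analysis_cohort"]
    frame = results["frame"]
    imputed = results["imputed_metabolites"]
    flags = cohort.data.set_index("participant_id").loc[imputed.index, "statin_flag"]
    adjusted = statin_residualize(imputed, flags.to_numpy())
    tau = config.profiling.get("tau", 0.5)
    omega = config.atlas.get("omega", 0.5)
    ks = config.robustness.get("ks", list(range(2, 11)))
    rows = []
    atlases_adj = {}
    for level, atl in results["atlases"].items():
        profs_adj = compute_all_profiles(adjusted, frame, tau=tau, level=level)
        atl_adj = composite_similarity(profs_adj, omega=omega)
        atlases_adj[level] = atl_adj
        sweep = ari_sweep(atl, atl_adj, ks)
        sweep.insert(0, "level", level)
        rows.append(sweep)
    return {
        "ari_table": pd.concat(rows, ignore_index=True),
        "adjusted_atlases": atlases_adj,
        "adjusted_matrix": adjusted,
    }
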