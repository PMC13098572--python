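# metaboatlas

A toolkit for building **case-control metabolomic atlases**: given a cohort
of participants with a high-dimensional metabolite panel (NMR-style), a
class/subclass disease hierarchy, medication flags and region labels, it

1. applies study exclusions with an arithmetic-checked cohort-flow ledger,
2. computes **disease-wise metabolic profiles** — for each disease, the mean
   over cases of control-standardized metabolite values (meanZ) and the set
   of altered metabolites (|meanZ| > 0.5),
3. organizes diseases by the **composite inter-disease similarity**

   *S = ω·J + (1−ω)·R′*,  ω = 0.5,

   where *J* is the Jaccard overlap of altered-metabolite sets and *R′* is
   the Spearman correlation of meanZ profiles rescaled to [0, 1], followed by
   complete-linkage clustering of *D = 1 − S* with fully deterministic
   tie-breaking,
4. fits **nested cross-validated discrimination models** (logistic
   regression, random forest, gradient boosting × metabolites-only /
   clinical-only / combined feature sets) with leakage-safe fold-wise
   preprocessing, geographic hold-out validation, 1,000-iteration bootstrap
   CIs and events-per-variable (EPV) warnings,
5. selects **cross-disease consensus features** from Shapley attributions
   (top-30 recurrence across ≥ 10 conditions with consistent direction) and
   re-evaluates parsimonious models restricted to that panel, and
6. probes **medication robustness** by statin residualization and the
   Adjusted Rand Index between adjusted and unadjusted disease clusterings.

It is aimed at biostatisticians and epidemiologists who want the full
pipeline — including a synthetic-cohort generator with planted ground truth —
as tested, reusable code rather than one-off analysis scripts. Real cohort
data (e.g. biobank NMR panels) are read from delimited text; everything can
also run end-to-end on generated data.

## Worked example

Generate a cohort with three planted disease groups (a lipid-signature
group, a graded second arm, and a metabolically null group), profile it, and
cluster the diseases:

```python
from metaboatlas import (
    GeneratorConfig, generate_cohort, build_phenotype_frame,
    filter_missingness, compute_all_profiles, composite_similarity,
    adjusted_rand_index,
)

config = GeneratorConfig(
    n_participants=4000, n_classes=3, subclasses_per_class=2,
    n_lipid_classes=1, n_gradient_classes=1,
    case_fraction_per_phenotype=0.05, shared_shift=1.2,
    missing_rate=0.02, region_weights=(1.0, 0.0, 0.0), seed=7,
)
cohort = generate_cohort(config)
frame = build_phenotype_frame(cohort, min_cases=100)

mets = cohort.metabolites().set_axis(cohort.data["participant_id"], axis=0)
retained = filter_missingness(mets, threshold=0.20)
imputed = mets[retained].fillna(mets[retained].median())

profiles = compute_all_profiles(imputed, frame, tau=0.5, level="subclass")
atlas = composite_similarity(profiles, omega=0.5)
print(atlas.S.round(2))
partition = atlas.cut(3)
print(partition.labels)
print(adjusted_rand_index(partition.labels, {p: p[:3] for p in atlas.phenotypes}))
```

Output:

```
       C01S1  C01S2  C02S1  C02S2  C03S1  C03S2
C01S1   1.00   0.65   0.30   0.25   0.27   0.28
C01S2   0.65   1.00   0.24   0.27   0.24   0.24
C02S1   0.30   0.24   1.00   0.63   0.26   0.28
C02S2   0.25   0.27   0.63   1.00   0.24   0.23
C03S1   0.27   0.24   0.26   0.24   1.00   0.74
C03S2   0.28   0.24   0.28   0.23   0.74   1.00

{'C01S1': 0, 'C01S2': 0, 'C02S1': 1, 'C02S2': 1, 'C03S1': 2, 'C03S2': 2}
1.0
```

Within-group similarities (0.63–0.74) stand far above between-group ones
(≈ 0.25), so the k = 3 dendrogram cut recovers the planted grouping exactly
(ARI = 1.0). The null group coheres through identical (empty) altered sets;
the lipid and gradient groups through their shared signatures.

The same pipeline is available from the shell, driven by a YAML config:

```
metaboatlas run-all --config config.yaml      # or: simulate | assemble |
                                              # profile | cluster | discriminate |
                                              # consensus | robustness
```

Each stage writes TSV artifacts (flow ledger, meanZ profiles, S/J/R′/D
matrices, Newick dendrograms, discrimination metrics, consensus panel,
Sankey edge table, statin-ARI sweep) plus a JSON manifest with per-stage
checksums; stages are cached by config hash so the expensive discrimination
stage is skipped while iterating on the atlas.

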