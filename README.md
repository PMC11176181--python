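# moclust — multi-omics prognostic subtyping of tumor cohorts

`moclust` is an analysis pipeline for integrating transcriptomic,
proteomic and metabolomic tumor profiles into shared latent factors,
screening those factors for survival association, clustering patients
into prognostic **multi-omics clusters (MOCs)**, transferring the
cluster labels to external cohorts that share only part of the assays,
and characterizing the clusters by differential features and gene-set
enrichment.  It is aimed at computational oncology groups who want a
fully specified, testable version of this workflow with a synthetic
ground-truth generator for every stage.

## The model

Each omics view (platform) `m` yields a samples × features matrix
`Y_m`.  The integration step fits the group factor decomposition

    Y_m = Z W_mᵀ + ε_m ,   m = 1..M

with one factor-score matrix `Z` (N × K) shared across views, per-view
weight matrices `W_m` and per-view isotropic noise `ε_m`, estimated by
ridge-penalized alternating least squares with whole-sample-per-view
missingness (a patient absent from a platform simply contributes no
rows there).  The factor count K is chosen over the grid {10, 15, 20,
30} by balancing total variance explained R² against the average
variance inflation factor (VIF) of the factor columns.

Downstream, a multivariate Cox proportional-hazards model over all K
factors (crude, and age-adjusted for robustness) selects the factors
with Wald p < 0.05; Hartigan–Wong k-means on those factor scores, with
the cluster count chosen by the gap statistic (silhouette reported),
defines the MOCs; Kaplan–Meier curves and (pairwise) log-rank tests
compare their survival.  Label transfer trains a random-forest /
linear-SVM / PLS-DA ensemble on SAM-selected differential transcripts
intersected with the external assay, and assigns each external sample
the class with the highest classifier-averaged probability.  Cluster
pairs are compared by GSEA on signal-to-noise-ranked transcripts,
`(μ_A − μ_B)/(σ_A + σ_B)`, with phenotype-permutation NES and FDR.

## Worked example

```bash
python analysis/01_generate_cohorts.py --seed 1 --out results/cohorts
python analysis/03_survival_screen_and_cluster.py --seed 1 --out results/clusters
```

The first command prints the cohort design:

```
discovery cohort: N=335, observed per view {'mrna': 308, 'protein': 315, 'metabolite': 228}, events=133
external cohort: N=300, views=['mrna'], shared transcripts=1200
```

i.e. 335 patients with the three platforms available for 308/315/228
of them, 133 composite survival events, and a 300-patient external
cohort measuring only 60% of the transcripts.  The second command
fits the 20-factor model, screens the factors and clusters:

```
survival-associated factors (Wald p<0.05): F1, F2, F3
  F1: HR=2.34 (2.05-2.66), p=1.27e-37
  F2: HR=0.50 (0.42-0.60), p=1.31e-14
  F3: HR=0.63 (0.56-0.72), p=7.14e-13
global PH test p = 0.808
gap statistic chose k = 3 (plain argmax also reported; 1-SE rule: 3); cluster sizes: {'MOC1': 133, 'MOC2': 59, 'MOC3': 143}; mean silhouette = 0.452
overall log-rank: chi2=194.01, df=2, p=7.44e-43
```

Three factors carry the survival signal (hazard ratios per factor
unit, with the proportional-hazards assumption not rejected), the gap
statistic finds three clusters, and the clusters differ strongly in
survival.  Because the cohort is synthetic, every number can be scored
against ground truth: the three selected factors are the three planted
prognostic factors and the cluster assignment reaches ARI ≈ 0.96
against the planted subtypes.

The remaining scripts (`02` variance explained and top loadings, `04`
cluster characterization, `05` external transfer, `06` enrichment, or
`00_run_all.py` for the whole workflow with a run manifest) follow the
same pattern; each accepts `--seed` and `--out` and prints what it
found.

## Layout

- `src/moclust/` — the library: `io_preprocess`, `synthetic`, `factor`,
  `survival`, `clustering`, `transfer`, `enrichment`, `characterize`,
  `pipeline`.
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — the methods note (model, assumptions, parameter
  choices, limitations).
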