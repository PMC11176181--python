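# Methods

## Multi-view factor model

The integration model is the group factor decomposition
`Y_m = Z W_mᵀ + ε_m` over M omics views measured on one sample roster,
with per-view isotropic Gaussian noise.  We estimate it by
ridge-penalized alternating least squares (ALS) maximizing the
penalized log-likelihood

    L = −½ Σ_m [ n_m D_m log σ²_m + ‖Y_m − Z W_mᵀ‖²_obs / σ²_m ]
        − (λ/2)(‖Z‖² + Σ_m ‖W_m‖²)

Each sweep solves three exact block updates — ridge regression for
each `W_m` on that view's observed samples, ridge regression for each
sample's score vector over its observed views weighted by 1/σ²_m, and
the closed-form noise update — so the objective trace is
non-decreasing by construction (asserted in tests).  Initialization is
a randomized SVD of the concatenated, zero-imputed blocks; given the
seed the fit is bit-reproducible.  Factors are canonicalized (ordered
by pooled variance explained, signed so the largest-magnitude loading
is positive) so outputs are comparable across runs.

This is a deterministic estimator of the same decomposition that
variational multi-omics factor tools fit with sparsity priors; we do
not claim posterior equivalence with those tools, only the shared
model contract, which is what the downstream pipeline depends on.

Preprocessing inside the fit: per-view feature centering is mandatory;
per-feature unit scaling defaults ON because the platforms live on
incomparable scales; each view is then rescaled to total variance
`D_m` so the ~2000-transcript view cannot dominate the 18-metabolite
view by feature count alone.  Missingness is whole-sample-per-view, as
with real per-platform availability.

Defaults: `ridge_lambda = 0.1`, `tol = 1e-6` (relative objective
change), `max_iter = 500`.  At the full study conditions the slow tail
of the ALS (rotations among near-degenerate background factors) can
exhaust the sweep cap before the tolerance is met; the model is then
returned with `converged=False` and a warning.  The factor estimates
are stable well before that point (re-fitting with 2000 sweeps moves
factor–truth correlations by < 0.002).

**Model selection.**  One fit per K in {10, 15, 20, 30}; score(K) =
minmax-normalized total R² minus minmax-normalized average VIF over
the grid, argmax with ties resolved to the smaller K.  Scores within
1% of the normalized range are treated as ties (parsimony): with a
hard R² plateau and flat VIF the raw argmax would be decided by fit
noise in the fourth digit.  The selection penalizes only high VIF; the
notion that a low VIF also signals a poor model has no operational
definition we could implement, so it is reported but not scored.

## Synthetic cohorts

The generator emulates a three-platform breast-tumor cohort with known
ground truth.  Defaults (the study conditions used by the tests and
the acceptance script):

| parameter | default | rationale |
|---|---|---|
| N | 335 | discovery-cohort size |
| views (features) | mrna 2000, protein 150, metabolite 18 | protein/metabolite at assay size; transcripts down-scaled ~10× from array scale so a full run fits a desk machine |
| observed per view | 308 / 315 / 228 | per-platform availability of the cohort design |
| K_total / K_prognostic | 20 / 3 | factor budget and planted prognostic factors |
| clusters | 3, weights (0.15, 0.41, 0.44) | three subtypes at the reported size proportions |
| separation | 5 within-cluster SDs per contrast axis | well-separated subtypes (basal vs luminal scale) |
| loadings | N(0, 0.5²), 70% sparse | sparse view-specific weights |
| noise SD | 1 per view | unit residual scale |
| survival | exponential PH, baseline 0.005/month, betas (−0.8, 0.7, 0.6), 60% uniform censoring | ~133 events of 335 under a composite endpoint, log-hazards of moderate clinical size |

Three cluster means span at most two dimensions, so the mean structure
sits on the first two prognostic axes as weight-orthogonal
Helmert-style contrasts (axis 1 splits cluster 1 from the rest, axis 2
splits cluster 2 from 3); orthogonality under the mixing weights keeps
the population covariance diagonal in the true axes, making each
factor individually identifiable rather than mixed by rotation.  The
third prognostic axis carries no mean structure but has inflated SD
(1.5) and a survival coefficient: it is prognostic without being
cluster-defining.  Identification of that axis is intrinsically weaker
— among 17 unit-variance background factors at N=335 its fitted
direction carries sampling leakage of order √(K/N), giving matched
correlations ≈ 0.94 (principal angle ≈ 18°) while the contrast axes
recover to < 10°.  Raising its variance to sharpen identification
makes k-means split along it instead of the cluster structure, so the
study conditions keep SD 1.5 and the recovery oracles treat the two
kinds of axes accordingly.

Censoring is independent uniform on (0, c) with c solved numerically
so the expected censored fraction hits the target — closed-form per
sample as `P(event) = 1 − (1 − e^{−rc})/(rc)` for exponential rate r.
Clinical covariates (grade, ER/PR/HER2, histology, subtype label) are
sampled with cluster-shifted multinomials reproducing the familiar
gradients (one cluster almost all grade III and hormone-receptor
negative).  Age is independent of the factors by design, which is what
makes the crude-vs-age-adjusted robustness check informative.

External cohorts redraw new samples from the same generative law,
emit only `⌈overlap · D_m⌉` features per retained view (identical
feature ids), and can drop views entirely (a transcriptome-only
cohort).  Gene-set fixtures draw enriched sets ≥ 80% from the truly
differential features and null sets from the rest.

What the generator does **not** emulate: real marginal distributions,
gene identities, feature–feature correlation beyond the factor model,
batch effects, informative censoring, or platform-specific artifacts.
Passing tests therefore demonstrate that the pipeline recovers the
structure it targets when the model class is correct — not performance
on any real cohort.

## Survival analysis

Cox fits use the Efron tie correction (event times in months tie
often).  The factor screen fits one multivariate Cox over all K
factors (crude) plus an age-adjusted companion; selection uses the
crude Wald p < 0.05, with the adjusted fit reported.  With 20
covariates at α = 0.05 the screen admits ~1 spurious factor per run on
average; the clustering step is robust to this because spurious
factors contribute only low-variance noise dimensions.  The
composite endpoint (BC death, metastasis or relapse) is realized as
time-to-first event.  The proportional-hazards diagnostic correlates
scaled Schoenfeld residuals with Kaplan–Meier-transformed event times
(per-covariate and global chi-square); its type-I error is verified at
≈ 5% by simulation.  Pairwise log-rank p-values are reported
unadjusted, as in standard survival figures, with BH-adjusted copies
alongside.

## Clustering

Hartigan–Wong k-means: k-means++ seeding, vectorized Lloyd passes,
then single-point reallocation sweeps with the n/(n±1) transfer
criterion until no move lowers the within-cluster SS; best of 25
starts.  The gap statistic uses B uniform-over-range reference
datasets; `chosen_k` is the smallest k whose gap reaches the global
maximum within one standard error.  A plain global argmax is unstable
here: on mixture factor scores the gap curve rises to a flat tail
whose ranking is decided by reference-simulation noise (observed:
Gap(3) = 1.008 vs Gap(5) = 1.021 at SE ≈ 0.03), and the
within-one-SE reading of "largest gap" fixes exactly that; the
conservative 1-SE rule is reported alongside.  Factor scores enter
k-means unstandardized (they carry meaningful heterogeneous variance);
a standardization flag exists.  Cluster labels are renamed MOC1..k by
descending mean of the first selected factor so numbering is stable
across seeds.

## Label transfer

SAM: d = (mean₂ − mean₁)/(s + s₀) with pooled-SE s and the fudge
factor s₀ chosen over the percentiles {0, 5, …, 100} of s to minimize
the coefficient of variation of the d spread across s-quantile
windows.  Null distributions come from label permutations (exhaustive
when fewer than requested exist); q-values are the median permutation
false-call count over the observed call count at each |d| cutoff,
monotonized.  SAM runs pairwise on cluster pairs; the union of
selections forms the DEG panel, which is then intersected with the
external assay.

The ensemble: random forest (500 trees; features-per-split grid
{√D, D/3, D/10}), linear-kernel SVM (cost grid {0.01, 0.1, 1, 10},
Platt-scaled probabilities) and PLS-DA (components 2..10).  PLS-DA
probabilities are one-hot PLS regression scores mapped through a
softmax — a package choice, isolated so a Bayes-on-scores alternative
can be swapped; note that linear one-hot regression cannot separate
collinear class means, which is a property of PLS-DA itself.
Hyperparameters maximize 5-fold stratified-CV macro one-vs-rest AUC;
the final model refits on all discovery samples.  Feature
standardization is learned on discovery and applied frozen to the
external cohort (no leakage; stands in for cross-platform scale
harmonization).  Prediction averages the three probability vectors
with equal weight; exact ties go to the lowest class index and are
flagged.

## Enrichment

Signal-to-noise scores use the standard SD floor
max(σ, 0.2·|μ|, 0.2) per group; ranking ties break lexicographically
by feature id for determinism.  The enrichment score is the signed
extremum of the weighted KS running sum (weight p = 1 by default;
p = 0 gives the classic statistic); the running sum ends at 0 by
construction (asserted).  Permutation nulls re-rank on permuted
phenotype labels; NES divides ES by the mean same-sign permuted ES;
nominal p is one-sided on the matching sign with the +1 correction;
FDR is the canonical pooled-NES tail-fraction ratio.  Desk-scale runs
default to 1000 permutations (the analysis scripts use 500–1000); the
`n_perm` flag accepts the full 10,000 where runtime permits.

## Problem sizes used by the tests

The acceptance suite runs 20 independent end-to-end replicates at the
full study conditions (N = 335, K = 20), with gap settings B = 40 and
k_max = 6 and 100 SAM permutations per cluster pair; the Cox bias
oracle uses 100 replicates at n = 1000; the Schoenfeld type-I oracle
200 replicates at n = 120; SAM null calibration 50 replicates at 250
features; GSEA examples use hand-size instances.  Unit tests run on a
structurally identical cohort scaled to N = 150 with 400/60/12
features.  These sizes are the package's desk-scale choices; every
threshold asserted is stated in the corresponding test.

## Known limitations

- The factor estimator is a point estimator; no uncertainty on Z or W.
- Missingness is whole-sample-per-view only; cell-level missingness is
  out of scope.
- The gap statistic uses the uniform-over-range reference; the
  PCA-aligned variant is not implemented (flag documented for future
  work).
- SAM's s₀ search uses 10 s-quantile windows (robust at desk-scale
  feature counts; the classical implementation uses 100).
- Probability calibration of the ensemble is not attempted; averaged
  probabilities are used as-is.
- Competing risks are not modeled; unknown-cause deaths are censored
  for cause-specific endpoints.
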