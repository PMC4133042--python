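# Methods

## Scope and model

The package estimates, for each region of interest (ROI) of a face-processing
network, the proportion of phenotypic variance in the regional fMRI response
captured jointly by common SNPs, and relates those per-region estimates to
functional-network properties.  The core is the GREML mixed model

    y = Xβ + g + ε,   g ~ N(0, A·V_G),   ε ~ N(0, I·V_E),

with **A** the genomic relationship matrix (GRM) from standardized dosages
and allele frequencies estimated in-sample after QC (missing dosages are
mean-imputed inside the GRM, contributing zero to the numerator; the
per-pair SNP count is tracked).  All estimation is restricted maximum
likelihood.

## Optimizer

`ai_reml` is a generic multi-component AI-REML engine used by both the
univariate (2 components) and bivariate (6 components) models:

- start at V_G = V_E = V_p/2 (bivariate: per-trait halves, covariances from
  the phenotypic covariance), one EM-REML warm-up step, then
  average-information (quasi-Newton) updates;
- convergence when a (near-)full AI step changes the restricted
  log-likelihood by less than 1e-8 (relative), with at most 100 iterations;
- constrained mode (default, GCTA-like) truncates variance components at
  1e-6·V_p.  A component pinned at this floor with a downhill gradient is
  held fixed and the AI system is solved for the free components only;
  without this active-set reduction, boundary fits (true V_G ≈ 0) oscillate
  and never satisfy the step criterion;
- a singular AI matrix (condition number > 1e10) switches to a minimum-norm
  pseudo-inverse ascent and marks the fit non-converged: the components are
  not separately identifiable there (e.g. GRM = I);
- steps that leave the positive-definite cone or decrease the likelihood
  are halved (up to 20 times) and ultimately replaced by an EM step.

Standard errors come from the inverse AI matrix; the SE of V_G/V_p (and of
r_G) uses the delta method.  The null model (fixed effects only) has a
closed-form REML optimum, σ̂² = RSS/(n−p), evaluated with the same
likelihood constant as the iterative fit so the LRT statistic is exact.

The LRT of V_G = 0 tests a parameter on the boundary of its space, so the
null distribution is the 50:50 mixture of a point mass at zero and χ²(1);
the α = 0.05 critical value is χ²₁(0.90) = 2.7055.  A full-model likelihood
more than 0.01 below the null raises an optimizer-fault error rather than
reporting a negative statistic.

Perfectly collinear trait pairs (phenotypic correlation exactly ±1) make
the bivariate model degenerate: the likelihood supremum sits at the
singular boundary r_G = ±1 and no interior iteration reaches it.  The model
detects this case, fits the common trait univariately, and reports the
boundary solution directly with a warning.

## Genotype QC and GRM conventions

SNP filters run in a fixed order — missingness > 5 %, Hardy–Weinberg exact
test p ≤ 1e-4, minor allele frequency < 1 % — followed by a per-sample call
rate < 97 % filter; the QC report records removals per filter in that
order (counts are order-dependent).  The HWE test is the conditional exact
test: all heterozygote counts of matching parity are enumerated given the
allele counts and outcomes no more probable than the observed one are
summed (no mid-p correction).  Relatedness pruning removes, greedily, the
individual in the most pairs with relatedness above the cutoff (0.05),
ties toward the lower sample index, until no such pair remains.  Genetic
PCs are eigenvectors of the double-centered GRM, ordered by eigenvalue,
each oriented so its largest-magnitude loading is positive.  GRM exchange
uses the GCTA text-triplet dialect (1-based lower-triangle rows
`i j nsnp value` plus a `.grm.id` file).

## Connectivity analysis

Each 160-volume run (TR 2.2 s) holds 19 task blocks of 8 volumes
(5 ambiguous-face, 5 angry-face, 9 non-biological-motion control) plus 8
rest volumes at the end of the run.  Per condition: take each block's 8
volumes shifted 2 TRs into the hemodynamic response (a window running off
the run is an error, never a silent truncation), mean-center within block,
concatenate (40 volumes for a face condition, 72 for control), append the
control series (default; a face-only flag exists), correlate all ROI pairs,
and threshold strictly at r > 0.3 — negative correlations never create
edges.  Nodal degree is the row sum of the adjacency matrix.  WM/CSF
nuisance channels are regressed out of the ROI channels by OLS before the
correlation step; a constant nuisance channel is dropped with a warning.

The per-ROI phenotype is a transparent stand-in for pipeline-extracted
percent signal change: 100 × (mean shifted condition signal − mean shifted
control signal) / whole-run mean signal.  Phenotypes are z-scored within
acquisition site; sex is carried as a covariate.

## Second-level statistics

- Expected false positives: n·α (1.25 for 25 tests at α = 0.05).
- Count-statistic null: each of 50,000 realizations draws one multivariate
  normal vector with the observed inter-ROI phenotypic correlation matrix
  (nearest-PSD repair with a warning if needed), converts coordinates to
  per-ROI null p-values — two-sided normal by default, or the
  boundary-mixture transform max(z,0)² mirroring the GREML LRT null — and
  counts those below α.  The p-value for the observed count uses the
  add-one estimator (1 + #{count ≥ observed})/(1 + N), so it is never zero
  and is exactly 1 for an observed count of 0.
- Trends across the 25 ROIs are plain OLS (statsmodels): linear fits report
  F(1, n−2), quadratic fits F(2, n−3) — (2, 22) for 25 ROIs.
- Subnetwork classification implements the verbal rule with explicit
  parameters: "Optional" = the k = 4 highest-degree-SD ROIs whose mean
  degree lies within a quantile band of means (default interquartile);
  "Obligatory" = the k = 4 highest-mean ROIs within the lowest-SD tertile,
  excluding ROIs already labelled Optional; ties break toward lower ROI
  index and the parameters are recorded in the result.  Applied to the
  published degree table with band (1/3, 0.70), the rule reproduces the
  published 4+4 grouping exactly; the default interquartile band is kept as
  the neutral choice for data where no external selection exists.
- Split-half reproducibility is the squared Pearson correlation of per-ROI
  mean %BSC between two random (seeded) halves of the cohort, computed on
  raw responses — per-site z-scored columns carry no regional profile (the
  half-means become exact mirror images and R² degenerates to 1).

## Synthetic cohort generator

The generator plants known truth for every estimated quantity.

**Genotypes.** Per SNP, a minor allele frequency p ~ U(0.05, 0.5) (range
configurable) and dosages Binomial(2, p); optional completely-at-random
missingness.  Defaults (n = 500 subjects, m = 2,000 SNPs, 200 causal) are
the desk-scale stand-in for a ~1,600-subject, ~500K-SNP array study.

**Phenotypes.** GCTA-style: standard-normal effects on the standardized
dosages of a shared causal SNP set, rescaled so the realized genetic
variance equals the target V_G/V_p exactly per ROI (so parameter-recovery
simulations are centered on the target); environmental noise multivariate
normal across ROIs with an exchangeable correlation (ρ = 0.35 default) as
the simplest PSD stand-in for the strong positive inter-ROI phenotypic
correlation of real data; additive per-site offsets (SD 0.3) removed by
the downstream per-site z-scoring; sex labels with a zero default effect.
The within/between-subject variance partition of real %BSC is not known to
us; the defaults are configurable, not inferred.

**Connectivity graphs.** Each subject's true graph draws each ROI pair
independently with probability from a Table-analog matrix: per-ROI
propensities are fitted so expected degree matches the published per-ROI
mean degrees, and the eight subnetwork ROIs carry the published pairwise
connection proportions.  A subject-level shift on the logit of every
pair's probability (SD 1.0) makes one subject's edges positively
dependent, overdispersing nodal degree across subjects the way real
cohorts are overdispersed relative to independent edges (degree variance ≈
Σp(1−p) + SD²·(Σp(1−p))²).  Calibration tests that need the
independent-edge regime set this SD to zero.

**BOLD runs.** Connectivity is ongoing: ROI noise is drawn with a
correlation matrix carrying `coupling_r` (default 0.5) on the edges of the
subject's graph, so condition-block correlations inherit it; face blocks
add a per-ROI activation amplitude (defaults taken from the published mean
%BSC profile) placed 2 TRs after block onset, giving a known
percent-signal-change truth.  The naive edge-target matrix is not positive
semi-definite for dense graphs, so it is calibrated by alternating
projections: PSD projection (eigenvalue clipping + diagonal
renormalization), edge entries reset to the target, non-edge fill-in
capped at 0.15.  For sparse graphs (and complete graphs, which are
equicorrelation-feasible) the target is met exactly; for dense graphs edge
correlations land at ≈ 0.40–0.47 — still cleanly above the 0.3 threshold,
with non-edges below ≈ 0.24 — so measured connection proportions are
mildly attenuated/blurred relative to the generating probabilities at
typical network densities.  A per-pair shared-latent mechanism was
rejected because its pairwise correlation dilutes as 1/degree and cannot
reach 0.5 on dense graphs.

**Heritability–network coupling.** In pipeline runs, per-ROI generating
heritabilities are rank-coupled to the expected degree variance (evenly
spaced on [0, 0.5] in variance order), planting the qualitative
heritability-tracks-degree-variance structure that the trend analyses then
estimate.

## What passing tests do and do not show

The generator draws SNPs in linkage equilibrium, Gaussian phenotypes, and
block-structured noise without hemodynamic convolution, motion, or scanner
drift; site effects are purely additive.  Passing tests therefore validate
the estimators and their calibration under the stated statistical model —
unbiased heritability recovery, exact-test agreement with enumeration,
type-I control of the boundary LRT, graph-metric correctness — not
robustness to LD structure, non-Gaussian noise, imaging artifacts, or real
hemodynamics.  Published real-data estimates are not reproduction targets:
the cohort they came from is not redistributable, and printed values enter
only as generator calibration (mean degrees, connection proportions,
activation profile) or as inputs to rule-recovery tests.

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen to keep the full suite
fast while leaving every statistical claim testable: parameter recovery at
n = 500, m = 2,000 over 50 replicates; type-I simulation at n = 120,
m = 250 over 400 replicates; bivariate checks at n = 300; the demo pipeline
at n = 300, m = 2,000 with 5,000 Monte-Carlo realizations (50,000 is the
analysis default).

## Known limitations

- No LD: SNPs are independent, so m = 2,000 here behaves like a much larger
  array panel in effective dimension per SNP.
- The GRM-vs-IBS distinction is collapsed: PCs come from the (centered)
  GRM; a separate identity-by-state matrix is not implemented.
- GWAS is plain per-SNP OLS (as in array-era practice), not a mixed-model
  association; no MAF-stratified or partitioned GREML.
- Dense-graph BOLD coupling is attenuated relative to its target (above);
  connection-proportion calibration is exact only in the sparse regime.
- The bivariate model handles missing data pairwise-complete only.
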