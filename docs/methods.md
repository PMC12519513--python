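# Methods

This document records the statistical models implemented in `cortsub`,
the default parameters, and the rationale for every non-obvious choice.

## 1. Synthetic cohort generator

The generator produces a study in which every downstream estimate has a
known ground truth.

**Parcellation.** `generate_parcellation(R)` places R ROI centroids on
a sphere shell of radius 70 mm with 3 mm radial jitter. Hemispheres are
mirrored (x → −x), and seven angular sectors are labelled with the
canonical resting-state networks (Visual … Default). The full Euclidean
distance matrix is computed once.

**Connectomes.** `generate_connectomes` draws, per modality
(functional, structural), a weighted graph with edge probability
decaying as `exp(−d/λ)` (λ = `distance_decay` = 30 mm) at target
`density` = 0.2, with weights that also decay with distance under
multiplicative log-normal noise. Two deliberate departures from a pure
geometric graph:

- **Within-network affinity** (`network_boost` = 2.0): edges between
  ROIs of the same network sector get boosted sampling odds, mimicking
  long-range intra-network functional connectivity.
- A minimum-spanning-tree union guarantees connectivity.

*Why the boost matters:* the rewired null preserves geometry
(distance-binned swaps). If the simulated connectome were predictable
from geometry alone, a network-coupled thinning map would be equally
predictable from every rewired network and the null would have no
power by construction. The community structure is the
topology-beyond-geometry signal the test is designed to detect.

**Cohort.** `generate_cohort` plants `k_true` = 2 subtypes (default
fractions 0.5/0.5). Subtype 1's vulnerable set is the Limbic + Default
sector (a limbic-predominant pattern); subtype 2's is a disjoint set.
Baseline thickness subtracts `subtype_profile_effect` = 0.35 mm on the
vulnerable ROIs, plus age, sex, per-subject random intercepts
(`intercept_sd` = 0.08 mm) and visit noise (`noise_sd` = 0.05 mm).
Covariates are subtype-enriched (age 68 vs 63, centiloid 45 vs 15,
APOE-e4 0.45 vs 0.25), and longitudinal centiloid and memory score
follow subtype-specific rates.

Thinning rates per ROI are a subtype template (vulnerable vs background
rates) multiplied by an iid per-ROI heterogeneity factor drawn from
`U(1−h, 1+h)` with `rate_heterogeneity` h = 0.5, then mixed with the
connectivity-weighted neighbour average at `network_coupling` = 0.3:

```
rate_coupled = (1 − c) · rate + c · (W @ rate) / strength
```

*Why heterogeneity matters:* without it the rate map is a smooth
function of the vulnerable-set geometry, and coupling through W adds
nothing identifiable; with it, the coupled map carries the imprint of
the actual adjacency, which the rewired null can detect.

**Expression.** `generate_expression` draws Gaussian random fields with
exponential covariance (`sa_length` = 30 mm, Cholesky factorization)
as null genes, and constructs coupled genes by mixing the z-scored
thinning map with a residualized field so the planted spatial
correlation (`coupling_r` = 0.8) is exact in expectation. All genes
are z-scored across ROIs.

**Realism limits.** The generator is a property-testing instrument,
not a biophysical model: geometry is a sphere shell, not a cortical
surface; networks are angular sectors; site effects are labels without
bias; thinning is linear in time. Published cohort numbers are
therefore not reproduced — the acceptance criteria are property-based.

## 2. Subtyping

Thickness is inverted per ROI as `max + margin − value`
(margin 0.01 mm), so larger values mean more atrophy and the matrix
stays strictly positive for NMF; the offsets are stored in the model so
follow-up scans can be mapped into the same space. A `global_max`
variant uses one offset for all ROIs.

`fit_nmf` runs `n_restarts` multiplicative-update Frobenius NMF fits
(scikit-learn's `NMF(solver="mu", init="random")` — exactly the
prescribed update scheme) and keeps the best-RSS factorization.
Components are matched across restarts by Hungarian assignment on
H-row correlations (optimal matching, at least as good as greedy), and
per-restart subject assignments are accumulated into a consensus
co-assignment matrix. Subject probabilities are L1-normalized W rows;
zero rows are flagged unassignable and get uniform probabilities; ties
resolve to the lower index with a warning.

**Rank selection** computes, per k, the cophenetic coefficient of the
consensus matrix (Pearson correlation between 1 − consensus distances
and the cophenetic distances of their average-linkage dendrogram; a
degenerate all-ones consensus is defined as 1.0) and the silhouette of
the hard assignment; the selected k maximizes (cophenetic, silhouette,
−k) lexicographically. RSS and ΔRSS are reported but not used for
selection; RSS is checked nonincreasing in k up to 1% restart noise.

## 3. Longitudinal models

**Random-intercept LMM.** `fit_random_intercept_lmm` implements REML
for `y = Xb + u_subject + e` by profiling the variance ratio
θ = τ²/σ². Each subject's marginal covariance is σ²(I + θJ), so for
fixed θ the GLS normal equations have a Woodbury closed form using only
per-subject sufficient statistics (`λ_g = θ/(1 + θ n_g)`); the −2 REML
criterion `(n−p)·log σ̂² + Σ log(1+θn_g) + log|X'V⁻¹X|` is minimized on
a log-θ grid refined by bounded scalar minimization. θ = 0 (OLS) is
used when no subject has repeated measures (with a warning) or when it
beats the interior optimum. Inference is Wald (normal reference). The
engine is cross-checked against `statsmodels` MixedLM in the test
suite; it exists in-package because per-ROI fitting reuses one design's
sufficient statistics across 100 outcomes, making the map fit ~100×
cheaper than refitting a generic mixed model per ROI.

**Thinning maps.** Per ROI: thickness ~ time × subtype + age + sex +
baseline centiloid + NMF assignment probability, with subtype 1 as the
reference level. Each subtype's marginal slope is the linear contrast
time (+ time:subtype_j), i.e. the estimated-marginal-means linear
trend under dummy coding. Subtypes without longitudinal subjects yield
NaN maps with a warning.

**Subtype characterization.** Logistic GLM (statsmodels, Binomial) of
subtype-1 membership on age, sex, centiloid, APOE-e4 and the NMF
probability; |coef| > 15 flags likely perfect separation (warning, not
an error).

**Follow-up stability.** Each subject's latest follow-up is inverted
with the stored offsets and Pearson-correlated against each H row; the
argmax is the follow-up subtype. Agreement is Krippendorff's nominal
alpha, `α = 1 − D_o/D_e`, from the coincidence matrix over all
pairable values with `D_e = (n² − Σ n_c²)/(n − 1)`; degenerate data
(one unit or a single observed code) is defined as α = 1 with a
warning. Instability (baseline ≠ follow-up) is modelled by logistic
regression on age, sex, follow-up time and the NMF probability.

## 4. Coordinated deformation models

`cdm_predict` computes `pred_i = Σ_j w_ij β_j / Σ_j w_ij` (normalized;
the raw weighted sum is available); `cdm_correlation` is the Pearson
correlation between predicted and observed maps. Two nulls, both
reported with permutation p-values `(count + 1)/(n_perm + 1)`,
one-sided "greater" by default:

**Rewired null** (`rewire_null`, default `n_bins` = 5,
`swaps_per_edge` = 10). Edges are binned by distance quantiles and
Maslov–Sneppen double-edge swaps are accepted when the replacement
pair occupies the same *pair* of distance bins (either assignment; both
reconnections are tried). This exactly preserves the degree sequence
and per-bin edge counts. Weights are then reassigned per bin following
the original distance-ordered weight sequence — the k-th closest
rewired edge of a bin receives the k-th closest original edge's weight
— which reproduces the original distance–weight Spearman correlation to
~1e-3 while keeping the weight multiset exactly. The strict per-edge
bin-matching rule with 10 bins accepted < 1% of swaps and produced
nulls nearly identical to the original network; the bin-pair
relaxation with 5 bins reaches ~9% acceptance and ~50% edge overlap
while holding the Spearman invariant within ±0.1.

**Variogram-matched surrogates** (`VariogramGenerator`). The empirical
variogram of the centred map is smoothed with a Gaussian kernel over 25
evenly spaced lags up to the 25th percentile of pairwise distances,
bandwidth = 3 lag spacings. Each surrogate permutes the map, smooths it
by distance-weighted k-nearest-neighbour averaging for candidate
k ∈ {6, 10, 16}, fits nonnegative (scale, nugget) coefficients to the
empirical variogram by NNLS, realizes the nugget as white noise, keeps
the best-fitting candidate, and finally rescales the surrogate to the
original map's mean and SD.

*Calibration rationale:* with the wider candidate grid {10, 20, 30,
50}, signed least-squares nuggets and no moment pinning, the
correlation null was overdispersed and the empirical type-I error fell
to ~0.01 at nominal 0.05. The defaults above were chosen by
calibrating on maps drawn from the surrogate process itself
(self-consistency ≈ 0.04) and on exponential-covariance fields
(type-I ≈ 0.03) — i.e. by fixing the method against its own null,
never against the planted-effect outcomes.

## 5. Imaging transcriptomics

Per-gene Pearson correlations between expression columns and a thinning
map; significance against `n_surr` variogram-matched surrogates of the
*thinning map* (generated once and shared across genes — it is the map,
not the genes, that is permuted), two-sided on |r| by default.
Zero-variance genes yield NaN and are excluded. ORA uses the upper-tail
hypergeometric probability `P(X ≥ x)` for each gene set intersected
with the measured universe (size filter [3, 500]), with
Benjamini–Hochberg q-values across tested sets.

## 6. Reproducibility

All randomness derives from one pipeline seed via
`numpy.random.SeedSequence(entropy=seed, spawn_key=(stream,))` with
fixed stream indices per stage (simulation 0, subtyping 1, rewiring 2,
surrogates 3, genes 4), so consuming more randomness in one stage never
shifts another. Derived seeds are reduced mod 2³¹−1. The pipeline
manifest records the configuration, stage seeds and SHA-256 input
checksums and contains no timestamps; identical configurations produce
byte-identical manifests.

## 7. Numerical choices and limitations

- NMF restarts default to 50 in the pipeline (10–20 in tests); the
  multiplicative-update solver's convergence warnings are suppressed
  inside the restart loop since only the best-RSS fit is kept.
- The REML profile uses a 17-point log-θ grid on [e⁻¹⁰, e⁶] before
  local refinement; θ is not profiled per ROI beyond this 1-D search.
- Wald (normal) inference is used throughout; with ≥ 400 subjects the
  normal approximation is adequate, but small-sample users should
  expect anticonservative p-values.
- Permutation p-values are bounded below by 1/(n_perm + 1); criteria at
  α = 0.05 need n_perm ≥ 100 (enforced).
- The rewired null relaxes per-edge bin matching to bin-pair matching;
  residual distance structure differences are controlled by the ±0.1
  Spearman invariant rather than being exactly zero.
- Variogram surrogates pin the first two moments; Pearson correlations
  are scale-free, so this affects only variogram reporting, not test
  statistics, but keeps surrogate maps physically comparable.
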