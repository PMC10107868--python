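# Methods

This note documents the statistical machinery, the numerical choices, and
what the synthetic-data generator does and does not emulate.

## Trees and covariance

Trees are rooted, strictly bifurcating, with non-negative branch lengths in
relative time (no calendar calibration). Polytomies are rejected at parse
time by default; `resolve_polytomies=True` resolves them arbitrarily into
zero-length branches, because downstream likelihoods assume bifurcation and
a silent resolution would be surprising.

The Brownian covariance C has C_ij equal to the branch length shared from
the root to the most recent common ancestor of species i and j; on an
ultrametric tree the diagonal is constant at the tree height T. Internally
every covariance is assembled from a branch × tip incidence matrix M as
Mᵀ diag(g) M, where g holds per-branch weights; this single primitive
yields BM (g = σ²·length), BMS (g = σ²_regime·length), EB (g on the
time-rescaled branch lengths) and OUMV (exponentially discounted branch
integrals, below).

Transforms:

- **λ (Pagel)** multiplies off-diagonal entries by λ ∈ [0, 1]. The upper
  bound is fixed at 1 (not the larger positive-definite limit) to match the
  usual interpretation scale; the bounds are a documented override.
- **EB** rescales a branch spanning node ages t1 → t2 to
  e^{r·t1}·expm1(r·(t2−t1))/r (r ≤ 0). The `expm1` form is exact in the
  r → 0 limit to machine precision; the naive difference of exponentials
  loses ~10 digits at r = 1e−10.

## Phylogenetic signal

**Pagel's λ** is estimated on the profile likelihood: for each λ the
ancestral mean μ and scale σ² have closed-form GLS/ML solutions, leaving a
one-dimensional bounded search (scipy bounded Brent, tolerance 1e−6, with
both endpoints evaluated explicitly since boundary optima at 0 and 1 are
common). Significance is a likelihood-ratio test of λ̂ against λ = 0 on
one χ² degree of freedom.

**Fritz–Purvis D** computes the observed sum of sister-clade differences
d_obs by a tips-to-root averaging pass (each internal node takes the mean
of its two children). The pass is expressed as a precomputed linear
operator on tip values, so the two nulls — tip-label permutation and
Brownian simulation rank-thresholded to the observed number of 1s — are
evaluated for all replicates with one matrix product each.
D = (d_obs − mean d_b)/(mean d_r − mean d_b). Empirical p-values are
one-sided — pRandom = P(d_r ≤ d_obs), pBrownian = P(d_b ≥ d_obs) — and
include the observed value in the null set (+1/+1), so p is never exactly 0.
Default n_sim = 1000; the seed is a required input.

## PGLS

V(λ) is the λ-transformed Brownian covariance; λ is fitted by profile ML
(same search strategy as above) jointly with the GLS coefficients.
Coefficient covariance is σ̂²(XᵀV⁻¹X)⁻¹ with σ̂² the GLS residual mean
square (denominator n − p); t statistics are two-sided Student-t with
df = n − p. R² is computed on whitened data (L⁻¹y on L⁻¹X, V = LLᵀ)
against the whitened intercept-only fit at the same λ, then adjusted.
Two classical identities pin the implementation down: at λ = 0 every output
matches ordinary least squares to machine precision, and at λ = 1 on an
ultrametric tree the slope equals the independent-contrasts regression
through the origin.

Transform policy: log for CD, NE, ER, ED, ID and pronotum length PL;
square root for DF; climate predictors untransformed. The battery fits one
single-predictor model per (response, predictor) pair — multi-predictor
models are out of scope by design — and attaches Shapiro normality of the
whitened residuals plus a residual-vs-fitted slope as diagnostics. A
Benjamini–Hochberg column is emitted for information only; inference is on
raw p at α = 0.05.

## Trait-evolution models

All seven models are multivariate normals over species means with
covariance V_model + diag(SE²), where SE is the within-species standard
error (delta-method transformed alongside the trait: SE/x for log,
SE/(2√x) for square root).

- **BM**: V = σ²C, mean z0. k = 2.
- **OU** (single optimum): V_ij = (σ²/2α)·e^{−2α(T−t_ij)}·(1−e^{−2α·t_ij})
  with t_ij the MRCA depth; the root sits at the optimum θ, which is also
  the mean. This is the branch-transform root convention of the standard
  single-regime fitting frameworks; the covariance differs from the
  stationary-root form by the (1−e^{−2αt}) factor. k = 3.
- **EB**: BM on the EB-rescaled tree. k = 3.
- **BMS**: per-regime σ² on a painted tree, one global mean θ. k = 3.
- **OUMV**: shared α, per-regime σ² and θ. Covariance accumulates per
  branch as σ²_regime(e^{2αt2}−e^{2αt1})/(2α)·e^{−2αT} over shared
  branches; the expected tip mean is W·θ where row i of W holds the
  exponentially discounted regime occupancy of the root→i path (root
  contributes e^{−αT} to the root regime; rows sum to 1). k = 5.

Mean parameters are always profiled out by GLS, so the optimizer works in
1–3 dimensions (log σ², log α, r). Fitting uses L-BFGS-B with 5 seeded
starts; bounds are σ² ∈ [1e−9, 1e6], α ∈ [1e−8, 50/T], r ∈ [−10/T, 0], and
boundary hits are flagged in the output rather than silently accepted.
AICc uses n = number of species with non-missing trait. The nested-limit
ladder (EB(r=0) = BM, OU(α→0) → BM, BMS(equal σ²) = BM, OUMV(one regime)
= OU) is asserted numerically in the test suite.

Regime paintings come from ML marginal ancestral states of the binary
habitat character under an equal-rates two-state Mk model. Marginals are
computed by the standard below/above two-pass algorithm, which for this
reversible model with stationary root prior coincides with the re-rooting
construction; a brute-force enumeration over all internal-state assignments
is the test oracle. A branch carries the state of its tipward node — stated
explicitly because the node-label interface leaves it ambiguous — and an
exact 0.5/0.5 marginal is an error unless a deterministic tie state is
supplied (the pipeline supplies state 0 by default via
`PipelineConfig.regime_tie_state`, so a fully symmetric node cannot abort a
batch run; set it to None to make ties fatal).

## Morphospace

PCA is computed on the correlation matrix (z-scored input, sample sd)
because the five temporal variables have incommensurate units; ER is
included among the temporal variables and DF excluded. Axis signs follow a
deterministic convention (largest-magnitude loading positive). Ancestral
coordinates per axis are the Brownian ML estimates, computed as the GLS
conditional expectation μ̂ + C_{k,tips}C⁻¹(x − μ̂1); the root estimate is
exactly the GLS grand mean, and the whole construction is checked against
an independent re-rooted-GLS oracle.

## Song analysis

The envelope is a moving RMS of the rectified signal. The window defaults
to 2 ms: the boundary bias of a centred RMS window at a 10%-of-peak
threshold is about half the window, and 2 ms keeps segmentation boundaries
within ±1 ms of the true burst edges while still bridging intra-echeme
pulse structure. Threshold (10% of peak), minimum duration (5 ms) and merge
gap (3 ms) are exposed as flags. Dominant frequency uses 12 evenly spaced
Hanning-windowed frames of 512 samples across each echeme; an echeme too
short for 12 frames is flagged and excluded. Per-echeme DF is the median of
its 12 points (robust to octave jumps); the song DF is the mean of
per-echeme values — the reduction is a package choice, as is storing ID as
missing (excluded from species means) for single-echeme songs. Manual
noise screening is replaced by an optional SNR gate, off by default.
Species aggregation is strictly two-level: individual = mean of its songs,
species = mean ± SE over individuals.

## Synthetic data

The generator produces every input with known ground truth: pure-birth
trees rescaled to height 1; traits simulated branchwise (exact OU
transitions; EB as BM on the rescaled tree; multi-regime variants over a
painting); binary traits by symmetric Mk simulation or by rank-thresholding
a Brownian latent; songs as raised-cosine tone bursts with optional white
noise at a stated SNR; ecological tables as Gaussian draws coloured by the
Cholesky factor of a target correlation. Everything is driven by
integer-seeded `numpy.random.Generator`s, so identical spec + seed gives
bit-identical output.

The packaged study-shaped default is a 14-species tree with a 9/5
arboreal/shrubby split and five replicate individuals per species, with a
constant within-species coefficient of variation of 0.15. Transformed-scale
Brownian rates and ancestral values (e.g. σ² = 0.6 at log ER ≈ 2.0,
σ² = 0.84 at log ID ≈ −2.6, σ² = 0.08 at √DF ≈ 3.5 with DF in kHz) were
chosen once to match the magnitudes reported for cicada calling songs, so
pipeline outputs are visually comparable to published tables without
claiming numeric equality.

What the generator does not emulate: real tymbal pulse structure within
echemes (bursts are pure tones), heteroscedastic or non-Gaussian
within-species variation, spatial structure in climate (tables are drawn
from a target correlation, not rasters), and observation effort differences
between species. Passing tests therefore demonstrate correctness of the
estimators under their own model assumptions and controlled misspecification
(outlier injection, permutation), not robustness to every property of field
recordings.

## Problem sizes

Calibration suites run at 256 tips × 200 replicates for λ and 64 tips ×
200 replicates × 1000 null simulations for D (the linear-operator
formulation makes these cheap). The acceptance script uses 128-tip/50-rep λ
and 64-tip/50-rep/500-simulation D calibrations, 20 synthetic songs and 100
pruning tables — sizes at which every Monte-Carlo mean is stable to well
within the bands checked.

## Known limitations

- OU/EB/OUMV require ultrametric trees (enforced); non-ultrametric data
  would need the fixed-root OU generalisation.
- The λ search space is [0, 1]; traits more overdispersed than a star
  phylogeny map to the boundary.
- BMS/OUMV assume the painting is known without error; uncertainty in the
  ancestral habitat states is not propagated into the model comparison.
- D's expectation is calibrated by simulation per tree, so extreme
  prevalence (one or two species in a state) makes D noisy; the permutation
  p-value remains valid.
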