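# Methods

Notation: J instruments (SNVs); for SNV j, `bx_jk` and `sx_jk` are the
effect and standard error on exposure k (serum iron, ferritin,
transferrin saturation, TIBC), `by_j` and `sy_j` the log-odds effect
and SE on the binary kidney-disease outcome. The two samples are
assumed independent (two-sample setting), effects small enough for the
linear approximation, and standard errors treated as known.

## Harmonization (`sumstats`)

Each SNV's (effect allele, other allele, effect sign, frequency) is
mapped to a canonical orientation: the lexicographic minimum over the
four equivalent codings (allele swap, strand complement, both). Because
the canonical form is a pure function of the coding class, harmonization
is invariant to how each input table happens to encode a SNV. Tables are
joined on rsid after canonicalization; mismatching allele pairs are
dropped with reason `allele_mismatch`.

Palindromic SNVs (A/T, C/G) cannot be resolved by strand, so they are
kept only when the minor-allele frequency is informative — i.e.
`min(eaf, 1 − eaf) < 0.42` in *every* table — and are then aligned by
minor-allele concordance; otherwise dropped as `palindromic_ambiguous`
(or `palindromic_no_eaf` when a frequency is missing). Every input SNV
is accounted for: `|input| = |kept| + |dropped|`, with one reason per
dropped SNV.

## Instrument selection (`instruments`)

Three nested strategies, each requiring genome-wide significance
(p < 5×10⁻⁸) and direction consistency with the biomarker loadings
(1, 1, 1, −1):

1. significant and consistent in all four biomarkers;
2. in serum iron, ferritin and transferrin saturation;
3. in serum iron alone.

Strategy 1 ⊆ 2 ⊆ 3 by construction. Subsequent QC:

- **MHC exclusion**: chr 6, 28,477,797–33,448,354 (GRCh37), boundaries
  inclusive — the region's extreme LD makes instruments unreliable.
- **Confounder / outcome exclusion**: SNVs annotated as associated with
  a confounder, or directly with the outcome, at p < 5×10⁻⁸.
- **Proxy substitution**: an instrument absent from the outcome table
  is replaced by the available SNV with the highest r² if r² ≥ 0.8
  (ties: smaller position distance, then rsid).
- **LD clumping**: greedy at r² < 0.01 — repeatedly keep the smallest
  p-value (ties: position, then rsid) and discard everything correlated
  with it above the threshold. All retained pairs satisfy r² < 0.01, so
  downstream estimators can treat instruments as independent.

Instrument strength uses `R² = 2 f (1 − f) β²` per SNV (standardized
trait) and `F = (R² / k) · (n − k − 1) / (1 − R²)`; F < 10 flags a weak
instrument. Power for a binary outcome of size N and case fraction φ at
odds ratio OR:
`power = Φ( √(N φ (1−φ) ΣR²) · |ln OR| − z_{1−α/2} )`.

## Univariable estimators (`estimators`)

- **Wald ratios**: `θ_j = by_j / bx_j`, first-order SE `sy_j / |bx_j|`
  (an optional second-order term adds the exposure uncertainty).
- **IVW**: inverse-variance-weighted mean of the ratios, equivalent to
  weighted least squares of `by` on `bx` through the origin with
  weights `1/sy²`. Fixed-effect SE is `(Σw)^{-1/2}`; the
  multiplicative-random-effect (MRE) variant inflates it by
  `max(1, √(Q/(J−1)))`, never deflating below fixed-effect. MRE is the
  headline estimator; the fixed-effect variant is used in the
  calibration studies because its SE is exact under the generator's
  assumptions.
- **Medians**: simple (equal weights), weighted (IVW weights),
  penalized weighted (weights multiplied by `min(1, 20 p_j)` where
  `p_j` is the one-SNV heterogeneity p-value, down-weighting outliers).
  The point estimate interpolates the weighted CDF at 0.5; SEs come
  from a seeded parametric bootstrap (default 1000 replicates).
- **MR-Egger**: weighted regression of `by` on `bx` with a free
  intercept after orienting all SNVs to `bx > 0`; the intercept tests
  directional pleiotropy. SEs are scaled by `max(1, residual SD)`.
- **Cochran's Q** about the IVW (df J−1) or Egger (df J−2) fit.
- **Multiple testing**: 4 exposures × 3 outcomes → Bonferroni threshold
  0.05/12 ≈ 0.0042; p-values below it are *significant*, between it and
  0.05 *suggestive*, else *null*.

## MRMix (`mrmix`)

For candidate θ the residuals `r_j = by_j − θ bx_j` are modelled as a
zero-mean two-component mixture: valid with variance
`s_j² = sy_j² + θ² sx_j²` (probability π₀) and invalid with variance
`s_j² + σ²`. (π₀, σ²) are fitted by EM at every θ on a grid; θ̂
maximizes the fitted π₀. A coarse pass (step 0.01 on [−0.5, 0.5] by
default) is refined at step 0.001 within one coarse step of its argmax.

Numerical details:

- Because the base variances differ per SNV, the σ² M-step has no
  closed form; a weighted-moment proposal is tried first and bisection
  on the derivative of the expected complete-data log-likelihood is
  used only where the proposal fails to improve it. Updates are only
  accepted when they improve that objective (generalized EM), so the
  observed log-likelihood is non-decreasing. All grid points run as one
  vectorized batch with converged points frozen and compacted out.
- Each grid point is fitted from three deterministic starts; the best
  log-likelihood is kept, exact ties going to the larger π₀.
- **Degenerate-maximizer guard.** When the data are nearly all valid
  but the residuals at some θ are fractionally overdispersed (an
  ordinary finite-J fluctuation), the unconstrained maximizer
  degenerates to π₀ ≈ 0 with σ² equal to the small variance excess —
  statistically indistinguishable from "all valid", yet it destroys the
  π₀ profile that the θ search maximizes, and no large-π₀ local optimum
  exists for any start to find. The boundary model (π₀ = 1, σ² = 0) is
  therefore evaluated in closed form at every grid point and kept
  unless the mixture beats it by more than the BIC allowance for its
  two extra parameters, `log J`. On clean data this produces exact
  π₀ = 1 plateaus, so π₀ ties across grid points are broken by higher
  log-likelihood (on the plateau the estimator reduces to the Gaussian
  maximum-likelihood θ), then by smaller |θ|.
- `mrmix_fit` caps EM at 2000 iterations per grid point (the
  free-standing `em_mixture` allows 10,000): the vectorized profile
  evaluates ~120 grid points × 3 starts, and the cap bounds runtime
  while the convergence flags record any point that hit it.

*Limitation*: the mixture model needs strong instruments; with weak
instruments at moderate J its mean absolute error can exceed IVW's even
under contamination. The robustness comparison in the test suite
therefore uses large exposure/outcome cohorts and strong pleiotropy
(direct effects ≈ 6× the outcome SE), the regime the method targets.

## Multivariable MR-BMA (`bma`)

Weighted regression of `by/sy` on the four weighted, column-normalized
exposure effect columns. For each of the 2⁴ factor subsets λ the
marginal likelihood is the normal model
`ỹ ~ N(0, I + τ² C_λ C_λᵀ)` with effect prior SD τ = 0.25 and
independent inclusion prior 0.5 per factor. Reported: posterior model
probabilities (summing to 1), per-factor marginal inclusion
probabilities (MIP), and model-averaged causal effects (θ_MACE).

Instrument diagnostics are computed on the highest-posterior model:
a SNV is removed when its Cochran Q contribution exceeds 10 or its
Cook's distance (statsmodels OLS influence on the weighted design)
exceeds the median of F(|λ|, J−|λ|). Removal is single-pass, followed
by one refit — mirroring the usual practice of reporting both the
initial and outlier-cleaned analyses rather than iterating to
exhaustion.

## Synthetic data (`simulate`)

What the generator emulates:

- A latent per-SNV iron-status effect (SD `latent_sd = 0.08`, sized so
  that a genome-wide-significant instrument set of a few dozen SNVs
  arises at the default cohort sizes) with biomarker loadings
  (1, 1, 1, −1) producing the four correlated exposure GWAS.
- A binary outcome GWAS: log-odds effects `θ ×` latent effect, with
  SEs `1/√(2 f (1−f) n φ (1−φ))`; default case fraction 0.024 matches
  a pooled kidney-disease case share.
- Cohort sizes default to one tenth of the motivating study's
  (iron 16,351; ferritin 24,614; transferrin saturation 13,147;
  TIBC 13,543; outcome 65,314) so examples and tests run in seconds
  while preserving the relative precision structure.
- `n_snv = 60` signal SNVs by default — enough that all three selection
  strategies retain a usable instrument set after QC.
- Block AR(1) LD (blocks of 5, adjacent r² 0.3 by default), SNVs placed
  outside the MHC, optional confounder-associated SNVs for the
  exclusion step, and optional invalid instruments with direct outcome
  effects of SD `sigma_pleio`.
- Two deliberate extensions beyond a pure one-factor model:
  `idio_sd` adds biomarker-specific effect noise (without it the four
  exposure columns are collinear and no multivariable method could
  separate them), and `causal_exposure` makes the outcome respond to
  one designated biomarker instead of the latent factor (the planted
  truth for MR-BMA experiments).

What it does not emulate: real LD panels or allele-frequency spectra,
sample overlap between exposure and outcome cohorts, winner's curse
from in-sample instrument discovery, population stratification, or
non-normal effect-size distributions. Binary-outcome effects are drawn
on the log-odds scale directly rather than through individual-level
logistic sampling.

All randomness flows through `numpy.random.SeedSequence` substreams, so
every table is a pure function of the config; derived integer seeds are
reduced mod 2³¹.

## Numerical choices

- TSV reading uses pandas with `float_precision="round_trip"` so a
  write/read cycle is byte-identical.
- Mixture log-likelihoods use `logsumexp`; responsibilities are
  computed from clipped log-density differences to avoid overflow.
- The BMA marginal likelihood is evaluated through the matrix
  determinant lemma on the J×J covariance (|λ| ≤ 4 ≪ J).
- Bootstrap and simulation seeds are explicit everywhere; nothing reads
  global random state.

## Limitations

- Estimators assume independent instruments; clumping at r² < 0.01 is
  the only treatment of LD (no correlated-instrument IVW).
- Median-estimator SEs are parametric-bootstrap approximations and
  inherit its Monte Carlo noise at small `boot_reps`.
- MRMix: grid-bounded θ, weak-instrument sensitivity (above), and the
  BIC guard means mild pleiotropy below the `log J` evidence allowance
  is reported as π₀ = 1.
- MR-BMA diagnostics are single-pass by design; heavily contaminated
  data may retain outliers a fully iterative scheme would remove.
- The power formula is the standard normal approximation for a binary
  outcome and ignores instrument uncertainty.
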