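# Methods

## Setting and assumptions

Two-sample Mendelian randomization treats genetic variants as
instrumental variables: a variant may be used to estimate the causal
effect of an exposure on an outcome if it (i) associates with the
exposure, (ii) is independent of confounders, and (iii) affects the
outcome only through the exposure (exclusion restriction). The package
works entirely from GWAS summary statistics; the exposure and outcome
samples are assumed non-overlapping (no sample-overlap correction is
attempted), effects are additive per allele, and outcome effects for
binary traits are log odds ratios. Instruments are LD-pruned upstream,
so all estimators treat them as independent; a correlated-instrument
IVW is deliberately out of scope.

## Instrument selection and harmonization

Selection keeps variants with exposure P below a genome-wide threshold
(default 5×10⁻⁸) and prunes greedily: take the remaining variant with
the lowest P, discard everything with r² ≥ 0.01 against it (LD is a
supplied matrix, never computed from genotypes), repeat. Ties in P break
lexicographically by variant ID so selection is order-invariant. Variants
absent from the LD matrix are treated as independent and logged.

Harmonization aligns the outcome record to the exposure's effect-allele
orientation: identical alleles pass; transposed alleles negate β_Y and
reflect EAF; strand-complement matches are complemented first. A
palindromic variant (A/T or C/G) cannot be resolved by letters, so it is
oriented by allele-frequency concordance when both EAFs lie outside
[0.5−w, 0.5+w] and dropped as ambiguous otherwise. The window default
w = 0.08 is the common practical choice; it is a config knob
(`palindrome_eaf_window`) and recorded in the harmonization metadata,
since sources differ on how palindromes should be treated and proxies
are not attempted. Every candidate variant receives exactly one audit
entry (kept / beta-flipped / strand-flipped / strand-and-beta-flipped /
palindrome-freq-flipped / dropped+reason), which is what the generator
tests count against ground truth.

## Estimators

* **Wald ratios.** θ̂_j = β̂_Yj/β̂_Xj with first-order delta SE
  σ_Yj/|β̂_Xj| by default. First order is the package default because it
  makes IVW exactly a weighted regression through the origin — giving an
  algebraic oracle — and is the dominant convention in two-sample MR;
  the second-order SE (adding β̂_Y²σ_X²/β̂_X⁴) is available by flag and
  never smaller. Variants with β̂_X = 0 are dropped with a log entry.
* **IVW.** Precision-weighted mean; fixed-effect SE (Σw)^(−1/2).
  Heterogeneity by Cochran's Q with J−1 df (undefined at J=1: Q is
  reported as NA and the fixed model forced). The automatic model uses
  random effects iff the Q-derived P < 0.05, implemented as
  *multiplicative* overdispersion — SE × max(1, √(Q/(J−1))) — rather
  than an additive DerSimonian–Laird variance component: it is floored
  at the fixed model, never shrinks the SE, and keeps the point estimate
  unchanged, which matches how heterogeneity-robust IVW is usually
  reported in this literature. P-values are normal.
* **Weighted median.** Interpolates the sorted ratios at standardized
  cumulative weight 0.5. SE by parametric bootstrap
  (θ*_j ~ N(θ̂_j, se_j), default 1000 draws, seeded). `n_boot=0` returns
  the point estimate alone (SE/CI/P = NaN) for simulation studies that
  only consume point estimates.
* **Weighted mode.** Argmax of the weighted Gaussian KDE over a 512-point
  grid spanning the ratios ±3 bandwidths, bandwidth
  φ·0.9·min(sd, iqr/1.34)·J^(−1/5) (φ=1 default). All-identical ratios
  short-circuit to the common value. SE by the same bootstrap.
* **MR-Egger.** Weighted regression of β̂_Y on β̂_X with intercept,
  weights 1/σ_Y², after orienting each variant to β̂_X ≥ 0 (the estimate
  is orientation-dependent otherwise). Both SEs carry the overdispersion
  factor max(1, √(RSS_w/(J−2))) and P-values use the t distribution with
  J−2 df — the standard small-sample treatment, since Egger fits two
  parameters to few points.
* **Contamination mixture.** Profile log-likelihood over a 1000-point
  grid spanning the ratios ±2·max(se): each variant contributes the
  larger of log N(θ̂_j; θ, se_j) (valid) and log N(θ̂_j; 0, √(se_j²+ψ²))
  (invalid), ψ defaulting to 1.5·sd(θ̂). The 95% confidence set keeps
  grid points within χ²₁(0.95)/2 of the maximum and may be a union of
  intervals; all intervals and the valid/invalid split at the maximum
  are kept in the payload, and no unimodality is forced. The scalar SE
  is the outer-hull half-width divided by 1.96; the P-value is a
  1-df likelihood-ratio test against θ=0.
* **MR-PRESSO.** Observed statistic: Σ_j w_j(β̂_Yj − θ̂_(−j)β̂_Xj)² with
  leave-one-out IVW predictions. The null distribution re-simulates
  β*_Yj ~ N(θ̂_(−j)β̂_Xj, σ_Yj) and *recomputes the leave-one-out fits on
  each simulated dataset* (n_sim = 1000 default). Global empirical
  P = (1+#{RSS* ≥ RSS})/(n_sim+1), so it is bounded below by
  1/(n_sim+1); per-variant outlier P-values are the empirical tails of
  each residual contribution, Bonferroni-multiplied by J. The distortion
  test is not implemented. Minimum four instruments (leave-one-out needs
  slack); the other sensitivity estimators require three, following the
  ">2 instruments" gate for sensitivity analyses.

## Mechanism clustering

Variant-level ratios are modeled as a mixture of K substantive normal
components N(θ_k, se_j²) (shared mean, variant-specific variance), a
null component N(0, se_j²), and a junk component uniform on
[min θ̂ − 2·range, max θ̂ + 2·range] — bounded, so the likelihood stays
proper (with a 10⁻⁶ width floor for degenerate inputs). EM updates
cluster means as responsibility- and precision-weighted averages;
convergence at log-likelihood gain < 10⁻⁶, cap 500 iterations, best of
20 seeded restarts with k-means++-style initial spread. K runs from 0 to
k_max (default 5) and is selected by BIC with 2K+1 free parameters
(means + mixing); the null and junk components exist at every K. This is
a self-contained re-implementation of the published mixture-model class
for clustered MR heterogeneity, not a binding to the original R package.

Reporting is deliberately conservative: a cluster is reported only when
at least 4 variants are assigned to it with conditional probability
≥ 0.8 (both thresholds configurable); variants failing the rule fall to
the null or junk cluster, whichever their responsibilities favour.
Raising either threshold can only shrink the reported set (tested as a
monotonicity property).

## Multiplicity, classification, power

BH q-values are computed per family via `statsmodels`
(`multipletests(method="fdr_bh")`), with an independent brute-force
step-up oracle in the tests. The default family pools both outcomes
within an exposure tier (`fdr_family="tier"`): in the emulated study
design, the best primary P of 0.005 maps to q = 0.170 = 34×0.005, which
is only consistent with one family of 17 exposures × 2 outcomes; the
per-(tier, outcome) alternative is available as `"tier_outcome"`.
Classification: significant iff q < 0.05; suggestive iff P < 0.05 and
q ≥ 0.05; null otherwise. Degenerate pairs (NaN P) do not count toward
the family size.

Power uses the two-sided normal approximation with non-centrality
|log OR|·√(N·R²·φ(1−φ)) for a binary outcome with case fraction φ, and
|β|·√(N·R²) for a continuous outcome. At OR = 1 the power is exactly α,
and OR and 1/OR give equal power.

## Synthetic data: what it emulates and what it does not

The generator draws latent instrument strengths γ_j ~ N(0.08, 0.02) with
exposure noise SE 0.01 — z-scores near 8, i.e. genome-wide-significant
instruments as a real exposure GWAS of ~10⁵ samples would supply — and
outcome SEs heterogeneous on [0.02, 0.05], matching the precision of an
outcome GWAS of tens of thousands of samples. Default sample-size
metadata mirrors that design (exposure N = 170,000; outcome
N = 63,926 with ~34% cases for the binary trait, N = 33,536 continuous).
Pleiotropy scenarios: none; balanced or directional direct effects
α_j ~ N(α_mean, α_sd) on a configured fraction of variants; or clustered
mechanisms where blocks of variants carry their own slope θ_k in place
of the causal effect. LD blocks induce correlated noise (correlation
√r²) in both datasets and populate the emitted LD matrix. Allele
pathologies — swapped alleles (transpose, negate β, reflect EAF), strand
flips (complement both alleles), palindromic allele pairs with optional
EAF forced near 0.5 — are applied to the outcome only, keeping the
exposure as the reference orientation so the harmonization audit has a
single-sided ground truth; strand flips skip palindromes because a
flipped palindrome is letter-identical to a swap and its truth label
would be ill-defined. One seeded RNG stream governs all draws, so equal
configs and seeds give byte-identical files; `resample_outcome` redraws
only the outcome noise under an independent seed for multi-outcome
designs sharing one instrument panel.

Deliberately not emulated: realistic allele-frequency spectra and
LD structure, sample overlap between the two GWAS, winner's-curse bias
in instrument discovery, weak instruments (default z ≈ 8), and indels or
multi-allelic variants (rejected at load). Passing tests therefore show
the estimators behave correctly under the stated model — calibration
under the null, robustness rankings under pleiotropy, recovery of
planted mechanisms — not that any particular real-data finding is
correct.

## Numerical choices and edge cases

* Cochran's Q is set to exactly 0 when all ratios are identical,
  avoiding ~10⁻³⁰ rounding residue from the weighted mean.
* P-values from z-statistics are clipped to [1e-300, 1] so records never
  carry a literal zero.
* Selection ties: lexicographic variant ID. Duplicate variant IDs at
  load: keep first, log the rest.
* The canonical TSV writes floats via `repr` and is read back with
  pandas `float_precision="round_trip"`, making write∘read the identity
  bit for bit.
* Study pipelines derive one sub-seed per exposure–outcome pair from the
  global seed; any stage failing with a degenerate-input or
  insufficient-instruments condition yields an NA row and the study
  continues (single-instrument exposures are normal).
* Simulation sizes in the test and acceptance suites (for example 1000
  null studies of 20 instruments, 500 pleiotropy replicates, 200
  outlier-injection replicates) were chosen to give Monte-Carlo error
  comfortably inside the asserted bands while keeping the default runs
  fast on a laptop.

## Known limitations

No multivariable MR, MR-RAPS, Steiger direction filtering, proxy-variant
lookup, or correlated-instrument methods; the MR-PRESSO distortion test
is omitted; LD must be supplied as a matrix. The contamination-mixture
scalar SE summarizes a possibly disconnected confidence set and should
be read alongside the interval payload. Cluster-model selection by BIC
at small J (< ~10) is conservative and may prefer K=0 when mechanisms
are weakly separated.
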