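"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the inputs of a two-sample Mendelian randomization
study: an exposure GWAS and an outcome GWAS measured on separate samples,
sharing a panel of variants.  For variant ``j`` with true instrument
strength ``gamma_j``:

    observed exposure beta  =  gamma_j + eps_xj,       eps_xj ~ N(0, se_xj)
    observed outcome beta   =  theta_j * gamma_j + alpha_j + eps_yj

where ``theta_j`` is the causal effect (a mechanism-specific slope in the
clustered scenario), ``alpha_j`` is a direct (horizontally pleiotropic)
effect on the outcome, and noise is correlated within LD blocks.  Allele
pathologies — swapped effect/other alleles, strand flips, palindromic
variants — are applied to the OUTCOME dataset only, so harmonization is
exercised against a fixed exposure orientation.  Every draw comes from a
single seeded RNG stream: identical config + seed reproduces byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import (
    SUMSTATS_COLUMNS,
    TRAIT_BINARY,
    TRAIT_CONTINUOUS,
    LDMatrix,
    SummaryDataset,
)

import pandas as pd

__all__ = ["SimConfig", "SimResult", "SimConfigError", "simulate_pair"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: allele pairs that are their own strand complement (ambiguous orientation)
PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
NON_PALINDROMIC_PAIRS = [
    (a, b)
    for a in "ACGT"
    for b in "ACGT"
    if a != b and COMPLEMENT[a] != b
]

PLEIOTROPY_MODES = ("none", "balanced", "directional", "clustered")


class SimConfigError(ValueError):
    """Invalid generative configuration; message names the offending field."""


@dataclass
class SimConfig:
    """Generative specification for one exposure/outcome summary-stat pair.

    Pleiotropy scenarios:

    * ``none`` — every variant is a valid instrument.
    * ``balanced`` / ``directional`` — a fraction ``frac_invalid`` of
      variants receive a direct effect alpha_j ~ N(alpha_mean, alpha_sd)
      (alpha_mean is 0 for balanced).
    * ``clustered`` — ``mechanisms`` is a list of (theta_k, n_k): the first
      n_1 variants act through mechanism 1 with slope theta_1, the next n_2
      through mechanism 2, etc.; remaining variants carry ``theta_true``.

    ``se_x`` / ``se_y`` may be a single scale or a (low, high) range drawn
    uniformly per variant.
    """

    n_variants: int = 30
    theta_true: float = 0.0
    beta_x_dist: tuple[float, float] = (0.08, 0.02)  # N(mean, sd) instrument strength
    se_x: float | tuple[float, float] = 0.01
    se_y: float | tuple[float, float] = (0.02, 0.05)
    pleiotropy_mode: str = "none"
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    frac_invalid: float = 0.0
    mechanisms: list[tuple[float, int]] = field(default_factory=list)
    ld_blocks: list[tuple[int, float]] = field(default_factory=list)
    frac_swapped: float = 0.0
    frac_flipped: float = 0.0
    frac_palindromic: float = 0.0
    palindromes_near_half: bool = False
    maf_dist: tuple[float, float] = (0.05, 0.40)
    n_sample_exposure: int = 170_000
    n_sample_outcome: int = 63_926
    outcome_binary: bool = True
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    seed: int = 0

    def validate(self) -> None:
        if self.n_variants < 1:
            raise SimConfigError("n_variants must be >= 1")
        if self.pleiotropy_mode not in PLEIOTROPY_MODES:
            raise SimConfigError(
                f"pleiotropy_mode must be one of {PLEIOTROPY_MODES}"
            )
        for name in ("frac_invalid", "frac_swapped", "frac_flipped", "frac_palindromic"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        for name in ("se_x", "se_y"):
            v = getattr(self, name)
            lo, hi = (v, v) if np.isscalar(v) else v
            if lo <= 0 or hi <= 0 or hi < lo:
                raise SimConfigError(f"{name} scales must be positive (low <= high)")
        if self.beta_x_dist[1] < 0:
            raise SimConfigError("beta_x_dist sd must be >= 0")
        lo, hi = self.maf_dist
        if not (0.0 < lo <= hi <= 0.5):
            raise SimConfigError("maf_dist range must lie within (0, 0.5]")
        if sum(size for size, _ in self.ld_blocks) > self.n_variants:
            raise SimConfigError("ld_blocks sizes sum exceeds n_variants")
        for _, r2 in self.ld_blocks:
            if not 0.0 <= r2 <= 1.0:
                raise SimConfigError("ld_blocks r2 must lie in [0, 1]")
        if self.pleiotropy_mode == "clustered":
            if not self.mechanisms:
                raise SimConfigError("mechanisms required for clustered pleiotropy")
            if sum(n for _, n in self.mechanisms) > self.n_variants:
                raise SimConfigError("mechanisms variant counts exceed n_variants")
        if self.pleiotropy_mode == "balanced" and self.alpha_mean != 0.0:
            raise SimConfigError("alpha_mean must be 0 for balanced pleiotropy")


@dataclass
class SimResult:
    exposure: SummaryDataset
    outcome: SummaryDataset
    truth: pd.DataFrame
    ld: LDMatrix


def _per_variant_scale(rng, spec, n) -> np.ndarray:
    if np.isscalar(spec):
        return np.full(n, float(spec))
    lo, hi = spec
    return rng.uniform(lo, hi, size=n)


def _ld_correlation(config: SimConfig) -> np.ndarray:
    """Block-diagonal correlation matrix; off-diagonal r = sqrt(r2)."""
    n = config.n_variants
    corr = np.eye(n)
    start = 0
    for size, r2 in config.ld_blocks:
        r = np.sqrt(r2)
        corr[start : start + size, start : start + size] = r
        np.fill_diagonal(corr[start : start + size, start : start + size], 1.0)
        start += size
    return corr


def _correlated_noise(rng, corr_chol, scales) -> np.ndarray:
    z = rng.standard_normal(len(scales))
    return (corr_chol @ z) * scales


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def simulate_pair(config: SimConfig) -> SimResult:
    """Generate an (exposure, outcome, truth, LD) bundle from ``config``.

    The truth table records, per variant, the latent instrument strength,
    the slope and direct effect actually used, a validity class, and which
    allele pathologies were applied to the outcome record.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_variants

    width = max(4, len(str(n)))
    snps = [f"rs{j + 1:0{width}d}" for j in range(n)]
    chrom = rng.integers(1, 23, size=n)
    pos = rng.integers(1, 250_000_000, size=n)

    # variant alleles (shared by both datasets pre-pathology)
    is_pal = rng.random(n) < config.frac_palindromic
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    for j in range(n):
        pool = PALINDROMIC_PAIRS if is_pal[j] else NON_PALINDROMIC_PAIRS
        ea[j], oa[j] = pool[rng.integers(len(pool))]

    eaf = rng.uniform(config.maf_dist[0], config.maf_dist[1], size=n)
    if config.palindromes_near_half:
        eaf[is_pal] = rng.uniform(0.45, 0.5, size=int(is_pal.sum()))

    gamma = rng.normal(config.beta_x_dist[0], config.beta_x_dist[1], size=n)
    se_x = _per_variant_scale(rng, config.se_x, n)
    se_y = _per_variant_scale(rng, config.se_y, n)

    # direct (pleiotropic) effects and per-variant slopes
    alpha = np.zeros(n)
    slope = np.full(n, config.theta_true)
    klass = np.array(["valid"] * n, dtype=object)
    mechanism = np.array(["none"] * n, dtype=object)
    if config.pleiotropy_mode in ("balanced", "directional"):
        invalid = rng.random(n) < config.frac_invalid
        alpha[invalid] = rng.normal(
            config.alpha_mean, config.alpha_sd, size=int(invalid.sum())
        )
        klass[invalid] = "pleiotropic"
    elif config.pleiotropy_mode == "clustered":
        start = 0
        for k, (theta_k, n_k) in enumerate(config.mechanisms, start=1):
            slope[start : start + n_k] = theta_k
            klass[start : start + n_k] = f"mechanism_{k}"
            mechanism[start : start + n_k] = f"mechanism_{k}"
            start += n_k

    corr = _ld_correlation(config)
    chol = np.linalg.cholesky(corr)
    beta_x = gamma + _correlated_noise(rng, chol, se_x)
    beta_y = slope * gamma + alpha + _correlated_noise(rng, chol, se_y)

    base = pd.DataFrame(
        {
            "snp": snps,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
        }
    )

    exp_table = base.copy()
    exp_table["beta"] = beta_x
    exp_table["se"] = se_x
    exp_table["pval"] = _pvalues(beta_x, se_x)
    exp_table["n"] = config.n_sample_exposure

    out_table = base.copy()
    out_table["beta"] = beta_y
    out_table["se"] = se_y
    out_table["pval"] = _pvalues(beta_y, se_y)
    out_table["n"] = config.n_sample_outcome

    # allele pathologies: outcome only; strand flips never hit palindromes
    # (for a palindrome a flip is letter-identical to a swap, so the truth
    # label would be ill-defined)
    swapped = rng.random(n) < config.frac_swapped
    flipped = (rng.random(n) < config.frac_flipped) & ~is_pal
    for j in np.flatnonzero(flipped):
        out_table.at[j, "effect_allele"] = COMPLEMENT[out_table.at[j, "effect_allele"]]
        out_table.at[j, "other_allele"] = COMPLEMENT[out_table.at[j, "other_allele"]]
    for j in np.flatnonzero(swapped):
        ea_j = out_table.at[j, "effect_allele"]
        out_table.at[j, "effect_allele"] = out_table.at[j, "other_allele"]
        out_table.at[j, "other_allele"] = ea_j
        out_table.at[j, "beta"] = -out_table.at[j, "beta"]
        out_table.at[j, "eaf"] = 1.0 - out_table.at[j, "eaf"]

    truth = pd.DataFrame(
        {
            "snp": snps,
            "beta_x_true": gamma,
            "slope": slope,
            "alpha": alpha,
            "class": klass,
            "mechanism": mechanism,
            "palindromic": is_pal,
            "swapped": swapped,
            "flipped": flipped,
        }
    )

    ld = LDMatrix(snps=list(snps), r2=corr**2)

    exposure = SummaryDataset(
        trait_name=config.exposure_name,
        trait_type=TRAIT_CONTINUOUS,
        table=exp_table[SUMSTATS_COLUMNS],
    )
    outcome = SummaryDataset(
        trait_name=config.outcome_name,
        trait_type=TRAIT_BINARY if config.outcome_binary else TRAIT_CONTINUOUS,
        table=out_table[SUMSTATS_COLUMNS],
    )
    return SimResult(exposure=exposure, outcome=outcome, truth=truth, ld=ld)


def resample_outcome(
    sim: SimResult,
    seed: int,
    outcome_name: str | None = None,
    binary: bool | None = None,
    n_sample: int | None = None,
) -> SummaryDataset:
    """Redraw the outcome's observational noise with an independent seed.

    Useful for studies testing one instrument panel against several
    outcomes: the instruments, alleles, applied pathologies, and latent
    truth (slopes and direct effects) are preserved; only the sampling
    noise of the outcome associations is new.  Pathology bookkeeping is
    honoured: variants recorded as swapped keep their transposed alleles
    and negated effect sign.
    """
    rng = np.random.default_rng(seed)
    old = sim.outcome.table
    truth = sim.truth
    mean = truth["slope"].to_numpy() * truth["beta_x_true"].to_numpy() + truth[
        "alpha"
    ].to_numpy()
    se = old["se"].to_numpy(float)
    beta = mean + rng.normal(0.0, se)
    sign = np.where(truth["swapped"].to_numpy(), -1.0, 1.0)
    table = old.copy()
    table["beta"] = sign * beta
    table["pval"] = _pvalues(table["beta"].to_numpy(float), se)
    if n_sample is not None:
        table["n"] = n_sample
    if binary is None:
        trait_type = sim.outcome.trait_type
    else:
        trait_type = TRAIT_BINARY if binary else TRAIT_CONTINUOUS
    return SummaryDataset(
        trait_name=outcome_name or sim.outcome.trait_name,
        trait_type=trait_type,
        table=table,
    )
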