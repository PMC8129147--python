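"""Causal-effect estimators for two-sample Mendelian randomization.

All methods operate on per-variant Wald ratios theta_j = beta_Yj / beta_Xj
with delta-method standard errors, and differ in which instruments they
assume valid:

* **IVW** — all instruments valid; inverse-variance-weighted pooling,
  equivalent (under first-order SEs) to weighted least squares of beta_Y
  on beta_X through the origin.  Fixed effects by default, switching to a
  multiplicative random-effects model when Cochran's Q signals
  heterogeneity (Q-derived P < 0.05).
* **Weighted median** — at least half the weight comes from valid
  instruments.
* **Weighted mode** — the largest group of agreeing estimates is valid
  (zero modal pleiotropy).
* **MR-Egger** — instrument strength independent of direct effects
  (InSIDE); the intercept estimates average directional pleiotropy.
* **Contamination mixture** — each variant is either valid (estimate
  normal about the causal effect) or invalid (normal about zero with
  inflated variance); profile likelihood over a grid of candidate effects.
* **MR-PRESSO** — residual-sum-of-squares global pleiotropy test with
  per-variant outlier detection by parametric simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .harmonize import HarmonizedSet

__all__ = [
    "RatioEstimates",
    "MRResult",
    "PressoResult",
    "DegenerateInputError",
    "InsufficientInstrumentsError",
    "wald_ratios",
    "ivw",
    "weighted_median",
    "weighted_mode",
    "mr_egger",
    "contamination_mixture",
    "mr_presso",
]

Z95 = stats.norm.ppf(0.975)


class DegenerateInputError(ValueError):
    """Input carries no usable instruments."""


class InsufficientInstrumentsError(ValueError):
    """Method requires more instruments than available."""


@dataclass
class RatioEstimates:
    """Per-variant Wald ratios with delta-method SEs and IVW weights."""

    snps: list[str]
    theta: np.ndarray
    se: np.ndarray

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if not (len(self.snps) == len(self.theta) == len(self.se)):
            raise ValueError("ratio-estimate fields must be parallel")
        if np.any(~np.isfinite(self.se)) or np.any(self.se <= 0):
            raise ValueError("ratio SEs must be positive and finite")

    @property
    def weights(self) -> np.ndarray:
        return 1.0 / self.se**2

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class MRResult:
    """One estimator's causal estimate on the beta (log-OR for binary) scale."""

    method: str
    estimate: float
    se: float
    ci95: tuple[float, float]
    pval: float
    n_snps: int
    effects_model: str = "n/a"  # fixed | random | n/a
    Q: float = np.nan
    Q_pval: float = np.nan
    extra: dict = field(default_factory=dict)

    def as_row(self) -> dict:
        row = {
            "method": self.method,
            "n_snps": self.n_snps,
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci95[0],
            "ci_high": self.ci95[1],
            "pval": self.pval,
            "effects_model": self.effects_model,
            "Q": self.Q,
            "Q_pval": self.Q_pval,
        }
        row["intercept"] = self.extra.get("intercept", np.nan)
        row["intercept_pval"] = self.extra.get("intercept_pval", np.nan)
        return row


@dataclass
class PressoResult:
    """MR-PRESSO global test and per-variant outlier p-values."""

    global_rss_obs: float
    global_pval: float
    outlier_pval: np.ndarray  # Bonferroni-adjusted, parallel to input order
    snps: list[str]
    n_sim: int
    seed: int

    def outliers(self, alpha: float = 0.05) -> list[str]:
        return [s for s, p in zip(self.snps, self.outlier_pval) if p < alpha]


def wald_ratios(h: HarmonizedSet, se_order: str = "first") -> RatioEstimates:
    """Per-variant causal estimates beta_Y/beta_X with delta-method SEs.

    ``se_order='first'`` gives se_Y/|beta_X| (the convention under which
    IVW is exactly WLS through the origin); ``'second'`` adds the
    instrument-uncertainty term sqrt(se_Y^2/beta_X^2 + beta_Y^2 se_X^2 / beta_X^4).
    Variants with beta_X == 0 are dropped (their ratio is undefined).
    """
    if se_order not in ("first", "second"):
        raise ValueError("se_order must be 'first' or 'second'")
    t = h.table
    nonzero = t["beta_x"].to_numpy() != 0.0
    if not nonzero.any():
        raise DegenerateInputError("all instrument-exposure effects are zero")
    t = t[nonzero]
    bx = t["beta_x"].to_numpy(float)
    by = t["beta_y"].to_numpy(float)
    sx = t["se_x"].to_numpy(float)
    sy = t["se_y"].to_numpy(float)
    theta = by / bx
    if se_order == "first":
        se = sy / np.abs(bx)
    else:
        se = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    return RatioEstimates(snps=list(t["snp"]), theta=theta, se=se)


def cochran_q(r: RatioEstimates, estimate: float) -> tuple[float, float]:
    """Cochran's heterogeneity Q about ``estimate`` and its chi-square P.

    P is NaN for a single instrument (0 degrees of freedom).
    """
    w = r.weights
    if np.all(r.theta == r.theta[0]):
        q = 0.0  # exact: no heterogeneity whatever the weighted mean rounds to
    else:
        q = float(np.sum(w * (r.theta - estimate) ** 2))
    df = r.n_snps - 1
    q_pval = float(stats.chi2.sf(q, df)) if df >= 1 else np.nan
    return q, q_pval


def ivw(r: RatioEstimates, model: str = "auto") -> MRResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``model='auto'`` uses fixed effects unless Cochran's Q-derived
    P < 0.05, in which case the SE is inflated by the multiplicative
    overdispersion factor max(1, sqrt(Q/(J-1))) (random effects, floored
    at the fixed model).  A single instrument forces the fixed model with
    Q undefined.
    """
    if model not in ("auto", "fixed", "random"):
        raise ValueError("model must be auto, fixed or random")
    if r.n_snps == 0:
        raise DegenerateInputError("no ratio estimates to pool")
    w = r.weights
    estimate = float(np.sum(w * r.theta) / np.sum(w))
    fixed_se = float(np.sum(w) ** -0.5)
    q, q_pval = cochran_q(r, estimate)

    if r.n_snps == 1:
        effects, se = "fixed", fixed_se
    elif model == "fixed":
        effects, se = "fixed", fixed_se
    elif model == "random" or (model == "auto" and q_pval < 0.05):
        effects = "random"
        se = fixed_se * max(1.0, np.sqrt(q / (r.n_snps - 1)))
    else:
        effects, se = "fixed", fixed_se

    pval = float(2.0 * stats.norm.sf(abs(estimate) / se))
    return MRResult(
        method="ivw",
        estimate=estimate,
        se=se,
        ci95=(estimate - Z95 * se, estimate + Z95 * se),
        pval=pval,
        n_snps=r.n_snps,
        effects_model=effects,
        Q=q,
        Q_pval=q_pval,
    )


def _weighted_median_point(theta: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(theta, kind="stable")
    th = theta[order]
    ws = w[order]
    s = (np.cumsum(ws) - 0.5 * ws) / np.sum(ws)
    return float(np.interp(0.5, s, th))


def _parametric_bootstrap_se(point_fn, r: RatioEstimates, n_boot: int, seed: int):
    """SD of ``point_fn`` over theta_j* ~ N(theta_j, se_j) resamples."""
    if n_boot <= 0:
        return np.nan
    rng = np.random.default_rng(seed)
    draws = rng.normal(r.theta, r.se, size=(n_boot, r.n_snps))
    w = r.weights
    estimates = np.array([point_fn(draws[b], w) for b in range(n_boot)])
    return float(np.std(estimates, ddof=1))


def _bootstrap_result(method, estimate, se, n_snps, n_boot, seed, extra=None) -> MRResult:
    if np.isnan(se):
        ci, pval = (np.nan, np.nan), np.nan
    else:
        ci = (estimate - Z95 * se, estimate + Z95 * se)
        pval = float(2.0 * stats.norm.sf(abs(estimate) / se))
    payload = {"n_boot": n_boot, "seed": seed}
    if extra:
        payload.update(extra)
    return MRResult(
        method=method,
        estimate=estimate,
        se=se,
        ci95=ci,
        pval=pval,
        n_snps=n_snps,
        extra=payload,
    )


def weighted_median(r: RatioEstimates, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of Wald ratios; consistent when >=50% of weight is valid.

    The point estimate interpolates the sorted ratios at standardized
    cumulative weight 0.5; the SE is a parametric bootstrap (``n_boot=0``
    returns the point estimate with NaN SE/CI/P).
    """
    if r.n_snps < 3:
        raise InsufficientInstrumentsError("weighted median needs >= 3 instruments")
    estimate = _weighted_median_point(r.theta, r.weights)
    se = _parametric_bootstrap_se(_weighted_median_point, r, n_boot, seed)
    return _bootstrap_result("weighted_median", estimate, se, r.n_snps, n_boot, seed)


def _silverman_bandwidth(theta: np.ndarray, phi: float) -> float:
    j = len(theta)
    sd = float(np.std(theta, ddof=1))
    iqr = float(np.subtract(*np.percentile(theta, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return phi * 0.9 * spread * j ** (-0.2)


def _mode_grid(theta: np.ndarray, h: float, n_grid: int) -> np.ndarray:
    lo = theta.min() - 3.0 * h
    hi = theta.max() + 3.0 * h
    return np.linspace(lo, hi, n_grid)


def _weighted_mode_point(
    theta: np.ndarray, w: np.ndarray, phi: float = 1.0, n_grid: int = 512
) -> float:
    h = _silverman_bandwidth(theta, phi)
    if h <= 0:  # all ratios identical
        return float(theta[0])
    grid = _mode_grid(theta, h, n_grid)
    dens = np.sum(
        w[None, :] * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2),
        axis=1,
    )
    return float(grid[np.argmax(dens)])


def weighted_mode(
    r: RatioEstimates,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
    n_grid: int = 512,
) -> MRResult:
    """Mode of the weighted kernel density of Wald ratios.

    Consistent when the largest group of agreeing per-variant estimates
    comes from valid instruments, even if they are a minority.  Bandwidth
    is the modified Silverman rule 0.9 min(sd, iqr/1.34) J^(-1/5) scaled
    by ``phi``.
    """
    if r.n_snps < 3:
        raise InsufficientInstrumentsError("weighted mode needs >= 3 instruments")
    estimate = _weighted_mode_point(r.theta, r.weights, phi, n_grid)
    point = lambda th, w: _weighted_mode_point(th, w, phi, n_grid)
    se = _parametric_bootstrap_se(point, r, n_boot, seed)
    return _bootstrap_result(
        "weighted_mode", estimate, se, r.n_snps, n_boot, seed, {"phi": phi}
    )


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger: weighted regression of beta_Y on beta_X with an intercept.

    Variants are first oriented so beta_X >= 0 (both betas negated where
    needed).  The slope is the causal estimate under InSIDE; the intercept
    estimates average directional pleiotropy.  Both SEs carry the
    multiplicative overdispersion factor max(1, sqrt(RSS_w/(J-2))) and
    P-values use the t distribution with J-2 degrees of freedom.
    """
    t = h.table[h.table["beta_x"] != 0.0]
    j = len(t)
    if j < 3:
        raise InsufficientInstrumentsError("MR-Egger needs >= 3 instruments")
    bx = t["beta_x"].to_numpy(float).copy()
    by = t["beta_y"].to_numpy(float).copy()
    sy = t["se_y"].to_numpy(float)
    neg = bx < 0
    bx[neg], by[neg] = -bx[neg], -by[neg]

    w = 1.0 / sy**2
    X = np.column_stack([np.ones(j), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid**2))
    inflate = max(1.0, np.sqrt(rss_w / (j - 2)))
    cov = np.linalg.inv(xtwx) * inflate**2
    se_int, se_slope = np.sqrt(np.diag(cov))
    intercept, slope = coef

    df = j - 2
    p_slope = float(2.0 * stats.t.sf(abs(slope) / se_slope, df))
    p_int = float(2.0 * stats.t.sf(abs(intercept) / se_int, df))
    tcrit = stats.t.ppf(0.975, df)
    return MRResult(
        method="mr_egger",
        estimate=float(slope),
        se=float(se_slope),
        ci95=(slope - tcrit * se_slope, slope + tcrit * se_slope),
        pval=p_slope,
        n_snps=j,
        extra={
            "intercept": float(intercept),
            "intercept_se": float(se_int),
            "intercept_pval": p_int,
            "overdispersion": float(inflate),
        },
    )


def contamination_mixture(
    r: RatioEstimates,
    psi: float | None = None,
    n_grid: int = 1000,
    grid_span: tuple[float, float] | None = None,
) -> MRResult:
    """Contamination-mixture estimate by profile likelihood over a grid.

    For candidate effect theta, a valid variant contributes
    log N(theta_j; theta, se_j) and an invalid one
    log N(theta_j; 0, sqrt(se_j^2 + psi^2)); each variant takes the larger.
    The estimate is the grid argmax; the 95% confidence set keeps every
    grid point within chi2_1(0.95)/2 of the maximum log-likelihood and may
    be a union of intervals (all recorded in the payload, with the
    valid/invalid split at the maximum).
    """
    if r.n_snps < 3:
        raise InsufficientInstrumentsError(
            "contamination mixture needs >= 3 instruments"
        )
    if psi is None:
        psi = 1.5 * float(np.std(r.theta, ddof=1))
        if psi <= 0:
            psi = 1.5 * float(np.mean(r.se))
    if psi <= 0:
        raise ValueError("psi must be positive")
    if grid_span is None:
        pad = 2.0 * float(r.se.max())
        grid_span = (float(r.theta.min()) - pad, float(r.theta.max()) + pad)
    if not (n_grid >= 10 and grid_span[1] > grid_span[0]):
        raise ValueError("degenerate contamination-mixture grid")
    grid = np.linspace(grid_span[0], grid_span[1], n_grid)

    # (grid, variant) log-likelihood under the valid component
    ll_valid = stats.norm.logpdf(
        r.theta[None, :], loc=grid[:, None], scale=r.se[None, :]
    )
    ll_invalid = stats.norm.logpdf(
        r.theta, loc=0.0, scale=np.sqrt(r.se**2 + psi**2)
    )  # constant in theta
    per_variant = np.maximum(ll_valid, ll_invalid[None, :])
    profile = per_variant.sum(axis=1)

    i_max = int(np.argmax(profile))
    estimate = float(grid[i_max])
    valid_at_max = ll_valid[i_max] >= ll_invalid

    cutoff = profile[i_max] - stats.chi2.ppf(0.95, 1) / 2.0
    inside = profile >= cutoff
    intervals = []
    start = None
    for i, flag in enumerate(inside):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            intervals.append((float(grid[start]), float(grid[i - 1])))
            start = None
    if start is not None:
        intervals.append((float(grid[start]), float(grid[-1])))

    ci = (intervals[0][0], intervals[-1][1])
    se = (ci[1] - ci[0]) / (2.0 * Z95)
    # likelihood-ratio P against theta = 0
    ll0 = float(
        np.sum(np.maximum(stats.norm.logpdf(r.theta, 0.0, r.se), ll_invalid))
    )
    lr = max(0.0, 2.0 * (float(profile[i_max]) - ll0))
    pval = float(stats.chi2.sf(lr, 1))
    return MRResult(
        method="contamination_mixture",
        estimate=estimate,
        se=float(se),
        ci95=ci,
        pval=pval,
        n_snps=r.n_snps,
        extra={
            "psi": float(psi),
            "ci_intervals": intervals,
            "valid_at_max": {s: bool(v) for s, v in zip(r.snps, valid_at_max)},
            "n_grid": n_grid,
        },
    )


def _loo_ivw(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over variants."""
    sw = np.sum(w)
    swt = np.sum(w * theta)
    return (swt - w * theta) / (sw - w)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, seed: int = 0) -> PressoResult:
    """MR-PRESSO global heterogeneity test and outlier search.

    The observed statistic is the weighted residual sum of squares of each
    variant about the leave-one-out IVW prediction; its null distribution
    is built by re-simulating outcome effects from the no-pleiotropy model
    (and recomputing the leave-one-out fits on each simulated dataset).
    Per-variant outlier P-values are the empirical tail probabilities of
    each residual contribution, Bonferroni-adjusted by the number of
    instruments.
    """
    t = h.table[h.table["beta_x"] != 0.0]
    j = len(t)
    if j < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 instruments")
    bx = t["beta_x"].to_numpy(float)
    by = t["beta_y"].to_numpy(float)
    sy = t["se_y"].to_numpy(float)
    theta_j = by / bx
    w = bx**2 / sy**2  # IVW weights under first-order SEs

    loo = _loo_ivw(theta_j, w)
    contrib_obs = w * (theta_j - loo) ** 2  # = (by - loo*bx)^2 / sy^2
    rss_obs = float(np.sum(contrib_obs))

    rng = np.random.default_rng(seed)
    by_sim = rng.normal(loo * bx, sy, size=(n_sim, j))
    theta_sim = by_sim / bx
    sw = np.sum(w)
    swt = theta_sim @ w
    loo_sim = (swt[:, None] - w * theta_sim) / (sw - w)
    contrib_sim = w * (theta_sim - loo_sim) ** 2
    rss_sim = contrib_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    tail = (1 + np.sum(contrib_sim >= contrib_obs[None, :], axis=0)) / (n_sim + 1)
    outlier_pval = np.minimum(1.0, tail * j)
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pval=outlier_pval,
        snps=list(t["snp"]),
        n_sim=n_sim,
        seed=seed,
    )
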