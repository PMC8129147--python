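"""Likelihood-based clustering of variant-specific causal estimates.

When instruments act on an exposure through distinct biological
mechanisms, their Wald ratios concentrate around mechanism-specific
values rather than a single causal effect.  This module fits, by EM, a
mixture over the per-variant ratio estimates with three component kinds:

* K substantive clusters:  theta_j ~ N(theta_k, se_j^2)  (shared mean,
  variant-specific variance),
* a null cluster:          theta_j ~ N(0, se_j^2),
* a junk cluster:          theta_j ~ Uniform over an interval extending
  two data ranges beyond the observed ratios, absorbing estimates that
  fit nowhere.

K is chosen by BIC over 0..k_max.  Reporting is conservative: a variant
belongs to a cluster only with conditional assignment probability >= 0.8,
and a cluster is reported only when at least 4 variants satisfy that
criterion; everything else falls to the null or junk cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import RatioEstimates
from .harmonize import HarmonizedSet

__all__ = [
    "ClusterModel",
    "EMConvergenceError",
    "fit_clusters",
    "apply_reporting_rule",
    "cluster_scatter_table",
    "PROB_MIN",
    "MIN_VARIANTS",
]

PROB_MIN = 0.8
MIN_VARIANTS = 4

NULL_LABEL = "null"
JUNK_LABEL = "junk"


class EMConvergenceError(RuntimeError):
    """EM failed to converge on every restart; carries the best partial fit."""

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class ClusterModel:
    """Fitted mixture over variant-specific ratio estimates.

    Component order in probability vectors: substantive clusters 1..K,
    then null, then junk.  ``labels`` holds per-variant hard assignments
    ("cluster_k", "null" or "junk") after the reporting rule.
    """

    snps: list[str]
    K: int
    means: np.ndarray  # length K
    mean_ses: np.ndarray
    mixing: np.ndarray  # length K + 2, sums to 1
    responsibilities: np.ndarray  # (J, K + 2), rows sum to 1
    labels: list[str]
    reported_clusters: list[int]  # 1-based indices of clusters passing the rule
    log_likelihood: float
    bic: float
    bic_path: dict[int, float]
    n_iter: int
    n_restarts: int
    seed: int
    prob_min: float = PROB_MIN
    min_variants: int = MIN_VARIANTS
    meta: dict = field(default_factory=dict)

    @property
    def n_reported(self) -> int:
        return len(self.reported_clusters)

    def assignment_prob(self) -> np.ndarray:
        """Each variant's probability for its argmax component."""
        return self.responsibilities.max(axis=1)


def _junk_bounds(theta: np.ndarray) -> tuple[float, float]:
    lo, hi = float(theta.min()), float(theta.max())
    rng = hi - lo
    if rng <= 0:
        rng = 1e-6  # width floor keeps the uniform density proper
    return lo - 2.0 * rng, hi + 2.0 * rng


def _component_loglik(theta, se, means, junk_lo, junk_hi) -> np.ndarray:
    """(J, K+2) per-variant log-density under each component."""
    j = len(theta)
    k = len(means)
    ll = np.empty((j, k + 2))
    if k:
        ll[:, :k] = stats.norm.logpdf(theta[:, None], means[None, :], se[:, None])
    ll[:, k] = stats.norm.logpdf(theta, 0.0, se)
    ll[:, k + 1] = -np.log(junk_hi - junk_lo)
    return ll


def _em_once(theta, se, k, rng, max_iter, tol):
    """One EM run from a k-means++-style initialization.

    Returns (means, mixing, responsibilities, loglik, n_iter, converged).
    """
    j = len(theta)
    junk_lo, junk_hi = _junk_bounds(theta)

    # spread initial means over observed ratios, favouring distant points
    means = np.empty(k)
    if k:
        means[0] = theta[rng.integers(j)]
        for i in range(1, k):
            d2 = np.min((theta[:, None] - means[None, :i]) ** 2, axis=1)
            probs = d2 / d2.sum() if d2.sum() > 0 else np.full(j, 1.0 / j)
            means[i] = theta[rng.choice(j, p=probs)]
    mixing = np.full(k + 2, 1.0 / (k + 2))

    w = 1.0 / se**2
    prev_ll = -np.inf
    converged = False
    ll_history = []
    for it in range(1, max_iter + 1):
        comp_ll = _component_loglik(theta, se, means, junk_lo, junk_hi)
        joint = comp_ll + np.log(np.maximum(mixing, 1e-300))[None, :]
        norm = np.logaddexp.reduce(joint, axis=1)
        resp = np.exp(joint - norm[:, None])
        ll = float(norm.sum())
        ll_history.append(ll)

        # M step: precision- and responsibility-weighted means
        for i in range(k):
            denom = np.sum(resp[:, i] * w)
            if denom > 0:
                means[i] = np.sum(resp[:, i] * w * theta) / denom
        mixing = resp.mean(axis=0)

        if ll - prev_ll < tol and it > 1:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll

    # final E step with converged parameters
    comp_ll = _component_loglik(theta, se, means, junk_lo, junk_hi)
    joint = comp_ll + np.log(np.maximum(mixing, 1e-300))[None, :]
    norm = np.logaddexp.reduce(joint, axis=1)
    resp = np.exp(joint - norm[:, None])
    ll = float(norm.sum())
    return means, mixing, resp, ll, it, converged, ll_history


def fit_clusters(
    r: RatioEstimates,
    k_max: int = 5,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-6,
    prob_min: float = PROB_MIN,
    min_variants: int = MIN_VARIANTS,
) -> ClusterModel:
    """Fit the mixture for each K in 0..k_max and select by BIC.

    Each K is fit from ``n_restarts`` seeded initializations, keeping the
    best log-likelihood; free parameters per model are the K means plus
    K+1 mixing proportions.  The returned model already carries the
    conservative reporting rule applied at (``prob_min``, ``min_variants``).
    """
    if r.n_snps < 2:
        raise ValueError("clustering needs >= 2 instruments")
    theta, se = r.theta, r.se
    rng = np.random.default_rng(seed)

    best = None
    bic_path: dict[int, float] = {}
    any_converged = False
    for k in range(k_max + 1):
        best_k = None
        for _ in range(max(1, n_restarts if k else 1)):
            means, mixing, resp, ll, n_iter, conv, _ = _em_once(
                theta, se, k, rng, max_iter, tol
            )
            any_converged = any_converged or conv
            if best_k is None or ll > best_k[3]:
                best_k = (means, mixing, resp, ll, n_iter, conv)
        means, mixing, resp, ll, n_iter, conv = best_k
        n_params = 2 * k + 1
        bic = -2.0 * ll + n_params * np.log(r.n_snps)
        bic_path[k] = float(bic)
        if best is None or bic < best["bic"]:
            best = dict(
                k=k, means=means, mixing=mixing, resp=resp, ll=ll,
                n_iter=n_iter, bic=float(bic),
            )

    model = ClusterModel(
        snps=list(r.snps),
        K=best["k"],
        means=np.asarray(best["means"], dtype=float),
        mean_ses=_cluster_mean_ses(best["resp"], se, best["k"]),
        mixing=best["mixing"],
        responsibilities=best["resp"],
        labels=[],
        reported_clusters=[],
        log_likelihood=best["ll"],
        bic=best["bic"],
        bic_path=bic_path,
        n_iter=best["n_iter"],
        n_restarts=n_restarts,
        seed=seed,
        prob_min=prob_min,
        min_variants=min_variants,
    )
    model = apply_reporting_rule(model, prob_min, min_variants)
    if not any_converged:
        raise EMConvergenceError(
            f"EM did not converge within {max_iter} iterations on any restart",
            best_fit=model,
        )
    return model


def _cluster_mean_ses(resp: np.ndarray, se: np.ndarray, k: int) -> np.ndarray:
    """SE of each cluster mean: inverse root of responsibility-weighted precision."""
    ses = np.empty(k)
    w = 1.0 / se**2
    for i in range(k):
        prec = np.sum(resp[:, i] * w)
        ses[i] = prec**-0.5 if prec > 0 else np.inf
    return ses


def apply_reporting_rule(
    model: ClusterModel,
    prob_min: float = PROB_MIN,
    min_variants: int = MIN_VARIANTS,
) -> ClusterModel:
    """Conservative reporting: keep clusters with >= ``min_variants`` variants
    assigned at conditional probability >= ``prob_min``; relabel everything
    else to the null or junk cluster (whichever is more probable)."""
    resp = model.responsibilities
    k = model.K
    reported = []
    for i in range(k):
        members = np.sum((resp.argmax(axis=1) == i) & (resp[:, i] >= prob_min))
        if members >= min_variants:
            reported.append(i + 1)

    labels = []
    for j in range(len(model.snps)):
        arg = int(resp[j].argmax())
        if arg < k and (arg + 1) in reported and resp[j, arg] >= prob_min:
            labels.append(f"cluster_{arg + 1}")
        elif resp[j, k] >= resp[j, k + 1]:
            labels.append(NULL_LABEL)
        else:
            labels.append(JUNK_LABEL)
    return replace(
        model,
        labels=labels,
        reported_clusters=reported,
        prob_min=prob_min,
        min_variants=min_variants,
    )


def cluster_scatter_table(model: ClusterModel, h: HarmonizedSet) -> pd.DataFrame:
    """Per-variant scatter rows (exposure vs outcome associations with 95% CI
    half-widths, cluster label and assignment probability), ready to plot."""
    t = h.table[h.table["beta_x"] != 0.0].reset_index(drop=True)
    if list(t["snp"]) != list(model.snps):
        raise ValueError("cluster model and harmonized set cover different variants")
    z = stats.norm.ppf(0.975)
    return pd.DataFrame(
        {
            "snp": model.snps,
            "beta_x": t["beta_x"],
            "se_x": t["se_x"],
            "beta_y": t["beta_y"],
            "se_y": t["se_y"],
            "ci_half_x": z * t["se_x"],
            "ci_half_y": z * t["se_y"],
            "cluster": model.labels,
            "assignment_prob": model.assignment_prob(),
        }
    )
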