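"""Multiplicity control, significance classification, and MR power.

Exposures are tested in families (by default one family per exposure
tier x outcome); within each family P-values are converted to
Benjamini-Hochberg q-values and classified:

* **significant** — q below the FDR threshold (default 5%),
* **suggestive**  — nominal P < 0.05 but q above the threshold,
* **null**        — otherwise.

Power uses the standard normal approximation for two-sample MR: with
instruments explaining a fraction R^2 of exposure variance, the IVW
z-statistic has non-centrality |log OR| * sqrt(N * R^2 * phi * (1 - phi))
for a binary outcome with case fraction phi (drop the phi(1-phi) factor
for a continuous outcome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PowerSpec",
    "bh_fdr",
    "classify",
    "mr_power_binary",
    "mr_power_continuous",
    "SIGNIFICANT",
    "SUGGESTIVE",
    "NULL",
]

SIGNIFICANT = "significant"
SUGGESTIVE = "suggestive"
NULL = "null"


@dataclass
class PowerSpec:
    """Inputs of the MR power calculation for a binary outcome."""

    n_total: int
    case_fraction: float
    r2: float
    or_alt: float
    alpha: float = 0.05

    def validate(self) -> None:
        if self.n_total < 1:
            raise ValueError("n_total must be >= 1")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0.0 < self.r2 < 1.0:
            raise ValueError("r2 must lie in (0, 1)")
        if self.or_alt <= 0:
            raise ValueError("or_alt must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order.

    q_(i) = min_{k >= i} m p_(k) / k, capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def classify(
    results: pd.DataFrame,
    alpha: float = 0.05,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Append BH q-values and a significance class to one family's results.

    ``results`` needs a ``pval`` column; rows with NaN P (degenerate
    pairs) get NaN q and class ``null`` and do not count toward the
    family size m.
    """
    out = results.copy()
    pv = out["pval"].to_numpy(float)
    ok = np.isfinite(pv)
    q = np.full(len(out), np.nan)
    if ok.any():
        q[ok] = bh_fdr(pv[ok])
    out["qval"] = q

    labels = []
    for p_i, q_i in zip(pv, q):
        if np.isfinite(q_i) and q_i < q_threshold:
            labels.append(SIGNIFICANT)
        elif np.isfinite(p_i) and p_i < alpha:
            labels.append(SUGGESTIVE)
        else:
            labels.append(NULL)
    out["classification"] = labels
    return out


def _power_from_ncp(x: float, alpha: float) -> float:
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    return float(stats.norm.cdf(-z + x) + stats.norm.cdf(-z - x))


def mr_power_binary(spec: PowerSpec) -> float:
    """Two-sided IVW power against OR = ``or_alt`` for a binary outcome."""
    spec.validate()
    b = np.log(spec.or_alt)
    x = abs(b) * np.sqrt(
        spec.n_total * spec.r2 * spec.case_fraction * (1.0 - spec.case_fraction)
    )
    return _power_from_ncp(x, spec.alpha)


def mr_power_continuous(
    n_total: int, r2: float, beta_alt: float, alpha: float = 0.05
) -> float:
    """Power for a continuous outcome (effect in SD units per exposure unit)."""
    if n_total < 1 or not 0.0 < r2 < 1.0 or not 0.0 < alpha < 1.0:
        raise ValueError("invalid power inputs")
    x = abs(beta_alt) * np.sqrt(n_total * r2)
    return _power_from_ncp(x, alpha)
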