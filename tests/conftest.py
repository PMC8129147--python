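import numpy as np
import pandas as pd
import pytest

from twosmr.harmonize import HarmonizedSet


def make_harmonized(beta_x, beta_y, se_x=None, se_y=None, snps=None) -> HarmonizedSet:
    """Build a HarmonizedSet directly from arrays (bypassing file I/O)."""
    beta_x = np.asarray(beta_x, dtype=float)
    beta_y = np.asarray(beta_y, dtype=float)
    n = len(beta_x)
    se_x = np.full(n, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    se_y = np.full(n, 0.05) if se_y is None else np.asarray(se_y, dtype=float)
    snps = snps or [f"rs{i + 1:04d}" for i in range(n)]
    table = pd.DataFrame(
        {
            "snp": snps,
            "beta_x": beta_x,
            "se_x": se_x,
            "beta_y": beta_y,
            "se_y": se_y,
            "eaf": np.full(n, 0.3),
        }
    )
    audit = pd.DataFrame({"snp": snps, "action": "kept", "reason": ""})
    return HarmonizedSet(
        exposure_name="exposure", outcome_name="outcome", table=table, audit=audit
    )


def random_harmonized(rng, j, theta=0.2):
    """Random but well-conditioned harmonized set for oracle comparisons."""
    beta_x = rng.normal(0.1, 0.03, j)
    beta_x[np.abs(beta_x) < 1e-3] = 0.05
    se_y = rng.uniform(0.01, 0.08, j)
    beta_y = theta * beta_x + rng.normal(0, se_y)
    se_x = rng.uniform(0.005, 0.02, j)
    return make_harmonized(beta_x, beta_y, se_x, se_y)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
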