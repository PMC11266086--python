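import numpy as np
import pandas as pd
import pytest

from mrlink.gwas_io import SummaryStatsTable
from mrlink.harmonize import HarmonizedDataset


def make_table(trait="trait", **cols) -> SummaryStatsTable:
    """Small canonical summary-stats table; keyword overrides per column."""
    from scipy import stats

    lengths = [len(v) for v in cols.values() if isinstance(v, (list, tuple, np.ndarray, pd.Series))]
    n = max(lengths) if lengths else 3
    base = {
        "SNP": [f"rs{i + 1}" for i in range(n)],
        "EA": ["A"] * n,
        "OA": ["G"] * n,
        "EAF": [0.3] * n,
        "BETA": [0.1] * n,
        "SE": [0.02] * n,
        "N": [100000] * n,
    }
    base.update(cols)
    if "P" in cols and "BETA" not in cols:
        # keep |beta/se| consistent with the requested p-values
        z = stats.norm.isf(np.asarray(cols["P"], float) / 2)
        base["BETA"] = list(z * np.asarray(base["SE"], float))
    elif "P" not in cols:
        z = np.abs(np.asarray(base["BETA"], float)) / np.asarray(base["SE"], float)
        base["P"] = list(np.clip(2 * stats.norm.sf(z), 1e-300, 1.0))
    return SummaryStatsTable(trait, pd.DataFrame(base))


def make_dataset(gamma, Gamma, se_Gamma, se_gamma=None) -> HarmonizedDataset:
    gamma = np.asarray(gamma, float)
    if se_gamma is None:
        se_gamma = np.full_like(gamma, 0.01)
    return HarmonizedDataset(
        variant_ids=np.array([f"rs{i + 1}" for i in range(len(gamma))], dtype=object),
        gamma=gamma,
        se_gamma=np.asarray(se_gamma, float),
        Gamma=np.asarray(Gamma, float),
        se_Gamma=np.asarray(se_Gamma, float),
    )


@pytest.fixture
def random_dataset():
    """Factory for random harmonized datasets with a well-behaved exposure."""

    def _make(k=50, seed=0, beta=0.1, pleiotropy=0.0):
        rng = np.random.default_rng(seed)
        gamma = rng.uniform(0.03, 0.15, k) * rng.choice([-1, 1], k)
        se_gamma = rng.uniform(0.002, 0.005, k)
        se_Gamma = rng.uniform(0.002, 0.006, k)
        Gamma = rng.normal(beta * gamma + pleiotropy, se_Gamma)
        return make_dataset(gamma, Gamma, se_Gamma, se_gamma)

    return _make
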