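import numpy as np
import pandas as pd
import pytest

from metabomr import simdata
from metabomr.preprocess import FeatureTable


@pytest.fixture
def ir_config():
    """10-SNP insulin-resistance score at a small n for fast unit tests."""
    return simdata.SimConfig.insulin_resistance(n_individuals=800, seed=7)


@pytest.fixture
def small_cohort(ir_config):
    g = simdata.simulate_genotypes(ir_config.rafs, ir_config.n_individuals,
                                   seed=ir_config.seed, snp_ids=ir_config.snp_ids)
    cohort, mets = simdata.simulate_cohort(g, ir_config)
    return g, cohort, mets


@pytest.fixture
def feature_table():
    return simdata.simulate_feature_table(n_samples=40, n_features=60, seed=11)


def make_feature_table(intensities: np.ndarray, rt=None, plates=None, order=None,
                       dup_pairs=None, log_scale=False) -> FeatureTable:
    """Hand-built FeatureTable for targeted preprocessing tests."""
    n, p = intensities.shape
    sample_ids = [f"s{i}" for i in range(n)]
    feats = pd.DataFrame({
        "id": [f"f{j}" for j in range(p)],
        "mz": np.linspace(100, 900, p),
        "rt_seconds": rt if rt is not None else np.full(p, 120.0),
        "annotation": [None] * p,
    })
    meta = pd.DataFrame({
        "plate": plates if plates is not None else ["p1"] * n,
        "order": order if order is not None else np.arange(n),
        "duplicate_pair": dup_pairs if dup_pairs is not None else np.arange(n) // 2,
    }, index=sample_ids)
    intens = pd.DataFrame(intensities, index=sample_ids, columns=list(feats["id"]))
    return FeatureTable(features=feats, intensities=intens, sample_meta=meta,
                        log_scale=log_scale)
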