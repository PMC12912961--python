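import numpy as np
import pytest

from oligocount import (
    SyntheticConfig,
    build_distribution,
    filter_observable,
    simulate_cluster_compositions,
)
from oligocount.oligomer import CopyNumberDistribution

# Wild-type generating condition: trimers with monomer mean 2.2 and an
# oligomer mean chosen so the full-ensemble mean copy number is 6.6.
WT_K = 3
WT_M = 2.2
WT_KMER_MEAN = 4.4 / 3.0
WT_N = 878

# Trimer-interface mutant condition: monomer + hexamer mixture.
MUT_K = 6
MUT_M = 2.0
MUT_KMER_MEAN = 1.0
MUT_N = 226


def wt_config(seed: int, n_clusters: int = WT_N, **kw) -> SyntheticConfig:
    return SyntheticConfig(
        seed=seed,
        oligomer_size=WT_K,
        monomer_mean=WT_M,
        oligomer_mean=WT_KMER_MEAN,
        n_clusters=n_clusters,
        **kw,
    )


def exact_distribution(pred: np.ndarray) -> CopyNumberDistribution:
    """An 'infinite sample' histogram whose observed frequencies equal a
    predicted distribution exactly (no truncation renormalization)."""
    counts = {n: float(p) for n, p in enumerate(pred) if n >= 1 and p > 0}
    mean = sum(n * p for n, p in counts.items())
    return CopyNumberDistribution(counts=counts, n_total=1, mean_N=mean)


@pytest.fixture(scope="session")
def wt_clusters():
    return simulate_cluster_compositions(wt_config(seed=11))


@pytest.fixture(scope="session")
def wt_distribution(wt_clusters):
    return build_distribution(filter_observable(wt_clusters))
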