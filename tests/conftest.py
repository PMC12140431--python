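import numpy as np
import pytest

from colocpriors.region_data import RegionSummaryStats


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def make_sumstats(
    q=5,
    trait_id="trait",
    trait_type="quantitative",
    chromosome="1",
    seed=0,
    ids=None,
    beta=None,
    se=None,
    **kw,
):
    """Small valid summary-statistic region for unit tests."""
    r = np.random.default_rng(seed)
    positions = np.sort(r.choice(np.arange(1, 10_000_000), size=q, replace=False))
    return RegionSummaryStats(
        trait_id=trait_id,
        trait_type=trait_type,
        variant_ids=ids if ids is not None else [f"rs{i}" for i in range(q)],
        chromosome=chromosome,
        positions=positions,
        beta=beta if beta is not None else r.normal(0, 0.1, q),
        se=se if se is not None else r.uniform(0.05, 0.2, q),
        maf=r.uniform(0.05, 0.5, q),
        n=np.full(q, 10_000.0),
        **kw,
    )


@pytest.fixture
def sumstats_factory():
    return make_sumstats
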