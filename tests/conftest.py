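import numpy as np
import pytest

from bioclimdyn import decompose as dc
from bioclimdyn import synthetic as sy
from bioclimdyn import trajectory as tj


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic dataset (seed 1) with its ground-truth metadata."""
    cfg = sy.SyntheticConfig(seed=1)
    dataset, meta = sy.generate_dataset(cfg)
    return dataset, meta


@pytest.fixture(scope="session")
def default_decompositions(default_dataset):
    dataset, _meta = default_dataset
    return {s.variable: dc.decompose(s) for s in dataset}


@pytest.fixture(scope="session")
def benchmark():
    return sy.benchmark_model()


@pytest.fixture(scope="session")
def ident_monthly(benchmark):
    """Noise-free monthly samples of the benchmark from the identifiable
    off-cycle start, 1404 samples (117 years)."""
    traj = tj.integrate(benchmark, sy.identification_start(),
                        horizon_months=1403, dt=1.0, substeps=8)
    assert not traj.diverged
    return traj.states


@pytest.fixture(scope="session")
def bench_search(ident_monthly):
    """Grid search on the noise-free monthly benchmark data (shared because
    each refine is the most expensive operation in the suite)."""
    grid = [tj.TMConfig(ridge_weight=w, optimizer_budget=65)
            for w in (1e-8, 1e-10, 1e-12)]
    return tj.search(ident_monthly, grid, seed=0)


@pytest.fixture(scope="session")
def ident_dense(benchmark):
    """Densely sampled (dt = 0.1 month) noise-free benchmark trajectory."""
    traj = tj.integrate(benchmark, sy.identification_start(),
                        horizon_months=1404, dt=0.1, substeps=2)
    assert not traj.diverged
    return traj.states
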