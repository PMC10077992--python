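import numpy as np
import pandas as pd
import pytest

import ddpsa
from ddpsa import (
    MCMCSettings,
    ModelConfig,
    ParameterState,
    PNSDMatrix,
    WindSeries,
    benchmark_spec,
    generate_dataset,
    replace_zeros,
    run_mcmc,
)
from ddpsa.inference import PosteriorDraws

# frozen study conditions of the synthetic recovery benchmark
BENCH_T = 150
BENCH_DATA_SEED = 42
BENCH_CHAIN_SEED = 1
BENCH_K = 6
BENCH_SETTINGS = dict(n_iter=4000, burn_in=2000, thin=5, seed=BENCH_CHAIN_SEED)


@pytest.fixture(scope="session")
def bench():
    """Benchmark dataset: K_true=3, P=15, T=150, ~7% missing, zeros cleaned."""
    spec = benchmark_spec()
    data, wind, truth = generate_dataset(spec, T=BENCH_T, seed=BENCH_DATA_SEED)
    data, _ = replace_zeros(data)
    return {"spec": spec, "data": data, "wind": wind, "truth": truth}


@pytest.fixture(scope="session")
def bench_draws(bench):
    """Full-length benchmark fit (K=6, 4000 iterations)."""
    cfg = ModelConfig(K=BENCH_K)
    return run_mcmc(bench["data"], bench["wind"], cfg, MCMCSettings(**BENCH_SETTINGS))


@pytest.fixture(scope="session")
def bench_draws_half(bench):
    """Half-length benchmark fit for the run-stability comparison."""
    cfg = ModelConfig(K=BENCH_K)
    settings = MCMCSettings(n_iter=2000, burn_in=1000, thin=5, seed=BENCH_CHAIN_SEED)
    return run_mcmc(bench["data"], bench["wind"], cfg, settings)


@pytest.fixture()
def toy():
    """Tiny deterministic instance (P=3, T=4, K=3) for oracle comparisons."""
    rng = np.random.default_rng(7)
    P, T, K = 3, 4, 3
    lam = rng.dirichlet(np.ones(P), size=K).T
    eta = rng.uniform(0.1, 0.9, size=(K - 1, T))
    c = rng.uniform(5.0, 20.0, size=T)
    state = ParameterState(
        lam=lam, eta=eta, c=c, mu_c=1.5, sigma_c=0.7,
        sigma=rng.uniform(0.2, 0.8, size=P), alpha=1.8,
        nu1=np.array([1.0, 3.0]), nu2=np.array([90.0, 270.0]),
        h1=np.array([2.0, 0.5]), h2=np.array([0.4, 1.1]),
    ).validate()
    wind = WindSeries(ws=rng.uniform(0.5, 6.0, size=T),
                      wd=rng.uniform(0.0, 360.0, size=T))
    values = rng.lognormal(mean=1.0, sigma=0.5, size=(P, T))
    mask = np.zeros((P, T), dtype=bool)
    mask[:, 2] = True   # one fully missing time step
    data = PNSDMatrix(
        times=pd.date_range("2019-01-25", periods=T, freq="3h"),
        bin_labels=np.array([20.0, 50.0, 200.0]),
        values=np.where(mask, 0, values), missing_mask=mask,
        block_labels=np.arange(T) % 2)
    config = ModelConfig(K=K, nu1_upper=8.0)
    return {"state": state, "wind": wind, "data": data, "config": config}


def make_draws(states, wind, settings=None) -> PosteriorDraws:
    """Wrap hand-built states as a single-chain PosteriorDraws."""
    settings = settings or MCMCSettings(n_iter=2, burn_in=0, thin=1, seed=0)
    return PosteriorDraws(
        chains=[list(states)], imputed_y=[np.empty((len(states), 0))],
        missing_cells=np.empty((0, 2), dtype=int),
        acceptance_rates={}, settings=settings, wind=wind)
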