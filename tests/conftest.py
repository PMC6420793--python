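import numpy as np
import pandas as pd
import pytest

from rescuemap.simulate import ConstructEffect, ElementConfig, SimConfig, simulate_experiment


def small_config(seed: int = 7, **kw) -> SimConfig:
    defaults = dict(
        n_genes=400,
        conditions=("iLuc", "iEF", "WT", "DEAD"),
        n_batches=3,
        construct_effects={
            "WT": ConstructEffect(0.8, 0.8, 0.0),
            "DEAD": ConstructEffect(0.0, 0.1, 0.0),
        },
        element_config=ElementConfig(n_promoter_ms=12, n_enhancer_ms=12, n_ets=8),
        seed=seed,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    counts, samples, truth = simulate_experiment(cfg)
    return cfg, counts, samples, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_counts(rng, genes=60, samples=6, mu=50.0, alpha=0.1) -> pd.DataFrame:
    lam = rng.gamma(1.0 / alpha, alpha * mu, size=(genes, samples))
    vals = rng.poisson(lam)
    return pd.DataFrame(vals, index=[f"g{i}" for i in range(genes)],
                        columns=[f"s{j}" for j in range(samples)])
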