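import numpy as np
import pandas as pd
import pytest

from homoeoflow import SimConfig, simulate_counts, simulate_universe


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(n_triplets=30, n_duplets=15, n_singletons_per_genome=8,
                     baseline_mean_range=(50.0, 300.0), seed=1234)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    genes, groups, truth = simulate_universe(small_config)
    counts, samples, factors = simulate_counts(truth, small_config)
    return {
        "config": small_config,
        "genes": genes,
        "groups": groups,
        "truth": truth,
        "counts": counts,
        "samples": samples,
        "size_factors": factors,
        "lengths": genes.set_index("gene_id")["length"],
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture(scope="session")
def nb_matrix_factory():
    def make(seed, n_genes, mean_range, alpha, size_factors=(1, 1, 1, 1),
             log2fc=None):
        rng = np.random.default_rng(seed)
        mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                                n_genes))
        sf = np.asarray(size_factors, dtype=float)
        half = len(sf) // 2
        mu_mat = np.tile(mu[:, None], (1, len(sf)))
        if log2fc is not None:
            mu_mat[:, half:] *= 2.0 ** np.asarray(log2fc)[:, None]
        mu_mat = mu_mat * sf[None, :]
        lam = rng.gamma(1.0 / alpha, alpha * mu_mat) if alpha > 0 else mu_mat
        counts = rng.poisson(lam)
        cols = [f"a{i}" for i in range(half)] + \
               [f"b{i}" for i in range(len(sf) - half)]
        return (pd.DataFrame(counts, columns=cols,
                             index=[f"g{i}" for i in range(n_genes)]),
                cols[:half], cols[half:], mu)
    return make
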