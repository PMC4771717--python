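import numpy as np
import pytest

from evikit import simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A small seeded synthetic dataset shared by read-only tests."""
    cds, models, truth = simulate.generate_genome(
        n_genes=400, length_log_mean=5.3, seed=11,
        slow_gene_fraction=0.02, high_tr_gene_fraction=0.02,
    )
    m, c, f, truth = simulate.generate_translatome(truth, seed=12)
    profiles = simulate.generate_coverage(truth, models, seed=13)
    return {
        "cds": cds,
        "models": models,
        "truth": truth,
        "m": m,
        "c": c,
        "f": f,
        "profiles": profiles,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
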