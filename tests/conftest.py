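import numpy as np
import pytest
from hypothesis import settings

from aoptox.hill import build_grid
from aoptox.synthetic_data import SynthConfig, generate_study

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def grid():
    return build_grid()


@pytest.fixture(scope="session")
def single_chain_study():
    """Tiny noiseless study in the single-chain regime (exact Hill fibers)."""
    cfg = SynthConfig(
        n_assays=6, n_proteins=6, n_pathways=3, n_chemicals=12,
        n_endpoints=2, endpoint_kinds=("continuous", "binary"),
        assay_protein_density=0.01, protein_pathway_density=0.01,
        true_assoc=[(0, 0, 0.5)], noise_sd=0.0, missing_frac=0.0, seed=42,
    )
    return cfg, *generate_study(cfg)


@pytest.fixture(scope="session")
def small_noisy_study():
    """Small study with noise, missingness, and promiscuous mappings."""
    cfg = SynthConfig(
        n_assays=10, n_proteins=6, n_pathways=4, n_chemicals=120,
        n_endpoints=4, true_assoc=[(0, 0, 0.5), (1, 1, 0.5), (2, 2, 0.5), (3, 3, 0.5)],
        seed=5,
    )
    return cfg, *generate_study(cfg)


def masked_r2(pred, obs, mask):
    p, o = pred[mask], obs[mask]
    return 1.0 - np.sum((p - o) ** 2) / np.sum((o - o.mean()) ** 2)
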