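import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nodeinfer as ni

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def tiny_embryo():
    """4 cells x 2 times x 2 species with coordinates; values hand-chosen."""
    rng = np.random.default_rng(42)
    conc = rng.uniform(0.1, 0.9, size=(2, 2, 4))
    coords = rng.normal(size=(4, 3))
    return ni.VirtualEmbryo(cell_ids=np.array([1, 2, 3, 4]),
                            times=np.array([1.0, 2.0]),
                            species=["a", "b"], conc=conc, coords=coords)


@pytest.fixture(scope="session")
def linear_embryo():
    """Noiseless 2-factor embryo with global linear law dy/dt = 2x1 - x2 + 0.3."""
    cfg = ni.linear_suite(n_cells=120, noise_sigma=0.0, seed=3)
    emb, truth = ni.make_embryo(cfg)
    return cfg, emb, truth


@pytest.fixture(scope="session")
def linear_node_bundle(linear_embryo):
    cfg, emb, _ = linear_embryo
    tp = ni.TuningParams(h=0.15, lam=0.0, d=2, r=2)
    return ni.fit_node_model(emb, "eve", cfg.factor_names, tp)


@pytest.fixture(scope="session")
def hill_embryo_small():
    """Noisy 5-factor Hill-law embryo (reduced size for unit tests)."""
    cfg = ni.hill_suite(n_cells=300, noise_sigma=0.02, seed=11)
    emb, truth = ni.make_embryo(cfg)
    return cfg, emb, truth
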