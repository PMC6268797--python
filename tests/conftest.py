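import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import glycopcs as g

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def table1_by_metal():
    """Packaged GM2 shift-table fixture split per metal."""
    by = {}
    for m in g.read_shift_table(g.gm2_table1_path()):
        by.setdefault(m.metal, []).append(m)
    return by


@pytest.fixture(scope="session")
def small_config():
    return g.GeneratorConfig(n_conformers=80, seed=11)


@pytest.fixture(scope="session")
def small_ensemble(small_config):
    """80-conformer synthetic ensemble with metal placed (fast tests)."""
    ens, truth = g.generate_ensemble(small_config)
    return ens


@pytest.fixture(scope="session")
def study_ensemble():
    """Full-size study ensemble: 2000 conformers, uniform weights 0.0005."""
    cfg = g.GeneratorConfig(n_conformers=2000, seed=0)
    ens, _ = g.generate_ensemble(cfg)
    return cfg, ens


@pytest.fixture(scope="session")
def fit_nuclei(small_ensemble):
    from glycopcs.synthetic import default_nuclei

    return default_nuclei(small_ensemble.conformers[0], 30)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
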