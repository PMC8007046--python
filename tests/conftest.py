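"""Shared fixtures: small deterministic tumors generated at test time."""

import numpy as np
import pytest
from hypothesis import settings

from metdiv import SimConfig, surviving_primary

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from metdiv.pipeline import run_paired


@pytest.fixture(scope="session")
def neutral_small():
    """Neutral fast-growth tumor, 3000 cells, 5 seeding events."""
    cfg = SimConfig(rho=0.72, u=0.15, u_b=0.0, s_mean=0.0, N_s=600,
                    N_final=3000, rng_seed=42)
    return surviving_primary(cfg)


@pytest.fixture(scope="session")
def neutral_10k():
    """Neutral tumor of 10^4 cells (peripheral-growth checks)."""
    cfg = SimConfig(rho=0.72, u=0.15, u_b=0.0, s_mean=0.0, N_s=2500,
                    N_final=10_000, rng_seed=7)
    return surviving_primary(cfg)


@pytest.fixture(scope="session")
def selective_small():
    """Tumor with strong drivers (subclonal expansions), 5000 cells."""
    cfg = SimConfig(rho=0.72, u=0.15, u_b=5e-4, s_mean=0.2, N_s=1000,
                    N_final=5000, rng_seed=3)
    return surviving_primary(cfg)


@pytest.fixture(scope="session")
def paired_small():
    """Full small paired run (primary 4000 cells, mets 1500)."""
    cfg = SimConfig(rho=0.72, u=0.15, u_b=1e-4, s_mean=0.1, N_s=1000,
                    N_final=4000, rng_seed=5)
    return run_paired(cfg, met_n_final=1500, n_regions=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
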