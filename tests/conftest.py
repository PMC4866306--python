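"""Shared fixtures: small simulated diallel populations."""

import numpy as np
import pytest

from diallelpred import simulate as sim


@pytest.fixture(scope="session")
def small_map():
    return sim.simulate_genetic_map(4, 15, 100.0, seed=11)


@pytest.fixture(scope="session")
def small_diallel(small_map):
    """10 x 10 diallel on a 4-chromosome, 60-site map."""
    panel_a, panel_alpha = sim.simulate_segregant_panel(
        small_map, 10, 10, n_meioses=12, seed=21
    )
    ped, G = sim.mate_diallel(panel_a, panel_alpha)
    return ped, G


@pytest.fixture(scope="session")
def medium_diallel():
    """20 x 20 diallel on a 16-chromosome, 320-site map."""
    m = sim.simulate_genetic_map(16, 20, 100.0, seed=31)
    panel_a, panel_alpha = sim.simulate_segregant_panel(
        m, 20, 20, n_meioses=12, seed=32
    )
    ped, G = sim.mate_diallel(panel_a, panel_alpha)
    return ped, G


@pytest.fixture(scope="session")
def additive_dataset(medium_diallel):
    """Purely additive polygenic trait (target additive fraction 0.8)."""
    ped, G = medium_diallel
    arch = sim.sample_architecture(
        G, n_traits=1, n_qtl=20, v_add=0.8, H2_mean=1.0, n_rep=1, seed=41
    )
    pheno = sim.simulate_phenotypes(G, arch, n_rep=1, seed=42)
    return ped, G, arch, pheno


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
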