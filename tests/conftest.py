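"""Shared fixtures: a small synthetic hospital panel with known truth
and one short reference fit, reused across the effect/report tests."""

import warnings

import numpy as np
import pytest

from geosfa.mcmc import run_mcmc
from geosfa.model import MCMCSettings, build_design
from geosfa.panel import prepare_panel
from geosfa.presets import get_preset
from geosfa.simulate import SimConfig, simulate_panel

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def small_sim():
    cfg = SimConfig(lattice_size=4, coarse_block=2, hospitals_per_district=3.0,
                    waves=(2006, 2010, 2013), seed=42)
    panel, graph, truth = simulate_panel(cfg)
    return panel, graph, truth, cfg


@pytest.fixture(scope="session")
def prepared(small_sim):
    panel, graph, truth, cfg = small_sim
    return prepare_panel(panel), graph, truth


@pytest.fixture(scope="session")
def fitted(prepared):
    """Short reference fit of the district struct+unstruct model."""
    panel, graph, truth = prepared
    mc = MCMCSettings(iterations=3000, burn_in=500, thinning=5, seed=7)
    spec = get_preset("model2", mcmc=mc)
    design = build_design(panel, graph, spec)
    draws = run_mcmc(design)
    return draws, design, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_toy_draws_design():
    """Tiny 3-observation design with 120 synthetic posterior draws,
    used to check the information-criteria formulas against brute-force
    two-pass computations."""
    from geosfa.mcmc import PosteriorDraws
    from geosfa.model import ModelDesign, ModelSpec

    spec = ModelSpec(name="toy", frontier_inputs=[], ineff_covariates=[],
                     struct_level=None, unstruct_level=None,
                     mcmc=MCMCSettings(iterations=10, burn_in=0,
                                       thinning=1, seed=0))
    n = 3
    design = ModelDesign(
        y=np.array([0.1, -0.5, 0.9]), X=np.ones((n, 1)), x_names=["c"],
        Z=np.zeros((n, 0)), z_names=[], z_means=np.zeros(0),
        struct_graph=None, struct_idx=None, unstruct_graph=None,
        unstruct_idx=None, unstruct_observed=None,
        hospital_ids=[0, 1, 2], hospital_idx=np.arange(n),
        wave_of_obs=np.full(n, 2006), spec=spec)
    gen = np.random.default_rng(4)
    S = 120
    draws = PosteriorDraws(
        beta=gen.normal(0, 0.3, (S, 1)),
        delta=np.zeros((S, 0)),
        u_star=np.abs(gen.normal(0, 0.5, (S, n))),
        alpha=np.ones((S, n)),
        sigma_v2=gen.uniform(0.3, 0.6, S),
        sigma_ustar2=gen.uniform(0.2, 0.5, S),
        meta={"data_fingerprint": design.data_fingerprint()})
    return draws, design
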