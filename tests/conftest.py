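import numpy as np
import pytest

from kickout.model import GuideSpec, KineticParams, PromoterPair
from kickout.simulate import SimulationConfig


@pytest.fixture
def full_guide() -> GuideSpec:
    """Full-complementarity guide: passage probability 0.026."""
    return GuideSpec("G20", 20, r=0.026, r_sd=0.003)


@pytest.fixture
def promoter_pair() -> PromoterPair:
    """Reference repressed to 0.32, target 2.6-fold stronger."""
    return PromoterPair("P_ref", "P_strong", strength_fold=2.6,
                        gamma_star_ref=0.32, strength_fold_sd=0.2,
                        gamma_star_ref_sd=0.04)


def make_sim_config(kon: float, r: float, *, koff: float = 0.0,
                    n_cells: int = 300, extrinsic_cv: float = 0.0,
                    dcas9_cv: float = 0.0, seed: int = 1,
                    **kwargs) -> SimulationConfig:
    return SimulationConfig(
        kinetics=KineticParams(gamma0=20.0, rebinding_rate=kon, koff=koff,
                               delta=1.0),
        guide=GuideSpec("g", 20, r=r),
        extrinsic_cv=extrinsic_cv, dcas9_cv=dcas9_cv, n_cells=n_cells,
        seed=seed, **kwargs)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
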