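import numpy as np
import pytest

from crossfeed.fitting import CommunitySpec, default_community
from crossfeed.imaging import AnalysisConfig
from crossfeed.model import EnvironmentParams, ExchangePairParams, StrainRates
from crossfeed.synthetic import SyntheticColonySpec, generate_colony


@pytest.fixture(scope="session")
def env() -> EnvironmentParams:
    return EnvironmentParams(cell_density=0.65, diffusion_D=2e5,
                             cell_length=3.0, cell_width=1.0)


@pytest.fixture(scope="session")
def community() -> CommunitySpec:
    return default_community()


def make_pair(u_n=1e3, l_n=0.1, mu_n=0.5, u_p=1e3, l_p=0.1, mu_p=0.5,
              I_C=10.0) -> ExchangePairParams:
    return ExchangePairParams(
        consumer=StrainRates(u_n, l_n, mu_n, I_C),
        producer=StrainRates(u_p, l_p, mu_p, I_C),
    )


@pytest.fixture(scope="session")
def small_colony_kwargs() -> dict:
    """Reduced colony geometry for fast imaging unit tests."""
    return dict(a=280.0, b=260.0, phi=0.4, rho_c=90.0, pixel_size=1.3,
                n_z_planes=3)


@pytest.fixture(scope="session")
def small_colony(small_colony_kwargs):
    spec = SyntheticColonySpec(target_yellow_fraction=0.6, sector_scale=50.0,
                               seed=7, **small_colony_kwargs)
    image, truth = generate_colony(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def small_config(small_colony) -> AnalysisConfig:
    spec, _, _ = small_colony
    return AnalysisConfig(rho_c=spec.rho_c)
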