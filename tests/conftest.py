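import numpy as np
import pytest

from eccwater import PRESETS, ReferenceSet

#: published moments (D, D Å) for the four bundled presets
PUBLISHED_MOMENTS = {
    "eccw2024": (2.167631, 2.444435),
    "tip4p2005": (2.305097, 2.296802),
    "tip4pfb": (2.427804, 2.170775),
    "opc4": (2.479542, 2.299607),
}

#: published per-property MAPE (%) rows and the resulting general cost C_G
PUBLISHED_MAPE_ROWS = {
    "eccw2024": ({"rho_1bar": 0.072, "D_OW": 7.0, "rdf_1p": 1.429, "rdf_1h": 25.6}, 0.262),
    "tip4p2005": ({"rho_1bar": 0.118, "D_OW": 3.1, "rdf_1p": 1.429, "rdf_1h": 24.2}, 0.208),
    "opc4": ({"rho_1bar": 0.233, "D_OW": 7.3, "rdf_1p": 0.714, "rdf_1h": 21.5}, 0.248),
    "tip4pfb": ({"rho_1bar": 0.085, "D_OW": 6.6, "rdf_1p": 1.486, "rdf_1h": 25.8}, 0.260),
}


@pytest.fixture(scope="session")
def reference() -> ReferenceSet:
    return ReferenceSet.default()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(params=sorted(PRESETS))
def preset_name(request) -> str:
    return request.param
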