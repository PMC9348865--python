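import numpy as np
import pytest

from refldesign import Layer, Parameter, Sample, synthesize_flux
from refldesign.samples import ParametricModel


class OneLayerModel(ParametricModel):
    """Two-parameter single-slab toy: thickness and SLD of one film on Si."""

    def __init__(self, thickness: float = 80.0, sld: float = 4.0):
        super().__init__()
        self.name = "one_layer"
        self.parameters = [
            Parameter("thickness", thickness, (10.0, 200.0)),
            Parameter("sld", sld, (1.0, 8.0)),
        ]

    def build(self, contrast_sld=None):
        v = {p.name: p.value for p in self.parameters}
        return Sample(
            superphase_sld=0.0,
            layers=[Layer(v["thickness"], v["sld"], roughness=3.0)],
            substrate_sld=2.07,
            substrate_roughness=3.0,
            background=1e-6,
            name=self.name,
        )


class BackgroundModel(ParametricModel):
    """Contrast-free stack whose only free parameter is the background.

    Expected counts are exactly linear in the parameter, giving the
    one-bin Poisson closed form FI = (∂λ/∂θ)²/λ per bin.
    """

    def __init__(self, background: float = 1e-5):
        super().__init__()
        self.name = "background_only"
        self.parameters = [Parameter("background", background, (1e-9, 1e-2))]

    def build(self, contrast_sld=None):
        return Sample(
            superphase_sld=2.07,
            layers=[],
            substrate_sld=2.07,
            background=self.param("background").value,
            name=self.name,
        )


@pytest.fixture(scope="session")
def flux():
    return synthesize_flux()


@pytest.fixture(scope="session")
def polarized_flux():
    return synthesize_flux(polarized=True)


@pytest.fixture()
def one_layer_model():
    return OneLayerModel()


@pytest.fixture()
def background_model():
    return BackgroundModel()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
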