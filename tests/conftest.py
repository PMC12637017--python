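import numpy as np
import pytest

import cryocontrast as cc


@pytest.fixture(scope="session")
def beam200():
    return cc.beam_parameters(200.0)


@pytest.fixture(scope="session")
def beam1000():
    return cc.beam_parameters(1000.0)


@pytest.fixture(scope="session")
def materials():
    return cc.default_materials()


@pytest.fixture(scope="session")
def ice(materials):
    return materials["vitreous_ice"]


@pytest.fixture(scope="session")
def protein(materials):
    return materials["protein"]


@pytest.fixture(scope="session")
def dna(materials):
    return materials["dna"]


@pytest.fixture(scope="session")
def mini_phage():
    """A small phage embedded mid-slab, shared by the imaging tests."""
    model = cc.build_phage(capsid_length=40.0, capsid_width=30.0,
                           shell_thickness=2.0, dna_shell_thickness=2.0,
                           dna_gap=1.0, dna_volume_fraction=0.4)
    return cc.embed_in_ice(model, 60.0, field_width=48.0)


@pytest.fixture(scope="session")
def mini_maps(mini_phage):
    return cc.rasterize(mini_phage, N=96, L=48.0, delta_t=2.0)


def ncc(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized cross-correlation of two images."""
    a = a - a.mean()
    b = b - b.mean()
    return float((a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum()))
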