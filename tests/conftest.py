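import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from surfmae.config import ModelConfig, PatchConfig, SurfaceConfig
from surfmae.ingest import make_fixture, synth_chain
from surfmae.surface import build_surface

PDB_TWO_CHAINS = """\
ATOM      1  N   ALA A   1       1.000   2.000   3.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       2.000   2.500   3.500  1.00  0.00           C
ATOM      3  C   ALA A   1       3.000   3.000   4.000  1.00  0.00           C
ATOM      4  N   GLY B   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      5  CA  GLY B   1      11.000  10.500  10.500  1.00  0.00           C
HETATM    6  O   HOH A   2       5.000   5.000   5.000  1.00  0.00           O
END
"""

PDB_ALTLOC = """\
ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C
ATOM      2  CA BALA A   1       1.200   0.000   0.000  0.50  0.00           C
ATOM      3  CB  ALA A   1       2.000   0.000   0.000  1.00  0.00           C
END
"""

PDB_WITH_IRON = """\
ATOM      1  CA  ALA A   1       1.000   0.000   0.000  1.00  0.00           C
ATOM      2 FE   HEM A   2       2.000   0.000   0.000  1.00  0.00          FE
END
"""


@pytest.fixture(scope="session")
def tiny_surface_cfg():
    return SurfaceConfig(target_points=256)


@pytest.fixture(scope="session")
def default_surface_cfg():
    return SurfaceConfig()


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(d=64, encoder_depth=2, encoder_heads=4,
                       decoder_depth=2, decoder_heads=4)


@pytest.fixture(scope="session")
def tiny_patch_cfg():
    return PatchConfig(g=32, k_prime=16, m=0.6)


@pytest.fixture(scope="session")
def small_cloud(tiny_surface_cfg):
    """A 256-point annotated surface of a 24-residue synthetic chain."""
    return build_surface(synth_chain(24, seed=1), tiny_surface_cfg, seed=1)


@pytest.fixture(scope="session")
def sphere_points():
    """2000 points on an analytic sphere of radius 5 Å, with outward normals."""
    n = 2000
    i = np.arange(n)
    phi = np.pi * (3 - np.sqrt(5)) * i
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z * z)
    pts = 5.0 * np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    return pts, pts / 5.0


@pytest.fixture(scope="session")
def single_atom():
    return make_fixture("single_atom", element="C")
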