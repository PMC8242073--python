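import numpy as np
import pytest

from ventmech import material as M
from ventmech import heartgeom as G
from ventmech.heartgeom import _structured_lv


@pytest.fixture(scope="session")
def params():
    return M.MaterialParameters()


@pytest.fixture(scope="session")
def fiber_x_frame():
    return M.FiberFrame(
        m=np.array([1.0, 0.0, 0.0]),
        s=np.array([0.0, 1.0, 0.0]),
        n=np.array([0.0, 0.0, 1.0]),
    )


@pytest.fixture(scope="session")
def coarse_lv():
    """Coarse truncated-ellipsoid LV scaled to a 60 mL cavity."""
    mesh = G.build_ideal_lv(target_edge_len=10.0)
    return G.scale_to_cavity(mesh, 60.0)


def make_tiny_lv(nc=10, nl=4, nt=2, cavity_ml=60.0):
    """Very coarse LV for solver/calibration tests."""
    m0 = G.build_ideal_lv(target_edge_len=10.0)
    meta = m0.meta
    mesh = _structured_lv(
        meta["a_endo"], meta["b_endo"], meta["a_epi"], meta["b_epi"],
        meta["z_c"], nc, nl, nt,
        {k: meta[k] for k in ("base_radius_endo", "wall_thickness",
                              "long_axis", "truncation_fraction",
                              "target_edge_len")})
    return G.scale_to_cavity(mesh, cavity_ml)


@pytest.fixture(scope="session")
def tiny_lv():
    return make_tiny_lv()


def random_deformation(rng, scale=0.1):
    """Random invertible deformation gradient near identity."""
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if np.linalg.det(F) > 0.3:
            return F
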