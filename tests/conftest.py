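import numpy as np
import pytest
from hypothesis import settings

import helixgauge as hg
from helixgauge import axis_frame, euler_series, geometry

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def b_spec():
    return hg.HelixSpec(n_bp=50)


@pytest.fixture(scope="session")
def b_duplex(b_spec):
    return hg.ideal_duplex(b_spec)


@pytest.fixture(scope="session")
def b_results(b_duplex):
    return hg.ChiralStateModel.from_structure(b_duplex).fit()


@pytest.fixture(scope="session")
def z_results():
    dup = hg.ideal_duplex(hg.spec_for_form("Z", n_bp=50))
    return hg.ChiralStateModel.from_structure(dup).fit()


@pytest.fixture(scope="session")
def mirror_results(b_duplex):
    return hg.ChiralStateModel.from_structure(hg.mirror(b_duplex)).fit()


def run_on_points(points_nm, min_step=0.0):
    """Run axis -> frames -> rotations -> euler -> geometry on raw axis points."""
    ax = axis_frame.axis_from_points(points_nm, min_step=min_step)
    fr = axis_frame.build_frames(ax.points)
    rot = euler_series.rotation_series(fr)
    eu = euler_series.cumulative_euler(rot, fr)
    geo = geometry.geometry_series(eu, ax)
    return ax, fr, rot, eu, geo


def random_rotation(rng):
    """Uniform-ish random proper rotation from a seeded generator."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
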