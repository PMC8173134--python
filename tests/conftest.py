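import numpy as np
import pytest

from ukacontact import phantom as ph


@pytest.fixture(scope="session")
def implant_set():
    return ph.make_implant_set()


@pytest.fixture(scope="session")
def femoral_component(implant_set):
    return implant_set.femoral_condyle


@pytest.fixture(scope="session")
def insert(implant_set):
    return implant_set.insert


@pytest.fixture(scope="session")
def baseplate(implant_set):
    return implant_set.baseplate


@pytest.fixture(scope="session")
def camera_pair():
    return ph.make_camera_pair()


@pytest.fixture(scope="session")
def icosphere():
    """Unit-test sphere mesh (radius 20 mm) for closed-form projection and
    contact oracles."""
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=3, radius=20.0)
    return ph.SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces), "world")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
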