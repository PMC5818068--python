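import numpy as np
import pytest

from lungcad import CTVolume, PhantomSpec, NoduleSpec, generate_phantom


@pytest.fixture(scope="session")
def quiet_spec():
    """Phantom spec with no vessels/noise/smoothing: pure geometry."""
    return PhantomSpec(vessel_count=0, noise_sigma_hu=0.0, edge_smoothing_mm=0.0)


@pytest.fixture(scope="session")
def lung_center(quiet_spec):
    """Center of the first lung ellipsoid (world mm)."""
    center, _ = quiet_spec.lung_ellipsoids()[0]
    return tuple(float(c) for c in center)


@pytest.fixture(scope="session")
def single_nodule_case(quiet_spec, lung_center):
    """One 10-mm, 400-HU nodule in an otherwise empty quiet phantom."""
    spec = PhantomSpec(
        vessel_count=0,
        noise_sigma_hu=0.0,
        edge_smoothing_mm=0.0,
        nodules=(NoduleSpec(lung_center, 10.0, 400.0),),
    )
    return generate_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def realistic_case():
    """A default-condition phantom (vessels, smoothing, noise) with two
    well-separated nodules of known size/contrast."""
    spec = PhantomSpec()
    lungs = spec.lung_ellipsoids()
    c0 = tuple(float(v) for v in lungs[0][0])
    c1 = tuple(float(v) for v in lungs[1][0])
    spec = PhantomSpec(
        nodules=(NoduleSpec(c0, 10.0, 450.0), NoduleSpec(c1, 8.0, 500.0))
    )
    return generate_phantom(spec, seed=23)


@pytest.fixture()
def small_volume():
    rng = np.random.default_rng(42)
    data = rng.integers(-1000, 400, size=(16, 16, 16)).astype(np.int16)
    return CTVolume(data, (0.7, 0.7, 1.25), (0.0, 0.0, 0.0))
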