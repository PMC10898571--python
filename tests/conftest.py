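import numpy as np
import pytest
from hypothesis import settings

import drsopt as d

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def phantom():
    return d.build_phantom()


@pytest.fixture(scope="session")
def disc(phantom):
    return d.build_discretization(phantom)


@pytest.fixture(scope="session")
def solver(disc):
    """Shared transport solver on the default phantom (factorization cached)."""
    return d.DiffusionSolver(disc, d.default_optics())


@pytest.fixture(scope="session")
def noise_free_spec():
    return d.GeneratorSpec(poisson_noise=False)


@pytest.fixture(scope="session")
def refs(noise_free_spec):
    return d.ReferenceIntensities.from_spectra(d.reference_spectra(noise_free_spec))


@pytest.fixture(scope="session")
def optimizer(solver, refs):
    return d.GeometryOptimizer(solver, refs)


@pytest.fixture(scope="session")
def point_surface(optimizer):
    """Full 441-detector SNR sweep for the centred point source."""
    return optimizer.snr_surface(d.point_source())


@pytest.fixture(scope="session")
def line_surface(optimizer):
    return optimizer.snr_surface(d.line_source())


@pytest.fixture(scope="session")
def snr4_count_scale():
    """Count scale calibrated so the expected band SNR at 100 µm equals 4."""
    spec = d.calibrate_noise_to_snr(d.GeneratorSpec(seed=0), 4.0)
    return spec.count_scale


def series_difference_pairs(series):
    """Pipeline a generated series into (difference spectrum, thickness) pairs."""
    from drsopt.calibration import difference_spectrum, normalize_to_polystyrene

    pairs = []
    for rec in series.records:
        fbr = normalize_to_polystyrene(rec.fbr)
        ic = normalize_to_polystyrene(rec.initial)
        pairs.append((difference_spectrum(fbr, ic), rec.thickness_um))
    return pairs


@pytest.fixture(scope="session")
def make_pairs():
    return series_difference_pairs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
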