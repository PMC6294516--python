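import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gqmelt as g
from gqmelt import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cd_species():
    return syn.default_cd_species()


@pytest.fixture(scope="session")
def uvrr_species():
    return syn.default_uvrr_species()


@pytest.fixture(scope="session")
def cd_peak(cd_species):
    return max(float(np.abs(s.amplitude).max()) for s in cd_species)


def make_cd_matrix(species, noise_sd, seed):
    spec = syn.SyntheticSpec(
        model=syn.TEL22_CD_PARAMS,
        species_spectra=species,
        temperatures=syn.cd_temperatures(),
        noise_sd=noise_sd,
        seed=seed,
        probe="cd",
    )
    return g.generate_melting_matrix(spec)


@pytest.fixture(scope="session")
def noiseless_cd_matrix(cd_species):
    return make_cd_matrix(cd_species, 0.0, 0)


@pytest.fixture(scope="session")
def noisy_cd_matrix(cd_species, cd_peak):
    """Four-species CD-like matrix at 2% of the peak spectral amplitude."""
    return make_cd_matrix(cd_species, 0.02 * cd_peak, 0)


@pytest.fixture(scope="session")
def sphere_curve():
    """Exact scattering curve of a homogeneous sphere, R = 20 A."""
    R = 20.0
    q = np.geomspace(0.02, 1.0, 120)
    x = q * R
    I = (3.0 * (np.sin(x) - x * np.cos(x)) / x**3) ** 2
    return g.SASCurve(q=q, intensity=I, sigma=0.01 * I), R


@pytest.fixture(scope="session")
def box_curve():
    """Exact form-factor curve of the 15 x 15 x 27 A parallelepiped."""
    box = g.BoxModel(15.0, None, 27.0)
    q = np.geomspace(0.02, 1.0, 150)
    I = g.parallelepiped_form_factor(q, box)
    return g.SASCurve(q=q, intensity=I, sigma=0.01 * I), box
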