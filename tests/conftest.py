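"""Shared fixtures: small fast phantoms with the same structure as the
full-size default (body, liver, heterogeneous tumor with central and
peripheral necrosis, viable cords, skin fiducials)."""

import numpy as np
import pytest

from petcontour import Ellipsoid, PhantomConfig, generate_phantom
from petcontour.registration import build_pair


def small_config(**overrides) -> PhantomConfig:
    base = dict(
        grid_shape=(64, 64, 48),
        body_center_mm=(32.0, 28.0),
        body_radii_mm=(24.0, 20.0),
        body_z_mm=(2.0, 46.0),
        tumor_center_mm=(32.0, 40.0, 24.0),
        tumor_radii_mm=(10.0, 10.0, 8.0),
        necrosis_spec=(
            Ellipsoid((32.0, 40.0, 24.0), (4.5, 4.5, 4.0)),
            Ellipsoid((39.2, 40.0, 24.0), (2.2, 2.2, 1.9)),
        ),
        viable_cords=(
            Ellipsoid((32.5, 40.5, 24.0), (0.5, 0.5, 3.0)),
            Ellipsoid((30.5, 38.5, 24.0), (0.75, 0.75, 2.6)),
        ),
        liver=Ellipsoid((20.0, 22.0, 14.0), (7.0, 6.0, 7.0)),
        n_sections=3,
        seed=11,
    )
    base.update(overrides)
    return PhantomConfig(**base)


@pytest.fixture(scope="session")
def default_small_phantom():
    """Small phantom with the default degradation (2 mm PSF, Poisson)."""
    return generate_phantom(small_config())


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Degradation-free phantom: no blur, no noise, no heterogeneity."""
    return generate_phantom(
        small_config(psf_fwhm_mm=0.0, noise_model="none", uptake_sd_fraction=0.0)
    )


def pairs_of(volume, truth):
    manifest = truth.manifest()
    return [
        build_pair(volume, truth.section(e.section_id), e) for e in manifest.entries
    ]


@pytest.fixture(scope="session")
def default_small_pairs(default_small_phantom):
    volume, truth = default_small_phantom
    return pairs_of(volume, truth)


@pytest.fixture(scope="session")
def clean_small_pairs(clean_small_phantom):
    volume, truth = clean_small_phantom
    return pairs_of(volume, truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(20150134)
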