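"""Shared fixtures: a seeded synthetic chart/camera and fitted models."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import endospectra as es

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def camera() -> es.SyntheticCamera:
    """Noiseless colorimetric camera with the sRGB transfer."""
    return es.SyntheticCamera()


@pytest.fixture(scope="session")
def fitted(camera):
    """Chart (seed 1) + fitted calibration and reconstruction models."""
    spectra = es.make_chart(1)
    chart = es.build_chart(spectra, camera)
    measured = es.rgb_to_camera_xyz(chart.rgb_measured)
    calib = es.fit_correction(chart, measured)
    model = es.fit_reconstruction(chart, calib, measured)
    return chart, measured, calib, model


@pytest.fixture(scope="session")
def phantom(camera) -> es.PhantomScene:
    """A varicose phantom living in the seed-1 spectral world."""
    return es.make_phantom(1001, size=(48, 48), label="varicose",
                           cam=camera, world_seed=1)
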