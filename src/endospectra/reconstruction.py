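"""RGB -> reflectance-spectrum reconstruction (the pipeline core).

The 24 reference spectra of the calibration chart are arranged as a
401x24 matrix, decomposed by PCA, and a multiple regression is fitted
from the polynomial expansion of each patch's corrected XYZ to its
principal-component scores.  Applying the chain

    sRGB decode -> primaries matrix -> polynomial correction ->
    expansion -> score regression -> mean + basis^T scores

to every pixel turns an ordinary RGB endoscopic frame into an
H x W x 401 hyperspectral cube on the 380-780 nm grid.

The number of retained components is the smallest k whose cumulative
explained variance reaches the configured threshold (default 99%).

The score regression uses an affine expansion of corrected XYZ by
default: with only 24 training patches, higher-degree expansions
interpolate the chart but extrapolate wildly on scene colors outside
its gamut.  Pass ``score_terms`` to use the full cubic set instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibrationModel, ColorChart, apply_correction, expand_variables
from .colorimetry import (
    N_BANDS,
    WAVELENGTHS,
    ColorMatchingFunctions,
    Illuminant,
    linear_rgb_to_xyz,
    srgb_decode,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReconstructionModel",
    "SpectralCube",
    "fit_reconstruction",
    "reconstruct_spectrum",
    "convert_image",
    "render_spectrum",
    "rgb_to_camera_xyz",
]

#: Reflectance validity range; slight overshoot above 1 is tolerated.
REFLECTANCE_MAX = 1.05

#: Default score-regression expansion: constant + X, Y, Z.
AFFINE_TERMS: list[tuple[int, int, int]] = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]


@dataclass
class SpectralCube:
    """H x W x 401 reflectance cube on the common wavelength grid."""

    data: np.ndarray
    wavelengths: np.ndarray = field(default_factory=lambda: WAVELENGTHS.copy())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[2] != N_BANDS:
            raise ValueError(f"cube must be H x W x {N_BANDS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("cube contains non-finite values")
        if np.asarray(self.wavelengths).shape != (N_BANDS,):
            raise ValueError("wavelength grid must have 401 samples")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]


@dataclass
class ReconstructionModel:
    """PCA basis + score regression mapping corrected XYZ to spectra."""

    mean_spectrum: np.ndarray  # (401,)
    basis: np.ndarray  # (k, 401), orthonormal rows
    score_map: np.ndarray  # (k, n_terms)
    variance_retained: float
    explained_variance: np.ndarray  # (k,) per-component variances
    score_terms: list = field(default_factory=lambda: list(AFFINE_TERMS))

    @property
    def n_components(self) -> int:
        return self.basis.shape[0]

    @property
    def fitted(self) -> bool:
        return self.mean_spectrum is not None


def fit_reconstruction(
    chart: ColorChart,
    calib: CalibrationModel,
    measured_xyz: np.ndarray,
    variance_threshold: float = 0.99,
    score_terms: list | None = None,
) -> ReconstructionModel:
    """Fit the PCA + regression reconstruction model on the 24 patches.

    ``measured_xyz`` are the camera XYZ of the chart patches (the same
    values the calibration was fitted on); they are corrected, expanded
    with ``score_terms`` (affine by default) and regressed onto the
    centered-spectrum principal scores by least squares.
    """
    if not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance_threshold must lie in (0, 1]")
    if not calib.fitted:
        raise RuntimeError("calibration model is not fitted")

    spectra = chart.reflectance_ref  # 401 x 24
    mean = spectra.mean(axis=1)
    centered = spectra - mean[:, None]  # 401 x 24

    # SVD of the centered ensemble; principal directions are columns of U.
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    var = s**2
    total = var.sum()
    if total <= 1e-24:  # all spectra identical
        k = 0
        retained = 1.0
    else:
        cum = np.cumsum(var) / total
        k = int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)
        k = min(k, len(s))
        retained = float(cum[k - 1])

    basis = u[:, :k].T  # k x 401
    scores = basis @ centered  # k x 24

    score_terms = list(AFFINE_TERMS) if score_terms is None else score_terms
    corrected = apply_correction(calib, np.asarray(measured_xyz, dtype=float))
    v = expand_variables(corrected, score_terms)  # 24 x n_terms
    if k > 0:
        score_map, *_ = np.linalg.lstsq(v, scores.T, rcond=None)
        score_map = score_map.T  # k x n_terms
    else:
        score_map = np.zeros((0, v.shape[1]))

    return ReconstructionModel(
        mean_spectrum=mean,
        basis=basis,
        score_map=score_map,
        variance_retained=retained,
        explained_variance=var[:k] / max(spectra.shape[1] - 1, 1),
        score_terms=score_terms,
    )


def rgb_to_camera_xyz(rgb: np.ndarray, gamma: float | None = None,
                      primaries: np.ndarray | None = None) -> np.ndarray:
    """Display RGB in [0,1] -> camera XYZ (Y scale 0-100)."""
    return linear_rgb_to_xyz(srgb_decode(rgb, gamma=gamma), matrix=primaries)


def _spectra_from_xyz(model: ReconstructionModel, calib: CalibrationModel,
                      camera_xyz: np.ndarray) -> np.ndarray:
    corrected = apply_correction(calib, camera_xyz)
    v = np.atleast_2d(expand_variables(corrected, model.score_terms))
    scores = v @ model.score_map.T  # n x k
    spectra = model.mean_spectrum[None, :] + scores @ model.basis  # n x 401
    n_clip = int(np.sum((spectra < 0) | (spectra > REFLECTANCE_MAX)))
    if n_clip:
        logger.debug("reconstruction clipped %d reflectance samples", n_clip)
    return np.clip(spectra, 0.0, REFLECTANCE_MAX)


def reconstruct_spectrum(model: ReconstructionModel, calib: CalibrationModel,
                         rgb: np.ndarray) -> np.ndarray:
    """Reconstruct the 401-sample reflectance spectrum of one RGB triple."""
    if not model.fitted or not calib.fitted:
        raise RuntimeError("models must be fitted before reconstruction")
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape != (3,):
        raise ValueError("expected a single RGB triple")
    return _spectra_from_xyz(model, calib, rgb_to_camera_xyz(rgb))[0]


def convert_image(model: ReconstructionModel, calib: CalibrationModel,
                  frame: np.ndarray) -> SpectralCube:
    """Convert an RGB raster (H x W x 3, uint8 or unit floats) to a cube.

    Distinct RGB triples are reconstructed once and scattered back to
    their pixel positions, which makes 8-bit frames (at most 2^24
    distinct colors, usually far fewer) much cheaper than per-pixel
    evaluation while producing identical output.
    """
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise ValueError("frame must be H x W x 3")
    if frame.shape[0] == 0 or frame.shape[1] == 0:
        raise ValueError("frame has no pixels")
    if frame.dtype == np.uint8:
        rgb = frame.astype(float) / 255.0
    else:
        rgb = frame.astype(float)
    h, w, _ = rgb.shape
    flat = rgb.reshape(-1, 3)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    spectra = _spectra_from_xyz(model, calib, rgb_to_camera_xyz(uniq))
    cube = spectra[inverse].reshape(h, w, N_BANDS)
    return SpectralCube(cube)


def render_spectrum(spectrum: np.ndarray, ill: Illuminant,
                    cmf: ColorMatchingFunctions) -> np.ndarray:
    """Forward-render reflectance to XYZ under an illuminant.

    X = k sum S(l) R(l) xbar(l)  (likewise Y, Z), with k fixed so a
    perfect reflector has Y = 100.  Accepts a single spectrum (401,) or
    a stack (..., 401).
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if spectrum.shape[-1] != N_BANDS:
        raise ValueError(f"spectrum must have {N_BANDS} samples")
    if not np.array_equal(ill.wavelengths, cmf.wavelengths):
        raise ValueError("illuminant and CMF grids differ")
    k = 100.0 / np.sum(ill.power * cmf.ybar)
    weights = ill.power[None, :] * cmf.as_matrix()  # 3 x 401
    return k * spectrum @ weights.T
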