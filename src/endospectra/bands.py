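"""Band selection and simulated narrow-band imaging.

Narrow-band endoscopy illuminates tissue at 415 nm and 540 nm — the
Soret and beta absorption peaks of hemoglobin — so mucosal capillaries
absorb strongly and appear dark against the surrounding tissue.  Given
a reconstructed hyperspectral cube, the same effect is obtained
computationally by averaging the cube over narrow Gaussian windows at
those centers and mapping the two band images to display channels
(540 nm to red; 415 nm to green and blue), which renders superficial
vessels brownish and deeper ones cyan, as in hardware narrow-band
imaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .colorimetry import N_BANDS, WAVELENGTHS, srgb_encode
from .reconstruction import ReconstructionModel, SpectralCube

__all__ = ["BandSelection", "NBIBandSpec", "select_bands", "extract_band_image", "simulate_nbi"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class BandSelection:
    indices: np.ndarray  # strictly increasing positions on the 401 grid
    wavelengths: np.ndarray
    scores: np.ndarray  # contribution score of each selected band
    method: str = "pca-loadings"


@dataclass(frozen=True)
class NBIBandSpec:
    """Two narrow illumination bands plus the false-color channel mix.

    ``mixing`` maps the (band_1, band_2) images to display (R, G, B);
    the default feeds red from the 540 nm image and green/blue from the
    415 nm image so that a spectrally flat scene renders neutral.
    """

    centers_nm: tuple[float, float] = (415.0, 540.0)
    fwhm_nm: tuple[float, float] = (30.0, 30.0)
    mixing: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 1.0], [1.0, 0.0], [1.0, 0.0]])
    )

    def __post_init__(self) -> None:
        for c in self.centers_nm:
            if not (WAVELENGTHS[0] <= c <= WAVELENGTHS[-1]):
                raise ValueError(f"band center {c} nm outside the 380-780 nm grid")
        for f in self.fwhm_nm:
            if f <= 0:
                raise ValueError("band FWHM must be positive")
        m = np.asarray(self.mixing, dtype=float)
        if m.shape != (3, 2):
            raise ValueError("mixing matrix must be 3x2")
        object.__setattr__(self, "mixing", m)


def select_bands(model: ReconstructionModel, n_bands: int,
                 min_separation_nm: float = 10.0) -> BandSelection:
    """Rank wavelengths by their principal-component contribution.

    The score of band j is the variance-weighted sum of squared basis
    loadings, sum_i var_i * basis[i, j]^2 — i.e. each band's share of the
    spectral variance captured by the retained eigenvectors.  Bands are
    picked greedily from the highest score down, skipping candidates
    closer than ``min_separation_nm`` to an already-chosen band; set the
    separation to 0 to disable the spacing rule.
    """
    if not (1 <= n_bands <= N_BANDS):
        raise ValueError(f"n_bands must be in [1, {N_BANDS}]")
    if model.n_components < 1:
        raise ValueError("model retains no components; nothing to rank")
    scores = model.explained_variance @ model.basis**2  # (401,)
    order = np.argsort(scores, kind="stable")[::-1]
    chosen: list[int] = []
    for idx in order:
        if len(chosen) == n_bands:
            break
        if min_separation_nm > 0 and any(
            abs(WAVELENGTHS[idx] - WAVELENGTHS[c]) < min_separation_nm for c in chosen
        ):
            continue
        chosen.append(int(idx))
    chosen.sort()
    sel = np.asarray(chosen, dtype=int)
    return BandSelection(
        indices=sel,
        wavelengths=WAVELENGTHS[sel],
        scores=scores[sel],
    )


def extract_band_image(cube: SpectralCube, center_nm: float, fwhm_nm: float) -> np.ndarray:
    """Gaussian-weighted spectral average around ``center_nm``.

    Weights are normalized to sum to 1, so a spectrally flat cube maps
    to its own reflectance level and the operation is linear in the
    cube.  Output values lie in [0, 1.05] like the cube itself.
    """
    if not (WAVELENGTHS[0] <= center_nm <= WAVELENGTHS[-1]):
        raise ValueError(f"band center {center_nm} nm outside the grid")
    if fwhm_nm <= 0:
        raise ValueError("FWHM must be positive")
    sigma = fwhm_nm * _FWHM_TO_SIGMA
    w = np.exp(-0.5 * ((WAVELENGTHS - center_nm) / sigma) ** 2)
    w /= w.sum()
    return cube.data @ w


def simulate_nbi(cube: SpectralCube, spec: NBIBandSpec | None = None) -> np.ndarray:
    """Render a false-color narrow-band image from a cube.

    Returns an H x W x 3 display-encoded (sRGB transfer) float raster in
    [0, 1].  Hemoglobin-rich structures, which absorb at both band
    centers, come out darker than the surrounding tissue.
    """
    spec = NBIBandSpec() if spec is None else spec
    if not np.array_equal(cube.wavelengths, WAVELENGTHS):
        raise ValueError("cube wavelength grid does not match the common grid")
    bands = np.stack(
        [extract_band_image(cube, c, f) for c, f in zip(spec.centers_nm, spec.fwhm_nm)],
        axis=-1,
    )  # H x W x 2
    display_linear = bands @ spec.mixing.T
    return srgb_encode(np.clip(display_linear, 0.0, 1.0))
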