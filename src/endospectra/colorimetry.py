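"""Color-space conversions and color-difference scoring.

All spectral quantities live on a fixed wavelength grid of 380-780 nm
sampled every 1 nm (401 samples).  Tristimulus values use the reflective
convention in which the reference white has Y = 100.

The CIE 1931 2-degree color-matching functions are provided as a
multi-lobe piecewise-Gaussian analytic model (accurate to about 1% of
peak), so the package carries no tabulated data; exact tabulations can be
loaded from plain-text files instead when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WAVELENGTHS",
    "N_BANDS",
    "Illuminant",
    "ColorMatchingFunctions",
    "WhitePoint",
    "SRGB_TO_XYZ",
    "XYZ_FROM_SRGB_WHITE",
    "srgb_decode",
    "srgb_encode",
    "linear_rgb_to_xyz",
    "xyz_to_linear_rgb",
    "lab_f",
    "lab_f_inv",
    "xyz_to_lab",
    "lab_to_xyz",
    "ciede2000",
    "cie_1931_cmfs",
    "illuminant_e",
    "illuminant_planckian",
    "white_point_from",
    "load_spectral_table",
    "save_spectral_table",
]

#: The common wavelength grid, 380..780 nm inclusive at 1 nm steps.
WAVELENGTHS: np.ndarray = np.arange(380.0, 781.0, 1.0)
N_BANDS: int = WAVELENGTHS.size  # 401

# CIELAB transfer-function constants (CIE 15): threshold (6/29)^3 and the
# linear-branch slope/offset printed to the precision in common use.
_LAB_THRESHOLD = 0.008856
_LAB_SLOPE = 7.787
_LAB_OFFSET = 0.137931  # = 16/116

# IEC 61966-2-1 sRGB primaries (D65 white), linear RGB -> XYZ with Y(white)=1.
SRGB_TO_XYZ: np.ndarray = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
#: XYZ of the sRGB white point on the Y=100 scale.
XYZ_FROM_SRGB_WHITE: np.ndarray = 100.0 * SRGB_TO_XYZ @ np.ones(3)


def _check_grid(wavelengths: np.ndarray) -> np.ndarray:
    w = np.asarray(wavelengths, dtype=float)
    if w.ndim != 1 or w.size != N_BANDS:
        raise ValueError(f"expected {N_BANDS} wavelength samples, got {w.size}")
    if np.any(np.diff(w) <= 0):
        raise ValueError("wavelengths must be strictly increasing")
    return w


@dataclass(frozen=True)
class Illuminant:
    """Spectral power distribution on the common 401-sample grid."""

    wavelengths: np.ndarray
    power: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _check_grid(self.wavelengths))
        p = np.asarray(self.power, dtype=float)
        if p.shape != (N_BANDS,):
            raise ValueError("illuminant power must have 401 samples")
        if np.any(p < 0) or not np.all(np.isfinite(p)):
            raise ValueError("illuminant power must be finite and nonnegative")
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class ColorMatchingFunctions:
    """Observer weighting curves x̄, ȳ, z̄ on the common grid."""

    wavelengths: np.ndarray
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "wavelengths", _check_grid(self.wavelengths))
        for attr in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (N_BANDS,):
                raise ValueError(f"{attr} must have 401 samples")
            if np.any(v < 0):
                raise ValueError(f"{attr} must be nonnegative")
            object.__setattr__(self, attr, v)

    def as_matrix(self) -> np.ndarray:
        """Return the 3x401 stack (x̄; ȳ; z̄)."""
        return np.stack([self.xbar, self.ybar, self.zbar])


@dataclass(frozen=True)
class WhitePoint:
    Xn: float
    Yn: float
    Zn: float

    def __post_init__(self) -> None:
        if min(self.Xn, self.Yn, self.Zn) <= 0:
            raise ValueError("white point tristimulus values must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.Xn, self.Yn, self.Zn])


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------

def _validate_unit(rgb: np.ndarray, what: str) -> np.ndarray:
    rgb = np.asarray(rgb, dtype=float)
    if np.any(rgb < 0) or np.any(rgb > 1):
        bad = np.argwhere((rgb < 0) | (rgb > 1))
        idx = tuple(bad[0])
        channel = "RGB"[idx[-1]] if rgb.ndim and rgb.shape[-1] == 3 else str(idx)
        raise ValueError(
            f"{what} component out of [0, 1] at channel {channel}: {rgb[idx]!r}"
        )
    return rgb


def srgb_decode(rgb: np.ndarray, gamma: float | None = None) -> np.ndarray:
    """Decode display-referred values to linear light.

    By default applies the piecewise sRGB electro-optical transfer
    function; pass ``gamma`` for a pure power law instead.  Input and
    output are in [0, 1]; any leading shape is accepted.
    """
    rgb = _validate_unit(rgb, "sRGB")
    if gamma is not None:
        return np.power(rgb, gamma)
    lo = rgb <= 0.04045
    out = np.where(lo, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)
    return out


def srgb_encode(linear: np.ndarray, gamma: float | None = None) -> np.ndarray:
    """Inverse of :func:`srgb_decode` (input clipped to [0, 1])."""
    linear = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    if gamma is not None:
        return np.power(linear, 1.0 / gamma)
    lo = linear <= 0.0031308
    return np.where(lo, 12.92 * linear, 1.055 * linear ** (1 / 2.4) - 0.055)


def linear_rgb_to_xyz(linear: np.ndarray, matrix: np.ndarray | None = None) -> np.ndarray:
    """Map linear RGB (unit scale) to XYZ on the Y=100 scale.

    ``matrix`` defaults to the sRGB primaries; it must be invertible so
    the display path stays round-trippable.
    """
    m = SRGB_TO_XYZ if matrix is None else np.asarray(matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValueError("primaries matrix must be 3x3")
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("primaries matrix is singular")
    linear = np.asarray(linear, dtype=float)
    return 100.0 * linear @ m.T


def xyz_to_linear_rgb(xyz: np.ndarray, matrix: np.ndarray | None = None) -> np.ndarray:
    m = SRGB_TO_XYZ if matrix is None else np.asarray(matrix, dtype=float)
    if abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("primaries matrix is singular")
    xyz = np.asarray(xyz, dtype=float)
    return (xyz / 100.0) @ np.linalg.inv(m).T


# ---------------------------------------------------------------------------
# CIELAB
# ---------------------------------------------------------------------------

def lab_f(n: np.ndarray | float) -> np.ndarray | float:
    """CIELAB compression: cube root above the CIE threshold, the
    matched linear ramp 7.787 n + 16/116 below it."""
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore"):
        out = np.where(
            n > _LAB_THRESHOLD,
            np.cbrt(np.maximum(n, 0.0)),
            _LAB_SLOPE * n + _LAB_OFFSET,
        )
    return out if out.ndim else float(out)


def lab_f_inv(t: np.ndarray | float) -> np.ndarray | float:
    t = np.asarray(t, dtype=float)
    cube_ok = t > _LAB_SLOPE * _LAB_THRESHOLD + _LAB_OFFSET
    out = np.where(cube_ok, t**3, (t - _LAB_OFFSET) / _LAB_SLOPE)
    return out if out.ndim else float(out)


def xyz_to_lab(xyz: np.ndarray, white: WhitePoint, clamp_negative_l: bool = True) -> np.ndarray:
    """XYZ -> CIELAB against ``white``.

    L* = 116 f(Y/Yn) - 16, a* = 500 [f(X/Xn) - f(Y/Yn)],
    b* = 200 [f(Y/Yn) - f(Z/Zn)].  For reflective imagery a slightly
    negative L* can only arise from the linear branch at Y = 0; it is
    clamped to 0 by default.
    """
    xyz = np.asarray(xyz, dtype=float)
    ratios = xyz / white.as_array()
    f = lab_f(ratios)
    f = np.atleast_2d(f)
    L = 116.0 * f[..., 1] - 16.0
    if clamp_negative_l:
        L = np.maximum(L, 0.0)
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    lab = np.stack([L, a, b], axis=-1)
    return lab[0] if np.asarray(xyz).ndim == 1 else lab


def lab_to_xyz(lab: np.ndarray, white: WhitePoint) -> np.ndarray:
    lab = np.asarray(lab, dtype=float)
    single = lab.ndim == 1
    lab = np.atleast_2d(lab)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    ratios = np.stack([lab_f_inv(fx), lab_f_inv(fy), lab_f_inv(fz)], axis=-1)
    xyz = ratios * white.as_array()
    return xyz[0] if single else xyz


# ---------------------------------------------------------------------------
# CIEDE2000
# ---------------------------------------------------------------------------

def ciede2000(lab1: np.ndarray, lab2: np.ndarray) -> np.ndarray | float:
    """CIEDE2000 color difference between Lab triples.

    Implements the published reference formula (Sharma, Wu & Dalal 2005
    implementation notes), with the standard weighting factors
    kL = kC = kH = 1.  Accepts broadcastable stacks of triples.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    scalar = lab1.ndim == 1 and lab2.ndim == 1
    L1, a1, b1 = np.moveaxis(np.atleast_2d(lab1), -1, 0)
    L2, a2, b2 = np.moveaxis(np.atleast_2d(lab2), -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1.0 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1.0 + G) * a1
    a2p = (1.0 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.degrees(np.arctan2(b1, a1p)) % 360.0
    h2p = np.degrees(np.arctan2(b2, a2p)) % 360.0
    h1p = np.where((b1 == 0) & (a1p == 0), 0.0, h1p)
    h2p = np.where((b2 == 0) & (a2p == 0), 0.0, h2p)

    dLp = L2 - L1
    dCp = C2p - C1p
    dh = h2p - h1p
    dh = np.where(dh > 180.0, dh - 360.0, dh)
    dh = np.where(dh < -180.0, dh + 360.0, dh)
    dh = np.where(C1p * C2p == 0.0, 0.0, dh)
    dHp = 2.0 * np.sqrt(C1p * C2p) * np.sin(np.radians(dh) / 2.0)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(habs <= 180.0, 0.5 * hsum,
                   np.where(hsum < 360.0, 0.5 * (hsum + 360.0), 0.5 * (hsum - 360.0)))
    hbp = np.where(C1p * C2p == 0.0, hsum, hbp)

    T = (1.0
         - 0.17 * np.cos(np.radians(hbp - 30.0))
         + 0.24 * np.cos(np.radians(2.0 * hbp))
         + 0.32 * np.cos(np.radians(3.0 * hbp + 6.0))
         - 0.20 * np.cos(np.radians(4.0 * hbp - 63.0)))
    d_theta = 30.0 * np.exp(-(((hbp - 275.0) / 25.0) ** 2))
    RC = 2.0 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1.0 + 0.015 * (Lbp - 50.0) ** 2 / np.sqrt(20.0 + (Lbp - 50.0) ** 2)
    SC = 1.0 + 0.045 * Cbp
    SH = 1.0 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2.0 * d_theta)) * RC

    dE = np.sqrt(
        (dLp / SL) ** 2
        + (dCp / SC) ** 2
        + (dHp / SH) ** 2
        + RT * (dCp / SC) * (dHp / SH)
    )
    return float(dE[0]) if scalar else dE


# ---------------------------------------------------------------------------
# Built-in observer and illuminants
# ---------------------------------------------------------------------------

def _piecewise_gaussian(x: np.ndarray, mu: float, s1: float, s2: float) -> np.ndarray:
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cie_1931_cmfs() -> ColorMatchingFunctions:
    """CIE 1931 2-degree observer via the multi-lobe Gaussian fit of
    Wyman, Sloan & Shirley (2013), evaluated on the 401-sample grid."""
    w = WAVELENGTHS
    x = (1.056 * _piecewise_gaussian(w, 599.8, 37.9, 31.0)
         + 0.362 * _piecewise_gaussian(w, 442.0, 16.0, 26.7)
         - 0.065 * _piecewise_gaussian(w, 501.1, 20.4, 26.2))
    y = (0.821 * _piecewise_gaussian(w, 568.8, 46.9, 40.5)
         + 0.286 * _piecewise_gaussian(w, 530.9, 16.3, 31.1))
    z = (1.217 * _piecewise_gaussian(w, 437.0, 11.8, 36.0)
         + 0.681 * _piecewise_gaussian(w, 459.0, 26.0, 13.8))
    return ColorMatchingFunctions(w, np.maximum(x, 0.0), np.maximum(y, 0.0),
                                  np.maximum(z, 0.0), name="CIE1931-2deg(gaussian-fit)")


def illuminant_e() -> Illuminant:
    """Equal-energy illuminant (flat spectrum)."""
    return Illuminant(WAVELENGTHS, np.ones(N_BANDS), name="E")


def illuminant_planckian(temperature_k: float = 6500.0) -> Illuminant:
    """Blackbody radiator at ``temperature_k``, peak-normalized.

    A 6500 K Planckian spectrum is a smooth stand-in for the broadband
    (xenon-like) lamp of a white-light endoscope.
    """
    if temperature_k <= 0:
        raise ValueError("temperature must be positive")
    lam = WAVELENGTHS * 1e-9
    h, c, kB = 6.62607015e-34, 2.99792458e8, 1.380649e-23
    power = (2 * h * c**2 / lam**5) / np.expm1(h * c / (lam * kB * temperature_k))
    return Illuminant(WAVELENGTHS, power / power.max(),
                      name=f"planckian-{temperature_k:g}K")


def white_point_from(ill: Illuminant, cmf: ColorMatchingFunctions) -> WhitePoint:
    """White point of a perfect reflector under ``ill``: Yn = 100."""
    if not np.array_equal(ill.wavelengths, cmf.wavelengths):
        raise ValueError("illuminant and CMF wavelength grids differ")
    k = 100.0 / np.sum(ill.power * cmf.ybar)
    return WhitePoint(
        Xn=k * float(np.sum(ill.power * cmf.xbar)),
        Yn=100.0,
        Zn=k * float(np.sum(ill.power * cmf.zbar)),
    )


# ---------------------------------------------------------------------------
# Plain-text spectral tables
# ---------------------------------------------------------------------------

def load_spectral_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a whitespace/comma-delimited table: wavelength + value columns.

    Returns ``(wavelengths, values)`` with values shaped (401, n_cols).
    """
    data = np.genfromtxt(path, delimiter=None, comments="#")
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError(f"{path}: expected wavelength + value columns")
    w = _check_grid(data[:, 0])
    return w, data[:, 1:]


def save_spectral_table(path, wavelengths: np.ndarray, values: np.ndarray) -> None:
    w = _check_grid(wavelengths)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[0] != N_BANDS:
        values = values.T
    np.savetxt(path, np.column_stack([w, values]), fmt="%.8g")
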