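"""Image- and spectrum-agreement scores (SSIM, PSNR, spectral RMSE)."""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["QualityReport", "ssim", "psnr", "spectral_rmse", "quality_report"]


@dataclass(frozen=True)
class QualityReport:
    ssim: float
    psnr_db: float  # math.inf for identical inputs
    rmse: float

    def to_dict(self) -> dict:
        d = asdict(self)
        if math.isinf(d["psnr_db"]):
            d["psnr_db"] = "inf"
        return d


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0,
         sigma: float = 1.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Structural similarity with an 11x11 Gaussian window (sigma 1.5)
    and the standard stabilizers K1 = 0.01, K2 = 0.03."""
    a, b = _check_pair(a, b)
    return float(
        structural_similarity(
            a, b, data_range=data_range, gaussian_weights=True, sigma=sigma,
            use_sample_covariance=False, K1=k1, K2=k2,
        )
    )


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """10 log10(peak^2 / MSE) in dB; +inf when the inputs are identical."""
    a, b = _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


def spectral_rmse(est: np.ndarray, ref: np.ndarray) -> float:
    """Root-mean-square difference between two spectra on a shared grid."""
    est, ref = _check_pair(est, ref)
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def quality_report(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> QualityReport:
    a, b = _check_pair(a, b)
    return QualityReport(
        ssim=ssim(a, b, data_range=data_range),
        psnr_db=psnr(a, b, peak=data_range),
        rmse=float(np.sqrt(np.mean((a - b) ** 2))),
    )
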