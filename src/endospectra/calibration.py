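"""Chart-based polynomial correction of the camera's XYZ response.

A 24-patch reference chart (Macbeth-style) is imaged by the endoscope
camera; the XYZ values computed from the camera RGB ("camera XYZ")
deviate from the colorimetric XYZ of the patches ("target XYZ") because
of the sensor's spectral sensitivities, residual nonlinearity and dark
offset.  The correction is a linear map on a polynomial expansion of
camera XYZ, limited to total degree 3 to avoid over-rectification: the
degree-1 block plays the role of the color-mixing terms, the degree-2/3
blocks absorb nonlinearity, and the constant term absorbs the dark
offset.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .colorimetry import (
    N_BANDS,
    WhitePoint,
    ciede2000,
    cie_1931_cmfs,
    illuminant_planckian,
    white_point_from,
    xyz_to_lab,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ColorChart",
    "CalibrationModel",
    "full_cubic_terms",
    "expand_variables",
    "fit_correction",
    "apply_correction",
]

N_PATCHES = 24

#: A monomial over (X, Y, Z) as exponent triples; (0, 0, 0) is the constant
#: (dark-offset) term.
Term = tuple[int, int, int]


def full_cubic_terms() -> list[Term]:
    """All monomials over (X, Y, Z) of total degree <= 3, constant first,
    then by ascending degree in lexicographic order: 20 terms."""
    terms = [
        t
        for degree in range(4)
        for t in sorted(
            t for t in itertools.product(range(4), repeat=3) if sum(t) == degree
        )
    ]
    return terms


def _default_white() -> WhitePoint:
    return white_point_from(illuminant_planckian(), cie_1931_cmfs())


@dataclass
class ColorChart:
    """A 24-patch calibration chart record.

    ``reflectance_ref`` holds the reference reflectance spectra, one
    column per patch, on the 401-sample 380-780 nm grid.
    """

    patch_ids: list[str]
    rgb_measured: np.ndarray  # 24x3, unit interval
    xyz_target: np.ndarray  # 24x3, Y in [0, 100]
    reflectance_ref: np.ndarray  # 401x24

    def __post_init__(self) -> None:
        self.rgb_measured = np.asarray(self.rgb_measured, dtype=float)
        self.xyz_target = np.asarray(self.xyz_target, dtype=float)
        self.reflectance_ref = np.asarray(self.reflectance_ref, dtype=float)
        if len(self.patch_ids) != N_PATCHES:
            raise ValueError(f"chart must have {N_PATCHES} patches, got {len(self.patch_ids)}")
        if self.rgb_measured.shape != (N_PATCHES, 3):
            raise ValueError("rgb_measured must be 24x3")
        if self.xyz_target.shape != (N_PATCHES, 3):
            raise ValueError("xyz_target must be 24x3")
        if self.reflectance_ref.shape != (N_BANDS, N_PATCHES):
            raise ValueError(f"reflectance_ref must be {N_BANDS}x{N_PATCHES}")
        if np.any(self.reflectance_ref < 0) or np.any(self.reflectance_ref > 1.05):
            raise ValueError("reference reflectances must lie in [0, 1.05]")


def expand_variables(
    xyz: np.ndarray, terms: list[Term] | None = None, standardize: bool = False,
    scale: np.ndarray | None = None,
) -> np.ndarray:
    """Evaluate the monomial expansion at one or many XYZ triples.

    Returns shape ``(..., n_terms)``.  XYZ is taken on the Y=100 scale
    and divided by 100 internally so that degree-3 terms stay O(1).
    With ``standardize`` the non-constant columns are z-scored using
    ``scale`` (mean, sd pairs) computed at fit time.
    """
    terms = full_cubic_terms() if terms is None else terms
    if not terms:
        raise ValueError("term list must be nonempty")
    for t in terms:
        if len(t) != 3 or any(e < 0 for e in t):
            raise ValueError(f"malformed term {t}")
        if sum(t) > 3:
            raise ValueError(f"term {t} exceeds degree 3")
    xyz = np.asarray(xyz, dtype=float) / 100.0
    single = xyz.ndim == 1
    xyz = np.atleast_2d(xyz)
    cols = [
        xyz[:, 0] ** i * xyz[:, 1] ** j * xyz[:, 2] ** k for (i, j, k) in terms
    ]
    v = np.stack(cols, axis=-1)
    if standardize:
        if scale is None:
            raise ValueError("standardize requires fitted scale parameters")
        mean, sd = scale
        v = (v - mean) / sd
        # keep the constant column an exact intercept
        const = [i for i, t in enumerate(terms) if sum(t) == 0]
        for i in const:
            v[:, i] = 1.0
    return v[0] if single else v


@dataclass
class CalibrationModel:
    """Fitted polynomial XYZ correction plus its training diagnostics."""

    terms: list[Term]
    matrix: np.ndarray  # 3 x n_terms
    standardize: bool = False
    scale: tuple[np.ndarray, np.ndarray] | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def fitted(self) -> bool:
        return self.matrix is not None and np.all(np.isfinite(self.matrix))

    def to_json(self, path=None) -> str:
        payload = {
            "terms": [list(t) for t in self.terms],
            "matrix": self.matrix.tolist(),
            "standardize": self.standardize,
            "scale": None
            if self.scale is None
            else [self.scale[0].tolist(), self.scale[1].tolist()],
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationModel":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        scale = payload.get("scale")
        return cls(
            terms=[tuple(t) for t in payload["terms"]],
            matrix=np.asarray(payload["matrix"], dtype=float),
            standardize=payload.get("standardize", False),
            scale=None if scale is None else (np.asarray(scale[0]), np.asarray(scale[1])),
            diagnostics=payload.get("diagnostics", {}),
        )


def _rmse_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(np.mean((a - b) ** 2, axis=1))


def fit_correction(
    chart: ColorChart,
    measured_xyz: np.ndarray,
    terms: list[Term] | None = None,
    standardize: bool = False,
    ridge: float = 0.0,
    white: WhitePoint | None = None,
) -> CalibrationModel:
    """Least-squares fit of the polynomial correction on the 24 patches.

    Solves ``min_C ||V C^T - xyz_target||^2`` where V stacks the expanded
    measured XYZ rows.  The minimum-norm solution is used (24 samples
    against 20 cubic terms is nearly square); ``ridge`` adds Tikhonov
    damping on the non-constant terms when the chart is noisy.

    Diagnostics record per-patch XYZ RMSE and mean CIEDE2000 against the
    targets both before and after correction.
    """
    terms = full_cubic_terms() if terms is None else terms
    measured_xyz = np.asarray(measured_xyz, dtype=float)
    if measured_xyz.shape != (N_PATCHES, 3):
        raise ValueError("measured_xyz must be 24x3")

    scale = None
    if standardize:
        raw = expand_variables(measured_xyz, terms)
        mean = raw.mean(axis=0)
        sd = raw.std(axis=0)
        sd[sd == 0] = 1.0
        scale = (mean, sd)
    v = expand_variables(measured_xyz, terms, standardize=standardize, scale=scale)

    rank = np.linalg.matrix_rank(v)
    if rank < min(v.shape) and ridge == 0.0:
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {min(v.shape)}; "
            "reduce the term set or enable ridge damping"
        )
    if ridge > 0.0:
        damp = np.full(len(terms), np.sqrt(ridge))
        for i, t in enumerate(terms):
            if sum(t) == 0:
                damp[i] = 0.0  # never shrink the dark-offset term
        a = np.vstack([v, np.diag(damp)])
        b = np.vstack([chart.xyz_target, np.zeros((len(terms), 3))])
        coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(v, chart.xyz_target, rcond=None)
    model = CalibrationModel(terms=terms, matrix=coef.T, standardize=standardize, scale=scale)

    corrected = apply_correction(model, measured_xyz)
    white = _default_white() if white is None else white
    lab_t = xyz_to_lab(chart.xyz_target, white)
    de_pre = ciede2000(xyz_to_lab(measured_xyz, white), lab_t)
    de_post = ciede2000(xyz_to_lab(corrected, white), lab_t)
    model.diagnostics = {
        "rmse_pre": _rmse_rows(measured_xyz, chart.xyz_target).tolist(),
        "rmse_post": _rmse_rows(corrected, chart.xyz_target).tolist(),
        "mean_rmse_pre": float(np.mean(_rmse_rows(measured_xyz, chart.xyz_target))),
        "mean_rmse_post": float(np.mean(_rmse_rows(corrected, chart.xyz_target))),
        "mean_de00_pre": float(np.mean(de_pre)),
        "mean_de00_post": float(np.mean(de_post)),
    }
    return model


def apply_correction(model: CalibrationModel, xyz: np.ndarray) -> np.ndarray:
    """Apply a fitted correction; negative tristimulus values are clamped
    to 0 (physical nonnegativity) and the clamp count logged."""
    if model.matrix is None:
        raise RuntimeError("calibration model is not fitted")
    v = expand_variables(xyz, model.terms, standardize=model.standardize, scale=model.scale)
    out = v @ model.matrix.T
    n_neg = int(np.sum(out < 0))
    if n_neg:
        logger.debug("apply_correction clamped %d negative tristimulus values", n_neg)
    return np.clip(out, 0.0, None)
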