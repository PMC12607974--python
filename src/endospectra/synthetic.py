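"""Seeded synthetic fixtures: camera, chart, vascular phantoms, dataset.

Every input the pipeline needs is generated programmatically so the
whole toolchain can be exercised end to end without any acquisition
hardware or external download:

* a synthetic camera with configurable spectral response, transfer
  function, dark offset, noise and an optional cubic XYZ distortion —
  the forward model that closed-loop tests invert;
* a 24-patch reference chart whose spectra are band-limited random
  curves (sums of at most six Gaussian bumps);
* tissue-like phantom frames with darkened vessel structures whose
  reflectance dips near 415 and 540 nm, mimicking hemoglobin
  absorption, together with their ground-truth spectral cubes;
* a class-balanced image dataset (eight classes; 1800/400/200
  train/validation/test split, 2400 frames in total by default).

The spectral world is deliberately low-dimensional: within one world
seed, chart and scene reflectances are drawn from a common
3-dimensional family (a broad scattering baseline plus two Gaussian
absorption shapes centered near 415 and 540 nm).  Reconstructing a
full spectrum from three color coordinates is only well-posed on such
a manifold; sharing it between the calibration chart and the scene is
what makes closed-loop spectral recovery a meaningful test rather than
an exercise in metamerism.  All generators are pure functions of their
seed and parameters.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .calibration import ColorChart, expand_variables, full_cubic_terms
from .colorimetry import (
    N_BANDS,
    WAVELENGTHS,
    ColorMatchingFunctions,
    Illuminant,
    cie_1931_cmfs,
    illuminant_planckian,
    srgb_encode,
    xyz_to_linear_rgb,
)
from .reconstruction import SpectralCube, render_spectrum

__all__ = [
    "SyntheticCamera",
    "SpectralWorld",
    "PhantomScene",
    "PHANTOM_CLASSES",
    "DEFAULT_CLASS_COUNTS",
    "spectral_world",
    "make_chart",
    "build_chart",
    "render_with_camera",
    "make_phantom",
    "make_dataset",
]

#: Per-class presets: (brightness range lo, hi; reflectance tint along
#: the 415 nm and 540 nm shapes relative to brightness; vessel count;
#: absorber strength).  Eight distinguishable gastrointestinal
#: categories; cancer/varicose carry the densest vasculature.
PHANTOM_CLASSES: dict[str, tuple[float, float, float, float, int, float]] = {
    "normal": (0.50, 0.85, 0.05, 0.10, 3, 0.55),
    "staining": (0.45, 0.80, 0.30, 0.05, 2, 0.40),
    "cancer": (0.35, 0.70, -0.15, -0.10, 8, 0.85),
    "varicose": (0.45, 0.80, -0.05, -0.15, 6, 0.90),
    "esophageal_junction": (0.50, 0.85, 0.10, -0.05, 4, 0.60),
    "inflammation": (0.40, 0.75, -0.20, 0.05, 5, 0.75),
    "duodenum": (0.55, 0.90, 0.05, 0.20, 3, 0.50),
    "stomach": (0.50, 0.85, 0.15, 0.15, 4, 0.55),
}

#: Default per-class (train, validation, test) counts: 2400 frames in
#: total, split 1800/400/200, with the cancer and varicose classes twice
#: as large as the others.
DEFAULT_CLASS_COUNTS: dict[str, tuple[int, int, int]] = {
    "normal": (180, 40, 20),
    "staining": (180, 40, 20),
    "cancer": (360, 80, 40),
    "varicose": (360, 80, 40),
    "esophageal_junction": (180, 40, 20),
    "inflammation": (180, 40, 20),
    "duodenum": (180, 40, 20),
    "stomach": (180, 40, 20),
}


@dataclass(frozen=True)
class SyntheticCamera:
    """Forward model: reflectance spectrum -> display RGB.

    The default sensitivities equal the observer color-matching
    functions, making the camera colorimetric: its raw response is
    exactly the scene XYZ, so calibration only has to undo the optional
    cubic ``distortion`` (a 3 x 20 coefficient matrix over the cubic
    monomials of XYZ/100), the dark offset and the noise.
    """

    sensitivities: np.ndarray | None = None  # 3 x 401; None -> CMFs
    transfer: str = "srgb"  # "srgb" | "linear"
    dark_offset: float = 0.0  # added in linear RGB
    noise_sd: float = 0.0  # Gaussian, linear domain
    distortion: np.ndarray | None = None  # 3 x 20 cubic map on XYZ
    quantize: bool = False  # round display RGB to 8 bits

    def __post_init__(self) -> None:
        if self.sensitivities is not None:
            s = np.asarray(self.sensitivities, dtype=float)
            if s.shape != (3, N_BANDS) or np.any(s < 0):
                raise ValueError("sensitivities must be nonnegative 3x401")
            object.__setattr__(self, "sensitivities", s)
        if self.transfer not in ("srgb", "linear"):
            raise ValueError("transfer must be 'srgb' or 'linear'")
        if self.distortion is not None:
            d = np.asarray(self.distortion, dtype=float)
            if d.shape != (3, len(full_cubic_terms())):
                raise ValueError("distortion must be 3 x 20 (cubic terms)")
            object.__setattr__(self, "distortion", d)


@dataclass(frozen=True)
class SpectralWorld:
    """The seeded 3-dimensional reflectance family of one synthetic run:
    reflectance = a0 * baseline + a1 * shape415 + a2 * shape540."""

    baseline: np.ndarray  # broad smooth curve, peak 1
    shape415: np.ndarray  # Gaussian near 415 nm
    shape540: np.ndarray  # Gaussian near 540 nm

    def spectrum(self, a0, a1, a2) -> np.ndarray:
        """Evaluate coefficients (arrays broadcast over leading axes)."""
        a0, a1, a2 = np.broadcast_arrays(np.asarray(a0, float),
                                         np.asarray(a1, float),
                                         np.asarray(a2, float))
        out = (a0[..., None] * self.baseline
               + a1[..., None] * self.shape415
               + a2[..., None] * self.shape540)
        return np.clip(out, 0.0, 1.05)


@dataclass
class PhantomScene:
    """A tissue phantom: ground-truth cube, vessel mask and WLI frame."""

    label: str
    cube: SpectralCube
    vessel_mask: np.ndarray  # boolean H x W
    frame: np.ndarray  # uint8 H x W x 3 display RGB
    absorber_strength: float


def spectral_world(seed: int) -> SpectralWorld:
    """Draw the per-seed reflectance basis (2-4 broad baseline bumps,
    plus ~30 nm Gaussian shapes at the 415/540 nm absorption centers)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EC7]))
    baseline = np.zeros(N_BANDS)
    for _ in range(int(rng.integers(2, 5))):
        c = rng.uniform(450.0, 750.0)
        w = rng.uniform(60.0, 150.0)
        baseline += rng.uniform(0.3, 1.0) * np.exp(-0.5 * ((WAVELENGTHS - c) / w) ** 2)
    baseline += rng.uniform(0.05, 0.2)
    baseline /= baseline.max()
    shape415 = np.exp(-0.5 * ((WAVELENGTHS - 415.0) / rng.uniform(25.0, 35.0)) ** 2)
    shape540 = np.exp(-0.5 * ((WAVELENGTHS - 540.0) / rng.uniform(25.0, 35.0)) ** 2)
    return SpectralWorld(baseline, shape415, shape540)


def make_chart(seed: int, mode: str = "random-smooth", n_patches: int = 24) -> np.ndarray:
    """Reference reflectance spectra for a 24-patch chart, 401 x 24.

    ``random-smooth`` draws, per patch, random coefficients over the
    seed's spectral world — each spectrum a nonnegative band-limited
    sum of at most six Gaussian bumps in [0, 1].  ``gray-ramp``
    produces a neutral lightness ramp (degenerate-geometry tests).
    """
    if mode == "gray-ramp":
        return np.stack(
            [np.full(N_BANDS, v) for v in np.linspace(0.04, 0.95, n_patches)], axis=1
        )
    if mode != "random-smooth":
        raise ValueError(f"unknown chart mode {mode!r}")
    world = spectral_world(seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC4A7]))
    cols = []
    for _ in range(n_patches):
        a0 = rng.uniform(0.15, 0.95)
        a1 = rng.uniform(-0.5, 0.5) * a0
        a2 = rng.uniform(-0.5, 0.5) * a0
        cols.append(np.clip(world.spectrum(a0, a1, a2), 0.01, 1.0))
    return np.stack(cols, axis=1)


def render_with_camera(
    cam: SyntheticCamera,
    spectra: np.ndarray,
    ill: Illuminant | None = None,
    cmf: ColorMatchingFunctions | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Image reflectance spectra through the synthetic camera.

    ``spectra`` has shape (..., 401); returns display RGB in [0, 1] with
    the same leading shape.  Noise requires an explicit ``rng`` so the
    caller owns the random stream.
    """
    ill = illuminant_planckian() if ill is None else ill
    cmf = cie_1931_cmfs() if cmf is None else cmf
    spectra = np.asarray(spectra, dtype=float)
    if spectra.shape[-1] != N_BANDS:
        raise ValueError(f"spectra must have {N_BANDS} samples")

    if cam.sensitivities is None:
        xyz = render_spectrum(spectra, ill, cmf)
    else:
        k = 100.0 / np.sum(ill.power * cmf.ybar)
        weights = ill.power[None, :] * cam.sensitivities
        xyz = k * spectra @ weights.T

    if cam.distortion is not None:
        v = expand_variables(xyz.reshape(-1, 3))
        xyz = (v @ cam.distortion.T).reshape(xyz.shape) * 100.0

    linear = np.clip(xyz_to_linear_rgb(xyz), 0.0, 1.0)
    linear = linear + cam.dark_offset
    if cam.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        linear = linear + rng.normal(0.0, cam.noise_sd, linear.shape)
    linear = np.clip(linear, 0.0, 1.0)
    rgb = srgb_encode(linear) if cam.transfer == "srgb" else linear
    if cam.quantize:
        rgb = np.round(rgb * 255.0) / 255.0
    return rgb


def build_chart(
    spectra: np.ndarray,
    cam: SyntheticCamera,
    ill: Illuminant | None = None,
    cmf: ColorMatchingFunctions | None = None,
    rng: np.random.Generator | None = None,
) -> ColorChart:
    """Assemble a ColorChart: camera RGB + colorimetric target XYZ."""
    ill = illuminant_planckian() if ill is None else ill
    cmf = cie_1931_cmfs() if cmf is None else cmf
    rgb = render_with_camera(cam, spectra.T, ill, cmf, rng=rng)
    xyz = render_spectrum(spectra.T, ill, cmf)
    return ColorChart(
        patch_ids=[f"patch{i:02d}" for i in range(spectra.shape[1])],
        rgb_measured=rgb,
        xyz_target=xyz,
        reflectance_ref=spectra,
    )


def _vessel_mask(rng: np.random.Generator, shape: tuple[int, int], n_vessels: int) -> np.ndarray:
    """Random smooth curves dilated to 2-6 px widths."""
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    for _ in range(n_vessels):
        # a meandering walk across the frame
        steps = max(h, w) * 2
        pos = np.array([rng.uniform(0, h - 1), rng.uniform(0, w - 1)])
        angle = rng.uniform(0, 2 * np.pi)
        curve = np.zeros(shape, dtype=bool)
        for _ in range(steps):
            angle += rng.normal(0.0, 0.25)
            pos = pos + np.array([np.sin(angle), np.cos(angle)])
            if not (0 <= pos[0] < h and 0 <= pos[1] < w):
                break
            curve[int(pos[0]), int(pos[1])] = True
        radius = int(rng.integers(1, 4))  # dilation -> 2-6 px widths
        mask |= ndimage.binary_dilation(curve, iterations=radius)
    return mask


def make_phantom(
    seed: int,
    size: tuple[int, int] = (64, 64),
    label: str = "normal",
    cam: SyntheticCamera | None = None,
    ill: Illuminant | None = None,
    cmf: ColorMatchingFunctions | None = None,
    world_seed: int | None = None,
) -> PhantomScene:
    """A tissue-like frame with vessel structures and its true cube.

    ``world_seed`` selects the spectral family; pass the chart's seed to
    keep scene and calibration chart on the same reflectance manifold
    (closed-loop setting).  Defaults to ``seed``.
    """
    if label not in PHANTOM_CLASSES:
        raise ValueError(f"unknown class label {label!r}; choose from {sorted(PHANTOM_CLASSES)}")
    h, w = size
    if h < 32 or w < 32:
        raise ValueError("phantom frames must be at least 32x32")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xFA47]))
    cam = SyntheticCamera() if cam is None else cam
    world = spectral_world(seed if world_seed is None else world_seed)

    lo, hi, tint415, tint540, n_vessels, strength = PHANTOM_CLASSES[label]

    # slowly varying brightness texture
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size), sigma=max(h, w) / 8)
    span = texture.max() - texture.min()
    if span > 0:
        texture = lo + (hi - lo) * (texture - texture.min()) / span
    else:
        texture = np.full(size, 0.5 * (lo + hi))

    mask = _vessel_mask(rng, size, n_vessels)
    strength = float(np.clip(strength * rng.uniform(0.85, 1.15), 0.0, 0.95))

    a0 = texture
    a1 = tint415 * a0 - np.where(mask, 0.45 * strength * a0, 0.0)
    a2 = tint540 * a0 - np.where(mask, 0.30 * strength * a0, 0.0)
    scene_cube = SpectralCube(world.spectrum(a0, a1, a2))

    rgb = render_with_camera(cam, scene_cube.data, ill, cmf,
                             rng=rng if cam.noise_sd > 0 else None)
    frame = np.round(np.clip(rgb, 0, 1) * 255).astype(np.uint8)
    return PhantomScene(label=label, cube=scene_cube, vessel_mask=mask,
                        frame=frame, absorber_strength=strength)


def make_dataset(
    seed: int,
    out_dir,
    counts: dict[str, tuple[int, int, int]] | None = None,
    size: tuple[int, int] = (64, 64),
    cam: SyntheticCamera | None = None,
) -> Path:
    """Write a class-balanced phantom dataset: ``<split>/<class>/*.png``.

    ``counts`` maps class -> (train, validation, test) counts; the
    default layout emits 2400 frames (1800/400/200).  All frames share
    the dataset seed's spectral world so classes differ by tint,
    texture and vasculature, not by colorimetry.  Returns the path of
    the manifest CSV (columns: path, class, split).
    """
    counts = DEFAULT_CLASS_COUNTS if counts is None else counts
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    splits = ("train", "validation", "test")
    rows = []
    root_rng = np.random.default_rng(seed)
    for label in sorted(counts):
        if any(c < 0 for c in counts[label]):
            raise ValueError(f"negative count for class {label!r}")
        class_seed = int(root_rng.integers(0, 2**31 - 1))
        idx = 0
        for split, n in zip(splits, counts[label]):
            if n == 0:
                continue
            split_dir = out_dir / split / label
            split_dir.mkdir(parents=True, exist_ok=True)
            for _ in range(n):
                scene = make_phantom(class_seed + idx, size=size, label=label,
                                     cam=cam, world_seed=seed)
                path = split_dir / f"{label}_{idx:04d}.png"
                iio.imwrite(path, scene.frame)
                rows.append((str(path.relative_to(out_dir)), label, split))
                idx += 1
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "class", "split"])
        writer.writerows(rows)
    return manifest
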