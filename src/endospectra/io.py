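"""Plain-format readers and writers.

* chart record: a patch CSV (id, R, G, B, X, Y, Z) plus a spectra CSV
  (wavelength column + 24 patch columns);
* hyperspectral cube: ENVI-style pair — a text header carrying
  samples/lines/bands/wavelengths and a flat little-endian float32
  binary, band-interleaved by pixel (BIP);
* confusion matrix: labeled CSV, rows = true class, columns = predicted.

Rasters are row-major with the origin at the top-left; the cube's band
axis is last.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import ColorChart, N_PATCHES
from .classification import ConfusionMatrix
from .colorimetry import N_BANDS, WAVELENGTHS
from .reconstruction import SpectralCube

__all__ = [
    "write_chart",
    "read_chart",
    "write_cube",
    "read_cube",
    "write_confusion",
    "read_confusion",
]


def write_chart(chart: ColorChart, patches_csv, spectra_csv) -> None:
    patches = pd.DataFrame(
        {
            "id": chart.patch_ids,
            "R": chart.rgb_measured[:, 0],
            "G": chart.rgb_measured[:, 1],
            "B": chart.rgb_measured[:, 2],
            "X": chart.xyz_target[:, 0],
            "Y": chart.xyz_target[:, 1],
            "Z": chart.xyz_target[:, 2],
        }
    )
    patches.to_csv(patches_csv, index=False)
    spectra = pd.DataFrame(chart.reflectance_ref, columns=chart.patch_ids)
    spectra.insert(0, "wavelength_nm", WAVELENGTHS)
    spectra.to_csv(spectra_csv, index=False)


def read_chart(patches_csv, spectra_csv) -> ColorChart:
    patches = pd.read_csv(patches_csv)
    required = {"id", "R", "G", "B", "X", "Y", "Z"}
    missing = required - set(patches.columns)
    if missing:
        raise ValueError(f"{patches_csv}: missing columns {sorted(missing)}")
    if len(patches) != N_PATCHES:
        raise ValueError(f"{patches_csv}: expected {N_PATCHES} patches, found {len(patches)}")
    spectra = pd.read_csv(spectra_csv)
    if "wavelength_nm" not in spectra.columns:
        raise ValueError(f"{spectra_csv}: missing wavelength_nm column")
    if len(spectra) != N_BANDS:
        raise ValueError(f"{spectra_csv}: expected {N_BANDS} rows, found {len(spectra)}")
    ids = [str(i) for i in patches["id"]]
    try:
        refl = spectra[ids].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{spectra_csv}: spectra columns do not match patch ids") from exc
    return ColorChart(
        patch_ids=ids,
        rgb_measured=patches[["R", "G", "B"]].to_numpy(dtype=float),
        xyz_target=patches[["X", "Y", "Z"]].to_numpy(dtype=float),
        reflectance_ref=refl,
    )


def write_cube(cube: SpectralCube, base_path) -> tuple[Path, Path]:
    """Write ``<base>.hdr`` (text header) and ``<base>.raw`` (BIP float32,
    little-endian)."""
    base = Path(base_path)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    lines = [
        "ENVI",
        f"samples = {cube.width}",
        f"lines = {cube.height}",
        f"bands = {N_BANDS}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 4",
        "interleave = bip",
        "byte order = 0",
        "wavelength units = nm",
        "wavelength = {" + ", ".join(f"{w:g}" for w in cube.wavelengths) + "}",
    ]
    hdr.write_text("\n".join(lines) + "\n")
    cube.data.astype("<f4").tofile(raw)
    return hdr, raw


def _parse_envi_header(hdr: Path) -> dict:
    text = hdr.read_text()
    # fold multi-line { ... } values onto one line before parsing
    folded = []
    buffer = None
    for lineno, line in enumerate(text.splitlines(), 1):
        if buffer is not None:
            buffer += " " + line.strip()
            if "}" in line:
                folded.append((lineno, buffer))
                buffer = None
            continue
        if "{" in line and "}" not in line:
            buffer = line.strip()
        else:
            folded.append((lineno, line.strip()))
    fields: dict[str, str] = {}
    for lineno, line in folded:
        if not line or line.upper() == "ENVI":
            continue
        if "=" not in line:
            raise ValueError(f"{hdr}:{lineno}: malformed header line: {line!r}")
        key, value = line.split("=", 1)
        fields[key.strip().lower()] = value.strip()
    return fields


def read_cube(base_path) -> SpectralCube:
    base = Path(base_path)
    hdr = base.with_suffix(".hdr")
    raw = base.with_suffix(".raw")
    fields = _parse_envi_header(hdr)
    try:
        samples = int(fields["samples"])
        lines = int(fields["lines"])
        bands = int(fields["bands"])
    except KeyError as exc:
        raise ValueError(f"{hdr}: missing required field {exc}") from exc
    if bands != N_BANDS:
        raise ValueError(f"{hdr}: cube has {bands} bands, expected {N_BANDS}")
    if fields.get("interleave", "bip").lower() != "bip":
        raise ValueError(f"{hdr}: only BIP interleave is supported")
    data = np.fromfile(raw, dtype="<f4")
    expected = samples * lines * bands
    if data.size != expected:
        raise ValueError(f"{raw}: has {data.size} values, header implies {expected}")
    wavelengths = WAVELENGTHS
    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array([float(v) for v in wl_text.split(",")])
    return SpectralCube(data.reshape(lines, samples, bands).astype(float),
                        wavelengths=wavelengths)


def write_confusion(cm: ConfusionMatrix, path) -> None:
    cm.to_frame().to_csv(path, index_label="true\\pred")


def read_confusion(path) -> ConfusionMatrix:
    frame = pd.read_csv(path, index_col=0)
    if frame.shape[0] != frame.shape[1]:
        raise ValueError(f"{path}: confusion matrix must be square, got {frame.shape}")
    if (frame.to_numpy() < 0).any():
        raise ValueError(f"{path}: negative cell in confusion matrix")
    return ConfusionMatrix.from_frame(frame)
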