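"""End-to-end orchestration: simulate -> calibrate -> convert -> enhance -> score.

A :class:`PipelineConfig` (YAML/JSON, schema-validated, unknown keys
rejected) drives the five stages over either synthetic fixtures or
user-supplied chart/frame files.  Every run writes stable file names
plus a machine-readable ``summary.json`` with per-stage SHA-256
checksums; the same configuration reproduces the same checksums.
All randomness flows from the single config seed through named
per-stage substreams.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from . import io as esio
from .bands import NBIBandSpec, select_bands, simulate_nbi
from .calibration import fit_correction
from .colorimetry import cie_1931_cmfs, illuminant_planckian, white_point_from
from .quality import quality_report
from .reconstruction import convert_image, fit_reconstruction, rgb_to_camera_xyz
from .synthetic import SyntheticCamera, build_chart, make_chart, make_phantom

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimulateOptions(_Strict):
    chart_mode: str = "random-smooth"
    phantom_class: str = "varicose"
    phantom_size: tuple[int, int] = (64, 64)
    camera_noise_sd: float = 0.0


class NBIOptions(_Strict):
    centers_nm: tuple[float, float] = (415.0, 540.0)
    fwhm_nm: tuple[float, float] = (30.0, 30.0)


class PipelineConfig(_Strict):
    """Validated run configuration.

    Either give ``chart_patches``/``chart_spectra`` (and optionally
    ``frame``) paths, or leave them unset to run on synthetic fixtures
    generated from ``seed``.
    """

    out_dir: Path
    seed: int = 0
    chart_patches: Path | None = None
    chart_spectra: Path | None = None
    frame: Path | None = None
    illuminant_temperature_k: float = 6500.0
    variance_threshold: float = Field(default=0.99, gt=0.0, le=1.0)
    standardize_expansion: bool = False
    ridge: float = 0.0
    n_bands: int = 8
    nbi: NBIOptions = NBIOptions()
    simulate: SimulateOptions = SimulateOptions()

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls.model_validate(payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _substream(seed: int, name: str) -> np.random.Generator:
    digest = hashlib.sha256(f"{seed}:{name}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the run summary (also written as
    ``summary.json`` in the output directory)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ill = illuminant_planckian(cfg.illuminant_temperature_k)
    cmf = cie_1931_cmfs()
    white = white_point_from(ill, cmf)
    stages: dict[str, dict] = {}
    artifacts: dict[str, Path] = {}

    def finish(stage: str, **files: Path) -> None:
        stages[stage] = {
            "status": "complete",
            "outputs": {k: str(p) for k, p in files.items()},
            "checksums": {k: _sha256(p) for k, p in files.items()},
        }
        artifacts.update(files)

    try:
        # -- stage 1: acquire inputs (load or simulate) -------------------
        if cfg.chart_patches and cfg.chart_spectra:
            chart = esio.read_chart(cfg.chart_patches, cfg.chart_spectra)
            frame = iio.imread(cfg.frame) if cfg.frame else None
            scene = None
        else:
            sim_seed = int(_substream(cfg.seed, "simulate").integers(0, 2**31 - 1))
            # chart RGB are patch means -> float precision; frames quantize anyway
            cam = SyntheticCamera(noise_sd=cfg.simulate.camera_noise_sd)
            spectra = make_chart(sim_seed, mode=cfg.simulate.chart_mode)
            chart = build_chart(spectra, cam, ill, cmf,
                                rng=_substream(cfg.seed, "chart-noise"))
            scene = make_phantom(sim_seed + 1, size=cfg.simulate.phantom_size,
                                 label=cfg.simulate.phantom_class, cam=cam,
                                 ill=ill, cmf=cmf, world_seed=sim_seed)
            frame = scene.frame
        patches_csv = out / "chart_patches.csv"
        spectra_csv = out / "chart_spectra.csv"
        esio.write_chart(chart, patches_csv, spectra_csv)
        files = {"chart_patches": patches_csv, "chart_spectra": spectra_csv}
        if frame is not None:
            frame_png = out / "frame.png"
            iio.imwrite(frame_png, np.asarray(frame, dtype=np.uint8))
            files["frame"] = frame_png
        finish("acquire", **files)

        # -- stage 2: camera calibration ---------------------------------
        measured_xyz = rgb_to_camera_xyz(chart.rgb_measured)
        calib = fit_correction(chart, measured_xyz,
                               standardize=cfg.standardize_expansion,
                               ridge=cfg.ridge, white=white)
        calib_json = out / "calibration.json"
        calib.to_json(calib_json)
        finish("calibrate", calibration=calib_json)

        # -- stage 3: spectral reconstruction ----------------------------
        model = fit_reconstruction(chart, calib, measured_xyz,
                                   variance_threshold=cfg.variance_threshold)
        model_json = out / "reconstruction.json"
        model_json.write_text(json.dumps({
            "n_components": model.n_components,
            "variance_retained": model.variance_retained,
            "mean_spectrum": model.mean_spectrum.tolist(),
            "basis": model.basis.tolist(),
            "score_map": model.score_map.tolist(),
        }, sort_keys=True))
        stage3_files = {"reconstruction": model_json}
        if frame is not None:
            cube = convert_image(model, calib, np.asarray(frame))
            hdr, raw = esio.write_cube(cube, out / "cube")
            stage3_files.update(cube_header=hdr, cube_data=raw)
        finish("convert", **stage3_files)

        # -- stage 4: narrow-band rendering + band ranking ---------------
        stage4_files = {}
        if model.n_components >= 1:
            selection = select_bands(model, cfg.n_bands)
            bands_csv = out / "bands.csv"
            with open(bands_csv, "w") as fh:
                fh.write("index,wavelength_nm,score\n")
                for i, w, s in zip(selection.indices, selection.wavelengths,
                                   selection.scores):
                    fh.write(f"{i},{w:g},{s:.8g}\n")
            stage4_files["bands"] = bands_csv
        if frame is not None:
            nbi_img = simulate_nbi(cube, NBIBandSpec(centers_nm=cfg.nbi.centers_nm,
                                                     fwhm_nm=cfg.nbi.fwhm_nm))
            nbi_png = out / "nbi.png"
            iio.imwrite(nbi_png, np.round(nbi_img * 255).astype(np.uint8))
            stage4_files["nbi"] = nbi_png
        finish("enhance", **stage4_files)

        # -- stage 5: quality metrics ------------------------------------
        metrics = {
            "calibration": calib.diagnostics,
            "variance_retained": model.variance_retained,
            "n_components": model.n_components,
        }
        if scene is not None:
            gray_est = cube.data.mean(axis=2)
            gray_ref = scene.cube.data.mean(axis=2)
            q = quality_report(gray_est, gray_ref, data_range=1.05)
            metrics["cube_vs_truth"] = q.to_dict()
            metrics["spectral_rmse_mean"] = float(
                np.sqrt(np.mean((cube.data - scene.cube.data) ** 2))
            )
        metrics_json = out / "metrics.json"
        metrics_json.write_text(json.dumps(metrics, indent=2, sort_keys=True))
        finish("score", metrics=metrics_json)
    except Exception as exc:
        stages["failed"] = {"status": "error", "error": f"{type(exc).__name__}: {exc}"}
        summary = {"seed": cfg.seed, "stages": stages}
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        logger.error("pipeline failed after %d stages: %s", len(stages) - 1, exc)
        raise

    from . import __version__

    summary = {"version": __version__, "seed": cfg.seed, "stages": stages}
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
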