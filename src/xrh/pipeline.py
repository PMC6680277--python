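"""End-to-end pipeline: simulate -> (preprocess) -> calibrate -> quantify -> render.

:class:`RunConfig` holds every stage's parameters; :func:`run_pipeline`
validates them all before any work starts, runs the stages, and writes a run
directory containing the outputs, a machine-readable JSON report (calibration
result, morphometry report, registration residuals) and a manifest with a
SHA-256 hash of every output file. Runs are deterministic under the seed.

Configs can be loaded from a TOML file (``RunConfig.from_toml``); sections
mirror the stage names.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import calibrate as cal
from . import morphometry as morph
from . import phantom as ph
from . import register as reg
from . import render
from . import volume_io as vio
from .preprocess import WindowSpec

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger("xrh")


class ConfigError(ValueError):
    """A stage parameter failed validation; the message names the field."""


@dataclass
class RunConfig:
    """Parameters for one full synthetic run.

    The sample is a foam phantom on a raw-ish 16-bit scale; the calibration
    phantom is a wax cylinder with the same material levels. Segmentation
    needs an explicit absolute threshold on the calibrated scale.
    """

    seed: int = 0
    out_dir: str = "xrh_run"
    log_level: str = "INFO"

    # simulate
    shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_um: float = 8.48
    sample_gray_air: float = 1200.0
    sample_gray_wax: float = 21000.0
    sample_gray_tissue: float = 27500.0
    noise_sigma: float = 150.0
    target_vf: float = 0.33
    feature_scale_um: float = 60.0
    phantom_gray_air: float = 800.0
    phantom_gray_wax: float = 24000.0

    # calibrate
    levels_method: str = "histogram_peaks"

    # quantify
    threshold: float | None = None
    bin_width_um: float | None = None

    # render
    window_level: float | None = None
    window_width: float | None = None

    # register (optional stage)
    do_register: bool = True
    n_landmarks: int = 12

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        flat: dict = {}
        for key, value in raw.items():
            if isinstance(value, dict):
                flat.update(value)
            else:
                flat[key] = value
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(flat) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "shape" in flat:
            flat["shape"] = tuple(flat["shape"])
        return cls(**flat)

    def validate(self) -> None:
        if self.threshold is None:
            raise ConfigError(
                "quantify.threshold is required: absolute segmentation thresholds "
                "are a protocol constraint and have no default"
            )
        if len(self.shape) != 3 or any(s < 8 for s in self.shape):
            raise ConfigError(f"simulate.shape must be a (nz,ny,nx) triple >= 8, got {self.shape}")
        if not self.voxel_size_um > 0:
            raise ConfigError(f"simulate.voxel_size_um must be > 0, got {self.voxel_size_um}")
        if not self.sample_gray_air < self.sample_gray_wax < self.sample_gray_tissue:
            raise ConfigError("simulate gray levels must satisfy air < wax < tissue")
        if not self.phantom_gray_air < self.phantom_gray_wax:
            raise ConfigError("simulate phantom gray levels must satisfy air < wax")
        if not 0.0 < self.target_vf < 1.0:
            raise ConfigError(f"simulate.target_vf must be in (0,1), got {self.target_vf}")
        if self.noise_sigma < 0:
            raise ConfigError("simulate.noise_sigma must be >= 0")
        if self.bin_width_um is not None and not self.bin_width_um > 0:
            raise ConfigError(f"quantify.bin_width_um must be > 0, got {self.bin_width_um}")
        if (self.window_level is None) != (self.window_width is None):
            raise ConfigError("render.window_level and render.window_width go together")
        if self.window_width is not None and not self.window_width > 0:
            raise ConfigError(f"render.window_width must be > 0, got {self.window_width}")
        if self.levels_method not in ("histogram_peaks", "roi_masks"):
            raise ConfigError(f"calibrate.levels_method unknown: {self.levels_method!r}")
        if self.n_landmarks < 3:
            raise ConfigError("register.n_landmarks must be >= 3")
        # reuse WindowSpec's own validation for any windowing fields
        if self.window_level is not None:
            render.RenderSettings(self.window_level, self.window_width)
        _ = WindowSpec  # preprocessing window fixed at its default in this pipeline


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Run the full synthetic workflow; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    report: dict = {"seed": config.seed, "config": {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in asdict(config).items()
        if k != "out_dir"  # keep the report path-independent and rerun-identical
    }}
    try:
        rng_seed = int(config.seed)

        log.info("simulate: foam sample %s + calibration phantom", config.shape)
        sample_spec = ph.PhantomSpec(
            shape=config.shape,
            voxel_size_um=config.voxel_size_um,
            gray_air=config.sample_gray_air,
            gray_wax=config.sample_gray_wax,
            gray_tissue=config.sample_gray_tissue,
            noise_sigma=config.noise_sigma,
            seed=rng_seed,
            calibration_state="preprocessed",
        )
        foam, truth = ph.make_foam_phantom(
            sample_spec, config.target_vf, config.feature_scale_um
        )
        # surround the foam block with air so the sample scan has both
        # reference materials, as a real FFPE scan does
        pad = max(4, min(config.shape) // 8)
        data = np.full(
            tuple(s + 2 * pad for s in config.shape),
            config.sample_gray_air,
            dtype=np.float64,
        )
        rng = np.random.default_rng(rng_seed + 1)
        if config.noise_sigma > 0:
            data += rng.normal(0.0, config.noise_sigma, size=data.shape)
        data[pad:-pad, pad:-pad, pad:-pad] = foam.data
        sample = vio.new_volume(
            data.astype(np.float32), config.voxel_size_um, "preprocessed"
        )
        voi = np.zeros(sample.data.shape, dtype=bool)
        voi[pad:-pad, pad:-pad, pad:-pad] = True

        phantom_spec = ph.PhantomSpec(
            shape=sample.data.shape,
            voxel_size_um=config.voxel_size_um,
            gray_air=config.phantom_gray_air,
            gray_wax=config.phantom_gray_wax,
            gray_tissue=config.phantom_gray_wax + 1.0,  # unused; wax-only phantom
            noise_sigma=config.noise_sigma,
            seed=rng_seed + 2,
            calibration_state="preprocessed",
        )
        phantom_vol = ph.make_calibration_phantom(phantom_spec)

        log.info("calibrate: %s material levels", config.levels_method)
        phantom_levels = cal.estimate_material_levels(phantom_vol, config.levels_method)
        sample_levels = cal.estimate_material_levels(sample, config.levels_method)
        result = cal.build_calibration(phantom_levels, sample_levels)
        calibrated = cal.apply_calibration(sample, result)
        report["calibration"] = result.to_dict()
        vio.write_volume(calibrated, out / "sample_calibrated.raw")

        log.info("quantify: threshold %.1f", config.threshold)
        binary = morph.segment_tissue(calibrated, config.threshold, voi)
        tmap = morph.local_thickness(binary)
        stats = morph.thickness_stats(tmap, config.bin_width_um)
        vf = morph.volume_fraction(binary)
        report["morphometry"] = stats.to_dict()
        report["morphometry"]["volume_fraction"] = vf
        report["ground_truth"] = {"volume_fraction": truth.true_volume_fraction}

        log.info("render: z-MIP")
        settings = None
        if config.window_level is not None:
            settings = render.RenderSettings(config.window_level, config.window_width)
        mip_img = render.mip(calibrated, "z", settings)
        mip8 = mip_img if settings is not None else (
            mip_img.astype(np.float64) / max(float(mip_img.max()), 1.0)
        )
        vio.write_image(mip8, out / "mip_z.png")

        if config.do_register:
            log.info("register: synthetic histology pair, %d landmarks", config.n_landmarks)
            nz, ny, nx = calibrated.data.shape
            plane = render.PlaneSpec(
                origin=(nz // 2, 0.0, 0.0),
                u_axis=(0.0, 0.0, 1.0),
                v_axis=(0.0, 1.0, 0.0),
                extent=(nx, ny),
            )
            hist, ct, pair_truth = ph.make_histology_pair(
                calibrated, plane, seed=rng_seed + 3, n_landmarks=config.n_landmarks
            )
            warp, warped = reg.elastic_register(
                hist, ct, pair_truth.landmarks_src, pair_truth.landmarks_dst
            )
            reg_report = reg.registration_report(warp)
            report["registration"] = {
                "mean_residual_px": reg_report["mean_residual_px"],
                "max_residual_px": reg_report["max_residual_px"],
                "mean_displacement_px": reg_report["mean_displacement_px"],
                "max_displacement_px": reg_report["max_displacement_px"],
            }
            vio.write_image(warped, out / "histology_warped.png")

        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=1))

        manifest = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name not in ("manifest.json", "run.log")
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        log.info("run complete: %s", out)
        return out
    finally:
        log.removeHandler(handler)
        handler.close()
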