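"""End-to-end orchestration: simulate -> demodulate -> calibrate -> invert ->
fit -> classify -> rank -> correlate, behind one validated configuration.

Each stage writes its outputs in standard formats (TIFF + JSON sidecar for
images, CSV for tables, JSON for reports) under the run directory, and a
manifest recording the configuration hash, per-stage seeds, completion
status, output checksums and warnings is written last. All randomness flows
from a single root seed, split deterministically per stage, so a rerun with
the same configuration reproduces the bundle byte for byte. With
``resume=True`` a stage whose outputs already exist is skipped unless an
upstream stage was re-executed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .classify import LabeledFeatureSet, crossvalidate, roc_over_k, to_binary_task
from .demodulation import (
    CalibrationConfig,
    DemodulatedStack,
    RawModulatedStack,
    ReflectanceStack,
    calibrate,
    demodulate,
)
from .light_transport import (
    ForwardModelConfig,
    OpticalPropertyMaps,
    apply_r2_mask,
    build_lut,
    invert_reflectance,
    load_lut,
    save_lut,
)
from .ranking import pearson_correlates, sffs_rank
from .spectral import load_default_basis, fit_pixelwise
from .synthetic import (
    AcquisitionConfig,
    CouplingConfig,
    default_phantom_spec,
    generate_ihc_table,
    generate_phantom_truth,
    render_raw_stack,
    render_reference_stack,
    roi_mean_parameters,
)

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "demodulate",
    "calibrate",
    "build_lut",
    "invert",
    "fit",
    "classify",
    "rank",
    "correlate",
)

_DEFAULT_CONFIG = {
    "version": "1",
    "acquisition": {
        "wavelengths": [658.0, 730.0, 850.0, 970.0],
        "n_frequencies": 30,
        "f_max": 0.33,
        "pixel_pitch": 0.27,
    },
    "model": {"n": 1.4, "lut_points": 64, "lambda0": 800.0},
    "masking": {"r2_threshold": 0.95},
    "classification": {
        "k": 9,
        "task": "subtypes",
        "seed": 0,
        "global_whiten": False,
        "outlier_fraction": 0.05,
        "roc": False,
    },
    "phantom": {"scale": 1, "noise_sigma": 0.01, "sd_scale": 1.0, "seed": 0},
    "calibration": {
        "reference_mua": [0.0048, 0.0045, 0.0042, 0.004],
        "reference_musp": [1.15, 1.1, 1.02, 0.95],
        "nominal_height": 120.0,
        "height_offset": 0.0,
    },
    "paths": {"out": "sfdikit_run"},
}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated pipeline configuration (see ``_DEFAULT_CONFIG`` for the schema)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = _merge_validate(_DEFAULT_CONFIG, self.raw, path="config")
        object.__setattr__(self, "raw", merged)

    def __getitem__(self, key):
        return self.raw[key]

    @property
    def acquisition(self) -> AcquisitionConfig:
        a = self.raw["acquisition"]
        return AcquisitionConfig(
            wavelengths=tuple(a["wavelengths"]),
            frequencies=tuple(np.linspace(0.0, a["f_max"], a["n_frequencies"])),
            pixel_pitch=a["pixel_pitch"],
        )

    @property
    def model(self) -> ForwardModelConfig:
        return ForwardModelConfig(n=self.raw["model"]["n"])

    @property
    def calibration(self) -> CalibrationConfig:
        c = self.raw["calibration"]
        return CalibrationConfig(
            np.asarray(c["reference_mua"]),
            np.asarray(c["reference_musp"]),
            c["nominal_height"],
            c["height_offset"],
        )

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True).encode()
        ).hexdigest()


def _merge_validate(defaults: dict, override: dict, path: str) -> dict:
    unknown = set(override) - set(defaults)
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {path}")
    out = {}
    for k, v in defaults.items():
        if k in override and isinstance(v, dict):
            if not isinstance(override[k], dict):
                raise ValueError(f"{path}.{k} must be a mapping")
            out[k] = _merge_validate(v, override[k], f"{path}.{k}")
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    return out


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(raw)


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    root_seed: int
    stage_seeds: dict
    stage_status: dict
    checksums: dict
    warnings: list

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "root_seed": self.root_seed,
            "stage_seeds": self.stage_seeds,
            "stage_status": self.stage_status,
            "checksums": self.checksums,
            "warnings": self.warnings,
        }


def _stage_seed(root_seed: int, stage: str) -> int:
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([root_seed, idx]).generate_state(1)[0] % 2**31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


STAGE_OUTPUTS = {
    "simulate": [
        "truth_params.tif", "labels.tif", "roi_ids.tif",
        "raw_tissue.tif", "raw_reference.tif", "ihc.csv",
    ],
    "demodulate": [
        "demod_tissue_mac.tif", "demod_tissue_mdc.tif",
        "demod_reference_mac.tif", "demod_reference_mdc.tif",
    ],
    "calibrate": ["reflectance.tif", "reflectance_valid.tif"],
    "build_lut": ["lut.npz"],
    "invert": ["mua.tif", "musp.tif", "r_squared.tif", "optics_valid.tif"],
    "fit": ["spectral_params.tif", "spectral_valid.tif", "features.csv"],
    "classify": ["report.json", "confusion.csv"],
    "rank": ["ranking.json", "ranking.csv"],
    "correlate": ["correlates.csv"],
}


def run_pipeline(
    config: PipelineConfig,
    seed: int = 0,
    out_dir=None,
    resume: bool = False,
    stop_after: str | None = None,
):
    """Execute the full analysis; returns (RunManifest, report bundle dict).

    ``stop_after`` truncates the run after the named stage (e.g. "simulate").
    On stage failure a ``FAILED`` marker naming the stage is left in the run
    directory, partial outputs are retained, and the error re-raised.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    out = Path(out_dir if out_dir is not None else config["paths"]["out"])
    out.mkdir(parents=True, exist_ok=True)
    acq = config.acquisition
    model_cfg = config.model
    cal_cfg = config.calibration
    warnings_log: list = []
    status: dict = {}
    seeds = {s: _stage_seed(seed, s) for s in STAGES}
    bundle: dict = {}
    upstream_ran = False

    def outputs_exist(stage: str) -> bool:
        paths = [out / f for f in STAGE_OUTPUTS[stage]]
        side = [
            sio.sidecar_path(p) for p in paths if p.suffix == ".tif"
        ]
        return all(p.exists() for p in [*paths, *side])

    def should_run(stage: str) -> bool:
        nonlocal upstream_ran
        if not resume or upstream_ran or not outputs_exist(stage):
            upstream_ran = True
            return True
        status[stage] = "skipped"
        return False

    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    current = None  # rolling in-memory state
    try:
        _run_stages(
            config, acq, model_cfg, cal_cfg, seeds, out, should_run, status,
            warnings_log, bundle, stop_after,
        )
    except Exception as e:
        stage = next((s for s in STAGES if s not in status), "unknown")
        status[stage] = "failed"
        failed_marker.write_text(json.dumps({"stage": stage, "error": str(e)}))
        raise

    manifest = RunManifest(
        config_hash=config.content_hash(),
        root_seed=seed,
        stage_seeds=seeds,
        stage_status=status,
        checksums={
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
        warnings=warnings_log,
    )
    (out / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=2, sort_keys=True)
    )
    return manifest, bundle


def _run_stages(config, acq, model_cfg, cal_cfg, seeds, out, should_run, status,
                warnings_log, bundle, stop_after=None):
    ph = config["phantom"]
    basis = load_default_basis()
    wl = list(acq.wavelengths)
    img_meta = {"axes": ["y", "x"]}

    # ---- simulate ----------------------------------------------------------
    if should_run("simulate"):
        spec = default_phantom_spec(
            seed=seeds["simulate"], scale=ph["scale"], sd_scale=ph["sd_scale"]
        )
        spec = dataclasses.replace(spec, noise_sigma=ph["noise_sigma"])
        truth = generate_phantom_truth(spec, wl, basis)
        rng = np.random.default_rng(seeds["simulate"] + 1)
        tissue_raw = render_raw_stack(truth, acq, spec, model_cfg=model_cfg, rng=rng)
        ref_raw = render_reference_stack(
            acq, cal_cfg.reference_mua, cal_cfg.reference_musp, truth.labels.shape,
            noise_sigma=ph["noise_sigma"], model_cfg=model_cfg, rng=rng,
        )
        ihc = generate_ihc_table(truth, CouplingConfig(), seed=seeds["simulate"] + 2)

        stack_meta = {
            "axes": ["wavelength", "frequency", "phase", "y", "x"],
            "wavelengths_nm": wl,
            "frequencies_mm": list(acq.frequencies),
            "phases_rad": list(acq.phases),
            "pixel_pitch_mm": acq.pixel_pitch,
        }
        sio.write_stack(out / "truth_params.tif", truth.params,
                        {"axes": ["parameter", "y", "x"],
                         "parameter_names": ["A", "b", "HbT", "O2_frac", "water_frac"],
                         "class_names": list(truth.class_names)})
        sio.write_stack(out / "labels.tif", truth.labels, img_meta | {"class_names": list(truth.class_names)})
        sio.write_stack(out / "roi_ids.tif", truth.roi_ids, img_meta)
        sio.write_stack(out / "raw_tissue.tif", tissue_raw.intensity, stack_meta)
        sio.write_stack(out / "raw_reference.tif", ref_raw.intensity, stack_meta)
        sio.write_table(out / "ihc.csv", ihc)
        status["simulate"] = "completed"

    if stop_after == "simulate":
        return bundle

    labels, labels_meta = sio.read_stack(out / "labels.tif")
    roi_ids, _ = sio.read_stack(out / "roi_ids.tif")
    truth_params, _ = sio.read_stack(out / "truth_params.tif")
    class_names = tuple(labels_meta["class_names"])
    ihc = sio.read_table(out / "ihc.csv", required_columns=["roi_id", "percent_stroma"])

    # ---- demodulate --------------------------------------------------------
    dem_meta = {
        "axes": ["wavelength", "frequency", "y", "x"],
        "wavelengths_nm": wl,
        "frequencies_mm": list(acq.frequencies),
    }
    if should_run("demodulate"):
        raw_t, meta_t = sio.read_stack(out / "raw_tissue.tif")
        raw_r, _ = sio.read_stack(out / "raw_reference.tif")
        freqs = np.asarray(meta_t["frequencies_mm"])
        phases = np.asarray(meta_t["phases_rad"])
        dem_t = demodulate(RawModulatedStack(raw_t, np.asarray(wl), freqs, phases, acq.pixel_pitch))
        dem_r = demodulate(RawModulatedStack(raw_r, np.asarray(wl), freqs, phases, acq.pixel_pitch))
        sio.write_stack(out / "demod_tissue_mac.tif", dem_t.m_ac, dem_meta)
        sio.write_stack(out / "demod_tissue_mdc.tif", dem_t.m_dc, dem_meta)
        sio.write_stack(out / "demod_reference_mac.tif", dem_r.m_ac, dem_meta)
        sio.write_stack(out / "demod_reference_mdc.tif", dem_r.m_dc, dem_meta)
        status["demodulate"] = "completed"

    # ---- calibrate ---------------------------------------------------------
    if should_run("calibrate"):
        mac_t, _ = sio.read_stack(out / "demod_tissue_mac.tif")
        mdc_t, _ = sio.read_stack(out / "demod_tissue_mdc.tif")
        mac_r, _ = sio.read_stack(out / "demod_reference_mac.tif")
        mdc_r, _ = sio.read_stack(out / "demod_reference_mdc.tif")
        freqs = np.asarray(acq.frequencies)
        dem_t = DemodulatedStack(mac_t, mdc_t, np.asarray(wl), freqs)
        dem_r = DemodulatedStack(mac_r, mdc_r, np.asarray(wl), freqs)
        refl = calibrate(dem_t, dem_r, cal_cfg, model_cfg)
        sio.write_stack(out / "reflectance.tif", refl.rd, dem_meta)
        sio.write_stack(out / "reflectance_valid.tif", refl.valid.astype(np.uint8), img_meta)
        status["calibrate"] = "completed"

    # ---- build_lut ---------------------------------------------------------
    if should_run("build_lut"):
        npts = config["model"]["lut_points"]
        lut = build_lut(
            np.geomspace(1e-3, 0.5, npts), np.geomspace(0.1, 5.0, npts),
            np.asarray(acq.frequencies), model_cfg,
        )
        save_lut(out / "lut.npz", lut)
        status["build_lut"] = "completed"
    lut = load_lut(out / "lut.npz")

    # ---- invert ------------------------------------------------------------
    if should_run("invert"):
        rd, _ = sio.read_stack(out / "reflectance.tif")
        valid, _ = sio.read_stack(out / "reflectance_valid.tif")
        refl = ReflectanceStack(rd, np.asarray(wl), np.asarray(acq.frequencies), valid.astype(bool))
        maps = invert_reflectance(refl, lut)
        maps = apply_r2_mask(maps, config["masking"]["r2_threshold"])
        masked_fraction = float(1.0 - maps.valid_mask.mean())
        warnings_log.append(
            {"stage": "invert", "masked_pixel_fraction": round(masked_fraction, 6)}
        )
        sio.write_stack(out / "mua.tif", maps.mua, dem_meta | {"axes": ["wavelength", "y", "x"]})
        sio.write_stack(out / "musp.tif", maps.musp, dem_meta | {"axes": ["wavelength", "y", "x"]})
        sio.write_stack(out / "r_squared.tif", maps.r_squared, dem_meta | {"axes": ["wavelength", "y", "x"]})
        sio.write_stack(out / "optics_valid.tif", maps.valid_mask.astype(np.uint8), img_meta)
        status["invert"] = "completed"

    # ---- fit ---------------------------------------------------------------
    if should_run("fit"):
        mua, _ = sio.read_stack(out / "mua.tif")
        musp, _ = sio.read_stack(out / "musp.tif")
        r2, _ = sio.read_stack(out / "r_squared.tif")
        valid, _ = sio.read_stack(out / "optics_valid.tif")
        maps = OpticalPropertyMaps(mua, musp, r2, valid.astype(bool), np.asarray(wl))
        spectral = fit_pixelwise(maps, basis, config["model"]["lambda0"])
        sio.write_stack(
            out / "spectral_params.tif", spectral.stack(),
            {"axes": ["parameter", "y", "x"],
             "parameter_names": ["A", "b", "HbT", "O2_percent", "water_percent"],
             "lambda0_nm": config["model"]["lambda0"]},
        )
        sio.write_stack(out / "spectral_valid.tif", spectral.valid_mask.astype(np.uint8), img_meta)
        features = spectral.feature_table(labels, class_names)
        features["roi_id"] = roi_ids[spectral.valid_mask & (labels >= 0)]
        sio.write_table(out / "features.csv", features)
        status["fit"] = "completed"

    features = sio.read_table(
        out / "features.csv",
        required_columns=["A", "b", "HbT", "O2_percent", "water_percent", "label"],
    )

    # ---- classify ----------------------------------------------------------
    cls_cfg = config["classification"]
    if should_run("classify"):
        data = LabeledFeatureSet.from_frame(features)
        if cls_cfg["task"] == "benign-malignant":
            data = to_binary_task(data)
        elif cls_cfg["task"] != "subtypes":
            raise ValueError(f"unknown classification task {cls_cfg['task']!r}")
        report = crossvalidate(
            data, k=cls_cfg["k"], seed=seeds["classify"] + cls_cfg["seed"],
            outlier_fraction=cls_cfg["outlier_fraction"],
            global_whiten=cls_cfg["global_whiten"],
        )
        payload = report.to_dict()
        if cls_cfg["roc"]:
            roc = roc_over_k(data if cls_cfg["task"] == "benign-malignant" else to_binary_task(data),
                             seed=seeds["classify"] + cls_cfg["seed"])
            payload["roc"] = roc.to_dict(orient="records")
            payload["optimal_k"] = roc.attrs["optimal_k"]
        (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True))
        conf = pd.DataFrame(report.confusion, index=report.class_names, columns=report.class_names)
        conf.index.name = "true"
        conf.to_csv(out / "confusion.csv")
        status["classify"] = "completed"
    bundle["report"] = json.loads((out / "report.json").read_text())

    # ---- rank --------------------------------------------------------------
    region_means = (
        features.groupby("roi_id")
        .agg({"A": "mean", "b": "mean", "HbT": "mean", "O2_percent": "mean",
              "water_percent": "mean", "label": "first"})
        .reset_index()
    )
    if should_run("rank"):
        rank_data = LabeledFeatureSet(
            region_means[["A", "b", "HbT", "O2_percent", "water_percent"]].to_numpy(),
            region_means["label"].to_numpy(),
        )
        ranking = sffs_rank(rank_data)
        (out / "ranking.json").write_text(json.dumps(
            {"order": list(ranking.order), "j_trace": list(ranking.j_trace),
             "history": [list(h) for h in ranking.history]},
            indent=2, sort_keys=True))
        sio.write_table(out / "ranking.csv", pd.DataFrame(
            {"rank": np.arange(1, len(ranking.order) + 1), "feature": ranking.order,
             "J": ranking.j_trace}))
        status["rank"] = "completed"
    bundle["ranking"] = json.loads((out / "ranking.json").read_text())

    # ---- correlate ---------------------------------------------------------
    if should_run("correlate"):
        corr = pearson_correlates(region_means, ihc)
        sio.write_table(out / "correlates.csv", corr)
        status["correlate"] = "completed"
    bundle["correlates"] = sio.read_table(out / "correlates.csv")
    bundle["truth_params"] = truth_params
    return bundle
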