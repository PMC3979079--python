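"""Synthetic phantom generator for the full structured-illumination pipeline.

Real breast-specimen acquisitions are not publicly available, so every
downstream stage is exercised on digital phantoms: images whose pixels carry
known spectral tissue parameters (A, b, HbT, %O2, %H2O) drawn from
class-conditional Gaussians, laid out as pathology regions of interest (ROIs)
over a homogeneous background. From the parameter maps the generator derives
per-wavelength absorption and reduced scattering through the same chromophore
and power-law forward maps the fitting stage inverts, renders raw three-phase
modulated image stacks (tissue plus a co-imaged reflectance standard) through
the diffusion forward model with an optional smooth gain field and
multiplicative Gaussian noise, and produces ROI-level immunohistochemistry
(IHC) tables whose values are linearly coupled to the ROI-mean spectral
parameters.

The default class preset is ordered to follow the qualitative trends reported
for breast pathologies (normal tissue with the highest scattering amplitude
and slope; fibroadenoma with lower amplitude; invasive cancer with elevated
hemoglobin and reduced oxygenation; DCIS with reduced oxygenation and more
water; treated invasive cancer with a steeper slope than untreated). The
magnitudes are generator conventions chosen to be physiologically plausible
for NIR breast imaging, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .demodulation import RawModulatedStack
from .light_transport import ForwardModelConfig, forward_rd
from .spectral import (
    LAMBDA0_NM,
    PARAMETER_NAMES,
    ChromophoreBasis,
    forward_mua,
    forward_musp,
    load_default_basis,
)

__all__ = [
    "PATHOLOGY_CLASSES",
    "BENIGN_CLASSES",
    "MALIGNANT_CLASSES",
    "RoiShape",
    "PhantomSpec",
    "TruthMaps",
    "AcquisitionConfig",
    "CouplingConfig",
    "default_phantom_spec",
    "generate_phantom_truth",
    "render_raw_stack",
    "render_reference_stack",
    "generate_ihc_table",
    "smooth_gain_field",
]

PATHOLOGY_CLASSES = ("NOR", "FA", "DCIS", "INV", "INV_RX")
BENIGN_CLASSES = frozenset({"NOR", "FA"})
MALIGNANT_CLASSES = frozenset({"DCIS", "INV", "INV_RX"})

# class -> (A mm^-1, b, HbT uM, O2 fraction, water fraction)
DEFAULT_CLASS_MEANS = {
    "NOR": (1.30, 1.00, 14.0, 0.72, 0.28),
    "FA": (0.85, 0.85, 16.0, 0.70, 0.35),
    "DCIS": (1.00, 0.75, 18.0, 0.55, 0.50),
    "INV": (0.95, 0.60, 28.0, 0.58, 0.40),
    "INV_RX": (1.05, 0.80, 20.0, 0.66, 0.38),
}
DEFAULT_CLASS_SDS = {c: (0.08, 0.06, 2.0, 0.04, 0.04) for c in PATHOLOGY_CLASSES}
DEFAULT_BACKGROUND = (1.00, 0.90, 12.0, 0.70, 0.25)


@dataclass(frozen=True)
class RoiShape:
    """A labelled region: axis-aligned rectangle or ellipse in pixel coordinates."""

    class_name: str
    kind: str  # "rect" | "ellipse"
    y0: int
    x0: int
    height: int
    width: int

    def mask(self, image_height: int, image_width: int) -> np.ndarray:
        if self.kind not in ("rect", "ellipse"):
            raise ValueError(f"unknown ROI kind {self.kind!r}")
        if (
            self.y0 < 0
            or self.x0 < 0
            or self.y0 + self.height > image_height
            or self.x0 + self.width > image_width
            or self.height <= 0
            or self.width <= 0
        ):
            raise ValueError(f"ROI {self} exceeds image bounds")
        m = np.zeros((image_height, image_width), dtype=bool)
        if self.kind == "rect":
            m[self.y0 : self.y0 + self.height, self.x0 : self.x0 + self.width] = True
        else:
            yy, xx = np.mgrid[0:image_height, 0:image_width]
            cy = self.y0 + (self.height - 1) / 2.0
            cx = self.x0 + (self.width - 1) / 2.0
            m = ((yy - cy) / (self.height / 2.0)) ** 2 + (
                (xx - cx) / (self.width / 2.0)
            ) ** 2 <= 1.0
        return m


@dataclass(frozen=True)
class PhantomSpec:
    """Complete recipe for one digital phantom; identical spec+seed is bit-reproducible."""

    image_height: int = 72
    image_width: int = 96
    classes: tuple = PATHOLOGY_CLASSES
    class_param_means: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MEANS))
    class_param_sds: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_SDS))
    roi_layout: tuple = ()
    background_params: tuple = DEFAULT_BACKGROUND
    noise_sigma: float = 0.01  # relative Gaussian intensity noise
    seed: int = 0

    def validate(self) -> None:
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        for c in self.classes:
            if c not in self.class_param_means or c not in self.class_param_sds:
                raise ValueError(f"missing parameter preset for class {c!r}")
            m = np.asarray(self.class_param_means[c], float)
            s = np.asarray(self.class_param_sds[c], float)
            if m.shape != (5,) or s.shape != (5,):
                raise ValueError(f"class {c!r}: parameter vectors must have 5 entries")
            if np.any(s < 0):
                raise ValueError(f"class {c!r}: SDs must be non-negative")
            if not (0.0 <= m[3] <= 1.0 and 0.0 <= m[4] <= 1.0):
                raise ValueError(f"class {c!r}: fraction means must lie in [0, 1]")
        occupied = np.zeros((self.image_height, self.image_width), dtype=bool)
        for roi in self.roi_layout:
            if roi.class_name not in self.classes:
                raise ValueError(f"unknown class name {roi.class_name!r} in ROI layout")
            m = roi.mask(self.image_height, self.image_width)
            if np.any(occupied & m):
                raise ValueError(f"overlapping ROIs at {roi}")
            occupied |= m


def default_phantom_spec(seed: int = 0, scale: int = 1, sd_scale: float = 1.0) -> PhantomSpec:
    """Six ROIs per pathology class (30 total) in a 72 x 96 image (scalable).

    ROIs tile a 5 x 6 grid so every class contributes enough regions for
    region-level covariances and the IHC correlates; ``sd_scale`` multiplies
    all class SDs, controlling class overlap.
    """
    s = scale
    rois = tuple(
        RoiShape(
            PATHOLOGY_CLASSES[i % 5],
            "rect" if i % 2 == 0 else "ellipse",
            (2 + 14 * (i // 6)) * s,
            (3 + 15 * (i % 6)) * s,
            10 * s,
            10 * s,
        )
        for i in range(30)
    )
    sds = {c: tuple(sd_scale * v for v in DEFAULT_CLASS_SDS[c]) for c in PATHOLOGY_CLASSES}
    return PhantomSpec(
        image_height=72 * s, image_width=96 * s, roi_layout=rois, seed=seed,
        class_param_sds=sds,
    )


@dataclass
class TruthMaps:
    """Ground truth: parameter maps, labels, ROI ids, and derived optical properties."""

    params: np.ndarray  # (5, H, W) ordered as PARAMETER_NAMES
    labels: np.ndarray  # (H, W) int, index into class_names, -1 = background
    roi_ids: np.ndarray  # (H, W) int, -1 = background
    class_names: tuple
    wavelengths: np.ndarray
    mua: np.ndarray  # (n_wl, H, W)
    musp: np.ndarray  # (n_wl, H, W)
    lambda0: float = LAMBDA0_NM


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry: wavelengths, frequency set, phase offsets, pixel pitch."""

    wavelengths: tuple = (658.0, 730.0, 850.0, 970.0)
    frequencies: tuple = tuple(np.linspace(0.0, 0.33, 30))
    phases: tuple = (0.0, 2.0 * np.pi / 3.0, 4.0 * np.pi / 3.0)
    pixel_pitch: float = 0.27  # mm

    def __post_init__(self) -> None:
        if len(self.phases) != 3:
            raise ValueError("three phase offsets are required")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")


def _derive_optical_maps(params: np.ndarray, wavelengths, basis: ChromophoreBasis, lambda0: float):
    a, b, hbt, o2, water = params
    c_hbo2 = hbt * o2
    c_hb = hbt * (1.0 - o2)
    shape = a.shape
    mua = forward_mua(c_hbo2.ravel(), c_hb.ravel(), water.ravel(), basis)
    musp = forward_musp(a.ravel(), b.ravel(), wavelengths, lambda0)
    n_wl = len(np.atleast_1d(wavelengths))
    return (
        mua.T.reshape((n_wl, *shape)),
        musp.T.reshape((n_wl, *shape)),
    )


def generate_phantom_truth(
    spec: PhantomSpec,
    wavelengths=AcquisitionConfig().wavelengths,
    basis: ChromophoreBasis | None = None,
) -> TruthMaps:
    """Sample per-pixel spectral parameters and derive per-wavelength optics.

    Each ROI's pixels are drawn i.i.d. from its class Gaussian; the two
    fraction parameters (O2, water) are clipped to [0, 1]; A, b and HbT are
    clipped to a small positive floor so derived optical properties stay
    strictly positive. The background carries the fixed background parameter
    vector. Note that here O2 and water are stored as fractions; the fitted
    maps downstream report them in percent.
    """
    spec.validate()
    basis = basis or load_default_basis()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_height, spec.image_width
    params = np.empty((5, h, w))
    params[:] = np.asarray(spec.background_params, float)[:, None, None]
    labels = np.full((h, w), -1, dtype=np.int32)
    roi_ids = np.full((h, w), -1, dtype=np.int32)

    for rid, roi in enumerate(spec.roi_layout):
        m = roi.mask(h, w)
        npix = int(m.sum())
        mean = np.asarray(spec.class_param_means[roi.class_name], float)
        sd = np.asarray(spec.class_param_sds[roi.class_name], float)
        draw = mean[:, None] + sd[:, None] * rng.standard_normal((5, npix))
        draw[0] = np.maximum(draw[0], 1e-3)  # A
        draw[1] = np.maximum(draw[1], 0.0)  # b
        draw[2] = np.maximum(draw[2], 0.0)  # HbT
        draw[3] = np.clip(draw[3], 0.0, 1.0)  # O2 fraction
        draw[4] = np.clip(draw[4], 1e-4, 1.0)  # water fraction
        params[:, m] = draw
        labels[m] = spec.classes.index(roi.class_name)
        roi_ids[m] = rid

    wl = np.asarray(wavelengths, float)
    mua, musp = _derive_optical_maps(params, wl, basis, LAMBDA0_NM)
    return TruthMaps(params, labels, roi_ids, tuple(spec.classes), wl, mua, musp)


def smooth_gain_field(shape, rng, amplitude: float = 0.2, n_modes: int = 3) -> np.ndarray:
    """A positive, smooth multiplicative gain (vignette-like), mean ~1."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    g = np.zeros((h, w))
    for _ in range(n_modes):
        fy, fx = rng.uniform(0.2, 1.5, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        g += np.cos(2 * np.pi * fy * yy / h + py) * np.cos(2 * np.pi * fx * xx / w + px)
    g = 1.0 + amplitude * g / n_modes
    return np.maximum(g, 0.05)


def _render(mua, musp, acq: AcquisitionConfig, gain, noise_sigma, rng, model_cfg):
    """Render the raw 5-axis stack for given per-wavelength (mua, musp) maps.

    For f > 0 the projected pattern is (1/2)(1 + cos(2 pi f x + phi_k));
    at f = 0 the instrument projects a uniform field, so the three frames are
    identical planar images.
    """
    n_wl, h, w = mua.shape
    freqs = np.asarray(acq.frequencies, float)
    phases = np.asarray(acq.phases, float)
    x_mm = np.arange(w) * acq.pixel_pitch
    out = np.empty((n_wl, len(freqs), 3, h, w))
    for i_f, f in enumerate(freqs):
        rd = forward_rd(mua, musp, f, model_cfg)  # (n_wl, h, w)
        base = gain[None] * rd
        for k, phi in enumerate(phases):
            if f == 0.0:
                pattern = np.ones(w)
            else:
                pattern = 0.5 * (1.0 + np.cos(2.0 * np.pi * f * x_mm + phi))
            out[:, i_f, k] = base * pattern[None, None, :]
    if noise_sigma > 0:
        out *= 1.0 + noise_sigma * rng.standard_normal(out.shape)
    np.maximum(out, 0.0, out=out)
    return out


def render_raw_stack(
    truth: TruthMaps,
    acq: AcquisitionConfig,
    spec: PhantomSpec,
    gain: np.ndarray | None = None,
    model_cfg: ForwardModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RawModulatedStack:
    """Render the tissue's raw modulated image stack (wavelength, freq, phase, y, x)."""
    if truth.mua is None or truth.musp is None:
        raise ValueError("truth maps must carry derived optical properties")
    model_cfg = model_cfg or ForwardModelConfig()
    rng = rng or np.random.default_rng(spec.seed + 1)
    h, w = truth.labels.shape
    gain = np.ones((h, w)) if gain is None else gain
    data = _render(truth.mua, truth.musp, acq, gain, spec.noise_sigma, rng, model_cfg)
    return RawModulatedStack(
        data, np.asarray(acq.wavelengths), np.asarray(acq.frequencies),
        np.asarray(acq.phases), acq.pixel_pitch,
    )


def render_reference_stack(
    acq: AcquisitionConfig,
    reference_mua,
    reference_musp,
    image_shape,
    noise_sigma: float = 0.0,
    gain: np.ndarray | None = None,
    model_cfg: ForwardModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> RawModulatedStack:
    """Render the co-imaged reflectance standard from its known homogeneous properties."""
    model_cfg = model_cfg or ForwardModelConfig()
    rng = rng or np.random.default_rng(0)
    h, w = image_shape
    n_wl = len(acq.wavelengths)
    mua = np.broadcast_to(
        np.atleast_1d(np.asarray(reference_mua, float))[:, None, None], (n_wl, h, w)
    ).copy()
    musp = np.broadcast_to(
        np.atleast_1d(np.asarray(reference_musp, float))[:, None, None], (n_wl, h, w)
    ).copy()
    gain = np.ones((h, w)) if gain is None else gain
    data = _render(mua, musp, acq, gain, noise_sigma, rng, model_cfg)
    return RawModulatedStack(
        data, np.asarray(acq.wavelengths), np.asarray(acq.frequencies),
        np.asarray(acq.phases), acq.pixel_pitch,
    )


@dataclass(frozen=True)
class CouplingConfig:
    """Linear couplings from ROI-mean spectral parameters to IHC measures.

    Signs follow the reported correlation structure: scattering slope
    correlates positively with stromal fraction and negatively with
    epithelial fraction and vascular measures; hemoglobin with vascular
    density. ``noise_sd`` is the SD of additive Gaussian noise on the raw
    (pre-normalization) values.
    """

    stroma_per_b: float = 40.0  # % stroma per unit slope b
    epithelium_per_b: float = -35.0
    mvd_per_hbt: float = 0.12  # % area per uM HbT
    mvd_per_b: float = -1.5
    mva_per_b: float = -120.0  # um^2 per unit b
    noise_sd: float = 6.0

    def scaled(self, factor: float) -> "CouplingConfig":
        return CouplingConfig(
            self.stroma_per_b * factor,
            self.epithelium_per_b * factor,
            self.mvd_per_hbt * factor,
            self.mvd_per_b * factor,
            self.mva_per_b * factor,
            self.noise_sd,
        )


IHC_COLUMNS = (
    "percent_epithelium",
    "percent_stroma",
    "percent_fat",
    "mvd_cd31",
    "mvd_cd105",
    "mva_cd31",
    "mva_cd105",
)


def roi_mean_parameters(truth: TruthMaps) -> pd.DataFrame:
    """One row per ROI: mean spectral parameters and the class label."""
    rows = []
    for rid in np.unique(truth.roi_ids):
        if rid < 0:
            continue
        m = truth.roi_ids == rid
        mean = truth.params[:, m].mean(axis=1)
        rows.append(
            {
                "roi_id": int(rid),
                "label": truth.class_names[int(truth.labels[m][0])],
                **dict(zip(PARAMETER_NAMES, mean)),
            }
        )
    return pd.DataFrame(rows)


def generate_ihc_table(
    truth: TruthMaps, coupling: CouplingConfig | None = None, seed: int = 0
) -> pd.DataFrame:
    """ROI-level immunohistochemistry table coupled to ROI-mean spectral parameters.

    Tissue-composition percentages (epithelium, stroma, fat) are clipped to
    be non-negative and renormalized to sum to exactly 100 per ROI; vascular
    measures are floored at 0.
    """
    coupling = coupling or CouplingConfig()
    means = roi_mean_parameters(truth)
    if len(means) < 3:
        raise ValueError("need at least 3 ROIs for meaningful correlates")
    rng = np.random.default_rng(seed)
    b = means["b"].to_numpy()
    hbt = means["HbT"].to_numpy()
    b0 = b.mean()
    hbt0 = hbt.mean()
    n = len(means)

    stroma = 45.0 + coupling.stroma_per_b * (b - b0) + coupling.noise_sd * rng.standard_normal(n)
    epith = 30.0 + coupling.epithelium_per_b * (b - b0) + coupling.noise_sd * rng.standard_normal(n)
    fat = 25.0 + coupling.noise_sd * rng.standard_normal(n)
    comp = np.clip(np.column_stack([epith, stroma, fat]), 0.0, None)
    comp = 100.0 * comp / comp.sum(axis=1, keepdims=True)

    mvd31 = np.maximum(
        0.0,
        2.5 + coupling.mvd_per_hbt * (hbt - hbt0) + coupling.mvd_per_b * (b - b0)
        + 0.05 * coupling.noise_sd * rng.standard_normal(n),
    )
    mvd105 = np.maximum(
        0.0,
        1.2 + 0.8 * coupling.mvd_per_hbt * (hbt - hbt0) + 0.8 * coupling.mvd_per_b * (b - b0)
        + 0.04 * coupling.noise_sd * rng.standard_normal(n),
    )
    mva31 = np.maximum(
        0.0, 260.0 + coupling.mva_per_b * (b - b0) + 4.0 * coupling.noise_sd * rng.standard_normal(n)
    )
    mva105 = np.maximum(
        0.0, 150.0 + 0.8 * coupling.mva_per_b * (b - b0) + 3.0 * coupling.noise_sd * rng.standard_normal(n)
    )

    return pd.DataFrame(
        {
            "roi_id": means["roi_id"],
            "label": means["label"],
            "percent_epithelium": comp[:, 0],
            "percent_stroma": comp[:, 1],
            "percent_fat": comp[:, 2],
            "mvd_cd31": mvd31,
            "mvd_cd105": mvd105,
            "mva_cd31": mva31,
            "mva_cd105": mva105,
        }
    )
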