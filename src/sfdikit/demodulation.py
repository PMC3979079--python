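"""Three-phase demodulation and reference-standard calibration.

A structured-illumination acquisition projects, for every wavelength and
spatial frequency, three sinusoidal patterns offset by 120 degrees. For a
pixel whose three intensities are ``I_k = DC + AC * cos(theta + phi_k)`` the
amplitude ``AC`` and offset ``DC`` are recovered exactly, pixel by pixel,
with no spatial filtering:

    m_ac = (sqrt(2)/3) * sqrt((I1-I2)^2 + (I2-I3)^2 + (I3-I1)^2)
    m_dc = (I1 + I2 + I3) / 3

Demodulation removes ambient light (a common additive offset) and, because
it is a per-pixel identity, is insensitive to the spatial structure of the
scene.

Calibration converts the demodulated tissue amplitude into absolute diffuse
reflectance by ratioing against a co-imaged reflectance standard of known
optical properties: any smooth system gain field (illumination
non-uniformity, collection vignette, source power) multiplies both stacks
and cancels exactly in the ratio. A small, systematic height offset between
tissue and standard scales the amplitude by an inverse-square factor
``(h - dh)^2 / h^2``; at the ~120 mm working distances of these systems a
1 mm offset gives 119^2/120^2, i.e. a negligible correction, so the default
``height_scale`` is 1 while the correction remains available.

At spatial frequency zero the projected pattern is uniform, so the planar
amplitude lives in ``m_dc``; :func:`modulation_amplitude` returns the
appropriate channel per frequency and :func:`calibrate` uses it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawModulatedStack",
    "DemodulatedStack",
    "ReflectanceStack",
    "CalibrationConfig",
    "demodulate",
    "modulation_amplitude",
    "calibrate",
]


@dataclass
class RawModulatedStack:
    """Raw intensity images indexed (wavelength, frequency, phase, y, x)."""

    intensity: np.ndarray
    wavelengths: np.ndarray  # nm
    frequencies: np.ndarray  # mm^-1
    phases: np.ndarray  # rad
    pixel_pitch: float  # mm

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.intensity.ndim != 5:
            raise ValueError("intensity must be 5-axis (wavelength, frequency, phase, y, x)")
        nw, nf, np_, _, _ = self.intensity.shape
        if np_ != 3 or len(self.phases) != 3:
            raise ValueError("exactly 3 phase offsets are required")
        if nw != len(self.wavelengths) or nf != len(self.frequencies):
            raise ValueError("axis lengths do not match metadata lists")
        if not np.all(np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError("intensities must be finite and non-negative")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")


@dataclass
class DemodulatedStack:
    """AC modulation amplitude and DC term, (wavelength, frequency, y, x)."""

    m_ac: np.ndarray
    m_dc: np.ndarray
    wavelengths: np.ndarray
    frequencies: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        if self.m_ac.shape != self.m_dc.shape:
            raise ValueError("m_ac and m_dc must share a shape")
        if np.any(self.m_ac < 0) or np.any(self.m_dc < 0):
            raise ValueError("demodulated amplitudes must be non-negative")


@dataclass
class ReflectanceStack:
    """Calibrated, dimensionless diffuse reflectance (wavelength, frequency, y, x)."""

    rd: np.ndarray
    wavelengths: np.ndarray
    frequencies: np.ndarray
    valid: np.ndarray = field(default=None)  # (y, x) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(self.rd.shape[2:], dtype=bool)


@dataclass(frozen=True)
class CalibrationConfig:
    """Known properties of the reflectance standard and the height geometry.

    ``reference_mua`` / ``reference_musp`` are per-wavelength optical
    properties (mm^-1) of the siloxane/TiO2-style standard; ``nominal_height``
    is the lens-to-sample working distance and ``height_offset`` any
    systematic tissue-vs-standard height difference (both mm).
    """

    reference_mua: np.ndarray
    reference_musp: np.ndarray
    nominal_height: float = 120.0
    height_offset: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "reference_mua", np.atleast_1d(np.asarray(self.reference_mua, float)))
        object.__setattr__(self, "reference_musp", np.atleast_1d(np.asarray(self.reference_musp, float)))
        if np.any(self.reference_mua <= 0) or np.any(self.reference_musp <= 0):
            raise ValueError("reference optical properties must be positive")
        if not self.nominal_height > 0:
            raise ValueError("nominal_height must be positive")
        if abs(self.height_offset) >= self.nominal_height:
            raise ValueError("|height_offset| must be smaller than nominal_height")

    @property
    def height_scale(self) -> float:
        """Inverse-square amplitude correction (h - dh)^2 / h^2."""
        return (self.nominal_height - self.height_offset) ** 2 / self.nominal_height**2


def demodulate(stack: RawModulatedStack) -> DemodulatedStack:
    """Extract the AC envelope and DC term from three-phase image triplets."""
    i1, i2, i3 = (stack.intensity[:, :, k] for k in range(3))
    if np.isnan(stack.intensity).any():
        raise ValueError("NaN pixels in raw stack")
    m_ac = (np.sqrt(2.0) / 3.0) * np.sqrt(
        (i1 - i2) ** 2 + (i2 - i3) ** 2 + (i3 - i1) ** 2
    )
    m_dc = (i1 + i2 + i3) / 3.0
    return DemodulatedStack(
        m_ac, m_dc, stack.wavelengths, stack.frequencies, stack.pixel_pitch
    )


def modulation_amplitude(dem: DemodulatedStack) -> np.ndarray:
    """Frequency-resolved modulation amplitude used for calibration.

    The three-phase identity yields the sinusoidal envelope at every nonzero
    frequency; at f = 0 the projected pattern is uniform and the planar
    amplitude is the DC term.
    """
    amp = dem.m_ac.copy()
    zero = np.asarray(dem.frequencies) == 0.0
    amp[:, zero] = dem.m_dc[:, zero]
    return amp


def calibrate(
    tissue: DemodulatedStack,
    reference: DemodulatedStack,
    cfg: CalibrationConfig,
    model_cfg=None,
) -> ReflectanceStack:
    """Convert demodulated tissue amplitudes into absolute diffuse reflectance.

    R_d,tissue = (M_tissue / M_reference) * R_d,model(ref properties, f) *
    height_scale. Pixels where the reference amplitude vanishes are flagged
    invalid rather than divided.
    """
    from .light_transport import ForwardModelConfig, forward_rd

    model_cfg = model_cfg or ForwardModelConfig()
    if tissue.m_ac.shape != reference.m_ac.shape:
        raise ValueError("tissue and reference stacks must share a shape")
    if not np.array_equal(tissue.wavelengths, reference.wavelengths) or not np.array_equal(
        tissue.frequencies, reference.frequencies
    ):
        raise ValueError("tissue and reference must share wavelength/frequency axes")
    n_wl = len(np.atleast_1d(tissue.wavelengths))
    if len(cfg.reference_mua) != n_wl or len(cfg.reference_musp) != n_wl:
        raise ValueError("reference properties must be given per wavelength")

    amp_tis = modulation_amplitude(tissue)
    amp_ref = modulation_amplitude(reference)
    freqs = np.asarray(tissue.frequencies, dtype=float)
    rd_model = forward_rd(
        cfg.reference_mua[:, None], cfg.reference_musp[:, None], freqs[None, :], model_cfg
    )  # (n_wl, n_freq)

    bad = amp_ref == 0.0
    safe_ref = np.where(bad, 1.0, amp_ref)
    rd = amp_tis / safe_ref * rd_model[:, :, None, None] * cfg.height_scale
    rd[bad] = np.nan
    valid = ~np.any(bad, axis=(0, 1))
    return ReflectanceStack(rd, tissue.wavelengths, freqs, valid)
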