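"""Spectral decomposition of per-wavelength optical properties.

Absorption at the four NIR wavelengths is unmixed into the three endogenous
chromophores — oxy-hemoglobin, deoxy-hemoglobin, and water — by non-negative
least squares:

    mua(lambda) = c_HbO2 * eps_HbO2(lambda) + c_Hb * eps_Hb(lambda)
                  + f_H2O * mua_water(lambda)

yielding total hemoglobin HbT = c_HbO2 + c_Hb (uM), oxygen saturation
%O2 = 100 * c_HbO2 / HbT, and %H2O = 100 * f_H2O (water fitted as a
fractional multiplier of the pure-water absorption spectrum). Reduced
scattering follows the empirical power law mus'(lambda) = A * (lambda /
lambda0)^-b, fitted as a line in log-log space; the amplitude A is mus' at
the reference wavelength lambda0 (800 nm by convention here) and the slope b
tracks the scatterer size distribution (larger b, more Rayleigh-like).

Together the five quantities (A, b, HbT, %O2, %H2O) are the spectral tissue
parameters used for pathology discrimination downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "ChromophoreBasis",
    "SpectralParameterMaps",
    "load_default_basis",
    "fit_chromophores",
    "fit_scattering",
    "fit_pixelwise",
    "forward_mua",
    "forward_musp",
    "PARAMETER_NAMES",
    "LAMBDA0_NM",
]

PARAMETER_NAMES = ("A", "b", "HbT", "O2_percent", "water_percent")
LAMBDA0_NM = 800.0


@dataclass(frozen=True)
class ChromophoreBasis:
    """Extinction/absorption basis: columns HbO2, Hb (mm^-1 uM^-1), water (mm^-1)."""

    wavelengths: np.ndarray
    eps_hbo2: np.ndarray
    eps_hb: np.ndarray
    mua_water: np.ndarray

    def __post_init__(self) -> None:
        for name in ("wavelengths", "eps_hbo2", "eps_hb", "mua_water"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.wavelengths) < 3:
            raise ValueError("need at least as many wavelengths as chromophores (3)")
        if any(np.any(v <= 0) for v in (self.eps_hbo2, self.eps_hb, self.mua_water)):
            raise ValueError("basis values must be positive")
        if np.linalg.matrix_rank(self.matrix) < 3:
            raise ValueError("basis matrix is rank-deficient")

    @property
    def matrix(self) -> np.ndarray:
        """Design matrix (n_wavelengths, 3): [eps_HbO2, eps_Hb, mua_water]."""
        return np.column_stack([self.eps_hbo2, self.eps_hb, self.mua_water])


def load_default_basis() -> ChromophoreBasis:
    """Basis at 658/730/850/970 nm from the packaged CSV asset."""
    with resources.files("sfdikit.data").joinpath("chromophore_basis.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return ChromophoreBasis(
        df["wavelength_nm"].to_numpy(),
        df["eps_hbo2"].to_numpy(),
        df["eps_hb"].to_numpy(),
        df["mua_water"].to_numpy(),
    )


def forward_mua(c_hbo2, c_hb, water_frac, basis: ChromophoreBasis) -> np.ndarray:
    """Absorption spectrum implied by chromophore amounts (the unmixing forward map)."""
    return (
        np.multiply.outer(np.asarray(c_hbo2, float), basis.eps_hbo2)
        + np.multiply.outer(np.asarray(c_hb, float), basis.eps_hb)
        + np.multiply.outer(np.asarray(water_frac, float), basis.mua_water)
    )


def forward_musp(a, b, wavelengths, lambda0: float = LAMBDA0_NM) -> np.ndarray:
    """Power-law reduced scattering mus'(lambda) = A (lambda/lambda0)^-b."""
    lam = np.asarray(wavelengths, float) / lambda0
    return np.multiply.outer(np.asarray(a, float), np.ones_like(lam)) * lam ** (
        -np.multiply.outer(np.asarray(b, float), np.ones_like(lam))
    )


def fit_chromophores(mua_spectrum, basis: ChromophoreBasis):
    """Unmix one absorption spectrum into (c_hbo2 uM, c_hb uM, water fraction).

    Non-negative least squares; a zero spectrum maps to (0, 0, 0).
    """
    y = np.asarray(mua_spectrum, dtype=float)
    if y.shape != basis.wavelengths.shape:
        raise ValueError("spectrum length must match basis wavelengths")
    finite = np.isfinite(y)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite absorption values")
    coef, _ = nnls(basis.matrix[finite], y[finite])
    return float(coef[0]), float(coef[1]), float(coef[2])


def derived_hemoglobin(c_hbo2: float, c_hb: float):
    """(HbT uM, O2 percent); %O2 is defined as 0 when HbT = 0."""
    hbt = c_hbo2 + c_hb
    o2 = 100.0 * c_hbo2 / hbt if hbt > 0 else 0.0
    return hbt, o2


def fit_scattering(musp_spectrum, wavelengths, lambda0: float = LAMBDA0_NM):
    """Fit the scattering power law; returns (A at lambda0 in mm^-1, slope b).

    Least-squares line in ln(mus') vs ln(lambda/lambda0); the slope estimate
    is exact on noiseless power-law data.
    """
    y = np.asarray(musp_spectrum, dtype=float)
    lam = np.asarray(wavelengths, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 wavelengths")
    if np.any(~np.isfinite(y)) or np.any(y <= 0):
        raise ValueError("reduced scattering must be positive and finite")
    x = np.log(lam / lambda0)
    slope, intercept = np.polyfit(x, np.log(y), 1)
    return float(np.exp(intercept)), float(-slope)


@dataclass
class SpectralParameterMaps:
    """Per-pixel five-parameter maps with validity and fit diagnostics."""

    A: np.ndarray
    b: np.ndarray
    HbT: np.ndarray
    O2_percent: np.ndarray
    water_percent: np.ndarray
    valid_mask: np.ndarray
    lambda0: float = LAMBDA0_NM
    mua_residual: np.ndarray | None = None

    def stack(self) -> np.ndarray:
        """(5, H, W) array ordered as PARAMETER_NAMES."""
        return np.stack([self.A, self.b, self.HbT, self.O2_percent, self.water_percent])

    def feature_table(self, labels: np.ndarray, class_names) -> pd.DataFrame:
        """Valid labelled pixels as a tidy feature table for classification.

        ``labels`` holds class indices into ``class_names`` (< 0 means
        background/unlabelled); one row per valid labelled pixel.
        """
        sel = self.valid_mask & (labels >= 0)
        ys, xs = np.nonzero(sel)
        feats = self.stack()[:, ys, xs].T
        return pd.DataFrame(
            {
                "sample_id": np.arange(sel.sum()),
                "group_id": labels[ys, xs],
                "A": feats[:, 0],
                "b": feats[:, 1],
                "HbT": feats[:, 2],
                "O2_percent": feats[:, 3],
                "water_percent": feats[:, 4],
                "label": [class_names[i] for i in labels[ys, xs]],
            }
        )


def fit_pixelwise(maps, basis: ChromophoreBasis, lambda0: float = LAMBDA0_NM) -> SpectralParameterMaps:
    """Apply both spectral fits to every valid pixel of OpticalPropertyMaps.

    Scattering fits are fully vectorized (closed-form simple regression in
    log-log space); chromophore unmixing runs NNLS per pixel. The validity
    mask propagates: pixels invalid upstream, or with non-positive mus',
    stay invalid and carry zero parameters.
    """
    wl = np.asarray(maps.wavelengths, dtype=float)
    if wl.shape != basis.wavelengths.shape or not np.allclose(wl, basis.wavelengths):
        raise ValueError("wavelengths of maps and basis do not match")
    n_wl, h, w = maps.mua.shape
    valid = maps.valid_mask & np.all(maps.musp > 0, axis=0) & np.all(
        np.isfinite(maps.mua) & np.isfinite(maps.musp), axis=0
    )

    a_map = np.zeros((h, w))
    b_map = np.zeros((h, w))
    hbt = np.zeros((h, w))
    o2 = np.zeros((h, w))
    water = np.zeros((h, w))
    resid = np.zeros((h, w))

    ys, xs = np.nonzero(valid)
    if len(ys):
        # scattering: simple regression slope/intercept, vectorized
        x = np.log(wl / lambda0)
        logy = np.log(maps.musp[:, ys, xs])  # (n_wl, npix)
        xm = x.mean()
        ym = logy.mean(axis=0)
        slope = ((x - xm)[:, None] * (logy - ym)).sum(axis=0) / np.sum((x - xm) ** 2)
        intercept = ym - slope * xm
        a_map[ys, xs] = np.exp(intercept)
        b_map[ys, xs] = -slope

        design = basis.matrix
        spectra = maps.mua[:, ys, xs]
        for j in range(len(ys)):
            coef, rnorm = nnls(design, spectra[:, j])
            t, o = derived_hemoglobin(coef[0], coef[1])
            hbt[ys[j], xs[j]] = t
            o2[ys[j], xs[j]] = o
            water[ys[j], xs[j]] = 100.0 * coef[2]
            resid[ys[j], xs[j]] = rnorm

    masked_fraction = 1.0 - valid.mean()
    import logging

    logging.getLogger(__name__).info(
        "spectral fit: %.1f%% of pixels masked", 100.0 * masked_fraction
    )
    return SpectralParameterMaps(a_map, b_map, hbt, o2, water, valid, lambda0, resid)
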