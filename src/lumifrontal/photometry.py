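"""Photopigment quantum catches and photoisomerization rates.

A stimulus photon-irradiance spectrum (photons cm^-2 s^-1 nm^-1), the lens
transmission, and a photopigment's spectral sensitivity are combined as the
trapezoidal integral of their product over wavelength, yielding the
pigment's quantum catch (photons cm^-2 s^-1, usually reported as log10).
Pigment sensitivities are generated from the Govardovskii A1 visual-pigment
nomogram (alpha band plus the short-wavelength beta band), peak-normalised
to 1.  Photoisomerization rates follow by scaling the per-area catch with
the photoreceptor's effective collecting area (rod 0.85 um^2, cone 1 um^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Spectrum",
    "LAMBDA_MAX_NM",
    "COLLECTING_AREA_UM2",
    "pigment_template",
    "synthetic_lens_transmission",
    "quantum_catch",
    "photoisomerization_rate",
]

#: literature-standard mouse pigment peaks (nm); user-overridable
LAMBDA_MAX_NM = {"rod": 498.0, "m_cone": 508.0, "s_cone": 360.0, "melanopsin": 480.0}

#: effective photoreceptor collecting areas (um^2)
COLLECTING_AREA_UM2 = {"rod": 0.85, "cone": 1.0}

DEFAULT_GRID_NM = np.arange(300.0, 781.0, 1.0)


@dataclass
class Spectrum:
    """Wavelength grid (nm, ascending) and non-negative values.

    Values are either photon irradiance (photons cm^-2 s^-1 nm^-1) or a
    dimensionless transmission/sensitivity (unit peak for sensitivities).
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.shape != v.shape or w.ndim != 1:
            raise ValueError("wavelengths and values must be equal-length 1-D")
        if len(w) > 1 and not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly ascending")
        if np.any(v < 0):
            raise ValueError("spectrum values must be non-negative")
        self.wavelengths_nm = w
        self.values = v

    def resample(self, grid_nm: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a common grid (zero outside support)."""
        vals = np.interp(grid_nm, self.wavelengths_nm, self.values, left=0.0, right=0.0)
        return Spectrum(np.asarray(grid_nm, dtype=float), vals)


def pigment_template(lambda_max_nm: float, grid_nm=DEFAULT_GRID_NM) -> Spectrum:
    """Unit-peak A1 pigment sensitivity from the Govardovskii nomogram.

    Valid for 330 <= lambda_max <= 600 nm.  Alpha band:
    S(x) = 1 / (exp(A (a - x)) + exp(B (b - x)) + exp(C (c - x)) + D) with
    x = lambda_max / lambda; plus the Gaussian beta band.
    """
    lm = float(lambda_max_nm)
    if not 330.0 <= lm <= 600.0:
        raise ValueError("lambda_max must lie in [330, 600] nm")
    grid = np.asarray(grid_nm, dtype=float)
    x = lm / grid
    A, B, C, D = 69.7, 28.0, -14.9, 0.674
    a = 0.8795 + 0.0459 * np.exp(-((lm - 300.0) ** 2) / 11940.0)
    b, c = 0.922, 1.104
    alpha = 1.0 / (np.exp(A * (a - x)) + np.exp(B * (b - x)) + np.exp(C * (c - x)) + D)
    lm_beta = 189.0 + 0.315 * lm
    b_beta = -40.5 + 0.195 * lm
    beta = 0.26 * np.exp(-(((grid - lm_beta) / b_beta) ** 2))
    s = alpha + beta
    return Spectrum(grid, s / s.max())


def synthetic_lens_transmission(grid_nm=DEFAULT_GRID_NM) -> Spectrum:
    """Smooth synthetic lens-transmission template (for tests and demos).

    A logistic cut-on emulating strong UV attenuation rising to full
    transmission in the visible; a stand-in shipped because measured lens
    curves live in external references.
    """
    grid = np.asarray(grid_nm, dtype=float)
    t = 1.0 / (1.0 + np.exp(-(grid - 345.0) / 12.0))
    return Spectrum(grid, t)


def quantum_catch(
    irradiance: Spectrum,
    pigment: Spectrum,
    lens: Spectrum | None = None,
    grid_nm=DEFAULT_GRID_NM,
) -> float:
    """Trapezoidal integral of irradiance x lens x pigment sensitivity.

    All spectra are linearly resampled onto a common grid first.  Disjoint
    wavelength supports yield zero catch with a warning.  Returns the catch
    in photons cm^-2 s^-1 (take log10 for the intensity axis).
    """
    grid = np.asarray(grid_nm, dtype=float)
    irr = irradiance.resample(grid).values
    pig = pigment.resample(grid).values
    product = irr * pig
    if lens is not None:
        product = product * lens.resample(grid).values
    catch = float(np.trapezoid(product, grid))
    if catch == 0.0 and irr.any() and pig.any():
        warnings.warn("irradiance and pigment spectra have disjoint support; zero catch",
                      stacklevel=2)
    return catch


def photoisomerization_rate(catch_per_um2: float, collecting_area_um2: float) -> float:
    """Photoisomerization rate (R*/photoreceptor/s) from a per-area catch.

    ``catch_per_um2`` is the quantum catch expressed per um^2 of collecting
    aperture; multiplying by the pigment-specific effective collecting area
    gives the per-photoreceptor isomerisation rate.
    """
    if collecting_area_um2 <= 0:
        raise ValueError("collecting area must be positive")
    return float(catch_per_um2 * collecting_area_um2)
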