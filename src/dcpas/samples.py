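"""Analytic sample absorption spectra and the photoacoustic source model.

The pressure amplitude generated at each beat note is, up to the scalar
conversion factor ``beta`` (Pa per absorbed W),

    p_n = beta * [1 - exp(-mu_a(nu_n) * L)] * I0(nu_n)

where ``mu_a`` is the base-e absorption coefficient, ``L`` the absorbing path
length and ``I0(nu_n)`` the beat-note intensity amplitude.  For weak
absorbers the bracket linearizes to ``mu_a * L``.

Three built-in samples emulate common targets in the 158-188 THz window
(the first C-H stretch overtone band): a strong, spectrally flat carbon
nanotube film and two weakly absorbing polymer films (a silicone, PDMS, and a
paraffin wax) with C-H overtone peaks.  Only relative amplitudes between the
built-ins are meaningful; the nanotube film is ~100x / ~50x stronger than
the PDMS / paraffin films respectively, and paraffin ~2x stronger than PDMS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .comb import BeatNoteSet

__all__ = [
    "AbsorptionSpectrum",
    "PeakModel",
    "spectrum_from_peaks",
    "builtin_sample",
    "absorbed_fraction",
    "pa_source_amplitudes",
    "BUILTIN_SAMPLES",
]


@dataclass
class AbsorptionSpectrum:
    """Base-e absorption coefficient on an optical-frequency grid.

    Attributes
    ----------
    nu_grid : ndarray
        Strictly increasing optical frequencies (Hz).
    mu_a : ndarray
        Absorption coefficient mu_a(nu) (1/m), non-negative.
    thickness : float
        Path length L contributing to the photoacoustic signal (m).
    beta : float
        Scalar pressure-conversion factor (Pa per W absorbed); assumed
        independent of acoustic frequency.
    """

    nu_grid: np.ndarray
    mu_a: np.ndarray
    thickness: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        self.nu_grid = np.asarray(self.nu_grid, dtype=float)
        self.mu_a = np.asarray(self.mu_a, dtype=float)
        if self.nu_grid.ndim != 1 or self.nu_grid.size < 2:
            raise ValueError("nu_grid must be a 1-D array with >= 2 points")
        if np.any(np.diff(self.nu_grid) <= 0):
            raise ValueError("nu_grid must be strictly increasing")
        if self.mu_a.shape != self.nu_grid.shape:
            raise ValueError("mu_a and nu_grid shapes differ")
        if np.any(~np.isfinite(self.mu_a)) or np.any(self.mu_a < 0):
            raise ValueError("mu_a must be finite and non-negative")
        if self.thickness <= 0:
            raise ValueError(f"thickness must be positive, got {self.thickness}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")

    def mu_at(self, nu) -> np.ndarray:
        """Linear interpolation of mu_a onto ``nu`` (inside the grid hull)."""
        nu = np.asarray(nu, dtype=float)
        if np.any(nu < self.nu_grid[0]) or np.any(nu > self.nu_grid[-1]):
            raise ValueError("requested frequencies fall outside the spectrum grid")
        return np.interp(nu, self.nu_grid, self.mu_a)


@dataclass
class PeakModel:
    """Sum-of-peaks parameterization of an absorption spectrum."""

    centers: np.ndarray
    fwhms: np.ndarray
    heights: np.ndarray
    baseline: float = 0.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        self.centers = np.atleast_1d(np.asarray(self.centers, dtype=float))
        self.fwhms = np.atleast_1d(np.asarray(self.fwhms, dtype=float))
        self.heights = np.atleast_1d(np.asarray(self.heights, dtype=float))
        if not (self.centers.size == self.fwhms.size == self.heights.size):
            raise ValueError("centers, fwhms and heights must have equal length")
        if np.any(self.fwhms <= 0):
            raise ValueError("all fwhms must be positive")
        if np.any(self.heights < 0) or self.baseline < 0:
            raise ValueError("heights and baseline must be non-negative")
        if self.shape not in ("gaussian", "lorentzian"):
            raise ValueError(f"unknown peak shape {self.shape!r}")


def spectrum_from_peaks(
    model: PeakModel,
    nu_grid: np.ndarray,
    thickness: float,
    beta: float = 1.0,
) -> AbsorptionSpectrum:
    """Evaluate a peak model on a frequency grid.

    Gaussian peaks are ``h * exp(-4 ln2 (nu-c)^2 / w^2)``; Lorentzian peaks
    ``h * (w/2)^2 / ((nu-c)^2 + (w/2)^2)``; both reach ``h/2`` at
    ``c +/- w/2`` by construction.
    """
    nu = np.asarray(nu_grid, dtype=float)
    if np.any(~np.isfinite(nu)):
        raise ValueError("nu_grid contains non-finite values")
    mu = np.full(nu.shape, model.baseline, dtype=float)
    for c, w, h in zip(model.centers, model.fwhms, model.heights):
        if model.shape == "gaussian":
            mu += h * np.exp(-4.0 * math.log(2.0) * ((nu - c) / w) ** 2)
        else:
            mu += h * (w / 2.0) ** 2 / ((nu - c) ** 2 + (w / 2.0) ** 2)
    return AbsorptionSpectrum(nu, mu, thickness=thickness, beta=beta)


# Built-in sample definitions.  Heights are chosen so the peak absorbed
# fraction of the PDMS-like film is ~1% and the paraffin-like film ~2%
# (hence a ~2x stronger photoacoustic signal), while the nanotube film
# absorbs nearly completely (~100x the PDMS signal).  Peak FWHMs default to
# 1.5 THz, typical of condensed-phase overtone features (hundreds of GHz to
# a few THz wide).
_DEFAULT_GRID = np.linspace(158e12, 188e12, 3001)  # 10 GHz step

BUILTIN_SAMPLES: dict[str, dict] = {
    "pdms_like": dict(
        # the 176.0 / 177.4 THz pair is only 1.4 THz apart; widths of 1.0 THz
        # keep them distinct maxima, as they are in the physical film
        centers_thz=(171.6, 176.0, 177.4),
        fwhms_thz=(1.5, 1.0, 1.0),
        peak_mu=(41.7, 33.3, 25.0),  # 1/m
        baseline_mu=2.0,
        thickness=240e-6,
    ),
    "paraffin_like": dict(
        centers_thz=(169.8, 173.1),
        fwhms_thz=(1.5, 1.5),
        peak_mu=(166.7, 150.0),
        baseline_mu=4.0,
        thickness=120e-6,
    ),
    "vacnt_like": dict(
        centers_thz=(),
        fwhms_thz=(),
        peak_mu=(),
        baseline_mu=2.0e5,  # mu_a * L = 5 -> absorbed fraction 0.993
        thickness=25e-6,
    ),
}


def builtin_sample(
    name: str,
    nu_grid: np.ndarray | None = None,
    beta: float = 1.0,
) -> AbsorptionSpectrum:
    """One of the built-in analytic samples.

    ``vacnt_like`` is a spectrally flat strong absorber (carbon-nanotube
    film); ``pdms_like`` has overtone peaks at 171.6, 176.0 and 177.4 THz;
    ``paraffin_like`` at 169.8 and 173.1 THz.
    """
    try:
        d = BUILTIN_SAMPLES[name]
    except KeyError:
        raise KeyError(
            f"unknown sample {name!r}; valid names: {sorted(BUILTIN_SAMPLES)}"
        ) from None
    grid = _DEFAULT_GRID if nu_grid is None else np.asarray(nu_grid, dtype=float)
    if len(d["centers_thz"]) == 0:
        mu = np.full(grid.shape, d["baseline_mu"], dtype=float)
        return AbsorptionSpectrum(grid, mu, thickness=d["thickness"], beta=beta)
    model = PeakModel(
        centers=np.asarray(d["centers_thz"]) * 1e12,
        fwhms=np.asarray(d["fwhms_thz"]) * 1e12,
        heights=np.asarray(d["peak_mu"], dtype=float),
        baseline=d["baseline_mu"],
    )
    return spectrum_from_peaks(model, grid, thickness=d["thickness"], beta=beta)


def absorbed_fraction(
    spec: AbsorptionSpectrum, nu, mode: str = "exact"
) -> np.ndarray:
    """Fraction of incident power absorbed over the path length.

    ``exact`` evaluates Beer's law, ``1 - exp(-mu_a * L)``; ``linearized``
    returns ``mu_a * L``, valid for weak absorbers (relative error about
    ``mu_a * L / 2``).
    """
    tau = spec.mu_at(nu) * spec.thickness
    if mode == "exact":
        return -np.expm1(-tau)
    if mode == "linearized":
        return tau
    raise ValueError(f"mode must be 'exact' or 'linearized', got {mode!r}")


def pa_source_amplitudes(
    spec: AbsorptionSpectrum, beats: BeatNoteSet, mode: str = "exact"
) -> np.ndarray:
    """Pressure amplitude (Pa) generated at each beat note.

    ``beta * absorbed_fraction(nu_n) * I0(nu_n)`` with ``I0`` the beat-note
    intensity amplitude; homogeneous of degree 1 in both tooth power and beta.
    """
    frac = absorbed_fraction(spec, beats.nu_optical, mode=mode)
    return spec.beta * frac * beats.amplitude
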