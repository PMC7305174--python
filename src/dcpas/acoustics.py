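"""Ultrasound transducer response, detection electronics and detector noise.

The transducer converts acoustic pressure to voltage with a band-pass
responsivity |H(f)| (normalized to 1 at its peak, default 7.5 MHz peak with
7.5 MHz FWHM).  The electronics apply a fixed gain (default 80 dB), a
low-pass filter (default 15 MHz, 4th-order Butterworth magnitude) and add
white Gaussian detector noise at the transducer output.  Acoustic
propagation through the water bath is modeled as a pure delay ``t_acoustic``
(default 14 us), i.e. a linear phase ``-2 pi f t_acoustic`` on every beat
note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .comb import BeatNoteSet

__all__ = [
    "TransducerResponse",
    "DetectionChain",
    "make_transducer",
    "transducer_from_curve",
    "apply_chain",
    "noise_samples",
]


@dataclass
class TransducerResponse:
    """Responsivity magnitude |H(f)| on an acoustic-frequency grid.

    ``magnitude`` is normalized to 1 at the peak; values between grid points
    are linearly interpolated, zero outside the tabulated range.
    """

    f_grid: np.ndarray
    magnitude: np.ndarray
    f_peak: float
    bandwidth_fwhm: float
    phase: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f_grid = np.asarray(self.f_grid, dtype=float)
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        if np.any(self.magnitude < 0):
            raise ValueError("responsivity magnitude must be non-negative")
        m = self.magnitude.max()
        if not math.isclose(m, 1.0, rel_tol=1e-9):
            raise ValueError("responsivity must be normalized to 1 at its peak")

    def __call__(self, f) -> np.ndarray:
        """|H| evaluated at frequencies ``f`` (Hz)."""
        return np.interp(np.asarray(f, dtype=float), self.f_grid, self.magnitude,
                         left=0.0, right=0.0)

    def phase_at(self, f) -> np.ndarray:
        if self.phase is None:
            return np.zeros(np.shape(np.asarray(f)))
        return np.interp(np.asarray(f, dtype=float), self.f_grid, self.phase,
                         left=0.0, right=0.0)


@dataclass
class DetectionChain:
    """Amplifier, low-pass filter, propagation delay and noise level.

    Attributes
    ----------
    gain_db : float
        Voltage gain after the transducer (dB, default 80).
    lowpass_cutoff : float
        Post-amplifier low-pass cutoff (Hz, default 15 MHz).
    lowpass_order : int
        Butterworth order of the low-pass magnitude model.
    noise_density : float
        Per-sample standard deviation of the additive white detector noise at
        the transducer output, before gain (V).
    t_acoustic : float
        Acoustic propagation delay from sample to transducer (s, default 14 us).
    """

    gain_db: float = 80.0
    lowpass_cutoff: float = 15e6
    lowpass_order: int = 4
    noise_density: float = 0.0
    t_acoustic: float = 14e-6

    def __post_init__(self) -> None:
        if self.lowpass_cutoff <= 0:
            raise ValueError("lowpass_cutoff must be positive")
        if self.noise_density < 0:
            raise ValueError("noise_density must be non-negative")
        if self.t_acoustic < 0:
            raise ValueError("t_acoustic must be non-negative")

    @property
    def gain(self) -> float:
        """Linear voltage gain, ``10**(gain_db/20)``."""
        return 10.0 ** (self.gain_db / 20.0)

    def lowpass_magnitude(self, f) -> np.ndarray:
        """Butterworth low-pass magnitude response at frequencies ``f``."""
        x = np.asarray(f, dtype=float) / self.lowpass_cutoff
        return 1.0 / np.sqrt(1.0 + x ** (2 * self.lowpass_order))


def make_transducer(
    f_peak: float = 7.5e6,
    bandwidth_fwhm: float = 7.5e6,
    shape: str = "gaussian",
    f_grid: np.ndarray | None = None,
) -> TransducerResponse:
    """Analytic transducer responsivity model.

    ``gaussian``: ``exp(-4 ln2 (f - f_peak)^2 / w^2)`` with FWHM ``w``;
    ``raised_cosine``: half-cosine reaching zero at ``f_peak +/- w``.  Both
    satisfy |H(f_peak)| = 1 and |H(f_peak +/- w/2)| = 1/2.
    """
    if f_peak <= 0 or bandwidth_fwhm <= 0:
        raise ValueError("f_peak and bandwidth_fwhm must be positive")
    if f_grid is None:
        f_hi = f_peak + 4.0 * bandwidth_fwhm
        f_grid = np.linspace(0.0, f_hi, 4096)
    f_grid = np.asarray(f_grid, dtype=float)
    x = (f_grid - f_peak) / bandwidth_fwhm
    if shape == "gaussian":
        mag = np.exp(-4.0 * math.log(2.0) * x**2)
    elif shape == "raised_cosine":
        mag = np.where(np.abs(x) <= 1.0, 0.5 * (1.0 + np.cos(math.pi * x)), 0.0)
    else:
        raise ValueError(f"unknown transducer shape {shape!r}")
    mag = mag / mag.max()
    return TransducerResponse(f_grid, mag, f_peak=f_peak, bandwidth_fwhm=bandwidth_fwhm)


def transducer_from_curve(f_hz: np.ndarray, magnitude: np.ndarray) -> TransducerResponse:
    """Transducer response from a tabulated calibration curve.

    The curve is renormalized to peak 1; peak frequency and FWHM are
    estimated from the tabulation.
    """
    f = np.asarray(f_hz, dtype=float)
    m = np.asarray(magnitude, dtype=float)
    if f.ndim != 1 or f.size < 2 or np.any(np.diff(f) <= 0):
        raise ValueError("calibration curve needs a strictly increasing f grid")
    m = m / m.max()
    k = int(np.argmax(m))
    above = np.where(m >= 0.5)[0]
    fwhm = f[above[-1]] - f[above[0]] if above.size > 1 else f[-1] - f[0]
    return TransducerResponse(f, m, f_peak=float(f[k]), bandwidth_fwhm=float(fwhm))


def apply_chain(
    pressure_amplitudes: np.ndarray,
    beats: BeatNoteSet,
    transducer: TransducerResponse,
    chain: DetectionChain,
) -> tuple[np.ndarray, np.ndarray]:
    """Convert per-beat pressure amplitudes to voltage amplitudes and phases.

    Returns ``(V_n, phi_n)`` with ``V_n = gain * |H(f_n)| * |LP(f_n)| * p_n``
    and ``phi_n = phase_n + phase_H(f_n) - 2 pi f_n t_acoustic``.
    """
    p = np.asarray(pressure_amplitudes, dtype=float)
    if p.size != len(beats):
        raise ValueError(
            f"pressure amplitudes ({p.size}) not aligned with beat notes ({len(beats)})"
        )
    f = beats.f_acoustic
    volts = chain.gain * transducer(f) * chain.lowpass_magnitude(f) * p
    phases = beats.phase + transducer.phase_at(f) - 2.0 * math.pi * f * chain.t_acoustic
    return volts, phases


def noise_samples(
    chain: DetectionChain,
    n: int,
    sample_rate: float,
    rng: np.random.Generator | int,
    filtered: bool = True,
    apply_gain: bool = True,
) -> np.ndarray:
    """Seeded white Gaussian detector-noise series of length ``n`` (V).

    Drawn at the transducer output with per-sample std ``noise_density``,
    then multiplied by the amplifier gain and band-limited by the low-pass
    magnitude model (both optional, on by default).
    """
    if n <= 0:
        raise ValueError(f"sample count must be positive, got {n}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    x = rng.normal(0.0, chain.noise_density, n) if chain.noise_density > 0 else np.zeros(n)
    if apply_gain:
        x = x * chain.gain
    if filtered and chain.noise_density > 0:
        freqs = np.fft.rfftfreq(n, d=1.0 / sample_rate)
        x = np.fft.irfft(np.fft.rfft(x) * chain.lowpass_magnitude(freqs), n=n)
    return x
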