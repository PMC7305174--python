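"""SNR definitions, scaling-law fits and acquisition-time projections.

Time-domain SNR is the interferogram centerburst peak divided by the noise
standard deviation outside the centerburst.  Spectral SNR is the per-bin
mean over repeated measurements divided by the per-bin standard deviation.
Under white detector noise, coherent averaging gives SNR = A * sqrt(tau),
and SNR grows linearly with optical power, so the averaging time needed for
a fixed SNR falls quadratically with signal amplitude (and with optical
power or absorbance) and linearly with comb repetition rate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .interferogram import Interferogram, SimScene, remove_acoustic_delay, synthesize
from .processing import Spectrum

__all__ = [
    "SNRResult",
    "ScalingScenario",
    "time_domain_snr",
    "spectral_snr",
    "fit_sqrt_tau",
    "fit_power_linear",
    "acquisition_time_scale",
    "apodization_snr_gain",
    "shots_to_reach_snr",
    "averaging_time_ratio_log10",
]


@dataclass
class SNRResult:
    """A single SNR measurement with its acquisition context."""

    value: float
    kind: str = "time_domain"
    averaging_time: float | None = None
    n_shots: int | None = None
    power: float | None = None

    @property
    def infinite(self) -> bool:
        return math.isinf(self.value)


def _circular_offsets(n: int, center: int) -> np.ndarray:
    return (np.arange(n) - center + n // 2) % n - n // 2


def time_domain_snr(
    igm: Interferogram,
    centerburst_halfwidth: float = 2.4e-6,
    exclusion_halfwidth: float | None = None,
    center_time: float | None = None,
) -> SNRResult:
    """Centerburst peak over out-of-burst noise standard deviation.

    The centerburst region is ``center_time +/- centerburst_halfwidth``
    (circular); noise is taken outside ``+/- exclusion_halfwidth`` (default
    3x the centerburst half-width).  A noiseless record reports an infinite
    SNR rather than raising.
    """
    if exclusion_halfwidth is None:
        exclusion_halfwidth = 3.0 * centerburst_halfwidth
    if exclusion_halfwidth < centerburst_halfwidth:
        raise ValueError("exclusion region must contain the centerburst region")
    n = len(igm)
    t_center = igm.t0 if center_time is None else center_time
    center = int(round(t_center * igm.sample_rate)) % n
    off = _circular_offsets(n, center)
    cb = np.abs(off) <= centerburst_halfwidth * igm.sample_rate
    noise = np.abs(off) > exclusion_halfwidth * igm.sample_rate
    if not noise.any():
        raise ValueError("noise region is empty; shrink the exclusion window")
    peak = float(np.max(np.abs(igm.samples[cb])))
    sigma = float(np.std(igm.samples[noise]))
    value = math.inf if sigma == 0.0 else peak / sigma
    tau = igm.n_averaged * igm.duration
    return SNRResult(value, kind="time_domain", averaging_time=tau,
                     n_shots=igm.n_averaged)


def spectral_snr(repeat_spectra: list[Spectrum]) -> np.ndarray:
    """Per-bin SNR over repeated measurements: mean magnitude / std.

    Needs at least 8 repeats on identical grids; bins with zero spread
    report infinity.  Masked bins (where any repeat is masked) are NaN.
    """
    if len(repeat_spectra) < 8:
        raise ValueError(
            f"need >= 8 repeated spectra for a spectral SNR, got {len(repeat_spectra)}"
        )
    first = repeat_spectra[0]
    for s in repeat_spectra[1:]:
        if len(s) != len(first) or not np.allclose(s.f_acoustic, first.f_acoustic):
            raise ValueError("repeated spectra must share the frequency grid")
    mags = np.stack([s.magnitude for s in repeat_spectra])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN masked bins
        mean = np.nanmean(mags, axis=0)
        std = np.nanstd(mags, axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(std == 0.0, np.inf, mean / std)
    out[np.any(np.isnan(mags), axis=0)] = np.nan
    return out


@dataclass
class FitResult:
    amplitude: float
    exponent: float

    def __iter__(self):
        yield self.amplitude
        yield self.exponent


def fit_sqrt_tau(points: list[SNRResult]) -> FitResult:
    """Fit SNR = A * sqrt(tau) in log space.

    Returns the amplitude A with the exponent pinned at 0.5, plus the
    free-exponent log-log slope as a white-noise diagnostic (0.5 for
    sqrt-time averaging; ~1 signals coherent drift).
    """
    tau = np.array([p.averaging_time for p in points], dtype=float)
    snr = np.array([p.value for p in points], dtype=float)
    if tau.size < 4:
        raise ValueError("need >= 4 points for a sqrt-tau fit")
    if np.any(tau <= 0) or np.any(snr <= 0) or np.any(~np.isfinite(snr)):
        raise ValueError("tau and SNR must be positive and finite")
    if tau.max() / tau.min() < 10.0:
        raise ValueError("points must span at least one decade in tau")
    amplitude = float(np.exp(np.mean(np.log(snr) - 0.5 * np.log(tau))))
    slope, _ = np.polyfit(np.log(tau), np.log(snr), 1)
    return FitResult(amplitude=amplitude, exponent=float(slope))


def fit_power_linear(points: list[SNRResult]) -> tuple[float, float, float]:
    """Linear fit of SNR vs optical power.

    Returns ``(slope, intercept, exponent)`` where the exponent is the
    log-log slope diagnostic: ~1 for detector-noise-limited operation,
    ~0.5 would indicate shot-noise limiting.
    """
    power = np.array([p.power for p in points], dtype=float)
    snr = np.array([p.value for p in points], dtype=float)
    if power.size < 3:
        raise ValueError("need >= 3 points for a power fit")
    if np.unique(power).size < 2:
        raise ValueError("need at least two distinct powers")
    slope, intercept = np.polyfit(power, snr, 1)
    exponent, _ = np.polyfit(np.log(power), np.log(snr), 1)
    return float(slope), float(intercept), float(exponent)


@dataclass
class ScalingScenario:
    """Ratios of a proposed configuration to the baseline one."""

    f_rep_factor: float = 1.0
    absorbance_factor: float = 1.0
    power_factor: float = 1.0
    noise_factor: float = 1.0
    baseline_time: float = 1.0

    def __post_init__(self) -> None:
        for name in ("f_rep_factor", "absorbance_factor", "power_factor",
                     "noise_factor", "baseline_time"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def acquisition_time_scale(scenario: ScalingScenario) -> tuple[float, float, float]:
    """Averaging-time and SNR factors for a proposed configuration.

    Time to a fixed SNR scales as 1/f_rep (finer tooth spacing than the
    target resolution wastes per-tooth power), inverse-quadratically in
    absorbance and optical power (signal amplitude enters SNR linearly) and
    quadratically in detector noise.  Returns
    ``(time_factor, snr_factor_at_fixed_time, projected_time)``.
    """
    s = scenario
    time_factor = (
        (1.0 / s.f_rep_factor)
        * (1.0 / s.absorbance_factor**2)
        * (1.0 / s.power_factor**2)
        * s.noise_factor**2
    )
    snr_factor = math.sqrt(1.0 / time_factor)
    return time_factor, snr_factor, s.baseline_time * time_factor


def apodization_snr_gain(resolution_hz: float = 500e9,
                         sample_spacing_hz: float = 160e6) -> float:
    """Per-element SNR gain from smoothing comb-tooth-spaced samples.

    Averaging ``resolution / spacing`` independent noisy spectral samples
    into one resolution element improves its SNR by the square root of that
    count: sqrt(500 GHz / 160 MHz) = sqrt(3125) ~ 56.
    """
    if resolution_hz <= 0 or sample_spacing_hz <= 0:
        raise ValueError("frequencies must be positive")
    if resolution_hz < sample_spacing_hz:
        raise ValueError("resolution element must contain >= 1 sample spacing")
    return math.sqrt(resolution_hz / sample_spacing_hz)


def _noiseless_pa_record(scene: SimScene) -> np.ndarray:
    """Delay-removed noiseless PA record of one shot (no jitter)."""
    beats, volts, phases = scene.noiseless_tables()
    pa = synthesize(volts, phases, beats.index, scene.pair.delta_f_rep,
                    scene.sample_rate, channel="pa")
    return remove_acoustic_delay(pa, scene.chain.t_acoustic).samples


def shots_to_reach_snr(
    scene: SimScene,
    threshold: float,
    seed: int,
    centerburst_halfwidth: float = 2.4e-6,
    exclusion_halfwidth: float | None = None,
    max_shots: int = 1 << 22,
    _chunk: int = 2048,
) -> int:
    """Number of coherently averaged shots until the time-domain SNR
    reaches ``threshold``.

    Simulates the scene shot by shot (fixed noiseless signal plus fresh
    seeded detector noise per shot; requires ``phase_jitter_std = 0``) and
    evaluates the SNR of the running average after every shot, returning the
    first crossing.  Noise generation is chunked for speed but each shot's
    noise is drawn individually, so the result is an exact sample path of
    the averaging process.
    """
    if scene.phase_jitter_std != 0:
        raise ValueError("shot-counting fast path assumes zero phase jitter")
    if scene.chain.noise_density <= 0:
        raise ValueError("scene must have nonzero detector noise")
    if exclusion_halfwidth is None:
        exclusion_halfwidth = 3.0 * centerburst_halfwidth

    signal = _noiseless_pa_record(scene)
    n = signal.size
    rate = scene.record_length * abs(scene.pair.delta_f_rep)
    off = _circular_offsets(n, 0)
    cb = np.abs(off) <= centerburst_halfwidth * rate
    noise_region = np.abs(off) > exclusion_halfwidth * rate
    if not cb.any() or not noise_region.any():
        raise ValueError("degenerate centerburst/noise regions for this record")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed))
    sig_cb = signal[cb]
    sig_nr = signal[noise_region]
    lp = scene.chain.lowpass_magnitude(np.fft.rfftfreq(n, d=1.0 / rate))
    cum = np.zeros(n)
    m_done = 0
    while m_done < max_shots:
        b = min(_chunk, max_shots - m_done)
        # row-major draw == one noise_samples() call per shot, vectorized
        block = rng.normal(0.0, scene.chain.noise_density, (b, n)) * scene.chain.gain
        block = np.fft.irfft(np.fft.rfft(block, axis=1) * lp, n=n, axis=1)
        np.cumsum(block, axis=0, out=block)
        counts = (m_done + 1 + np.arange(b))[:, None]
        avg_cb = (cum[cb] + block[:, cb]) / counts
        avg_nr = (cum[noise_region] + block[:, noise_region]) / counts
        peaks = np.max(np.abs(sig_cb + avg_cb), axis=1)
        sigmas = np.std(sig_nr + avg_nr, axis=1)
        snrs = peaks / sigmas
        hit = np.nonzero(snrs >= threshold)[0]
        if hit.size:
            return m_done + int(hit[0]) + 1
        cum += block[-1]
        m_done += b
    raise RuntimeError(
        f"SNR threshold {threshold} not reached within {max_shots} shots"
    )


def averaging_time_ratio_log10(
    scene_weak: SimScene,
    scene_strong: SimScene,
    threshold: float,
    seeds: list[int],
    **snr_kwargs,
) -> np.ndarray:
    """log10 of the averaging-time ratio (weak / strong) per noise seed.

    Both scenes are run against the identical detector-noise stream for each
    seed (paired comparison), so the ratio isolates the effect of the signal
    amplitude.  With a 100x amplitude ratio the expected value is 4 orders
    of magnitude.
    """
    out = np.empty(len(seeds))
    for i, s in enumerate(seeds):
        m_weak = shots_to_reach_snr(scene_weak, threshold, seed=s, **snr_kwargs)
        m_strong = shots_to_reach_snr(scene_strong, threshold, seed=s, **snr_kwargs)
        out[i] = math.log10(m_weak / m_strong)
    return out
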