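"""Time-domain interferogram synthesis and coherent averaging.

A dual-comb measurement records one interferogram per repetition-rate beat
period ``1/|delta_f_rep|``.  Because every beat note sits at an exact integer
multiple of ``|delta_f_rep|``, a one-period record of length
``N = round(sample_rate / |delta_f_rep|)`` has each beat note on an exact
FFT bin, and the time series can be synthesized by placing the complex beat
amplitudes on those bins and inverse transforming.  Only baseband (radio
frequency) signals are simulated; optical-rate fields never appear.

Repeated shots are co-added coherently: with white detector noise the signal
grows like M and the noise like sqrt(M), so SNR improves as sqrt(M), i.e. as
the square root of averaging time.  An optional per-shot global phase
(rigid interferogram phase jitter) emulates residual comb phase noise; it is
estimated from the high-SNR optical reference channel and removed before
co-adding, as real-time dual-comb averaging systems do.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import hilbert

from . import acoustics, samples
from .acoustics import DetectionChain, TransducerResponse
from .comb import BeatNoteSet, CombPair, beat_notes, check_alias_free
from .samples import AbsorptionSpectrum

logger = logging.getLogger(__name__)

__all__ = [
    "Interferogram",
    "SimScene",
    "synthesize",
    "synthesize_from_beats",
    "simulate_shot",
    "coherent_average",
    "remove_acoustic_delay",
]


@dataclass
class Interferogram:
    """Uniformly sampled one-period voltage record.

    ``t0`` is the nominal centerburst time (s); the record is periodic, so
    all window and shift operations are circular.  ``n_averaged`` counts the
    coherently co-added shots contributing to the record.
    """

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0
    channel: str = "reference"
    n_averaged: int = 1

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_averaged < 1:
            raise ValueError("n_averaged must be >= 1")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def synthesize(
    amplitudes: np.ndarray,
    phases: np.ndarray,
    bin_indices: np.ndarray,
    delta_f_rep: float,
    sample_rate: float,
    channel: str = "reference",
) -> Interferogram:
    """Synthesize one interferogram period from on-grid beat notes.

    The record has length ``N = round(sample_rate / |delta_f_rep|)`` (exactly
    one period ``1/|delta_f_rep|``; the effective sample rate is
    ``N * |delta_f_rep|``), and beat note ``n`` occupies FFT bin ``n``:

        samples(t) = sum_n A_n cos(2 pi n |delta_f_rep| t + phi_n)

    A DC term (bin 0) is excluded.  Beat notes at or above the Nyquist bin
    raise a configuration error (aliasing).
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases, dtype=float)
    idx = np.asarray(bin_indices, dtype=np.int64)
    if not (amplitudes.size == phases.size == idx.size):
        raise ValueError("amplitudes, phases and bin_indices must have equal length")
    if delta_f_rep == 0:
        raise ValueError("delta_f_rep must be nonzero")
    n = int(round(sample_rate / abs(delta_f_rep)))
    if n < 2:
        raise ValueError("sample_rate too low for one beat period")
    keep = idx > 0  # DC excluded
    idx, amplitudes, phases = idx[keep], amplitudes[keep], phases[keep]
    if idx.size and idx.max() >= (n + 1) // 2:
        raise ValueError(
            f"beat note at bin {idx.max()} aliases: record of {n} samples "
            f"holds bins up to {(n + 1) // 2 - 1}"
        )
    spec = np.zeros(n // 2 + 1, dtype=complex)
    spec[idx] = 0.5 * n * amplitudes * np.exp(1j * phases)
    out = np.fft.irfft(spec, n=n)
    return Interferogram(out, sample_rate=n * abs(delta_f_rep), channel=channel)


def synthesize_from_beats(
    beats: BeatNoteSet, delta_f_rep: float, sample_rate: float, **kw
) -> Interferogram:
    """Convenience wrapper: synthesize directly from a beat-note table."""
    return synthesize(
        beats.amplitude, beats.phase, beats.index, delta_f_rep, sample_rate, **kw
    )


@dataclass
class SimScene:
    """One simulated measurement configuration.

    Aggregates the comb pair, sample, transducer, detection chain, digitizer
    rate and the per-shot phase-jitter level; ``seed`` makes every shot
    reproducible.
    """

    pair: CombPair
    sample: AbsorptionSpectrum
    transducer: TransducerResponse
    chain: DetectionChain
    sample_rate: float = 30e6
    phase_jitter_std: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        report = check_alias_free(self.pair)
        if not report.passed:
            raise ValueError(f"scene is not alias-free: {report}")
        n_max = self.pair.n_start + self.pair.n_teeth - 1
        f_max = n_max * abs(self.pair.delta_f_rep)
        if self.sample_rate < 2.5 * f_max:
            raise ValueError(
                f"sample_rate {self.sample_rate:.3g} Hz below 2.5x the maximum "
                f"beat frequency {f_max:.3g} Hz"
            )

    @property
    def record_length(self) -> int:
        return int(round(self.sample_rate / abs(self.pair.delta_f_rep)))

    def shot_rng(self, shot_index: int) -> np.random.Generator:
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(shot_index,))
        return np.random.default_rng(ss)

    def noiseless_tables(self):
        """Beat table plus noiseless reference / PA voltage amplitudes & phases."""
        beats = beat_notes(self.pair)
        p = samples.pa_source_amplitudes(self.sample, beats)
        volts, phases = acoustics.apply_chain(p, beats, self.transducer, self.chain)
        return beats, volts, phases


def simulate_shot(
    scene: SimScene, shot_index: int = 0
) -> tuple[Interferogram, Interferogram]:
    """Simulate one shot: (optical reference, photoacoustic) interferograms.

    Both channels share a common per-shot global phase drawn from
    ``N(0, phase_jitter_std^2)``; the PA channel carries the transducer /
    electronics response, the ``t_acoustic`` propagation delay and additive
    detector noise.  The optical reference is treated as noiseless (high-SNR
    photodetection).
    """
    rng = scene.shot_rng(shot_index)
    jitter = (
        rng.normal(0.0, scene.phase_jitter_std) if scene.phase_jitter_std > 0 else 0.0
    )
    beats, volts, phases = scene.noiseless_tables()
    dfr, rate = scene.pair.delta_f_rep, scene.sample_rate

    ref = synthesize(
        beats.amplitude, beats.phase + jitter, beats.index, dfr, rate,
        channel="reference",
    )
    pa = synthesize(volts, phases + jitter, beats.index, dfr, rate, channel="pa")
    if scene.chain.noise_density > 0:
        pa.samples = pa.samples + acoustics.noise_samples(
            scene.chain, len(pa), pa.sample_rate, rng
        )
    return ref, pa


def _global_phase(igm: Interferogram) -> tuple[float, int]:
    """Global phase estimated from the analytic signal at the centerburst peak."""
    z = hilbert(igm.samples)
    k = int(np.argmax(np.abs(z)))
    return float(np.angle(z[k])), k


def coherent_average(
    shots: list[Interferogram],
    correct_phase: bool = False,
    references: list[Interferogram] | None = None,
) -> Interferogram:
    """Sample-wise coherent mean of repeated shots.

    With ``correct_phase`` each shot's global phase is estimated from the
    corresponding reference shot (or from the shot itself when no references
    are given) and counter-rotated via the analytic signal before averaging.
    """
    if not shots:
        raise ValueError("cannot average an empty shot list")
    first = shots[0]
    for s in shots[1:]:
        if len(s) != len(first) or s.sample_rate != first.sample_rate:
            raise ValueError("all shots must share length and sample rate")
        if s.channel != first.channel:
            raise ValueError("all shots must come from the same channel")
    if references is not None and len(references) != len(shots):
        raise ValueError("need one reference per shot")

    acc = np.zeros(len(first))
    for i, s in enumerate(shots):
        if correct_phase:
            ref = references[i] if references is not None else s
            phi, _ = _global_phase(ref)
            acc += np.real(hilbert(s.samples) * np.exp(-1j * phi))
        else:
            acc += s.samples
    out = acc / len(shots)
    return Interferogram(
        out,
        sample_rate=first.sample_rate,
        t0=first.t0,
        channel=first.channel,
        n_averaged=sum(s.n_averaged for s in shots),
    )


def remove_acoustic_delay(igm: Interferogram, t_acoustic: float) -> Interferogram:
    """Circularly shift the record to undo the acoustic propagation delay.

    Shifts by ``round(t_acoustic * sample_rate)`` samples so the PA
    centerburst re-aligns with ``t0``.  Shifts beyond one record length wrap
    (the record is periodic) with a logged warning.
    """
    if t_acoustic < 0:
        raise ValueError("t_acoustic must be non-negative")
    shift = int(round(t_acoustic * igm.sample_rate))
    if shift >= len(igm):
        logger.warning(
            "delay of %d samples exceeds the %d-sample record; wrapping",
            shift, len(igm),
        )
        shift %= len(igm)
    if shift == 0:
        return replace(igm, samples=igm.samples.copy())
    return replace(igm, samples=np.roll(igm.samples, -shift))
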