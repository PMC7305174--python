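"""Dual frequency-comb model and the optical <-> ultrasound frequency mapping.

Two combs with repetition rates ``f_rep1`` and ``f_rep2 = f_rep1 + delta_f_rep``
produce one radio-frequency beat note per tooth pair.  With the zeroth teeth
overlapping at optical frequency ``nu0``, pair ``n`` beats at

    f_n = n * |delta_f_rep|

and the corresponding optical frequency follows the linear mapping

    nu = nu0 + scale * f_us,     scale = (f_rep1 + f_rep2) / (2 * |delta_f_rep|)

so a broad optical band is compressed into a narrow ultrasound band that an
acoustic transducer can detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CombParams",
    "CombPair",
    "BeatNoteSet",
    "AliasReport",
    "build_comb_pair",
    "beat_notes",
    "optical_from_ultrasound",
    "ultrasound_from_optical",
    "check_alias_free",
]


@dataclass
class CombParams:
    """One frequency comb over the modeled band.

    Parameters
    ----------
    f_rep : float
        Repetition rate (tooth spacing) in Hz.
    nu_start : float
        Optical frequency of the first modeled tooth (Hz).
    n_teeth : int
        Number of teeth in the modeled band.
    tooth_power : float or ndarray
        Per-tooth optical power in W; scalar for a flat envelope or an array
        of length ``n_teeth`` carrying the spectral envelope.
    """

    f_rep: float
    nu_start: float
    n_teeth: int
    tooth_power: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.f_rep <= 0:
            raise ValueError(f"f_rep must be positive, got {self.f_rep}")
        if self.n_teeth < 1:
            raise ValueError(f"n_teeth must be >= 1, got {self.n_teeth}")
        p = np.asarray(self.tooth_power)
        if np.any(p < 0):
            raise ValueError("tooth_power must be non-negative")
        if p.ndim == 1 and p.size != self.n_teeth:
            raise ValueError(
                f"tooth_power length {p.size} does not match n_teeth {self.n_teeth}"
            )

    def powers(self) -> np.ndarray:
        """Per-tooth powers as an array of length ``n_teeth``."""
        p = np.asarray(self.tooth_power, dtype=float)
        if p.ndim == 0:
            return np.full(self.n_teeth, float(p))
        return p


@dataclass
class CombPair:
    """Two combs plus the derived multi-heterodyne mapping constants.

    ``scale`` is the bandwidth-compression factor of the mapping and ``nu0``
    the optical frequency that maps to zero acoustic frequency.  ``n_start``
    is the absolute index (counted from the overlapping zeroth tooth at
    ``nu0``) of the first modeled tooth pair.
    """

    comb1: CombParams
    comb2: CombParams
    delta_f_rep: float
    scale: float
    nu0: float
    n_start: int = 0

    def __post_init__(self) -> None:
        if self.delta_f_rep == 0:
            raise ValueError("delta_f_rep = 0: optical->acoustic mapping is degenerate")
        if self.comb1.n_teeth != self.comb2.n_teeth:
            raise ValueError("both combs must model the same number of teeth")
        expected = (self.comb1.f_rep + self.comb2.f_rep) / (2.0 * abs(self.delta_f_rep))
        if not math.isclose(self.scale, expected, rel_tol=1e-12):
            raise ValueError("scale inconsistent with repetition rates")

    @property
    def n_teeth(self) -> int:
        return self.comb1.n_teeth

    @property
    def f_rep_mean(self) -> float:
        return 0.5 * (self.comb1.f_rep + self.comb2.f_rep)


@dataclass
class BeatNoteSet:
    """Per-tooth-pair beat-note records.

    ``f_acoustic[n] = index[n] * |delta_f_rep|`` exactly; ``amplitude`` is the
    intensity beat amplitude ``2*sqrt(P1*P2)`` in W.
    """

    index: np.ndarray
    nu_optical: np.ndarray
    f_acoustic: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int64)
        self.nu_optical = np.asarray(self.nu_optical, dtype=float)
        self.f_acoustic = np.asarray(self.f_acoustic, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.phase is None:
            self.phase = np.zeros_like(self.amplitude)
        else:
            self.phase = np.asarray(self.phase, dtype=float)
        n = self.index.size
        for name in ("nu_optical", "f_acoustic", "amplitude", "phase"):
            if getattr(self, name).size != n:
                raise ValueError(f"field {name!r} length mismatch with index")
        if np.any(self.amplitude < 0):
            raise ValueError("beat-note amplitudes must be non-negative")

    def __len__(self) -> int:
        return int(self.index.size)


@dataclass
class AliasReport:
    """Result of the dual-comb non-aliasing check."""

    max_beat_hz: float
    limit_hz: float
    passed: bool

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        verdict = "alias-free" if self.passed else "ALIASED (mapping not one-to-one)"
        return (
            f"max beat {self.max_beat_hz / 1e6:.3f} MHz vs limit "
            f"{self.limit_hz / 1e6:.3f} MHz: {verdict}"
        )


DEFAULT_ANCHOR = (7.5e6, 171.2e12)
"""Default mapping anchor: 7.5 MHz acoustic corresponds to 171.2 THz optical."""


def _envelope_powers(
    nu: np.ndarray,
    nu_center: float,
    envelope: str | np.ndarray,
    total_power: float,
    envelope_fwhm: float | None,
) -> np.ndarray:
    if isinstance(envelope, str):
        if envelope == "uniform":
            w = np.ones(nu.size)
        elif envelope == "gaussian":
            if envelope_fwhm is None or envelope_fwhm <= 0:
                raise ValueError("gaussian envelope requires a positive envelope_fwhm")
            w = np.exp(-4.0 * math.log(2.0) * ((nu - nu_center) / envelope_fwhm) ** 2)
        else:
            raise ValueError(f"unknown envelope {envelope!r}")
    else:
        w = np.asarray(envelope, dtype=float)
        if w.size != nu.size:
            raise ValueError("tabulated envelope length does not match tooth count")
        if np.any(w < 0):
            raise ValueError("tabulated envelope must be non-negative")
    return total_power * w / w.sum()


def build_comb_pair(
    f_rep1: float,
    delta_f_rep: float,
    nu_center: float,
    bandwidth: float,
    envelope: str | np.ndarray = "uniform",
    total_power: float = 24e-3,
    envelope_fwhm: float | None = None,
    anchor: tuple[float, float] = DEFAULT_ANCHOR,
    nu0: float | None = None,
) -> CombPair:
    """Build a comb pair spanning ``[nu_center - bw/2, nu_center + bw/2)``.

    The mapping offset ``nu0`` (optical frequency of the zero-frequency beat)
    is rarely known directly; by default it is solved from one anchor point
    ``(f_us, nu)`` of the linear mapping, e.g. the transducer peak at
    7.5 MHz corresponding to 171.2 THz.

    Parameters
    ----------
    f_rep1 : float
        Repetition rate of comb 1 (Hz).
    delta_f_rep : float
        Repetition-rate difference ``f_rep2 - f_rep1`` (Hz); must be nonzero.
    nu_center, bandwidth : float
        Center and full width of the modeled optical band (Hz).
    envelope : {"uniform", "gaussian"} or ndarray
        Spectral envelope of the per-tooth powers.
    total_power : float
        Total optical power per comb (W), distributed over the envelope.
    envelope_fwhm : float, optional
        FWHM of the Gaussian power envelope (Hz); required for "gaussian".
    anchor : (float, float)
        ``(f_us, nu)`` pair pinning the mapping, ignored when ``nu0`` given.
    nu0 : float, optional
        Explicit mapping offset (Hz).
    """
    if f_rep1 <= 0:
        raise ValueError(f"f_rep1 must be positive, got {f_rep1}")
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    if delta_f_rep == 0:
        raise ValueError("delta_f_rep = 0: optical->acoustic mapping is degenerate")
    if bandwidth < f_rep1:
        raise ValueError("bandwidth must contain at least one tooth (>= f_rep1)")

    f_rep2 = f_rep1 + delta_f_rep
    scale = (f_rep1 + f_rep2) / (2.0 * abs(delta_f_rep))
    if nu0 is None:
        anchor_f_us, anchor_nu = anchor
        nu0 = anchor_nu - scale * anchor_f_us

    f_mean = 0.5 * (f_rep1 + f_rep2)
    lo = nu_center - bandwidth / 2.0
    hi = nu_center + bandwidth / 2.0
    if lo < nu0:
        raise ValueError(
            "optical band extends below nu0; teeth there would map to negative "
            "acoustic frequencies"
        )
    # half-open tooth grid [lo, hi): first tooth at index ceil((lo-nu0)/f_mean)
    n_lo = math.ceil((lo - nu0) / f_mean)
    n_hi = math.ceil((hi - nu0) / f_mean)  # exclusive
    n_teeth = n_hi - n_lo
    if n_teeth < 1:
        raise ValueError("no comb teeth fall inside the requested band")

    idx = np.arange(n_lo, n_hi, dtype=np.int64)
    nu = nu0 + idx * f_mean
    powers = _envelope_powers(nu, nu_center, envelope, total_power, envelope_fwhm)

    comb1 = CombParams(f_rep1, nu0 + n_lo * f_rep1, n_teeth, powers)
    comb2 = CombParams(f_rep2, nu0 + n_lo * f_rep2, n_teeth, powers.copy())
    return CombPair(comb1, comb2, delta_f_rep, scale, nu0, n_start=n_lo)


def beat_notes(pair: CombPair, phases: np.ndarray | None = None) -> BeatNoteSet:
    """Beat-note table of a comb pair: ``f_n = n * |delta_f_rep|`` exactly.

    The optical frequency assigned to pair ``n`` is the mapped frequency
    ``nu0 + scale * f_n`` (the mean-comb tooth; comb 1 and comb 2 teeth differ
    from it by at most ``n * delta_f_rep / 2``, a relative 1e-8 effect).

    Parameters
    ----------
    phases : ndarray, optional
        Per-beat phases in rad (default all zero: transform-limited pulse,
        symmetric centerburst).
    """
    idx = np.arange(pair.n_start, pair.n_start + pair.n_teeth, dtype=np.int64)
    f_ac = idx * abs(pair.delta_f_rep)
    nu = pair.nu0 + pair.scale * f_ac
    amplitude = 2.0 * np.sqrt(pair.comb1.powers() * pair.comb2.powers())
    if phases is not None:
        phases = np.asarray(phases, dtype=float)
        if phases.size != idx.size:
            raise ValueError("phases length does not match tooth count")
    return BeatNoteSet(idx, nu, f_ac, amplitude, phases)


def optical_from_ultrasound(pair: CombPair, f_us):
    """Map ultrasound frequency to optical frequency: ``nu0 + scale * f_us``."""
    f_us = np.asarray(f_us, dtype=float)
    if np.any(f_us < 0):
        raise ValueError("ultrasound frequency must be non-negative")
    out = pair.nu0 + pair.scale * f_us
    return float(out) if out.ndim == 0 else out


def ultrasound_from_optical(pair: CombPair, nu):
    """Inverse mapping: ``(nu - nu0) / scale``; requires ``nu >= nu0``."""
    nu = np.asarray(nu, dtype=float)
    if np.any(nu < pair.nu0):
        raise ValueError("optical frequency below nu0 maps to negative f_us")
    out = (nu - pair.nu0) / pair.scale
    return float(out) if out.ndim == 0 else out


def check_alias_free(pair: CombPair) -> AliasReport:
    """Check the standard dual-comb non-aliasing condition.

    The optical->acoustic mapping is one-to-one only while the highest beat
    note stays below half the repetition rate; beyond that, beat orders fold
    on top of each other.
    """
    n_max = pair.n_start + pair.n_teeth - 1
    max_beat = n_max * abs(pair.delta_f_rep)
    limit = pair.comb1.f_rep / 2.0
    return AliasReport(max_beat_hz=max_beat, limit_hz=limit, passed=max_beat < limit)
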