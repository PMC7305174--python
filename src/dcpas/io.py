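"""Plain-text interchange: columnar CSV plus JSON sidecars.

All numeric columns are written with 12 significant digits so files
round-trip losslessly at that precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .comb import BeatNoteSet
from .interferogram import Interferogram
from .processing import RecoveredSpectrum
from .samples import AbsorptionSpectrum

__all__ = [
    "write_beat_notes",
    "read_beat_notes",
    "write_interferogram",
    "read_interferogram",
    "write_absorption_spectrum",
    "read_absorption_spectrum",
    "write_recovered_spectrum",
    "read_recovered_spectrum",
]

_FLOAT_FMT = "%.12g"


def write_beat_notes(beats: BeatNoteSet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "index": beats.index,
            "nu_optical_Hz": beats.nu_optical,
            "f_acoustic_Hz": beats.f_acoustic,
            "amplitude_W": beats.amplitude,
            "phase_rad": beats.phase,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_beat_notes(path: str | Path) -> BeatNoteSet:
    df = pd.read_csv(path)
    return BeatNoteSet(
        index=df["index"].to_numpy(),
        nu_optical=df["nu_optical_Hz"].to_numpy(),
        f_acoustic=df["f_acoustic_Hz"].to_numpy(),
        amplitude=df["amplitude_W"].to_numpy(),
        phase=df["phase_rad"].to_numpy(),
    )


def write_interferogram(igm: Interferogram, path: str | Path) -> None:
    """Write (t_s, volts) CSV plus a <path>.json metadata sidecar."""
    path = Path(path)
    pd.DataFrame({"t_s": igm.times, "volts": igm.samples}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    meta = {
        "sample_rate_Hz": igm.sample_rate,
        "t0_s": igm.t0,
        "channel": igm.channel,
        "n_averaged": igm.n_averaged,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def read_interferogram(path: str | Path) -> Interferogram:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        rate = meta["sample_rate_Hz"]
        t0 = meta.get("t0_s", 0.0)
        channel = meta.get("channel", "reference")
        n_avg = meta.get("n_averaged", 1)
    else:  # infer the rate from the time column
        t = df["t_s"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t)))
        t0, channel, n_avg = 0.0, "reference", 1
    return Interferogram(df["volts"].to_numpy(), sample_rate=rate, t0=t0,
                         channel=channel, n_averaged=n_avg)


def write_absorption_spectrum(spec: AbsorptionSpectrum, path: str | Path) -> None:
    pd.DataFrame({"nu_Hz": spec.nu_grid, "mu_a_per_m": spec.mu_a}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_absorption_spectrum(
    path: str | Path, thickness: float, beta: float = 1.0
) -> AbsorptionSpectrum:
    df = pd.read_csv(path)
    return AbsorptionSpectrum(
        df["nu_Hz"].to_numpy(), df["mu_a_per_m"].to_numpy(),
        thickness=thickness, beta=beta,
    )


def write_recovered_spectrum(rec: RecoveredSpectrum, path: str | Path) -> None:
    norm = rec.pa_normalized
    pd.DataFrame(
        {
            "nu_optical_Hz": norm.nu_optical,
            "f_acoustic_Hz": norm.f_acoustic,
            "excitation_mag": rec.excitation.magnitude,
            "pa_raw_mag": rec.pa_raw.magnitude,
            "pa_normalized": norm.magnitude,
            "masked": (~norm.mask).astype(int),
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recovered_spectrum(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
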