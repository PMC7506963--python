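"""Core signal containers and their delimited-text persistence.

Two streams run through the whole pipeline: a multichannel surface-EMG
recording sampled at ``fs_emg`` (default 1200 Hz) and a scalar knee-joint
angle series sampled at ``fs_angle`` (default 120 Hz).  Both are stored as
plain NumPy arrays with explicit sampling rates; files on disk are CSV
(one column per muscle for EMG, a single column for the angle) with a JSON
sidecar carrying rates, the ground-truth electromechanical delay when known,
and the RNG seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Muscle order used everywhere: rectus femoris, biceps femoris,
#: semitendinosus, gracilis, semimembranosus, sartorius, medial
#: gastrocnemius, tibialis anterior.
DEFAULT_MUSCLES = ("RF", "BF", "ST", "GC", "SM", "SR", "MG", "TA")


@dataclass
class EmgRecording:
    """Raw or filtered multichannel sEMG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in volts or any linear unit.
    fs : float
        Sampling rate in Hz.
    channel_names : tuple of str
        Muscle labels, one per row of ``samples``.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple = DEFAULT_MUSCLES

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_names = tuple(self.channel_names)
        if self.samples.shape[0] != len(self.channel_names):
            raise ValueError(
                f"{self.samples.shape[0]} channels but "
                f"{len(self.channel_names)} channel names"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EMG samples contain NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class AngleSeries:
    """Scalar joint-angle trajectory in degrees at ``fs`` Hz."""

    values: np.ndarray
    fs: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle series contains NaN or Inf")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


# ---------------------------------------------------------------------------
# CSV + sidecar persistence
# ---------------------------------------------------------------------------

def write_emg_csv(rec: EmgRecording, path) -> None:
    """Write EMG as CSV with one column per muscle (header row)."""
    df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_names))
    df.to_csv(path, index=False)


def read_emg_csv(path, fs: float) -> EmgRecording:
    df = pd.read_csv(path)
    return EmgRecording(df.to_numpy().T, fs=fs, channel_names=tuple(df.columns))


def write_angle_csv(angle: AngleSeries, path) -> None:
    """Write the angle as a single-column CSV."""
    pd.DataFrame({"angle_deg": angle.values}).to_csv(path, index=False)


def read_angle_csv(path, fs: float) -> AngleSeries:
    df = pd.read_csv(path)
    return AngleSeries(df.iloc[:, 0].to_numpy(), fs=fs)


def write_sidecar(path, **meta) -> None:
    """Write a JSON metadata sidecar (fs values, delay, seed, ...)."""
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_sidecar(path) -> dict:
    return json.loads(Path(path).read_text())
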