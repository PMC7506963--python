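"""RMS feature extraction, time-advance alignment, and normalization.

The estimation target is the knee angle, but muscle electrical activity
leads the mechanical motion by an electromechanical delay of roughly
20-200 ms.  The feature set therefore pairs each (lagged) angle sample with
two RMS series per muscle:

* the *concurrent* RMS, computed over EMG windows shifted forward by ``k``
  samples so that they are simultaneous with the lagged angle, and
* the *time-advanced* RMS (RMSTAF), computed over unshifted windows, which
  leads the lagged angle by the advance time ``delta_t``.

With the angle lagged by ``l`` samples and the EMG by ``k`` samples,

    l = ceil(delta_t * fs_angle),        k = l * fs_emg / fs_angle,

window ``h`` of an RMS series with offset ``ofs`` covers EMG samples
``(h-1)*N + ofs + 1 .. h*N + ofs`` (1-based inclusive), N the window width.
The angle (120 Hz) is pairwise-averaged down to the 60 Hz feature rate with
the same lag convention.  Eight muscles x {concurrent, time-advanced} give
the 16-column feature matrix (RRTAF).

All indices printed in the formulas above are 1-based inclusive; storage is
0-based NumPy but the public contract keeps the 1-based statement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import AngleSeries, EmgRecording


@dataclass
class WindowConfig:
    """Continuous split window: width and increment equal (non-overlapping)."""

    width_N: int = 20
    increment_M: int = 20

    def __post_init__(self):
        if self.width_N < 1:
            raise ValueError("window width must be >= 1")
        if self.width_N != self.increment_M:
            raise ValueError("continuous split window requires width == increment")


@dataclass
class AlignmentParams:
    """Time-advance bookkeeping: delta_t and the derived shifts l (angle
    samples) and k (EMG samples)."""

    delta_t: float
    fs_angle: float
    fs_emg: float
    l: int
    k: int


def compute_shift_points(delta_t: float, fs_angle: float, fs_emg: float) -> AlignmentParams:
    """Derive the shift counts l = ceil(delta_t * fs_angle) and
    k = l * fs_emg / fs_angle.

    Raises if k would not be integral or the rates are inconsistent.
    """
    if delta_t < 0:
        raise ValueError("delta_t must be nonnegative")
    if fs_angle > fs_emg:
        raise ValueError("fs_angle must not exceed fs_emg")
    l = math.ceil(delta_t * fs_angle)
    k_exact = l * fs_emg / fs_angle
    k = round(k_exact)
    if abs(k_exact - k) > 1e-9:
        raise ValueError(f"k = l*fs_emg/fs_angle = {k_exact} is not integral")
    return AlignmentParams(delta_t=delta_t, fs_angle=fs_angle, fs_emg=fs_emg, l=l, k=k)


@dataclass
class FeatureSeries:
    """One RMS feature stream at the feature rate fs_emg / width_N."""

    values: np.ndarray
    fs: float
    kind: str = "concurrent"  # or "time_advanced"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.kind not in ("concurrent", "time_advanced"):
            raise ValueError(f"unknown feature kind {self.kind!r}")


def rms_windows(signal: np.ndarray, cfg: WindowConfig = WindowConfig(),
                offset_k: int = 0, fs: float | None = None,
                kind: str = "concurrent") -> FeatureSeries:
    """Split-window RMS with a sample offset.

    Window ``h`` (1-based) covers samples ``(h-1)*N + offset_k + 1`` through
    ``h*N + offset_k`` inclusive; with ``offset_k = k`` this is the
    concurrent feature, with ``offset_k = 0`` the time-advanced one.  Output
    length is ``floor((len(signal) - offset_k) / N)``.
    """
    x = np.asarray(signal, dtype=float).ravel()
    N = cfg.width_N
    if offset_k < 0:
        raise ValueError("offset must be nonnegative")
    usable = x.size - offset_k
    if usable < N:
        raise ValueError("signal shorter than one window after offset")
    n_win = usable // N
    w = x[offset_k: offset_k + n_win * N].reshape(n_win, N)
    vals = np.sqrt(np.mean(w * w, axis=1))
    fs_feat = (fs / N) if fs is not None else float("nan")
    return FeatureSeries(vals, fs=fs_feat, kind=kind)


def smooth_feature(f: FeatureSeries, fs_feature: float | None = None) -> FeatureSeries:
    """Second-order Butterworth low-pass at 5 Hz, zero-phase.

    Raw split-window RMS vibrates acutely; this matches the smoothing the
    feature-rate streams receive before modelling.  Zero-phase application
    preserves the temporal alignment the shift arithmetic establishes.
    """
    fs = fs_feature if fs_feature is not None else f.fs
    if not np.isfinite(fs) or fs <= 10.0:
        raise ValueError("feature rate must exceed 10 Hz (5 Hz cutoff below Nyquist)")
    sos = sps.butter(2, 5.0, btype="lowpass", fs=fs, output="sos")
    # padlen guard for very short series
    padlen = min(3 * 6, max(f.values.size - 1, 0))
    out = sps.sosfiltfilt(sos, f.values, padlen=padlen)
    return FeatureSeries(out, fs=fs, kind=f.kind)


def subsample_angle(angle, lag_l: int = 0) -> np.ndarray:
    """Pairwise-average the angle (factor 2, e.g. 120 -> 60 Hz) after
    discarding the first ``lag_l`` samples.

    Window ``h`` (1-based) averages angle samples ``2*(h-1) + lag_l + 1``
    and ``2*h + lag_l``; output length is ``floor((len - lag_l) / 2)``.
    """
    x = angle.values if isinstance(angle, AngleSeries) else np.asarray(angle, dtype=float)
    x = x.ravel()
    if lag_l < 0:
        raise ValueError("lag must be nonnegative")
    usable = x.size - lag_l
    if usable < 2:
        raise ValueError("fewer than one full averaging window after lag")
    n = usable // 2
    return x[lag_l: lag_l + 2 * n].reshape(n, 2).mean(axis=1)


@dataclass
class AlignedFeatureSet:
    """Feature matrix X [T x 2*n_muscles] with aligned angle targets y [T].

    Columns alternate concurrent and time-advanced RMS per muscle, muscles
    in the recording's channel order; names are ``<muscle>_rms`` and
    ``<muscle>_rmstaf``.
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple
    fs_feature: float
    alignment: AlignmentParams | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.shape[0] != self.y.size:
            raise ValueError("X rows and y length differ")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("column count does not match feature_names")

    @property
    def n_steps(self) -> int:
        return self.X.shape[0]

    def rms_only(self) -> "AlignedFeatureSet":
        """Drop the time-advanced columns, keeping one concurrent RMS per muscle."""
        idx = [i for i, n in enumerate(self.feature_names) if n.endswith("_rms")]
        return AlignedFeatureSet(self.X[:, idx], self.y,
                                 tuple(self.feature_names[i] for i in idx),
                                 self.fs_feature, self.alignment)


def build_aligned_features(emg: EmgRecording, angle: AngleSeries,
                           cfg: WindowConfig = WindowConfig(),
                           ap: AlignmentParams | None = None,
                           smooth: bool = True) -> AlignedFeatureSet:
    """Assemble the aligned feature matrix and target vector.

    For each muscle the concurrent RMS (window offset k) and time-advanced
    RMS (offset 0) are computed, each smoothed at the feature rate; the
    target is the pairwise-averaged angle lagged by l samples.  The three
    streams are right-trimmed to their minimum common length so that step
    t = 1 stays aligned across all of them.
    """
    if ap is None:
        ap = compute_shift_points(0.2, angle.fs, emg.fs)
    if abs(emg.duration_s - angle.duration_s) > 0.5:
        raise ValueError("EMG and angle recordings cover different epochs")
    fs_feat = emg.fs / cfg.width_N
    y = subsample_angle(angle, lag_l=ap.l)

    cols, names = [], []
    for m, name in enumerate(emg.channel_names):
        sig = emg.samples[m]
        conc = rms_windows(sig, cfg, offset_k=ap.k, fs=emg.fs, kind="concurrent")
        adv = rms_windows(sig, cfg, offset_k=0, fs=emg.fs, kind="time_advanced")
        if smooth:
            conc = smooth_feature(conc)
            adv = smooth_feature(adv)
        cols.extend([conc.values, adv.values])
        names.extend([f"{name}_rms", f"{name}_rmstaf"])

    T = min(min(c.size for c in cols), y.size)
    X = np.column_stack([c[:T] for c in cols])
    return AlignedFeatureSet(X, y[:T], tuple(names), fs_feat, ap)


# ---------------------------------------------------------------------------
# Min-max normalization to [-1, 1], fit on training data only
# ---------------------------------------------------------------------------

@dataclass
class NormalizationParams:
    """Per-column min/max mapping the training data onto [y_min, y_max].

    Fit on the training split only; the test split reuses these parameters
    and may land outside [-1, 1] (values are never clipped, so the affine
    map stays invertible and angle errors can be reported in degrees).
    """

    x_min: np.ndarray
    x_max: np.ndarray
    y_min: float = -1.0
    y_max: float = 1.0

    def __post_init__(self):
        self.x_min = np.atleast_1d(np.asarray(self.x_min, dtype=float))
        self.x_max = np.atleast_1d(np.asarray(self.x_max, dtype=float))


def fit_normalization(data: np.ndarray, y_min: float = -1.0,
                      y_max: float = 1.0) -> NormalizationParams:
    """Learn per-column extremes; rejects degenerate (constant) columns."""
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    lo, hi = arr.min(axis=0), arr.max(axis=0)
    if np.any(hi <= lo):
        bad = np.nonzero(hi <= lo)[0]
        raise ValueError(f"degenerate (constant) column(s) {bad.tolist()}: x_max == x_min")
    return NormalizationParams(lo, hi, y_min, y_max)


def apply_normalization(data: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Map data through the learned affine transform (no clipping)."""
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = params.y_min + (params.y_max - params.y_min) * (
        (arr - params.x_min) / (params.x_max - params.x_min))
    return out[:, 0] if squeeze else out


def invert_normalization(data: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Exact inverse of :func:`apply_normalization`."""
    arr = np.asarray(data, dtype=float)
    squeeze = arr.ndim == 1
    if squeeze:
        arr = arr[:, None]
    out = params.x_min + (params.x_max - params.x_min) * (
        (arr - params.y_min) / (params.y_max - params.y_min))
    return out[:, 0] if squeeze else out
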