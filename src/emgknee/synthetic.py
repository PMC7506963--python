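"""Synthetic treadmill-gait generator: paired knee angle and sEMG streams.

No public dataset exists for the acquisition regime this package targets
(eight lower-limb muscles at 1200 Hz plus motion-capture knee angle at
120 Hz during 1.0 m/s treadmill walking), so every downstream stage is
exercised against this simulator.  It produces:

* a smooth periodic knee-flexion trajectory (three harmonics of the stride
  frequency, spanning roughly 0-60 degrees over a 1.2 s stride);
* per-muscle activation envelopes that are phase-shifted, rectified
  functions of the angle and its derivative evaluated ``delay_s`` seconds
  AHEAD of the angle - muscle electrical activity leads the mechanical
  motion, the electromechanical delay the whole method is built around;
* sEMG channels: envelope x band-limited (10-500 Hz) unit-variance
  Gaussian carrier, plus optional 50 Hz power-line interference and white
  measurement noise.

The first muscle (RF) has zero phase offset and no derivative term, so its
envelope is an exact affine image of the angle ``delay_s`` ahead; this is
the channel the delay-recovery utilities lean on.

The defaults are stand-ins chosen for plausibility, not fits to any
subject: real gait EMG has stride-to-stride variability, crosstalk and
non-stationary noise that this generator deliberately omits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .signals import DEFAULT_MUSCLES, AngleSeries, EmgRecording

# Knee-flexion template: degrees as a function of stride phase theta
# (3 harmonics; range ~0.8-58.7 deg, biphasic like treadmill walking).
ANGLE_FOURIER = {
    "offset": 27.0,
    "cos": (-22.0, -6.0, 2.0),
    "sin": (8.0, -7.0, 3.0),
}

# Per-muscle stride-phase offsets (rad) and derivative mixing weights.
# RF is the reference channel: zero offset, pure angle dependence.
MUSCLE_PHASE = (0.0, 3.1, 2.9, 0.8, 2.7, 0.6, 4.4, 5.5)
MUSCLE_DERIV_WEIGHT = (0.0, 0.2, -0.15, 0.1, 0.25, -0.1, 0.3, -0.3)

ENVELOPE_FLOOR = 0.1  # resting muscle tone, fraction of peak activation


@dataclass
class GaitSimConfig:
    """Simulator settings.

    delay_s is the ground-truth electromechanical lead of sEMG over the
    angle, physiologically 0.02-0.2 s; interference_amp is the 50 Hz
    power-line amplitude relative to the unit-variance carrier.
    """

    duration_s: float = 60.0
    stride_period_s: float = 1.2
    fs_emg: float = 1200.0
    fs_angle: float = 120.0
    delay_s: float = 0.2
    n_muscles: int = 8
    interference_amp: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0
    flat_envelopes: bool = False  # diagnostic mode: constant unit envelopes

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0.0 <= self.delay_s <= 0.25):
            raise ValueError("delay_s must lie in [0, 0.25] s")
        ratio = self.fs_emg / self.fs_angle
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("fs_emg must be an integer multiple of fs_angle")
        if self.n_muscles < 1 or self.n_muscles > len(MUSCLE_PHASE):
            raise ValueError(f"n_muscles must be in 1..{len(MUSCLE_PHASE)}")


@dataclass
class SyntheticRecording:
    """Paired EMG + angle with the ground truth that produced them."""

    emg: EmgRecording
    angle: AngleSeries
    truth_delay_s: float
    truth_envelopes: np.ndarray  # (n_muscles, n_emg_samples), nonnegative


def _angle_template(t: np.ndarray, stride_period_s: float) -> np.ndarray:
    """Knee angle in degrees at times t (seconds)."""
    theta = 2.0 * np.pi * t / stride_period_s
    a = np.full_like(t, ANGLE_FOURIER["offset"], dtype=float)
    for h, (ac, as_) in enumerate(zip(ANGLE_FOURIER["cos"], ANGLE_FOURIER["sin"]), start=1):
        a += ac * np.cos(h * theta) + as_ * np.sin(h * theta)
    return a


def _angle_template_deriv(t: np.ndarray, stride_period_s: float) -> np.ndarray:
    w = 2.0 * np.pi / stride_period_s
    theta = w * t
    d = np.zeros_like(t, dtype=float)
    for h, (ac, as_) in enumerate(zip(ANGLE_FOURIER["cos"], ANGLE_FOURIER["sin"]), start=1):
        d += h * w * (-ac * np.sin(h * theta) + as_ * np.cos(h * theta))
    return d


def _envelope(m: int, t: np.ndarray, cfg: GaitSimConfig) -> np.ndarray:
    """Activation envelope of muscle m at times t; leads the angle by delay_s."""
    shift = MUSCLE_PHASE[m] * cfg.stride_period_s / (2.0 * np.pi)
    t_adv = t + cfg.delay_s + shift
    a = _angle_template(t_adv, cfg.stride_period_s)
    lo = _template_range.min
    span = _template_range.span
    drive = (a - lo) / span
    gamma = MUSCLE_DERIV_WEIGHT[m]
    if gamma != 0.0:
        d = _angle_template_deriv(t_adv, cfg.stride_period_s)
        drive = drive + gamma * d / _template_range.dmax
    drive = np.maximum(drive, 0.0)
    peak = drive.max()
    if peak > 0:
        drive = drive / peak
    return ENVELOPE_FLOOR + (1.0 - ENVELOPE_FLOOR) * drive


class _TemplateRange:
    """Extremes of the angle template over one stride, computed once."""

    def __init__(self):
        t = np.linspace(0.0, 1.2, 4096, endpoint=False)
        a = _angle_template(t, 1.2)
        d = _angle_template_deriv(t, 1.2)
        self.min = float(a.min())
        self.max = float(a.max())
        self.span = self.max - self.min
        self.dmax = float(np.abs(d).max())


_template_range = _TemplateRange()


def _bandlimited_carrier(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to 10-500 Hz."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, [10.0, 500.0], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    return x / x.std()


def simulate_recording(config: GaitSimConfig) -> SyntheticRecording:
    """Generate one synchronized sEMG + knee-angle recording.

    Deterministic given ``config.seed``.  Random draws happen in a fixed
    order: per muscle (in muscle order) first the carrier noise, then the
    measurement noise, so seeds are portable across runs and platforms.
    """
    config.validate()
    n_emg = int(round(config.duration_s * config.fs_emg))
    n_ang = int(round(config.duration_s * config.fs_angle))
    t_emg = np.arange(n_emg) / config.fs_emg
    t_ang = np.arange(n_ang) / config.fs_angle

    angle = AngleSeries(_angle_template(t_ang, config.stride_period_s), fs=config.fs_angle)

    rng = np.random.default_rng(config.seed)
    interference = config.interference_amp * np.sin(2.0 * np.pi * 50.0 * t_emg)

    envelopes = np.empty((config.n_muscles, n_emg))
    emg = np.empty((config.n_muscles, n_emg))
    for m in range(config.n_muscles):
        if config.flat_envelopes:
            env = np.ones(n_emg)
        else:
            env = _envelope(m, t_emg, config)
        carrier = _bandlimited_carrier(n_emg, config.fs_emg, rng)
        noise = config.noise_sd * rng.standard_normal(n_emg)
        envelopes[m] = env
        emg[m] = env * carrier + interference + noise

    rec = EmgRecording(emg, fs=config.fs_emg,
                       channel_names=DEFAULT_MUSCLES[: config.n_muscles])
    return SyntheticRecording(emg=rec, angle=angle,
                              truth_delay_s=config.delay_s,
                              truth_envelopes=envelopes)


# ---------------------------------------------------------------------------
# Delay recovery (brute-force cross-correlation over integer lags)
# ---------------------------------------------------------------------------

def envelope_angle_lag(rec: SyntheticRecording, channel: int = 0,
                       max_lag_s: float = 0.3) -> float:
    """Lag (seconds) of the peak cross-correlation between the smoothed
    rectified EMG envelope of ``channel`` and the angle, both at the angle
    rate.

    The lag convention pairs envelope sample ``i`` with angle sample
    ``i - lag``; because muscle activity leads the motion, the returned lag
    is approximately ``-truth_delay_s``.
    """
    fs_emg = rec.emg.fs
    fs_ang = rec.angle.fs
    ratio = int(round(fs_emg / fs_ang))
    rect = np.abs(rec.emg.samples[channel])
    sos = sps.butter(2, 5.0, btype="lowpass", fs=fs_emg, output="sos")
    env = sps.sosfiltfilt(sos, rect)[::ratio]
    ang = rec.angle.values
    n = min(env.size, ang.size)
    env, ang = env[:n], ang[:n]

    max_lag = int(round(max_lag_s * fs_ang))
    best_lag, best_r = 0, -np.inf
    for lag in range(-max_lag, max_lag + 1):
        # envelope sample i pairs with angle sample i - lag
        if lag < 0:
            e, a = env[:lag], ang[-lag:]
        elif lag > 0:
            e, a = env[lag:], ang[:-lag]
        else:
            e, a = env, ang
        r = np.corrcoef(e, a)[0, 1]
        if r > best_r:
            best_r, best_lag = r, lag
    return best_lag / fs_ang
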