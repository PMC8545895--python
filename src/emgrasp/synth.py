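"""Synthetic multi-channel surface-EMG generator.

Surface EMG is emulated as amplitude-modulated, band-limited Gaussian
noise: each muscle's interference-pattern carrier is white noise passed
through a 4th-order zero-phase 20-450 Hz Butterworth band-pass, scaled
by a deterministic activation envelope, linearly mixed with its
anatomical neighbours (electrode crosstalk), and summed with a
band-limited baseline noise floor. This surrogate reproduces the first-
and second-order statistics that amplitude and spectral EMG features
respond to, without modelling individual motor units.

The experiment structure being emulated is a reach-to-grasp protocol:
six prehensile patterns (spherical, tripod, power, lateral, tip,
extension) x two object weights (light/heavy) x ``n_reps`` repetitions.
Each class activates the muscles through a distinct synergy: per-muscle
gains, per-muscle onset lags relative to the movement onset, a
class-specific ramp time, and a slow class-specific sinusoidal
modulation of the envelope standing in for reach kinematics. The triceps
always ramps first (lag 0) so that the movement onset is detectable from
triceps activity, and every trial opens with a quiescent pre-onset
baseline. Heavy objects scale the envelopes by ``weight_gain`` and delay
the non-triceps lags slightly, so weight discrimination has both an
amplitude and a timing cue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .dataio import CHANNELS_6, FS_HZ, GRASPS, WEIGHTS, ChannelSet, EmgTrial

_TRICEPS_IDX = CHANNELS_6.index("triceps")

__all__ = ["SynergyProfile", "SynthSpec", "default_synergy", "generate_trial", "generate_dataset"]

# per-class per-muscle activation gains, rows = GRASPS, cols = CHANNELS_6
# (deltoid, biceps, triceps, latissimus, trapezius, pectoralis); every row
# has gains > 0.2, rows differ pairwise in >= 2 channels, triceps > 0 always
_GAINS_6 = np.array(
    [
        [0.90, 0.70, 0.50, 0.30, 0.40, 0.60],  # spherical
        [0.50, 0.90, 0.40, 0.60, 0.30, 0.30],  # tripod
        [0.70, 0.60, 0.90, 0.50, 0.60, 0.40],  # power
        [0.40, 0.30, 0.60, 0.90, 0.50, 0.70],  # lateral
        [0.60, 0.50, 0.30, 0.40, 0.90, 0.50],  # tip
        [0.30, 0.40, 0.70, 0.60, 0.70, 0.90],  # extension
    ]
)
# forearm extension (flexor/extensor carpi radialis) for the 8-channel montage
_GAINS_FOREARM = np.array(
    [
        [0.80, 0.40],
        [0.60, 0.70],
        [0.90, 0.50],
        [0.50, 0.80],
        [0.70, 0.60],
        [0.20, 0.90],
    ]
)

# per-class per-muscle activation lag after movement onset, ms; the triceps
# column is zero so the onset anchor is always the first muscle to ramp
_LAG_MS_6 = np.array(
    [
        [120, 240, 0, 360, 60, 300],
        [300, 60, 0, 120, 240, 420],
        [60, 360, 0, 240, 420, 120],
        [240, 120, 0, 60, 300, 180],
        [420, 300, 0, 180, 120, 60],
        [180, 420, 0, 300, 180, 240],
    ],
    dtype=float,
)
_LAG_MS_FOREARM = np.array(
    [[180, 90], [60, 300], [300, 150], [120, 240], [240, 60], [90, 360]],
    dtype=float,
)

# class-specific envelope dynamics: linear rise time to plateau and the
# frequency of the slow kinematic modulation of the envelope
_RAMP_MS = np.array([150.0, 250.0, 200.0, 300.0, 180.0, 350.0])
_MOD_HZ = np.array([1.5, 2.0, 2.5, 3.0, 3.5, 4.0])
_MOD_DEPTH = 0.25


@dataclass(frozen=True)
class SynergyProfile:
    """Deterministic class->muscle activation model for the six grasps."""

    gains: np.ndarray  # [6 x channels] in [0, 1]
    lag_ms: np.ndarray  # [6 x channels] activation lag after onset
    ramp_ms: np.ndarray  # [6] linear rise time to plateau
    mod_hz: np.ndarray  # [6] slow kinematic envelope modulation
    mod_depth: float = _MOD_DEPTH
    weight_gain: float = 1.6  # heavy-object amplitude multiplier
    heavy_lag_ms: float = 60.0  # extra non-triceps lag for heavy objects
    # button-press burst: the protocol starts every trial with the same
    # timer-button push, a triceps activation independent of grasp class
    # and object weight — this is what makes the onset anchor reliable
    press_gain: float = 0.6
    press_ramp_ms: float = 100.0
    press_decay_ms: float = 500.0

    def __post_init__(self) -> None:
        gains = np.asarray(self.gains, dtype=float)
        if gains.ndim != 2 or gains.shape[0] != len(GRASPS):
            raise ValueError("gains must be a [6 x channels] matrix")
        if gains.min() < 0 or gains.max() > 1:
            raise ValueError("gains must lie in [0, 1]")
        if not np.all(gains.max(axis=1) > 0.2):
            raise ValueError("every class must activate at least one muscle > 0.2")
        for a in range(len(GRASPS)):
            for b in range(a + 1, len(GRASPS)):
                if np.sum(gains[a] != gains[b]) < 2:
                    raise ValueError(
                        f"classes {GRASPS[a]} and {GRASPS[b]} differ in < 2 channels"
                    )
        if self.weight_gain <= 1.0:
            raise ValueError("weight_gain must exceed 1")

    @property
    def n_channels(self) -> int:
        return self.gains.shape[1]


@dataclass(frozen=True)
class SynthSpec:
    """Dataset-level generation parameters."""

    n_channels: int = 6
    n_reps: int = 10
    trial_duration_s: float = 3.0
    pre_onset_s: float = 0.3  # quiescent baseline before the triceps ramp
    noise_sd: float = 0.05  # baseline noise floor, relative to unit gains
    crosstalk: float = 0.1  # linear mixing into anatomically adjacent channels
    bandpass: tuple[float, float] = (20.0, 450.0)
    seed: int = 0
    subject: str = "sim"

    def __post_init__(self) -> None:
        if self.n_channels not in (6, 8):
            raise ValueError("n_channels must be 6 or 8")
        if self.trial_duration_s * FS_HZ < 400 + 100:
            raise ValueError("trial too short for 400-sample windowing")
        if self.pre_onset_s < 0.2:
            raise ValueError("pre-onset baseline must be >= 200 ms")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.crosstalk < 1:
            raise ValueError("crosstalk must lie in [0, 1)")
        lo, hi = self.bandpass
        if not 0 < lo < hi < FS_HZ / 2:
            raise ValueError("bandpass must lie strictly inside (0, Nyquist)")


def default_synergy(n_channels: int) -> SynergyProfile:
    """The fixed, documented synergy profile for the 6- or 8-channel montage.

    The 8-channel profile extends the 6-channel one with the forearm pair.
    Deterministic: involves no randomness.
    """
    if n_channels == 6:
        gains, lags = _GAINS_6, _LAG_MS_6
    elif n_channels == 8:
        gains = np.hstack([_GAINS_6, _GAINS_FOREARM])
        lags = np.hstack([_LAG_MS_6, _LAG_MS_FOREARM])
    else:
        raise ValueError(f"no default synergy for {n_channels} channels")
    return SynergyProfile(
        gains=gains, lag_ms=lags, ramp_ms=_RAMP_MS.copy(), mod_hz=_MOD_HZ.copy()
    )


def _bandpass_sos(bandpass: tuple[float, float]):
    return sps.butter(4, bandpass, btype="bandpass", fs=FS_HZ, output="sos")


def _bandlimited_noise(rng: np.random.Generator, n: int, n_ch: int, sos) -> np.ndarray:
    """Unit-variance band-limited Gaussian carrier, [n x n_ch]."""
    white = rng.standard_normal((n, n_ch))
    filt = sps.sosfiltfilt(sos, white, axis=0)
    return filt / filt.std(axis=0, keepdims=True)


def _envelopes(
    grasp: str, weight: str, profile: SynergyProfile, spec: SynthSpec, n: int
) -> np.ndarray:
    """Deterministic per-channel activation envelope, [n x channels]."""
    ci = GRASPS.index(grasp)
    t = np.arange(n) / FS_HZ
    gains = profile.gains[ci].copy()
    lags = profile.lag_ms[ci] / 1000.0
    if weight == "heavy":
        gains = np.clip(gains * profile.weight_gain, 0.0, None)
        extra = np.full_like(lags, profile.heavy_lag_ms / 1000.0)
        extra[lags == 0.0] = 0.0  # the onset anchor (triceps) keeps lag 0
        lags = lags + extra
    ramp = profile.ramp_ms[ci] / 1000.0
    onset = spec.pre_onset_s

    env = np.zeros((n, profile.n_channels))
    for m in range(profile.n_channels):
        t0 = onset + lags[m]
        rel = t - t0
        rise = np.clip(rel / ramp, 0.0, 1.0)
        mod = 1.0 + profile.mod_depth * np.sin(
            2 * np.pi * profile.mod_hz[ci] * rel + 2 * np.pi * m / profile.n_channels
        )
        env[:, m] = gains[m] * rise * np.where(rel > 0, mod, 0.0)

    # the timer-button press drives the triceps identically in every trial
    tri_idx = _TRICEPS_IDX
    rel0 = t - onset
    ramp_p = profile.press_ramp_ms / 1000.0
    decay_p = profile.press_decay_ms / 1000.0
    burst = (
        profile.press_gain
        * np.clip(rel0 / ramp_p, 0.0, 1.0)
        * np.exp(-np.clip(rel0 - ramp_p, 0.0, None) / decay_p)
    )
    burst[rel0 <= 0] = 0.0
    env[:, tri_idx] = np.maximum(env[:, tri_idx], burst)
    return np.clip(env, 0.0, None)


def _crosstalk_matrix(n_ch: int, crosstalk: float) -> np.ndarray:
    """Row-stochastic mixing of each channel with its anatomical neighbours."""
    mix = np.eye(n_ch)
    for i in range(n_ch):
        for j in (i - 1, i + 1):
            if 0 <= j < n_ch:
                mix[i, j] = crosstalk
    return mix / mix.sum(axis=1, keepdims=True)


def generate_trial(
    grasp: str,
    weight: str,
    profile: SynergyProfile,
    spec: SynthSpec,
    seed: int,
    repetition: int = 1,
) -> EmgTrial:
    """Generate one trial; bit-identical for identical arguments."""
    if grasp not in GRASPS:
        raise ValueError(f"unknown grasp {grasp!r}")
    if weight not in WEIGHTS:
        raise ValueError(f"unknown weight {weight!r}")
    if profile.n_channels != spec.n_channels:
        raise ValueError("profile and spec disagree on channel count")

    rng = np.random.default_rng(seed)
    n = int(round(spec.trial_duration_s * FS_HZ))
    sos = _bandpass_sos(spec.bandpass)

    carrier = _bandlimited_noise(rng, n, spec.n_channels, sos)
    floor = spec.noise_sd * _bandlimited_noise(rng, n, spec.n_channels, sos)
    env = _envelopes(grasp, weight, profile, spec, n)

    mixed = (env * carrier) @ _crosstalk_matrix(spec.n_channels, spec.crosstalk).T
    signal = mixed + floor
    return EmgTrial(
        signal=signal,
        fs=FS_HZ,
        grasp=grasp,
        weight=weight,
        subject=spec.subject,
        repetition=repetition,
        channels=ChannelSet.default(spec.n_channels),
    )


def trial_seed(base_seed: int, grasp: str, weight: str, repetition: int) -> int:
    """Deterministic per-trial seed derived from the dataset seed and labels."""
    ss = np.random.SeedSequence(
        entropy=base_seed,
        spawn_key=(GRASPS.index(grasp), WEIGHTS.index(weight), repetition),
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def generate_dataset(
    spec: SynthSpec, profile: SynergyProfile | None = None
) -> list[EmgTrial]:
    """Generate the full 6 grasps x 2 weights x n_reps balanced dataset.

    A pure function of (spec, profile): per-trial seeds are derived
    deterministically from ``spec.seed`` and the trial's labels.
    """
    if profile is None:
        profile = default_synergy(spec.n_channels)
    trials = []
    for grasp in GRASPS:
        for weight in WEIGHTS:
            for rep in range(1, spec.n_reps + 1):
                trials.append(
                    generate_trial(
                        grasp,
                        weight,
                        profile,
                        spec,
                        seed=trial_seed(spec.seed, grasp, weight, rep),
                        repetition=rep,
                    )
                )
    return trials
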