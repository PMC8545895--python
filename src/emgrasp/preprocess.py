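"""Front-end conditioning: amplitude normalization, movement-onset
detection from the triceps, reach-phase truncation and sliding-window
segmentation.

Amplitude normalization is per-muscle min-max over a reference trial
set (by default every trial, mirroring the reference processing chain;
a train-only scope is available to avoid test-fold leakage). Movement
onset is the first sustained supra-threshold excursion of the smoothed,
rectified triceps envelope: baseline statistics come from the first
200 ms, the threshold is baseline mean + 3 SD, and the envelope must
stay above threshold for at least 25 ms. Because the rule operates on
the baseline-mean-subtracted rectified signal it is invariant to the
per-channel affine normalization, so it may be applied before or after
normalization with an identical result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .dataio import ChannelSet, EmgTrial

__all__ = [
    "NormalizationStats",
    "Segment",
    "NoOnsetError",
    "fit_normalization",
    "apply_normalization",
    "detect_onset",
    "truncate_reach_phase",
    "segment_windows",
]


class NoOnsetError(RuntimeError):
    """The triceps envelope never crossed the onset threshold."""


@dataclass(frozen=True)
class NormalizationStats:
    """Per-channel min/max over the reference trial set."""

    mins: np.ndarray
    maxs: np.ndarray
    scope: str  # "all_trials" or "train_only"
    channel_names: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, dtype=float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, dtype=float))


@dataclass
class Segment:
    """A 400-sample window cut from one trial's reach phase."""

    data: np.ndarray  # [window x channels]
    grasp: str
    weight: str
    subject: str
    repetition: int
    start: int  # window start index within the truncated trial
    trial_id: int  # index of the source trial within its dataset


def fit_normalization(
    trials: list[EmgTrial], scope: str = "all_trials"
) -> NormalizationStats:
    """Per-muscle global min/max over the given (scoped) trials."""
    if not trials:
        raise ValueError("cannot fit normalization on an empty trial list")
    channels = trials[0].channels
    for t in trials:
        if t.channels != channels:
            raise ValueError("trials must share one channel set")
    stacked_min = np.min([t.signal.min(axis=0) for t in trials], axis=0)
    stacked_max = np.max([t.signal.max(axis=0) for t in trials], axis=0)
    degenerate = np.flatnonzero(stacked_max <= stacked_min)
    if degenerate.size:
        names = [channels.names[i] for i in degenerate]
        raise ValueError(f"degenerate (constant) channel(s): {names}")
    return NormalizationStats(
        mins=stacked_min, maxs=stacked_max, scope=scope, channel_names=channels.names
    )


def apply_normalization(trial: EmgTrial, stats: NormalizationStats) -> EmgTrial:
    """Map each channel through (x - min) / (max - min), clipped to [0, 1].

    Values from the reference set land in [0, 1] exactly; out-of-range
    values (possible when stats were fit on a training subset) are
    clipped so the downstream [0, 1] contract always holds.
    """
    if trial.channels.names != stats.channel_names:
        raise ValueError("trial channels do not match normalization stats")
    scaled = (trial.signal - stats.mins) / (stats.maxs - stats.mins)
    return EmgTrial(
        signal=np.clip(scaled, 0.0, 1.0),
        fs=trial.fs,
        grasp=trial.grasp,
        weight=trial.weight,
        subject=trial.subject,
        repetition=trial.repetition,
        channels=trial.channels,
    )


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Causal (trailing-window) moving average; ramp-in over the first samples."""
    c = np.cumsum(np.concatenate([[0.0], x]))
    out = np.empty_like(x)
    idx = np.arange(1, len(x) + 1)
    lo = np.maximum(idx - width, 0)
    out[:] = (c[idx] - c[lo]) / (idx - lo)
    return out


def detect_onset(
    trial: EmgTrial,
    channels: ChannelSet | None = None,
    cfg: RunConfig | None = None,
) -> int:
    """First sustained supra-threshold sample of the triceps envelope.

    Envelope = causal 50-ms moving average of |x - baseline mean|;
    baseline = first 200 ms of the envelope; threshold = baseline mean +
    3 SD; the crossing must hold for >= 25 ms.
    """
    cfg = cfg or RunConfig()
    channels = channels or trial.channels
    fs = trial.fs
    n_base = int(round(cfg.onset_baseline_ms * fs / 1000.0))
    n_smooth = max(1, int(round(cfg.onset_smooth_ms * fs / 1000.0)))
    n_hold = max(1, int(round(cfg.onset_hold_ms * fs / 1000.0)))
    if trial.n_samples <= n_base + n_hold:
        raise ValueError("trial too short for onset detection")

    x = trial.signal[:, channels.triceps_index]
    rectified = np.abs(x - x[:n_base].mean())
    envelope = _moving_average(rectified, n_smooth)
    baseline = envelope[:n_base]
    threshold = baseline.mean() + cfg.onset_threshold_sd * baseline.std()

    above = envelope > threshold
    # first index from which the envelope stays above threshold for n_hold samples
    if n_hold > 1:
        kernel = np.ones(n_hold)
        runs = np.convolve(above.astype(float), kernel, mode="valid")
        candidates = np.flatnonzero(runs >= n_hold)
    else:
        candidates = np.flatnonzero(above)
    if candidates.size == 0:
        raise NoOnsetError("no sustained supra-threshold triceps activity found")
    return int(candidates[0])


def truncate_reach_phase(trial: EmgTrial, onset: int, fraction: float) -> EmgTrial:
    """Keep samples [onset, onset + round(fraction * (end - onset)))."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    if onset < 0 or onset >= trial.n_samples:
        raise ValueError("onset outside the trial")
    length = int(round(fraction * (trial.n_samples - onset)))
    if length < 400:
        raise ValueError(
            f"truncated reach phase holds {length} samples, need >= 400"
        )
    return EmgTrial(
        signal=trial.signal[onset : onset + length],
        fs=trial.fs,
        grasp=trial.grasp,
        weight=trial.weight,
        subject=trial.subject,
        repetition=trial.repetition,
        channels=trial.channels,
    )


def segment_windows(
    trial: EmgTrial, window: int = 400, step: int = 50, trial_id: int = 0
) -> list[Segment]:
    """Cut sliding windows starting at 0, step, 2*step, ...

    Count = floor((L - window) / step) + 1; half-open 0-based intervals.
    """
    L = trial.n_samples
    if L < window:
        raise ValueError(f"trial of {L} samples is shorter than one {window}-sample window")
    starts = range(0, L - window + 1, step)
    return [
        Segment(
            data=trial.signal[s : s + window],
            grasp=trial.grasp,
            weight=trial.weight,
            subject=trial.subject,
            repetition=trial.repetition,
            start=s,
            trial_id=trial_id,
        )
        for s in starts
    ]
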