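"""Run configuration and logging for the EMG reach-to-grasp pipeline.

A single flat :class:`RunConfig` carries every tunable of the pipeline:
windowing, spectrogram geometry, PCA size, CNN architecture and training
hyper-parameters, baseline-feature settings and cross-validation layout.
Defaults reproduce the reference processing chain (400/50 windowing,
200/100/256 Hamming STFT, 95 kept frequencies, 25 PCs on a 5x5 grid,
400 conv filters of size 4x4, SGD with lr 0.001 / momentum 0.9 / batch 32
/ 100 epochs, 10-fold CV).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger("emgrasp")


def setup_logging(level: int | str = logging.INFO) -> logging.Logger:
    """Attach a stream handler to the package logger (idempotent)."""
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@dataclass
class RunConfig:
    """All pipeline parameters. See module docstring for provenance of defaults."""

    # segmentation
    window_samples: int = 400
    step_samples: int = 50
    # spectrogram (STFT) geometry: 400-sample segment -> 3 frames of 200
    # samples (hop 100), zero-padded FFT of length 256 -> 129 one-sided bins
    stft_window: int = 200
    stft_hop: int = 100
    stft_nfft: int = 256
    keep_freqs: int = 95
    # PCA / grid embedding
    n_pcs: int = 25
    grid_side: int = 5
    pca_per_channel: bool = True
    # CNN architecture
    conv_filters: int = 400
    conv_kernel: int = 4
    fc_size: int = 400
    dropout: float = 0.5
    cnn_two_stage: bool = False  # optional extra 2x2 conv stage, off by default
    # CNN training
    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 32
    epochs: int = 100
    # reach-phase truncation (fraction of the post-onset trial retained)
    reach_fraction_healthy: float = 0.40
    reach_fraction_amputee: float = 0.49
    # movement-onset detector (triceps envelope rule)
    onset_baseline_ms: float = 200.0
    onset_smooth_ms: float = 50.0
    onset_hold_ms: float = 25.0
    onset_threshold_sd: float = 3.0
    # time-domain / AR baseline features
    ar_order: int = 4
    zc_threshold: float = 0.01
    ssc_threshold: float = 0.01
    # SVM baseline
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    # cross-validation
    k_folds: int = 10
    norm_scope: str = "all_trials"  # or "train_only"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.grid_side**2 != self.n_pcs:
            raise ValueError(
                f"grid_side^2 ({self.grid_side}^2) must equal n_pcs ({self.n_pcs})"
            )
        if self.window_samples <= self.stft_window:
            raise ValueError("window_samples must exceed stft_window")
        if not 0 < self.step_samples <= self.window_samples:
            raise ValueError("step_samples must be in (0, window_samples]")
        if self.stft_nfft < self.stft_window:
            raise ValueError("stft_nfft must be >= stft_window")
        if self.keep_freqs > self.stft_nfft // 2 + 1:
            raise ValueError("keep_freqs exceeds the number of one-sided FFT bins")
        for name in ("reach_fraction_healthy", "reach_fraction_amputee"):
            frac = getattr(self, name)
            if not 0.0 < frac <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("invalid CNN training hyper-parameters")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.norm_scope not in ("all_trials", "train_only"):
            raise ValueError("norm_scope must be 'all_trials' or 'train_only'")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
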