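"""Per-segment short-time Fourier spectrogram features.

Each 400-sample segment channel is decomposed into three Hamming-
windowed frames (length 200, hop 100, frame starts 0/100/200), each
zero-padded to an FFT length of 256, giving a one-sided magnitude
spectrogram of 129 frequencies x 3 time bins. The first 95 frequency
rows (0 to ~367 Hz) are retained, each channel plane is min-max
normalized to [0, 1], and planes are flattened frequency-major to a
285-vector per channel. The frame placement and raw |FFT| magnitudes
are part of the contract (tests check them against a direct DFT), so
frames are computed explicitly rather than through a windowing helper
with its own centering and scaling conventions.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import windows

from .config import RunConfig, logger
from .preprocess import Segment

__all__ = [
    "stft_spectrogram",
    "truncate_frequencies",
    "normalize_spec",
    "vectorize_channels",
    "devectorize_channels",
    "segment_spec_vectors",
]


def _frame_starts(n: int, cfg: RunConfig) -> np.ndarray:
    return np.arange(0, n - cfg.stft_window + 1, cfg.stft_hop)


def stft_spectrogram(segment_channel: np.ndarray, cfg: RunConfig | None = None) -> np.ndarray:
    """Magnitude spectrogram of one segment channel, [129 x 3] by default."""
    cfg = cfg or RunConfig()
    x = np.asarray(segment_channel, dtype=float)
    if x.ndim != 1 or x.shape[0] != cfg.window_samples:
        raise ValueError(
            f"expected a 1-D segment of {cfg.window_samples} samples, got shape {x.shape}"
        )
    win = windows.hamming(cfg.stft_window, sym=True)
    starts = _frame_starts(len(x), cfg)
    frames = np.stack([x[s : s + cfg.stft_window] * win for s in starts], axis=1)
    return np.abs(np.fft.rfft(frames, n=cfg.stft_nfft, axis=0))


def truncate_frequencies(spec: np.ndarray, keep: int = 95) -> np.ndarray:
    """Retain the lowest ``keep`` frequency rows, order preserved."""
    spec = np.asarray(spec)
    if spec.shape[0] < keep:
        raise ValueError(f"spectrogram has {spec.shape[0]} rows, cannot keep {keep}")
    return spec[:keep]


def normalize_spec(tensor: np.ndarray) -> np.ndarray:
    """Min-max normalize each channel plane of a [freq x time x C] tensor to [0, 1].

    A constant plane (no spectral contrast) maps to all zeros with a warning.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("expected a [freq x time x channels] tensor")
    if not np.all(np.isfinite(tensor)):
        raise ValueError("spectrogram tensor contains non-finite values")
    lo = tensor.min(axis=(0, 1), keepdims=True)
    hi = tensor.max(axis=(0, 1), keepdims=True)
    span = hi - lo
    flat = span == 0
    if np.any(flat):
        logger.warning(
            "constant spectrogram plane(s) in channel(s) %s mapped to zeros",
            np.flatnonzero(flat.ravel()).tolist(),
        )
        span = np.where(flat, 1.0, span)
        lo = np.where(flat, tensor.min(axis=(0, 1), keepdims=True), lo)
    return (tensor - lo) / span


def vectorize_channels(tensor: np.ndarray) -> np.ndarray:
    """Flatten each [F x T] channel plane frequency-major to an [F*T x C] matrix.

    Cell (f, t) of channel c maps to row f*T + t of column c; exactly
    inverted by :func:`devectorize_channels`.
    """
    tensor = np.asarray(tensor)
    if tensor.ndim != 3:
        raise ValueError("expected a [freq x time x channels] tensor")
    F, T, C = tensor.shape
    return tensor.reshape(F * T, C)


def devectorize_channels(vectors: np.ndarray, freq_bins: int, time_bins: int) -> np.ndarray:
    vectors = np.asarray(vectors)
    if vectors.shape[0] != freq_bins * time_bins:
        raise ValueError("vector length does not match freq_bins * time_bins")
    return vectors.reshape(freq_bins, time_bins, vectors.shape[1])


def segment_spec_vectors(segments: list[Segment], cfg: RunConfig | None = None) -> np.ndarray:
    """Full spectrogram feature path for a list of segments.

    Returns an array [n_segments x (keep_freqs * n_frames) x channels] of
    [0, 1]-normalized, frequency-major vectorized spectrograms.
    """
    cfg = cfg or RunConfig()
    out = []
    for seg in segments:
        planes = np.stack(
            [
                truncate_frequencies(stft_spectrogram(seg.data[:, c], cfg), cfg.keep_freqs)
                for c in range(seg.data.shape[1])
            ],
            axis=2,
        )
        out.append(vectorize_channels(normalize_spec(planes)))
    return np.stack(out, axis=0)
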