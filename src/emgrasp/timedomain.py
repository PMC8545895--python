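"""Time-domain and autoregressive baseline features (TDAR).

Per channel per segment: mean absolute value (MAV), zero crossings (ZC),
slope-sign changes (SSC), waveform length (WL) and the coefficients of
an AR(p) model fitted by the Yule-Walker normal equations. The five are
concatenated channel-major into one feature vector of length
C * (4 + p). Segments arrive min-max normalized to [0, 1], so each
channel is mean-centered here first: the classic definitions assume a
zero-mean signal (ZC of a non-negative signal is identically zero, and
the AR model is defined on the demeaned process).

Definitions (x of length N, i = 0..N-1):
  MAV = (1/N) sum |x_i|
  WL  = sum |x_{i+1} - x_i|
  ZC  = #{i : x_i * x_{i+1} < 0 and |x_i - x_{i+1}| >= zc_threshold}
  SSC = #{i in 1..N-2 : (x_i - x_{i-1})(x_i - x_{i+1}) > 0
          and max(|x_i - x_{i-1}|, |x_i - x_{i+1}|) >= ssc_threshold}
"""

from __future__ import annotations

import numpy as np
from statsmodels.regression.linear_model import yule_walker

from .config import RunConfig
from .preprocess import Segment

__all__ = ["compute_td", "fit_ar", "extract_tdar", "tdar_feature_length", "DegenerateSignalError"]


class DegenerateSignalError(ValueError):
    """The signal is constant: AR coefficients are undefined."""


def compute_td(
    x: np.ndarray, zc_threshold: float = 0.0, ssc_threshold: float = 0.0
) -> tuple[float, int, int, float]:
    """(MAV, ZC, SSC, WL) of a zero-mean signal; see module docstring."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.shape[0] < 3:
        raise ValueError("signal must be 1-D with at least 3 samples")
    diff = np.diff(x)
    mav = float(np.mean(np.abs(x)))
    wl = float(np.sum(np.abs(diff)))
    zc = int(np.sum((x[:-1] * x[1:] < 0) & (np.abs(diff) >= zc_threshold)))
    back = x[1:-1] - x[:-2]
    fwd = x[1:-1] - x[2:]
    ssc = int(
        np.sum((back * fwd > 0) & (np.maximum(np.abs(back), np.abs(fwd)) >= ssc_threshold))
    )
    return mav, zc, ssc, wl


def fit_ar(x: np.ndarray, order: int = 4) -> np.ndarray:
    """AR(p) coefficients a_1..a_p of x_i = sum_k a_k x_{i-k} + e.

    Solved from the autocorrelation (Yule-Walker) normal equations with
    the biased autocovariance estimator; deterministic.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if x.shape[0] < 10 * order:
        raise ValueError(f"need at least {10 * order} samples for AR({order})")
    if np.ptp(x) == 0:
        raise DegenerateSignalError("constant signal: AR model undefined")
    coeffs, _sigma = yule_walker(x, order=order, method="mle")
    return np.asarray(coeffs, dtype=float)


def tdar_feature_length(n_channels: int, ar_order: int) -> int:
    return n_channels * (4 + ar_order)


def extract_tdar(segment: Segment, cfg: RunConfig | None = None) -> np.ndarray:
    """Concatenated per-channel [MAV, ZC, SSC, WL, a_1..a_p], channel-major."""
    cfg = cfg or RunConfig()
    data = np.asarray(segment.data, dtype=float)
    feats = []
    for c in range(data.shape[1]):
        x = data[:, c] - data[:, c].mean()
        mav, zc, ssc, wl = compute_td(x, cfg.zc_threshold, cfg.ssc_threshold)
        ar = fit_ar(x, cfg.ar_order)
        feats.append(np.concatenate([[mav, zc, ssc, wl], ar]))
    return np.concatenate(feats)
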