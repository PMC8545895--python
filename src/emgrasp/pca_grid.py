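"""Per-channel PCA of vectorized spectrograms and the 5x5 grid embedding.

One PCA model is fitted per channel on the training segments only,
keeping the top 25 principal components. Component sign is fixed by
making each component's largest-magnitude entry positive, so fits are
run-to-run identical. The 25 scores are then rearranged into a 5x5
grid with the most significant component at the center cell and
successive components spiralling outward (positions ordered by
Chebyshev distance from the center, ties broken row-major): convolution
kernels overlap central cells most often, so the highest-variance
scores receive the most filter support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .config import RunConfig

__all__ = [
    "PcaModel",
    "fit_pca",
    "transform",
    "rearrange_grid",
    "grid_order",
    "ungrid",
    "grids_from_scores",
]


@dataclass(frozen=True)
class PcaModel:
    """Per-channel PCA: means [C x D], components [C x D x n_pcs] with
    orthonormal columns ordered by decreasing explained variance."""

    means: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.means.shape[0]

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    @property
    def n_pcs(self) -> int:
        return self.components.shape[2]


def _fix_signs(components: np.ndarray) -> np.ndarray:
    """Make each component's largest-|entry| positive (columns = components)."""
    idx = np.argmax(np.abs(components), axis=0)
    signs = np.sign(components[idx, np.arange(components.shape[1])])
    signs[signs == 0] = 1.0
    return components * signs


def fit_pca(train_vectors: np.ndarray, cfg: RunConfig | None = None) -> PcaModel:
    """Fit one PCA per channel on training vectors [n x D x C].

    Requires at least n_pcs + 1 training segments. Must only ever see
    the training split of a fold.
    """
    cfg = cfg or RunConfig()
    train_vectors = np.asarray(train_vectors, dtype=float)
    if train_vectors.ndim != 3:
        raise ValueError("expected training vectors of shape [segments x D x channels]")
    n, d, n_ch = train_vectors.shape
    if n < cfg.n_pcs + 1:
        raise ValueError(f"need at least {cfg.n_pcs + 1} training segments, got {n}")
    means = np.empty((n_ch, d))
    comps = np.empty((n_ch, d, cfg.n_pcs))
    evar = np.empty((n_ch, cfg.n_pcs))
    for c in range(n_ch):
        pca = PCA(n_components=cfg.n_pcs, svd_solver="full")
        pca.fit(train_vectors[:, :, c])
        means[c] = pca.mean_
        comps[c] = _fix_signs(pca.components_.T)
        evar[c] = pca.explained_variance_
    return PcaModel(means=means, components=comps, explained_variance=evar)


def transform(model: PcaModel, vectors: np.ndarray) -> np.ndarray:
    """Project vectors [n x D x C] to scores [n x n_pcs x C]."""
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 3 or vectors.shape[1] != model.n_features:
        raise ValueError(
            f"expected vectors of shape [n x {model.n_features} x {model.n_channels}]"
        )
    if vectors.shape[2] != model.n_channels:
        raise ValueError("channel count does not match the fitted model")
    scores = np.empty((vectors.shape[0], model.n_pcs, model.n_channels))
    for c in range(model.n_channels):
        scores[:, :, c] = (vectors[:, :, c] - model.means[c]) @ model.components[c]
    return scores


def grid_order(side: int = 5) -> list[tuple[int, int]]:
    """Grid positions ordered center-out: by Chebyshev distance from the
    center cell, ties broken row-major. Position r receives PC rank r."""
    ctr = side // 2
    cells = [(i, j) for i in range(side) for j in range(side)]
    return sorted(cells, key=lambda ij: (max(abs(ij[0] - ctr), abs(ij[1] - ctr)), ij))


def rearrange_grid(scores: np.ndarray, side: int = 5) -> np.ndarray:
    """Place the r-th most significant PC score at the r-th center-out cell."""
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (side * side,):
        raise ValueError(f"expected {side * side} scores, got shape {scores.shape}")
    grid = np.empty((side, side))
    for rank, (i, j) in enumerate(grid_order(side)):
        grid[i, j] = scores[rank]
    return grid


def ungrid(grid: np.ndarray, side: int = 5) -> np.ndarray:
    """Exact inverse of :func:`rearrange_grid`."""
    grid = np.asarray(grid, dtype=float)
    if grid.shape != (side, side):
        raise ValueError(f"expected a {side}x{side} grid")
    return np.array([grid[i, j] for (i, j) in grid_order(side)])


def grids_from_scores(scores: np.ndarray, side: int = 5) -> np.ndarray:
    """Vectorized [n x n_pcs x C] -> [n x side x side x C] rearrangement."""
    scores = np.asarray(scores, dtype=float)
    n, n_pcs, n_ch = scores.shape
    if n_pcs != side * side:
        raise ValueError("score dimension does not match the grid size")
    order = grid_order(side)
    grids = np.empty((n, side, side, n_ch))
    for rank, (i, j) in enumerate(order):
        grids[:, i, j, :] = scores[:, rank, :]
    return grids
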