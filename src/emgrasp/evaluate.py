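"""Cross-validated evaluation of the two classification methods.

Segments are divided into k folds (default 10) at random without
overlap; the held-out fold rotates in order. Two fold modes exist:
``random_segment`` assigns segments independently (mirroring the
reference protocol — note that windows of one trial can then appear on
both sides of a split), and ``grouped_by_trial`` keeps all windows of a
trial in one fold. Everything that is *fitted* — PCA, feature z-scoring
and the classifiers — only ever sees the nine training folds; the
per-muscle amplitude normalization follows the configured scope
(``all_trials`` by default, ``train_only`` for a leakage-free variant).

Two tasks are supported: ``grasp6`` (six prehensile patterns) and
``weight2`` (light vs heavy within one grasp).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig, logger
from .dataio import GRASPS, WEIGHTS, EmgTrial
from .preprocess import (
    Segment,
    apply_normalization,
    detect_onset,
    fit_normalization,
    segment_windows,
    truncate_reach_phase,
)
from .spectral import segment_spec_vectors
from .timedomain import extract_tdar
from . import pca_grid
from .classifiers import build_cnn, predict, train_cnn, train_svm

__all__ = [
    "FoldPlan",
    "CvResult",
    "make_folds",
    "build_segments",
    "weight_binary_task",
    "cross_validate",
    "confusion",
    "report",
]

METHODS = ("pca-cnn", "tdar-svm")
TASKS = ("grasp6", "weight2")


@dataclass(frozen=True)
class FoldPlan:
    """A disjoint k-fold partition of segment indices."""

    k: int
    assignment: np.ndarray  # fold index per segment
    mode: str
    seed: int

    def folds(self):
        """Yield (train_idx, test_idx), the test fold rotating in order."""
        for f in range(self.k):
            test = np.flatnonzero(self.assignment == f)
            train = np.flatnonzero(self.assignment != f)
            yield train, test


@dataclass
class CvResult:
    """Aggregated cross-validation outcome for one method/task pair."""

    method: str
    task: str
    classes: list
    fold_accuracies: list
    mean_accuracy: float
    sd_accuracy: float
    confusion_counts: np.ndarray  # true rows x predicted columns
    confusion_normalized: np.ndarray
    n_segments: int
    fold_predictions: list = field(default_factory=list)  # per fold: dict

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "task": self.task,
            "classes": list(self.classes),
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "mean_accuracy": float(self.mean_accuracy),
            "sd_accuracy": float(self.sd_accuracy),
            "confusion_counts": self.confusion_counts.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "n_segments": int(self.n_segments),
            "fold_predictions": self.fold_predictions,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CvResult":
        return cls(
            method=d["method"],
            task=d["task"],
            classes=list(d["classes"]),
            fold_accuracies=[float(a) for a in d["fold_accuracies"]],
            mean_accuracy=float(d["mean_accuracy"]),
            sd_accuracy=float(d["sd_accuracy"]),
            confusion_counts=np.asarray(d["confusion_counts"]),
            confusion_normalized=np.asarray(d["confusion_normalized"]),
            n_segments=int(d["n_segments"]),
            fold_predictions=d.get("fold_predictions", []),
        )


def make_folds(
    segments: list[Segment] | int,
    k: int = 10,
    mode: str = "random_segment",
    seed: int = 0,
) -> FoldPlan:
    """Random balanced partition into k disjoint folds.

    ``random_segment`` balances segment counts (sizes differ by <= 1);
    ``grouped_by_trial`` balances trial counts and never splits a trial.
    """
    if isinstance(segments, int):
        n = segments
        trial_ids = None
    else:
        n = len(segments)
        trial_ids = np.array([s.trial_id for s in segments])
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} segments")
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if mode == "random_segment":
        for f, chunk in enumerate(np.array_split(rng.permutation(n), k)):
            assignment[chunk] = f
    elif mode == "grouped_by_trial":
        if trial_ids is None:
            raise ValueError("grouped_by_trial mode needs Segment objects")
        uniq = np.unique(trial_ids)
        if uniq.size < k:
            raise ValueError(f"cannot group {uniq.size} trials into {k} folds")
        for f, chunk in enumerate(np.array_split(rng.permutation(uniq), k)):
            assignment[np.isin(trial_ids, chunk)] = f
    else:
        raise ValueError(f"unknown fold mode {mode!r}")
    return FoldPlan(k=k, assignment=assignment, mode=mode, seed=seed)


def weight_binary_task(trials: list[EmgTrial], grasp: str) -> list[EmgTrial]:
    """Restrict a dataset to one grasp, leaving the light/heavy labels."""
    if grasp not in GRASPS:
        raise ValueError(f"unknown grasp {grasp!r}")
    subset = [t for t in trials if t.grasp == grasp]
    present = {t.weight for t in subset}
    if present != set(WEIGHTS):
        raise ValueError(
            f"grasp {grasp!r} does not contain both weights (found {sorted(present)})"
        )
    return subset


def build_segments(
    trials: list[EmgTrial], cfg: RunConfig, reach_fraction: float
) -> list[Segment]:
    """Onset-anchor, truncate to the reach phase and window every trial."""
    segments: list[Segment] = []
    for tid, trial in enumerate(trials):
        onset = detect_onset(trial, cfg=cfg)
        truncated = truncate_reach_phase(trial, onset, reach_fraction)
        segments.extend(
            segment_windows(
                truncated, cfg.window_samples, cfg.step_samples, trial_id=tid
            )
        )
    return segments


def confusion(
    y_true: np.ndarray, y_pred: np.ndarray, classes: list
) -> tuple[np.ndarray, np.ndarray]:
    """Counts matrix (true rows x predicted columns) and its row-normalization."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("true and predicted label lists differ in length")
    k = len(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[index[t], index[p]] += 1
    rows = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, rows, out=np.zeros((k, k), dtype=float), where=rows > 0
    )
    return counts, normalized


def _fold_seed(seed: int, fold: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(fold,))
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


def _segment_stats(segments: list[Segment], idx: np.ndarray):
    data = np.concatenate([segments[i].data for i in idx], axis=0)
    lo, hi = data.min(axis=0), data.max(axis=0)
    if np.any(hi <= lo):
        raise ValueError("degenerate channel in training segments")
    return lo, hi


def _normalize_segment_data(segments, idx, lo, hi):
    out = []
    for i in idx:
        s = segments[i]
        out.append(
            Segment(
                data=np.clip((s.data - lo) / (hi - lo), 0.0, 1.0),
                grasp=s.grasp,
                weight=s.weight,
                subject=s.subject,
                repetition=s.repetition,
                start=s.start,
                trial_id=s.trial_id,
            )
        )
    return out


def cross_validate(
    trials: list[EmgTrial],
    method: str,
    task: str = "grasp6",
    cfg: RunConfig | None = None,
    seed: int = 0,
    grasp: str | None = None,
    reach_fraction: float | None = None,
    fold_mode: str = "random_segment",
    permute_labels: bool = False,
) -> CvResult:
    """Full k-fold evaluation of one method on one task.

    ``permute_labels`` shuffles the segment labels once (seeded) before
    folding, giving the chance-level control.
    """
    cfg = cfg or RunConfig()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}")
    if task == "weight2":
        if grasp is None:
            raise ValueError("weight2 task needs a grasp")
        trials = weight_binary_task(trials, grasp)
        label_attr, class_order = "weight", list(WEIGHTS)
    else:
        label_attr, class_order = "grasp", list(GRASPS)
    reach_fraction = (
        cfg.reach_fraction_healthy if reach_fraction is None else reach_fraction
    )

    if cfg.norm_scope == "all_trials":
        stats = fit_normalization(trials, scope="all_trials")
        prepared = [apply_normalization(t, stats) for t in trials]
    else:
        prepared = trials  # normalization is fitted per fold below

    segments = build_segments(prepared, cfg, reach_fraction)
    labels = np.array([getattr(s, label_attr) for s in segments])
    if permute_labels:
        perm_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(7919,))
        )
        labels = perm_rng.permutation(labels)
    classes = [c for c in class_order if c in set(labels)]
    plan = make_folds(segments, cfg.k_folds, fold_mode, seed)
    logger.info(
        "cross-validating %s / %s on %d segments (%d folds)",
        method,
        task,
        len(segments),
        cfg.k_folds,
    )

    # feature extraction is segment-local (no fitting), so with the global
    # normalization scope it can be computed once for all folds
    global_scope = cfg.norm_scope == "all_trials"
    if global_scope:
        if method == "pca-cnn":
            vectors_all = segment_spec_vectors(segments, cfg)
        else:
            tdar_all = np.stack([extract_tdar(s, cfg) for s in segments])

    fold_accuracies, fold_predictions = [], []
    y_true_all, y_pred_all = [], []
    for fold, (train_idx, test_idx) in enumerate(plan.folds()):
        if global_scope:
            if method == "pca-cnn":
                train_vec, test_vec = vectors_all[train_idx], vectors_all[test_idx]
            else:
                train_feat, test_feat = tdar_all[train_idx], tdar_all[test_idx]
        else:
            lo, hi = _segment_stats(segments, train_idx)
            train_segs = _normalize_segment_data(segments, train_idx, lo, hi)
            test_segs = _normalize_segment_data(segments, test_idx, lo, hi)
            if method == "pca-cnn":
                train_vec = segment_spec_vectors(train_segs, cfg)
                test_vec = segment_spec_vectors(test_segs, cfg)
            else:
                train_feat = np.stack([extract_tdar(s, cfg) for s in train_segs])
                test_feat = np.stack([extract_tdar(s, cfg) for s in test_segs])

        fseed = _fold_seed(seed, fold)
        if method == "pca-cnn":
            if not cfg.pca_per_channel:
                train_vec = train_vec.reshape(train_vec.shape[0], -1, 1)
                test_vec = test_vec.reshape(test_vec.shape[0], -1, 1)
            pca = pca_grid.fit_pca(train_vec, cfg)
            grids_train = pca_grid.grids_from_scores(
                pca_grid.transform(pca, train_vec), cfg.grid_side
            )
            grids_test = pca_grid.grids_from_scores(
                pca_grid.transform(pca, test_vec), cfg.grid_side
            )
            spec = build_cnn(grids_train.shape[3], len(classes), cfg)
            model = train_cnn(spec, grids_train, labels[train_idx], fseed, cfg)
            y_pred, _ = predict(model, grids_test)
        else:
            model = train_svm(train_feat, labels[train_idx], cfg, fseed)
            y_pred, _ = predict(model, test_feat)

        y_true = labels[test_idx]
        acc = float(np.mean(y_pred == y_true))
        fold_accuracies.append(acc)
        fold_predictions.append(
            {
                "fold": fold,
                "test_indices": test_idx.tolist(),
                "true": list(map(str, y_true)),
                "predicted": list(map(str, y_pred)),
            }
        )
        y_true_all.append(y_true)
        y_pred_all.append(np.asarray(y_pred))
        logger.info("fold %d: accuracy %.3f", fold, acc)

    counts, normalized = confusion(
        np.concatenate(y_true_all), np.concatenate(y_pred_all), classes
    )
    return CvResult(
        method=method,
        task=task,
        classes=classes,
        fold_accuracies=fold_accuracies,
        mean_accuracy=float(np.mean(fold_accuracies)),
        sd_accuracy=float(np.std(fold_accuracies, ddof=1)),
        confusion_counts=counts,
        confusion_normalized=normalized,
        n_segments=len(segments),
        fold_predictions=fold_predictions,
    )


RESULTS_SCHEMA_VERSION = 1


def report(results: list[CvResult], out_dir: str | Path) -> dict[str, Path]:
    """Write machine-readable results, an accuracy table and confusion heatmaps."""
    if not results:
        raise ValueError("no results to report")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    payload = {
        "schema_version": RESULTS_SCHEMA_VERSION,
        "results": [r.to_dict() for r in results],
    }
    paths["results_json"] = out_dir / "results.json"
    paths["results_json"].write_text(json.dumps(payload, indent=2) + "\n")

    table = pd.DataFrame(
        [
            {
                "method": r.method,
                "task": r.task,
                "n_folds": len(r.fold_accuracies),
                "n_segments": r.n_segments,
                "mean_accuracy": r.mean_accuracy,
                "sd_accuracy": r.sd_accuracy,
            }
            for r in results
        ]
    )
    paths["accuracy_table"] = out_dir / "accuracy_table.csv"
    table.to_csv(paths["accuracy_table"], index=False)

    for i, r in enumerate(results):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(r.confusion_normalized, cmap="viridis", vmin=0, vmax=1)
        ax.set_xticks(range(len(r.classes)), r.classes, rotation=45, ha="right")
        ax.set_yticks(range(len(r.classes)), r.classes)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        ax.set_title(f"{r.method} / {r.task}")
        fig.colorbar(im, ax=ax)
        fig.tight_layout()
        p = out_dir / f"confusion_{i}_{r.method.replace('-', '_')}_{r.task}.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths[f"heatmap_{i}"] = p
    return paths
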