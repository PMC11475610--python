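"""Soft-voting ensembles of probabilistic classifiers.

A fitted classifier contributes an N x K matrix of class probabilities.
Fusion is a convex combination of those matrices followed by a
per-sample argmax; the combination weights live on the unit simplex and
can be fixed (average voting), derived from hard labels (majority
voting), or searched with the Equilibrium Optimizer so that ensemble
accuracy on a held-out fitness set is maximized.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eo import EOConfig, optimize

__all__ = [
    "PredictionMatrix",
    "EnsembleWeights",
    "normalize_weights",
    "weighted_soft_vote",
    "fitness_accuracy",
    "optimize_ensemble_weights",
    "majority_vote",
    "average_vote",
    "read_prediction_csv",
    "write_prediction_csv",
    "read_labels_csv",
    "write_labels_csv",
]

_ROW_TOL = 1e-6


@dataclass
class PredictionMatrix:
    """Per-model class-probability matrix: one row per sample."""

    probabilities: np.ndarray
    model_name: str = "model"

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] < 1 or p.shape[1] < 2:
            raise ValueError("probabilities must be an N x K matrix with K >= 2")
        if np.any(p < -_ROW_TOL) or np.any(p > 1 + _ROW_TOL):
            raise ValueError(f"{self.model_name}: probabilities outside [0, 1]")
        if not np.allclose(p.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValueError(f"{self.model_name}: probability rows must sum to 1")
        self.probabilities = p

    @property
    def n_samples(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[1]

    def hard_labels(self) -> np.ndarray:
        """Per-sample argmax labels (ties -> lowest class index)."""
        return np.argmax(self.probabilities, axis=1)


@dataclass
class EnsembleWeights:
    """Non-negative per-model weights summing to 1."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("an ensemble needs at least 2 model weights")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1; use normalize_weights")
        self.weights = w

    def __len__(self) -> int:
        return self.weights.size

    def rounded(self, decimals: int = 2) -> np.ndarray:
        return np.round(self.weights, decimals)


def normalize_weights(raw: Sequence[float]) -> EnsembleWeights:
    """Project raw non-negative scores onto the unit simplex by scaling."""
    w = np.asarray(raw, dtype=float)
    if np.any(w < 0):
        raise ValueError("raw weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("at least one raw weight must be strictly positive")
    return EnsembleWeights(w / total)


def _check_shapes(matrices: Sequence[PredictionMatrix]) -> tuple[int, int]:
    if len(matrices) < 1:
        raise ValueError("at least one prediction matrix required")
    n, k = matrices[0].n_samples, matrices[0].n_classes
    for m in matrices[1:]:
        if (m.n_samples, m.n_classes) != (n, k):
            raise ValueError(
                f"shape mismatch: {m.model_name} is {m.probabilities.shape}, "
                f"expected {(n, k)}"
            )
    return n, k


def weighted_soft_vote(
    matrices: Sequence[PredictionMatrix], w: EnsembleWeights | Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """Fuse model probabilities with simplex weights and take the argmax.

    Returns the fused N x K matrix (rows again sum to 1, being convex
    combinations of stochastic rows) and the predicted label vector.
    """
    if isinstance(w, EnsembleWeights):
        weights = w.weights
    else:
        # raw sequences are accepted so a degenerate single-model
        # "ensemble" with weight (1,) is usable
        weights = np.asarray(w, float)
        if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
    _check_shapes(matrices)
    if weights.size != len(matrices):
        raise ValueError("one weight per model required")
    stack = np.stack([m.probabilities for m in matrices])  # M x N x K
    fused = np.tensordot(weights, stack, axes=1)
    return fused, np.argmax(fused, axis=1)


def fitness_accuracy(
    matrices: Sequence[PredictionMatrix],
    w: EnsembleWeights | Sequence[float],
    truth: Sequence[int],
) -> float:
    """Accuracy of the weighted soft vote against ground-truth labels.

    This is the objective EO maximizes when searching ensemble weights.
    """
    truth = np.asarray(truth, dtype=int)
    n, k = _check_shapes(matrices)
    if truth.shape != (n,):
        raise ValueError("truth labels must align with the prediction rows")
    if truth.min() < 0 or truth.max() >= k:
        raise ValueError("truth labels out of class range")
    _, predicted = weighted_soft_vote(matrices, w)
    return float(np.mean(predicted == truth))


def optimize_ensemble_weights(
    matrices: Sequence[PredictionMatrix],
    truth: Sequence[int],
    config: EOConfig | None = None,
    *,
    seed: int = 0,
) -> tuple[EnsembleWeights, float]:
    """Search simplex weights maximizing fused accuracy with EO.

    The raw search space is the box [0, 1]^M; every raw vector is
    normalized onto the simplex before scoring, and the returned weights
    are the normalized optimum.  The initial population is warm-started
    with the M degenerate one-model vectors and the uniform vector, all
    feasible points, so with elitism the optimized fitness can never
    fall below any single model's accuracy or the plain average vote.
    """
    m = len(matrices)
    if m < 2:
        raise ValueError("an ensemble needs at least 2 models")
    _check_shapes(matrices)
    if config is None:
        config = EOConfig(dimension=m, seed=seed)
    elif config.dimension != m:
        raise ValueError(f"EOConfig.dimension must equal the model count {m}")

    truth = np.asarray(truth, dtype=int)
    stack = np.stack([mat.probabilities for mat in matrices])

    def fitness(raw: np.ndarray) -> float:
        total = raw.sum()
        w = raw / total if total > 0 else np.full(m, 1.0 / m)
        fused = np.tensordot(w, stack, axes=1)
        return float(np.mean(np.argmax(fused, axis=1) == truth))

    warm = np.vstack([np.eye(m), np.full((1, m), 1.0)])
    result = optimize(fitness, config, init_positions=warm)
    weights = normalize_weights(np.where(result.best_position > 0, result.best_position, 0))
    return weights, result.best_fitness


def majority_vote(matrices: Sequence[PredictionMatrix]) -> np.ndarray:
    """Per-sample mode of the models' hard labels (ties -> lowest index)."""
    if len(matrices) < 2:
        raise ValueError("majority voting needs at least 2 models")
    _, k = _check_shapes(matrices)
    hard = np.stack([m.hard_labels() for m in matrices])  # M x N
    counts = np.apply_along_axis(np.bincount, 0, hard, minlength=k)  # K x N
    return np.argmax(counts, axis=0)


def average_vote(matrices: Sequence[PredictionMatrix]) -> np.ndarray:
    """Unweighted soft vote: fuse with uniform weights, take the argmax."""
    if len(matrices) < 2:
        raise ValueError("average voting needs at least 2 models")
    uniform = EnsembleWeights(np.full(len(matrices), 1.0 / len(matrices)))
    _, predicted = weighted_soft_vote(matrices, uniform)
    return predicted


# ---------------------------------------------------------------------------
# CSV interchange: one file per model, header = class names, row per sample.

def write_prediction_csv(path: str | Path, matrix: PredictionMatrix,
                         class_names: Sequence[str] | None = None) -> None:
    k = matrix.n_classes
    cols = list(class_names) if class_names is not None else [f"class_{i}" for i in range(k)]
    if len(cols) != k:
        raise ValueError("one column name per class required")
    pd.DataFrame(matrix.probabilities, columns=cols).to_csv(path, index=False)


def read_prediction_csv(path: str | Path, model_name: str | None = None) -> PredictionMatrix:
    df = pd.read_csv(path)
    name = model_name if model_name is not None else Path(path).stem
    return PredictionMatrix(df.to_numpy(dtype=float), model_name=name)


def write_labels_csv(path: str | Path, labels: Sequence[int]) -> None:
    pd.DataFrame({"label": np.asarray(labels, dtype=int)}).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["label"].to_numpy(dtype=int)
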