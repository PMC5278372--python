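"""Analytic Hierarchy Process (AHP) weight derivation.

Weights are the normalized principal eigenvector of a positive reciprocal
pairwise-comparison matrix, computed by power iteration. Consistency is
summarized by the consistency index CI = (lambda_max - n)/(n - 1) and the
consistency ratio CR = CI / RI(n), with RI the standard random-index table.
A CR above 0.10 signals a judgement matrix too inconsistent to trust; the
function warns but still returns the weights.

Because published studies often report only the resulting weights and not the
comparison matrices behind them, :func:`weight_vector` also accepts weights
directly (validated to be non-negative and to sum to one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["PairwiseMatrix", "WeightVector", "ahp_weights", "weight_vector", "RANDOM_INDEX"]

#: Saaty random consistency index for matrix orders 1..10.
RANDOM_INDEX = (0.0, 0.0, 0.58, 0.90, 1.12, 1.24, 1.32, 1.41, 1.45, 1.49)

_RECIPROCITY_TOL = 1e-9


@dataclass(frozen=True)
class PairwiseMatrix:
    """Positive reciprocal comparison matrix over n labelled items."""

    labels: tuple[str, ...]
    a: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        n = len(self.labels)
        if a.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if np.any(a <= 0):
            raise ValueError("pairwise comparisons must be positive")
        if not np.allclose(np.diag(a), 1.0, atol=_RECIPROCITY_TOL):
            raise ValueError("diagonal of a pairwise matrix must be 1")
        if not np.allclose(a * a.T, 1.0, atol=1e-6):
            raise ValueError("matrix is not reciprocal (a[j,i] != 1/a[i,j])")

    @property
    def n(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path) -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(df.columns), df.to_numpy(dtype=float))


@dataclass(frozen=True)
class WeightVector:
    """Non-negative weights over labelled items, summing to one."""

    labels: tuple[str, ...]
    w: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.w, dtype=float)
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if w.shape != (len(self.labels),):
            raise ValueError("weight length does not match labels")
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum():.12f})")

    def as_series(self) -> pd.Series:
        return pd.Series(self.w, index=list(self.labels), name="weight")

    def __getitem__(self, label: str) -> float:
        return float(self.w[self.labels.index(label)])


def weight_vector(labels: Sequence[str], w: Sequence[float], *, normalize: bool = False) -> WeightVector:
    """Build a WeightVector, optionally normalizing to unit sum first."""
    w = np.asarray(w, dtype=float)
    if normalize:
        s = w.sum()
        if s <= 0:
            raise ValueError("cannot normalize weights with non-positive sum")
        w = w / s
    return WeightVector(tuple(labels), w)


def ahp_weights(matrix: PairwiseMatrix, *, tol: float = 1e-10, max_iter: int = 10000):
    """Derive weights from a pairwise matrix by power iteration.

    Returns ``(WeightVector, lambda_max, CI, CR)``. CR is defined as 0 for
    n <= 2 (such matrices are always consistent). Emits a UserWarning when
    CR > 0.10.
    """
    a = matrix.a
    n = matrix.n
    if not (2 <= n <= 10):
        raise ValueError("AHP supports 2 to 10 items")
    w = np.full(n, 1.0 / n)
    lam = float(n)
    for _ in range(max_iter):
        v = a @ w
        lam = float(v.sum())  # since w sums to 1, Rayleigh-style estimate
        v = v / v.sum()
        if np.max(np.abs(v - w)) < tol:
            w = v
            break
        w = v
    # lambda_max from the converged eigenvector: mean of (Aw)_i / w_i
    ratios = (a @ w) / w
    lambda_max = float(ratios.mean())
    ci = (lambda_max - n) / (n - 1) if n > 1 else 0.0
    cr = 0.0 if n <= 2 else ci / RANDOM_INDEX[n - 1]
    if cr > 0.10:
        warnings.warn(
            f"consistency ratio CR={cr:.3f} exceeds 0.10; judgements are inconsistent",
            UserWarning,
            stacklevel=2,
        )
    return WeightVector(matrix.labels, w), lambda_max, ci, cr
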