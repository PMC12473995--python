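"""Entropy weighting: min-max standardization, information entropy, weights.

The entropy weight method assigns each indicator an objective weight that
grows with the dispersion of its standardized values across samples: an
indicator whose proportions p_ij are nearly uniform carries little
information (entropy E_j near 1) and gets a small weight.

Pipeline:

1. min-max standardize each column to [0, 1], reversing cost columns so that
   1 always means "best" (``standardize_minmax``);
2. E_j = -k * sum_i p_ij ln p_ij with p_ij = x*_ij / sum_i x*_ij and
   k = 1/ln(n), using the convention 0*ln 0 = 0 (``compute_entropy``);
3. w_j = (1 - E_j) / sum_j (1 - E_j) (``compute_weights``).

A constant column standardizes to all ones (uniform proportions, E_j = 1,
weight 0) rather than dividing by zero — the correct "no information"
outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .indicators import INDICATORS, POLARITY, DataMatrix

__all__ = [
    "StandardizedMatrix",
    "WeightVector",
    "standardize_minmax",
    "compute_entropy",
    "compute_weights",
    "entropy_weights",
    "uniform_weights",
]

NORM_TOL = 1e-12  # absolute tolerance on sum(w) == 1


class DegenerateWeightsError(ValueError):
    """All indicators carry zero information (every E_j == 1).

    Callers that want to proceed anyway should fall back to
    :func:`uniform_weights`.
    """


@dataclass
class StandardizedMatrix:
    """Min-max standardized values in [0, 1] with a link to the source matrix."""

    values: np.ndarray
    columns: tuple[str, ...]
    source: DataMatrix | None = field(default=None, repr=False)


@dataclass
class WeightVector:
    """Entropy-derived indicator weights with the audit trail behind them."""

    weights: np.ndarray
    entropy: np.ndarray
    proportions: np.ndarray = field(repr=False)
    k: float = float("nan")
    columns: tuple[str, ...] = INDICATORS

    def __post_init__(self) -> None:
        if np.any(self.weights < 0):
            raise ValueError("negative weight")
        if abs(self.weights.sum() - 1.0) > NORM_TOL:
            raise ValueError(f"weights sum to {self.weights.sum()!r}, not 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.columns, map(float, self.weights)))

    def __getitem__(self, indicator: str) -> float:
        return float(self.weights[self.columns.index(indicator)])


def standardize_minmax(matrix: DataMatrix | np.ndarray,
                       polarity: dict[str, str] | None = None) -> StandardizedMatrix:
    """Min-max standardize each indicator column to [0, 1].

    Benefit columns map to ``(x - min) / (max - min)``; cost columns to
    ``(max - x) / (max - min)``.  Constant columns map to all ones.
    """
    if isinstance(matrix, DataMatrix):
        values, columns, source = matrix.values, matrix.columns, matrix
    else:
        values = np.asarray(matrix, dtype=float)
        columns = INDICATORS[: values.shape[1]]
        source = None
    pol = polarity or POLARITY
    if values.shape[0] < 2:
        raise ValueError("standardization needs n >= 2 samples")
    out = np.empty_like(values, dtype=float)
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    for j, col in enumerate(columns):
        span = hi[j] - lo[j]
        if span == 0.0:
            out[:, j] = 1.0
        elif pol[col] == "benefit":
            out[:, j] = (values[:, j] - lo[j]) / span
        else:
            out[:, j] = (hi[j] - values[:, j]) / span
    return StandardizedMatrix(values=out, columns=tuple(columns), source=source)


def compute_entropy(std: StandardizedMatrix | np.ndarray) -> np.ndarray:
    """Information entropy E_j of each standardized column, in [0, 1]."""
    values = std.values if isinstance(std, StandardizedMatrix) else np.asarray(std, float)
    n = values.shape[0]
    if n < 2:
        raise ValueError("entropy undefined for n < 2 (k = 1/ln(n))")
    colsum = values.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("standardized column sums must be positive")
    p = values / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    k = 1.0 / np.log(n)
    return -k * plogp.sum(axis=0)


def compute_weights(entropy: np.ndarray,
                    proportions: np.ndarray | None = None,
                    columns: tuple[str, ...] = INDICATORS,
                    n: int | None = None) -> WeightVector:
    """Weights w_j = (1 - E_j) / sum_j (1 - E_j).

    Raises
    ------
    DegenerateWeightsError
        If every E_j equals 1 (no column carries information); fall back to
        :func:`uniform_weights` if a weight vector is still needed.
    """
    entropy = np.asarray(entropy, dtype=float)
    info = 1.0 - entropy
    # numerical fuzz from p*log(p) can leave E_j a hair above 1
    info = np.where(np.abs(info) < 1e-14, 0.0, info)
    total = info.sum()
    if total <= 0:
        raise DegenerateWeightsError(
            "all indicators have entropy 1 (zero information); "
            "use uniform_weights() as a fallback"
        )
    w = info / total
    if proportions is None:
        proportions = np.empty((0, len(entropy)))
    k = 1.0 / np.log(n) if n and n > 1 else float("nan")
    return WeightVector(weights=w, entropy=entropy, proportions=proportions,
                        k=k, columns=tuple(columns[: len(entropy)]))


def entropy_weights(matrix: DataMatrix) -> WeightVector:
    """Full pipeline: standardize, entropy, weights — one call."""
    std = standardize_minmax(matrix)
    e = compute_entropy(std)
    colsum = std.values.sum(axis=0)
    p = std.values / colsum
    return compute_weights(e, proportions=p, columns=std.columns, n=matrix.n)


def uniform_weights(columns: tuple[str, ...] = INDICATORS) -> WeightVector:
    """Equal weights 1/m — the explicit fallback when entropy is degenerate."""
    m = len(columns)
    return WeightVector(
        weights=np.full(m, 1.0 / m),
        entropy=np.full(m, np.nan),
        proportions=np.empty((0, m)),
        columns=tuple(columns),
    )
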