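"""Ordinal-pattern symbolization and generalized weighted complexity measures.

A time series is sliced into overlapping segments of ``D`` samples spaced
``tau`` apart; each segment is mapped to the permutation (ordinal pattern)
describing the rank order of its samples.  The empirical distribution of the
``D!`` patterns yields permutation entropy; weighting each segment's
contribution by its local variance raised to ``q/2`` generalizes it to a
family of amplitude-sensitive distributions.  ``q = 0`` recovers plain
pattern counting, ``q = 2`` the variance-weighted variant; negative ``q``
emphasizes low-amplitude segments, positive ``q`` high-amplitude ones.

From any pattern distribution the module computes Shannon entropy ``S``,
normalized entropy ``H = S / ln(D!)``, the disequilibrium ``Q`` (normalized
Jensen-Shannon divergence from the uniform distribution), and the statistical
complexity ``C = Q * H``, which vanishes for both perfectly ordered and
perfectly random signals.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from .errors import DegenerateSignalError, InvalidDistributionError, NonFiniteDataError

__all__ = [
    "OrdinalConfig",
    "Pattern",
    "PatternDistribution",
    "ComplexityPoint",
    "QPoint",
    "enumerate_patterns",
    "encode_pattern",
    "segment_weight",
    "ordinal_distribution",
    "shannon_entropy",
    "normalized_entropy",
    "jensen_shannon_divergence",
    "statistical_complexity",
    "max_divergence",
    "q_sweep",
]

#: Absolute tolerance on |sum(p) - 1| below which a vector counts as normalized.
NORMALIZATION_ATOL = 1e-9

_MAX_D = 8  # D! grows too fast beyond this for pattern statistics to be meaningful


@dataclass(frozen=True)
class OrdinalConfig:
    """Embedding parameters shared by every downstream computation.

    Parameters
    ----------
    D : int
        Number of samples per pattern (embedding dimension), 2..8.
    tau : int
        Delay in samples between consecutive pattern samples.
    q_grid : tuple of float
        Strictly increasing entropic indices to sweep.  The default is the
        integer grid -10..10 (21 values).
    """

    D: int = 4
    tau: int = 1
    q_grid: tuple[float, ...] = tuple(float(q) for q in range(-10, 11))

    def __post_init__(self) -> None:
        if not (2 <= int(self.D) <= _MAX_D):
            raise ValueError(f"D must be in [2, {_MAX_D}], got {self.D}")
        if int(self.tau) < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        grid = tuple(float(q) for q in self.q_grid)
        if len(grid) == 0:
            raise ValueError("q_grid must be non-empty")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("q_grid must be strictly increasing")
        object.__setattr__(self, "q_grid", grid)

    @property
    def n_patterns(self) -> int:
        return math.factorial(self.D)

    @property
    def min_length(self) -> int:
        """Shortest series yielding at least one segment."""
        return (self.D - 1) * self.tau + 1


@dataclass(frozen=True)
class Pattern:
    """An ordinal pattern: the time-ordered tuple of ranks of a segment.

    ``ranks[t]`` is the rank of the ``t``-th sample among the segment's values
    (0 = smallest), so an increasing segment is ``(0, 1, 2, 3)``.  ``index``
    is the pattern's position in the lexicographic enumeration of all ``D!``
    rank tuples and is stable across runs.
    """

    ranks: tuple[int, ...]
    index: int

    @property
    def name(self) -> str:
        """Compact label, e.g. ``'0123'`` for the increasing pattern."""
        return "".join(str(r) for r in self.ranks)


@lru_cache(maxsize=None)
def enumerate_patterns(D: int) -> tuple[Pattern, ...]:
    """All ``D!`` ordinal patterns in lexicographic order of rank tuples."""
    if not (2 <= D <= _MAX_D):
        raise ValueError(f"D must be in [2, {_MAX_D}], got {D}")
    return tuple(
        Pattern(ranks=perm, index=i)
        for i, perm in enumerate(itertools.permutations(range(D)))
    )


@lru_cache(maxsize=None)
def _pattern_lookup(D: int) -> dict[tuple[int, ...], Pattern]:
    return {p.ranks: p for p in enumerate_patterns(D)}


def _as_segment(segment: Sequence[float]) -> np.ndarray:
    seg = np.asarray(segment, dtype=float)
    if seg.ndim != 1:
        raise ValueError("segment must be one-dimensional")
    if not np.all(np.isfinite(seg)):
        raise NonFiniteDataError("segment contains non-finite values")
    return seg


def encode_pattern(segment: Sequence[float]) -> Pattern:
    """Ordinal pattern of a length-``D`` segment.

    Ties are broken by temporal order: of two equal samples the earlier one
    receives the lower rank (stable-sort convention).
    """
    seg = _as_segment(segment)
    D = seg.size
    if not (2 <= D <= _MAX_D):
        raise ValueError(f"segment length must be in [2, {_MAX_D}], got {D}")
    order = np.argsort(seg, kind="stable")
    ranks = np.empty(D, dtype=int)
    ranks[order] = np.arange(D)
    return _pattern_lookup(D)[tuple(int(r) for r in ranks)]


def segment_weight(segment: Sequence[float]) -> float:
    """Amplitude weight of a segment: the population variance of its samples."""
    seg = _as_segment(segment)
    if seg.size < 2:
        raise ValueError("segment must contain at least two samples")
    return float(np.var(seg))


@dataclass(frozen=True)
class PatternDistribution:
    """Probability vector over the ``D!`` ordinal patterns at one entropic index.

    ``probs[i]`` corresponds to ``enumerate_patterns(D)[i]``.  ``n_segments``
    is the number of windows the series yielded; ``n_degenerate`` counts
    zero-variance windows that had to be excluded (only possible at q < 0).
    """

    probs: np.ndarray
    q: float
    n_segments: int
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if self.n_segments > 0:
            _check_normalized(probs)

    @classmethod
    def uniform(cls, M: int, q: float = 0.0) -> "PatternDistribution":
        """Uniform reference distribution over ``M`` patterns."""
        return cls(probs=np.full(M, 1.0 / M), q=q, n_segments=0)

    @classmethod
    def delta(cls, M: int, index: int = 0, q: float = 0.0) -> "PatternDistribution":
        """Fully ordered reference: all mass on a single pattern."""
        p = np.zeros(M)
        p[index] = 1.0
        return cls(probs=p, q=q, n_segments=0)

    def __len__(self) -> int:
        return self.probs.size


@dataclass(frozen=True)
class ComplexityPoint:
    """Entropy/complexity summary of one pattern distribution.

    S is Shannon entropy in nats, H = S/ln(D!) the normalized entropy,
    Q the disequilibrium (normalized Jensen-Shannon divergence from uniform),
    C = Q * H the statistical complexity, and q the entropic index used.
    """

    S: float
    H: float
    Q: float
    C: float
    q: float


@dataclass(frozen=True)
class QPoint:
    """One entry of a q-sweep: the distribution and its complexity summary."""

    q: float
    distribution: PatternDistribution
    complexity: ComplexityPoint


def _check_normalized(probs: np.ndarray) -> None:
    if np.any(probs < -NORMALIZATION_ATOL):
        raise InvalidDistributionError("probabilities must be non-negative")
    total = float(probs.sum())
    if abs(total - 1.0) > NORMALIZATION_ATOL:
        raise InvalidDistributionError(
            f"probabilities sum to {total!r}, expected 1 within {NORMALIZATION_ATOL}"
        )


def _symbolize(series: Sequence[float], D: int, tau: int) -> tuple[np.ndarray, np.ndarray]:
    """Pattern index and variance weight of every overlapping segment.

    Returns ``(pattern_indices, weights)``, each of length ``T - (D-1)*tau``.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise NonFiniteDataError("series contains non-finite values")
    n = x.size - (D - 1) * tau
    if n < 1:
        raise ValueError(
            f"series of length {x.size} too short for D={D}, tau={tau} "
            f"(need at least {(D - 1) * tau + 1} samples)"
        )
    idx = np.arange(n)[:, None] + tau * np.arange(D)[None, :]
    seg = x[idx]

    order = np.argsort(seg, axis=1, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.broadcast_to(np.arange(D), (n, D)), axis=1)

    # Lexicographic (Lehmer) index: sum_j c_j * (D-1-j)! with
    # c_j = #{k > j : ranks[k] < ranks[j]}.
    upper = np.triu(np.ones((D, D), dtype=bool), k=1)
    greater = ranks[:, :, None] > ranks[:, None, :]
    c = (greater & upper).sum(axis=2)
    factorials = np.array([math.factorial(D - 1 - j) for j in range(D)])
    pattern_idx = c @ factorials

    weights = seg.var(axis=1)
    return pattern_idx.astype(np.intp), weights


def _weighted_probs(
    pattern_idx: np.ndarray, weights: np.ndarray, q: float, M: int
) -> tuple[np.ndarray, int]:
    """Generalized pattern probabilities p(pi, q) from symbolized segments.

    Weights enter as w^(q/2), computed in log space to avoid overflow at
    large |q|.  Zero-variance segments contribute weight 1 at q = 0 (the
    w^0 := 1 convention, reducing to plain counting), weight 0 at q > 0, and
    are excluded at q < 0 where w^(q/2) diverges; the exclusion count is
    returned.  Raises ``DegenerateSignalError`` if q != 0 and every segment
    has zero variance.
    """
    n = pattern_idx.size
    if q == 0:
        counts = np.bincount(pattern_idx, minlength=M).astype(float)
        return counts / n, 0

    positive = weights > 0
    n_pos = int(positive.sum())
    if n_pos == 0:
        raise DegenerateSignalError(
            f"all {n} segments have zero variance; p(pi, q) undefined for q={q}",
            n_segments=n,
        )
    n_degenerate = (n - n_pos) if q < 0 else 0

    log_w = np.full(n, -np.inf)
    log_w[positive] = (q / 2.0) * np.log(weights[positive])
    log_w -= log_w[positive].max()
    wq = np.exp(log_w)  # exp(-inf) = 0 drops zero-variance segments
    probs = np.bincount(pattern_idx, weights=wq, minlength=M) / wq.sum()
    return probs, n_degenerate


def ordinal_distribution(
    series: Sequence[float], config: OrdinalConfig, q: float = 0.0
) -> PatternDistribution:
    """Generalized weighted ordinal-pattern distribution of a series at one q."""
    pattern_idx, weights = _symbolize(series, config.D, config.tau)
    probs, n_degenerate = _weighted_probs(pattern_idx, weights, q, config.n_patterns)
    return PatternDistribution(
        probs=probs, q=float(q), n_segments=pattern_idx.size, n_degenerate=n_degenerate
    )


def _entropy(p: np.ndarray) -> float:
    nz = p[p > 0]
    return max(float(-(nz * np.log(nz)).sum()), 0.0)


def shannon_entropy(dist: PatternDistribution) -> float:
    """Shannon entropy of the pattern distribution, in nats (0 log 0 := 0)."""
    _check_normalized(dist.probs)
    return _entropy(dist.probs)


def normalized_entropy(dist: PatternDistribution) -> float:
    """Entropy normalized by its maximum ln(D!); lies in [0, 1]."""
    return shannon_entropy(dist) / math.log(len(dist))


def jensen_shannon_divergence(P: PatternDistribution, U: PatternDistribution) -> float:
    """Jensen-Shannon divergence S[(P+U)/2] - (S[P] + S[U]) / 2.

    Symmetric, non-negative, and zero iff the distributions coincide.
    """
    if len(P) != len(U):
        raise ValueError(f"length mismatch: {len(P)} vs {len(U)}")
    _check_normalized(P.probs)
    _check_normalized(U.probs)
    mid = 0.5 * (P.probs + U.probs)
    return _entropy(mid) - 0.5 * (_entropy(P.probs) + _entropy(U.probs))


@lru_cache(maxsize=None)
def max_divergence(M: int) -> float:
    """Jensen-Shannon divergence between a delta and the uniform over M states.

    Closed form: -(1/2) [ ((M+1)/M) ln(M+1) - 2 ln(2M) + ln M ].  Its inverse
    is the normalization constant Q0 that makes the disequilibrium Q equal 1
    for a fully ordered distribution.
    """
    return -0.5 * (((M + 1) / M) * math.log(M + 1) - 2 * math.log(2 * M) + math.log(M))


def statistical_complexity(dist: PatternDistribution) -> ComplexityPoint:
    """Entropy, disequilibrium and complexity C = Q * H of a distribution."""
    M = len(dist)
    S = shannon_entropy(dist)
    H = S / math.log(M)
    U = PatternDistribution.uniform(M, q=dist.q)
    Q = jensen_shannon_divergence(dist, U) / max_divergence(M)
    return ComplexityPoint(S=S, H=H, Q=Q, C=Q * H, q=dist.q)


def q_sweep(series: Sequence[float], config: OrdinalConfig) -> list[QPoint]:
    """Distribution and complexity at every q of the config's grid.

    The series is symbolized once; each grid value then reweights the same
    segments, so the result is identical to independent single-q calls.
    """
    pattern_idx, weights = _symbolize(series, config.D, config.tau)
    M = config.n_patterns
    out = []
    for q in config.q_grid:
        probs, n_degenerate = _weighted_probs(pattern_idx, weights, q, M)
        dist = PatternDistribution(
            probs=probs, q=q, n_segments=pattern_idx.size, n_degenerate=n_degenerate
        )
        out.append(QPoint(q=q, distribution=dist, complexity=statistical_complexity(dist)))
    return out
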