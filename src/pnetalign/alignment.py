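"""Similarity propagation and one-to-one alignment extraction.

The node-pair similarity vector R solves R = alpha * E(A) R + (1 - alpha) * S
where E(A) is the expected support matrix and S the normalized sequence
similarity vector; R is found by power iteration with per-step L1
renormalization.  The alignment is then the maximum-weight bipartite matching
of R read as an m x n weight grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
from scipy.optimize import linear_sum_assignment

from .networks import UncertainNetwork
from .support import SupportMatrix, expected_support_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityVector",
    "SeqSimilarity",
    "IterationConfig",
    "Alignment",
    "PowerIterationInfo",
    "normalize_seqsim",
    "power_iterate",
    "extract_alignment",
    "align",
]

# lexicographic tie-break refinement is skipped above this many weight entries
_LEX_REFINE_LIMIT = 4096
_WEIGHT_TOL = 1e-9


@dataclass
class SimilarityVector:
    """Nonnegative m x n score grid, readable as the flattened (row-major) vector."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D grid")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("similarity values must be finite and nonnegative")
        self.values = values

    @property
    def m(self) -> int:
        return self.values.shape[0]

    @property
    def n(self) -> int:
        return self.values.shape[1]

    @property
    def flat(self) -> np.ndarray:
        return self.values.ravel()

    @classmethod
    def uniform(cls, m: int, n: int) -> "SimilarityVector":
        return cls(np.full((m, n), 1.0 / (m * n)))

    @classmethod
    def from_flat(cls, vec: np.ndarray, m: int, n: int) -> "SimilarityVector":
        return cls(np.asarray(vec, dtype=float).reshape(m, n))


class SeqSimilarity:
    """Sparse table of pairwise sequence-similarity scores; missing pairs are 0."""

    def __init__(self, pairs: Mapping[tuple[str, str], float] | None = None) -> None:
        self._scores: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), s in pairs.items():
                self.set(a, b, s)

    def set(self, a: str, b: str, score: float) -> None:
        score = float(score)
        if not np.isfinite(score) or score < 0:
            raise ValueError(f"sequence similarity must be finite and >= 0, got {score}")
        self._scores[(a, b)] = score

    def get(self, a: str, b: str) -> float:
        return self._scores.get((a, b), 0.0)

    def items(self):
        return self._scores.items()

    def __len__(self) -> int:
        return len(self._scores)


@dataclass(frozen=True)
class IterationConfig:
    alpha: float = 0.6
    eps: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.eps <= 0:
            raise ValueError(f"eps must be > 0, got {self.eps}")
        if self.max_iter < 1:
            raise ValueError(f"max_iter must be >= 1, got {self.max_iter}")


@dataclass(frozen=True)
class PowerIterationInfo:
    iterations: int
    residual: float
    converged: bool


@dataclass
class Alignment:
    """One-to-one matching across the two node sets with per-pair scores."""

    pairs: list[tuple[str, str]]
    pair_scores: dict[tuple[str, str], float]
    total_weight: float
    nodes1: list[str] | None = field(default=None, repr=False)
    nodes2: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("alignment is not one-to-one")
        self.pairs = sorted(self.pairs)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(self.pairs)

    def as_mapping(self) -> dict[str, str]:
        return dict(self.pairs)


def normalize_seqsim(
    raw: SeqSimilarity | None, nodes1: list[str], nodes2: list[str]
) -> SimilarityVector:
    """L1-normalize the score table onto the m x n grid.

    An empty or all-zero table falls back to the uniform vector 1/(m*n).
    """
    m, n = len(nodes1), len(nodes2)
    if raw is None or len(raw) == 0:
        return SimilarityVector.uniform(m, n)
    idx1 = {v: i for i, v in enumerate(nodes1)}
    idx2 = {v: i for i, v in enumerate(nodes2)}
    grid = np.zeros((m, n))
    for (a, b), s in raw.items():
        if s < 0:
            raise ValueError(f"negative sequence similarity for pair ({a!r}, {b!r})")
        if a in idx1 and b in idx2:
            grid[idx1[a], idx2[b]] = s
    total = grid.sum()
    if total == 0.0:
        return SimilarityVector.uniform(m, n)
    return SimilarityVector(grid / total)


def power_iterate(
    EA: SupportMatrix, Evec: SimilarityVector, cfg: IterationConfig = IterationConfig()
) -> tuple[SimilarityVector, PowerIterationInfo]:
    """Iterate R <- alpha*E(A)*R + (1-alpha)*Evec from the uniform start.

    R is renormalized to L1 norm 1 each step; convergence is declared when
    the L1 difference between successive (renormalized) iterates drops to
    eps or below.  Non-convergence at max_iter is reported via the info
    flag, not raised.
    """
    m, n = EA.m, EA.n
    if (Evec.m, Evec.n) != (m, n):
        raise ValueError(
            f"dimension mismatch: support matrix is {m}x{n} pairs, "
            f"seqsim vector is {Evec.m}x{Evec.n}")
    evec = Evec.flat
    r = np.full(m * n, 1.0 / (m * n))
    alpha = cfg.alpha
    diff = np.inf
    iterations = 0
    for iterations in range(1, cfg.max_iter + 1):
        r_new = alpha * EA.matvec(r) + (1.0 - alpha) * evec
        if alpha > 0.0:
            # with alpha = 0 the update is exactly Evec (already L1 = 1);
            # renormalizing would only shuffle last-ulp bits
            norm = r_new.sum()
            if norm <= 0:
                raise ArithmeticError("iterate collapsed to zero; cannot renormalize")
            r_new /= norm
        diff = float(np.abs(r_new - r).sum())
        r = r_new
        if diff <= cfg.eps:
            break
    converged = diff <= cfg.eps
    if not converged:
        logger.warning("power iteration did not converge in %d iterations "
                       "(last L1 difference %.3g)", cfg.max_iter, diff)
    return (
        SimilarityVector.from_flat(r, m, n),
        PowerIterationInfo(iterations=iterations, residual=diff, converged=converged),
    )


def _lsa_weight(weights: np.ndarray) -> float:
    ri, ci = linear_sum_assignment(weights, maximize=True)
    return float(weights[ri, ci].sum())


def _lexicographic_refine(weights: np.ndarray, optimum: float) -> list[tuple[int, int]]:
    """Lexicographically smallest sorted pair list among maximum-weight matchings.

    Greedy: for each slot pick the smallest free (row, col) in lexicographic
    order whose fixing still allows total weight within _WEIGHT_TOL of the
    optimum (checked by re-solving the reduced assignment problem).
    """
    m, n = weights.shape
    k = min(m, n)
    tol = _WEIGHT_TOL * max(1.0, abs(optimum))
    free_rows = list(range(m))
    free_cols = list(range(n))
    fixed: list[tuple[int, int]] = []
    fixed_weight = 0.0
    for _ in range(k):
        chosen = None
        for i in free_rows:
            for j in free_cols:
                rest_rows = [r for r in free_rows if r != i]
                rest_cols = [c for c in free_cols if c != j]
                rest = 0.0
                if rest_rows and rest_cols:
                    rest = _lsa_weight(weights[np.ix_(rest_rows, rest_cols)])
                if fixed_weight + weights[i, j] + rest >= optimum - tol:
                    chosen = (i, j)
                    break
            if chosen:
                break
        if chosen is None:  # pragma: no cover - optimum always attainable
            raise RuntimeError("tie-break refinement failed to extend the matching")
        fixed.append(chosen)
        fixed_weight += weights[chosen]
        free_rows.remove(chosen[0])
        free_cols.remove(chosen[1])
    return fixed


def extract_alignment(
    R: SimilarityVector,
    nodes1: list[str] | None = None,
    nodes2: list[str] | None = None,
) -> Alignment:
    """Maximum-weight bipartite matching of cardinality min(m, n) on R.

    Ties among equal-weight optima are broken toward the lexicographically
    smallest sorted pair-index sequence (refined exhaustively for instances
    up to _LEX_REFINE_LIMIT weight entries; larger instances use the plain —
    still deterministic — assignment solution).
    """
    weights = R.values
    m, n = weights.shape
    nodes1 = list(nodes1) if nodes1 is not None else [str(i) for i in range(m)]
    nodes2 = list(nodes2) if nodes2 is not None else [str(j) for j in range(n)]
    if len(nodes1) != m or len(nodes2) != n:
        raise ValueError("node label lists do not match the weight grid")

    ri, ci = linear_sum_assignment(weights, maximize=True)
    optimum = float(weights[ri, ci].sum())
    if m * n <= _LEX_REFINE_LIMIT:
        index_pairs = _lexicographic_refine(weights, optimum)
    else:
        index_pairs = sorted(zip(ri.tolist(), ci.tolist()))
    pairs = [(nodes1[i], nodes2[j]) for i, j in index_pairs]
    scores = {(nodes1[i], nodes2[j]): float(weights[i, j]) for i, j in index_pairs}
    return Alignment(
        pairs=pairs,
        pair_scores=scores,
        total_weight=float(sum(scores.values())),
        nodes1=nodes1,
        nodes2=nodes2,
    )


@dataclass(frozen=True)
class AlignResult:
    alignment: Alignment
    similarity: SimilarityVector
    info: PowerIterationInfo


def align(
    g1: UncertainNetwork,
    g2: UncertainNetwork,
    seqsim: SeqSimilarity | None = None,
    cfg: IterationConfig = IterationConfig(),
    mode: Literal["exact", "paper_literal"] = "exact",
) -> AlignResult:
    """Full pipeline: expected support matrix, power iteration, matching."""
    EA = expected_support_matrix(g1, g2, mode=mode)
    evec = normalize_seqsim(seqsim, g1.nodes, g2.nodes)
    R, info = power_iterate(EA, evec, cfg)
    alignment = extract_alignment(R, g1.nodes, g2.nodes)
    return AlignResult(alignment=alignment, similarity=R, info=info)
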