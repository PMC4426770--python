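"""Probability generating functions for node degrees of uncertain networks.

The degree of a node whose incident edges exist independently with
probabilities ``p_e`` is a sum of independent Bernoulli variables, so its
generating function is the product of ``(1 - p_e + p_e * z)`` over incident
edges.  Conditioning on one incident edge being present divides that product
by the edge's own factor and shifts the degree up by one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import UncertainNetwork

__all__ = [
    "Polynomial",
    "DegreeDistribution",
    "poly_multiply",
    "node_degree_pgf",
    "conditional_degree_pgf",
    "degree_distribution",
]

# tolerance within which division artefacts may be clamped back into [0, 1]
_CLAMP_TOL = 1e-9


class Polynomial:
    """Dense polynomial in ascending powers; used as a PGF Q(z) = sum c_k z^k."""

    __slots__ = ("coeffs",)

    def __init__(self, coeffs) -> None:
        arr = np.atleast_1d(np.asarray(coeffs, dtype=float))
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("coefficients must be a non-empty 1-D sequence")
        # normalize exact trailing zeros away, keeping at least the constant
        last = arr.size - 1
        while last > 0 and arr[last] == 0.0:
            last -= 1
        self.coeffs = arr[: last + 1].copy()

    @property
    def degree(self) -> int:
        return self.coeffs.size - 1

    def __call__(self, z: float) -> float:
        # Horner in ascending-power storage
        acc = 0.0
        for c in self.coeffs[::-1]:
            acc = acc * z + c
        return acc

    def mean(self) -> float:
        """Q'(1): the mean when the polynomial is a PGF."""
        k = np.arange(self.coeffs.size)
        return float(np.dot(k, self.coeffs))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Polynomial):
            return NotImplemented
        return self.coeffs.shape == other.coeffs.shape and bool(
            np.all(self.coeffs == other.coeffs))

    def __repr__(self) -> str:
        return f"Polynomial({self.coeffs.tolist()})"


def poly_multiply(a: Polynomial, b: Polynomial) -> Polynomial:
    """Coefficient convolution: (a * b)(z)."""
    return Polynomial(np.convolve(a.coeffs, b.coeffs))


def _divide_bernoulli_factor(coeffs: np.ndarray, p: float) -> np.ndarray:
    """Divide a polynomial by (1 - p + p*z) via ascending-power synthetic division.

    With p = 1 the divisor is z, which is a pure index shift and requires a
    (numerically) zero constant term.  Quotient coefficients are clamped into
    [0, 1] only when within _CLAMP_TOL of the bound; larger excursions mean
    the division is numerically unstable and raise instead of being hidden.
    """
    if p == 1.0:
        if abs(coeffs[0]) > _CLAMP_TOL:
            raise ArithmeticError(
                "division by z requires a zero constant term "
                f"(got {coeffs[0]!r})")
        q = coeffs[1:].copy() if coeffs.size > 1 else np.array([0.0])
    else:
        c0 = 1.0 - p
        q = np.empty(coeffs.size - 1 if coeffs.size > 1 else 1)
        if coeffs.size == 1:
            q[0] = coeffs[0] / c0
        else:
            prev = 0.0
            for k in range(q.size):
                prev = (coeffs[k] - p * prev) / c0
                q[k] = prev
    out = q.copy()
    low = out < 0.0
    high = out > 1.0
    if np.any(out[low] < -_CLAMP_TOL) or np.any(out[high] > 1.0 + _CLAMP_TOL):
        raise ArithmeticError(
            "conditional PGF division produced coefficients far outside [0, 1]; "
            "refusing to clamp silently")
    out[low] = 0.0
    out[high] = 1.0
    return out


def node_degree_pgf(g: UncertainNetwork, v: str) -> Polynomial:
    """PGF of the degree of ``v``: product of (1 - p_e + p_e z) over incident edges.

    An isolated node yields the constant polynomial [1.0] (degree 0 surely).
    """
    coeffs = np.array([1.0])
    for _, p in g.incident_edges(v):
        coeffs = np.convolve(coeffs, [1.0 - p, p])
    return Polynomial(coeffs)


def conditional_degree_pgf(g: UncertainNetwork, v: str, e: tuple[str, str]) -> Polynomial:
    """PGF of the degree contribution of the incident edges of ``v`` other than ``e``.

    If Q' is the returned quotient, the distribution of the degree of ``v``
    conditioned on ``e`` being present is P(D = k | e) = coefficient k-1 of
    Q' for k = 1..d_max (the conditioned edge itself contributes the +1).
    """
    a, b = e
    if v not in (a, b) or not g.has_edge(a, b):
        raise ValueError(f"edge {e!r} is not incident to node {v!r}")
    p = g.probability(a, b)
    full = node_degree_pgf(g, v)
    return Polynomial(_divide_bernoulli_factor(full.coeffs, p))


@dataclass(frozen=True)
class DegreeDistribution:
    """Distribution P(D = k), k = 0..d_max, of a node's degree."""

    probs: np.ndarray
    d_max: int

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        object.__setattr__(self, "probs", probs)
        if probs.size != self.d_max + 1:
            raise ValueError("length of probs must be d_max + 1")
        if np.any(probs < -1e-12) or np.any(probs > 1.0 + 1e-12):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")

    def p_zero(self) -> float:
        return float(self.probs[0])

    def mean(self) -> float:
        return float(np.dot(np.arange(self.probs.size), self.probs))


def degree_distribution(g: UncertainNetwork, v: str) -> DegreeDistribution:
    """Exact degree distribution of ``v``, read off the PGF coefficients."""
    pgf = node_degree_pgf(g, v)
    d_max = len(g.incident_edges(v))
    probs = np.zeros(d_max + 1)
    probs[: pgf.coeffs.size] = pgf.coeffs
    return DegreeDistribution(probs=probs, d_max=d_max)
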