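"""Synthetic instance generators and brute-force oracles.

Generators produce uncertain networks with Erdős–Rényi topology, perturbed
copies with a planted node correspondence, sequence-similarity tables and
annotations.  The oracles recompute small-instance answers the slow,
unarguable way (full possible-worlds enumeration, exhaustive injections) and
anchor the test suite.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import sparse

from .alignment import SeqSimilarity
from .metrics import AnnotationMap
from .networks import UncertainNetwork, iter_implication_graphs
from .support import SupportMatrix, deterministic_support_matrix

__all__ = [
    "GeneratorConfig",
    "generate_uncertain_network",
    "perturb_network",
    "generate_seqsim",
    "generate_annotations",
    "oracle_expected_support",
    "oracle_max_matching",
]

_PROB_FLOOR = 1e-6  # jitter clamps here instead of deleting the edge


@dataclass(frozen=True)
class GeneratorConfig:
    """Erdős–Rényi uncertain-network recipe.

    ``prob_law`` is one of ``("constant", p)``, ``("uniform", lo, hi)`` or
    ``("beta", a, b)``; all laws must be supported on (0, 1].
    """

    n_nodes: int
    density: float
    prob_law: tuple = ("uniform", 0.3, 1.0)
    seed: int = 0
    label_prefix: str = "v"

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("need at least 2 nodes")
        if not 0.0 < self.density <= 1.0:
            raise ValueError("density must be in (0, 1]")
        kind = self.prob_law[0]
        if kind == "constant":
            (p,) = self.prob_law[1:]
            if not 0.0 < p <= 1.0:
                raise ValueError("constant probability must be in (0, 1]")
        elif kind == "uniform":
            lo, hi = self.prob_law[1:]
            if not 0.0 < lo <= hi <= 1.0:
                raise ValueError("uniform bounds must satisfy 0 < lo <= hi <= 1")
        elif kind == "beta":
            a, b = self.prob_law[1:]
            if a <= 0 or b <= 0:
                raise ValueError("beta parameters must be positive")
        else:
            raise ValueError(f"unknown probability law {kind!r}")


def _draw_probability(law: tuple, rng: np.random.Generator) -> float:
    kind = law[0]
    if kind == "constant":
        return float(law[1])
    if kind == "uniform":
        return float(rng.uniform(law[1], law[2]))
    # beta, clamped away from 0 so the edge remains representable
    return float(max(rng.beta(law[1], law[2]), _PROB_FLOOR))


def generate_uncertain_network(cfg: GeneratorConfig) -> UncertainNetwork:
    """G(n, density) topology with independently drawn edge probabilities."""
    rng = np.random.default_rng(cfg.seed)
    width = len(str(cfg.n_nodes - 1))
    labels = [f"{cfg.label_prefix}{i:0{width}d}" for i in range(cfg.n_nodes)]
    net = UncertainNetwork(nodes=labels)
    for a, b in itertools.combinations(labels, 2):
        if rng.random() < cfg.density:
            net.add_edge(a, b, _draw_probability(cfg.prob_law, rng))
    return net


def perturb_network(
    g: UncertainNetwork,
    edge_flip_rate: float = 0.0,
    prob_jitter: float = 0.0,
    seed: int = 0,
    label_prefix: str = "w",
) -> tuple[UncertainNetwork, dict[str, str]]:
    """Relabeled copy with toggled edges and jittered probabilities.

    Every unordered node pair is flipped (edge added or removed) with
    probability ``edge_flip_rate``; surviving probabilities receive additive
    uniform jitter in [-prob_jitter, prob_jitter], clamped to
    [_PROB_FLOOR, 1].  Returns the copy and the planted old-label -> new-label
    mapping.
    """
    if not 0.0 <= edge_flip_rate <= 1.0 or not 0.0 <= prob_jitter <= 1.0:
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed)
    old = g.nodes
    width = len(str(len(old) - 1)) if len(old) > 1 else 1
    mapping = {v: f"{label_prefix}{i:0{width}d}" for i, v in enumerate(old)}
    out = UncertainNetwork(nodes=[mapping[v] for v in old])
    for a, b in itertools.combinations(old, 2):
        has = g.has_edge(a, b)
        if rng.random() < edge_flip_rate:
            has = not has
            p = _draw_probability(("uniform", 0.3, 1.0), rng) if has else 0.0
        elif has:
            p = g.probability(a, b)
        else:
            p = 0.0
        if has:
            if prob_jitter > 0:
                p = float(np.clip(p + rng.uniform(-prob_jitter, prob_jitter),
                                  _PROB_FLOOR, 1.0))
            out.add_edge(mapping[a], mapping[b], p)
    return out, mapping


def generate_seqsim(
    mapping: dict[str, str],
    signal: float,
    noise: float,
    seed: int = 0,
    nodes1: list[str] | None = None,
    nodes2: list[str] | None = None,
) -> SeqSimilarity:
    """Scores signal + noise*U(0,1) on planted pairs, noise*U(0,1) on decoys."""
    if signal < 0 or noise < 0:
        raise ValueError("signal and noise must be nonnegative")
    rng = np.random.default_rng(seed)
    nodes1 = list(nodes1) if nodes1 is not None else list(mapping.keys())
    nodes2 = list(nodes2) if nodes2 is not None else list(mapping.values())
    sim = SeqSimilarity()
    for a in nodes1:
        for b in nodes2:
            base = signal if mapping.get(a) == b else 0.0
            sim.set(a, b, base + noise * rng.random())
    return sim


def generate_annotations(
    mapping: dict[str, str],
    n_terms: int = 25,
    terms_per_node: int = 3,
    shared_fraction: float = 0.8,
    seed: int = 0,
) -> AnnotationMap:
    """Annotate planted partners with mostly shared random term sets."""
    rng = np.random.default_rng(seed)
    vocab = [f"GO:{i:07d}" for i in range(n_terms)]
    ann = AnnotationMap()
    for a, b in mapping.items():
        terms = rng.choice(n_terms, size=min(terms_per_node, n_terms), replace=False)
        for t in terms:
            ann.add(a, vocab[t])
            if rng.random() < shared_fraction:
                ann.add(b, vocab[t])
            else:
                ann.add(b, vocab[int(rng.integers(n_terms))])
    return ann


def oracle_expected_support(
    g1: UncertainNetwork, g2: UncertainNetwork, cap: int = 10
) -> SupportMatrix:
    """Exact E(A) by probability-weighted average over all joint worlds.

    Exponential in |E1| + |E2| (capped); the defining oracle for
    ``expected_support_matrix`` in exact mode.
    """
    if g1.n_edges + g2.n_edges > cap:
        raise ValueError(
            f"joint world count 2**{g1.n_edges + g2.n_edges} exceeds cap 2**{cap}")
    m, n = g1.n_nodes, g2.n_nodes
    mn = m * n
    acc = np.zeros((mn, mn))
    worlds2 = list(iter_implication_graphs(g2, cap=cap))
    for w1, p1 in iter_implication_graphs(g1, cap=cap):
        for w2, p2 in worlds2:
            acc += (p1 * p2) * deterministic_support_matrix(w1, w2).dense()
    return SupportMatrix(m, n, sparse.csr_matrix(acc), np.zeros(mn))


def oracle_max_matching(
    weights: np.ndarray, cap: int = 7
) -> tuple[list[tuple[int, int]], float]:
    """Exhaustive maximum-weight matching over all injections of the smaller side.

    Ties are broken toward the lexicographically smallest sorted pair list,
    mirroring ``extract_alignment``.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2:
        raise ValueError("weights must be a 2-D grid")
    m, n = weights.shape
    if min(m, n) > cap:
        raise ValueError(f"min(m, n) = {min(m, n)} exceeds oracle cap {cap}")
    transposed = m > n
    W = weights.T if transposed else weights
    rows, cols = W.shape
    best_weight = -np.inf
    best_pairs: list[tuple[int, int]] | None = None
    for cols_choice in itertools.permutations(range(cols), rows):
        w = float(sum(W[i, j] for i, j in enumerate(cols_choice)))
        pairs = sorted(
            (j, i) if transposed else (i, j) for i, j in enumerate(cols_choice))
        if (w > best_weight + 1e-12
                or (abs(w - best_weight) <= 1e-12 and pairs < best_pairs)):
            best_weight = w
            best_pairs = pairs
    assert best_pairs is not None
    return best_pairs, best_weight
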