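"""Alignment quality metrics: agreement, GO consistency, and the global score."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .alignment import Alignment, SeqSimilarity
from .networks import UncertainNetwork

__all__ = [
    "AnnotationMap",
    "MetricReport",
    "agreement",
    "goc",
    "gnas",
    "conserved_interactions",
    "pairwise_comparison_count",
]


class AnnotationMap:
    """Node label -> set of (opaque) GO term identifiers."""

    def __init__(self, terms: Mapping[str, set[str]] | None = None) -> None:
        self._terms: dict[str, set[str]] = {}
        if terms:
            for node, ts in terms.items():
                self._terms[node] = set(ts)

    def add(self, node: str, term: str) -> None:
        self._terms.setdefault(node, set()).add(term)

    def get(self, node: str) -> set[str]:
        return self._terms.get(node, set())

    def __len__(self) -> int:
        return len(self._terms)

    @classmethod
    def load(cls, path: str) -> "AnnotationMap":
        """Read a two-column TSV ``node<TAB>term`` (``#`` comments allowed)."""
        ann = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) != 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected 2 columns, got {len(cols)}")
                ann.add(cols[0], cols[1])
        return ann

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# node\tterm\n")
            for node in self._terms:
                for term in sorted(self._terms[node]):
                    fh.write(f"{node}\t{term}\n")


@dataclass(frozen=True)
class MetricReport:
    goc: float
    gnas: float
    conserved_edges: float
    seq_sum: float
    agreement: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.goc <= 1.0:
            raise ValueError("goc must be in [0, 1]")
        if self.gnas < 0 or self.conserved_edges < 0 or self.seq_sum < 0:
            raise ValueError("gnas components must be nonnegative")
        if self.agreement is not None and not 0.0 <= self.agreement <= 1.0:
            raise ValueError("agreement must be in [0, 1]")


def agreement(
    a1: Alignment, a2: Alignment, denominator: Literal["union", "size"] = "union"
) -> float:
    """Fraction of aligned pairs shared by two alignments of the same instance.

    ``union`` divides the common-pair count by the size of the union of the
    two pair sets (well defined for unequal cardinalities); ``size`` divides
    by the (common) alignment size and requires equal cardinalities.
    """
    for attr in ("nodes1", "nodes2"):
        u1, u2 = getattr(a1, attr), getattr(a2, attr)
        if u1 is not None and u2 is not None and set(u1) != set(u2):
            raise ValueError("alignments are over different node universes")
    s1, s2 = a1.pair_set(), a2.pair_set()
    if not s1 and not s2:
        return 1.0
    common = len(s1 & s2)
    if denominator == "union":
        return common / len(s1 | s2)
    if denominator == "size":
        if len(s1) != len(s2):
            raise ValueError("size denominator requires equal-cardinality alignments")
        return common / len(s1)
    raise ValueError(f"unknown denominator {denominator!r}")


def goc(
    a: Alignment,
    ann: AnnotationMap,
    unannotated: Literal["skip", "zero"] = "skip",
) -> float:
    """Mean Jaccard overlap of term sets over aligned pairs.

    Pairs where both members have empty term sets are skipped by default
    (``unannotated="zero"`` counts every pair, scoring such pairs 0).
    Returns 0.0 for an alignment with no scorable pairs.
    """
    total = 0.0
    counted = 0
    for u, v in a.pairs:
        tu, tv = ann.get(u), ann.get(v)
        if not tu and not tv:
            if unannotated == "zero":
                counted += 1
            continue
        total += len(tu & tv) / len(tu | tv)
        counted += 1
    return total / counted if counted else 0.0


def conserved_interactions(
    a: Alignment,
    g1: UncertainNetwork,
    g2: UncertainNetwork,
    mode: Literal["support", "expected"] = "support",
) -> float:
    """Count aligned couple pairs whose endpoints interact in both networks.

    ``support`` counts an uncertain edge as present whenever its probability
    is positive; ``expected`` sums p1(u, u') * p2(v, v') instead, giving the
    expected conserved-edge count over possible worlds.
    """
    pairs = a.pairs
    total = 0.0
    for k, (u, v) in enumerate(pairs):
        for u2, v2 in pairs[k + 1:]:
            if g1.has_edge(u, u2) and g2.has_edge(v, v2):
                if mode == "support":
                    total += 1.0
                elif mode == "expected":
                    total += g1.probability(u, u2) * g2.probability(v, v2)
                else:
                    raise ValueError(f"unknown conserved mode {mode!r}")
    return total


def gnas(
    a: Alignment,
    g1: UncertainNetwork,
    g2: UncertainNetwork,
    seqsim: SeqSimilarity | None = None,
    alpha: float = 0.6,
    conserved_mode: Literal["support", "expected"] = "support",
    ann: AnnotationMap | None = None,
) -> MetricReport:
    """Global alignment score alpha * |conserved edges| + (1 - alpha) * sum seq(u, v)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    conserved = conserved_interactions(a, g1, g2, mode=conserved_mode)
    seq_sum = 0.0
    if seqsim is not None:
        seq_sum = math.fsum(seqsim.get(u, v) for u, v in a.pairs)
    score = alpha * conserved + (1.0 - alpha) * seq_sum
    return MetricReport(
        goc=goc(a, ann) if ann is not None else 0.0,
        gnas=score,
        conserved_edges=conserved,
        seq_sum=seq_sum,
    )


def pairwise_comparison_count(n_networks: int) -> int:
    """Number of unordered all-vs-all comparison groups among n networks."""
    if n_networks < 0:
        raise ValueError("network count must be nonnegative")
    return math.comb(n_networks, 2)
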