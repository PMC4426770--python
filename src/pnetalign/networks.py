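"""Network data model and TSV I/O.

Two graph flavours are supported: :class:`DeterministicNetwork` (plain
undirected graphs) and :class:`UncertainNetwork` (each edge carries an
independent existence probability in ``(0, 1]``).  An uncertain network
with ``k`` probabilistic edges induces ``2**k`` possible deterministic
worlds; :func:`enumerate_implication_graphs` materializes them together
with their probabilities, which is the brute-force semantics everything
else is tested against.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "UncertainNetwork",
    "DeterministicNetwork",
    "NetworkParseError",
    "load_network",
    "save_network",
    "enumerate_implication_graphs",
    "implication_probability",
]

#: refuse to enumerate worlds above this many edges (output size is 2**|E|)
DEFAULT_ENUMERATION_CAP = 20


class NetworkParseError(ValueError):
    """Raised for malformed network files (carries the offending line number)."""


def _canonical(index: dict[str, int], a: str, b: str) -> tuple[str, str]:
    """Order an edge's endpoints by node index so lookups are orientation-free."""
    return (a, b) if index[a] <= index[b] else (b, a)


class UncertainNetwork:
    """Undirected graph whose edges exist independently with given probabilities.

    Nodes are identified by their literal (case-sensitive) string labels and
    keep first-appearance order; isolated nodes are allowed.  Probabilities
    must lie in ``(0, 1]`` — an edge with probability 0 cannot exist in any
    world and is not representable.
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str, float]] = (),
    ) -> None:
        self._nodes: list[str] = []
        self._index: dict[str, int] = {}
        self._prob: dict[tuple[str, str], float] = {}
        for v in nodes:
            self.add_node(v)
        for a, b, p in edges:
            self.add_edge(a, b, p)

    # -- construction -------------------------------------------------

    def add_node(self, label: str) -> None:
        if not isinstance(label, str) or not label:
            raise ValueError(f"node label must be a non-empty string, got {label!r}")
        if label in self._index:
            raise ValueError(f"duplicate node label {label!r}")
        self._index[label] = len(self._nodes)
        self._nodes.append(label)

    def add_edge(self, a: str, b: str, prob: float = 1.0) -> None:
        if a == b:
            raise ValueError(f"self-loop on node {a!r} is not allowed")
        if not 0.0 < prob <= 1.0:
            raise ValueError(f"edge probability must be in (0, 1], got {prob}")
        for v in (a, b):
            if v not in self._index:
                self.add_node(v)
        key = _canonical(self._index, a, b)
        if key in self._prob:
            raise ValueError(f"duplicate edge between {a!r} and {b!r}")
        self._prob[key] = float(prob)

    # -- basic accessors ----------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self._prob)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._prob)

    def node_index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node {label!r}") from None

    def has_edge(self, a: str, b: str) -> bool:
        if a not in self._index or b not in self._index:
            return False
        return _canonical(self._index, a, b) in self._prob

    def probability(self, a: str, b: str) -> float:
        key = _canonical(self._index, a, b)
        try:
            return self._prob[key]
        except KeyError:
            raise KeyError(f"no edge between {a!r} and {b!r}") from None

    def incident_edges(self, v: str) -> list[tuple[tuple[str, str], float]]:
        """All (edge, probability) pairs touching node ``v``."""
        self.node_index(v)
        return [(e, p) for e, p in self._prob.items() if v in e]

    def expected_degree(self, v: str) -> float:
        return math.fsum(p for _, p in self.incident_edges(v))

    def is_deterministic(self) -> bool:
        return all(p == 1.0 for p in self._prob.values())

    def to_deterministic(self) -> "DeterministicNetwork":
        if not self.is_deterministic():
            raise ValueError("network has edges with probability < 1")
        return DeterministicNetwork(self._nodes, self.edges)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UncertainNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._prob == other._prob

    def __repr__(self) -> str:
        return f"UncertainNetwork(n_nodes={self.n_nodes}, n_edges={self.n_edges})"


class DeterministicNetwork:
    """Plain undirected graph; equivalent to an UncertainNetwork with all p = 1."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()) -> None:
        self._nodes = list(nodes)
        if len(set(self._nodes)) != len(self._nodes):
            raise ValueError("duplicate node labels")
        self._index = {v: i for i, v in enumerate(self._nodes)}
        self._edges: set[tuple[str, str]] = set()
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r} is not allowed")
            if a not in self._index or b not in self._index:
                raise ValueError(f"edge ({a!r}, {b!r}) references unknown node")
            key = _canonical(self._index, a, b)
            if key in self._edges:
                raise ValueError(f"duplicate edge between {a!r} and {b!r}")
            self._edges.add(key)

    @property
    def nodes(self) -> list[str]:
        return list(self._nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._edges)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def node_index(self, label: str) -> int:
        return self._index[label]

    def has_edge(self, a: str, b: str) -> bool:
        if a not in self._index or b not in self._index:
            return False
        return _canonical(self._index, a, b) in self._edges

    def degree(self, v: str) -> int:
        if v not in self._index:
            raise KeyError(f"unknown node {v!r}")
        return sum(1 for e in self._edges if v in e)

    def neighbors(self, v: str) -> set[str]:
        out = set()
        for a, b in self._edges:
            if a == v:
                out.add(b)
            elif b == v:
                out.add(a)
        return out

    def to_uncertain(self) -> UncertainNetwork:
        return UncertainNetwork(self._nodes, [(a, b, 1.0) for a, b in sorted(
            self._edges, key=lambda e: (self._index[e[0]], self._index[e[1]]))])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DeterministicNetwork):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((tuple(self._nodes), frozenset(self._edges)))

    def __repr__(self) -> str:
        return f"DeterministicNetwork(n_nodes={self.n_nodes}, n_edges={len(self._edges)})"


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_network(path: str) -> UncertainNetwork:
    """Read a network from a TSV edge list.

    Lines starting with ``#`` are comments.  Each data row has 2 or 3
    whitespace/tab-separated columns: ``node_a  node_b  [probability]``;
    a missing probability means 1.  Rows with probability exactly 0 are
    dropped (logged) because such edges exist in no world.
    """
    net = UncertainNetwork()
    n_rows = 0
    n_dropped = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) not in (2, 3):
                raise NetworkParseError(
                    f"{path}:{lineno}: expected 2 or 3 columns, got {len(cols)}")
            a, b = cols[0], cols[1]
            if len(cols) == 3:
                try:
                    p = float(cols[2])
                except ValueError:
                    raise NetworkParseError(
                        f"{path}:{lineno}: non-numeric probability {cols[2]!r}") from None
                if not math.isfinite(p) or p < 0.0 or p > 1.0:
                    raise NetworkParseError(
                        f"{path}:{lineno}: probability {p} outside [0, 1]")
            else:
                p = 1.0
            n_rows += 1
            if p == 0.0:
                n_dropped += 1
                logger.warning("%s:%d: dropping zero-probability edge %s-%s",
                               path, lineno, a, b)
                # endpoints still become (possibly isolated) nodes
                for v in (a, b):
                    if v not in net._index:
                        net.add_node(v)
                continue
            try:
                net.add_edge(a, b, p)
            except ValueError as exc:
                raise NetworkParseError(f"{path}:{lineno}: {exc}") from None
    if n_rows == 0:
        raise NetworkParseError(f"{path}: empty network file")
    if n_dropped:
        logger.info("%s: dropped %d zero-probability edges", path, n_dropped)
    return net


def save_network(net: UncertainNetwork, path: str, header: Sequence[str] = ()) -> None:
    """Write the network in the same TSV dialect (probabilities, 6 sig. digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        fh.write("# node_a\tnode_b\tprobability\n")
        for (a, b), p in net._prob.items():
            fh.write(f"{a}\t{b}\t{p:.6g}\n")


# ---------------------------------------------------------------------------
# Possible-worlds semantics
# ---------------------------------------------------------------------------

def implication_probability(g: UncertainNetwork, world: DeterministicNetwork) -> float:
    """Probability that the uncertain graph realizes exactly this world.

    The world must use the same node set and only edges of ``g``; its
    probability is the product of p_e over present edges times (1 - p_e)
    over absent ones.
    """
    if world.nodes != g.nodes:
        raise ValueError("world must be defined on the same ordered node set")
    world_edges = world.edges
    g_edges = set(g.edges)
    extra = world_edges - g_edges
    if extra:
        raise ValueError(f"world contains edges absent from the uncertain graph: {sorted(extra)}")
    prob = 1.0
    for e in g.edges:
        p = g._prob[e]
        prob *= p if e in world_edges else (1.0 - p)
    return prob


def iter_implication_graphs(
    g: UncertainNetwork, cap: int = DEFAULT_ENUMERATION_CAP
) -> Iterator[tuple[DeterministicNetwork, float]]:
    """Lazily yield every possible world with its probability."""
    edges = g.edges
    if len(edges) > cap:
        raise ValueError(
            f"refusing to enumerate 2**{len(edges)} worlds (cap is {cap} edges); "
            "this operation is meant for small oracle instances only")
    probs = [g._prob[e] for e in edges]
    nodes = g.nodes
    for mask in itertools.product((False, True), repeat=len(edges)):
        present = [e for e, keep in zip(edges, mask) if keep]
        w = 1.0
        for p, keep in zip(probs, mask):
            w *= p if keep else (1.0 - p)
        yield DeterministicNetwork(nodes, present), w


def enumerate_implication_graphs(
    g: UncertainNetwork, cap: int = DEFAULT_ENUMERATION_CAP
) -> list[tuple[DeterministicNetwork, float]]:
    """All 2**|E| deterministic worlds of ``g`` with probabilities summing to 1."""
    return list(iter_implication_graphs(g, cap=cap))
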