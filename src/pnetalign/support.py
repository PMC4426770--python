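"""Expected support matrix for node-pair similarity propagation.

For deterministic networks the support matrix couples node pair (i, j) to
(u, v) with weight 1/(d_u * d_v) when (i, u) and (j, v) are edges, and gives
every pair involving an isolated node the uniform weight 1/(m*n).  When the
networks are uncertain the degrees are random, and we build the entrywise
expectation of that matrix instead.

The isolated-node ("acnode") contribution is constant along each column-pair
(u, v), so it is kept as an implicit rank-one structure — a length-(m*n)
vector applied during matrix-vector products — rather than materialized into
the sparse matrix.
"""

from __future__ import annotations

import logging
from typing import Literal

import numpy as np
from scipy import sparse

from .networks import DeterministicNetwork, UncertainNetwork
from .pgf import (
    DegreeDistribution,
    conditional_degree_pgf,
    degree_distribution,
    node_degree_pgf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SupportMatrix",
    "acnode_probability",
    "expected_support_matrix",
    "deterministic_support_matrix",
]

Mode = Literal["exact", "paper_literal"]


class SupportMatrix:
    """Sparse (m*n) x (m*n) support matrix over flattened node-pair indices.

    Row/column index of the pair (i, j) is ``i * n + j`` (row-major).  The
    full matrix is ``topo[rc, cc] + acnode[cc] / (m*n)``: ``topo`` holds the
    topological (edge-adjacency) entries and ``acnode[cc]`` is the
    isolated-node probability mass of column pair ``cc``.
    """

    def __init__(self, m: int, n: int, topo: sparse.spmatrix, acnode: np.ndarray) -> None:
        if m < 1 or n < 1:
            raise ValueError("both networks must be nonempty")
        mn = m * n
        if topo.shape != (mn, mn):
            raise ValueError(f"topo must be {(mn, mn)}, got {topo.shape}")
        acnode = np.asarray(acnode, dtype=float)
        if acnode.shape != (mn,):
            raise ValueError(f"acnode vector must have length {mn}")
        if topo.nnz and topo.min() < 0:
            raise ValueError("support entries must be nonnegative")
        if np.any(acnode < 0):
            raise ValueError("acnode probabilities must be nonnegative")
        self.m = m
        self.n = n
        self.topo = topo.tocsr()
        self.acnode = acnode

    @property
    def shape(self) -> tuple[int, int]:
        mn = self.m * self.n
        return (mn, mn)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        """(topo + ones * acnode^T / (m*n)) @ x without densifying."""
        x = np.asarray(x, dtype=float)
        out = self.topo @ x
        out += float(self.acnode @ x) / (self.m * self.n)
        return out

    def dense(self) -> np.ndarray:
        """Materialize the full matrix (small instances / tests only)."""
        return self.topo.toarray() + self.acnode[None, :] / (self.m * self.n)

    def entry(self, i: int, j: int, u: int, v: int) -> float:
        rc = i * self.n + j
        cc = u * self.n + v
        return float(self.topo[rc, cc]) + self.acnode[cc] / (self.m * self.n)


def acnode_probability(
    du: DegreeDistribution, dv: DegreeDistribution, mode: Mode = "exact"
) -> float:
    """Probability that the product of the two (independent) degrees is zero.

    ``exact`` applies inclusion-exclusion, P(Du=0) + P(Dv=0) - P(Du=0)P(Dv=0).
    ``paper_literal`` returns the bare sum P(Du=0) + P(Dv=0), clamped to 1
    with a warning when the sum exceeds it.
    """
    p0u = du.p_zero()
    p0v = dv.p_zero()
    if mode == "exact":
        return p0u + p0v - p0u * p0v
    if mode == "paper_literal":
        s = p0u + p0v
        if s > 1.0:
            logger.warning(
                "literal acnode probability %.6g exceeds 1; clamping", s)
            return 1.0
        return s
    raise ValueError(f"unknown mode {mode!r}")


def _conditional_inverse_moment(g: UncertainNetwork, v: str, e: tuple[str, str]) -> float:
    """E[1/D_v | e present] = sum_k q_{k-1} / k over the quotient PGF q."""
    q = conditional_degree_pgf(g, v, e).coeffs
    k = np.arange(1, q.size + 1, dtype=float)
    return float(np.sum(q / k))


def expected_support_matrix(
    g1: UncertainNetwork, g2: UncertainNetwork, mode: Mode = "exact"
) -> SupportMatrix:
    """Entrywise expected support matrix of two uncertain networks.

    For each edge pair e1 = (v_i, v_u) of network 1 and e2 = (v_j, v_v) of
    network 2 (in all four orientation combinations) the topological entry at
    ([i, j], [u, v]) is

        S = E[1/D_u | e1 present] * E[1/D_v | e2 present]

    using conditional degree distributions; in ``exact`` mode S is further
    multiplied by p_{e1} * p_{e2}, the probability that the enabling edges
    exist, which makes the matrix the true possible-worlds expectation (and
    column-stochastic).  ``paper_literal`` omits that factor and uses the
    additive acnode probability.
    """
    if mode not in ("exact", "paper_literal"):
        raise ValueError(f"unknown mode {mode!r}")
    m, n = g1.n_nodes, g2.n_nodes
    if m == 0 or n == 0:
        raise ValueError("both networks must have at least one node")

    # E[1/D | incident edge present], per (node, edge) orientation
    def inverse_moments(g: UncertainNetwork) -> dict[tuple[str, tuple[str, str]], float]:
        out = {}
        for e in g.edges:
            for endpoint in e:
                out[(endpoint, e)] = _conditional_inverse_moment(g, endpoint, e)
        return out

    s1 = inverse_moments(g1)
    s2 = inverse_moments(g2)

    rows, cols, vals = [], [], []
    for e1 in g1.edges:
        p1 = g1.probability(*e1)
        for e2 in g2.edges:
            p2 = g2.probability(*e2)
            scale = p1 * p2 if mode == "exact" else 1.0
            for (i_lab, u_lab) in (e1, e1[::-1]):
                su = s1[(u_lab, e1)]
                i = g1.node_index(i_lab)
                u = g1.node_index(u_lab)
                for (j_lab, v_lab) in (e2, e2[::-1]):
                    sv = s2[(v_lab, e2)]
                    j = g2.node_index(j_lab)
                    v = g2.node_index(v_lab)
                    rows.append(i * n + j)
                    cols.append(u * n + v)
                    vals.append(scale * su * sv)
    mn = m * n
    topo = sparse.coo_matrix((vals, (rows, cols)), shape=(mn, mn)).tocsr()

    p0_1 = np.array([node_degree_pgf(g1, x).coeffs[0] for x in g1.nodes])
    p0_2 = np.array([node_degree_pgf(g2, x).coeffs[0] for x in g2.nodes])
    if mode == "exact":
        acnode = (p0_1[:, None] + p0_2[None, :] - p0_1[:, None] * p0_2[None, :]).ravel()
    else:
        acnode = p0_1[:, None] + p0_2[None, :]
        over = acnode > 1.0
        if np.any(over):
            logger.warning(
                "literal acnode probability exceeds 1 for %d node pairs; clamping",
                int(over.sum()))
            acnode[over] = 1.0
        acnode = acnode.ravel()
    return SupportMatrix(m, n, topo, acnode)


def deterministic_support_matrix(
    G1: DeterministicNetwork, G2: DeterministicNetwork
) -> SupportMatrix:
    """Classical support matrix of two deterministic networks.

    Entry ([i, j], [u, v]) = (1/d_u) * (1/d_v) when (v_i, v_u) is an edge of
    network 1 and (v_j, v_v) an edge of network 2; every column pair where
    d_u or d_v is zero carries the uniform 1/(m*n) instead.
    """
    m, n = G1.n_nodes, G2.n_nodes
    if m == 0 or n == 0:
        raise ValueError("both networks must have at least one node")
    deg1 = {x: G1.degree(x) for x in G1.nodes}
    deg2 = {x: G2.degree(x) for x in G2.nodes}

    rows, cols, vals = [], [], []
    for e1 in G1.edges:
        for e2 in G2.edges:
            for (i_lab, u_lab) in (e1, e1[::-1]):
                i = G1.node_index(i_lab)
                u = G1.node_index(u_lab)
                inv_du = 1.0 / deg1[u_lab]
                for (j_lab, v_lab) in (e2, e2[::-1]):
                    j = G2.node_index(j_lab)
                    v = G2.node_index(v_lab)
                    rows.append(i * n + j)
                    cols.append(u * n + v)
                    vals.append(inv_du * (1.0 / deg2[v_lab]))
    mn = m * n
    topo = sparse.coo_matrix((vals, (rows, cols)), shape=(mn, mn)).tocsr()

    z1 = np.array([1.0 if deg1[x] == 0 else 0.0 for x in G1.nodes])
    z2 = np.array([1.0 if deg2[x] == 0 else 0.0 for x in G2.nodes])
    acnode = (z1[:, None] + z2[None, :] - z1[:, None] * z2[None, :]).ravel()
    return SupportMatrix(m, n, topo, acnode)


def dump_mtx(sm: SupportMatrix, mtx_path: str, sidecar_path: str,
             nodes1: list[str], nodes2: list[str]) -> None:
    """Debug dump: Matrix Market coordinate file plus a flat-index legend TSV."""
    from scipy.io import mmwrite

    mmwrite(mtx_path, sparse.coo_matrix(sm.dense()))
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        fh.write("# flat_index\tnode1\tnode2\n")
        for i, a in enumerate(nodes1):
            for j, b in enumerate(nodes2):
                fh.write(f"{i * sm.n + j}\t{a}\t{b}\n")
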