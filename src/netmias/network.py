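"""Gene network construction, random walk with restart, and centrality measures.

The guilt-by-association step scores every gene in an undirected molecular
interaction network by its network proximity to a small seed set (the MHC
class I antigen-presentation genes plus PDCD1/CD274 by default).  Proximity
is the stationary probability of a random walk that restarts at the seeds
with probability ``gamma`` at every step:

    p_{t+1} = (1 - gamma) * W @ p_t + gamma * p_0

where ``W`` is the column-normalised adjacency matrix and ``p_0`` spreads
unit mass uniformly over the seeds.  Genes with higher stationary probability
are more functionally associated with the seed pathway.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

#: Default seed set: MHC class I heavy chains plus the checkpoint pair.
DEFAULT_SEED_GENES = ("HLA-A", "HLA-B", "HLA-C", "PDCD1", "CD274")


class ConvergenceError(RuntimeError):
    """Raised when the power/RWR iteration fails to reach the tolerance."""


@dataclass(frozen=True)
class GeneNetwork:
    """Simple undirected graph over gene identifiers.

    Nodes are kept in lexicographic order so that every derived matrix is
    reproducible.  Self-loops and duplicate edges are removed at build time.
    """

    nodes: tuple[str, ...]
    edges: frozenset[frozenset[str]]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def node_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.nodes)}

    def adjacency(self) -> sp.csr_matrix:
        """Binary symmetric adjacency matrix in node order."""
        idx = self.node_index()
        rows, cols = [], []
        for edge in self.edges:
            a, b = tuple(edge)
            rows += [idx[a], idx[b]]
            cols += [idx[b], idx[a]]
        data = np.ones(len(rows))
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(self.n_nodes, self.n_nodes)
        )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(tuple(e) for e in self.edges)
        return g

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency().sum(axis=1)).ravel()


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic walk matrix W[i, j] = a_ij / degree(j).

    Columns of isolated (degree-0) nodes are all-zero and their identities
    are recorded in ``isolated_nodes``; mass landing there is only
    re-injected through the restart term.
    """

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]
    isolated_nodes: tuple[str, ...]


@dataclass(frozen=True)
class SeedSet:
    """Non-empty subset of network nodes carrying equal initial mass."""

    genes: tuple[str, ...]

    def initial_vector(self, nodes: tuple[str, ...]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(nodes)}
        p0 = np.zeros(len(nodes))
        for g in self.genes:
            p0[idx[g]] = 1.0 / len(self.genes)
        return p0


@dataclass(frozen=True)
class AssociationScores:
    """Stationary RWR probabilities per gene ("association score")."""

    scores: pd.Series  # index: gene ids, values in [0, 1]
    gamma: float
    tol: float
    n_iter: int


@dataclass(frozen=True)
class CentralityScores:
    scores: pd.Series
    method: str


@dataclass(frozen=True)
class RankedList:
    """Genes ordered by descending score with average-tie ranks.

    ``percentile`` is 100 * rank / n, so the best gene of n=1000 sits at
    percentile 0.1 and the worst at 100.
    """

    table: pd.DataFrame = field(repr=False)  # columns: gene, score, rank, percentile

    @property
    def genes(self) -> pd.Index:
        return pd.Index(self.table["gene"])

    @property
    def scores(self) -> pd.Series:
        return pd.Series(self.table["score"].values, index=self.table["gene"].values)

    @property
    def ranks(self) -> pd.Series:
        return pd.Series(self.table["rank"].values, index=self.table["gene"].values)

    @property
    def percentiles(self) -> pd.Series:
        return pd.Series(
            self.table["percentile"].values, index=self.table["gene"].values
        )


def build_network(edge_records) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (gene_a, gene_b) pairs.

    Self-loops are dropped (count logged) and duplicate edges collapsed.
    Raises ``ValueError`` on an empty record list or blank gene ids.
    """
    records = list(edge_records)
    if not records:
        raise ValueError("empty network")
    edges: set[frozenset[str]] = set()
    nodes: set[str] = set()
    n_self = 0
    for a, b in records:
        a, b = str(a).strip(), str(b).strip()
        if not a or not b:
            raise ValueError(f"blank gene id in edge record ({a!r}, {b!r})")
        nodes.update((a, b))
        if a == b:
            n_self += 1
            continue
        edges.add(frozenset((a, b)))
    if n_self:
        logger.info("dropped %d self-loop(s)", n_self)
    return GeneNetwork(nodes=tuple(sorted(nodes)), edges=frozenset(edges))


def column_normalize(net: GeneNetwork) -> TransitionMatrix:
    """Column-normalised adjacency: each non-isolated column sums to 1."""
    if net.n_nodes == 0:
        raise ValueError("empty network")
    adj = net.adjacency().tocsc()
    deg = np.asarray(adj.sum(axis=0)).ravel()
    isolated = tuple(g for g, d in zip(net.nodes, deg) if d == 0)
    if isolated:
        logger.warning("isolated nodes get zero transition columns: %s", isolated)
    with np.errstate(divide="ignore"):
        inv = np.where(deg > 0, 1.0 / np.maximum(deg, 1), 0.0)
    w = (adj @ sp.diags(inv)).tocsr()
    return TransitionMatrix(matrix=w, nodes=net.nodes, isolated_nodes=isolated)


def random_walk_with_restart(
    w: TransitionMatrix,
    seeds: SeedSet,
    gamma: float = 0.5,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> AssociationScores:
    """Iterate the restart walk to stationarity.

    Convergence is declared when the L1 norm of ``p_{t+1} - p_t`` drops below
    ``tol``.  Deterministic given (network, seeds, gamma, tol).
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0, 1), got {gamma}")
    if tol <= 0:
        raise ValueError("tol must be positive")
    missing = [g for g in seeds.genes if g not in w.nodes]
    if missing or not seeds.genes:
        raise ValueError(f"invalid seed set; missing from network: {missing}")
    p0 = seeds.initial_vector(w.nodes)
    p = p0.copy()
    mat = w.matrix
    for it in range(1, max_iter + 1):
        p_next = (1.0 - gamma) * (mat @ p) + gamma * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return AssociationScores(
                scores=pd.Series(p, index=list(w.nodes)),
                gamma=gamma,
                tol=tol,
                n_iter=it,
            )
    raise ConvergenceError(
        f"random walk did not converge after {max_iter} iterations "
        f"(last L1 residual {residual:.3e})"
    )


def solve_rwr_linear(
    w: TransitionMatrix, seeds: SeedSet, gamma: float = 0.5
) -> pd.Series:
    """Closed-form stationary solution gamma * (I - (1-gamma) W)^-1 p0.

    Dense direct solve; intended for small networks and as an internal
    cross-check of the iterative path.
    """
    n = len(w.nodes)
    a = np.eye(n) - (1.0 - gamma) * w.matrix.toarray()
    p = gamma * np.linalg.solve(a, seeds.initial_vector(w.nodes))
    return pd.Series(p, index=list(w.nodes))


def degree_centrality(net: GeneNetwork) -> CentralityScores:
    """Total degree: number of distinct neighbours of each gene."""
    deg = net.degrees().astype(int)
    return CentralityScores(
        scores=pd.Series(deg, index=list(net.nodes)), method="degree"
    )


def betweenness_centrality(net: GeneNetwork) -> CentralityScores:
    """Fraction-of-shortest-paths betweenness, unnormalised.

    Each unordered pair {s, t} with s != t != i contributes
    P_st(i) / P_st once; disconnected pairs contribute 0.
    """
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=False)
    return CentralityScores(
        scores=pd.Series([bc[g] for g in net.nodes], index=list(net.nodes)),
        method="betweenness",
    )


def eigenvector_centrality(
    net: GeneNetwork, tol: float = 1e-14, max_iter: int = 100_000
) -> CentralityScores:
    """Principal-eigenvector centrality on the largest connected component.

    Power iteration on A + I (same principal eigenvector as A, but strictly
    positive spectrum gap on connected graphs, so bipartite components cannot
    oscillate) from an all-ones start for determinism.  Values are
    max-normalised to 1; nodes outside the largest component get 0.
    """
    if net.n_edges == 0:
        raise ValueError("eigenvector centrality undefined on an edgeless network")
    g = net.to_networkx()
    comp = max(nx.connected_components(g), key=lambda c: (len(c), min(c)))
    comp_nodes = sorted(comp)
    idx = {g_: i for i, g_ in enumerate(comp_nodes)}
    sub = net.adjacency()[
        np.ix_([net.node_index()[g_] for g_ in comp_nodes],
               [net.node_index()[g_] for g_ in comp_nodes])
    ]
    shifted = sub + sp.eye(len(comp_nodes), format="csr")
    v = np.ones(len(comp_nodes))
    v /= np.linalg.norm(v)
    for _ in range(max_iter):
        v_next = shifted @ v
        v_next /= np.linalg.norm(v_next)
        if np.abs(v_next - v).max() < tol:
            v = v_next
            break
        v = v_next
    else:
        raise ConvergenceError("eigenvector power iteration did not converge")
    v = np.abs(v)
    v /= v.max()
    out = pd.Series(0.0, index=list(net.nodes))
    for g_ in comp_nodes:
        out[g_] = v[idx[g_]]
    return CentralityScores(scores=out, method="eigenvector")


def rank_and_percentile(scores: pd.Series) -> RankedList:
    """Rank genes by descending score; ties get the average rank.

    percentile(g) = 100 * rank(g) / n, in (0, 100].
    """
    if len(scores) == 0:
        raise ValueError("cannot rank an empty score vector")
    s = pd.Series(scores)
    ranks = rankdata(-s.values, method="average")
    n = len(s)
    tbl = pd.DataFrame(
        {
            "gene": s.index,
            "score": s.values,
            "rank": ranks,
            "percentile": 100.0 * ranks / n,
        }
    )
    # descending score; lexicographic gene id breaks ties deterministically
    tbl = tbl.sort_values(["rank", "gene"], kind="mergesort").reset_index(drop=True)
    return RankedList(table=tbl)
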