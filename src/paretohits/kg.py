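"""Graph-structural and embedding features from a heterogeneous knowledge graph.

A knowledge graph here is a typed edge list: entities (genes, diseases,
compounds, ...) connected by typed relations. Two families of features are
derived from it:

* structural — degree and unique-neighbor counts on the full graph;
  PageRank and betweenness centralities on the protein-protein-interaction
  (PPI) subgraph induced by the "interacts" relation;
* embedding-based — RESCAL bilinear tensor factorization of the full graph,
  followed by exact L2 distances from gene nodes to anchor entities
  (by default the EGFR gene node and the NSCLC disease node), under the
  assumption that genes relevant to EGFR-inhibitor resistance sit close to
  those anchors in embedding space.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PPI_RELATION = "interacts"


@dataclasses.dataclass
class KnowledgeGraph:
    """Typed nodes and typed directed edges.

    ``edges`` is a list of (source, relation, target) triples; node types
    live in ``node_types`` (defaulting to "unknown" for nodes only seen in
    edges).
    """

    edges: list[tuple[str, str, str]]
    node_types: dict[str, str] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        n_dup = 0
        for t in self.edges:
            if t in seen:
                n_dup += 1
                continue
            seen.add(t)
            deduped.append(t)
        if n_dup:
            logger.warning("dropped %d duplicate triple(s)", n_dup)
        self.edges = deduped
        if self.node_types:
            endpoints = {s for s, _, _ in self.edges} | {t for _, _, t in self.edges}
            dangling = endpoints - set(self.node_types)
            if dangling:
                raise ValueError(
                    f"edge endpoint(s) missing from node list: {sorted(dangling)[:5]}"
                )

    @property
    def nodes(self) -> list[str]:
        if self.node_types:
            return sorted(self.node_types)
        ns = {s for s, _, _ in self.edges} | {t for _, _, t in self.edges}
        return sorted(ns)

    @property
    def relations(self) -> list[str]:
        return sorted({r for _, r, _ in self.edges})

    def node_type(self, node: str) -> str:
        return self.node_types.get(node, "unknown")


def read_graph(path: str | Path, node_types_path: str | Path | None = None
               ) -> KnowledgeGraph:
    """Read a TSV edge list (source, relation, target) with optional node types."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"source", "relation", "target"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    edges = list(df[["source", "relation", "target"]].itertuples(index=False, name=None))
    node_types: dict[str, str] = {}
    if node_types_path is not None:
        nt = pd.read_csv(node_types_path, sep="\t", dtype=str)
        node_types = dict(zip(nt["node"], nt["type"]))
    return KnowledgeGraph(edges=edges, node_types=node_types)


def write_graph(graph: KnowledgeGraph, path: str | Path,
                node_types_path: str | Path | None = None) -> None:
    pd.DataFrame(graph.edges, columns=["source", "relation", "target"]).to_csv(
        path, sep="\t", index=False
    )
    if node_types_path is not None and graph.node_types:
        pd.DataFrame(
            sorted(graph.node_types.items()), columns=["node", "type"]
        ).to_csv(node_types_path, sep="\t", index=False)


def to_networkx(graph: KnowledgeGraph, undirected: bool = True) -> nx.Graph:
    g: nx.Graph = nx.Graph() if undirected else nx.DiGraph()
    g.add_nodes_from(graph.nodes)
    for s, r, t in graph.edges:
        g.add_edge(s, t)
    return g


def structural_metrics(graph: KnowledgeGraph) -> pd.DataFrame:
    """Per-node degree (incident triples, all relations) and unique neighbors."""
    if not graph.nodes:
        raise ValueError("empty graph")
    degree = {n: 0 for n in graph.nodes}
    neighbors: dict[str, set[str]] = {n: set() for n in graph.nodes}
    for s, _, t in graph.edges:
        degree[s] += 1
        neighbors[s].add(t)
        if t != s:
            degree[t] += 1
            neighbors[t].add(s)
    out = pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "unique_neighbors": pd.Series({n: len(v) for n, v in neighbors.items()}),
        }
    )
    out.index.name = "node"
    return out.sort_index()


def ppi_subgraph(graph: KnowledgeGraph, relation: str = PPI_RELATION
                 ) -> KnowledgeGraph:
    """Undirected subgraph induced by one relation (default "interacts")."""
    if relation not in graph.relations:
        raise ValueError(
            f"relation {relation!r} absent; available: {graph.relations}"
        )
    edges = [(s, r, t) for s, r, t in graph.edges if r == relation]
    nodes = {s for s, _, _ in edges} | {t for _, _, t in edges}
    types = {n: graph.node_type(n) for n in nodes} if graph.node_types else {}
    return KnowledgeGraph(edges=edges, node_types=types)


def pagerank(graph: KnowledgeGraph, damping: float = 0.85, tol: float = 1e-9,
             max_iter: int = 200) -> pd.Series:
    """Power-iteration PageRank on the graph treated as undirected.

    Iterates until the L1 change drops below ``tol``; raises if ``max_iter``
    is reached first. Scores sum to 1. Dangling (isolated) nodes distribute
    their mass uniformly.
    """
    if not 0 < damping < 1:
        raise ValueError("damping must lie in (0, 1)")
    nodes = graph.nodes
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    nbrs: list[set[int]] = [set() for _ in range(n)]
    for s, _, t in graph.edges:
        if s == t:
            continue
        nbrs[idx[s]].add(idx[t])
        nbrs[idx[t]].add(idx[s])
    deg = np.array([len(x) for x in nbrs], dtype=float)
    p = np.full(n, 1.0 / n)
    for it in range(max_iter):
        new = np.full(n, (1.0 - damping) / n)
        dangling_mass = p[deg == 0].sum()
        new += damping * dangling_mass / n
        contrib = np.where(deg > 0, p / np.maximum(deg, 1), 0.0)
        for i, ns in enumerate(nbrs):
            for j in ns:
                new[i] += damping * contrib[j]
        if np.abs(new - p).sum() < tol:
            return pd.Series(new, index=nodes, name="pagerank")
        p = new
    raise RuntimeError(f"PageRank failed to converge within {max_iter} iterations")


def betweenness(graph: KnowledgeGraph, normalized: bool = False) -> pd.Series:
    """Exact shortest-path betweenness (Brandes), endpoints excluded.

    Unnormalized by default: raw mediated-pair counts (each unordered pair
    counted once on an undirected graph).
    """
    g = to_networkx(graph, undirected=True)
    bc = nx.betweenness_centrality(g, normalized=normalized)
    return pd.Series(bc, name="betweenness").reindex(graph.nodes)


# ---------------------------------------------------------------------------
# RESCAL embeddings


@dataclasses.dataclass
class EmbeddingMatrix:
    """RESCAL factors: one rank-r vector per node, one r x r core per relation."""

    node_ids: list[str]
    vectors: np.ndarray  # (n_nodes, rank)
    relation_cores: dict[str, np.ndarray]  # relation -> (rank, rank)
    losses: list[float] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_ids):
            raise ValueError("vectors must be (n_nodes, rank)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("non-finite embedding entries")

    @property
    def rank(self) -> int:
        return self.vectors.shape[1]

    def vector(self, node: str) -> np.ndarray:
        try:
            i = self.node_ids.index(node)
        except ValueError:
            raise KeyError(f"node {node!r} not embedded") from None
        return self.vectors[i]


def _rescal_loss(X: list[np.ndarray], A: np.ndarray, R: list[np.ndarray],
                 lam: float) -> float:
    loss = 0.0
    for Xk, Rk in zip(X, R):
        loss += float(np.linalg.norm(Xk - A @ Rk @ A.T) ** 2)
    loss += lam * float(np.linalg.norm(A) ** 2)
    loss += lam * sum(float(np.linalg.norm(Rk) ** 2) for Rk in R)
    return loss


def rescal_fit_tensor(X: list[np.ndarray], rank: int, iterations: int = 50,
                      regularization: float = 0.01, seed: int = 0,
                      tol: float = 1e-9) -> tuple[np.ndarray, list[np.ndarray],
                                                  list[float]]:
    """Alternating least squares for X_k ~ A R_k A^T on dense slices.

    Returns (A, [R_k], per-iteration penalized losses). The A-update is the
    standard simultaneous left/right least-squares step; a monotonicity
    safeguard rejects any A-update that would increase the penalized loss,
    so the recorded loss sequence is non-increasing by construction.
    """
    n = X[0].shape[0]
    if rank < 1:
        raise ValueError("rank must be >= 1")
    if rank > n:
        raise ValueError(f"rank {rank} exceeds node count {n}")
    rng = np.random.default_rng(seed)
    A = rng.uniform(-1.0, 1.0, size=(n, rank))
    lam = float(regularization)

    def update_R(A: np.ndarray) -> list[np.ndarray]:
        AtA = A.T @ A
        Z = np.kron(AtA, AtA) + lam * np.eye(rank * rank)
        R = []
        for Xk in X:
            rhs = (A.T @ Xk @ A).reshape(rank * rank)
            R.append(np.linalg.solve(Z, rhs).reshape(rank, rank))
        return R

    R = update_R(A)
    losses = [_rescal_loss(X, A, R, lam)]
    for _ in range(iterations):
        # A-update (Nickel-style): stack left and right factor roles.
        E = np.zeros((n, rank))
        F = np.zeros((rank, rank))
        AtA = A.T @ A
        for Xk, Rk in zip(X, R):
            E += Xk @ A @ Rk.T + Xk.T @ A @ Rk
            F += Rk @ AtA @ Rk.T + Rk.T @ AtA @ Rk
        A_new = np.linalg.solve((F + lam * np.eye(rank)).T, E.T).T
        R_new = update_R(A_new)
        loss_new = _rescal_loss(X, A_new, R_new, lam)
        if loss_new <= losses[-1]:
            A, R = A_new, R_new
            losses.append(loss_new)
        else:
            # Safeguard: keep the current factors; refresh R only if it helps.
            R_ref = update_R(A)
            loss_ref = _rescal_loss(X, A, R_ref, lam)
            if loss_ref <= losses[-1]:
                R = R_ref
                losses.append(loss_ref)
            else:
                losses.append(losses[-1])
                break
        if len(losses) >= 2 and losses[-2] - losses[-1] < tol * max(losses[0], 1.0):
            break
    return A, R, losses


def rescal_fit(graph: KnowledgeGraph, rank: int = 32, iterations: int = 50,
               regularization: float = 0.01, seed: int = 0) -> EmbeddingMatrix:
    """Fit RESCAL embeddings to the stacked relation adjacency tensor.

    One binary adjacency slice per relation type (directed as stored);
    deterministic given ``seed``.
    """
    nodes = graph.nodes
    if not nodes:
        raise ValueError("empty graph")
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    relations = graph.relations
    X = [np.zeros((n, n)) for _ in relations]
    rel_idx = {r: k for k, r in enumerate(relations)}
    for s, r, t in graph.edges:
        X[rel_idx[r]][idx[s], idx[t]] = 1.0
    A, R, losses = rescal_fit_tensor(
        X, rank=rank, iterations=iterations, regularization=regularization,
        seed=seed,
    )
    logger.info("RESCAL converged in %d iterations (loss %.4g -> %.4g)",
                len(losses) - 1, losses[0], losses[-1])
    return EmbeddingMatrix(
        node_ids=nodes, vectors=A,
        relation_cores={r: R[rel_idx[r]] for r in relations},
        losses=losses,
    )


def anchor_distances(emb: EmbeddingMatrix, genes: Iterable[str],
                     anchors: Iterable[str]) -> pd.DataFrame:
    """Exact L2 distances from each gene to each anchor entity."""
    genes = list(genes)
    anchors = list(anchors)
    pos = {v: i for i, v in enumerate(emb.node_ids)}
    for node in [*genes, *anchors]:
        if node not in pos:
            raise KeyError(f"node {node!r} not present in the embedding")
    G = emb.vectors[[pos[g] for g in genes]]
    out = {}
    for a in anchors:
        av = emb.vectors[pos[a]]
        out[f"dist_{a}"] = np.linalg.norm(G - av, axis=1)
    df = pd.DataFrame(out, index=pd.Index(genes, name="gene"))
    return df


def graph_feature_table(graph: KnowledgeGraph, genes: Iterable[str],
                        anchors: Iterable[str] = ("EGFR", "NSCLC"),
                        rank: int = 16, iterations: int = 50,
                        regularization: float = 0.01, seed: int = 0,
                        ppi_relation: str = PPI_RELATION) -> pd.DataFrame:
    """Assemble the six per-gene graph features.

    degree and unique_neighbors on the full graph; pagerank and betweenness
    on the PPI subgraph (genes outside it get 0); RESCAL anchor distances
    on the full graph.
    """
    genes = list(genes)
    metrics = structural_metrics(graph)
    ppi = ppi_subgraph(graph, ppi_relation)
    pr = pagerank(ppi)
    bt = betweenness(ppi)
    emb = rescal_fit(graph, rank=rank, iterations=iterations,
                     regularization=regularization, seed=seed)
    dists = anchor_distances(emb, genes, anchors)
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["degree"] = metrics["degree"].reindex(genes).fillna(0).astype(float)
    out["unique_neighbors"] = (
        metrics["unique_neighbors"].reindex(genes).fillna(0).astype(float)
    )
    out["pagerank"] = pr.reindex(genes).fillna(0.0)
    out["betweenness"] = bt.reindex(genes).fillna(0.0)
    for c in dists.columns:
        out[c] = dists[c]
    return out
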