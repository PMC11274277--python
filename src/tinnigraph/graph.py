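"""Epsilon-threshold similarity graph over feature vectors.

One node per sample row; an undirected edge joins two nodes when the
Euclidean distance between their feature vectors is strictly below the
threshold epsilon (default 0.2, intended for features rescaled to
[0, 1] per column). The symmetric-normalized adjacency with self-loops,
D^-1/2 (A + I) D^-1/2, is the propagation operator of the GCN layers.

Cross-validation masks can be built transductively (one global graph,
per-fold node masks) or inductively (per-fold graphs rebuilt from
training rows only, so no edge ever touches a held-out row during
training). A transductive graph couples train and test samples — the
protocol the original method implies — and is therefore labeled as a
leakage risk in the logs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import pdist, squareform
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

from .features import FeatureMatrix

__all__ = [
    "FeatureGraph",
    "NormalizedAdjacency",
    "build_graph",
    "normalize_adjacency",
    "FoldSpec",
    "make_fold_masks",
    "export_graph",
    "import_graph",
]

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.2


@dataclass
class FeatureGraph:
    """Undirected graph over samples: node features X, labels y, edges (i < j)."""

    X: np.ndarray
    y: np.ndarray
    edges: np.ndarray             # (m, 2) int, i < j
    edge_dists: np.ndarray        # (m,) float
    epsilon: float
    metric: str = "euclidean"
    groups: np.ndarray | None = None   # provenance group per node (e.g. subject)

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(i), int(j)) for i, j in self.edges}


def build_graph(fm: FeatureMatrix, epsilon: float = DEFAULT_EPSILON) -> FeatureGraph:
    """Exhaustive pairwise Euclidean distances; edge iff dist < epsilon (strict)."""
    if fm.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not np.all(np.isfinite(fm.X)):
        raise ValueError("non-finite features")
    d = squareform(pdist(fm.X, metric="euclidean"))
    iu, ju = np.triu_indices(fm.n_samples, k=1)
    mask = d[iu, ju] < epsilon
    edges = np.stack([iu[mask], ju[mask]], axis=1).astype(int)
    groups = None
    if "subject" in fm.provenance.columns:
        groups = fm.provenance["subject"].to_numpy()
    return FeatureGraph(X=fm.X.copy(), y=fm.y.copy(), edges=edges,
                        edge_dists=d[iu, ju][mask], epsilon=float(epsilon),
                        groups=groups)


@dataclass
class NormalizedAdjacency:
    """D^-1/2 (A + I) D^-1/2 as a sparse symmetric operator."""

    matrix: sp.csr_matrix
    degrees: np.ndarray           # row sums of A + I

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    def dense(self) -> np.ndarray:
        return self.matrix.toarray()


def normalize_adjacency(g: FeatureGraph) -> NormalizedAdjacency:
    """Symmetric normalization with self-loops; isolated nodes keep degree 1."""
    n = g.n_nodes
    if n == 0:
        raise ValueError("empty graph")
    if g.n_edges:
        i, j = g.edges[:, 0], g.edges[:, 1]
        rows = np.concatenate([i, j, np.arange(n)])
        cols = np.concatenate([j, i, np.arange(n)])
    else:
        rows = cols = np.arange(n)
    vals = np.ones(rows.shape[0])
    a_hat = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    degrees = np.asarray(a_hat.sum(axis=1)).ravel()
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    norm = sp.diags(d_inv_sqrt) @ a_hat @ sp.diags(d_inv_sqrt)
    return NormalizedAdjacency(matrix=norm.tocsr(), degrees=degrees)


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldSpec:
    """Node-index masks for one cross-validation fold.

    In inductive mode ``train_graph`` is the graph rebuilt from the
    train+validation rows only and ``train_index`` maps its node ids back
    to global node ids; training never sees a test row or its edges.
    """

    fold: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    train_graph: FeatureGraph | None = None
    train_index: np.ndarray | None = None


def make_fold_masks(g: FeatureGraph, n_folds: int = 10,
                    mode: str = "transductive", seed: int = 0,
                    groups: np.ndarray | None = None) -> list[FoldSpec]:
    """Stratified k-fold node masks; validation set is the next fold's test set.

    When ``groups`` is given (or carried by the graph's provenance), folds
    are stratified at the group level (StratifiedGroupKFold), so all epochs
    of one recording land in the same fold — sibling-epoch leakage across
    folds is otherwise enough to defeat any inductive evaluation.
    """
    if mode not in ("transductive", "inductive"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if groups is None:
        groups = g.groups
    y = g.y
    idx = np.arange(g.n_nodes)
    if groups is not None:
        splitter = StratifiedGroupKFold(n_splits=n_folds, shuffle=True,
                                        random_state=seed)
        test_sets = [test for _, test in splitter.split(idx, y, groups)]
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        test_sets = [test for _, test in splitter.split(idx, y)]

    if mode == "transductive":
        logger.warning(
            "transductive folds: test nodes share the training graph "
            "(train/test coupling through edges and features)")

    folds: list[FoldSpec] = []
    for k in range(n_folds):
        test = np.sort(test_sets[k])
        val = np.sort(test_sets[(k + 1) % n_folds])
        train = np.sort(np.setdiff1d(idx, np.concatenate([test, val])))
        for name, part in (("train", train), ("val", val), ("test", test)):
            if part.size == 0:
                raise ValueError(f"fold {k}: empty {name} set")
            if name != "test" and len(np.unique(y[part])) < 2:
                raise ValueError(f"fold {k}: {name} set lacks a class")
        spec = FoldSpec(fold=k, train_idx=train, val_idx=val, test_idx=test)
        if mode == "inductive":
            sub = np.sort(np.concatenate([train, val]))
            d = squareform(pdist(g.X[sub]))
            iu, ju = np.triu_indices(sub.size, k=1)
            m = d[iu, ju] < g.epsilon
            spec.train_graph = FeatureGraph(
                X=g.X[sub], y=y[sub],
                edges=np.stack([iu[m], ju[m]], axis=1).astype(int),
                edge_dists=d[iu, ju][m], epsilon=g.epsilon,
                groups=None if groups is None else np.asarray(groups)[sub])
            spec.train_index = sub
        folds.append(spec)
    return folds


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_graph(g: FeatureGraph, path: str | Path, format: str = "graphml") -> Path:
    """Write GraphML (node features/labels as attributes) or a TSV edge list."""
    path = Path(path)
    if format == "graphml":
        G = nx.Graph(epsilon=repr(g.epsilon), metric=g.metric)
        for i in range(g.n_nodes):
            G.add_node(int(i), features=json.dumps(g.X[i].tolist()),
                       label=int(g.y[i]))
        for (i, j), d in zip(g.edges, g.edge_dists):
            G.add_edge(int(i), int(j), distance=repr(float(d)))
        nx.write_graphml(G, path)
    elif format == "tsv":
        lines = ["i\tj\tdistance"]
        lines += [f"{int(i)}\t{int(j)}\t{float(d)!r}"
                  for (i, j), d in zip(g.edges, g.edge_dists)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def import_graph(path: str | Path) -> FeatureGraph:
    """Read a GraphML file written by :func:`export_graph`."""
    G = nx.read_graphml(Path(path), node_type=int)
    order = sorted(G.nodes)
    X = np.array([json.loads(G.nodes[i]["features"]) for i in order])
    y = np.array([int(G.nodes[i]["label"]) for i in order])
    edges, dists = [], []
    for i, j, attrs in G.edges(data=True):
        a, b = (i, j) if i < j else (j, i)
        edges.append((a, b))
        dists.append(float(attrs["distance"]))
    if edges:
        order_e = np.lexsort((np.array(edges)[:, 1], np.array(edges)[:, 0]))
        edges_arr = np.array(edges, dtype=int)[order_e]
        dists_arr = np.array(dists)[order_e]
    else:
        edges_arr = np.empty((0, 2), dtype=int)
        dists_arr = np.empty(0)
    return FeatureGraph(X=X, y=y, edges=edges_arr, edge_dists=dists_arr,
                        epsilon=float(G.graph["epsilon"]),
                        metric=G.graph.get("metric", "euclidean"))
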