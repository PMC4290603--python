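"""Dataset containers and plain-text readers/writers.

The central container is :class:`NetworkedDataset`: an undirected network over
``N`` nodes, a nonnegative ``N x M`` feature-count table (categorical protein
attributes are one-hot encoded to indicator "words"), and a partially observed
binary ``N x K`` multi-label table.  All files are whitespace/tab-delimited
text; node ordering is first-appearance order and every downstream table is
indexed by position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger("smcc")

__all__ = [
    "NetworkedDataset",
    "ScoreTable",
    "read_edge_list",
    "read_feature_table",
    "read_label_table",
    "load_dataset",
    "write_scores",
    "read_scores",
]


def _as_csr(a) -> sp.csr_array:
    if sp.issparse(a):
        return sp.csr_array(a)
    return sp.csr_array(np.asarray(a, dtype=float))


@dataclass
class NetworkedDataset:
    """Attributed, partially labeled network ``(V, E, X, Y, C)``.

    Parameters
    ----------
    node_ids : list of str
        Ordered node identifiers, length ``N``.
    adjacency : scipy sparse / array, shape (N, N)
        Symmetric binary interaction matrix with zero diagonal.
    counts : ndarray, shape (N, M)
        Nonnegative feature counts ``n(x_i, w_j)``.
    labels : ndarray, shape (N, K)
        Binary label table; rows of unlabeled nodes are all zero.
    labeled_mask : ndarray of bool, shape (N,)
        True for the ``n'`` annotated nodes.
    class_names : list of str
        The ``K`` label names.
    feature_names : list of str, optional
    """

    node_ids: list
    adjacency: sp.csr_array
    counts: np.ndarray
    labels: np.ndarray
    labeled_mask: np.ndarray
    class_names: list
    feature_names: list | None = None

    def __post_init__(self):
        self.adjacency = _as_csr(self.adjacency)
        self.counts = np.asarray(self.counts, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.int8)
        self.labeled_mask = np.asarray(self.labeled_mask, dtype=bool)
        n = len(self.node_ids)
        if n < 1 or self.counts.shape[1] < 1 or self.labels.shape[1] < 1:
            raise ValueError("N, M and K must all be >= 1")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if self.counts.shape[0] != n or self.labels.shape[0] != n:
            raise ValueError("table row counts do not match node count")
        if self.labeled_mask.shape != (n,):
            raise ValueError("labeled_mask length does not match node count")
        if (self.adjacency - self.adjacency.T).count_nonzero() != 0:
            raise ValueError("adjacency must be symmetric")
        if self.adjacency.diagonal().any():
            raise ValueError("adjacency must have a zero diagonal")
        vals = self.adjacency.data
        if vals.size and not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be binary")
        if (self.counts < 0).any():
            raise ValueError("feature counts must be nonnegative")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary")
        if self.labeled_mask.sum() < 1:
            raise ValueError("at least one labeled node is required")
        if (self.labels[self.labeled_mask].sum(axis=1) < 1).any():
            raise ValueError("every labeled node must carry >= 1 positive label")
        if len(self.class_names) != self.labels.shape[1]:
            raise ValueError("class_names length does not match label table")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def n_classes(self) -> int:
        return self.labels.shape[1]

    @property
    def n_labeled(self) -> int:
        return int(self.labeled_mask.sum())


@dataclass
class ScoreTable:
    """Per-node label probabilities plus derived relevant-label sets."""

    node_ids: list
    class_names: list
    scores: np.ndarray
    relevant_sets: list = field(default_factory=list)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2:
            raise ValueError("scores must be 2-D")
        if (self.scores < 0).any():
            raise ValueError("scores must be nonnegative")
        if not np.allclose(self.scores.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("score rows must sum to 1 within 1e-9")
        if len(self.relevant_sets) != len(self.node_ids):
            raise ValueError("one relevant set per node is required")
        allowed = set(self.class_names)
        for s in self.relevant_sets:
            if not s:
                raise ValueError("relevant sets must be nonempty")
            if not set(s) <= allowed:
                raise ValueError("relevant sets must be subsets of the classes")


# ---------------------------------------------------------------------------
# readers


def read_edge_list(path, node_ids=None):
    """Read a 2-column undirected edge list.

    Returns ``(adjacency, node_ids)``; node order is first appearance unless
    an explicit ``node_ids`` list is supplied.  Self loops are dropped with a
    warning, duplicate edges collapse to a single undirected edge.
    """
    pairs = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if not toks:
                continue
            if len(toks) != 2:
                raise ValueError(f"malformed edge line: {line!r}")
            pairs.append((toks[0], toks[1]))
    if not pairs:
        raise ValueError(f"{path}: empty edge list")
    if node_ids is None:
        node_ids = []
        seen = {}
        for a, b in pairs:
            for t in (a, b):
                if t not in seen:
                    seen[t] = len(node_ids)
                    node_ids.append(t)
    index = {v: i for i, v in enumerate(node_ids)}
    rows, cols = [], []
    n_loops = 0
    for a, b in pairs:
        if a == b:
            n_loops += 1
            continue
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
    if n_loops:
        logger.warning("dropped %d self-loop rows", n_loops)
    if not rows:
        raise ValueError(f"{path}: no valid (non-self-loop) edges")
    n = len(node_ids)
    adj = sp.csr_array(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    adj.data[:] = 1.0  # collapse duplicates
    return adj, list(node_ids)


def read_feature_table(path, encoding="categorical"):
    """Read a TSV feature table (header row; first column = node id).

    ``encoding='categorical'`` expands every (attribute, value) pair into an
    indicator column with count 1; missing values become an explicit
    ``(attr, missing)`` indicator.  ``encoding='counts'`` uses the numeric
    values as-is and rejects negatives.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise ValueError("duplicate node ids in feature table")
    if encoding == "counts":
        vals = df.astype(float)
        if (vals.values < 0).any():
            raise ValueError("negative value in counts-encoded feature table")
        return vals.values, list(df.index.astype(str)), list(df.columns)
    if encoding != "categorical":
        raise ValueError(f"unknown encoding {encoding!r}")
    filled = df.fillna("missing")
    onehot = pd.get_dummies(filled, prefix_sep="=", dtype=float)
    return onehot.values, list(df.index.astype(str)), list(onehot.columns)


def read_label_table(path, node_ids):
    """Read a TSV label table over a known node universe.

    Nodes absent from the file are unlabeled; listed nodes must carry at
    least one positive label, appear once, and be known.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"node(s) listed more than once in label table: {dup}")
    class_names = list(df.columns)
    index = {v: i for i, v in enumerate(node_ids)}
    n, k = len(node_ids), len(class_names)
    labels = np.zeros((n, k), dtype=np.int8)
    mask = np.zeros(n, dtype=bool)
    for nid, row in df.iterrows():
        nid = str(nid)
        if nid not in index:
            raise ValueError(f"unknown node id in label table: {nid!r}")
        vals = row.values.astype(float)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError(f"non-binary label entry for node {nid!r}")
        if vals.sum() < 1:
            raise ValueError(f"labeled node {nid!r} has an all-zero label row")
        i = index[nid]
        labels[i] = vals.astype(np.int8)
        mask[i] = True
    return labels, mask, class_names


def load_dataset(edges_path, features_path, labels_path, encoding="categorical"):
    """Assemble a :class:`NetworkedDataset` from the three TSV files.

    Node order: first appearance in the edge list, then any feature-table
    nodes absent from the edge list appended as isolated nodes (logged).
    """
    adj, node_ids = read_edge_list(edges_path)
    counts, feat_ids, feat_names = read_feature_table(features_path, encoding)
    extra = [v for v in feat_ids if v not in set(node_ids)]
    if extra:
        logger.info("retaining %d isolated node(s) present only in the feature table", len(extra))
        n_new = len(node_ids) + len(extra)
        adj = sp.csr_array(
            (adj.data, adj.indices, np.concatenate([adj.indptr, np.full(len(extra), adj.indptr[-1])])),
            shape=(n_new, n_new),
        )
        node_ids = node_ids + extra
    row_of = {v: i for i, v in enumerate(feat_ids)}
    missing = [v for v in node_ids if v not in row_of]
    if missing:
        raise ValueError(f"nodes missing from the feature table: {missing[:5]}")
    counts = counts[[row_of[v] for v in node_ids]]
    labels, mask, class_names = read_label_table(labels_path, node_ids)
    return NetworkedDataset(
        node_ids=node_ids,
        adjacency=adj,
        counts=counts,
        labels=labels,
        labeled_mask=mask,
        class_names=class_names,
        feature_names=feat_names,
    )


# ---------------------------------------------------------------------------
# score I/O


def write_scores(table: ScoreTable, path):
    """Write a ScoreTable as TSV (15 significant digits; lossless at 1e-9)."""
    with open(path, "w") as fh:
        fh.write("node_id\t" + "\t".join(map(str, table.class_names)) + "\trelevant\n")
        for nid, row, rel in zip(table.node_ids, table.scores, table.relevant_sets):
            probs = "\t".join(f"{v:.15g}" for v in row)
            fh.write(f"{nid}\t{probs}\t{';'.join(map(str, rel))}\n")


def read_scores(path) -> ScoreTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    class_names = list(df.columns[:-1])
    scores = df[class_names].values.astype(float)
    relevant = [str(s).split(";") for s in df["relevant"]]
    return ScoreTable(
        node_ids=list(df.index.astype(str)),
        class_names=class_names,
        scores=scores,
        relevant_sets=relevant,
    )
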