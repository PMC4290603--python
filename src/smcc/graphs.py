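"""Latent graph construction for the ensemble classifier.

Three kinds of graphs feed the network regularizer:

* ``ppi`` — the observed interaction network itself.
* ``rwr`` — an even-step random walk with restart: the walker moves on the
  two-step transition structure of the network (so it favors triangle-closing
  level-1 neighbors and well-connected level-2 neighbors) and restarts with a
  fixed probability; the accumulated visiting probabilities become edge
  weights.
* ``predsim`` — a kNN graph over nodes' class-confidence vectors produced by
  one-vs-rest probabilistic classifiers trained on the labeled nodes'
  attribute features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.linear_model import LogisticRegression

from .data import NetworkedDataset

logger = logging.getLogger("smcc")

__all__ = [
    "LatentGraph",
    "RWRConfig",
    "KNNConfig",
    "ppi_graph",
    "even_step_rwr",
    "prediction_similarity",
    "SklearnProbabilisticClassifier",
]


@dataclass
class LatentGraph:
    """Symmetric nonnegative weighted adjacency with provenance."""

    weights: sp.csr_array
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("ppi", "rwr", "predsim"):
            raise ValueError(f"unknown latent graph kind {self.kind!r}")
        self.weights = sp.csr_array(self.weights)
        if not np.isfinite(self.weights.data).all():
            raise ValueError("graph weights must be finite")
        if (self.weights.data < 0).any():
            raise ValueError("graph weights must be nonnegative")
        if (abs(self.weights - self.weights.T) > 1e-12).count_nonzero():
            raise ValueError("graph weights must be symmetric")
        if self.kind in ("ppi", "predsim") and self.weights.diagonal().any():
            raise ValueError(f"{self.kind} graph must have a zero diagonal")


@dataclass
class RWRConfig:
    restart: float = 0.1
    steps: int = 10

    def __post_init__(self):
        if not 0 < self.restart < 1:
            raise ValueError("restart probability must lie in (0, 1)")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass
class KNNConfig:
    k: int = 10

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")


def ppi_graph(dataset: NetworkedDataset) -> LatentGraph:
    """The observed interaction network, passed through unchanged."""
    return LatentGraph(dataset.adjacency.copy(), "ppi")


def even_step_rwr(dataset: NetworkedDataset, config: RWRConfig | None = None) -> LatentGraph:
    """Even-step random walk with restart over the network.

    Forms the two-step reachability counts ``E @ E``, column-normalizes them
    to a transition matrix ``P``, accumulates
    ``R = sum_{t=1..T} restart * (1 - restart)^t * P^t`` and symmetrizes the
    result as ``(R + R^T) / 2``.
    """
    if config is None:
        config = RWRConfig()
    e = dataset.adjacency.toarray()
    p2 = e @ e
    col = p2.sum(axis=0)
    dead = col == 0
    if dead.any():
        logger.info("%d node(s) unreachable by two-step walks; columns left zero", int(dead.sum()))
    phat = np.divide(p2, col, out=np.zeros_like(p2), where=col > 0)
    r = np.zeros_like(phat)
    pt = np.eye(len(col))
    decay = 1.0
    for _ in range(config.steps):
        pt = phat @ pt
        decay *= 1.0 - config.restart
        r += config.restart * decay * pt
    r = 0.5 * (r + r.T)
    return LatentGraph(sp.csr_array(r), "rwr", {"restart": config.restart, "steps": config.steps})


class SklearnProbabilisticClassifier:
    """Default base classifier: a linear probabilistic model (C = 1.0).

    Satisfies the ``train(features, binary_targets)`` /
    ``predict_confidences(features)`` contract; degenerate single-class
    training sets yield a constant confidence equal to the labeled prior.
    """

    def __init__(self, estimator=None):
        self._factory = estimator
        self._model = None
        self._constant = None

    def train(self, features, targets):
        targets = np.asarray(targets)
        if len(np.unique(targets)) < 2:
            self._constant = float(np.mean(targets))
            self._model = None
            return
        self._model = (
            self._factory() if self._factory is not None
            else LogisticRegression(C=1.0, max_iter=1000)
        )
        self._model.fit(features, targets)
        self._constant = None

    def predict_confidences(self, features):
        if self._model is None:
            return np.full(np.asarray(features).shape[0], self._constant)
        proba = self._model.predict_proba(features)
        pos = list(self._model.classes_).index(1)
        return proba[:, pos]


def prediction_similarity(
    dataset: NetworkedDataset,
    base_classifier=None,
    knn: KNNConfig | None = None,
    seed=None,
) -> LatentGraph:
    """kNN graph over one-vs-rest class-confidence vectors.

    For each class a probabilistic classifier is trained on the labeled
    nodes' feature counts and scores every node; the per-node confidence
    vectors are scaled to unit length and their pairwise cosine similarities
    sparsified to a binary symmetric kNN graph (edge iff either endpoint is
    among the other's k nearest neighbors; ties broken by node order).
    """
    if knn is None:
        knn = KNNConfig()
    n, k_classes = dataset.n_nodes, dataset.n_classes
    if knn.k >= n:
        raise ValueError("k must be smaller than the number of nodes")
    mask = dataset.labeled_mask
    conf = np.zeros((n, k_classes))
    for c in range(k_classes):
        clf = base_classifier if base_classifier is not None else SklearnProbabilisticClassifier()
        y = dataset.labels[mask, c]
        if len(np.unique(y)) < 2:
            logger.info("class %d one-vs-rest problem is degenerate; constant confidence", c)
        clf.train(dataset.counts[mask], y)
        conf[:, c] = clf.predict_confidences(dataset.counts)
    norms = np.linalg.norm(conf, axis=1, keepdims=True)
    zero_rows = (norms == 0).ravel()
    if zero_rows.any():
        conf[zero_rows] = 1.0
        norms = np.linalg.norm(conf, axis=1, keepdims=True)
    unit = conf / norms
    sim = unit @ unit.T
    np.fill_diagonal(sim, -np.inf)  # exclude self from neighbor lists
    adj = np.zeros((n, n), dtype=float)
    for i in range(n):
        # stable sort => ties broken by node order
        nbrs = np.argsort(-sim[i], kind="stable")[: knn.k]
        adj[i, nbrs] = 1.0
        adj[nbrs, i] = 1.0
    np.fill_diagonal(adj, 0.0)
    return LatentGraph(sp.csr_array(adj), "predsim", {"k": knn.k})
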