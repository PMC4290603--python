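"""EGM-SMCC: ensemble of GM-SMCC models over multiple latent graphs.

One GM-SMCC model is fitted per latent graph (each model's network
regularizer uses that graph) and the per-node label probability tables are
combined by an arithmetic mean; the relevant-label sets are derived from the
averaged table.  An ``average-graphs`` mode instead averages the graph
weight matrices and fits a single model (the "mean-graph" variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import ScoreTable
from .graphs import LatentGraph, ppi_graph, even_step_rwr, prediction_similarity
from .model import GMSMCC, GMSMCCResults, predict_labels

logger = logging.getLogger("smcc")

__all__ = ["EGMSMCC", "EnsembleResult", "fit_ensemble", "default_graphs"]


def default_graphs(dataset, seed=None) -> list[LatentGraph]:
    """The standard trio: observed network, even-step RWR, prediction-similarity kNN."""
    return [
        ppi_graph(dataset),
        even_step_rwr(dataset),
        prediction_similarity(dataset, seed=seed),
    ]


@dataclass
class EnsembleResult:
    """Component fits plus their averaged probability table.

    ``component_results`` is aligned with ``graphs``; the average is taken
    over the converged components only (non-converged ones are retained for
    inspection but excluded from the mean).
    """

    component_results: list
    graphs: list
    averaged_scores: np.ndarray
    dataset: object

    def __post_init__(self):
        if len(self.component_results) < 1:
            raise ValueError("ensemble requires at least one component")
        if not np.allclose(self.averaged_scores.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("averaged rows must sum to 1 within 1e-9")

    @property
    def component_scores(self):
        return [r.scores for r in self.component_results]

    def predict_labels(self) -> ScoreTable:
        return predict_labels(
            self.averaged_scores, self.dataset.node_ids, self.dataset.class_names
        )

    def summary(self) -> str:
        lines = ["EGM-SMCC ensemble summary", "========================="]
        for res, g in zip(self.component_results, self.graphs):
            kind = getattr(g, "kind", "custom")
            lines.append(
                f"component [{kind}]: {res.n_iterations} iterations, converged={res.converged}"
            )
        lines.append(f"components combined: {len(self.component_results)}")
        return "\n".join(lines)


class EGMSMCC:
    """Ensemble model: one GM-SMCC per latent graph, predictions averaged.

    Parameters mirror :class:`~smcc.model.GMSMCC`; ``graphs`` defaults to the
    {ppi, rwr, predsim} trio constructed from the dataset, and ``mode``
    selects between averaging the fitted models' probability tables
    (``'average-models'``) and averaging the graph weights before a single
    fit (``'average-graphs'``).
    """

    def __init__(self, dataset, graphs=None, alpha=3.0, beta=0.1, mode="average-models", seed=None):
        if mode not in ("average-models", "average-graphs"):
            raise ValueError(f"unknown ensemble mode {mode!r}")
        self.dataset = dataset
        self.graphs = graphs if graphs is not None else default_graphs(dataset, seed=seed)
        if not self.graphs:
            raise ValueError("at least one latent graph is required")
        self.alpha = alpha
        self.beta = beta
        self.mode = mode

    def fit(self, **fit_kwargs) -> EnsembleResult:
        ds = self.dataset
        if self.mode == "average-graphs":
            mean_w = sum(sp.csr_array(getattr(g, "weights", g)) for g in self.graphs) / len(self.graphs)
            res = GMSMCC(ds, graph=mean_w, alpha=self.alpha, beta=self.beta).fit(**fit_kwargs)
            return EnsembleResult([res], self.graphs, res.scores.copy(), ds)
        results: list[GMSMCCResults] = []
        for g in self.graphs:
            results.append(GMSMCC(ds, graph=g, alpha=self.alpha, beta=self.beta).fit(**fit_kwargs))
        kept = [r for r in results if r.converged]
        if not kept:
            raise RuntimeError("no ensemble component converged")
        dropped = len(results) - len(kept)
        if dropped:
            logger.warning("%d non-converged component(s) excluded from the average", dropped)
        avg = np.mean([r.scores for r in kept], axis=0)
        return EnsembleResult(results, self.graphs, avg, ds)


def fit_ensemble(dataset, graphs, alpha=3.0, beta=0.1, mode="average-models", **fit_kwargs):
    """Functional wrapper around :class:`EGMSMCC`."""
    return EGMSMCC(dataset, graphs=graphs, alpha=alpha, beta=beta, mode=mode).fit(**fit_kwargs)
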