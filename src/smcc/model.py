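"""GM-SMCC: a graph- and label-regularized pLSA model for semi-supervised
multi-label collective classification.

The model treats the ``K`` functional classes as the latent variables of a
pLSA mixture over node feature counts and maximizes

    O = L - alpha * R - beta * H

where ``L`` is the pLSA log-likelihood
``sum_ij n(x_i, w_j) log sum_k P(w_j|c_k) P(c_k|x_i)``,
``R`` penalizes symmetric-KL divergence between the class distributions of
linked nodes (network smoothness), and ``H`` penalizes symmetric-KL-shaped
divergence between the per-node probability profiles of correlated labels,
weighted by the cosine label-affinity matrix ``F``.

Fitting is EM with the labeled nodes' ``P(c|x)`` rows clamped to a uniform
distribution over their known labels at every iteration.  The regularized
M-step for ``P(c|x)`` solves a sparse symmetric linear system obtained from
the Lagrangian stationarity conditions under the ``log x ~ 1 - 1/x``
approximation; with ``alpha = beta = 0`` the system is diagonal and the
update reduces exactly to the textbook pLSA M-step.

Usage follows the model/results convention::

    model = GMSMCC(dataset, graph=None, alpha=3.0, beta=0.1)
    res = model.fit()
    res.predict_labels()      # ScoreTable with relevant-label sets
    res.objective_trace       # per-iteration (O, L, R, H)
"""

from __future__ import annotations

import logging
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import cg, spsolve

from .data import NetworkedDataset, ScoreTable

logger = logging.getLogger("smcc")

__all__ = [
    "ModelParams",
    "RegularizerWeights",
    "LabelAffinity",
    "MStepSystem",
    "GMSMCC",
    "GMSMCCResults",
    "symmetric_kl",
    "log_likelihood",
    "network_regularizer",
    "label_affinity",
    "label_regularizer",
    "objective",
    "clamp_labeled",
    "init_params",
    "e_step",
    "m_step_pwc",
    "m_step_pcx",
    "build_mstep_system",
    "predict_labels",
    "instance_similarity",
]

DEFAULT_EPS = 1e-12

ObjectiveParts = namedtuple("ObjectiveParts", "objective loglik network_pen label_pen")


# ---------------------------------------------------------------------------
# parameter containers


@dataclass
class ModelParams:
    """The two conditional probability tables of the mixture.

    ``p_w_given_c`` is M x K and column-stochastic; ``p_c_given_x`` is N x K
    and row-stochastic.
    """

    p_w_given_c: np.ndarray
    p_c_given_x: np.ndarray

    def __post_init__(self):
        self.p_w_given_c = np.asarray(self.p_w_given_c, dtype=float)
        self.p_c_given_x = np.asarray(self.p_c_given_x, dtype=float)
        if self.p_w_given_c.shape[1] != self.p_c_given_x.shape[1]:
            raise ValueError("class dimensions of the two tables disagree")
        if (self.p_w_given_c < 0).any() or (self.p_c_given_x < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.allclose(self.p_w_given_c.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("columns of P(w|c) must sum to 1 within 1e-9")
        if not np.allclose(self.p_c_given_x.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of P(c|x) must sum to 1 within 1e-9")


@dataclass
class RegularizerWeights:
    alpha: float = 3.0
    beta: float = 0.1

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("regularization weights must be nonnegative")


@dataclass
class LabelAffinity:
    """Symmetric K x K cosine co-occurrence matrix F over the labels."""

    f: np.ndarray

    def __post_init__(self):
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2 or self.f.shape[0] != self.f.shape[1]:
            raise ValueError("affinity must be square")
        if not np.allclose(self.f, self.f.T, atol=1e-12):
            raise ValueError("affinity must be symmetric")
        if (self.f < -1e-12).any() or (self.f > 1 + 1e-9).any():
            raise ValueError("affinity entries must lie in [0, 1]")


# ---------------------------------------------------------------------------
# elementary quantities


def _floor_renorm_rows(mat, eps):
    out = np.maximum(mat, eps)
    return out / out.sum(axis=1, keepdims=True)


def symmetric_kl(p, q, eps=DEFAULT_EPS):
    """Symmetric KL divergence 0.5*[D(p||q) + D(q||p)] with natural log.

    Entries are floored at ``eps`` and each vector renormalized before the
    divergence is taken, so exact zeros (e.g. from label clamping) stay
    finite.  Zero iff p == q after flooring.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("p and q must have the same length")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise ValueError("non-finite input to symmetric_kl")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if abs(p.sum() - 1) > 1e-6 or abs(q.sum() - 1) > 1e-6:
        raise ValueError("inputs must sum to 1")
    ph = np.maximum(p, eps)
    ph = ph / ph.sum()
    qh = np.maximum(q, eps)
    qh = qh / qh.sum()
    return float(0.5 * np.sum((ph - qh) * (np.log(ph) - np.log(qh))))


def _pcx_of(params):
    return params.p_c_given_x if isinstance(params, ModelParams) else np.asarray(params, float)


def log_likelihood(dataset: NetworkedDataset, params: ModelParams, eps=DEFAULT_EPS):
    """pLSA log-likelihood L = sum_ij n(x_i,w_j) log sum_k P(w_j|c_k)P(c_k|x_i)."""
    counts = dataset.counts
    mix = params.p_c_given_x @ params.p_w_given_c.T
    nz = counts > 0
    vals = mix[nz]
    n_floored = int((vals <= 0).sum())
    if n_floored:
        logger.warning("floored %d zero mixture cells in the likelihood", n_floored)
    return float(np.sum(counts[nz] * np.log(np.maximum(vals, eps))))


def network_regularizer(params, adjacency, eps=DEFAULT_EPS):
    """R = sum over ordered node pairs of E_is * symKL(z_i, z_s).

    Each undirected edge contributes twice (once per orientation).  Weighted
    graphs are consumed as-is, the weight scaling the pairwise divergence.
    """
    pcx = _pcx_of(params)
    z = _floor_renorm_rows(pcx, eps)
    logz = np.log(z)
    rows, cols, w = sp.find(sp.csr_array(adjacency))
    if rows.size == 0:
        return 0.0
    d = 0.5 * np.sum((z[rows] - z[cols]) * (logz[rows] - logz[cols]), axis=1)
    return float(np.sum(w * d))


def label_affinity(dataset: NetworkedDataset) -> LabelAffinity:
    """Cosine similarity F_kl between the labeled-node indicator columns.

    Each class column over the labeled nodes is scaled to unit Euclidean
    length; classes without labeled positives get a zero row/column with
    F_kk fixed at 1 by convention.
    """
    y = dataset.labels[dataset.labeled_mask].astype(float)
    norms = np.linalg.norm(y, axis=0)
    empty = norms == 0
    if empty.any():
        logger.warning("%d class(es) have no labeled positives", int(empty.sum()))
    yn = np.divide(y, norms, out=np.zeros_like(y), where=norms > 0)
    f = yn.T @ yn
    np.fill_diagonal(f, 1.0)
    return LabelAffinity(np.clip(f, 0.0, 1.0))


def label_regularizer(params, affinity: LabelAffinity, eps=DEFAULT_EPS):
    """H = sum over ordered class pairs of F_kl * symKL-shaped(r_k, r_l).

    The columns r_k of P(c|x) are used raw (floored at ``eps`` but *not*
    renormalized): they are profiles over instances, not distributions, and
    the penalty follows the written form of the objective.
    """
    r = np.maximum(_pcx_of(params), eps)
    logr = np.log(r)
    c = r.T @ logr  # c[k, l] = sum_i r_ik log r_il
    diag = np.diag(c)
    d = 0.5 * (diag[:, None] + diag[None, :] - c - c.T)
    return float(np.sum(affinity.f * d))


def objective(dataset, params, adjacency, affinity, weights: RegularizerWeights, eps=DEFAULT_EPS):
    """O = L - alpha*R - beta*H; returns (O, L, R, H)."""
    ll = log_likelihood(dataset, params, eps)
    r = network_regularizer(params, adjacency, eps) if weights.alpha > 0 else 0.0
    h = label_regularizer(params, affinity, eps) if weights.beta > 0 else 0.0
    return ObjectiveParts(ll - weights.alpha * r - weights.beta * h, ll, r, h)


# ---------------------------------------------------------------------------
# EM pieces


def clamp_labeled(pcx, dataset: NetworkedDataset):
    """Reset labeled rows of P(c|x) to uniform over their known labels."""
    pcx = np.array(_pcx_of(pcx), dtype=float, copy=True)
    mask = dataset.labeled_mask
    y = dataset.labels[mask].astype(float)
    pcx[mask] = y / y.sum(axis=1, keepdims=True)
    return pcx


def init_params(dataset: NetworkedDataset, smoothing=None) -> ModelParams:
    """Initialize from the labeled class priors.

    P(w|c) columns are smoothed relative co-occurrence frequencies of each
    feature with each class over the labeled nodes (default smoothing 1/M);
    unlabeled P(c|x) rows get the labeled-set class-prior distribution and
    labeled rows are clamped.
    """
    m = dataset.n_features
    s = (1.0 / m) if smoothing is None else float(smoothing)
    yl = dataset.labels[dataset.labeled_mask].astype(float)
    xl = dataset.counts[dataset.labeled_mask]
    nwc = xl.T @ yl  # M x K co-occurrence counts
    if (yl.sum(axis=0) == 0).any():
        logger.warning("class(es) with zero labeled positives initialized to uniform columns")
    pwc = nwc + s
    pwc = pwc / pwc.sum(axis=0, keepdims=True)
    prior = yl.sum(axis=0)
    prior = prior / prior.sum()
    pcx = np.tile(prior, (dataset.n_nodes, 1))
    pcx = clamp_labeled(pcx, dataset)
    return ModelParams(pwc, pcx)


class Posterior:
    """Lazy accessor for the E-step posteriors P(c_k | x_i, w_j).

    The full N x M x K tensor is never materialized; only the cells with
    n(x_i, w_j) > 0 enter the M-step sums, via the sparse ratio matrix
    S_ij = n_ij / sum_k P(w_j|c_k)P(c_k|x_i).
    """

    def __init__(self, counts, pwc, pcx):
        self.pwc = np.asarray(pwc, float)
        self.pcx = np.asarray(pcx, float)
        self.n_classes = self.pwc.shape[1]
        counts = sp.csr_array(counts)
        rows, cols, nvals = sp.find(counts)
        mix = np.sum(self.pcx[rows] * self.pwc[cols], axis=1)
        zero = mix <= 0
        if zero.any():
            logger.warning("%d cells with zero mixture; posterior set uniform", int(zero.sum()))
        svals = np.zeros_like(nvals, dtype=float)
        svals[~zero] = nvals[~zero] / mix[~zero]
        self._s = sp.csr_array((svals, (rows, cols)), shape=counts.shape)
        self._zero_cells = (rows[zero], cols[zero], nvals[zero])

    def at(self, i, j):
        """Posterior vector over the K classes at cell (i, j)."""
        post = self.pwc[j] * self.pcx[i]
        den = post.sum()
        if den <= 0:
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return post / den

    def node_class_totals(self):
        """N x K array Z with Z[i,k] = sum_j n(x_i,w_j) * P(c_k|x_i,w_j)."""
        z = self.pcx * (self._s @ self.pwc)
        ri, _, nv = self._zero_cells
        if ri.size:
            np.add.at(z, ri, (nv / self.n_classes)[:, None])
        return z

    def feature_class_totals(self):
        """M x K array with entry [j,k] = sum_i n(x_i,w_j) * P(c_k|x_i,w_j)."""
        t = self.pwc * (self._s.T @ self.pcx)
        _, cj, nv = self._zero_cells
        if cj.size:
            np.add.at(t, cj, (nv / self.n_classes)[:, None])
        return t


def e_step(dataset: NetworkedDataset, params: ModelParams) -> Posterior:
    """Bayes posterior over the latent classes at every observed count cell."""
    return Posterior(dataset.counts, params.p_w_given_c, params.p_c_given_x)


def m_step_pwc(dataset: NetworkedDataset, posterior: Posterior):
    """pLSA M-step for P(w|c): posterior-weighted feature frequencies per class."""
    num = posterior.feature_class_totals()
    col = num.sum(axis=0)
    empty = col <= 0
    if empty.any():
        logger.warning("%d empty class(es) in M-step; columns left unchanged", int(empty.sum()))
        num[:, empty] = posterior.pwc[:, empty]
        col = num.sum(axis=0)
    return num / col


@dataclass
class MStepSystem:
    """The symmetric linear system of the regularized M-step for P(c|x).

    Class-major stacking: the unknown y concatenates the K per-class
    node vectors, index k*N + i.  The assembled matrix is
    ``diag(omega) + alpha * graph_operator + beta * label_operator`` where
    the graph operator is I_K kron L_E (per-class graph Laplacian) and the
    label operator is L_F kron I_N (per-node label Laplacian), both PSD.
    """

    z: np.ndarray
    omega_diag: np.ndarray
    graph_operator: sp.csr_array
    label_operator: sp.csr_array
    alpha: float
    beta: float
    n_nodes: int
    n_classes: int

    def matrix(self) -> sp.csr_array:
        a = sp.diags_array(self.omega_diag, format="csr")
        if self.alpha > 0:
            a = a + self.alpha * self.graph_operator
        if self.beta > 0:
            a = a + self.beta * self.label_operator
        return sp.csr_array(a)


def _laplacian(w) -> sp.csr_array:
    w = sp.csr_array(w)
    deg = np.asarray(w.sum(axis=1)).ravel()
    return sp.csr_array(sp.diags_array(deg) - w)


def build_mstep_system(dataset, posterior, adjacency, affinity, weights) -> MStepSystem:
    n, k = dataset.n_nodes, posterior.n_classes
    z2d = posterior.node_class_totals()
    rho = z2d.sum(axis=1)
    row_counts = np.asarray(dataset.counts.sum(axis=1)).ravel()
    # posterior normalization makes rho_i the per-node total count
    if not np.allclose(rho, row_counts, rtol=1e-9, atol=1e-9):
        raise AssertionError("Omega diagonal does not equal per-node total counts")
    graph_op = sp.csr_array(sp.kron(sp.eye_array(k), _laplacian(adjacency), format="csr"))
    label_op = sp.csr_array(sp.kron(_laplacian(affinity.f), sp.eye_array(n), format="csr"))
    return MStepSystem(
        z=z2d.T.ravel(),
        omega_diag=np.tile(rho, k),
        graph_operator=graph_op,
        label_operator=label_op,
        alpha=weights.alpha,
        beta=weights.beta,
        n_nodes=n,
        n_classes=k,
    )


def _solve_spd(a, b, x0):
    sol, info = cg(a, b, x0=x0, rtol=1e-12, atol=0.0, maxiter=5 * len(b))
    if info != 0 or not np.isfinite(sol).all():
        logger.warning("CG did not converge (info=%s); falling back to direct solve", info)
        sol = spsolve(sp.csc_array(a), b)
    return sol


def m_step_pcx(dataset, posterior, adjacency, affinity, weights, eps=DEFAULT_EPS, prev_pcx=None):
    """Regularized M-step for P(c|x): solve the sparse symmetric system,
    floor/renormalize rows, re-clamp labeled rows."""
    n, k = dataset.n_nodes, posterior.n_classes
    if prev_pcx is None:
        prev_pcx = posterior.pcx
    system = build_mstep_system(dataset, posterior, adjacency, affinity, weights)
    a = system.matrix()
    b = system.z
    deg = np.asarray(sp.csr_array(adjacency).sum(axis=1)).ravel()
    bad = (np.asarray(dataset.counts.sum(axis=1)).ravel() == 0) & (deg == 0)
    y = np.empty(n * k)
    x0 = prev_pcx.T.ravel()
    if bad.any():
        logger.warning("%d isolated zero-count node(s); rows kept at previous value", int(bad.sum()))
        keep = ~np.tile(bad, k)
        idx = np.flatnonzero(keep)
        a_red = a[idx][:, idx]
        y[keep] = _solve_spd(a_red, b[keep], x0[keep])
        y[~keep] = x0[~keep]
    else:
        y[:] = _solve_spd(a, b, x0)
    pcx = y.reshape(k, n).T
    pcx = _floor_renorm_rows(pcx, eps)
    return clamp_labeled(pcx, dataset)


# ---------------------------------------------------------------------------
# prediction helpers


def predict_labels(scores, node_ids=None, class_names=None) -> ScoreTable:
    """Split each node's labels into relevant/irrelevant by the largest-gap rule.

    Scores are sorted in decreasing order (stable, so ties keep class order);
    the threshold is the midpoint of the largest gap between successive sorted
    values and the relevant set is every label scoring above it.  The top
    label is always relevant; an all-equal row falls back to the first class.
    """
    scores = np.asarray(scores, dtype=float)
    n, k = scores.shape
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(n)]
    if class_names is None:
        class_names = [f"c{j + 1}" for j in range(k)]
    names = np.asarray(class_names, dtype=object)
    relevant = []
    for row in scores:
        if k == 1:
            relevant.append([names[0]])
            continue
        order = np.argsort(-row, kind="stable")
        s = row[order]
        gaps = s[:-1] - s[1:]
        g = int(np.argmax(gaps))  # first occurrence wins exact ties
        if gaps[g] <= 0:
            logger.warning("all-equal score row; relevant set set to the first class")
            relevant.append([names[order[0]]])
            continue
        t = 0.5 * (s[g] + s[g + 1])
        relevant.append(list(names[row > t]))
    return ScoreTable(list(node_ids), list(class_names), scores, relevant)


def instance_similarity(scores, i, j):
    """Cosine similarity of two nodes' class-probability vectors in [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    a, b = scores[i], scores[j]
    return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))


# ---------------------------------------------------------------------------
# model / results objects


class GMSMCC:
    """Graph- and label-regularized semi-supervised pLSA classifier.

    Parameters
    ----------
    dataset : NetworkedDataset
    graph : LatentGraph, sparse matrix or None
        Network whose links are smoothed over; defaults to the dataset's
        own interaction network.
    alpha, beta : float
        Weights of the network and label regularizers.
    affinity : LabelAffinity, optional
        Precomputed label-affinity matrix; derived from the labeled nodes
        by default.
    """

    def __init__(self, dataset, graph=None, alpha=3.0, beta=0.1, affinity=None, eps=DEFAULT_EPS):
        self.dataset = dataset
        w = dataset.adjacency if graph is None else getattr(graph, "weights", graph)
        self.graph_weights = sp.csr_array(w)
        if self.graph_weights.shape != (dataset.n_nodes, dataset.n_nodes):
            raise ValueError("graph shape does not match the dataset")
        self.weights = RegularizerWeights(alpha, beta)
        self.affinity = affinity if affinity is not None else label_affinity(dataset)
        self.eps = eps

    def fit(self, max_iter=50, tol=1e-4, smoothing=None, start_params=None, seed=None):
        """Run EM until the relative objective change drops below ``tol``.

        ``seed`` is accepted for interface symmetry; the EM itself is
        deterministic given its inputs.
        """
        if max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if tol < 0:
            raise ValueError("tol must be nonnegative")
        ds, w = self.dataset, self.weights
        params = start_params if start_params is not None else init_params(ds, smoothing)
        trace = []
        converged = False
        prev_o = None
        for it in range(1, max_iter + 1):
            post = e_step(ds, params)
            pwc = m_step_pwc(ds, post)
            pcx = m_step_pcx(
                ds, post, self.graph_weights, self.affinity, w,
                eps=self.eps, prev_pcx=params.p_c_given_x,
            )
            params = ModelParams(pwc, pcx)
            parts = objective(ds, params, self.graph_weights, self.affinity, w, self.eps)
            if not np.isfinite(parts.objective):
                raise RuntimeError(f"non-finite objective at iteration {it}: {parts}")
            trace.append((it, *parts))
            logger.info(
                "iter %d\tO=%.6f\tL=%.6f\tR=%.6f\tH=%.6f",
                it, parts.objective, parts.loglik, parts.network_pen, parts.label_pen,
            )
            if prev_o is not None and abs(parts.objective - prev_o) / max(abs(prev_o), 1e-300) < tol:
                converged = True
                prev_o = parts.objective
                break
            prev_o = parts.objective
        trace_df = pd.DataFrame(
            trace, columns=["iteration", "objective", "loglik", "network_pen", "label_pen"]
        )
        return GMSMCCResults(self, params, trace_df, converged)


class GMSMCCResults:
    """Fit results: final parameter tables, objective trace and predictions."""

    def __init__(self, model: GMSMCC, params: ModelParams, trace: pd.DataFrame, converged: bool):
        self.model = model
        self.params = params
        self.objective_trace = trace
        self.converged = bool(converged)
        self.n_iterations = len(trace)

    @property
    def scores(self):
        """N x K row-stochastic table of P(c_k | x_i)."""
        return self.params.p_c_given_x

    def predict_labels(self) -> ScoreTable:
        ds = self.model.dataset
        return predict_labels(self.scores, ds.node_ids, ds.class_names)

    def instance_similarity(self, i, j):
        return instance_similarity(self.scores, i, j)

    def summary(self) -> str:
        ds = self.model.dataset
        last = self.objective_trace.iloc[-1]
        card = np.mean([len(s) for s in self.predict_labels().relevant_sets])
        lines = [
            "GM-SMCC fit summary",
            "===================",
            f"nodes: {ds.n_nodes}  features: {ds.n_features}  classes: {ds.n_classes}",
            f"labeled: {ds.n_labeled} ({100 * ds.n_labeled / ds.n_nodes:.1f}%)",
            f"alpha: {self.model.weights.alpha:g}  beta: {self.model.weights.beta:g}",
            f"iterations: {self.n_iterations}  converged: {self.converged}",
            f"objective: {last['objective']:.4f}  loglik: {last['loglik']:.4f}",
            f"network penalty: {last['network_pen']:.4f}  label penalty: {last['label_pen']:.4f}",
            f"mean predicted label cardinality: {card:.2f}",
        ]
        return "\n".join(lines)
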