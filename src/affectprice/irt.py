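"""Item response theory scoring for the affect scales.

Two measurement models are supported, matching the two instruments:

* a graded response model (GRM) for the four ordered 0-3 depression items,
  with cumulative-category logistic curves
  ``P(X >= k | theta) = logistic(a * (theta - b_k))`` and strictly ordered
  thresholds ``b_1 < ... < b_{K-1}``;
* a two-parameter logistic (2PL) model for the twelve yes/no neuroticism
  items, which is the two-category special case of the GRM.

Item parameters are estimated by marginal maximum likelihood with an EM
algorithm over a fixed quadrature grid; the latent scale is identified by a
standard-normal prior (mean 0, SD 1). Person scores are expected a
posteriori (EAP) means with posterior SDs on the same grid, so most
respondents land between -3 and +3 on the latent metric and a positive
theta indicates endorsement of the construct.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GradedItemParams",
    "BinaryItemParams",
    "ThetaEstimate",
    "QuadratureGrid",
    "DegenerateItemError",
    "default_grid",
    "fit_graded_model",
    "fit_2pl",
    "eap_theta",
    "eap_scores",
]

_PROB_FLOOR = 1e-12


class DegenerateItemError(ValueError):
    """Raised when an item has fewer than two observed categories."""


@dataclass(frozen=True)
class GradedItemParams:
    """GRM item: discrimination ``a`` and ordered thresholds."""

    a: float
    thresholds: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"discrimination must be positive, got {self.a}")
        th = np.asarray(self.thresholds, dtype=float)
        if th.ndim != 1 or th.size < 1:
            raise ValueError("thresholds must be a non-empty 1-D sequence")
        if np.any(np.diff(th) <= 0):
            raise ValueError(f"thresholds must be strictly increasing, got {tuple(th)}")


@dataclass(frozen=True)
class BinaryItemParams:
    """2PL item: discrimination ``a`` and difficulty ``b``."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError(f"discrimination must be positive, got {self.a}")


@dataclass(frozen=True)
class ThetaEstimate:
    eap_mean: float
    posterior_sd: float


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed latent-scale grid with normalized standard-normal prior weights."""

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.nodes.shape != self.weights.shape:
            raise ValueError("nodes and weights must have equal shape")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        if abs(float(self.weights.sum()) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def default_grid(n_nodes: int = 61, span: float = 6.0) -> QuadratureGrid:
    """Equally spaced nodes on [-span, span] weighted by the N(0,1) density."""
    nodes = np.linspace(-span, span, n_nodes)
    w = norm.pdf(nodes)
    return QuadratureGrid(nodes=nodes, weights=w / w.sum())


def _thresholds_matrix(items: Sequence[GradedItemParams | BinaryItemParams]):
    """Common internal form: list of (a, thresholds-array)."""
    out = []
    for it in items:
        if isinstance(it, BinaryItemParams):
            out.append((it.a, np.array([it.b], dtype=float)))
        else:
            out.append((it.a, np.asarray(it.thresholds, dtype=float)))
    return out


def category_probabilities(a: float, thresholds: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """(len(theta), K) category probabilities of the graded response model."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    th = np.asarray(thresholds, dtype=float)
    F = expit(a * (theta[:, None] - th[None, :]))  # P(X >= k), k = 1..K-1
    P = np.empty((theta.size, th.size + 1))
    P[:, 0] = 1.0 - F[:, 0]
    if th.size > 1:
        P[:, 1:-1] = F[:, :-1] - F[:, 1:]
    P[:, -1] = F[:, -1]
    return np.clip(P, _PROB_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# EM estimation
# ---------------------------------------------------------------------------


def _pack(a: float, th: np.ndarray) -> np.ndarray:
    """Unconstrained parameterization: [log a, b1, log gaps...]."""
    x = np.empty(th.size + 1)
    x[0] = np.log(a)
    x[1] = th[0]
    if th.size > 1:
        x[2:] = np.log(np.diff(th))
    return x


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(x[0]))
    th = np.empty(x.size - 1)
    th[0] = x[1]
    if th.size > 1:
        th[1:] = th[0] + np.cumsum(np.exp(x[2:]))
    return a, th


def _item_negll(x: np.ndarray, r: np.ndarray, nodes: np.ndarray):
    """Expected complete-data negative log-likelihood of one item + gradient.

    r is the (Q, K) table of expected category counts at each quadrature node.
    """
    a, th = _unpack(x)
    F = expit(a * (nodes[:, None] - th[None, :]))  # (Q, K-1)
    K = th.size + 1
    P = np.empty((nodes.size, K))
    P[:, 0] = 1.0 - F[:, 0]
    if K > 2:
        P[:, 1:-1] = F[:, :-1] - F[:, 1:]
    P[:, -1] = F[:, -1]
    P = np.clip(P, _PROB_FLOOR, None)
    nll = -float(np.sum(r * np.log(P)))

    W = r / P  # (Q, K)
    # d nll / d F_k for k = 1..K-1: F_k enters P_{k-1} with -1 and P_k with +1
    G = -(W[:, 1:] - W[:, :-1])  # (Q, K-1)
    dF_da = F * (1.0 - F) * (nodes[:, None] - th[None, :])
    dF_db = -a * F * (1.0 - F)
    g_a = float(np.sum(G * dF_da))
    g_b = np.sum(G * dF_db, axis=0)  # per threshold

    grad = np.empty_like(x)
    grad[0] = a * g_a  # d/d log a
    grad[1] = float(np.sum(g_b))  # b1 shifts every threshold
    if th.size > 1:
        # log-gap d_l moves thresholds b_l..b_{K-1}
        tail = np.cumsum(g_b[::-1])[::-1]
        grad[2:] = np.exp(x[2:]) * tail[1:]
    return nll, grad


_BOUNDS_LOGA = (-4.0, 2.5)
_BOUNDS_B = (-8.0, 8.0)
_BOUNDS_LOGGAP = (-6.0, 3.0)
_WEAK_A = 0.2


def _start_values(counts: np.ndarray) -> np.ndarray:
    """Logit start thresholds from marginal cumulative proportions, a = 1."""
    p = counts / counts.sum()
    tail = np.clip(1.0 - np.cumsum(p)[:-1], 1e-3, 1 - 1e-3)  # P(X >= k)
    th = -np.log(tail / (1.0 - tail))  # b_k = -logit(P(X >= k)) at a = 1
    # enforce strict ordering
    for k in range(1, th.size):
        if th[k] <= th[k - 1]:
            th[k] = th[k - 1] + 1e-3
    return _pack(1.0, th)


def _fit_mml(
    X: np.ndarray,
    n_categories: int,
    grid: QuadratureGrid,
    max_iter: int,
    tol: float,
    item_names: Sequence[str] | None,
) -> tuple[list[tuple[float, np.ndarray]], dict]:
    X = np.asarray(X)
    if X.ndim != 2:
        raise ValueError("response matrix must be 2-D")
    n, J = X.shape
    names = list(item_names) if item_names is not None else [f"item{j}" for j in range(J)]
    if np.any(X < 0) or np.any(X >= n_categories):
        raise ValueError(
            f"responses must lie in 0..{n_categories - 1}; refusal sentinels must be filtered upstream"
        )
    for j in range(J):
        if np.unique(X[:, j]).size < 2:
            raise DegenerateItemError(
                f"item {names[j]!r} has a single observed category and cannot be calibrated"
            )

    patterns, counts = np.unique(X, axis=0, return_counts=True)
    R = patterns.shape[0]
    nodes, prior = grid.nodes, grid.weights
    Q = nodes.size

    # one-hot per item for expected-count accumulation
    onehot = [np.eye(n_categories)[patterns[:, j]] * counts[:, None] for j in range(J)]

    params = []
    for j in range(J):
        cat_counts = np.bincount(X[:, j], minlength=n_categories).astype(float)
        params.append(_start_values(cat_counts))

    bounds = [
        [_BOUNDS_LOGA, _BOUNDS_B] + [_BOUNDS_LOGGAP] * (n_categories - 2)
    ][0]

    ll_trace: list[float] = []
    converged = False
    for it in range(max_iter):
        # E-step: posterior over nodes for each response pattern
        L = np.ones((R, Q))
        P_items = []
        for j in range(J):
            a, th = _unpack(params[j])
            Pj = category_probabilities(a, th, nodes)  # (Q, K)
            P_items.append(Pj)
            L *= Pj[:, patterns[:, j]].T
        post = L * prior[None, :]
        marg = post.sum(axis=1)
        ll = float(np.sum(counts * np.log(np.clip(marg, _PROB_FLOOR, None))))
        ll_trace.append(ll)
        post /= marg[:, None]

        if it > 0 and abs(ll - ll_trace[-2]) <= tol * (abs(ll_trace[-2]) + 1.0):
            converged = True
            break

        # M-step: per-item maximization of the expected complete-data ll
        for j in range(J):
            r = post.T @ onehot[j]  # (Q, K)
            res = optimize.minimize(
                _item_negll,
                params[j],
                args=(r, nodes),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 30, "ftol": 1e-10},
            )
            params[j] = res.x

    fitted = [_unpack(x) for x in params]
    weak = [names[j] for j, (a, _) in enumerate(fitted) if a < _WEAK_A]
    diagnostics = {
        "loglik": ll_trace[-1],
        "loglik_trace": ll_trace,
        "n_iter": len(ll_trace),
        "converged": converged,
        "weak_items": weak,
        "n_patterns": R,
        "n_obs": n,
    }
    return fitted, diagnostics


def fit_graded_model(
    X: np.ndarray,
    n_categories: int = 4,
    grid: QuadratureGrid | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    item_names: Sequence[str] | None = None,
) -> tuple[list[GradedItemParams], dict]:
    """Calibrate a graded response model by EM marginal maximum likelihood.

    Returns item parameter estimates and a diagnostics dict (log-likelihood
    trace — non-decreasing across iterations — convergence flag, weakly
    identified items).
    """
    grid = grid or default_grid()
    fitted, diag = _fit_mml(X, n_categories, grid, max_iter, tol, item_names)
    return [GradedItemParams(a=a, thresholds=tuple(th)) for a, th in fitted], diag


def fit_2pl(
    X: np.ndarray,
    grid: QuadratureGrid | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    item_names: Sequence[str] | None = None,
) -> tuple[list[BinaryItemParams], dict]:
    """Calibrate a two-parameter logistic model for binary items."""
    grid = grid or default_grid()
    fitted, diag = _fit_mml(X, 2, grid, max_iter, tol, item_names)
    return [BinaryItemParams(a=a, b=float(th[0])) for a, th in fitted], diag


# ---------------------------------------------------------------------------
# EAP scoring
# ---------------------------------------------------------------------------


def eap_scores(
    items: Sequence[GradedItemParams | BinaryItemParams],
    X: np.ndarray,
    grid: QuadratureGrid | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected-a-posteriori mean and SD for each row of a response matrix.

    Deterministic given item parameters and grid; response patterns must be
    complete (refusals are excluded upstream, never imputed).
    """
    grid = grid or default_grid()
    X = np.asarray(X)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(items):
        raise ValueError(f"pattern length {X.shape[1]} does not match {len(items)} items")
    nodes, prior = grid.nodes, grid.weights
    L = np.ones((X.shape[0], nodes.size))
    for j, (a, th) in enumerate(_thresholds_matrix(items)):
        if np.any(X[:, j] < 0) or np.any(X[:, j] > th.size):
            raise ValueError(f"responses for item {j} outside 0..{th.size}")
        Pj = category_probabilities(a, th, nodes)
        L *= Pj[:, X[:, j]].T
    post = L * prior[None, :]
    post /= post.sum(axis=1, keepdims=True)
    mean = post @ nodes
    var = post @ (nodes**2) - mean**2
    return mean, np.sqrt(np.clip(var, 0.0, None))


def eap_theta(
    items: Sequence[GradedItemParams | BinaryItemParams],
    pattern: Sequence[int],
    grid: QuadratureGrid | None = None,
) -> ThetaEstimate:
    """EAP estimate for a single response pattern."""
    mean, sd = eap_scores(items, np.asarray(pattern, dtype=int), grid)
    return ThetaEstimate(eap_mean=float(mean[0]), posterior_sd=float(sd[0]))
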