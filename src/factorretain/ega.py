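"""Exploratory graph analysis: the number of factors as the number of
communities in a penalized partial-correlation network.

Pipeline:

1. **Network estimation.**  A Gaussian graphical model is fitted by the
   graphical lasso over a log-spaced grid of 100 penalties from the largest
   absolute off-diagonal correlation down to 1% of it; the penalty is chosen
   by the extended Bayesian information criterion
   ``EBIC = -2 L + E log n + 4 gamma E log J`` with
   ``L = (n/2)(log det K - tr(S K))`` and ``E`` the number of nonzero
   off-diagonal precision entries (gamma defaults to 0.5).  Edge weights
   are absolute partial correlations ``-K_vw / sqrt(K_vv K_ww)``.

2. **Community detection.**  The Walktrap algorithm: short random walks
   (4 steps by default) define node profiles; communities are merged
   agglomeratively, each step joining the adjacent pair whose merge least
   increases the within-community sum of squared profile distances (the
   Ward criterion).  The merge level maximizing weighted modularity is the
   reported partition.

3. **Unidimensionality binding.**  Walktrap's modularity objective
   penalizes single-community solutions, so a 4-variable unidimensional
   block (loadings 0.70) is simulated, pushed through the same analysis
   arm, and column-bound to the data.  If the combined solution has at
   most 2 communities the data are declared unidimensional (1 factor);
   otherwise the pipeline is rerun on the original variables alone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .arms import AnalysisArm
from .correlation import CorrelationEstimate, repair_psd
from .criteria import CriterionFailure, _arm_data
from .sampling import draw_from_corr

try:  # warm-startable path solver; fall back to the public single-shot API
    from sklearn.covariance._graph_lasso import _graphical_lasso

    def _glasso(S, alpha, cov_init, tol, max_iter):
        out = _graphical_lasso(S, alpha=alpha, cov_init=cov_init, tol=tol,
                               enet_tol=1e-4, max_iter=max_iter)
        return out[0], out[1]
except ImportError:  # pragma: no cover
    from sklearn.covariance import graphical_lasso

    def _glasso(S, alpha, cov_init, tol, max_iter):
        return graphical_lasso(S, alpha=alpha, tol=tol, max_iter=max_iter)

__all__ = [
    "Network",
    "Partition",
    "ebic_glasso",
    "walktrap_partition",
    "modularity",
    "ega_count",
    "ega_count_from_corr",
    "EstimationError",
]

logger = logging.getLogger(__name__)

_EDGE_EPS = 1e-8


class EstimationError(CriterionFailure):
    """Network estimation failed (no usable solution on the penalty grid)."""


@dataclass
class Network:
    """A weighted partial-correlation graph."""

    weights: np.ndarray        # absolute partial correlations, zero diagonal
    partial_corr: np.ndarray   # signed partial correlations
    n_obs: int
    penalty: float = float("nan")
    ebic: float = float("nan")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def strength(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))


@dataclass
class Partition:
    """A community assignment plus the agglomeration trace behind it."""

    assignment: np.ndarray
    n_communities: int
    modularity: float
    merge_trace: list = field(default_factory=list)
    levels: list = field(default_factory=list)  # assignments per merge level


def ebic_glasso(S, n: int, gamma: float = 0.5, n_lambda: int = 100,
                lambda_min_ratio: float = 0.01, tol: float = 1e-3,
                max_iter: int = 100) -> Network:
    """Graphical lasso with EBIC penalty selection.

    ``S`` is a correlation estimate (PSD-repaired first if needed); ``n``
    the sample size behind it.  Precision entries below 1e-8 in magnitude
    are treated as zero edges.
    """
    M = S.R_hat if isinstance(S, CorrelationEstimate) else np.asarray(S, float)
    M = repair_psd(M).R_hat if np.linalg.eigvalsh(M)[0] < 1e-6 else M
    p = M.shape[0]
    offdiag_max = float(np.max(np.abs(M - np.diag(np.diag(M)))))
    if offdiag_max < 1e-12:
        K = np.diag(1.0 / np.diag(M))
        return _network_from_precision(K, n, penalty=float("inf"))

    grid = np.logspace(np.log10(offdiag_max),
                       np.log10(offdiag_max * lambda_min_ratio), n_lambda)
    best = None
    cov_init = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for alpha in grid:
            try:
                cov, K = _glasso(M, float(alpha), cov_init, tol, max_iter)
            except FloatingPointError:
                continue
            cov_init = cov
            sign, logdet = np.linalg.slogdet(K)
            if sign <= 0:
                continue
            Kz = np.where(np.abs(K) < _EDGE_EPS, 0.0, K)
            E = int(np.count_nonzero(np.triu(Kz, 1)))
            loglik = (n / 2.0) * (logdet - float(np.sum(M * K)))
            ebic = -2.0 * loglik + E * np.log(n) + 4.0 * gamma * E * np.log(p)
            if best is None or ebic < best[0]:
                best = (ebic, float(alpha), Kz)
    if best is None:
        raise EstimationError("no positive-definite solution on the penalty grid")
    ebic, alpha, K = best
    return _network_from_precision(K, n, penalty=alpha, ebic=ebic)


def _network_from_precision(K: np.ndarray, n: int, penalty: float,
                            ebic: float = float("nan")) -> Network:
    d = np.sqrt(np.diag(K))
    pcor = -K / np.outer(d, d)
    np.fill_diagonal(pcor, 0.0)
    pcor[np.abs(pcor) < _EDGE_EPS] = 0.0
    return Network(weights=np.abs(pcor), partial_corr=pcor, n_obs=n,
                   penalty=penalty, ebic=ebic)


# ---------------------------------------------------------------------------
# Walktrap

def _walk_profiles(weights: np.ndarray, steps: int) -> tuple[np.ndarray, np.ndarray]:
    """t-step random-walk transition profiles and node strengths.

    Zero-strength rows get an all-zero profile; they stay singletons.
    """
    s = weights.sum(axis=1)
    P = np.zeros_like(weights)
    active = s > 0
    P[active] = weights[active] / s[active, None]
    return np.linalg.matrix_power(P, steps), s


def _profile_dist2(p1: np.ndarray, p2: np.ndarray, inv_ns: np.ndarray) -> float:
    diff = p1 - p2
    return float(np.sum(diff * diff * inv_ns))


def walktrap_partition(net: Network, steps: int = 4) -> Partition:
    """Agglomerative Walktrap clustering with modularity selection.

    Maintains per-community mean walk profiles; at each level merges the
    adjacent pair minimizing the Ward increase in within-community squared
    profile distance, ``dsigma = |C1||C2| / (n (|C1|+|C2|)) * d2(C1, C2)``.
    Only communities joined by at least one edge are merge candidates, so
    disconnected components are never merged.  The returned partition is
    the merge level with maximum modularity; the full trace is retained.
    """
    W = net.weights
    n = W.shape[0]
    if n == 0:
        raise ValueError("empty network")
    T, s = _walk_profiles(W, steps)
    if net.n_edges == 0:
        logger.info("empty graph: singleton partition of all %d nodes", n)
        assign = np.arange(n)
        return Partition(assignment=assign, n_communities=n, modularity=0.0,
                         merge_trace=[], levels=[assign.copy()])
    inv_ns = np.zeros(n)
    inv_ns[s > 0] = 1.0 / s[s > 0]

    profiles = {v: T[v] for v in range(n)}
    sizes = {v: 1 for v in range(n)}
    adj = {v: set(np.flatnonzero(W[v] > 0)) for v in range(n)}
    assign = np.arange(n)
    levels = [assign.copy()]
    trace = []
    next_label = n

    def dsigma(c1: int, c2: int) -> float:
        d2 = _profile_dist2(profiles[c1], profiles[c2], inv_ns)
        return sizes[c1] * sizes[c2] / (sizes[c1] + sizes[c2]) * d2 / n

    # candidate merge costs for adjacent community pairs
    costs = {}
    for v in range(n):
        for w in adj[v]:
            if v < w:
                costs[(v, w)] = dsigma(v, w)

    while costs:
        (c1, c2), ds = min(costs.items(), key=lambda kv: (kv[1], kv[0]))
        c3 = next_label
        next_label += 1
        profiles[c3] = (sizes[c1] * profiles[c1] + sizes[c2] * profiles[c2]) / (
            sizes[c1] + sizes[c2]
        )
        sizes[c3] = sizes[c1] + sizes[c2]
        neighbors = (adj[c1] | adj[c2]) - {c1, c2}
        adj[c3] = neighbors
        for nb in neighbors:
            adj[nb].discard(c1)
            adj[nb].discard(c2)
            adj[nb].add(c3)
        for key in [k for k in costs if c1 in k or c2 in k]:
            del costs[key]
        for c in (c1, c2):
            del profiles[c], sizes[c], adj[c]
        for nb in neighbors:
            key = (min(c3, nb), max(c3, nb))
            costs[key] = dsigma(c3, nb)
        assign = assign.copy()
        assign[(assign == c1) | (assign == c2)] = c3
        levels.append(assign.copy())
        trace.append({"merged": (c1, c2), "into": c3, "dsigma": ds})

    best_q, best_level = -np.inf, 0
    for i, lvl in enumerate(levels):
        q = modularity(net, lvl)
        if q > best_q + 1e-12:
            best_q, best_level = q, i
    chosen = _relabel(levels[best_level])
    return Partition(assignment=chosen,
                     n_communities=int(chosen.max()) + 1,
                     modularity=best_q, merge_trace=trace, levels=levels)


def _relabel(assign: np.ndarray) -> np.ndarray:
    _, out = np.unique(assign, return_inverse=True)
    return out


def modularity(net: Network, assignment: np.ndarray) -> float:
    """Weighted modularity Q = sum_j (e_jj - a_j^2) of a node partition.

    ``e_jj`` is the fraction of total edge weight inside community j and
    ``a_j`` the fraction of edge ends attached to it.
    """
    W = net.weights if isinstance(net, Network) else np.asarray(net, float)
    assign = np.asarray(assignment)
    total = W.sum()  # counts each undirected edge twice
    if total <= 0:
        raise ValueError("modularity undefined for a graph with zero weight")
    q = 0.0
    for c in np.unique(assign):
        mask = assign == c
        e_in = W[np.ix_(mask, mask)].sum() / total
        a = W[mask].sum() / total
        q += e_in - a * a
    return float(q)


# ---------------------------------------------------------------------------
# The EGA retention criterion

#: population correlation matrix of the simulated unidimensional block:
#: four variables loading 0.70 on one factor.
_UNI_BLOCK_R = np.full((4, 4), 0.49)
np.fill_diagonal(_UNI_BLOCK_R, 1.0)


#: penalty-grid floor used inside the EGA pipeline.  The generic default of
#: :func:`ebic_glasso` (0.01) lets EBIC walk into very dense solutions when
#: the input matrix is ill-conditioned (pairwise tetrachoric estimates
#: especially); the EGA convention of a 0.1 floor keeps the selected
#: network sparse enough for community structure to be meaningful.
EGA_LAMBDA_MIN_RATIO = 0.1


def _ega_solution(S: CorrelationEstimate, n: int, gamma: float,
                  steps: int) -> Partition:
    net = ebic_glasso(S, n, gamma=gamma,
                      lambda_min_ratio=EGA_LAMBDA_MIN_RATIO)
    if net.n_edges == 0:
        # no structure survives the penalty: every node is its own community
        assign = np.arange(net.n_nodes)
        return Partition(assignment=assign, n_communities=net.n_nodes,
                         modularity=0.0)
    return walktrap_partition(net, steps=steps)


def ega_count_from_corr(S: CorrelationEstimate | np.ndarray, n: int,
                        gamma: float = 0.5, steps: int = 4) -> int:
    """Community count of the EGA network for a correlation matrix alone
    (no unidimensionality binding — used on population matrices and as the
    second stage of :func:`ega_count`)."""
    if not isinstance(S, CorrelationEstimate):
        S = CorrelationEstimate(R_hat=np.asarray(S, float), kind="pearson",
                                n_obs=n)
    return _ega_solution(S, n, gamma, steps).n_communities


def ega_count(sample, arm: AnalysisArm, rng: np.random.Generator | None = None,
              gamma: float = 0.5, steps: int = 4) -> int:
    """EGA retention count with the unidimensionality binding.

    A 4-variable unidimensional block (loadings 0.70) is simulated at the
    sample's size, transformed through the arm pipeline, and column-bound
    to the observed data.  At most 2 communities on the combined data
    signal a unidimensional structure (return 1); otherwise the count of
    the EGA solution on the original variables is returned.
    """
    rng = rng if rng is not None else np.random.default_rng()
    data = _arm_data(sample, arm)
    n_obs = data.shape[0]
    block = draw_from_corr(_UNI_BLOCK_R, n_obs, rng)
    block = arm.transform(block)
    combined = np.hstack([data, block])
    S_comb = arm.correlation_of(combined)
    part = _ega_solution(S_comb, n_obs, gamma, steps)
    if part.n_communities <= 2:
        return 1
    S_obs = arm.correlation_of(data)
    return _ega_solution(S_obs, n_obs, gamma, steps).n_communities
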