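"""Cancer progression models fitted to cross-sectional binary matrices.

Three model families are supported:

* **MHN** (Mutual Hazard Networks) — every event (gene) has a baseline
  rate ``theta_ii`` and each present event multiplies the rate of every
  other event by ``theta_ij``; the model is a continuous-time Markov
  chain on the full genotype hypercube.
* **CBN** (Conjunctive Bayesian Networks, H-CBN style) — a restriction
  poset with AND semantics plus per-gene exponential waiting-time rates
  ``lambda_i`` and a per-locus observation error ``epsilon``; the
  structure is found by simulated annealing with the rates profiled out
  by maximum likelihood at each candidate poset.
* **OT** (Oncogenetic Trees) — a maximum-weight branching over genes
  rooted at the wild type, with edge weights interpreted as conditional
  child-given-parent probabilities.

All likelihoods use the standard observation scheme for cross-sectional
data: the chain starts at the wild type and is observed at an
exponentially distributed sampling time with rate 1, so the genotype
distribution at observation solves the linear system ``(I - Q)^T p = e_wt``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .landscapes import (
    RestrictionDAG,
    dag_compatible_genotypes,
    genotype_str,
    n_mutations,
)

__all__ = [
    "RateMatrix",
    "MHNModel",
    "CBNModel",
    "OTModel",
    "ROOT",
    "mhn_rate_matrix",
    "cbn_rate_matrix",
    "ctmc_marginal",
    "fit_mhn",
    "fit_cbn",
    "fit_ot",
    "cbn_loglik",
    "sample_ctmc_observations",
]

MAX_GENES = 15  # 2^15 states; beyond this the dense state space is refused

#: Pseudo-parent marking genes that hang directly off the wild-type root.
ROOT = -1


# ---------------------------------------------------------------------------
# Rate matrices and the cross-sectional observation model
# ---------------------------------------------------------------------------

@dataclass
class RateMatrix:
    """CTMC generator over a set of genotype states.

    Off-diagonal entries are nonzero only between genotypes one added
    mutation apart; each diagonal entry is minus its row sum.
    """

    G: int
    states: np.ndarray  # sorted genotype ints
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        self.index = {int(s): k for k, s in enumerate(self.states)}

    def out_rates(self, g: int) -> dict[int, float]:
        """Outgoing rates from genotype ``g`` keyed by target genotype."""
        k = self.index[g]
        row = self.Q[k]
        return {
            int(self.states[m]): float(row[m])
            for m in np.nonzero(row > 0)[0]
            if m != k
        }


def ctmc_marginal(rm: RateMatrix) -> np.ndarray:
    """Distribution of the chain at an Exp(1) sampling time from the wild type.

    Solves ``(I - Q)^T p = e_wt``; the result is a proper probability
    vector aligned with ``rm.states``.
    """
    n = len(rm.states)
    A = np.eye(n) - rm.Q
    e0 = np.zeros(n)
    e0[rm.index[0]] = 1.0
    p = np.linalg.solve(A.T, e0)
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def sample_ctmc_observations(rm: RateMatrix, n: int, seed=None) -> np.ndarray:
    """Monte-Carlo draws of the genotype observed at an Exp(1) time.

    Simulates the jump chain directly (first-jump competing exponentials
    against the sampling clock); serves as an independent stochastic
    oracle for :func:`ctmc_marginal` and as a data generator for
    parameter-recovery experiments.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n, dtype=np.int64)
    for k in range(n):
        state = 0
        while True:
            i = rm.index[state]
            total = -rm.Q[i, i]
            # sampling clock rate 1 vs total outgoing rate
            if rng.random() < 1.0 / (1.0 + total):
                break
            row = rm.Q[i].copy()
            row[i] = 0.0
            state = int(rng.choice(rm.states, p=row / row.sum()))
        out[k] = state
    return out


# ---------------------------------------------------------------------------
# Mutual Hazard Networks
# ---------------------------------------------------------------------------

@dataclass
class MHNModel:
    """Pairwise multiplicative-hazard model.

    ``theta`` is a positive G x G matrix: ``theta[i, i]`` is the baseline
    rate of event i and ``theta[i, j]`` the multiplicative effect of a
    present event j on event i (1 = no interaction).
    """

    theta: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2 or self.theta.shape[0] != self.theta.shape[1]:
            raise ValueError("theta must be square")
        if np.any(self.theta <= 0):
            raise ValueError("theta entries must be positive")

    @property
    def G(self) -> int:
        return self.theta.shape[0]

    def to_dict(self) -> dict:
        return {"type": "mhn", "theta": self.theta.tolist()}


def _bit_matrix(G: int) -> np.ndarray:
    states = np.arange(1 << G)
    return ((states[:, None] >> np.arange(G)) & 1).astype(float)


def _mhn_rates(log_theta: np.ndarray) -> np.ndarray:
    """Rate of adding event a to each state x: shape (2^G, G); 0 where a in x."""
    G = log_theta.shape[0]
    B = _bit_matrix(G)
    # sum_{j in x} log theta[a, j] for every state x and event a
    lr = B @ log_theta.T + np.diag(log_theta)[None, :]
    rates = np.exp(lr)
    rates[B.astype(bool)] = 0.0
    return rates


def mhn_rate_matrix(model: MHNModel) -> RateMatrix:
    """Dense CTMC generator on all ``2^G`` genotypes implied by ``theta``."""
    G = model.G
    if G > MAX_GENES:
        raise ValueError(f"state space too large for G={G} (max {MAX_GENES})")
    rates = _mhn_rates(np.log(model.theta))
    n = 1 << G
    Q = np.zeros((n, n))
    states = np.arange(n)
    for a in range(G):
        free = (states >> a) & 1 == 0
        Q[states[free], states[free] | (1 << a)] = rates[free, a]
    Q[states, states] = -Q.sum(axis=1)
    return RateMatrix(G=G, states=states, Q=Q)


def _mhn_loglik_grad(log_theta: np.ndarray, weights: np.ndarray):
    """Log-likelihood of observed-state counts and its gradient in log-theta.

    ``weights[x]`` is the number of observations of genotype ``x`` (length
    2^G).  Uses the adjoint of the linear observation system, so the cost
    is two LU solves regardless of G.
    """
    G = log_theta.shape[0]
    n = 1 << G
    rates = _mhn_rates(log_theta)
    states = np.arange(n)
    Q = np.zeros((n, n))
    for a in range(G):
        free = (states >> a) & 1 == 0
        Q[states[free], states[free] | (1 << a)] = rates[free, a]
    Q[states, states] = -Q.sum(axis=1)
    A = np.eye(n) - Q
    lu, piv = scipy.linalg.lu_factor(A.T)
    e0 = np.zeros(n)
    e0[0] = 1.0
    p = scipy.linalg.lu_solve((lu, piv), e0)
    p = np.clip(p, 1e-300, None)
    ll = float(weights @ np.log(p))
    g = weights / p
    r = scipy.linalg.lu_solve((lu, piv), g, trans=1)  # solves A r = g
    B = _bit_matrix(G)
    grad = np.zeros((G, G))
    for a in range(G):
        free = (states >> a) & 1 == 0
        x = states[free]
        c = rates[free, a] * p[x] * (r[x | (1 << a)] - r[x])
        grad[a] = c @ B[x]
        grad[a, a] = c.sum()
    return ll, grad


def _as_genotype_counts(data, G: int | None = None) -> tuple[np.ndarray, int]:
    """Binary matrix (array / DataFrame / sample) -> counts over genotype ints."""
    if hasattr(data, "matrix"):
        data = data.matrix
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy()
    data = np.asarray(data)
    if data.ndim != 2:
        raise ValueError("data must be a 2-D binary matrix")
    if not np.isin(data, (0, 1)).all():
        raise ValueError("data entries must be 0 or 1")
    G = G or data.shape[1]
    ints = data.astype(np.int64) @ (1 << np.arange(G, dtype=np.int64))
    return np.bincount(ints, minlength=1 << G).astype(float), G


def fit_mhn(data, l1_penalty: float = 0.01, seed=None) -> MHNModel:
    """Penalized maximum-likelihood fit of an MHN.

    Maximizes the mean log-likelihood of the observed genotypes under the
    Exp(1)-time observation model, minus an L1 penalty (smoothed for
    differentiability) on the off-diagonal log-effects that shrinks the
    model toward independent events.  Deterministic given the data.
    """
    weights, G = _as_genotype_counts(data)
    if G > MAX_GENES:
        raise ValueError(f"state space too large for G={G}")
    ntot = weights.sum()
    if ntot < 1:
        raise ValueError("need at least one observation")
    # Independence initialization from marginal frequencies.
    B = _bit_matrix(G)
    freq = np.clip((weights @ B) / ntot, 1e-3, 1 - 1e-3)
    lt0 = np.zeros((G, G))
    np.fill_diagonal(lt0, np.log(freq / (1 - freq)))
    off = ~np.eye(G, dtype=bool)
    eps = 1e-10

    def objective(x):
        lt = x.reshape(G, G)
        ll, grad = _mhn_loglik_grad(lt, weights)
        smooth = np.sqrt(lt[off] ** 2 + eps)
        f = -ll / ntot + l1_penalty * smooth.sum()
        gpen = np.zeros((G, G))
        gpen[off] = l1_penalty * lt[off] / smooth
        return f, (-grad / ntot + gpen).ravel()

    res = scipy.optimize.minimize(
        objective,
        lt0.ravel(),
        jac=True,
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * (G * G),
        options={"maxiter": 500, "ftol": 1e-11},
    )
    lt = res.x.reshape(G, G)
    ll, _ = _mhn_loglik_grad(lt, weights)
    return MHNModel(
        theta=np.exp(lt),
        meta={
            "loglik": ll,
            "penalty": l1_penalty,
            "n": int(ntot),
            "converged": bool(res.success),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# Conjunctive Bayesian Networks
# ---------------------------------------------------------------------------

@dataclass
class CBNModel:
    """Restriction poset with exponential waiting times and observation noise."""

    poset: RestrictionDAG
    lambdas: np.ndarray
    epsilon: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.lambdas.shape != (self.poset.G,):
            raise ValueError("need one rate per gene")
        if np.any(self.lambdas <= 0):
            raise ValueError("rates must be positive")
        if not 0.0 <= self.epsilon < 0.5:
            raise ValueError("epsilon must be in [0, 0.5)")

    @property
    def G(self) -> int:
        return self.poset.G

    def to_dict(self) -> dict:
        return {
            "type": "cbn",
            "parents": {
                str(i + 1): sorted(str(p + 1) for p in self.poset.parents[i])
                for i in range(self.G)
                if self.poset.parents[i]
            },
            "lambdas": self.lambdas.tolist(),
            "epsilon": self.epsilon,
        }


def cbn_rate_matrix(model: CBNModel) -> RateMatrix:
    """Generator on the poset-compatible genotypes: gene i fires at
    ``lambda_i`` once all its parents are mutated."""
    G = model.G
    states = np.array(sorted(dag_compatible_genotypes(model.poset)), dtype=np.int64)
    index = {int(s): k for k, s in enumerate(states)}
    parent_masks = [sum(1 << p for p in model.poset.parents[i]) for i in range(G)]
    n = len(states)
    Q = np.zeros((n, n))
    for k, g in enumerate(states):
        g = int(g)
        for i in range(G):
            if (g >> i) & 1:
                continue
            if (g & parent_masks[i]) == parent_masks[i]:
                Q[k, index[g | (1 << i)]] = model.lambdas[i]
    Q[np.arange(n), np.arange(n)] = -Q.sum(axis=1)
    return RateMatrix(G=G, states=states, Q=Q)


def _error_kernel(states: np.ndarray, observed: np.ndarray, G: int, eps: float) -> np.ndarray:
    """P(observe y | true x) under independent per-locus flips: shape (|x|, |y|)."""
    d = np.array([[(int(x) ^ int(y)).bit_count() for y in observed] for x in states])
    if eps == 0.0:
        return (d == 0).astype(float)
    return eps**d * (1 - eps) ** (G - d)


def cbn_loglik(model: CBNModel, data) -> float:
    """Observed-data log-likelihood; ``-inf`` if data contradict an
    error-free poset."""
    weights, G = _as_genotype_counts(data, model.G)
    observed = np.nonzero(weights)[0]
    rm = cbn_rate_matrix(model)
    p = ctmc_marginal(rm)
    kern = _error_kernel(rm.states, observed, G, model.epsilon)
    py = p @ kern
    if np.any(py[weights[observed] > 0] <= 0):
        return float("-inf")
    return float(weights[observed] @ np.log(py))


def _cbn_profile_fit(
    poset: RestrictionDAG,
    weights: np.ndarray,
    observed: np.ndarray,
    x0: np.ndarray,
    maxiter: int,
) -> tuple[float, np.ndarray]:
    """Maximize the likelihood over (log-lambdas, epsilon) for a fixed poset."""
    G = poset.G
    states = np.array(sorted(dag_compatible_genotypes(poset)), dtype=np.int64)
    index = {int(s): k for k, s in enumerate(states)}
    parent_masks = [sum(1 << p for p in poset.parents[i]) for i in range(G)]
    n = len(states)
    d = np.array([[(int(x) ^ int(y)).bit_count() for y in observed] for x in states])
    w = weights[observed]
    e0 = np.zeros(n)
    e0[index[0]] = 1.0
    trans = [
        (k, index[int(g) | (1 << i)], i)
        for k, g in enumerate(states)
        for i in range(G)
        if not (int(g) >> i) & 1 and (int(g) & parent_masks[i]) == parent_masks[i]
    ]
    rows = np.array([t[0] for t in trans])
    cols = np.array([t[1] for t in trans])
    gene = np.array([t[2] for t in trans])

    def negll(x):
        lam = np.exp(x[:G])
        eps = x[G]
        Q = np.zeros((n, n))
        Q[rows, cols] = lam[gene]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        p = np.linalg.solve((np.eye(n) - Q).T, e0)
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        kern = eps**d * (1 - eps) ** (G - d)
        py = np.clip(p @ kern, 1e-300, None)
        return -float(w @ np.log(py))

    res = scipy.optimize.minimize(
        negll,
        x0,
        method="L-BFGS-B",
        bounds=[(-7.0, 7.0)] * G + [(1e-6, 0.45)],
        options={"maxiter": maxiter, "ftol": 1e-9},
    )
    return -res.fun, res.x


def _poset_edges(poset: RestrictionDAG) -> frozenset[tuple[int, int]]:
    return frozenset(
        (p, c) for c in range(poset.G) for p in poset.parents[c]
    )


def _edges_to_poset(G: int, edges) -> RestrictionDAG | None:
    parents: dict[int, set[int]] = {i: set() for i in range(G)}
    for p, c in edges:
        parents[c].add(p)
    try:
        return RestrictionDAG(G=G, parents={k: frozenset(v) for k, v in parents.items()})
    except ValueError:
        return None


def fit_cbn(
    data,
    seed=None,
    anneal_steps: int = 150,
    t0: float = 2.0,
    t1: float = 0.01,
    epsilon0: float = 0.05,
    inner_maxiter: int = 30,
) -> CBNModel:
    """H-CBN-style fit: simulated annealing over restriction posets.

    Starting from the empty poset, cover relations are added/removed at
    random (staying acyclic); each candidate poset is scored by the
    observed-data likelihood with the per-gene rates and the observation
    error profiled out by a bounded quasi-Newton step (warm-started from
    the current parameters).  The best poset seen is refit with a larger
    iteration budget.  Deterministic given (data, seed).
    """
    weights, G = _as_genotype_counts(data)
    if weights.sum() < 1:
        raise ValueError("need at least one observation")
    observed = np.nonzero(weights)[0]
    rng = np.random.default_rng(seed)

    B = _bit_matrix(G)
    freq = np.clip((weights @ B) / weights.sum(), 1e-3, 1 - 1e-3)
    x0 = np.concatenate([np.log(freq / (1 - freq)), [epsilon0]])

    cur_edges: frozenset[tuple[int, int]] = frozenset()
    cur_poset = _edges_to_poset(G, cur_edges)
    cur_ll, cur_x = _cbn_profile_fit(cur_poset, weights, observed, x0, inner_maxiter)
    best = (cur_ll, cur_poset, cur_x)
    cache: dict[frozenset, tuple[float, np.ndarray]] = {cur_edges: (cur_ll, cur_x)}

    pairs = [(a, b) for a in range(G) for b in range(G) if a != b]
    for step in range(anneal_steps):
        temp = t0 * (t1 / t0) ** (step / max(1, anneal_steps - 1))
        a, b = pairs[rng.integers(len(pairs))]
        edges = set(cur_edges)
        if (a, b) in edges:
            edges.remove((a, b))
        else:
            edges.add((a, b))
        edges = frozenset(edges)
        cand = _edges_to_poset(G, edges)
        if cand is None:  # cyclic proposal
            continue
        if edges in cache:
            ll, x = cache[edges]
        else:
            ll, x = _cbn_profile_fit(cand, weights, observed, cur_x, inner_maxiter)
            cache[edges] = (ll, x)
        if ll >= cur_ll or rng.random() < math.exp((ll - cur_ll) / max(temp, 1e-12)):
            cur_edges, cur_poset, cur_ll, cur_x = edges, cand, ll, x
            if ll > best[0]:
                best = (ll, cand, x)

    ll, x = _cbn_profile_fit(best[1], weights, observed, best[2], 200)
    if ll < best[0]:
        ll, x = best[0], best[2]
    return CBNModel(
        poset=best[1],
        lambdas=np.exp(x[:G]),
        epsilon=float(x[G]),
        meta={"loglik": ll, "seed": seed, "anneal_steps": anneal_steps},
    )


# ---------------------------------------------------------------------------
# Oncogenetic trees
# ---------------------------------------------------------------------------

@dataclass
class OTModel:
    """Rooted tree over genes; each gene depends on at most one other gene.

    ``parent[i]`` is the parent gene of gene i (``ROOT`` for genes hanging
    off the wild type) and ``weights[i]`` the estimated conditional
    probability of observing gene i mutated given its parent is.
    """

    G: int
    parent: dict[int, int]
    weights: dict[int, float]
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "type": "ot",
            "parent": {
                str(i + 1): "root" if p == ROOT else str(p + 1)
                for i, p in self.parent.items()
            },
            "weights": {str(i + 1): w for i, w in self.weights.items()},
        }


def fit_ot(data) -> OTModel:
    """Desper-style oncogenetic tree via maximum-weight arborescence.

    Pairwise weights ``log(f_ij / ((f_i + f_j) f_j))`` are computed from
    marginal and joint mutation frequencies on the complete digraph over
    {root} + genes (the root has marginal frequency 1) and Edmonds'
    algorithm returns the maximum-weight spanning arborescence.  Genes
    never observed mutated are attached to the root with weight 0 and
    flagged.
    """
    import networkx as nx

    if hasattr(data, "matrix"):
        data = data.matrix
    if isinstance(data, pd.DataFrame):
        data = data.to_numpy()
    X = np.asarray(data, dtype=float)
    if not np.isin(X, (0, 1)).all():
        raise ValueError("data entries must be 0 or 1")
    n, G = X.shape
    f = X.mean(axis=0)
    joint = (X.T @ X) / n

    graph = nx.DiGraph()
    graph.add_node(ROOT)
    zero_genes = [i for i in range(G) if f[i] == 0]
    for j in range(G):
        if f[j] > 0:
            # root -> j: f_root = 1, joint(root, j) = f_j
            graph.add_edge(ROOT, j, weight=math.log(f[j] / ((1.0 + f[j]) * f[j])))
    for i in range(G):
        for j in range(G):
            if i == j or f[i] == 0 or f[j] == 0 or joint[i, j] == 0:
                continue
            graph.add_edge(i, j, weight=math.log(joint[i, j] / ((f[i] + f[j]) * f[j])))
    parent: dict[int, int] = {}
    weights: dict[int, float] = {}
    if graph.number_of_edges():
        arb = nx.algorithms.tree.branchings.maximum_spanning_arborescence(
            graph, attr="weight"
        )
        for u, v in arb.edges:
            parent[v] = u
            weights[v] = float(joint[u, v] / f[u]) if u != ROOT else float(f[v])
    for i in zero_genes:
        parent[i] = ROOT
        weights[i] = 0.0
    return OTModel(
        G=G,
        parent=parent,
        weights=weights,
        meta={"zero_frequency_genes": zero_genes, "n": n},
    )
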