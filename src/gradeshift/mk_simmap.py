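"""Mk-model likelihood, marginal ancestral states, and stochastic mapping.

The composite "collapsed" habitat dataset (marine / non-marine via the direct
pathway / non-marine via the freshwater pathway) evolves under a continuous
time Markov chain with instantaneous rate matrix Q.  Soft tip priors enter
the pruning algorithm as tip partial likelihoods and, during stochastic
mapping, as sampling weights — a tip's state is sampled, not fixed.

Stochastic character maps are full histories: a state for every node plus a
piecewise-constant state path along every edge, drawn conditional on the tip
data.  Branch paths are endpoint-conditioned CTMC draws via rejection
sampling, falling back to uniformization after a configurable attempt cap
(rejection is exact but degenerate on long branches with unequal endpoints).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize

from .grades import TipPriorMatrix
from .tree_io import Phylogeny

__all__ = [
    "MkModel",
    "CharacterHistory",
    "HistorySummary",
    "mk_loglik",
    "marginal_asr",
    "fit_mk",
    "sample_histories",
    "summarize_histories",
    "history_to_simmap",
]

STRUCTURES = ("ER", "SYM", "ARD", "ordered")


def _rate_index(structure: str, k: int) -> list[list[int | None]]:
    """Map (i, j) -> parameter index (None = structurally zero)."""
    idx: list[list[int | None]] = [[None] * k for _ in range(k)]
    if structure == "ER":
        for i in range(k):
            for j in range(k):
                if i != j:
                    idx[i][j] = 0
    elif structure == "SYM":
        p = 0
        for i in range(k):
            for j in range(i + 1, k):
                idx[i][j] = idx[j][i] = p
                p += 1
    elif structure == "ARD":
        p = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    idx[i][j] = p
                    p += 1
    elif structure == "ordered":
        p = 0
        for i in range(k - 1):
            idx[i][i + 1] = p
            idx[i + 1][i] = p + 1
            p += 2
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return idx


def n_rates(structure: str, k: int) -> int:
    flat = [v for row in _rate_index(structure, k) for v in row if v is not None]
    return max(flat) + 1


def build_q(structure: str, rates: np.ndarray, k: int) -> np.ndarray:
    idx = _rate_index(structure, k)
    Q = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            if idx[i][j] is not None:
                Q[i, j] = rates[idx[i][j]]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    A = np.vstack([Q.T, np.ones(k)])
    b = np.zeros(k + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


@dataclass(frozen=True)
class MkModel:
    """CTMC model for an (optionally ordered) discrete character."""

    states: tuple
    Q: np.ndarray
    root_prior: np.ndarray
    structure: str = "ARD"

    def __post_init__(self):
        Q = np.asarray(self.Q, dtype=float)
        rp = np.asarray(self.root_prior, dtype=float)
        object.__setattr__(self, "Q", Q)
        object.__setattr__(self, "root_prior", rp)
        k = len(self.states)
        if Q.shape != (k, k):
            raise ValueError("Q shape does not match state count")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if np.max(np.abs(Q.sum(axis=1))) > 1e-10:
            raise ValueError("Q rows must sum to 0")
        if abs(rp.sum() - 1.0) > 1e-9 or np.any(rp < 0):
            raise ValueError("root_prior must be a probability vector")
        if self.structure == "ordered":
            for i in range(k):
                for j in range(k):
                    if abs(i - j) > 1 and off[i, j] != 0:
                        raise ValueError("ordered structure forbids non-adjacent rates")

    @property
    def k(self) -> int:
        return len(self.states)

    @classmethod
    def from_rates(cls, structure: str, rates, k: int,
                   states=None, root_prior="stationary") -> "MkModel":
        rates = np.asarray(rates, dtype=float)
        Q = build_q(structure, rates, k)
        if states is None:
            states = tuple(range(k))
        if isinstance(root_prior, str):
            if root_prior == "stationary":
                rp = stationary_distribution(Q)
            elif root_prior == "flat":
                rp = np.full(k, 1.0 / k)
            else:
                raise ValueError(root_prior)
        else:
            rp = np.asarray(root_prior, dtype=float)
        return cls(tuple(states), Q, rp, structure)


# ---------------------------------------------------------------------------
# pruning likelihood and marginals
# ---------------------------------------------------------------------------

def _check_inputs(tree: Phylogeny, priors: TipPriorMatrix, model: MkModel):
    if priors.n_states != model.k:
        raise ValueError(
            f"prior columns ({priors.n_states}) != model states ({model.k})"
        )
    if list(priors.tips) != list(tree.tip_labels):
        priors = priors.reordered(list(tree.tip_labels))
    return priors


def _edge_pmats(tree: Phylogeny, Q: np.ndarray) -> list:
    P = [None] * tree.n_nodes
    for v in range(tree.n_nodes - 1):
        P[v] = expm(Q * tree.brlen[v])
        if not np.all(np.isfinite(P[v])):
            raise FloatingPointError("non-finite transition matrix (exp overflow)")
    return P


def _down_partials(tree, tipvals, P, k):
    """Scaled conditional likelihoods of the data below each node."""
    D = np.zeros((tree.n_nodes, k))
    logscale = np.zeros(tree.n_nodes)
    for v in range(tree.n_nodes):
        if tree.is_tip(v):
            D[v] = tipvals[v]
        else:
            part = np.ones(k)
            for c in tree.children(v):
                part = part * (P[c] @ D[c])
                logscale[v] += logscale[c]
            D[v] = part
        s = D[v].sum()
        if s <= 0:
            raise FloatingPointError("zero partial likelihood (inconsistent data)")
        D[v] /= s
        logscale[v] += math.log(s)
    return D, logscale


def mk_loglik(tree: Phylogeny, priors: TipPriorMatrix, model: MkModel) -> float:
    """Pruning-algorithm log-likelihood with soft tip priors as tip partials."""
    priors = _check_inputs(tree, priors, model)
    P = _edge_pmats(tree, model.Q)
    D, logscale = _down_partials(tree, priors.values, P, model.k)
    root = tree.root
    return float(math.log(model.root_prior @ D[root]) + logscale[root])


def marginal_asr(tree: Phylogeny, priors: TipPriorMatrix, model: MkModel) -> pd.DataFrame:
    """Marginal posterior state probabilities at every node (up-down pass)."""
    priors = _check_inputs(tree, priors, model)
    k = model.k
    P = _edge_pmats(tree, model.Q)
    D, _ = _down_partials(tree, priors.values, P, k)
    U = np.zeros((tree.n_nodes, k))
    U[tree.root] = model.root_prior
    for v in range(tree.n_nodes - 1, tree.n_tips - 1, -1):
        kids = tree.children(v)
        msgs = {c: P[c] @ D[c] for c in kids}
        for c in kids:
            above = U[v].copy()
            for s in kids:
                if s != c:
                    above *= msgs[s]
            u = above @ P[c]
            tot = u.sum()
            U[c] = u / tot if tot > 0 else u
    post = U * D
    post /= post.sum(axis=1, keepdims=True)
    labels = [tree.labels[v] if v < tree.n_tips else f"node{v}"
              for v in range(tree.n_nodes)]
    return pd.DataFrame(post, index=labels, columns=list(model.states))


# ---------------------------------------------------------------------------
# maximum-likelihood fit
# ---------------------------------------------------------------------------

@dataclass
class MkFit:
    model: MkModel
    loglik: float
    converged: bool
    degenerate: bool
    n_params: int
    message: str = ""


def fit_mk(tree: Phylogeny, priors: TipPriorMatrix, structure: str = "ER",
           root_prior: str = "stationary", n_starts: int = 3,
           min_rate: float = 1e-8, max_rate: float = 1e4) -> MkFit:
    """Maximum-likelihood Q under the given rate structure (multi-start)."""
    priors = _check_inputs(tree, priors, MkModel.from_rates(
        structure, np.ones(n_rates(structure, priors.n_states)), priors.n_states))
    k = priors.n_states
    npar = n_rates(structure, k)
    observed = {int(np.argmax(row)) for row in priors.values}
    degenerate = len(observed) < 2

    height = float(tree.depths()[: tree.n_tips].max())
    if degenerate:
        rates = np.full(npar, min_rate)
        model = MkModel.from_rates(structure, rates, k, root_prior=root_prior)
        return MkFit(model, mk_loglik(tree, priors, model), True, True, npar,
                     "single observed state; rate at lower boundary")

    def nll(logr):
        model = MkModel.from_rates(structure, np.exp(logr), k, root_prior=root_prior)
        try:
            return -mk_loglik(tree, priors, model)
        except FloatingPointError:
            return 1e12

    bounds = [(math.log(min_rate), math.log(max_rate))] * npar
    starts = [np.full(npar, math.log(s / height)) for s in (0.1, 1.0, 5.0)][:n_starts]
    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    model = MkModel.from_rates(structure, np.exp(best.x), k, root_prior=root_prior)
    return MkFit(model, -float(best.fun), bool(best.success), False, npar,
                 str(best.message))


# ---------------------------------------------------------------------------
# stochastic character mapping
# ---------------------------------------------------------------------------

@dataclass
class CharacterHistory:
    """One sampled history: node states plus segments along every edge.

    ``edges[v]`` lists ``(state, duration)`` segments from the parent of v
    down to v; durations sum to the branch length and adjacent segments
    differ in state.
    """

    node_states: np.ndarray
    edges: dict[int, list[tuple[int, float]]]
    n_states: int

    def transition_counts(self) -> np.ndarray:
        """k x k matrix of realized transitions summed over edges."""
        k = self.n_states
        C = np.zeros((k, k), dtype=int)
        for segs in self.edges.values():
            for (a, _), (b, _) in zip(segs[:-1], segs[1:]):
                C[a, b] += 1
        return C


class PathSamplingError(FloatingPointError):
    pass


def _forward_path(Q, rates, a, t, rng):
    segs = [(a, 0.0)]
    state, time = a, 0.0
    while True:
        r = rates[state]
        dt = rng.exponential(1.0 / r) if r > 0 else math.inf
        if time + dt >= t:
            segs[-1] = (state, segs[-1][1] + (t - time))
            return segs
        time += dt
        segs[-1] = (state, segs[-1][1] + dt)
        probs = Q[state].copy()
        probs[state] = 0.0
        probs /= probs.sum()
        state = int(rng.choice(len(probs), p=probs))
        segs.append((state, 0.0))


def _uniformization_path(Q, a, b, t, rng, tol=1e-12):
    """Endpoint-conditioned path via the uniformized jump chain."""
    k = Q.shape[0]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0:
        if a != b:
            raise PathSamplingError(
                "zero dominating rate with unequal endpoints"
            )
        return [(a, t)]
    R = np.eye(k) + Q / lam
    # weights over the number of uniformized jumps
    Rpow = [np.eye(k)]
    weights = []
    logpois = -lam * t
    n = 0
    total = 0.0
    n_max = int(lam * t + 12 * math.sqrt(lam * t) + 50)
    while n <= n_max:
        w = math.exp(logpois) * Rpow[n][a, b]
        weights.append(w)
        total += w
        if n >= 1 and total > 0 and w < tol * total and n > lam * t:
            break
        n += 1
        Rpow.append(Rpow[-1] @ R)
        logpois += math.log(lam * t) - math.log(n)
    if total <= 0:
        raise PathSamplingError("endpoint pair has zero probability")
    nn = int(rng.choice(len(weights), p=np.asarray(weights) / total))
    states = [a]
    for step in range(1, nn):
        # nn - step uniformized jumps remain after placing state `step`
        prev = states[-1]
        w = np.clip(R[prev] * Rpow[nn - step][:, b], 0, None)
        states.append(int(rng.choice(k, p=w / w.sum())))
    if nn >= 1:
        states.append(b)
    times = np.sort(rng.uniform(0.0, t, size=nn))
    # collapse virtual jumps
    segs: list[tuple[int, float]] = []
    bounds = np.concatenate([[0.0], times, [t]])
    for s, dur in zip(states, np.diff(bounds)):
        if segs and segs[-1][0] == s:
            segs[-1] = (s, segs[-1][1] + dur)
        else:
            segs.append((int(s), float(dur)))
    return segs


def _conditioned_path(Q, rates, a, b, t, rng, max_rejects):
    if t <= 0:
        return [(int(a), 0.0)]
    for _ in range(max_rejects):
        segs = _forward_path(Q, rates, a, t, rng)
        if segs[-1][0] == b:
            return segs
    return _uniformization_path(Q, a, b, t, rng)


def sample_histories(tree: Phylogeny, priors: TipPriorMatrix, model: MkModel,
                     n_sim: int = 100, seed: int = 0,
                     max_rejects: int = 1000) -> list[CharacterHistory]:
    """Draw stochastic character maps conditional on the soft tip data.

    Node states are sampled root-to-tips from their conditional
    distributions (tips included); each edge path is then drawn conditioned
    on its endpoints.  Histories are independent and reproducible: history i
    uses a generator derived from ``(seed, i)``.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    priors = _check_inputs(tree, priors, model)
    k = model.k
    P = _edge_pmats(tree, model.Q)
    D, _ = _down_partials(tree, priors.values, P, k)
    rates = -np.diag(model.Q)
    histories = []
    for i in range(n_sim):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), i]))
        states = np.zeros(tree.n_nodes, dtype=int)
        w = model.root_prior * D[tree.root]
        states[tree.root] = rng.choice(k, p=w / w.sum())
        for v in range(tree.n_nodes - 2, -1, -1):
            p = P[v][states[tree.parent[v]]] * D[v]
            states[v] = rng.choice(k, p=p / p.sum())
        edges = {}
        for v in range(tree.n_nodes - 1):
            edges[v] = _conditioned_path(
                model.Q, rates, int(states[tree.parent[v]]), int(states[v]),
                float(tree.brlen[v]), rng, max_rejects)
        histories.append(CharacterHistory(states, edges, k))
    return histories


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class HistorySummary:
    node_probs: pd.DataFrame      # nodes x states frequencies
    per_history: pd.DataFrame     # one row per map: shift counts by type
    median_shifts_to_nonmarine: float
    shift_quantiles: dict[str, float]


def summarize_histories(histories: list[CharacterHistory],
                        tree: Phylogeny,
                        marine_state: int = 0) -> HistorySummary:
    """Node posterior state table and shift-count distribution.

    Transition types: marine -> non-marine ("shift"), any -> marine
    ("reversal"), and non-marine <-> non-marine ("pathway switch", only
    meaningful when the two non-marine pathways are separate states).
    """
    if not histories:
        raise ValueError("need at least one history")
    k = histories[0].n_states
    n_nodes = len(histories[0].node_states)
    if n_nodes != tree.n_nodes:
        raise ValueError("histories do not match the tree")
    freq = np.zeros((n_nodes, k))
    rows = []
    for h in histories:
        if len(h.node_states) != n_nodes or h.n_states != k:
            raise ValueError("histories on mismatched trees/state spaces")
        freq[np.arange(n_nodes), h.node_states] += 1
        C = h.transition_counts()
        shifts = int(C[marine_state].sum())
        reversals = int(C[:, marine_state].sum())
        switches = int(C.sum() - shifts - reversals)
        rows.append((shifts, reversals, switches, int(C.sum())))
    freq /= len(histories)
    labels = [tree.labels[v] if v < tree.n_tips else f"node{v}"
              for v in range(n_nodes)]
    node_probs = pd.DataFrame(freq, index=labels, columns=list(range(k)))
    per = pd.DataFrame(rows, columns=["to_nonmarine", "reversal",
                                      "pathway_switch", "total"])
    qs = per["to_nonmarine"].quantile([0.025, 0.25, 0.5, 0.75, 0.975])
    return HistorySummary(
        node_probs, per,
        float(per["to_nonmarine"].median()),
        {f"q{int(q * 1000) / 10}": float(v) for q, v in qs.items()},
    )


def history_to_simmap(tree: Phylogeny, history: CharacterHistory) -> str:
    """Serialise one history as SIMMAP-style annotated Newick."""

    def seg_str(v: int) -> str:
        parts = [f"{s},{d:.9g}" for s, d in reversed(history.edges[v])]
        return ":{" + ":".join(parts) + "}"

    def rec(v: int) -> str:
        if tree.is_tip(v):
            s = tree.labels[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children(v)) + ")"
        if v != tree.root:
            s += seg_str(v)
        return s

    return rec(tree.root) + ";"


def expected_transitions_conditioned(Q: np.ndarray, a: int, b: int, t: float,
                                     n_grid: int = 2001) -> float:
    """E[# realized transitions | start a, end b, duration t].

    Independent check for the path samplers: integrates
    sum_{i != j} q_ij P_ai(s) P_jb(t-s) ds / P_ab(t) on a dense grid.
    """
    s = np.linspace(0.0, t, n_grid)
    k = Q.shape[0]
    Pab = expm(Q * t)[a, b]
    vals = np.zeros(n_grid)
    for m, sm in enumerate(s):
        P1 = expm(Q * sm)
        P2 = expm(Q * (t - sm))
        tot = 0.0
        for i in range(k):
            for j in range(k):
                if i != j:
                    tot += P1[a, i] * Q[i, j] * P2[j, b]
        vals[m] = tot
    return float(np.trapezoid(vals, s) / Pab)
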