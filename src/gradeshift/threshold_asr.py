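"""Bayesian threshold-model ancestral state reconstruction.

An ordered discrete character (terrestriality grade) is modeled through an
unobserved continuous *liability* evolving along the tree by Brownian motion
(BM), an Ornstein-Uhlenbeck process (OU, pull toward the root's sampled
liability), or BM on a lambda-transformed tree.  Ordered thresholds
``-inf < t_1=0 < t_2 < ... < t_{m-1} < inf`` carve the liability axis into m
grade intervals; a node is in grade k when its liability lies in
``[t_k, t_{k+1})`` (grade 0 below 0).

Identifiability convention: the diffusion rate sigma^2 is fixed at 1 and the
first threshold at 0, anchoring the liability scale; the root liability gets
a vague Normal(0, root_sd^2) prior.  Soft tip priors act through the
Metropolis ratio pi(grade(l'))/pi(grade(l)) when a tip's liability crosses a
threshold, so tip grades are resampled rather than fixed.

The sampler is Metropolis-within-Gibbs with sliding-window proposals,
auto-tuned toward 25-45% acceptance during burnin and frozen afterwards
(preserving detailed balance in the retained portion of the chain).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _thresh_kernel as K
from .grades import TipPriorMatrix
from .tree_io import Phylogeny

log = logging.getLogger(__name__)

KINDS = {"BM": K.KIND_BM, "OU": K.KIND_OU, "lambda": K.KIND_LAMBDA}

__all__ = [
    "LiabilityModel",
    "ThresholdChain",
    "liability_loglik",
    "run_threshold_mcmc",
    "ancestral_states",
    "dic",
    "threshold_spacing",
]


@dataclass(frozen=True)
class LiabilityModel:
    """Evolution model of the liability: BM, OU or lambda-BM.

    sigma2 is fixed at 1 by convention; ``alpha`` (OU pull) and ``lam``
    (Pagel lambda in [0,1]) are the kind's single free parameter.
    """

    kind: str = "BM"
    sigma2: float = 1.0
    alpha: float = 1.0
    lam: float = 1.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown liability model kind {self.kind!r}")
        if self.kind == "OU" and not self.alpha > 0:
            raise ValueError("OU requires alpha > 0")
        if self.kind == "lambda" and not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")


def _lambda_blens(tree: Phylogeny, lam: float) -> np.ndarray:
    """Pagel-lambda branch lengths: pendant edges keep tip heights."""
    depth = tree.depths()
    out = np.empty(tree.n_nodes - 1)
    for v in range(tree.n_nodes - 1):
        if tree.is_tip(v):
            out[v] = tree.brlen[v] + (1 - lam) * depth[tree.parent[v]]
        else:
            out[v] = lam * tree.brlen[v]
    return out


def liability_loglik(tree: Phylogeny, liabilities: np.ndarray,
                     model: LiabilityModel, root_sd: float = 1e3,
                     include_root_prior: bool = True) -> float:
    """Log-density of one liability per node under the edge-wise model.

    Zero-length edges demand exact inheritance: unequal liabilities across
    such an edge give ``-inf`` (flagged with a warning).
    """
    liab = np.asarray(liabilities, dtype=float)
    if liab.shape != (tree.n_nodes,):
        raise ValueError("need exactly one liability per node")
    s2 = model.sigma2
    theta = liab[tree.root]
    blen = (_lambda_blens(tree, model.lam) if model.kind == "lambda"
            else tree.brlen[: tree.n_nodes - 1])
    tot = 0.0
    for v in range(tree.n_nodes - 1):
        p, c, b = liab[tree.parent[v]], liab[v], blen[v]
        if b <= 0:
            if p != c:
                warnings.warn(
                    f"zero-length edge above node {v} with unequal liabilities"
                )
                return -np.inf
            continue
        if model.kind == "OU":
            w = np.exp(-model.alpha * b)
            mean = p * w + theta * (1 - w)
            var = s2 * (1 - np.exp(-2 * model.alpha * b)) / (2 * model.alpha)
        else:
            mean, var = p, s2 * b
        tot += -0.5 * ((c - mean) ** 2 / var + np.log(2 * np.pi * var))
    if include_root_prior:
        tot += -0.5 * (theta ** 2 / root_sd ** 2 + np.log(2 * np.pi * root_sd ** 2))
    return float(tot)


# ---------------------------------------------------------------------------
# chain container
# ---------------------------------------------------------------------------

@dataclass
class ThresholdChain:
    """Retained MCMC samples plus sampler settings and acceptance rates."""

    tree: Phylogeny
    grades: tuple
    liab: np.ndarray        # (S, n_nodes)
    thresholds: np.ndarray  # (S, m-1)
    param: np.ndarray       # (S,) alpha, lambda, or zeros for BM
    deviance: np.ndarray    # (S,)
    settings: dict
    acceptance: dict

    @property
    def n_samples(self) -> int:
        return self.liab.shape[0]

    @property
    def burnin_index(self) -> int:
        return int(np.floor(self.settings["burnin"] * self.n_samples))

    def retained(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.burnin_index:]

    @property
    def n_retained(self) -> int:
        return self.n_samples - self.burnin_index

    def sample_grades(self) -> np.ndarray:
        """(S_retained, n_nodes) grade of every node in every retained sample."""
        liab = self.retained(self.liab)
        thr = self.retained(self.thresholds)
        out = np.empty(liab.shape, dtype=np.int64)
        for s in range(liab.shape[0]):
            out[s] = np.searchsorted(thr[s], liab[s], side="right")
        return out

    def to_csv(self, path: str) -> None:
        m1 = self.thresholds.shape[1]
        cols = {}
        for j in range(m1):
            cols[f"t{j + 1}"] = self.thresholds[:, j]
        cols["param"] = self.param
        cols["deviance"] = self.deviance
        for v in range(self.tree.n_nodes):
            name = (self.tree.labels[v] if v < self.tree.n_tips else f"node{v}")
            cols[f"liab_{name}"] = self.liab[:, v]
        pd.DataFrame(cols).to_csv(path, index_label="sample")


def _liability_groups(tree: Phylogeny):
    """Merge nodes linked by zero-length edges (exact inheritance)."""
    parent = list(range(tree.n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for v in range(tree.n_nodes - 1):
        if tree.brlen[v] == 0.0:
            parent[find(v)] = find(tree.parent[v])
    reps = {}
    group_of = np.empty(tree.n_nodes, dtype=np.int64)
    for v in range(tree.n_nodes):
        r = find(v)
        if r not in reps:
            reps[r] = len(reps)
        group_of[v] = reps[r]
    return group_of, len(reps)


def run_threshold_mcmc(
    tree: Phylogeny,
    priors: TipPriorMatrix,
    kind: str = "BM",
    ngen: int = 2_000_000,
    burnin: float = 0.2,
    thin: int = 200,
    seed: int = 0,
    proposal_liab: float = 1.0,
    proposal_thr: float = 0.2,
    proposal_param: float = 1.0,
    root_sd: float = 1e3,
    force_root_grade0: bool = True,
    thr_max: float = 20.0,
    tune_interval: int = 2_000,
) -> ThresholdChain:
    """MCMC over liabilities, thresholds and the model parameter.

    ``ngen`` counts elementary updates taken in a fixed cyclic sweep; a
    sample is recorded every ``thin`` generations and the first ``burnin``
    fraction of samples is discarded by downstream summaries.

    Free thresholds get a flat prior on ``(0, thr_max)`` (order-preserving).
    A proper upper bound matters when a grade is never observed at the
    tips: its bounding threshold is then data-free and an unbounded flat
    prior would let it wander without limit.  ``thr_max`` is in liability
    units (sigma = 1 per unit branch length), so the default 20 is far
    beyond any reachable liability on trees of height ~1.
    """
    if proposal_liab <= 0 or proposal_thr <= 0 or proposal_param <= 0:
        raise ValueError("proposal widths must be > 0")
    if kind not in KINDS:
        raise ValueError(f"unknown model kind {kind!r}")
    if list(priors.tips) != list(tree.tip_labels):
        priors = priors.reordered(list(tree.tip_labels))
    pvals = priors.values
    m = pvals.shape[1]
    if m < 2:
        raise ValueError("need at least 2 grades")
    observed = {int(g) for row in pvals for g in np.flatnonzero(row > 0)}
    if len(observed) < 2:
        warnings.warn("all tip priors concentrate on one grade; "
                      "the posterior will collapse to it")

    group_of, G = _liability_groups(tree)
    root_group = int(group_of[tree.root])

    # edges between distinct groups only (zero-length edges are merged)
    eP, eC, eB, ePend, ePd = [], [], [], [], []
    depth = tree.depths()
    has_tip = np.zeros(G, dtype=bool)
    for t in range(tree.n_tips):
        has_tip[group_of[t]] = True
    for v in range(tree.n_nodes - 1):
        gp, gc = group_of[tree.parent[v]], group_of[v]
        if gp == gc:
            continue
        eP.append(gp)
        eC.append(gc)
        eB.append(float(tree.brlen[v]))
        ePend.append(bool(has_tip[gc]))
        ePd.append(float(depth[tree.parent[v]]))
    e_par = np.asarray(eP, dtype=np.int64)
    e_child = np.asarray(eC, dtype=np.int64)
    e_blen = np.asarray(eB)
    e_pend = np.asarray(ePend)
    e_pdepth = np.asarray(ePd)

    # incidence lists
    inc = [[] for _ in range(G)]
    for e in range(len(e_par)):
        inc[e_par[e]].append(e)
        inc[e_child[e]].append(e)
    inc_ptr = np.zeros(G + 1, dtype=np.int64)
    inc_idx = np.empty(sum(len(x) for x in inc), dtype=np.int64)
    pos = 0
    for i in range(G):
        inc_ptr[i] = pos
        for e in inc[i]:
            inc_idx[pos] = e
            pos += 1
    inc_ptr[G] = pos

    tip_group = group_of[: tree.n_tips].copy()
    gt = [[] for _ in range(G)]
    for t in range(tree.n_tips):
        gt[tip_group[t]].append(t)
    gtip_ptr = np.zeros(G + 1, dtype=np.int64)
    gtip_idx = np.empty(tree.n_tips, dtype=np.int64)
    pos = 0
    for i in range(G):
        gtip_ptr[i] = pos
        for t in gt[i]:
            gtip_idx[pos] = t
            pos += 1
    gtip_ptr[G] = pos

    with np.errstate(divide="ignore"):
        tip_logprior = np.log(pvals)

    # ---- initial state ------------------------------------------------
    thr0 = np.arange(m - 1, dtype=float) * 0.5
    if thr0[-1] >= thr_max:
        raise ValueError("thr_max too small for the number of grades")
    mids = np.empty(m)
    for k in range(m):
        lo = -np.inf if k == 0 else thr0[k - 1]
        hi = np.inf if k == m - 1 else thr0[k]
        if np.isinf(lo):
            mids[k] = hi - 0.5
        elif np.isinf(hi):
            mids[k] = lo + 0.5
        else:
            mids[k] = 0.5 * (lo + hi)
    liab0_nodes = np.zeros(tree.n_nodes)
    for t in range(tree.n_tips):
        liab0_nodes[t] = mids[int(np.argmax(pvals[t]))]
    for v in range(tree.n_tips, tree.n_nodes):
        kids = tree.children(v)
        liab0_nodes[v] = float(np.mean([liab0_nodes[c] for c in kids]))
    if force_root_grade0 and liab0_nodes[tree.root] >= 0:
        liab0_nodes[tree.root] = -0.5
    g0 = np.zeros(G)
    for v in range(tree.n_nodes):
        g0[group_of[v]] = liab0_nodes[v]
    # tips win inside a group (their priors constrain the value)
    for t in range(tree.n_tips):
        g0[tip_group[t]] = liab0_nodes[t]
    if force_root_grade0 and g0[root_group] >= 0:
        g0[root_group] = -0.5

    param0 = {"BM": 0.0, "OU": 1.0, "lambda": 0.9}[kind]
    n_free = m - 2
    w_liab = np.full(G, float(proposal_liab))
    w_thr = np.full(max(n_free, 1), float(proposal_thr))
    w_param = np.array([float(proposal_param)])
    w_scale = np.array([0.2])

    burnin_gen = int(burnin * ngen)
    out_g, out_thr, out_param, out_dev, acc = K.run_kernel(
        KINDS[kind], g0.copy(), thr0.copy(), float(param0),
        e_par, e_child, e_blen, e_pend, e_pdepth,
        inc_ptr, inc_idx,
        tip_group, gtip_ptr, gtip_idx, tip_logprior,
        root_group, float(root_sd), bool(force_root_grade0), float(thr_max),
        int(ngen), int(thin), int(burnin_gen), int(tune_interval),
        w_liab, w_thr, w_param, w_scale, int(seed) % (2 ** 31 - 1),
    )

    liab = out_g[:, group_of]
    acceptance = {
        "liability": float(np.mean(acc[:G])),
        "threshold": float(np.mean(acc[G:G + n_free])) if n_free else float("nan"),
        "param": float(acc[G + n_free]) if kind != "BM" else float("nan"),
        "scale": float(acc[-1]),
    }
    settings = dict(kind=kind, ngen=int(ngen), burnin=float(burnin),
                    thin=int(thin), seed=int(seed), root_sd=float(root_sd),
                    force_root_grade0=bool(force_root_grade0),
                    thr_max=float(thr_max), sigma2=1.0, n_grades=m)
    return ThresholdChain(tree, tuple(range(m)), liab, out_thr, out_param,
                          out_dev, settings, acceptance)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def ancestral_states(chain: ThresholdChain, min_samples: int = 100) -> pd.DataFrame:
    """Posterior grade probabilities at internal nodes (rows sum to 1)."""
    if chain.n_retained < min_samples:
        raise ValueError(
            f"only {chain.n_retained} post-burnin samples (< {min_samples})"
        )
    tree = chain.tree
    grades = chain.sample_grades()
    m = chain.settings["n_grades"]
    internal = range(tree.n_tips, tree.n_nodes)
    probs = np.zeros((tree.n_nodes - tree.n_tips, m))
    for row, v in enumerate(internal):
        counts = np.bincount(grades[:, v], minlength=m)
        probs[row] = counts / grades.shape[0]
    idx = [f"node{v}" for v in internal]
    return pd.DataFrame(probs, index=idx, columns=list(chain.grades))


def tip_state_frequencies(chain: ThresholdChain) -> pd.DataFrame:
    """Posterior grade frequencies of the (resampled) tip states."""
    grades = chain.sample_grades()
    m = chain.settings["n_grades"]
    tree = chain.tree
    probs = np.zeros((tree.n_tips, m))
    for t in range(tree.n_tips):
        probs[t] = np.bincount(grades[:, t], minlength=m) / grades.shape[0]
    return pd.DataFrame(probs, index=list(tree.tip_labels),
                        columns=list(chain.grades))


@dataclass(frozen=True)
class DicResult:
    dic: float
    p_d: float
    mean_deviance: float
    plugin_deviance: float


def _augmented_deviance(chain: ThresholdChain, liab, thr, param) -> float:
    """Deviance (-2 log augmented likelihood) at a given parameter point."""
    tree = chain.tree
    kind = chain.settings["kind"]
    model = LiabilityModel(
        kind=kind,
        alpha=param if kind == "OU" else 1.0,
        lam=param if kind == "lambda" else 1.0,
    )
    ll = liability_loglik(tree, liab, model, include_root_prior=False)
    pvals = chain._prior_values
    grades = np.searchsorted(thr, liab[: tree.n_tips], side="right")
    with np.errstate(divide="ignore"):
        tip_ll = float(np.sum(np.log(pvals[np.arange(tree.n_tips), grades])))
    return -2.0 * (ll + tip_ll)


def dic(chain: ThresholdChain, priors: TipPriorMatrix | None = None) -> DicResult:
    """Deviance information criterion from the recorded per-sample deviance.

    ``DIC = mean(D) + p_D`` with ``p_D = mean(D) - D(posterior means)``.
    The plugin point uses posterior-mean liabilities, thresholds and model
    parameter.  ``priors`` must be supplied to evaluate the plugin tip-prior
    terms (the same matrix the chain was run with).
    """
    dev = chain.retained(chain.deviance)
    if dev.shape[0] < 10:
        raise ValueError("need at least 10 post-burnin samples for DIC")
    mean_dev = float(dev.mean())
    if priors is None:
        raise ValueError("dic() needs the TipPriorMatrix used for the run")
    if list(priors.tips) != list(chain.tree.tip_labels):
        priors = priors.reordered(list(chain.tree.tip_labels))
    chain._prior_values = priors.values
    liab_bar = chain.retained(chain.liab).mean(axis=0)
    thr_bar = chain.retained(chain.thresholds).mean(axis=0)
    par_bar = float(chain.retained(chain.param).mean())
    plugin = _augmented_deviance(chain, liab_bar, thr_bar, par_bar)
    p_d = mean_dev - plugin
    return DicResult(mean_dev + p_d, p_d, mean_dev, plugin)


def threshold_spacing(chain: ThresholdChain, ci: float = 0.95) -> pd.DataFrame:
    """Posterior widths of interior grade intervals and successive ratios.

    Interval k (for grades 1..m-2) is ``[t_k, t_{k+1})``; its width measures
    how much liability change is needed to pass through that grade.  The
    ratio column compares each interval with the previous one — large ratios
    mean it is that many times "harder" to cross into the next grade.
    """
    m = chain.settings["n_grades"]
    if m < 3:
        log.info("threshold_spacing: fewer than 3 grades, nothing to report")
        return pd.DataFrame(
            columns=["grade", "width_mean", "width_lo", "width_hi",
                     "ratio_vs_prev_mean", "ratio_lo", "ratio_hi"])
    thr = chain.retained(chain.thresholds)
    widths = np.diff(thr, axis=1)  # (S, m-2) widths of grades 1..m-2
    a = (1 - ci) / 2
    rows = []
    for k in range(widths.shape[1]):
        w = widths[:, k]
        ratio = w / widths[:, k - 1] if k else None
        rows.append({
            "grade": k + 1,
            "width_mean": float(w.mean()),
            "width_lo": float(np.quantile(w, a)),
            "width_hi": float(np.quantile(w, 1 - a)),
            "ratio_vs_prev_mean": float(ratio.mean()) if k else float("nan"),
            "ratio_lo": float(np.quantile(ratio, a)) if k else float("nan"),
            "ratio_hi": float(np.quantile(ratio, 1 - a)) if k else float("nan"),
        })
    return pd.DataFrame(rows)
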