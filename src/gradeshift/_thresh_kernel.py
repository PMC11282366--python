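"""Numba kernel for the threshold-model Metropolis-within-Gibbs sampler.

One *generation* is one elementary Metropolis update (a single liability
group, a single free threshold, or the evolution-model parameter), taken in
a fixed cyclic sweep.  The wrapper in :mod:`gradeshift.threshold_asr`
prepares flat arrays; everything here is plain numpy inside ``@njit``.

Model kinds: 0 = BM, 1 = OU (optimum at the sampled root liability),
2 = lambda (Pagel tree transform).  sigma2 is fixed at 1 to anchor the
liability scale.
"""

import math

import numpy as np
from numba import njit

KIND_BM = 0
KIND_OU = 1
KIND_LAMBDA = 2

LOG2PI = math.log(2.0 * math.pi)


@njit(cache=True)
def _grade(x, thr):
    g = 0
    for k in range(thr.shape[0]):
        if x >= thr[k]:
            g += 1
        else:
            break
    return g


@njit(cache=True)
def _refresh_edge_cache(kind, param, e_blen, e_pend, e_pdepth, ew, evar):
    n = e_blen.shape[0]
    for e in range(n):
        b = e_blen[e]
        if kind == KIND_OU:
            a = param
            ew[e] = math.exp(-a * b)
            if a > 0.0:
                evar[e] = (1.0 - math.exp(-2.0 * a * b)) / (2.0 * a)
            else:
                evar[e] = b
        elif kind == KIND_LAMBDA:
            ew[e] = 1.0
            if e_pend[e]:
                evar[e] = b + (1.0 - param) * e_pdepth[e]
            else:
                evar[e] = param * b
        else:
            ew[e] = 1.0
            evar[e] = b


@njit(cache=True)
def _edge_logdens(p, c, w, v, theta):
    mean = p * w + theta * (1.0 - w)
    return -0.5 * ((c - mean) * (c - mean) / v + math.log(v) + LOG2PI)


@njit(cache=True)
def _full_edge_loglik(g, e_par, e_child, ew, evar, theta):
    tot = 0.0
    for e in range(e_par.shape[0]):
        tot += _edge_logdens(g[e_par[e]], g[e_child[e]], ew[e], evar[e], theta)
    return tot


@njit(cache=True)
def _tip_loglik(g, thr, tip_group, tip_logprior):
    tot = 0.0
    for i in range(tip_group.shape[0]):
        lp = tip_logprior[i, _grade(g[tip_group[i]], thr)]
        if lp == -np.inf:
            return -np.inf
        tot += lp
    return tot


@njit(cache=True)
def run_kernel(kind, g, thr, param,
               e_par, e_child, e_blen, e_pend, e_pdepth,
               inc_ptr, inc_idx,
               tip_group, gtip_ptr, gtip_idx, tip_logprior,
               root_group, root_sd, force_root, thr_max,
               ngen, thin, burnin_gen, tune_interval,
               w_liab, w_thr, w_param, w_scale, seed):
    np.random.seed(seed)
    G = g.shape[0]
    E = e_par.shape[0]
    m1 = thr.shape[0]              # number of thresholds (m - 1)
    n_free = m1 - 1                # t_1 fixed at 0
    has_param = 1 if kind != KIND_BM else 0
    # last slot: global scale move (liabilities and free thresholds jointly;
    # tip grades are invariant under it, so only the Gaussian part changes).
    # It decorrelates the overall liability scale from the thresholds, the
    # slow direction of single-site updates under point-mass tip priors.
    cycle = G + n_free + has_param + 1

    ew = np.empty(E)
    evar = np.empty(E)
    _refresh_edge_cache(kind, param, e_blen, e_pend, e_pdepth, ew, evar)
    theta = g[root_group]

    n_samples = ngen // thin
    out_g = np.empty((n_samples, G))
    out_thr = np.empty((n_samples, m1))
    out_param = np.empty(n_samples)
    out_dev = np.empty(n_samples)

    acc = np.zeros(cycle)
    tries = np.zeros(cycle)
    acc_total = np.zeros(cycle)
    tries_total = np.zeros(cycle)

    s_idx = 0
    for gen in range(ngen):
        slot = gen % cycle
        if slot < G:
            # ---- liability group update ----
            i = slot
            old = g[i]
            new = old + (np.random.random() - 0.5) * w_liab[i]
            tries[slot] += 1.0
            tries_total[slot] += 1.0
            ok = True
            if i == root_group and force_root and new >= 0.0:
                ok = False
            delta = 0.0
            if ok:
                # tip-prior terms for tips in this group
                for idx in range(gtip_ptr[i], gtip_ptr[i + 1]):
                    t = gtip_idx[idx]
                    lp_new = tip_logprior[t, _grade(new, thr)]
                    if lp_new == -np.inf:
                        ok = False
                        break
                    delta += lp_new - tip_logprior[t, _grade(old, thr)]
            if ok:
                if i == root_group:
                    delta += -0.5 * (new * new - old * old) / (root_sd * root_sd)
                if i == root_group and kind == KIND_OU:
                    base = _full_edge_loglik(g, e_par, e_child, ew, evar, theta)
                    g[i] = new
                    prop = _full_edge_loglik(g, e_par, e_child, ew, evar, new)
                    g[i] = old
                    delta += prop - base
                else:
                    for idx in range(inc_ptr[i], inc_ptr[i + 1]):
                        e = inc_idx[idx]
                        p = g[e_par[e]]
                        c = g[e_child[e]]
                        delta -= _edge_logdens(p, c, ew[e], evar[e], theta)
                        if e_par[e] == i:
                            p = new
                        if e_child[e] == i:
                            c = new
                        delta += _edge_logdens(p, c, ew[e], evar[e], theta)
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    g[i] = new
                    if i == root_group:
                        theta = new
                    acc[slot] += 1.0
                    acc_total[slot] += 1.0
        elif slot < G + n_free:
            # ---- free threshold update (order-preserving) ----
            k = 1 + (slot - G)
            old = thr[k]
            new = old + (np.random.random() - 0.5) * w_thr[k - 1]
            tries[slot] += 1.0
            tries_total[slot] += 1.0
            upper = thr_max if k == m1 - 1 else thr[k + 1]
            ok = new > thr[k - 1] and new < upper
            if ok:
                delta = 0.0
                for t in range(tip_group.shape[0]):
                    x = g[tip_group[t]]
                    g_old = _grade(x, thr)
                    thr[k] = new
                    g_new = _grade(x, thr)
                    thr[k] = old
                    if g_new != g_old:
                        lp_new = tip_logprior[t, g_new]
                        if lp_new == -np.inf:
                            ok = False
                            break
                        delta += lp_new - tip_logprior[t, g_old]
                if ok and (delta >= 0.0 or np.random.random() < math.exp(delta)):
                    thr[k] = new
                    acc[slot] += 1.0
                    acc_total[slot] += 1.0
        elif slot == cycle - 1:
            # ---- global scale move: (g, thr) -> (c*g, c*thr) ----
            tries[slot] += 1.0
            tries_total[slot] += 1.0
            # scaling preserves liability signs, so the root-state
            # constraint and all tip grades are automatically kept
            c = math.exp((np.random.random() - 0.5) * w_scale[0])
            ok = m1 == 1 or thr[m1 - 1] * c < thr_max
            if ok:
                # quadratic form of the Gaussian part at scale 1
                q = 0.0
                for e in range(E):
                    mean = g[e_par[e]] * ew[e] + theta * (1.0 - ew[e])
                    q += (g[e_child[e]] - mean) * (g[e_child[e]] - mean) / evar[e]
                q += (g[root_group] * g[root_group]) / (root_sd * root_sd)
                delta = (-0.5 * (c * c - 1.0) * q
                         + (G + n_free) * math.log(c))
                if delta >= 0.0 or np.random.random() < math.exp(delta):
                    for i in range(G):
                        g[i] *= c
                    for k in range(1, m1):
                        thr[k] *= c
                    theta = g[root_group]
                    acc[slot] += 1.0
                    acc_total[slot] += 1.0
        else:
            # ---- evolution-model parameter update ----
            tries[slot] += 1.0
            tries_total[slot] += 1.0
            base = _full_edge_loglik(g, e_par, e_child, ew, evar, theta)
            if kind == KIND_OU:
                # log random walk; half-Cauchy-like vague prior on alpha
                new = param * math.exp((np.random.random() - 0.5) * w_param[0])
                if new > 1e-300 and new < 1e300:
                    ew2 = np.empty(E)
                    ev2 = np.empty(E)
                    _refresh_edge_cache(kind, new, e_blen, e_pend, e_pdepth,
                                        ew2, ev2)
                    prop = _full_edge_loglik(g, e_par, e_child, ew2, ev2, theta)
                    delta = (prop - base
                             + math.log(1.0 + param * param)
                             - math.log(1.0 + new * new)
                             + math.log(new) - math.log(param))
                    if delta >= 0.0 or np.random.random() < math.exp(delta):
                        param = new
                        ew = ew2
                        evar = ev2
                        acc[slot] += 1.0
                        acc_total[slot] += 1.0
            else:  # lambda in [0, 1], uniform prior
                new = param + (np.random.random() - 0.5) * w_param[0]
                if 0.0 <= new <= 1.0:
                    ew2 = np.empty(E)
                    ev2 = np.empty(E)
                    _refresh_edge_cache(kind, new, e_blen, e_pend, e_pdepth,
                                        ew2, ev2)
                    prop = _full_edge_loglik(g, e_par, e_child, ew2, ev2, theta)
                    if prop - base >= 0.0 or np.random.random() < math.exp(prop - base):
                        param = new
                        ew = ew2
                        evar = ev2
                        acc[slot] += 1.0
                        acc_total[slot] += 1.0

        # ---- adaptive proposal widths (burnin only) ----
        if gen < burnin_gen and (gen + 1) % tune_interval == 0:
            for s in range(cycle):
                if tries[s] >= 10.0:
                    rate = acc[s] / tries[s]
                    if s < G:
                        if rate > 0.45:
                            w_liab[s] *= 1.3
                        elif rate < 0.25:
                            w_liab[s] /= 1.3
                    elif s < G + n_free:
                        if rate > 0.45:
                            w_thr[s - G] *= 1.3
                        elif rate < 0.25:
                            w_thr[s - G] /= 1.3
                    elif s == cycle - 1:
                        if rate > 0.45:
                            w_scale[0] *= 1.3
                        elif rate < 0.25:
                            w_scale[0] /= 1.3
                    else:
                        if rate > 0.45:
                            w_param[0] *= 1.3
                        elif rate < 0.25:
                            w_param[0] /= 1.3
                    acc[s] = 0.0
                    tries[s] = 0.0

        # ---- record ----
        if (gen + 1) % thin == 0:
            out_g[s_idx] = g
            out_thr[s_idx] = thr
            out_param[s_idx] = param
            dev_ll = (_full_edge_loglik(g, e_par, e_child, ew, evar, theta)
                      + _tip_loglik(g, thr, tip_group, tip_logprior))
            out_dev[s_idx] = -2.0 * dev_ll
            s_idx += 1

    acc_rate = np.zeros(cycle)
    for s in range(cycle):
        if tries_total[s] > 0:
            acc_rate[s] = acc_total[s] / tries_total[s]
    return out_g, out_thr, out_param, out_dev, acc_rate
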