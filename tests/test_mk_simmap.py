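import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2_contingency

from gradeshift import mk_simmap as mk
from gradeshift import synthetic
from tests.conftest import priors_from_rows


def brute_force_loglik(tree, prior_rows, model):
    """Exhaustive sum over all node-state assignments (tips weighted by priors)."""
    k = model.k
    P = [expm(model.Q * tree.brlen[v]) for v in range(tree.n_nodes - 1)]
    tot = 0.0
    for assign in itertools.product(range(k), repeat=tree.n_nodes):
        p = model.root_prior[assign[tree.root]]
        for v in range(tree.n_nodes - 1):
            p *= P[v][assign[tree.parent[v]], assign[v]]
        for t in range(tree.n_tips):
            p *= prior_rows[t, assign[t]]
        tot += p
    return math.log(tot)


def random_model(k, seed, structure="ARD"):
    rng = np.random.default_rng(seed)
    rates = rng.uniform(0.1, 1.2, mk.n_rates(structure, k))
    return mk.MkModel.from_rates(structure, rates, k, root_prior="flat")


class TestMkLoglik:
    def test_zero_rate_matrix_reduces_to_prior_product(self, make_tree):
        t = make_tree("(A:1,B:1);")
        model = mk.MkModel((0, 1), np.zeros((2, 2)), np.array([0.6, 0.4]))
        rows = np.array([[0.9, 0.1], [0.3, 0.7]])
        pm = priors_from_rows(t, rows)
        expected = math.log(0.6 * 0.9 * 0.3 + 0.4 * 0.1 * 0.7)
        assert mk.mk_loglik(t, pm, model) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("nwk,k,seed", [
        ("((A:1,B:1):0.5,(C:0.7,D:0.8):1.2);", 3, 1),
        ("((A:1,B:1):0.5,(C:0.7,D:0.8):1.2);", 2, 2),
        ("(((A:0.3,B:0.6):0.4,C:1.1):0.2,(D:0.5,E:0.9):0.7);", 3, 3),
        ("(A:1,B:1,C:2);", 3, 4),
        ("(A:0.4,B:0.9,C:0.2,D:1.5,E:0.8);", 2, 5),
    ])
    def test_matches_brute_force_enumeration(self, make_tree, nwk, k, seed):
        t = make_tree(nwk)
        model = random_model(k, seed)
        rng = np.random.default_rng(seed + 100)
        rows = rng.dirichlet(np.ones(k), size=t.n_tips)
        pm = priors_from_rows(t, rows)
        assert mk.mk_loglik(t, pm, model) == pytest.approx(
            brute_force_loglik(t, rows, model), abs=1e-8)

    def test_rate_time_rescaling_invariance(self, make_tree):
        t1 = make_tree("((A:1,B:1):0.5,C:1.5);")
        t2 = make_tree("((A:2,B:2):1.0,C:3.0);")
        rows = np.array([[1, 0], [0, 1], [1, 0]], dtype=float)
        m_fast = random_model(2, 7)
        m_slow = mk.MkModel(m_fast.states, m_fast.Q / 2.0, m_fast.root_prior)
        ll1 = mk.mk_loglik(t1, priors_from_rows(t1, rows), m_fast)
        ll2 = mk.mk_loglik(t2, priors_from_rows(t2, rows), m_slow)
        assert ll1 == pytest.approx(ll2, abs=1e-10)

    def test_transition_matrix_rows_sum_to_one(self):
        model = random_model(3, 11)
        for t in (0.0, 0.5, 10.0, 1e3):
            P = expm(model.Q * t)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)


class TestFitMk:
    def test_single_observed_state_flags_degenerate(self, tree4):
        pm = priors_from_rows(tree4, np.tile([1.0, 0.0], (4, 1)))
        fit = mk.fit_mk(tree4, pm, structure="ER")
        assert fit.degenerate
        assert fit.model.Q[0, 1] <= 1e-7

    def test_er_nested_in_ard(self, make_tree):
        t = make_tree("((A:1,B:1):0.5,(C:0.7,D:0.8):1.2);")
        rows = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 1, 0]], float)
        pm = priors_from_rows(t, rows)
        assert mk.fit_mk(t, pm, "ER").loglik <= mk.fit_mk(t, pm, "ARD").loglik + 1e-6

    def test_er_rate_recovery_majority(self):
        hits = 0
        for rep in range(1, 11):
            tree = synthetic.simulate_tree(200, seed=rep, height=1.0)
            Q = mk.build_q("ER", [0.5], 2)
            states = synthetic.simulate_mk(tree, Q, np.array([0.5, 0.5]),
                                           seed=100 + rep)
            rows = np.zeros((200, 2))
            rows[np.arange(200), states[:200]] = 1.0
            pm = priors_from_rows(tree, rows)
            fit = mk.fit_mk(tree, pm, structure="ER")
            hits += abs(fit.model.Q[0, 1] - 0.5) / 0.5 <= 0.5
        assert hits > 5


class TestSampleHistories:
    def test_zero_rates_identical_tips_give_constant_maps(self, tree4):
        model = mk.MkModel((0, 1), np.zeros((2, 2)), np.array([1.0, 0.0]))
        pm = priors_from_rows(tree4, np.tile([1.0, 0.0], (4, 1)))
        hists = mk.sample_histories(tree4, pm, model, n_sim=20, seed=1)
        for h in hists:
            assert np.all(h.node_states == 0)
            assert h.transition_counts().sum() == 0

    def test_root_state_frequency_matches_bayes(self, make_tree):
        # two-tip tree: closed-form root posterior via matrix exponential
        t = make_tree("(A:0.8,B:1.4);")
        model = random_model(2, 21)
        rows = np.array([[1.0, 0.0], [0.0, 1.0]])
        pm = priors_from_rows(t, rows)
        Pa = expm(model.Q * 0.8)
        Pb = expm(model.Q * 1.4)
        w = model.root_prior * Pa[:, 0] * Pb[:, 1]
        analytic = w / w.sum()
        hists = mk.sample_histories(t, pm, model, n_sim=10_000, seed=5)
        freq = np.mean([h.node_states[t.root] == 0 for h in hists])
        assert freq == pytest.approx(analytic[0], abs=0.02)

    def test_mean_transitions_match_quadrature_oracle(self):
        Q = random_model(3, 3).Q
        rates = -np.diag(Q)
        rng = np.random.default_rng(17)
        ns = [len(mk._conditioned_path(Q, rates, 0, 1, 1.3, rng, 1000)) - 1
              for _ in range(6000)]
        oracle = mk.expected_transitions_conditioned(Q, 0, 1, 1.3, n_grid=801)
        se = np.std(ns) / np.sqrt(len(ns))
        assert np.mean(ns) == pytest.approx(oracle, abs=3 * se)

    def test_rejection_and_uniformization_agree(self):
        # two-sample test on transition counts over a fixed edge
        Q = random_model(3, 3).Q
        rates = -np.diag(Q)
        r1, r2 = np.random.default_rng(11), np.random.default_rng(12)
        nr = [len(mk._conditioned_path(Q, rates, 0, 1, 1.3, r1, 10 ** 9)) - 1
              for _ in range(5000)]
        nu = [len(mk._uniformization_path(Q, 0, 1, 1.3, r2)) - 1
              for _ in range(5000)]
        m = max(max(nr), max(nu))
        c1 = np.bincount(nr, minlength=m + 1)
        c2 = np.bincount(nu, minlength=m + 1)
        keep = (c1 + c2) >= 5
        _, p, *_ = chi2_contingency(np.vstack([c1[keep], c2[keep]]))
        assert p > 0.01

    def test_segment_durations_sum_to_branch_lengths(self, tree4):
        model = random_model(3, 9)
        rng = np.random.default_rng(2)
        pm = priors_from_rows(tree4, rng.dirichlet(np.ones(3), size=4))
        (h,) = mk.sample_histories(tree4, pm, model, n_sim=1, seed=3)
        for v, segs in h.edges.items():
            assert sum(d for _, d in segs) == pytest.approx(tree4.brlen[v])
            for (s1, _), (s2, _) in zip(segs[:-1], segs[1:]):
                assert s1 != s2

    def test_reproducible_under_seed(self, tree4):
        model = random_model(2, 4)
        pm = priors_from_rows(tree4, np.tile([0.5, 0.5], (4, 1)))
        h1 = mk.sample_histories(tree4, pm, model, n_sim=5, seed=42)
        h2 = mk.sample_histories(tree4, pm, model, n_sim=5, seed=42)
        for a, b in zip(h1, h2):
            assert np.array_equal(a.node_states, b.node_states)
            assert a.edges == b.edges


class TestSummaries:
    def test_constant_histories_summary(self, tree4):
        model = mk.MkModel((0, 1), np.zeros((2, 2)), np.array([1.0, 0.0]))
        pm = priors_from_rows(tree4, np.tile([1.0, 0.0], (4, 1)))
        hists = mk.sample_histories(tree4, pm, model, n_sim=10, seed=0)
        summ = mk.summarize_histories(hists, tree4)
        assert np.all(summ.node_probs[0].to_numpy() == 1.0)
        assert summ.median_shifts_to_nonmarine == 0

    def test_median_of_handbuilt_counts(self, tree4):
        model = mk.MkModel((0, 1), np.zeros((2, 2)), np.array([1.0, 0.0]))
        pm = priors_from_rows(tree4, np.tile([1.0, 0.0], (4, 1)))
        hists = mk.sample_histories(tree4, pm, model, n_sim=3, seed=0)
        # plant 1, 2 and 4 marine->non-marine shifts on distinct edges
        for h, n in zip(hists, [1, 2, 4]):
            for edge in range(n):
                b = float(tree4.brlen[edge])
                h.edges[edge] = [(0, b / 2), (1, b / 2)]
        summ = mk.summarize_histories(hists, tree4)
        assert list(summ.per_history["to_nonmarine"]) == [1, 2, 4]
        assert summ.median_shifts_to_nonmarine == 2

    def test_node_frequencies_match_marginal_asr(self, make_tree):
        t = make_tree("(((A:0.4,B:0.7):0.5,C:1.0):0.3,(D:0.6,E:0.2):0.9);")
        model = random_model(3, 6)
        rng = np.random.default_rng(8)
        pm = priors_from_rows(t, rng.dirichlet(np.ones(3), size=5))
        marg = mk.marginal_asr(t, pm, model)
        hists = mk.sample_histories(t, pm, model, n_sim=4000, seed=9)
        summ = mk.summarize_histories(hists, t)
        err = np.abs(marg.to_numpy() - summ.node_probs.to_numpy()).max()
        assert err < 0.03

    def test_simmap_serialisation_roundtrips_states(self, tree4):
        model = random_model(2, 10)
        pm = priors_from_rows(tree4, np.tile([0.5, 0.5], (4, 1)))
        (h,) = mk.sample_histories(tree4, pm, model, n_sim=1, seed=1)
        s = mk.history_to_simmap(tree4, h)
        assert s.endswith(";") and "{" in s
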