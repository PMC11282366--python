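import numpy as np
import pandas as pd
import pytest

from gradeshift import transitions as tr
from gradeshift import synthetic
from gradeshift.transitions import UNCERTAIN
from tests.conftest import priors_from_rows


def node_table(tree, rows):
    idx = [f"node{v}" for v in range(tree.n_tips, tree.n_nodes)]
    return pd.DataFrame(rows, index=idx, columns=list(range(len(rows[0]))))


class TestAssignNodeGrades:
    def test_clear_winner(self, tree3):
        t = node_table(tree3, [[0.9, 0.1], [0.6, 0.4]])
        g = tr.assign_node_grades(t, min_prob=0.5)
        assert list(g) == [0, 0]

    def test_tie_breaks_to_lower_grade(self, tree3, caplog):
        t = node_table(tree3, [[0.45, 0.45, 0.1], [1.0, 0.0, 0.0]])
        g = tr.assign_node_grades(t, min_prob=0.4)
        assert g.iloc[0] == 0

    def test_below_min_prob_is_uncertain(self, tree3):
        t = node_table(tree3, [[0.4, 0.3, 0.3], [1.0, 0.0, 0.0]])
        g = tr.assign_node_grades(t, min_prob=0.5)
        assert g.iloc[0] == UNCERTAIN


class TestCountShifts:
    def test_all_marine_means_no_events(self, make_tree):
        t = make_tree("(((A:1,B:1):1,C:2):1,(D:1.5,E:1.5):1.5);")
        ng = pd.Series(0, index=[f"node{v}" for v in range(t.n_tips, t.n_nodes)])
        tg = pd.Series(0, index=list(t.tip_labels))
        rep = tr.count_shifts(t, ng, tg)
        assert rep.node_shifts == [] and rep.reversals == []
        assert rep.min_origins == 0

    def test_handbuilt_shift_and_reversal(self, make_tree):
        # 5-tip caterpillar: node5=(A,B), node6=(node5,C), node7=(node6,D), root
        t = make_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        grades = {5: 2, 6: 2, 7: 0, 8: 0}
        ng = pd.Series({f"node{v}": g for v, g in grades.items()})
        tg = pd.Series(0, index=list(t.tip_labels))
        rep = tr.count_shifts(t, ng, tg)
        assert [(e, f, g) for e, f, g in rep.node_shifts] == [(6, 0, 2)]
        assert len(rep.reversals) == 0
        assert rep.min_origins == 1

    def test_nested_deepening_counts_one_origin(self, make_tree):
        t = make_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        ng = pd.Series({"node5": 3, "node6": 1, "node7": 0, "node8": 0})
        tg = pd.Series(0, index=list(t.tip_labels))
        rep = tr.count_shifts(t, ng, tg)
        assert rep.min_origins == 1  # 0 -> 1 -> 3 is one origin

    def test_reversal_detected(self, make_tree):
        t = make_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        ng = pd.Series({"node5": 0, "node6": 2, "node7": 2, "node8": 0})
        tg = pd.Series(0, index=list(t.tip_labels))
        rep = tr.count_shifts(t, ng, tg)
        assert len(rep.node_shifts) == 1
        assert [(e, f, g) for e, f, g in rep.reversals] == [(5, 2, 0)]

    def test_uncertain_edges_skipped_and_reported(self, make_tree):
        t = make_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        ng = pd.Series({"node5": 2, "node6": UNCERTAIN, "node7": 0, "node8": 0})
        tg = pd.Series(0, index=list(t.tip_labels))
        rep = tr.count_shifts(t, ng, tg)
        assert rep.min_origins == 0
        assert len(rep.skipped_edges) > 0

    def test_report_matches_independent_edge_scan_and_conservation(self):
        tree = synthetic.simulate_tree(40, seed=6, height=1.0)
        rng = np.random.default_rng(4)
        g = rng.choice([0, 1], size=tree.n_nodes, p=[0.7, 0.3])
        g[tree.root] = 0
        ng = pd.Series({f"node{v}": int(g[v])
                        for v in range(tree.n_tips, tree.n_nodes)})
        tg = pd.Series({tree.labels[t]: int(g[t]) for t in range(tree.n_tips)})
        rep = tr.count_shifts(tree, ng, tg)
        # independent exhaustive scan over internal edges
        shifts = {v for v in range(tree.n_tips, tree.n_nodes - 1)
                  if g[tree.parent[v]] == 0 and g[v] >= 1}
        revs = {v for v in range(tree.n_tips, tree.n_nodes - 1)
                if g[tree.parent[v]] >= 1 and g[v] == 0}
        assert {e for e, *_ in rep.node_shifts} == shifts
        assert {e for e, *_ in rep.reversals} == revs
        # conservation: on any internal root-to-node path, origins minus
        # reversals equals the net marine/non-marine change of the endpoints
        for v in range(tree.n_tips, tree.n_nodes):
            ups = downs = 0
            u = v
            while u != tree.root:
                ups += u in shifts
                downs += u in revs
                u = tree.parent[u]
            assert ups - downs == int(g[v] >= 1) - int(g[tree.root] >= 1)

    def test_min_origins_monotone_in_min_prob(self, make_tree):
        t = make_tree("((((A:1,B:1):1,C:2):1,D:3):1,E:4);")
        table = node_table(t, [[0.2, 0.8], [0.45, 0.55], [0.9, 0.1], [1, 0]])
        tg = pd.Series(0, index=list(t.tip_labels))
        origins = []
        for mp in (0.5, 0.6, 0.9):
            ng = tr.assign_node_grades(table, min_prob=mp)
            origins.append(tr.count_shifts(t, ng, tg).min_origins)
        assert origins == sorted(origins, reverse=True)


class TestCombineAndRange:
    def _rep(self, pathway, shifts):
        r = tr.TransitionReport(pathway=pathway)
        r.node_shifts = shifts
        r.min_origins = len(shifts)
        r.max_origins = len(shifts)
        return r

    def test_disjoint_shift_sets_pool(self):
        comp = tr.combine_pathways(self._rep("direct", [(5, 0, 2)]),
                                   self._rep("indirect", [(9, 0, 1)]))
        assert comp.min_origins == 2 and comp.pathway_switches == []

    def test_shared_edge_is_one_origin_plus_switch(self):
        comp = tr.combine_pathways(self._rep("direct", [(5, 0, 2)]),
                                   self._rep("indirect", [(5, 0, 1)]))
        assert comp.min_origins == 1
        assert comp.pathway_switches == [5]

    def test_same_pathway_rejected(self):
        with pytest.raises(ValueError):
            tr.combine_pathways(self._rep("direct", []), self._rep("direct", []))

    def test_paper_style_bookkeeping_seven_to_seventeen(self):
        # 7 reconstructed node origins + 9 soft-prior-only families + 1
        # fossil -> at least 7, node+tip total 16, and up to 17 origins
        tree = synthetic.simulate_tree(60, seed=11, height=1.0)
        internals = [v for v in range(tree.n_tips, tree.n_nodes)
                     if 2 <= len(tree.clade_tips(v)) <= 5]
        chosen = []
        used = set()
        for v in internals:
            tips = tree.clade_tips(v)
            if tips & used:
                continue
            chosen.append(v)
            used |= tips
            if len(chosen) == 7:
                break
        assert len(chosen) == 7
        g = np.zeros(tree.n_nodes, dtype=int)
        for v in chosen[:3]:
            g[v] = 2
            for u in _desc(tree, v):
                g[u] = 2
        direct_g = g.copy()
        g = np.zeros(tree.n_nodes, dtype=int)
        for v in chosen[3:]:
            g[v] = 2
            for u in _desc(tree, v):
                g[u] = 2
        indirect_g = g

        free = [t for t in range(tree.n_tips)
                if tree.labels[t] not in
                {lab for v in chosen for lab in tree.clade_tips(v)}][:9]
        assert len(free) == 9

        fam = {}
        for i, v in enumerate(chosen):
            for lab in tree.clade_tips(v):
                fam[lab] = f"fam{i}"
        for j, t in enumerate(free):
            fam[tree.labels[t]] = f"soft{j}"
        for t in range(tree.n_tips):
            fam.setdefault(tree.labels[t], "marine")

        rows_d = np.zeros((tree.n_tips, 3))
        rows_i = np.zeros((tree.n_tips, 3))
        for t in range(tree.n_tips):
            rows_d[t, direct_g[t]] = 1.0
            rows_i[t, indirect_g[t]] = 1.0
        for t in free:
            rows_d[t] = [0.75, 0.25, 0.0]
        pm_d = priors_from_rows(tree, rows_d)
        pm_i = priors_from_rows(tree, rows_i)

        reps = {}
        for pathway, gg, pm in (("direct", direct_g, pm_d),
                                ("indirect", indirect_g, pm_i)):
            ng = pd.Series({f"node{v}": int(gg[v])
                            for v in range(tree.n_tips, tree.n_nodes)})
            tg = pd.Series({tree.labels[t]: int(gg[t])
                            for t in range(tree.n_tips)})
            reps[pathway] = tr.count_shifts(tree, ng, tg, pathway=pathway)
        assert reps["direct"].min_origins == 3
        assert reps["indirect"].min_origins == 4
        comp = tr.combine_pathways(reps["direct"], reps["indirect"])
        lo, hi = tr.origin_range(comp, tree, [pm_d, pm_i], fam,
                                 fossil_additions=1)
        assert (lo, hi) == (7, 17)
        assert lo + len(comp.tip_only_families) == 16

    def test_zero_everything(self, tree3):
        comp = self._rep("composite", [])
        comp.pathway = "composite"
        pm = priors_from_rows(tree3, np.tile([1.0, 0.0], (3, 1)))
        lo, hi = tr.origin_range(comp, tree3, pm,
                                 {t: "f" for t in tree3.tip_labels})
        assert (lo, hi) == (0, 0)

    def test_full_mass_cutoff_excludes_soft_tips(self, tree3):
        comp = self._rep("composite", [])
        comp.pathway = "composite"
        pm = priors_from_rows(tree3, np.tile([0.5, 0.5], (3, 1)))
        fam = {t: f"f{t}" for t in tree3.tip_labels}
        lo_all, hi_all = tr.origin_range(comp, tree3, pm, fam, mass_cutoff=1e-9)
        comp2 = self._rep("composite", [])
        lo1, hi1 = tr.origin_range(comp2, tree3, pm, fam, mass_cutoff=1.0)
        assert hi_all == 3 and hi1 == 0  # max monotone in the cutoff

    def test_bad_cutoff_rejected(self, tree3):
        comp = self._rep("composite", [])
        pm = priors_from_rows(tree3, np.tile([1.0, 0.0], (3, 1)))
        with pytest.raises(ValueError, match="mass_cutoff"):
            tr.origin_range(comp, tree3, pm, {}, mass_cutoff=0.0)


def _desc(tree, v):
    out, stack = [], list(tree.children(v))
    while stack:
        u = stack.pop()
        out.append(u)
        if u >= tree.n_tips:
            stack.extend(tree.children(u))
    return out


def test_report_serialisation(tmp_path, tree3):
    rep = tr.TransitionReport(pathway="direct", node_shifts=[(4, 0, 2)],
                              min_origins=1, max_origins=2)
    s = rep.to_json(str(tmp_path / "r.json"))
    assert '"direct"' in s
    txt = rep.summary_text()
    assert "at least 1" in txt
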