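"""Transition bookkeeping: node shifts, reversals, switches, origin ranges.

Reconstructed posterior grade tables are turned into discrete calls per
node, then scanned edge-by-edge for marine -> non-marine shifts (origins)
and non-marine -> marine reversals.  Because a phylogeny samples only some
species per family, families whose tips carry prior probability at
non-marine grades but show no reconstructed shift at any node add to the
*maximum* origin count, as do known fossil transitions outside the tree:

    min_origins = node shifts
    max_origins = min_origins + tip-only families + fossil additions
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .grades import TipPriorMatrix
from .tree_io import Phylogeny

log = logging.getLogger(__name__)

UNCERTAIN = -1

__all__ = [
    "TransitionReport",
    "assign_node_grades",
    "count_shifts",
    "combine_pathways",
    "origin_range",
]


@dataclass
class TransitionReport:
    """Shift bookkeeping for one pathway or the two-pathway composite."""

    pathway: str
    node_shifts: list = field(default_factory=list)      # (child, from, to)
    reversals: list = field(default_factory=list)        # (child, from, to)
    tip_shifts: list = field(default_factory=list)       # edges to single tips
    pathway_switches: list = field(default_factory=list)
    skipped_edges: list = field(default_factory=list)    # uncertain endpoint
    tip_only_families: list = field(default_factory=list)
    fossil_additions: int = 0
    min_origins: int | None = None
    max_origins: int | None = None

    def to_json(self, path: str | None = None) -> str:
        s = json.dumps(asdict(self), indent=2, default=int)
        if path:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def summary_text(self) -> str:
        lines = [
            f"pathway: {self.pathway}",
            f"node shifts to non-marine: {len(self.node_shifts)}",
            f"reversals to marine: {len(self.reversals)}",
            f"tip-level shifts: {len(self.tip_shifts)}",
            f"pathway switches: {len(self.pathway_switches)}",
            f"edges skipped (uncertain): {len(self.skipped_edges)}",
        ]
        if self.min_origins is not None:
            lines.append(
                f"origins: at least {self.min_origins}, up to {self.max_origins}"
                f" ({len(self.tip_only_families)} tip-only families,"
                f" {self.fossil_additions} fossil additions)")
        return "\n".join(lines)


def assign_node_grades(table: pd.DataFrame, min_prob: float = 0.5) -> pd.Series:
    """Max-posterior grade per node, or UNCERTAIN below ``min_prob``.

    Exact ties break deterministically to the lower grade (logged).
    """
    cols = np.asarray([int(c) for c in table.columns])
    vals = table.to_numpy()
    out = np.empty(len(table), dtype=np.int64)
    for i, row in enumerate(vals):
        best = float(row.max())
        if best < min_prob:
            out[i] = UNCERTAIN
            continue
        winners = cols[np.isclose(row, best, rtol=0, atol=1e-12)]
        if len(winners) > 1:
            log.warning("node %s: tie between grades %s; taking the lower",
                        table.index[i], list(winners))
        out[i] = int(winners.min())
    return pd.Series(out, index=table.index, name="grade")


def _node_grade_array(tree: Phylogeny, node_grades: pd.Series,
                      tip_grades: pd.Series) -> np.ndarray:
    g = np.full(tree.n_nodes, UNCERTAIN, dtype=np.int64)
    for t in range(tree.n_tips):
        lbl = tree.labels[t]
        if lbl in tip_grades.index:
            g[t] = int(tip_grades[lbl])
    for v in range(tree.n_tips, tree.n_nodes):
        key = f"node{v}"
        if key in node_grades.index:
            g[v] = int(node_grades[key])
        elif v in node_grades.index:
            g[v] = int(node_grades[v])
    return g


def count_shifts(tree: Phylogeny, node_grades: pd.Series,
                 tip_grades: pd.Series, pathway: str = "direct",
                 marine: frozenset = frozenset({0})) -> TransitionReport:
    """Edge scan for one pathway.

    A *node shift* is an edge whose parent is marine (grade in ``marine``)
    and whose child is a non-marine internal node; a *reversal* runs the
    other way.  Edges leading to single tips are tallied separately
    (``tip_shifts``): with family-level priors a lone non-marine tip is
    evidence of a within-family transition, not a reconstructed node shift.
    Edges with an uncertain endpoint are skipped and reported.
    """
    g = _node_grade_array(tree, node_grades, tip_grades)
    rep = TransitionReport(pathway=pathway)
    for v in range(tree.n_nodes - 1):
        pg, cg = g[tree.parent[v]], g[v]
        if pg == UNCERTAIN or cg == UNCERTAIN:
            rep.skipped_edges.append((int(v), int(pg), int(cg)))
            continue
        p_marine, c_marine = pg in marine, cg in marine
        if tree.is_tip(v):
            if p_marine and not c_marine:
                rep.tip_shifts.append((int(v), int(pg), int(cg)))
            continue
        if p_marine and not c_marine:
            rep.node_shifts.append((int(v), int(pg), int(cg)))
        elif not p_marine and c_marine:
            rep.reversals.append((int(v), int(pg), int(cg)))
    rep.min_origins = len(rep.node_shifts)
    rep.max_origins = rep.min_origins
    return rep


def combine_pathways(direct: TransitionReport,
                     indirect: TransitionReport) -> TransitionReport:
    """Pool the two pathways' origins into a composite report.

    An edge inferred as a shift in *both* pathways' reconstructions is one
    origin plus a pathway switch, not two origins.
    """
    if direct.pathway == indirect.pathway:
        raise ValueError("combine_pathways needs two distinct pathways")
    d_edges = {e for e, *_ in direct.node_shifts}
    i_edges = {e for e, *_ in indirect.node_shifts}
    both = d_edges & i_edges
    comp = TransitionReport(pathway="composite")
    comp.node_shifts = (
        [s for s in direct.node_shifts]
        + [s for s in indirect.node_shifts if s[0] not in both]
    )
    comp.pathway_switches = sorted(both)
    comp.reversals = direct.reversals + indirect.reversals
    comp.tip_shifts = direct.tip_shifts + indirect.tip_shifts
    comp.skipped_edges = direct.skipped_edges + indirect.skipped_edges
    comp.min_origins = len(comp.node_shifts)
    comp.max_origins = comp.min_origins
    return comp


def origin_range(composite: TransitionReport, tree: Phylogeny,
                 priors: list[TipPriorMatrix] | TipPriorMatrix,
                 family_map: dict[str, str],
                 mass_cutoff: float = 1e-9,
                 fossil_additions: int = 0) -> tuple[int, int]:
    """(min, max) convergent origins of non-marine life.

    ``min`` is the composite node-shift count.  Each family whose tips carry
    at least ``mass_cutoff`` total prior mass at non-marine grades, but with
    no non-marine ancestor on the path to the root, adds one possible
    origin; user-supplied fossil transitions outside the tree add the rest.
    The default cutoff counts any nonzero prior mass.
    """
    if not 0 < mass_cutoff <= 1:
        raise ValueError("mass_cutoff must lie in (0, 1]")
    if isinstance(priors, TipPriorMatrix):
        priors = [priors]

    shift_children = {e for e, *_ in composite.node_shifts}

    # ancestors at-or-below which a non-marine shift was reconstructed
    nonmarine_anc = np.zeros(tree.n_nodes, dtype=bool)
    for e in shift_children:
        stack = [e]
        while stack:
            u = stack.pop()
            if nonmarine_anc[u]:
                continue
            nonmarine_anc[u] = True
            if u >= tree.n_tips:
                stack.extend(tree.children(u))

    qualifying: set[str] = set()
    for t in range(tree.n_tips):
        lbl = tree.labels[t]
        mass = 0.0
        for pm in priors:
            row = pm.table.loc[lbl] if lbl in pm.table.index else None
            if row is not None:
                mass = max(mass, float(row.iloc[1:].sum()))
        if mass < mass_cutoff:
            continue
        if nonmarine_anc[t]:
            continue  # already inside a reconstructed origin
        fam = family_map.get(lbl)
        if fam is None:
            raise ValueError(f"tip {lbl!r} missing from family map")
        qualifying.add(fam)

    composite.tip_only_families = sorted(qualifying)
    composite.fossil_additions = int(fossil_additions)
    composite.min_origins = len(composite.node_shifts)
    composite.max_origins = (composite.min_origins + len(qualifying)
                             + int(fossil_additions))
    return composite.min_origins, composite.max_origins


def annotated_newick(tree: Phylogeny, report: TransitionReport) -> str:
    """Newick with per-edge shift/reversal flags for tree viewers."""
    shifts = {e for e, *_ in report.node_shifts} | {e for e, *_ in report.tip_shifts}
    revs = {e for e, *_ in report.reversals}

    def rec(v: int) -> str:
        if tree.is_tip(v):
            s = tree.labels[v]
        else:
            s = "(" + ",".join(rec(c) for c in tree.children(v)) + ")"
        if v in shifts:
            s += "[&shift=1]"
        elif v in revs:
            s += "[&reversal=1]"
        if v != tree.root:
            s += f":{tree.brlen[v]:.12g}"
        return s

    return rec(tree.root) + ";"
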