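"""Chronogram sensitivity analysis: between-group PCA of node ages.

Posterior chronogram samples sharing one topology (e.g. runs differing by
fossil-calibration strategy or clock model) are aligned clade-by-clade to a
reference tree, giving a samples x internal-nodes matrix of ages.  A
between-group PCA (bgPCA) then finds the age-space axes separating the
methodological groups: eigenvectors of the covariance of the group mean age
vectors, onto which all samples are projected (at most g-1 non-trivial
axes for g groups).  "Extreme" chronograms at +/-1 SD along an axis make
the separation interpretable as actual trees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tree_io import Phylogeny, node_ages

log = logging.getLogger(__name__)

__all__ = [
    "align_ages",
    "bgpca",
    "axis_extreme_tree",
    "BgPcaResult",
    "drop_tips",
]


class TopologyMismatch(ValueError):
    pass


def drop_tips(tree: Phylogeny, drop: list[str]) -> Phylogeny:
    """Remove tips (e.g. outgroups) and suppress resulting unifurcations."""
    from . import tree_io
    import dendropy

    dt = dendropy.Tree.get(data=tree_io.write_newick(tree), schema="newick",
                           preserve_underscores=True)
    taxa = [t for t in dt.taxon_namespace if t.label in set(drop)]
    if taxa:
        dt.prune_taxa(taxa)
    return tree_io._from_dendropy(dt)


def align_ages(samples: list[Phylogeny], reference: Phylogeny,
               tolerance: float = 1e-4) -> pd.DataFrame:
    """Rows = samples, columns = reference internal nodes, entries = ages.

    Every sample must be topologically identical to the reference (same tip
    set, same clades); children order may differ.
    """
    ref_bip = reference.bipartitions()
    ref_tips = frozenset(reference.tip_labels)
    internal = list(range(reference.n_tips, reference.n_nodes))
    cols = [f"node{v}" for v in internal]
    rows = np.empty((len(samples), len(internal)))
    for s, tree in enumerate(samples):
        if frozenset(tree.tip_labels) != ref_tips:
            missing = ref_tips - frozenset(tree.tip_labels)
            extra = frozenset(tree.tip_labels) - ref_tips
            raise TopologyMismatch(
                f"sample {s}: tip set differs (missing={sorted(missing)[:3]}, "
                f"extra={sorted(extra)[:3]})")
        ages = node_ages(tree, tolerance=tolerance).ages
        got = tree.bipartitions()
        for clade, v in got.items():
            if clade not in ref_bip:
                raise TopologyMismatch(
                    f"sample {s}: clade {sorted(clade)[:4]}... not in reference")
        row = np.full(len(internal), np.nan)
        for j, v in enumerate(internal):
            clade = reference.clade_tips(v)
            if clade not in got:
                raise TopologyMismatch(
                    f"sample {s}: reference clade {sorted(clade)[:4]}... absent")
            row[j] = ages[got[clade]]
        rows[s] = row
    return pd.DataFrame(rows, columns=cols)


@dataclass
class BgPcaResult:
    loadings: pd.DataFrame      # axes x nodes (orthonormal rows)
    projections: pd.DataFrame   # samples x axes, plus group column
    group_means: pd.DataFrame   # groups x axes (projected)
    var_explained: np.ndarray   # fraction of between-group variance per axis
    grand_mean: np.ndarray
    axis_sd: np.ndarray         # SD of sample projections per axis
    standardized: bool
    scale: np.ndarray


def bgpca(matrix: pd.DataFrame, groups, standardize: bool = False) -> BgPcaResult:
    """Between-group PCA of the age matrix.

    Axes are the eigenvectors of the (unweighted) covariance of group mean
    age vectors; all samples are projected after centering on the grand
    mean of group means.  ``standardize`` optionally z-scales each node's
    ages first (default off: raw ages, in Myr).
    """
    groups = pd.Series(list(groups), name="group")
    if len(groups) != len(matrix):
        raise ValueError("one group label per sample required")
    counts = groups.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least 2 groups")
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"groups with fewer than 2 samples: {bad}")

    X = matrix.to_numpy(dtype=float)
    scale = np.ones(X.shape[1])
    if standardize:
        scale = X.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        X = X / scale

    names = sorted(counts.index)
    M = np.vstack([X[groups.to_numpy() == g_].mean(axis=0) for g_ in names])
    mu = M.mean(axis=0)
    Mc = M - mu
    # eigen-decomposition of the between-group covariance via SVD
    U, sv, Vt = np.linalg.svd(Mc, full_matrices=False)
    g = len(names)
    n_axes = min(g - 1, Mc.shape[1])
    ev = sv ** 2 / max(g - 1, 1)
    keep = [i for i in range(n_axes) if sv[i] > 1e-12 * (sv[0] if sv[0] > 0 else 1)]
    if not keep:
        log.info("bgpca: zero between-group variance; no axes")
        loadings = np.zeros((0, Mc.shape[1]))
        ev = np.zeros(0)
    else:
        loadings = Vt[keep]
        ev = ev[keep]
    proj = (X - mu) @ loadings.T
    axes = [f"bgPC{i + 1}" for i in range(loadings.shape[0])]
    load_df = pd.DataFrame(loadings, index=axes, columns=matrix.columns)
    proj_df = pd.DataFrame(proj, columns=axes, index=matrix.index)
    proj_df["group"] = groups.to_numpy()
    gm = pd.DataFrame(Mc @ loadings.T, index=names, columns=axes)
    var_exp = ev / ev.sum() if ev.size else ev
    axis_sd = proj.std(axis=0, ddof=1) if proj.shape[0] > 1 else np.zeros(len(axes))
    return BgPcaResult(load_df, proj_df, gm, var_exp, mu, axis_sd,
                       standardize, scale)


def axis_extreme_tree(result: BgPcaResult, reference: Phylogeny,
                      axis: int = 0, sd_multiplier: float = 1.0,
                      strict: bool = False):
    """Chronogram at ``mean + sd_multiplier * SD`` along one bgPCA axis.

    Returns ``(ages, tree, n_clipped)``: the displaced internal-node age
    vector, a Phylogeny with branch lengths rebuilt from those ages, and the
    number of nodes clipped to keep every parent at least as old as its
    children.  Clipping more than 10% of nodes logs a warning (or raises
    under ``strict``).
    """
    if result.loadings.shape[0] <= axis:
        raise ValueError(f"axis {axis} not available")
    load = result.loadings.to_numpy()[axis]
    sd = float(result.axis_sd[axis])
    ages = (result.grand_mean + sd_multiplier * sd * load) * result.scale

    n_int = reference.n_nodes - reference.n_tips
    full = np.zeros(reference.n_nodes)
    full[reference.n_tips:] = ages
    # enforce parent >= child >= 0 (tips sit at age 0), root downward
    n_clipped = 0
    if full[reference.root] < 0:
        full[reference.root] = 0.0
        n_clipped += 1
    for v in range(reference.n_nodes - 2, reference.n_tips - 1, -1):
        pa = full[reference.parent[v]]
        clipped = min(max(full[v], 0.0), pa)
        if clipped != full[v]:
            full[v] = clipped
            n_clipped += 1
    if n_clipped > 0.1 * n_int:
        msg = f"axis_extreme_tree: clipped {n_clipped}/{n_int} node ages"
        if strict:
            raise ValueError(msg)
        log.warning(msg)

    brlen = np.zeros(reference.n_nodes)
    for v in range(reference.n_nodes - 1):
        brlen[v] = full[reference.parent[v]] - full[v]
    tree = Phylogeny(reference.labels, reference.parent.copy(), brlen,
                     reference.n_tips)
    return full[reference.n_tips:], tree, n_clipped
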