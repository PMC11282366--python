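"""Rooted time-calibrated trees: reading, validation, indexing, ages, MRCA.

The in-memory representation is a flat, array-backed :class:`Phylogeny` with a
fixed node indexing convention used by every downstream matrix in the package:

* nodes ``0 .. n_tips-1`` are the tips, sorted by label;
* nodes ``n_tips .. n_nodes-1`` are internal nodes in postorder;
* the root is always the last node.

With this convention, iterating node indices in increasing order is itself a
valid postorder traversal (every child index is smaller than its parent's),
and iterating in decreasing order is a valid preorder.

Parsing and serialisation of Newick and NEXUS (including translate tables and
multi-tree TREES blocks for posterior samples) are delegated to dendropy;
validation and indexing are done here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "Phylogeny",
    "NodeAges",
    "TreeError",
    "ParseError",
    "ValidationError",
    "read_tree",
    "read_trees",
    "write_newick",
    "node_ages",
    "mrca",
]


class TreeError(Exception):
    """Base class for tree I/O and validation problems."""


class ParseError(TreeError):
    """Malformed Newick/NEXUS input."""


class ValidationError(TreeError):
    """Structurally parseable input violating a Phylogeny invariant."""


@dataclass(frozen=True)
class Phylogeny:
    """Rooted tree with branch lengths in Myr, array-indexed.

    Parameters
    ----------
    labels
        One label per node.  Tip labels are unique and non-empty; internal
        labels may be empty strings.
    parent
        Parent index per node; ``-1`` for the root.
    brlen
        Duration of the edge above each node (0.0 for the root).
    n_tips
        Number of tips; tips occupy indices ``0 .. n_tips-1``.
    """

    labels: tuple[str, ...]
    parent: np.ndarray
    brlen: np.ndarray
    n_tips: int
    _children: list[list[int]] = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        parent = np.asarray(self.parent, dtype=np.int64)
        brlen = np.asarray(self.brlen, dtype=np.float64)
        object.__setattr__(self, "parent", parent)
        object.__setattr__(self, "brlen", brlen)
        n = len(self.labels)
        if self.n_tips < 2:
            raise ValidationError("a phylogeny needs at least 2 tips")
        if parent.shape != (n,) or brlen.shape != (n,):
            raise ValidationError("labels/parent/brlen length mismatch")
        tips = list(self.labels[: self.n_tips])
        if any(not t for t in tips):
            raise ValidationError("empty tip label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise ValidationError(f"duplicate tip labels: {dup}")
        if tips != sorted(tips):
            raise ValidationError("tips must be label-sorted (indexing convention)")
        roots = np.flatnonzero(parent < 0)
        if roots.size != 1 or roots[0] != n - 1:
            raise ValidationError("exactly one root required, at the last index")
        if np.any(parent[:-1] <= np.arange(n - 1)):
            raise ValidationError("parent index must exceed child index (postorder)")
        if np.any(brlen < 0):
            raise ValidationError("negative branch length")
        kids: list[list[int]] = [[] for _ in range(n)]
        for v in range(n - 1):
            kids[parent[v]].append(v)
        for v in range(self.n_tips, n):
            if not kids[v]:
                raise ValidationError(f"internal node {v} has no children")
        object.__setattr__(self, "_children", kids)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return self.labels[: self.n_tips]

    def children(self, v: int) -> list[int]:
        return self._children[v]

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def tip_index(self, label: str) -> int:
        try:
            return self._tip_lookup[label]
        except AttributeError:
            lookup = {t: i for i, t in enumerate(self.tip_labels)}
            object.__setattr__(self, "_tip_lookup", lookup)
            return self._tip_lookup[label]

    def depths(self) -> np.ndarray:
        """Time from the root to each node (sum of branch lengths)."""
        d = np.zeros(self.n_nodes)
        for v in range(self.n_nodes - 2, -1, -1):
            d[v] = d[self.parent[v]] + self.brlen[v]
        return d

    def clade_tips(self, v: int) -> frozenset[str]:
        """Labels of tips descending from (or equal to) node v."""
        if v < self.n_tips:
            return frozenset((self.labels[v],))
        out: list[str] = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(self.labels[u])
            else:
                stack.extend(self._children[u])
        return frozenset(out)

    def bipartitions(self) -> dict[frozenset[str], int]:
        """Map from each internal node's tip set to its node index."""
        sets: list[frozenset[str]] = [frozenset((t,)) for t in self.tip_labels]
        out: dict[frozenset[str], int] = {}
        for v in range(self.n_tips, self.n_nodes):
            s = frozenset().union(*(sets[c] for c in self._children[v]))
            sets.append(s)
            out[s] = v
        return out


@dataclass(frozen=True)
class NodeAges:
    """Ages (Myr before present) per node, plus an ultrametricity flag."""

    ages: np.ndarray
    height: float
    ultrametric: bool
    tip_depth_spread: float


def _normalize_label(raw: str) -> str:
    """Documented normalisation: strip quotes/outer whitespace, keep underscores."""
    s = raw.strip()
    if len(s) >= 2 and s[0] == s[-1] == "'":
        s = s[1:-1]
    return s


def _from_dendropy(dtree: dendropy.Tree) -> Phylogeny:
    dtree = dtree.clone(depth=1)
    # suppress "knuckles" (unifurcations) but retain polytomies
    dtree.suppress_unifurcations()
    leaves = [lf for lf in dtree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValidationError("a phylogeny needs at least 2 tips")
    tip_labels = []
    for lf in leaves:
        if lf.taxon is None or not lf.taxon.label:
            raise ValidationError("tip without a label")
        tip_labels.append(_normalize_label(lf.taxon.label))
    if len(set(tip_labels)) != len(tip_labels):
        dup = sorted({t for t in tip_labels if tip_labels.count(t) > 1})
        raise ValidationError(f"duplicate tip labels: {dup}")
    order = sorted(range(len(leaves)), key=lambda i: tip_labels[i])
    index: dict[int, int] = {}
    labels: list[str] = []
    for rank, i in enumerate(order):
        index[id(leaves[i])] = rank
        labels.append(tip_labels[i])
    n_tips = len(labels)
    internals = [nd for nd in dtree.postorder_node_iter() if not nd.is_leaf()]
    for k, nd in enumerate(internals):
        index[id(nd)] = n_tips + k
        labels.append(_normalize_label(nd.label) if nd.label else "")
    n = len(labels)
    parent = np.full(n, -1, dtype=np.int64)
    brlen = np.zeros(n)
    for nd in dtree.preorder_node_iter():
        v = index[id(nd)]
        if nd.parent_node is not None:
            parent[v] = index[id(nd.parent_node)]
            el = nd.edge.length
            if el is None:
                el = 0.0
            if el < 0:
                raise ValidationError(
                    f"negative branch length {el} above node {labels[v] or v}"
                )
            brlen[v] = float(el)
    return Phylogeny(tuple(labels), parent, brlen, n_tips)


def read_trees(path: str, format: str = "newick") -> list[Phylogeny]:
    """Read one or more trees (e.g. a posterior sample) from a file.

    NEXUS translate tables are resolved by dendropy; underscores in unquoted
    labels are preserved verbatim.
    """
    fmt = format.lower()
    if fmt not in ("newick", "nexus"):
        raise ValueError(f"unknown tree format: {format!r}")
    try:
        tl = dendropy.TreeList.get(
            path=path, schema=fmt, preserve_underscores=True
        )
    except (dendropy.utility.error.DataParseError) as e:
        msg = str(e)
        if "Duplicate taxon labels" in msg or "Multiple occurrences" in msg:
            raise ValidationError(f"duplicate tip labels in {path}") from e
        raise ParseError(f"{path}: {e}") from e
    except FileNotFoundError:
        raise
    if len(tl) == 0:
        raise ParseError(f"{path}: no trees found")
    return [_from_dendropy(t) for t in tl]


def read_tree(path: str, format: str = "newick") -> Phylogeny:
    """Read a single rooted tree; errors if the file holds none."""
    return read_trees(path, format=format)[0]


def _quote(label: str) -> str:
    specials = set("()[]{}/\\,;:=*'\"`<>^ \t\n")
    if any(ch in specials for ch in label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    """Serialise to plain Newick (branch lengths, quoted labels as needed)."""

    def rec(v: int) -> str:
        if tree.is_tip(v):
            s = _quote(tree.labels[v])
        else:
            s = "(" + ",".join(rec(c) for c in tree.children(v)) + ")"
            if tree.labels[v]:
                s += _quote(tree.labels[v])
        if v != tree.root:
            s += f":{tree.brlen[v]:.12g}"
        return s

    out = rec(tree.root) + ";"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(out + "\n")
    return out


def node_ages(tree: Phylogeny, tolerance: float = 1e-4) -> NodeAges:
    """Node ages (Myr before present) from tip depths.

    Ages are ``height - depth`` where ``height`` is the maximum tip depth.
    Trees whose tip-depth spread exceeds ``tolerance * height`` are flagged
    non-ultrametric (MCMC chronogram summaries are near- but rarely exactly
    ultrametric).
    """
    d = tree.depths()
    tip_d = d[: tree.n_tips]
    height = float(tip_d.max())
    if height <= 0:
        raise ValidationError("tree has zero height")
    spread = float(tip_d.max() - tip_d.min())
    ages = height - d
    return NodeAges(ages, height, spread <= tolerance * height, spread)


def mrca(tree: Phylogeny, tip_set) -> int:
    """Most recent common ancestor of a non-empty set of tip labels."""
    tips = list(tip_set)
    if not tips:
        raise ValueError("tip_set must be non-empty")
    try:
        nodes = [tree.tip_index(t) for t in tips]
    except KeyError as e:
        raise KeyError(f"unknown tip label: {e.args[0]!r}") from None
    d = tree.depths()
    cur = nodes[0]
    for v in nodes[1:]:
        a, b = cur, v
        while a != b:
            if d[a] >= d[b]:
                a = tree.parent[a]
            else:
                b = tree.parent[b]
        cur = a
    return int(cur)
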