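"""Rooted phylogenetic trees with branch lengths in Myr.

The tree model is deliberately small: integer node ids, parent links,
branch lengths, and tip labels.  Ages run backward from the tips
(present = 0), so the root of an ultrametric tree sits at the crown age.
Plain newick parsing is delegated to dendropy; the simmap dialect
(curly-brace regime annotations on branches, as written by stochastic
character mapping) is parsed here because no installed reader speaks it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "RegimePaintedTree",
    "TreeError",
    "read_newick",
    "write_newick",
    "read_simmap",
    "write_simmap",
    "vcv_matrix",
    "branching_times",
]

#: relative tolerance (x tree height) for declaring a tree ultrametric
ULTRAMETRIC_RTOL = 1e-8


class TreeError(ValueError):
    """Malformed tree or tree/data mismatch."""


@dataclass
class PhyloTree:
    """Rooted tree: ``parent[i]`` is the parent id (-1 at the root),
    ``lengths[i]`` the length of the branch above node ``i`` (0 at the
    root), ``labels[i]`` the tip name (None on internal nodes)."""

    parent: np.ndarray
    lengths: np.ndarray
    labels: list
    root: int

    _children: list = field(default=None, repr=False, compare=False)
    _depths: np.ndarray = field(default=None, repr=False, compare=False)
    _postorder: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int64)
        self.lengths = np.asarray(self.lengths, dtype=float)
        n = self.parent.size
        if self.lengths.size != n or len(self.labels) != n:
            raise TreeError("parent/lengths/labels size mismatch")
        if np.any(self.lengths < 0):
            raise TreeError("negative branch length")
        roots = np.nonzero(self.parent < 0)[0]
        if roots.size != 1 or roots[0] != self.root:
            raise TreeError("tree must have exactly one root")
        tips = [self.labels[i] for i in self.tip_ids]
        if any(t is None for t in tips):
            raise TreeError("every tip must carry a label")
        if len(set(tips)) != len(tips):
            dup = sorted({t for t in tips if tips.count(t) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")

    # -- structure ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def children(self) -> list:
        if self._children is None:
            ch = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._children = ch
        return self._children

    @property
    def tip_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if not c],
                        dtype=np.int64)

    @property
    def internal_ids(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.children) if c],
                        dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return self.tip_ids.size

    @property
    def tip_labels(self) -> list:
        return [self.labels[i] for i in self.tip_ids]

    def tip_index(self) -> dict:
        """Map tip label -> node id."""
        return {self.labels[i]: int(i) for i in self.tip_ids}

    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def postorder(self) -> np.ndarray:
        """Node ids, children always before parents (iterative DFS)."""
        if self._postorder is None:
            order = []
            stack = [(self.root, False)]
            while stack:
                v, expanded = stack.pop()
                if expanded:
                    order.append(v)
                else:
                    stack.append((v, True))
                    for c in self.children[v]:
                        stack.append((c, False))
            self._postorder = np.array(order, dtype=np.int64)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    # -- metrics -----------------------------------------------------------

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for v in self.preorder():
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.lengths[v]
            self._depths = d
        return self._depths

    @property
    def height(self) -> float:
        """Maximum root-to-tip depth (the crown age for an ultrametric tree)."""
        return float(self.depths()[self.tip_ids].max())

    def ages(self) -> np.ndarray:
        """Node ages backward from the present (= height - depth)."""
        return self.height - self.depths()

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.depths()[self.tip_ids]
        h = d.max()
        if h == 0:
            return True
        return bool((h - d.min()) <= rtol * h)

    @property
    def total_branch_length(self) -> float:
        return float(self.lengths.sum() - self.lengths[self.root])

    def mrca_matrix(self) -> np.ndarray:
        """(n_tips, n_tips) node ids of pairwise MRCAs, tip order = tip_ids."""
        tips = self.tip_ids
        pos = {int(t): k for k, t in enumerate(tips)}
        n = tips.size
        M = np.empty((n, n), dtype=np.int64)
        below = {}
        for v in self.postorder():
            kids = self.children[v]
            if not kids:
                below[v] = [pos[v]]
                M[pos[v], pos[v]] = v
            else:
                sets = [below.pop(c) for c in kids]
                for a in range(len(sets)):
                    for b in range(a + 1, len(sets)):
                        ia = np.array(sets[a])[:, None]
                        ib = np.array(sets[b])[None, :]
                        M[ia, ib] = v
                        M[ib.T, ia.T] = v
                merged = [i for s in sets for i in s]
                below[v] = merged
        return M

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.parent.copy(), self.lengths.copy(),
                         list(self.labels), self.root)


@dataclass
class RegimePaintedTree:
    """A tree whose branches carry ordered (regime, duration) segments,
    listed root-to-tip; durations on a branch sum to its length."""

    tree: PhyloTree
    #: per node id: list of (regime, duration) for the branch above it
    paintings: list
    regimes: tuple = None

    def __post_init__(self):
        t = self.tree
        labels = set()
        for v in range(t.n_nodes):
            if v == t.root:
                continue
            segs = self.paintings[v]
            tot = sum(d for _, d in segs)
            blen = t.lengths[v]
            if abs(tot - blen) > 1e-8 * max(1.0, blen):
                raise TreeError(
                    f"segments on branch above node {v} sum to {tot}, "
                    f"branch length is {blen}")
            for r, d in segs:
                if d < 0:
                    raise TreeError("negative segment duration")
                if d == 0 and blen > 0 and len(segs) > 1:
                    raise TreeError("zero-length segment on nonzero branch")
                labels.add(r)
            for (r1, _), (r2, _) in zip(segs, segs[1:]):
                if r1 == r2:
                    raise TreeError("adjacent segments share a regime")
        if self.regimes is None:
            self.regimes = tuple(sorted(labels, key=str))
        else:
            unknown = labels - set(self.regimes)
            if unknown:
                raise TreeError(f"unknown regime labels: {sorted(unknown, key=str)}")

    def tip_regimes(self) -> dict:
        """Regime at each tip (tipward end of the tip branch)."""
        t = self.tree
        out = {}
        for i in t.tip_ids:
            if i == t.root:
                continue
            out[t.labels[i]] = self.paintings[i][-1][0]
        return out

    def root_regime(self):
        t = self.tree
        # regime at the rootward end of any root-child branch
        for c in t.children[t.root]:
            return self.paintings[c][0][0]
        raise TreeError("root has no children")


# ---------------------------------------------------------------------------
# newick I/O (plain: dendropy; simmap: local parser)
# ---------------------------------------------------------------------------

def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    lengths = np.zeros(len(nodes))
    labels = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            parent[i] = idx[id(nd.parent_node)]
            lengths[i] = nd.edge.length if nd.edge.length is not None else 0.0
        if nd.is_leaf():
            labels[i] = (nd.taxon.label if nd.taxon is not None
                         else nd.label)
    return PhyloTree(parent, lengths, labels, 0)


def read_newick(text: str) -> PhyloTree:
    """Parse a newick string (branch lengths required, polytomies kept)."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeError(f"newick parse error: {exc}") from exc
    return _from_dendropy(dtree)


def write_newick(tree: PhyloTree, precision: int = 12) -> str:
    def rec(v: int) -> str:
        kids = tree.children[v]
        if kids:
            s = "(" + ",".join(rec(c) for c in kids) + ")"
        else:
            s = tree.labels[v]
        if v != tree.root:
            s += f":{tree.lengths[v]:.{precision}g}"
        return s

    return rec(tree.root) + ";"


class _SimmapParser:
    """Recursive-descent parser for phytools-style simmap newick, where a
    branch length is replaced by ``{regime,dur:regime,dur:...}`` with the
    segments running root-to-tip."""

    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0
        self.parent = []
        self.lengths = []
        self.labels = []
        self.paintings = []

    def error(self, msg: str):
        raise TreeError(f"simmap parse error at char {self.pos}: {msg}")

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def new_node(self, parent: int):
        self.parent.append(parent)
        self.lengths.append(0.0)
        self.labels.append(None)
        self.paintings.append(None)
        return len(self.parent) - 1

    def parse(self):
        root = self.parse_clade(-1)
        if self.peek() == ";":
            self.pos += 1
        tree = PhyloTree(np.array(self.parent), np.array(self.lengths),
                         self.labels, root)
        return tree, self.paintings

    def parse_clade(self, parent: int) -> int:
        v = self.new_node(parent)
        if self.peek() == "(":
            self.pos += 1
            while True:
                self.parse_clade(v)
                if self.peek() == ",":
                    self.pos += 1
                    continue
                if self.peek() == ")":
                    self.pos += 1
                    break
                self.error("expected ',' or ')'")
        label = self.parse_label()
        if label:
            self.labels[v] = label
        if self.peek() == ":":
            self.pos += 1
            if self.peek() == "{":
                segs = self.parse_segments()
            else:
                self.error("expected '{' after ':' in simmap text")
            self.paintings[v] = segs
            self.lengths[v] = sum(d for _, d in segs)
        return v

    def parse_label(self) -> str:
        start = self.pos
        while self.peek() and self.peek() not in ":,(){};":
            self.pos += 1
        return self.text[start:self.pos].strip()

    def parse_segments(self):
        assert self.peek() == "{"
        self.pos += 1
        end = self.text.find("}", self.pos)
        if end < 0:
            self.error("unterminated '{'")
        body = self.text[self.pos:end]
        self.pos = end + 1
        segs = []
        for part in body.split(":"):
            bits = part.split(",")
            if len(bits) != 2:
                self.error(f"bad segment '{part}'")
            segs.append((bits[0].strip(), float(bits[1])))
        return segs


def read_simmap(text: str, regimes=None) -> RegimePaintedTree:
    """Parse simmap-annotated newick into a :class:`RegimePaintedTree`.

    Segment durations on each branch must sum to the branch length (they
    define it); adjacent equal-regime segments are merged.
    """
    tree, paintings = _SimmapParser(text).parse()
    cleaned = [None] * tree.n_nodes
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        segs = paintings[v]
        if segs is None:
            raise TreeError(f"branch above node {v} lacks a segment map")
        cleaned[v] = _merge_segments(segs)
    return RegimePaintedTree(tree, cleaned, regimes=tuple(regimes) if regimes else None)


def _merge_segments(segs):
    nz = [(r, d) for r, d in segs if d > 0]
    if not nz:  # zero-length branch keeps one zero segment
        return [segs[0]]
    out = [nz[0]]
    for r, d in nz[1:]:
        if out[-1][0] == r:
            out[-1] = (r, out[-1][1] + d)
        else:
            out.append((r, d))
    return out


def write_simmap(painted: RegimePaintedTree, precision: int = 12) -> str:
    tree = painted.tree

    def seg_str(v: int) -> str:
        segs = painted.paintings[v]
        return "{" + ":".join(f"{r},{d:.{precision}g}" for r, d in segs) + "}"

    def rec(v: int) -> str:
        kids = tree.children[v]
        s = ("(" + ",".join(rec(c) for c in kids) + ")") if kids else tree.labels[v]
        if v != tree.root:
            s += ":" + seg_str(v)
        return s

    return rec(tree.root) + ";"


# ---------------------------------------------------------------------------
# shared phylogenetic quantities
# ---------------------------------------------------------------------------

def vcv_matrix(tree: PhyloTree) -> np.ndarray:
    """Phylogenetic covariance: entry (i, j) is the root-to-MRCA path
    length shared by tips i and j (tip order = ``tree.tip_ids``)."""
    depths = tree.depths()
    M = tree.mrca_matrix()
    return depths[M]


def branching_times(tree: PhyloTree, rtol: float = ULTRAMETRIC_RTOL) -> np.ndarray:
    """Ages of internal nodes, descending; requires an ultrametric tree.

    The maximum is the crown age.
    """
    if not tree.is_ultrametric(rtol):
        raise TreeError("branching_times requires an ultrametric tree")
    ages = tree.ages()[tree.internal_ids]
    return np.sort(ages)[::-1]
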