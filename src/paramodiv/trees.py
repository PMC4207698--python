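"""Rooted phylogenies, tree samples and specimen tables.

Trees are stored as flat arrays (parent pointers, per-node subtending edge
lengths, postorder) so the likelihood engines can traverse them cheaply.
Parsing and format handling (Newick, NEXUS with translate tables) is
delegated to :mod:`dendropy`.

Time is measured in the units of the input branch lengths (Ma for dated
chronograms). Tips occupy node indices ``0 .. n_tips-1``; internal nodes
follow; the root is the last node in postorder.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "TreeSample",
    "SamplingFractions",
    "read_tree_sample",
    "read_specimen_table",
    "validate_specimen_table",
    "species_tip_map",
    "sample_exemplars",
    "phylo_covariance",
    "check_ultrametric",
    "SPECIMEN_COLUMNS",
    "MICROHABITATS",
]


class _N:
    """Mutable node used while building/pruning trees."""

    __slots__ = ("children", "length", "label")

    def __init__(self, length=0.0, label=None):
        self.children: list[_N] = []
        self.length = float(length)
        self.label = label


class Phylogeny:
    """A rooted tree with nonnegative branch lengths and unique tip labels.

    Attributes
    ----------
    tip_labels : list of str
        Labels of tips, in node-index order (tips are nodes ``0..n_tips-1``).
    parent : ndarray of int
        Parent node index per node; the root has parent ``-1``.
    edge_length : ndarray of float
        Length of the edge subtending each node; ``0.0`` at the root.
    children : list of ndarray
        Child node indices per node (empty for tips).
    postorder : ndarray of int
        Node indices in postorder (children before parents; root last).
    """

    def __init__(self, tip_labels, parent, edge_length, children):
        self.tip_labels = list(tip_labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.children = [np.asarray(c, dtype=np.int64) for c in children]
        self._validate()
        self.postorder = self._postorder()

    # -- construction -------------------------------------------------

    @classmethod
    def _from_build(cls, root: _N) -> "Phylogeny":
        tips: list[_N] = []
        internals: list[_N] = []

        def collect(n):
            if n.children:
                for c in n.children:
                    collect(c)
                internals.append(n)
            else:
                tips.append(n)

        collect(root)
        order = tips + internals
        index = {id(n): i for i, n in enumerate(order)}
        n_nodes = len(order)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        elen = np.zeros(n_nodes)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for n in order:
            i = index[id(n)]
            elen[i] = n.length
            for c in n.children:
                j = index[id(c)]
                parent[j] = i
                children[i].append(j)
        elen[index[id(root)]] = 0.0
        return cls([t.label for t in tips], parent, elen, children)

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "Phylogeny":
        def conv(nd) -> _N:
            n = _N(nd.edge.length or 0.0)
            if nd.is_leaf():
                n.label = (nd.taxon.label if nd.taxon else nd.label or "").strip()
            else:
                n.children = [conv(c) for c in nd.child_nodes()]
            return n

        return cls._from_build(conv(tree.seed_node))

    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True)
        return cls.from_dendropy(tree)

    def _validate(self):
        if len(set(self.tip_labels)) != len(self.tip_labels):
            raise ValueError("tip labels are not unique")
        if np.any(self.edge_length < 0):
            raise ValueError("negative edge length")
        roots = np.flatnonzero(self.parent == -1)
        if roots.size != 1:
            raise ValueError(f"tree must have exactly one root, found {roots.size}")

    def _postorder(self) -> np.ndarray:
        order = []
        stack = [int(np.flatnonzero(self.parent == -1)[0])]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(int(c) for c in self.children[n])
        return np.array(order[::-1], dtype=np.int64)

    # -- basic properties ----------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return int(self.postorder[-1])

    @property
    def is_binary(self) -> bool:
        return all(len(c) in (0, 2) for c in self.children)

    def tip_index(self, label: str) -> int:
        return self.tip_labels.index(label)

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        depth = np.zeros(self.n_nodes)
        for n in self.postorder[::-1]:
            if self.parent[n] >= 0:
                depth[n] = depth[self.parent[n]] + self.edge_length[n]
        return depth

    @property
    def height(self) -> float:
        return float(self.node_depths()[: self.n_tips].max())

    @property
    def total_length(self) -> float:
        return float(self.edge_length.sum())

    # -- algebra -------------------------------------------------------

    def vcv(self) -> np.ndarray:
        """Brownian-motion covariance: shared root-to-MRCA path lengths."""
        depth = self.node_depths()
        ntip = self.n_tips
        C = np.zeros((ntip, ntip))
        tipsets: dict[int, np.ndarray] = {}
        for n in self.postorder:
            if len(self.children[n]) == 0:
                tipsets[n] = np.array([n])
                C[n, n] = depth[n]
            else:
                kids = [tipsets[int(c)] for c in self.children[n]]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        C[np.ix_(kids[a], kids[b])] = depth[n]
                        C[np.ix_(kids[b], kids[a])] = depth[n]
                tipsets[n] = np.concatenate(kids)
        return C

    def resolve_polytomies(self) -> "Phylogeny":
        """Return a binary tree; multifurcations become zero-length splits.

        Children are combined deterministically in alphabetical order of the
        lexicographically smallest tip label below each child.
        """
        if self.is_binary:
            return self
        mins: dict[int, str] = {}
        for n in self.postorder:
            if len(self.children[n]) == 0:
                mins[n] = self.tip_labels[n]
            else:
                mins[n] = min(mins[int(c)] for c in self.children[n])

        def conv(n: int) -> _N:
            node = _N(self.edge_length[n], self.tip_labels[n] if n < self.n_tips else None)
            kids = sorted((int(c) for c in self.children[n]), key=lambda c: mins[c])
            built = [conv(c) for c in kids]
            while len(built) > 2:
                joint = _N(0.0)
                joint.children = built[:2]
                built = [joint] + built[2:]
            node.children = built
            return node

        return Phylogeny._from_build(conv(self.root))

    def retain_tips(self, labels: Iterable[str]) -> "Phylogeny":
        """Prune to the given tips, suppressing degree-2 nodes by summing
        their incident edge lengths. Root-to-tip depths of retained tips are
        conserved whenever at least two of the root's subtrees retain tips."""
        keep_labels = set(labels)
        missing = keep_labels - set(self.tip_labels)
        if missing:
            raise ValueError(f"tips not in tree: {sorted(missing)}")
        if len(keep_labels) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        keep = np.zeros(self.n_nodes, dtype=bool)
        for n in self.postorder:
            if len(self.children[n]) == 0:
                keep[n] = self.tip_labels[n] in keep_labels
            else:
                keep[n] = any(keep[int(c)] for c in self.children[n])

        def build(n: int, extra: float) -> _N:
            kept_kids = [int(c) for c in self.children[n] if keep[int(c)]]
            if not kept_kids:  # tip
                return _N(self.edge_length[n] + extra, self.tip_labels[n])
            if len(kept_kids) == 1:
                return build(kept_kids[0], extra + self.edge_length[n])
            node = _N(self.edge_length[n] + extra)
            node.children = [build(c, 0.0) for c in kept_kids]
            return node

        # descend past any unary chain at the root (stem is dropped)
        r = self.root
        while sum(keep[int(c)] for c in self.children[r]) == 1:
            r = next(int(c) for c in self.children[r] if keep[int(c)])
        root = _N(0.0)
        root.children = [build(int(c), 0.0) for c in self.children[r] if keep[int(c)]]
        if not root.children:  # r is itself a tip
            raise ValueError("cannot prune to fewer than 2 tips")
        return Phylogeny._from_build(root)

    # -- I/O -----------------------------------------------------------

    def to_newick(self) -> str:
        def wr(n: int) -> str:
            if len(self.children[n]) == 0:
                return f"{self.tip_labels[n]}:{float(self.edge_length[n])!r}"
            inner = ",".join(wr(int(c)) for c in self.children[n])
            if n == self.root:
                return f"({inner})"
            return f"({inner}):{float(self.edge_length[n])!r}"

        return wr(self.root) + ";"

    def to_dendropy(self, taxon_namespace=None) -> dendropy.Tree:
        return dendropy.Tree.get(data=self.to_newick(), schema="newick",
                                 preserve_underscores=True,
                                 taxon_namespace=taxon_namespace)

    def __repr__(self):
        return f"<Phylogeny {self.n_tips} tips, height {self.height:.4g}>"


@dataclass
class TreeSample:
    """An ordered sample of trees (e.g. from a Bayesian posterior)."""

    trees: list[Phylogeny]
    source: str = ""

    def __post_init__(self):
        if not self.trees:
            raise ValueError("empty tree sample")

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    def __getitem__(self, i):
        return self.trees[i]


@dataclass
class SamplingFractions:
    """Per-state probability that a described species appears in the tree.

    ``f0`` applies to state 0 (non-páramo by the package's coding), ``f1``
    to state 1 (páramo). The study's counts give f1 = 22/43 and f0 = 4/12.
    """

    f0: float = 4.0 / 12.0
    f1: float = 22.0 / 43.0

    def __post_init__(self):
        for name in ("f0", "f1"):
            f = getattr(self, name)
            if not (0.0 < f <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {f}")


def read_tree_sample(path, schema: str | None = None,
                     require_same_tips: bool = True) -> TreeSample:
    """Read a Newick (one tree per line) or NEXUS trees-block file.

    Tip labels are whitespace-trimmed; branch lengths are kept at full
    precision. With ``require_same_tips`` every tree must carry an identical
    tip label set, and an error names the offending trees otherwise.
    """
    path = str(path)
    if schema is None:
        with open(path) as fh:
            head = fh.read(512).lstrip()
        schema = "nexus" if head.lower().startswith("#nexus") else "newick"
    tlist = dendropy.TreeList.get(path=path, schema=schema,
                                  preserve_underscores=True)
    if not len(tlist):
        raise ValueError(f"no trees parsed from {path}")
    trees = [Phylogeny.from_dendropy(t) for t in tlist]
    if require_same_tips:
        ref = set(trees[0].tip_labels)
        bad = [i for i, t in enumerate(trees) if set(t.tip_labels) != ref]
        if bad:
            raise ValueError(
                f"trees with tip sets differing from tree 0: {bad[:20]}"
                + ("..." if len(bad) > 20 else ""))
    return TreeSample(trees, source=path)


def write_tree_sample(sample: TreeSample, path) -> None:
    with open(path, "w") as fh:
        for t in sample:
            fh.write(t.to_newick() + "\n")


# ---------------------------------------------------------------------
# specimen tables

SPECIMEN_COLUMNS = ["specimen_id", "species_id", "paramo", "microhabitat",
                    "altitude", "pinnae_length", "leaves_per_frond"]
MICROHABITATS = {"sheltered", "exposed", "unknown"}


def validate_specimen_table(df: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a specimen table and return it.

    ``paramo`` uses the package's positive coding: 1 = present in páramo.
    """
    missing = [c for c in SPECIMEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"specimen table missing columns: {missing}")
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids: {dups[:10]}")
    if not df["paramo"].isin([0, 1]).all():
        raise ValueError("paramo column must be binary (1 = present in páramo)")
    bad_mh = set(df["microhabitat"].dropna()) - MICROHABITATS
    if bad_mh:
        raise ValueError(f"unknown microhabitat values: {sorted(bad_mh)}")
    num = df[["altitude", "pinnae_length", "leaves_per_frond"]].apply(
        pd.to_numeric, errors="coerce")
    with_traits = num.dropna(how="all").index
    if (num.loc[with_traits, "pinnae_length"].dropna() <= 0).any():
        raise ValueError("pinnae_length must be positive")
    if (num.loc[with_traits, "leaves_per_frond"].dropna() < 1).any():
        raise ValueError("leaves_per_frond must be >= 1")
    alt = num["altitude"].dropna()
    if ((alt < 0) | (alt > 6000)).any():
        raise ValueError("altitude outside 0-6000 m")
    return df


def read_specimen_table(path) -> pd.DataFrame:
    return validate_specimen_table(pd.read_csv(path))


def species_tip_map(table: pd.DataFrame) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for sp, grp in table.groupby("species_id", sort=True):
        out[str(sp)] = sorted(str(s) for s in grp["specimen_id"])
    return out


def sample_exemplars(tree: Phylogeny, table: pd.DataFrame,
                     rng: np.random.Generator | int) -> Phylogeny:
    """Reduce a multi-specimen tree to one randomly chosen tip per species.

    Each species present in the table must have at least one specimen tip in
    the tree; the retained tip is drawn uniformly among that species'
    in-tree specimens. Pruning sums through the resulting degree-2 nodes, so
    retained tips keep their root-to-tip depth.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.Generator(np.random.Philox(rng))
    in_tree = set(tree.tip_labels)
    chosen = []
    for sp, specimens in species_tip_map(table).items():
        avail = [s for s in specimens if s in in_tree]
        if not avail:
            raise ValueError(f"species {sp!r} has no specimen tip in the tree")
        chosen.append(avail[int(rng.integers(len(avail)))])
    pruned = tree.retain_tips(chosen)
    return pruned


def phylo_covariance(tree: Phylogeny) -> np.ndarray:
    """Tips × tips shared-path-length (BM) covariance matrix."""
    return tree.vcv()


def check_ultrametric(tree: Phylogeny, tol: float = 1e-6) -> tuple[bool, float]:
    """True iff all root-to-tip distances lie within ``tol`` of their mean.

    Returns ``(is_ultrametric, max_abs_deviation)``.
    """
    d = tree.node_depths()[: tree.n_tips]
    dev = float(np.abs(d - d.mean()).max())
    return dev <= tol, dev
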