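"""Phylogeny handling: newick IO, cophenetic distances, support-threshold
polytomy collapsing, clade pruning, and the historical-species branch
decomposition that underlies the similarity-sensitive diversity profile.

Trees are wrapped :class:`PhyloTree` objects backed by a rooted dendropy tree
with branch lengths and (optional) internal-node support values on [0, 100],
as written by common maximum-likelihood programs (support as the internal
node label). Tips are operational taxonomic units (OTUs); trees need not be
ultrametric — every statistic here is defined per-tip via root-to-tip depths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

__all__ = [
    "TreeError",
    "NewickParseError",
    "DistanceMatrix",
    "PhyloTree",
    "HistoricalDecomposition",
    "read_newick",
    "write_newick",
    "cophenetic_distances",
    "collapse_low_support",
    "prune_to_tips",
    "decompose_historical",
]


class TreeError(ValueError):
    """Invalid tree or invalid tree operation."""


class NewickParseError(TreeError):
    """Malformed newick input."""


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric cophenetic (path-length) distance matrix with taxon labels."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if np.any(v < 0):
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "values", v)
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )

    def index_of(self, labels: Iterable[str]) -> np.ndarray:
        idx = self._index
        try:
            return np.array([idx[l] for l in labels], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown taxon label: {exc.args[0]!r}") from None

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        ix = self.index_of(labels)
        return DistanceMatrix(tuple(labels), self.values[np.ix_(ix, ix)])

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self._index[a], self._index[b]])


class PhyloTree:
    """Rooted phylogeny with branch lengths and internal support values.

    Thin wrapper around a dendropy tree that caches the per-branch arrays
    (lengths, descendant-tip incidence, root-to-tip depths) used by the
    diversity, dispersion, and UniFrac machinery. Tip order in every derived
    array is the sorted tip-label order, so matrices from trees that share
    tips are directly comparable.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dupes}")
        if any(l is None for l in labels):
            raise TreeError("every tip must be labelled")
        self.tip_labels: tuple[str, ...] = tuple(sorted(labels))
        self._arrays: tuple | None = None
        self._coph: DistanceMatrix | None = None

    # ---------------------------------------------------------------- io
    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(str(exc)) from None
        return cls(tree)

    @classmethod
    def from_file(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_newick(self) -> str:
        s = self._tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        )
        return s.strip() + "\n"

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def supports(self) -> list[float | None]:
        """Support values of internal non-root nodes, in preorder."""
        out = []
        for nd in self._tree.preorder_node_iter():
            if nd.is_leaf() or nd is self._tree.seed_node:
                continue
            out.append(_node_support(nd))
        return out

    # ------------------------------------------------------- branch arrays
    def branch_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (lengths, incidence, tip_depths).

        lengths: (B,) branch lengths ℓ_b for every edge with a length,
        including a root edge when one is present.
        incidence: (B, S) boolean matrix; incidence[b, i] is True when tip i
        (sorted-label order) descends through branch b.
        tip_depths: (S,) root-to-tip path lengths T_i.
        """
        if self._arrays is None:
            self._arrays = self._build_arrays()
        return self._arrays

    def _build_arrays(self):
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        S = len(index)
        lengths: list[float] = []
        rows: list[np.ndarray] = []
        tips_below: dict[int, np.ndarray] = {}
        depths = np.zeros(S)
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                below = np.array([index[nd.taxon.label]], dtype=int)
            else:
                below = np.concatenate(
                    [tips_below.pop(id(ch)) for ch in nd.child_nodes()]
                )
            tips_below[id(nd)] = below
            elen = nd.edge.length
            if elen is None:
                if nd is not self._tree.seed_node:
                    raise TreeError("branch without a length")
                continue
            if elen < 0:
                raise TreeError("negative branch length")
            lengths.append(float(elen))
            row = np.zeros(S, dtype=bool)
            row[below] = True
            rows.append(row)
            depths[below] += elen
        return (
            np.array(lengths, dtype=float),
            np.array(rows, dtype=bool),
            depths,
        )

    def tip_depths(self) -> np.ndarray:
        return self.branch_arrays()[2]

    # --------------------------------------------------------- operations
    def cophenetic_matrix(self) -> DistanceMatrix:
        if self._coph is not None:
            return self._coph
        index = {lab: i for i, lab in enumerate(self.tip_labels)}
        S = len(index)
        D = np.zeros((S, S))
        node_depth: dict[int, float] = {id(self._tree.seed_node): 0.0}
        tips_below: dict[int, np.ndarray] = {}
        tip_depth = np.zeros(S)
        for nd in self._tree.preorder_node_iter():
            if nd is not self._tree.seed_node:
                elen = nd.edge.length
                if elen is None:
                    raise TreeError("branch without a length")
                node_depth[id(nd)] = node_depth[id(nd.parent_node)] + elen
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                i = index[nd.taxon.label]
                tips_below[id(nd)] = np.array([i], dtype=int)
                tip_depth[i] = node_depth[id(nd)]
                continue
            child_sets = [tips_below.pop(id(ch)) for ch in nd.child_nodes()]
            d0 = node_depth[id(nd)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    ca, cb = child_sets[a], child_sets[b]
                    block = tip_depth[ca][:, None] + tip_depth[cb][None, :] - 2 * d0
                    D[np.ix_(ca, cb)] = block
                    D[np.ix_(cb, ca)] = block.T
            tips_below[id(nd)] = np.concatenate(child_sets)
        self._coph = DistanceMatrix(self.tip_labels, D)
        return self._coph

    def collapse_low_support(self, threshold_percent: float) -> "PhyloTree":
        """Collapse internal non-root nodes whose support is below the
        threshold into polytomies.

        The collapsed node's branch length is added to each child's branch so
        that every root-to-tip depth T_i is exactly preserved; the perturbation
        is purely topological. Nodes without a support value are never
        collapsed.
        """
        if not (0 <= threshold_percent <= 100):
            raise ValueError("threshold must be in [0, 100]")
        tree = dendropy.Tree(self._tree)
        for nd in list(tree.postorder_node_iter()):
            if nd.is_leaf() or nd is tree.seed_node or nd.parent_node is None:
                continue
            support = _node_support(nd)
            if support is None or support >= threshold_percent:
                continue
            parent = nd.parent_node
            elen = nd.edge.length or 0.0
            for ch in list(nd.child_nodes()):
                nd.remove_child(ch)
                ch.edge.length = (ch.edge.length or 0.0) + elen
                parent.add_child(ch)
            parent.remove_child(nd)
        return PhyloTree(tree)

    def prune_to_tips(self, labels: Iterable[str]) -> "PhyloTree":
        """Minimal induced subtree on the given tips; path lengths among the
        kept tips are preserved (suppressed degree-2 nodes sum their branch
        lengths)."""
        labels = list(labels)
        if not labels:
            raise TreeError("cannot prune to an empty tip set")
        known = set(self.tip_labels)
        for lab in labels:
            if lab not in known:
                raise TreeError(f"unknown tip label: {lab!r}")
        sub = self._tree.extract_tree_with_taxa_labels(labels)
        return PhyloTree(sub)


def _node_support(nd: dendropy.Node) -> float | None:
    label = nd.label
    if label is None:
        return None
    try:
        return float(label)
    except ValueError:
        return None


@dataclass(frozen=True)
class HistoricalDecomposition:
    """Branch decomposition of a community for phylogenetic Hill numbers.

    A "historical species" is a pair (i, b): extant taxon i together with a
    branch b on its root-to-tip path. With p_i the relative abundance of taxon
    i, T_i its root-to-tip depth and ℓ_b the length of branch b, the
    historical abundances are π_(i,b) = ℓ_b · p_i / T_i, which sum to one.
    a_b = Σ_{j ∈ I_b} p_j is the abundance of the clade below branch b; it is
    the similarity-weighted ordinariness (Zπ)_(i,b) of every historical
    species on that branch. w_b = Σ_{i ∈ I_b} π_(i,b) collects the historical
    abundance carried by branch b.
    """

    tip_labels: tuple[str, ...]
    abundances: np.ndarray  # p_i, (S,)
    branch_lengths: np.ndarray  # ℓ_b, (B,)
    incidence: np.ndarray  # I_b indicator, (B, S) bool
    tip_depths: np.ndarray  # T_i, (S,)
    branch_abundances: np.ndarray  # a_b, (B,)
    branch_weights: np.ndarray  # w_b, (B,)

    def historical_abundances(self) -> np.ndarray:
        """Dense (B, S) matrix of π_(i,b); zero where i ∉ I_b or p_i = 0."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(self.tip_depths > 0, self.abundances / self.tip_depths, 0.0)
        return self.incidence * np.outer(self.branch_lengths, ratio)


ABUNDANCE_SUM_TOL = 1e-6


def decompose_historical(
    tree: PhyloTree, abundances: Mapping[str, float] | np.ndarray
) -> HistoricalDecomposition:
    """Decompose a community on a tree into historical species.

    ``abundances`` is either a mapping from tip label to relative abundance or
    an array aligned with ``tree.tip_labels``; it must be non-negative and sum
    to 1. Taxa absent from the mapping have abundance 0. Raises
    :class:`TreeError` if a taxon with positive abundance sits at zero
    root-to-tip depth (degenerate: its historical species are undefined).
    """
    if isinstance(abundances, Mapping):
        unknown = set(abundances) - set(tree.tip_labels)
        if unknown:
            raise TreeError(f"abundances for unknown tips: {sorted(unknown)}")
        p = np.array([float(abundances.get(l, 0.0)) for l in tree.tip_labels])
    else:
        p = np.asarray(abundances, dtype=float)
        if p.shape != (tree.n_tips,):
            raise ValueError("abundance vector length does not match tip count")
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    if abs(p.sum() - 1.0) > ABUNDANCE_SUM_TOL:
        raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")
    lengths, incidence, depths = tree.branch_arrays()
    if np.any((p > 0) & (depths <= 0)):
        raise TreeError("taxon with positive abundance has zero root-to-tip depth")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(depths > 0, p / depths, 0.0)
    a = incidence @ p
    w = lengths * (incidence @ ratio)
    return HistoricalDecomposition(
        tip_labels=tree.tip_labels,
        abundances=p,
        branch_lengths=lengths,
        incidence=incidence,
        tip_depths=depths,
        branch_abundances=a,
        branch_weights=w,
    )


# Functional aliases matching the operation-level surface.
def read_newick(text: str) -> PhyloTree:
    return PhyloTree.from_newick(text)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def cophenetic_distances(tree: PhyloTree) -> DistanceMatrix:
    return tree.cophenetic_matrix()


def collapse_low_support(tree: PhyloTree, threshold_percent: float) -> PhyloTree:
    return tree.collapse_low_support(threshold_percent)


def prune_to_tips(tree: PhyloTree, labels: Iterable[str]) -> PhyloTree:
    return tree.prune_to_tips(labels)
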