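"""Unweighted UniFrac beta diversity between rarefied samples.

Unweighted UniFrac is the fraction of the tree's covered branch length that
is unique to one of two communities: branches are counted when they lie on
the root-to-tip path of at least one present taxon (the root-inclusive
convention of the original formulation, so the placement of the root matters
and is part of the input). It depends only on presence/absence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .tables import CommunityTable
from .tree import PhyloTree

__all__ = ["BetaDistanceMatrix", "unweighted_unifrac", "unifrac_matrix"]


@dataclass(frozen=True)
class BetaDistanceMatrix:
    """Pairwise sample distances in [0, 1] with rarefaction provenance."""

    labels: tuple[str, ...]
    values: np.ndarray
    depth: int
    n_reps: int
    seed: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("beta distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("beta distance matrix must have a zero diagonal")
        if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
            raise ValueError("unweighted UniFrac distances must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def _tip_mask(tree: PhyloTree, taxa: Iterable[str]) -> np.ndarray:
    index = {lab: i for i, lab in enumerate(tree.tip_labels)}
    mask = np.zeros(tree.n_tips, dtype=bool)
    for t in taxa:
        if t not in index:
            raise ValueError(f"taxon {t!r} is not a tip of the tree")
        mask[index[t]] = True
    return mask


def unweighted_unifrac(tree: PhyloTree, taxa_a: Iterable[str], taxa_b: Iterable[str]) -> float:
    """Unweighted UniFrac distance between two presence sets of tree tips."""
    mask_a = _tip_mask(tree, taxa_a)
    mask_b = _tip_mask(tree, taxa_b)
    if not (mask_a.any() or mask_b.any()):
        raise ValueError("the union of the two taxon sets is empty")
    lengths, incidence, _ = tree.branch_arrays()
    in_a = incidence @ mask_a > 0
    in_b = incidence @ mask_b > 0
    union = float(lengths[in_a | in_b].sum())
    shared = float(lengths[in_a & in_b].sum())
    if union == 0:
        return 0.0
    return 1.0 - shared / union


def unifrac_matrix(
    table: CommunityTable,
    tree: PhyloTree,
    depth: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
) -> BetaDistanceMatrix:
    """Mean pairwise unweighted UniFrac over matched rarefactions.

    All samples are rarefied to ``depth`` (default: the smallest sample
    total) in each replicate, distances computed on the rarefied presence
    sets, and averaged over ``n_reps`` replicates.
    """
    samples = table.sample_ids
    totals = table.counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if (totals < depth).any():
        low = list(totals.index[totals < depth])
        raise ValueError(f"samples below rarefaction depth {depth}: {low}")
    missing = set(table.counts.index[(table.counts > 0).any(axis=1)]) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"table taxa missing from tree: {sorted(missing)[:5]}")
    lengths, incidence, _ = tree.branch_arrays()
    tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}
    row_ix = np.array([tip_index[t] for t in table.counts.index])
    counts = table.counts.to_numpy()
    rng = np.random.default_rng(seed)
    n = len(samples)
    acc = np.zeros((n, n))
    for _ in range(n_reps):
        # branch coverage per sample after matched rarefaction
        covered = np.zeros((lengths.size, n), dtype=bool)
        for j in range(n):
            sub = rng.multivariate_hypergeometric(counts[:, j], depth)
            mask = np.zeros(len(tip_index), dtype=bool)
            mask[row_ix[sub > 0]] = True
            covered[:, j] = incidence @ mask > 0
        blen = covered * lengths[:, None]
        branch_totals = blen.sum(axis=0)
        shared = blen.T @ covered  # shared[i, j] = Σ ℓ_b over branches in both
        union = branch_totals[:, None] + branch_totals[None, :] - shared
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(union > 0, 1.0 - shared / union, 0.0)
        np.fill_diagonal(d, 0.0)
        acc += d
    acc /= n_reps
    acc = (acc + acc.T) / 2  # symmetric by construction; guard float noise
    return BetaDistanceMatrix(tuple(samples), acc, depth=depth, n_reps=n_reps, seed=seed)
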