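"""Effective-number diversity: naive and similarity-sensitive Hill numbers,
the phylogenetic diversity profile over the historical-species decomposition,
and rarefaction-averaged per-sample profiles.

The order parameter q tunes sensitivity to rare taxa: q = 0 counts taxa
(richness), q = 1 is the exponential of Shannon entropy, q = 2 the inverse
Simpson concentration, and q = ∞ the reciprocal of the dominant taxon's share
(Berger–Parker). The similarity-sensitive family replaces each taxon's own
abundance with its similarity-weighted "ordinariness" (Zp)_i; with Z the
identity it reduces exactly to the naive Hill numbers, and with the ancestry
indicator over historical species it yields a phylogenetic diversity profile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree import PhyloTree, decompose_historical

__all__ = [
    "DEFAULT_Q_GRID",
    "DiversityProfile",
    "naive_hill",
    "similarity_hill",
    "phylo_hill",
    "rarefy_counts",
    "rarefied_profile",
]

#: q from 0 to 5 in steps of 0.1 (the plotted profile range).
DEFAULT_Q_GRID: np.ndarray = np.round(np.arange(0.0, 5.0 + 1e-9, 0.1), 10)

_NORM_TOL = 1e-9


def _check_abundances(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("abundance vector must be one-dimensional")
    if np.any(p < 0):
        raise ValueError("abundances must be non-negative")
    if abs(p.sum() - 1.0) > _NORM_TOL:
        raise ValueError(f"abundances must sum to 1 (got {p.sum()!r})")
    return p


def _hill(weights: np.ndarray, ordinariness: np.ndarray, q: float) -> float:
    """Generalized Hill number (Σ_i w_i z_i^{q-1})^{1/(1-q)} restricted to
    w_i > 0, with the analytic q = 1 and q = ∞ limits."""
    mask = weights > 0
    w = weights[mask]
    z = ordinariness[mask]
    if np.any(z <= 0):
        raise ValueError("zero ordinariness for a present taxon (degenerate similarity)")
    if q == np.inf:
        return float(1.0 / np.max(z))
    if q < 0:
        raise ValueError("q must be non-negative")
    if q == 1:
        return float(np.exp(-np.sum(w * np.log(z))))
    s = float(np.sum(w * z ** (q - 1.0)))
    return float(s ** (1.0 / (1.0 - q)))


def naive_hill(p, q: float) -> float:
    """Hill number of order q for a relative-abundance vector.

    (Σ_{p_i>0} p_i^q)^{1/(1-q)} for q ∉ {1, ∞}; exp(−Σ p_i ln p_i) at q = 1;
    1 / max_i p_i at q = ∞. At q = 0 this is the number of taxa with p_i > 0.
    """
    p = _check_abundances(p)
    return _hill(p, p, q)


def similarity_hill(p, Z, q: float) -> float:
    """Similarity-sensitive Hill number ^qD^Z(p).

    Z is a taxon × taxon similarity matrix with unit diagonal and entries in
    [0, 1]; (Zp)_i is the ordinariness of taxon i. Z = I recovers
    :func:`naive_hill`.
    """
    p = _check_abundances(p)
    Z = np.asarray(Z, dtype=float)
    if Z.shape != (p.size, p.size):
        raise ValueError("similarity matrix shape does not match abundances")
    if np.any(Z < 0) or np.any(Z > 1):
        raise ValueError("similarities must lie in [0, 1]")
    if not np.allclose(np.diag(Z), 1.0):
        raise ValueError("similarity matrix must have a unit diagonal")
    return _hill(p, Z @ p, q)


def phylo_hill(tree: PhyloTree, abundances, q: float) -> float:
    """Phylogenetic diversity profile value ^qD^Z(π) at order q.

    Computed over historical species (taxon i, branch b) with abundances
    π_(i,b) = ℓ_b p_i / T_i and ordinariness (Zπ)_(i,b) = a_b, the relative
    abundance of the clade below branch b. The (i,b) sum collapses to a
    per-branch sum with weights w_b = Σ_{i∈I_b} π_(i,b), so the full
    historical-by-historical similarity matrix is never materialized.
    """
    d = decompose_historical(tree, abundances)
    return _hill(d.branch_weights, d.branch_abundances, q)


def rarefy_counts(counts, depth: int, seed) -> np.ndarray | pd.Series:
    """Subsample a count vector without replacement to exactly ``depth``.

    Multivariate-hypergeometric draw; deterministic for a given integer seed
    (a numpy Generator is also accepted). ``depth`` must not exceed the total.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    values = counts.to_numpy() if isinstance(counts, pd.Series) else np.asarray(counts)
    if not np.issubdtype(values.dtype, np.integer):
        if np.any(values != np.floor(values)):
            raise ValueError("counts must be integers")
        values = values.astype(np.int64)
    if np.any(values < 0):
        raise ValueError("counts must be non-negative")
    total = int(values.sum())
    if depth < 0 or depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds total count {total}")
    sub = rng.multivariate_hypergeometric(values, depth)
    if isinstance(counts, pd.Series):
        return pd.Series(sub, index=counts.index)
    return sub


@dataclass(frozen=True)
class DiversityProfile:
    """A diversity profile: ^qD over a grid of q values for one sample."""

    sample_id: str
    qs: np.ndarray
    values: np.ndarray
    depth: int
    n_reps: int
    variant: str  # "naive" | "phylogenetic"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.sample_id,
                "q": self.qs,
                "value": self.values,
                "depth": self.depth,
                "n_reps": self.n_reps,
                "variant": self.variant,
            }
        )


def _profile_values(p: np.ndarray, qs: np.ndarray) -> np.ndarray:
    return np.array([_hill(p, p, q) for q in qs])


def _phylo_profile_values(tree: PhyloTree, p_full: np.ndarray, qs: np.ndarray) -> np.ndarray:
    d = decompose_historical(tree, p_full)
    return np.array([_hill(d.branch_weights, d.branch_abundances, q) for q in qs])


def rarefied_profile(
    counts: pd.Series,
    tree: PhyloTree | None = None,
    q_grid=None,
    depth: int | None = None,
    n_reps: int = 100,
    seed: int = 0,
    sample_id: str | None = None,
) -> DiversityProfile:
    """Rarefaction-averaged diversity profile for one sample.

    ``counts`` is a taxon-indexed integer Series. Each of ``n_reps``
    replicates rarefies the counts to ``depth`` (default: the sample total,
    i.e. no subsampling) and evaluates the profile on the rarefied relative
    abundances; the profile values are averaged per q. With a tree the
    phylogenetic variant ^qD^Z(π) is computed; without one, the naive variant
    (Z = I).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if not isinstance(counts, pd.Series):
        raise TypeError("counts must be a taxon-indexed pandas Series")
    qs = DEFAULT_Q_GRID if q_grid is None else np.asarray(q_grid, dtype=float)
    total = int(counts.sum())
    if total < 1:
        raise ValueError("sample has no counts")
    if depth is None:
        depth = total
    rng = np.random.default_rng(seed)
    if tree is not None:
        missing = set(counts.index[counts > 0]) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"taxa with counts missing from the tree: {sorted(missing)[:5]}")
        tip_index = {lab: i for i, lab in enumerate(tree.tip_labels)}
        cols = np.array([tip_index[l] for l in counts.index if l in tip_index])
        kept = counts[[l for l in counts.index if l in tip_index]]
    acc = np.zeros(qs.size)
    for _ in range(n_reps):
        sub = rarefy_counts(counts, depth, rng)
        if tree is None:
            p = sub.to_numpy(dtype=float) / depth
            acc += _profile_values(p, qs)
        else:
            p_full = np.zeros(tree.n_tips)
            p_full[cols] = sub[kept.index].to_numpy(dtype=float) / depth
            acc += _phylo_profile_values(tree, p_full, qs)
    return DiversityProfile(
        sample_id=sample_id or str(counts.name or "sample"),
        qs=qs,
        values=acc / n_reps,
        depth=depth,
        n_reps=n_reps,
        variant="naive" if tree is None else "phylogenetic",
    )
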