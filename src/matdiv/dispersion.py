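"""Phylogenetic dispersion: mean pairwise distance (MPD), permutation null
models, standardized effect sizes, and guild-level tests.

The standardized effect size MPD_SES = (MPD_obs − mean_null) / sd_null
compares a community's mean pairwise cophenetic distance against the
distribution of the same (identically rarefied) statistic on randomized
communities. Negative SES indicates phylogenetic clustering (the signature
expected under habitat filtering with conserved niches); positive SES
indicates overdispersion (the signature of limiting similarity). Three
randomization routines are provided, in the tradition of community-
phylogenetics software:

* ``independent_swap`` — checkerboard swaps on the taxa × sample table,
  preserving per-taxon occupancy and per-sample richness;
* ``phylogeny_pool`` — random draws of the observed richness from the taxa
  pool;
* ``taxa_labels`` — label shuffles of the cophenetic distance matrix
  restricted to the pool.

Significance is a one-tailed rank test at α = 0.05 in each direction: a
sample is clustered (overdispersed) if its observed value falls below (above)
95% of the randomized values.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import CommunityTable, POOL_SCOPES
from .tree import DistanceMatrix, PhyloTree

__all__ = [
    "mpd",
    "null_independent_swap",
    "null_taxa_labels",
    "null_phylogeny_pool",
    "ses_mpd",
    "guild_dispersion",
    "guild_members",
    "rank_test",
    "SwapExhaustedWarning",
]

logger = logging.getLogger(__name__)

ALPHA = 0.05

#: Default swap schedule inside ses_mpd: attempted swaps before the first
#: null table is drawn, and attempted swaps between successive draws.
SWAP_BURNIN = 10_000
SWAP_INTERVAL = 1_000


class SwapExhaustedWarning(UserWarning):
    """Raised when no checkerboard submatrix could be found to swap."""


# --------------------------------------------------------------------- MPD
def mpd(distances, taxa_or_abundances, weighting: str = "presence") -> float:
    """Mean pairwise phylogenetic distance of a community.

    With ``weighting="presence"``, the mean of d(i, j) over unordered pairs of
    distinct present taxa; with ``weighting="proportional"``, the
    abundance-weighted mean Σ_{i≠j} p_i p_j d(i,j) / Σ_{i≠j} p_i p_j.

    ``taxa_or_abundances`` is an iterable of taxon labels (presence) or a
    mapping label → abundance (either weighting).
    """
    if not isinstance(distances, DistanceMatrix):
        raise TypeError("distances must be a DistanceMatrix")
    if weighting not in ("presence", "proportional"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if isinstance(taxa_or_abundances, Mapping):
        items = [(k, float(v)) for k, v in taxa_or_abundances.items() if v > 0]
        labels = [k for k, _ in items]
        weights = np.array([v for _, v in items])
    else:
        labels = list(taxa_or_abundances)
        weights = np.ones(len(labels))
    if len(labels) < 2:
        raise ValueError("MPD is undefined for fewer than 2 present taxa")
    idx = distances.index_of(labels)
    sub = distances.values[np.ix_(idx, idx)]
    if weighting == "presence":
        m = len(idx)
        return float(sub.sum() / (m * (m - 1)))
    p = weights / weights.sum()
    denom = 1.0 - float(p @ p)
    return float(p @ sub @ p) / denom


def _mpd_presence(sub: np.ndarray) -> float:
    m = sub.shape[0]
    return float(sub.sum() / (m * (m - 1)))


def _mpd_proportional(sub: np.ndarray, p: np.ndarray) -> float:
    return float(p @ sub @ p) / (1.0 - float(p @ p))


# ------------------------------------------------------------- null models
def _checkerboard_swap(
    mat: np.ndarray,
    rng: np.random.Generator,
    n_swaps: int,
    count: str = "successful",
    max_attempts: int | None = None,
) -> tuple[np.ndarray, int]:
    """Perform 2×2 checkerboard swaps on a count matrix in place-on-a-copy.

    A swappable submatrix has the pattern [x, 0; 0, y] (or its mirror) with
    x, y > 0; the swap moves the two values across the zero diagonal, which
    preserves row and column occupancy (presence) totals exactly and carries
    the count values with the swap. ``count`` selects whether ``n_swaps``
    counts successful or attempted swaps. Returns (matrix, n_successful).
    """
    if count not in ("successful", "attempted"):
        raise ValueError("count must be 'successful' or 'attempted'")
    mat = mat.copy()
    n_rows, n_cols = mat.shape
    if n_rows < 2 or n_cols < 2:
        return mat, 0
    done = 0
    attempts = 0
    if max_attempts is None:
        max_attempts = 500 * n_swaps if count == "successful" else n_swaps
    block = 4096
    while attempts < max_attempts and (count == "attempted" or done < n_swaps):
        k = min(block, max_attempts - attempts)
        r = rng.integers(0, n_rows, size=(k, 2))
        c = rng.integers(0, n_cols, size=(k, 2))
        for (r1, r2), (c1, c2) in zip(r, c):
            attempts += 1
            if r1 == r2 or c1 == c2:
                continue
            a = mat[r1, c1]
            b = mat[r1, c2]
            cc = mat[r2, c1]
            d = mat[r2, c2]
            if a > 0 and d > 0 and b == 0 and cc == 0:
                mat[r1, c2] = a
                mat[r2, c1] = d
                mat[r1, c1] = 0
                mat[r2, c2] = 0
            elif b > 0 and cc > 0 and a == 0 and d == 0:
                mat[r1, c1] = b
                mat[r2, c2] = cc
                mat[r1, c2] = 0
                mat[r2, c1] = 0
            else:
                continue
            done += 1
            if count == "successful" and done >= n_swaps:
                break
            if count == "attempted" and attempts >= max_attempts:
                break
    return mat, done


def null_independent_swap(count_matrix, n_swaps: int, seed) -> np.ndarray:
    """Randomize a taxa × sample count table with ``n_swaps`` successful
    checkerboard swaps; row and column presence sums are preserved exactly.

    If no swappable checkerboard exists the input is returned unchanged with
    a :class:`SwapExhaustedWarning`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mat = np.asarray(count_matrix)
    if mat.ndim != 2 or mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("count matrix must have at least 2 rows and 2 columns")
    out, done = _checkerboard_swap(mat, rng, n_swaps, count="successful")
    if done < n_swaps:
        warnings.warn(
            f"only {done}/{n_swaps} checkerboard swaps were possible",
            SwapExhaustedWarning,
            stacklevel=2,
        )
    return out


def null_taxa_labels(distances: DistanceMatrix, pool: Sequence[str], seed) -> DistanceMatrix:
    """Shuffle distance-matrix labels uniformly within a taxa pool.

    Matrix values are untouched, so the off-diagonal distance multiset is
    invariant; only the taxon ↔ row assignment changes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(pool)
    if len(pool) < 2:
        raise ValueError("pool must contain at least 2 taxa")
    positions = distances.index_of(pool)
    labels = list(distances.labels)
    perm = rng.permutation(len(pool))
    for slot, src in zip(positions, perm):
        labels[slot] = pool[src]
    return DistanceMatrix(tuple(labels), distances.values)


def null_phylogeny_pool(
    sample_taxa: Sequence[str],
    pool: Sequence[str],
    seed,
    abundances: Mapping[str, float] | None = None,
):
    """Draw a random community of the observed richness from the taxa pool.

    Uniform sampling without replacement. When ``abundances`` is given, the
    observed abundances are reassigned to the drawn taxa in random order and
    a mapping is returned; otherwise a list of taxa.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = list(pool)
    richness = len(sample_taxa)
    if richness > len(pool):
        raise ValueError("sample richness exceeds pool size")
    drawn_idx = rng.choice(len(pool), size=richness, replace=False)
    drawn = [pool[i] for i in drawn_idx]
    if abundances is None:
        return drawn
    values = np.array([abundances[t] for t in sample_taxa], dtype=float)
    rng.shuffle(values)
    return dict(zip(drawn, values))


# --------------------------------------------------------------- rank test
def rank_test(observed: float, nulls: np.ndarray) -> tuple[float, float, float]:
    """Mid-rank of the observed value among the nulls (observed included).

    Returns (rank, p_low, p_high) with rank = 1 + #{null < obs} + ties/2,
    p_low = rank/(n+1), p_high = (n+2−rank)/(n+1) for n null values.
    """
    n = nulls.size
    less = int(np.sum(nulls < observed))
    ties = int(np.sum(nulls == observed))
    rank = 1.0 + less + ties / 2.0
    p_low = rank / (n + 1)
    p_high = (n + 2 - rank) / (n + 1)
    return rank, p_low, p_high


def _call(p_low: float, p_high: float, degenerate: bool) -> str:
    if degenerate:
        return "degenerate"
    if p_low <= ALPHA:
        return "clustered"
    if p_high <= ALPHA:
        return "overdispersed"
    return "ns"


# ----------------------------------------------------------------- ses_mpd
def _sample_statistic(
    counts: np.ndarray,
    sub_d: np.ndarray,
    weighting: str,
    rarefy_depth: int | None,
    n_rarefactions: int,
    rng: np.random.Generator,
) -> float:
    """MPD of one community over the pool, rarefaction-averaged if asked."""
    if rarefy_depth is None:
        if weighting == "presence":
            idx = np.flatnonzero(counts > 0)
            return _mpd_presence(sub_d[np.ix_(idx, idx)])
        p = counts / counts.sum()
        idx = np.flatnonzero(counts > 0)
        return _mpd_proportional(sub_d[np.ix_(idx, idx)], p[idx])
    ints = counts.astype(np.int64)
    # A randomized community need not conserve the sample total (checkerboard
    # swaps move counts between samples), so rarefy to its own total when
    # that falls below the common depth.
    depth = min(rarefy_depth, int(ints.sum()))
    nz = np.flatnonzero(ints > 0)
    draws = rng.multivariate_hypergeometric(ints[nz], depth, size=n_rarefactions)
    present = draws > 0
    m = present.sum(axis=1)
    bad = m < 2
    tries = 0
    while bad.any() and tries < 100:
        redraw = rng.multivariate_hypergeometric(ints[nz], depth, size=int(bad.sum()))
        draws[bad] = redraw
        present = draws > 0
        m = present.sum(axis=1)
        bad = m < 2
        tries += 1
    if bad.any():
        raise ValueError("rarefied community has fewer than 2 taxa")
    d_nz = sub_d[np.ix_(nz, nz)]
    if weighting == "presence":
        mask = present.astype(float)
        sums = np.einsum("rj,rj->r", mask @ d_nz, mask)
        return float(np.mean(sums / (m * (m - 1))))
    p = draws / depth
    num = np.einsum("rj,rj->r", p @ d_nz, p)
    den = 1.0 - np.einsum("rj,rj->r", p, p)
    return float(np.mean(num / den))


_NULL_MODELS = ("independent_swap", "phylogeny_pool", "taxa_labels")


def ses_mpd(
    table: CommunityTable,
    tree: PhyloTree,
    null_model: str = "taxa_labels",
    pool_scope: str = "all",
    weighting: str = "presence",
    n_null: int = 999,
    rarefy_depth: int | str | None = None,
    n_rarefactions: int = 100,
    seed: int = 0,
    swap_burnin: int = SWAP_BURNIN,
    swap_interval: int = SWAP_INTERVAL,
    binarize_swap: bool = False,
    guild: str = "all",
) -> pd.DataFrame:
    """Standardized effect size of rarefied MPD for every sample.

    The observed statistic is the mean MPD over ``n_rarefactions`` rarefied
    subsamples (``rarefy_depth="min"`` rarefies to the smallest sample total,
    None computes the plain MPD); each of
    ``n_null`` randomized communities is scored with the identical procedure.
    Returns one row per sample with observed MPD, null mean/sd, SES, mid-rank
    of the observed among the nulls, one-tailed p values, and the
    clustered/overdispersed/ns call at α = 0.05. Samples whose community (or
    rarefied community) has fewer than 2 taxa are skipped with a logged
    reason. A null distribution with zero spread (e.g. a sample containing
    its entire pool under taxa-label shuffling) yields a degenerate flag and
    no significance call.
    """
    if null_model not in _NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}; expected one of {_NULL_MODELS}")
    if weighting not in ("presence", "proportional"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if pool_scope not in POOL_SCOPES:
        raise ValueError(f"unknown pool scope {pool_scope!r}")
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if rarefy_depth == "min":
        rarefy_depth = int(table.counts.sum(axis=0).min())
    missing = set(table.counts.index[(table.counts > 0).any(axis=1)]) - set(tree.tip_labels)
    if missing:
        raise ValueError(f"table taxa missing from tree: {sorted(missing)[:5]}")
    distances = tree.cophenetic_matrix()
    ss = np.random.SeedSequence(seed)
    rows = []
    for group_label, samples, pool in table.pool_groups(pool_scope):
        if len(pool) < 2:
            logger.warning("pool %r has fewer than 2 taxa; skipped", group_label)
            continue
        pool_ix = distances.index_of(pool)
        sub_d = distances.values[np.ix_(pool_ix, pool_ix)]
        block = table.counts.loc[pool, samples].to_numpy()
        group_rng = np.random.default_rng(ss.spawn(1)[0])

        swap_tables: list[np.ndarray] | None = None
        if null_model == "independent_swap":
            mat = (block > 0).astype(np.int64) if binarize_swap else block
            mat, _ = _checkerboard_swap(mat, group_rng, swap_burnin, count="attempted")
            swap_tables = []
            for _ in range(n_null):
                mat, _ = _checkerboard_swap(mat, group_rng, swap_interval, count="attempted")
                swap_tables.append(mat)

        for j, sample in enumerate(samples):
            counts = block[:, j].astype(float)
            present = int(np.sum(counts > 0))
            total = int(counts.sum())
            if present < 2:
                logger.warning("sample %r has <2 taxa; skipped", sample)
                continue
            if rarefy_depth is not None and rarefy_depth > total:
                logger.warning(
                    "sample %r total %d below rarefaction depth %d; skipped",
                    sample, total, rarefy_depth,
                )
                continue
            srng = np.random.default_rng(ss.spawn(1)[0])
            obs = _sample_statistic(
                counts, sub_d, weighting, rarefy_depth, n_rarefactions, srng
            )
            nulls = np.empty(n_null)
            if null_model == "independent_swap":
                for k in range(n_null):
                    nulls[k] = _sample_statistic(
                        swap_tables[k][:, j].astype(float),
                        sub_d, weighting, rarefy_depth, n_rarefactions, srng,
                    )
            elif null_model == "taxa_labels":
                for k in range(n_null):
                    nulls[k] = _sample_statistic(
                        counts[srng.permutation(len(pool))],
                        sub_d, weighting, rarefy_depth, n_rarefactions, srng,
                    )
            else:  # phylogeny_pool
                nz = np.flatnonzero(counts > 0)
                values = counts[nz]
                for k in range(n_null):
                    null_counts = np.zeros(len(pool))
                    slots = srng.choice(len(pool), size=nz.size, replace=False)
                    null_counts[slots] = srng.permutation(values)
                    nulls[k] = _sample_statistic(
                        null_counts, sub_d, weighting, rarefy_depth, n_rarefactions, srng
                    )
            null_mean = float(nulls.mean())
            null_sd = float(nulls.std(ddof=1))
            # identical nulls can show sd ~ 1 ulp from summation round-off
            degenerate = not (nulls.max() > nulls.min())
            ses = (obs - null_mean) / null_sd if not degenerate else np.nan
            rank, p_low, p_high = rank_test(obs, nulls)
            rows.append(
                {
                    "sample": sample,
                    "guild": guild,
                    "null_model": null_model,
                    "pool_scope": pool_scope,
                    "pool_group": group_label,
                    "weighting": weighting,
                    "n_null": n_null,
                    "pool_size": len(pool),
                    "richness": present,
                    "obs_mpd": obs,
                    "null_mean": null_mean,
                    "null_sd": null_sd,
                    "ses": ses,
                    "rank": rank,
                    "p_low": p_low if not degenerate else np.nan,
                    "p_high": p_high if not degenerate else np.nan,
                    "call": _call(p_low, p_high, degenerate),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)


# ------------------------------------------------------------------ guilds
def guild_members(
    taxonomy: Mapping[str, str], rules: Iterable[str], taxa: Iterable[str]
) -> list[str]:
    """Taxa whose lineage string contains any of the rule substrings."""
    rules = list(rules)
    out = []
    for t in taxa:
        lineage = taxonomy.get(t, "")
        if any(r in lineage for r in rules):
            out.append(t)
    return out


def guild_dispersion(
    table: CommunityTable,
    tree: PhyloTree,
    taxonomy: Mapping[str, str],
    guild_definitions: Mapping[str, Sequence[str]],
    **ses_kwargs,
) -> pd.DataFrame:
    """Run :func:`ses_mpd` within each functional guild.

    For each guild the tree is pruned to the guild's members, the count table
    restricted to them, and the taxa pool rebuilt inside the guild before
    delegating to :func:`ses_mpd`. Guilds selecting fewer than 2 taxa, and
    samples with fewer than 2 present guild members, are skipped with a
    logged reason.
    """
    frames = []
    for name, rules in guild_definitions.items():
        members = guild_members(taxonomy, rules, table.taxon_ids)
        members = [m for m in members if m in set(tree.tip_labels)]
        if len(members) < 2:
            logger.warning("guild %r selects <2 taxa; skipped", name)
            continue
        sub_counts = table.counts.loc[members]
        keep = sub_counts.columns[(sub_counts > 0).sum(axis=0) >= 2]
        if len(keep) == 0:
            logger.warning("guild %r present in no sample; skipped", name)
            continue
        sub_table = CommunityTable(sub_counts[keep], table.metadata.loc[keep])
        sub_tree = tree.prune_to_tips(members)
        frames.append(ses_mpd(sub_table, sub_tree, guild=name, **ses_kwargs))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)
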