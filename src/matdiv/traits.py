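"""Ortholog-group trait richness: rarefaction and pooled-resampling nulls.

Functional trait richness is proxied by the number of distinct ortholog
groups (KO/COG/NOG) detected in a sample's annotated genes. Because samples
differ in the number of annotated gene instances, richness is rarefied to a
common instance depth; the null expectation draws the same number of
instances without replacement from the pool of gene instances detected
across the whole core, so a sample holding fewer (more) distinct groups than
the null distribution is functionally depleted (enriched) relative to a
random slice of the core's gene pool. Category-level tests rarefy at the
whole-pool depth and then count only the groups belonging to the category.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dispersion import ALPHA, rank_test
from .tables import TraitTable

__all__ = ["rarefied_trait_richness", "trait_null", "trait_ses"]


def _as_int_counts(counts) -> np.ndarray:
    arr = counts.to_numpy() if isinstance(counts, pd.Series) else np.asarray(counts)
    if np.any(arr < 0) or np.any(arr != np.floor(arr)):
        raise ValueError("counts must be non-negative integers")
    return arr.astype(np.int64)


def rarefied_trait_richness(
    sample_counts, depth: int, n_reps: int = 100, seed=0,
    category_mask: np.ndarray | None = None,
) -> float:
    """Mean number of distinct ortholog groups in ``n_reps`` without-
    replacement subsamples of ``depth`` gene instances.

    ``category_mask`` optionally restricts the richness count to a subset of
    groups (the subsample itself is always drawn from all groups).
    """
    counts = _as_int_counts(sample_counts)
    total = int(counts.sum())
    if depth < 1 or depth > total:
        raise ValueError(f"depth {depth} out of range (sample total {total})")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    acc = 0
    for _ in range(n_reps):
        sub = rng.multivariate_hypergeometric(counts, depth)
        hit = sub > 0
        if category_mask is not None:
            hit = hit & category_mask
        acc += int(hit.sum())
    return acc / n_reps


def trait_null(
    sample_instance_count: int,
    pooled_counts,
    n_reps: int = 1000,
    seed=0,
    category_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Null distribution of trait richness under pooled resampling.

    Each replicate draws ``sample_instance_count`` gene instances without
    replacement from the pooled multiset (instance-weighted across the core's
    samples) and records the number of distinct groups, optionally restricted
    to a category.
    """
    pool = _as_int_counts(pooled_counts)
    pool_total = int(pool.sum())
    if pool_total < 1:
        raise ValueError("empty pool")
    if sample_instance_count < 1 or sample_instance_count > pool_total:
        raise ValueError(
            f"draw size {sample_instance_count} out of range (pool total {pool_total})"
        )
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty(n_reps, dtype=np.int64)
    for k in range(n_reps):
        sub = rng.multivariate_hypergeometric(pool, sample_instance_count)
        hit = sub > 0
        if category_mask is not None:
            hit = hit & category_mask
        out[k] = int(hit.sum())
    return out


def trait_ses(
    trait_table: TraitTable,
    depth: int | None = None,
    n_reps: int = 100,
    n_null: int = 1000,
    categories: list[str] | None = None,
    seed: int = 0,
    pool_weighting: str = "instance",
) -> pd.DataFrame:
    """Rarefied trait richness versus the pooled-resampling null, per sample
    and per category.

    ``depth`` defaults to the smallest per-sample instance total. The null
    draw size equals the rarefaction depth (both count gene instances).
    ``pool_weighting="instance"`` (default) draws from the instance-weighted
    pool across all samples; ``"group"`` gives every detected group a single
    pool instance. Ranks, one-tailed p values and the depleted/enriched/ns
    call at α = 0.05 follow the same rank-test convention as the MPD
    dispersion tests.
    """
    if n_null < 99:
        raise ValueError("n_null must be at least 99")
    if pool_weighting not in ("instance", "group"):
        raise ValueError(f"unknown pool weighting {pool_weighting!r}")
    counts = trait_table.counts
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    pool = trait_table.pooled_counts().to_numpy()
    if pool_weighting == "group":
        pool = (pool > 0).astype(np.int64)
    pool_richness = int((pool > 0).sum())
    group_index = list(counts.index)
    cat_names = ["all"] + sorted(categories if categories is not None else trait_table.categories)
    masks: dict[str, np.ndarray | None] = {"all": None}
    for cat in cat_names:
        if cat == "all":
            continue
        members = set(trait_table.categories.get(cat, ()))
        masks[cat] = np.array([g in members for g in group_index])
    ss = np.random.SeedSequence(seed)
    rows = []
    for sample in trait_table.sample_ids:
        total = int(totals[sample])
        if depth > total:
            raise ValueError(
                f"sample {sample!r} has {total} instances, below depth {depth}"
            )
        rng = np.random.default_rng(ss.spawn(1)[0])
        sample_counts = counts[sample].to_numpy()
        # One set of rarefaction subsamples and one set of null draws per
        # sample; each category reads its richness off the same draws.
        obs_hits = [
            rng.multivariate_hypergeometric(sample_counts, depth) > 0
            for _ in range(n_reps)
        ]
        null_hits = [
            rng.multivariate_hypergeometric(pool, depth) > 0 for _ in range(n_null)
        ]
        for cat in cat_names:
            mask = masks[cat]
            if mask is None:
                obs = float(np.mean([h.sum() for h in obs_hits]))
                nulls = np.array([h.sum() for h in null_hits], dtype=float)
            else:
                obs = float(np.mean([(h & mask).sum() for h in obs_hits]))
                nulls = np.array([(h & mask).sum() for h in null_hits], dtype=float)
            assert obs <= pool_richness
            null_mean = float(nulls.mean())
            null_sd = float(nulls.std(ddof=1))
            degenerate = not (nulls.max() > nulls.min())
            ses = (obs - null_mean) / null_sd if not degenerate else np.nan
            rank, p_low, p_high = rank_test(obs, nulls)
            if degenerate:
                call = "degenerate" if obs != null_mean else "ns"
                if obs == null_mean:
                    degenerate = False
            elif p_low <= ALPHA:
                call = "depleted"
            elif p_high <= ALPHA:
                call = "enriched"
            else:
                call = "ns"
            rows.append(
                {
                    "sample": sample,
                    "namespace": trait_table.namespace,
                    "category": cat,
                    "depth": depth,
                    "n_reps": n_reps,
                    "n_null": n_null,
                    "obs_richness": obs,
                    "null_mean": null_mean,
                    "null_sd": null_sd,
                    "ses": ses,
                    "rank": rank,
                    "p_low": p_low,
                    "p_high": p_high,
                    "call": call,
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame(rows)
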