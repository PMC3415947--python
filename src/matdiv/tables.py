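"""In-memory containers for the study's tabular inputs.

A :class:`CommunityTable` is an OTU × sample integer count matrix with
per-sample metadata (core, collection year, layer label, depth interval in
mm). A :class:`TraitTable` is an ortholog-group × sample instance-count
matrix (KO/COG/NOG namespace) with an optional many-to-many category map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CommunityTable", "TraitTable", "POOL_SCOPES"]

#: Taxa-pool scopes: the candidate-colonist set for each sample is the set of
#: taxa detected anywhere in the study, within the sample's collection year,
#: or within the sample's core.
POOL_SCOPES = ("all", "per_year", "per_core")

_METADATA_COLUMNS = ("core", "year", "layer", "depth_top_mm", "depth_bottom_mm")


@dataclass
class CommunityTable:
    """Samples × taxa counts plus sample metadata.

    ``counts`` is indexed by taxon id with one column per sample id;
    ``metadata`` is indexed by sample id with columns core, year, layer,
    depth_top_mm, depth_bottom_mm (depth intervals are half-open
    [top, bottom) in mm).
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        counts = self.counts
        if not np.issubdtype(counts.to_numpy().dtype, np.number):
            raise ValueError("counts must be numeric")
        arr = counts.to_numpy()
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("counts must be non-negative integers")
        self.counts = counts.astype(np.int64)
        missing = set(counts.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"metadata missing samples: {sorted(missing)}")
        for col in _METADATA_COLUMNS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata missing column {col!r}")
        if (self.counts.sum(axis=0) == 0).any():
            empty = list(self.counts.columns[self.counts.sum(axis=0) == 0])
            raise ValueError(f"all-zero samples: {empty}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    def drop_empty_taxa(self) -> tuple["CommunityTable", int]:
        """Remove taxa absent from every sample; returns (table, n_dropped)."""
        keep = self.counts.sum(axis=1) > 0
        dropped = int((~keep).sum())
        if dropped == 0:
            return self, 0
        return CommunityTable(self.counts.loc[keep], self.metadata), dropped

    def scope_key(self, scope: str) -> pd.Series:
        """Grouping key per sample for a taxa-pool scope."""
        if scope == "all":
            return pd.Series("all", index=self.metadata.index)
        if scope == "per_year":
            return self.metadata["year"].astype(str)
        if scope == "per_core":
            return self.metadata["core"].astype(str)
        raise ValueError(f"unknown pool scope {scope!r}; expected one of {POOL_SCOPES}")

    def pool_groups(self, scope: str) -> list[tuple[str, list[str], list[str]]]:
        """Partition samples by pool scope.

        Returns (group label, sample ids, pool taxa) triples, where the pool
        is the sorted set of taxa detected in at least one sample of the
        group. Every sample's observed taxa are contained in its pool by
        construction.
        """
        key = self.scope_key(scope)
        out = []
        for label in sorted(key.loc[self.sample_ids].unique()):
            samples = [s for s in self.sample_ids if key[s] == label]
            block = self.counts[samples]
            pool = sorted(block.index[(block > 0).any(axis=1)])
            out.append((str(label), samples, pool))
        return out


@dataclass
class TraitTable:
    """Ortholog-group × sample instance counts with optional categories.

    ``categories`` maps a category name to the tuple of group ids it
    contains; a group may appear in several categories.
    """

    counts: pd.DataFrame
    namespace: str = "KO"
    categories: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if np.any(arr < 0) or np.any(arr != np.floor(arr)):
            raise ValueError("trait counts must be non-negative integers")
        self.counts = self.counts.astype(np.int64)
        if self.namespace not in ("KO", "COG", "NOG"):
            raise ValueError(f"unknown ortholog namespace {self.namespace!r}")
        known = set(self.counts.index)
        for cat, groups in self.categories.items():
            unknown = set(groups) - known
            if unknown:
                raise ValueError(
                    f"category {cat!r} references unknown groups: {sorted(unknown)[:5]}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def pooled_counts(self) -> pd.Series:
        """Instance-weighted pool: per-group instance totals over all samples."""
        return self.counts.sum(axis=1)
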