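"""Readers and writers for the study's plain-text formats, and the flat
analysis configuration.

All tabular IO is TSV with optional ``#``-prefixed provenance header lines;
trees are newick with internal-node support labels. The configuration is a
flat ``key = value`` text file (lists comma-separated, guilds as
``guild.<name> = <lineage substring>[,<substring>...]``).
"""

from __future__ import annotations

import hashlib
import io as _io
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .tables import CommunityTable, TraitTable
from .tree import DistanceMatrix, PhyloTree

__all__ = [
    "AnalysisConfig",
    "read_config",
    "write_config",
    "read_community_table",
    "write_community_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_trait_table",
    "write_trait_table",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_tsv",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------- tsv plumbing
def _provenance_lines(provenance: dict | None) -> str:
    if not provenance:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in provenance.items())


def write_tsv(df: pd.DataFrame, path, provenance: dict | None = None, index=True) -> None:
    """Write a DataFrame as TSV with optional provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(_provenance_lines(provenance) + buf.getvalue())


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# --------------------------------------------------------- community table
def read_community_table(path, metadata_path) -> CommunityTable:
    """Read an OTU × sample count TSV plus a sample-metadata TSV.

    Cells must be non-negative integers (a cell like ``3.5`` raises a parse
    error naming its row and column); taxa absent from every sample are
    dropped with a logged count; every sample must appear in the metadata.
    """
    raw = _read_tsv(path, index_col=0, dtype=str)
    counts = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=np.int64)
    for col in raw.columns:
        for row, cell in raw[col].items():
            try:
                value = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at taxon {row!r}, sample {col!r}"
                ) from None
            counts.at[row, col] = value
    metadata = _read_tsv(metadata_path, index_col=0)
    table = CommunityTable(counts, metadata)
    table, dropped = table.drop_empty_taxa()
    if dropped:
        logger.info("dropped %d taxa absent from every sample", dropped)
    return table


def write_community_table(
    table: CommunityTable, path, metadata_path, provenance: dict | None = None
) -> None:
    write_tsv(table.counts, path, provenance)
    write_tsv(table.metadata, metadata_path, provenance)


# --------------------------------------------------------------- taxonomy
def read_taxonomy(path) -> dict[str, str]:
    """OTU → semicolon-delimited lineage string."""
    df = _read_tsv(path, header=0, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("taxonomy file needs two columns: otu, lineage")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_taxonomy(taxonomy: dict[str, str], path, provenance: dict | None = None) -> None:
    df = pd.DataFrame(
        {"otu": list(taxonomy), "lineage": [taxonomy[k] for k in taxonomy]}
    )
    write_tsv(df, path, provenance, index=False)


# ------------------------------------------------------------ trait table
def read_trait_table(path, category_path=None) -> TraitTable:
    """Read an ortholog-group instance-count TSV (group_id, namespace, then
    one column per sample) and an optional group → category map TSV."""
    df = _read_tsv(path, dtype={0: str})
    if "group_id" not in df.columns or "namespace" not in df.columns:
        raise ValueError("trait table needs 'group_id' and 'namespace' columns")
    namespaces = df["namespace"].unique()
    if len(namespaces) != 1:
        raise ValueError(f"trait table mixes namespaces: {sorted(namespaces)}")
    counts = df.set_index("group_id").drop(columns=["namespace"]).astype(np.int64)
    counts.index.name = None
    categories: dict[str, tuple[str, ...]] = {}
    if category_path is not None:
        cmap = _read_tsv(category_path, dtype=str)
        if cmap.shape[1] < 2:
            raise ValueError("category map needs two columns: group_id, category")
        grouped: dict[str, list[str]] = {}
        for g, c in zip(cmap.iloc[:, 0], cmap.iloc[:, 1]):
            grouped.setdefault(c, []).append(g)
        categories = {c: tuple(sorted(gs)) for c, gs in grouped.items()}
    return TraitTable(counts=counts, namespace=str(namespaces[0]), categories=categories)


def write_trait_table(
    trait_table: TraitTable, path, category_path=None, provenance: dict | None = None
) -> None:
    df = trait_table.counts.copy()
    df.insert(0, "namespace", trait_table.namespace)
    df.index.name = "group_id"
    write_tsv(df, path, provenance)
    if category_path is not None:
        rows = [
            {"group_id": g, "category": c}
            for c in sorted(trait_table.categories)
            for g in trait_table.categories[c]
        ]
        write_tsv(pd.DataFrame(rows), category_path, provenance, index=False)


# -------------------------------------------------------- distance matrix
def write_distance_matrix(matrix, path, provenance: dict | None = None) -> None:
    """Write a labeled square distance matrix (DistanceMatrix or
    BetaDistanceMatrix) as TSV."""
    df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    write_tsv(df, path, provenance)


def read_distance_matrix(path) -> DistanceMatrix:
    df = _read_tsv(path, index_col=0)
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


# ------------------------------------------------------------------ config
@dataclass
class AnalysisConfig:
    """Configuration of a full study-shaped run.

    ``rarefy_depth`` is either the string ``"min"`` (rarefy to the smallest
    sample total, the study's policy) or a fixed integer depth. The
    dispersion stage runs the full factorial of null models × pool scopes ×
    weightings × support-collapse thresholds.
    """

    table: str = "table.tsv"
    metadata: str = "metadata.tsv"
    tree: str = "tree.nwk"
    taxonomy: str = "taxonomy.tsv"
    traits: str = "traits.tsv"
    categories: str = "categories.tsv"
    output_dir: str = "results"
    rarefy_depth: str | int = "min"
    n_rarefactions: int = 100
    n_null: int = 999
    trait_n_null: int = 1000
    q_min: float = 0.0
    q_max: float = 5.0
    q_step: float = 0.1
    null_models: tuple[str, ...] = ("independent_swap", "phylogeny_pool", "taxa_labels")
    pool_scopes: tuple[str, ...] = ("all", "per_year", "per_core")
    weightings: tuple[str, ...] = ("presence", "proportional")
    collapse_thresholds: tuple[float, ...] = (0.0, 50.0, 80.0)
    guilds: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0

    def q_grid(self) -> np.ndarray:
        n = int(round((self.q_max - self.q_min) / self.q_step))
        return np.round(self.q_min + self.q_step * np.arange(n + 1), 10)

    def to_text(self) -> str:
        lines = []
        for key in (
            "table", "metadata", "tree", "taxonomy", "traits", "categories",
            "output_dir", "rarefy_depth", "n_rarefactions", "n_null",
            "trait_n_null", "q_min", "q_max", "q_step", "seed",
        ):
            lines.append(f"{key} = {getattr(self, key)}")
        lines.append("null_models = " + ",".join(self.null_models))
        lines.append("pool_scopes = " + ",".join(self.pool_scopes))
        lines.append("weightings = " + ",".join(self.weightings))
        lines.append(
            "collapse_thresholds = " + ",".join(str(t) for t in self.collapse_thresholds)
        )
        for name in sorted(self.guilds):
            lines.append(f"guild.{name} = " + ",".join(self.guilds[name]))
        return "\n".join(lines) + "\n"

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_text().encode()).hexdigest()[:16]


_LIST_KEYS = {"null_models", "pool_scopes", "weightings", "collapse_thresholds"}
_INT_KEYS = {"n_rarefactions", "n_null", "trait_n_null", "seed"}
_FLOAT_KEYS = {"q_min", "q_max", "q_step"}


def read_config(path) -> AnalysisConfig:
    cfg = AnalysisConfig()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        value = value.strip()
        if key.startswith("guild."):
            cfg.guilds[key[len("guild."):]] = tuple(
                v.strip() for v in value.split(",") if v.strip()
            )
        elif key in _LIST_KEYS:
            items = tuple(v.strip() for v in value.split(",") if v.strip())
            if key == "collapse_thresholds":
                items = tuple(float(v) for v in items)
            setattr(cfg, key, items)
        elif key in _INT_KEYS:
            setattr(cfg, key, int(value))
        elif key in _FLOAT_KEYS:
            setattr(cfg, key, float(value))
        elif key == "rarefy_depth":
            cfg.rarefy_depth = "min" if value == "min" else int(value)
        elif hasattr(cfg, key):
            setattr(cfg, key, value)
        else:
            raise ValueError(f"line {lineno}: unknown config key {key!r}")
    _validate_config(cfg)
    return cfg


def _validate_config(cfg: AnalysisConfig) -> None:
    from .dispersion import _NULL_MODELS
    from .tables import POOL_SCOPES

    for m in cfg.null_models:
        if m not in _NULL_MODELS:
            raise ValueError(f"unknown null model {m!r}")
    for s in cfg.pool_scopes:
        if s not in POOL_SCOPES:
            raise ValueError(f"unknown pool scope {s!r}")
    for w in cfg.weightings:
        if w not in ("presence", "proportional"):
            raise ValueError(f"unknown weighting {w!r}")
    for t in cfg.collapse_thresholds:
        if not (0 <= t <= 100):
            raise ValueError(f"collapse threshold {t} outside [0, 100]")


def write_config(cfg: AnalysisConfig, path) -> None:
    Path(path).write_text(cfg.to_text())
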