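"""Synthetic mat-community generator.

Produces phylogenies, conserved traits, community samples, count tables and
ortholog-trait tables with the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without the study's (undeposited)
sequence data. The generative regimes are stand-ins for assembly processes,
not estimates of them:

* ``filtering`` — habitat filtering: taxa are admitted with weight
  exp(−strength · (trait − optimum)²) around a per-sample optimum, where the
  trait evolved by Brownian motion on the tree (phylogenetic niche
  conservatism), so strong filtering yields phylogenetically clustered
  communities;
* ``neutral`` — uniform sampling of taxa;
* ``competition`` — limiting similarity: greedy max–min cophenetic-distance
  selection, interpolating toward uniform as strength → 0, so strong
  competition yields overdispersed communities.

Sequencing is emulated as a multinomial draw over lognormal relative
abundances at a configurable depth. All generators are pure functions of
their arguments and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import CommunityTable, TraitTable
from .tree import PhyloTree

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_tree",
    "evolve_trait",
    "assemble_community",
    "sample_counts",
    "simulate_trait_table",
    "assign_taxonomy",
    "simulate_dataset",
    "simulate_mat_study",
    "DEFAULT_TRAIT_CATEGORIES",
]

REGIMES = ("filtering", "neutral", "competition")

DEFAULT_TRAIT_CATEGORIES = (
    "photosynthesis",
    "sulfur_metabolism",
    "carbohydrate_metabolism",
    "abc_transporters",
    "oxidative_phosphorylation",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic community study.

    Rates are per-lineage; ``trait_sigma`` is the Brownian-motion rate of the
    conserved niche trait; ``regime_strength`` = 0 collapses filtering and
    competition to the neutral regime; ``abundance_shape`` is the lognormal
    sigma of the rank-abundance distribution; ``sequencing_depths`` gives one
    sequencing depth per sample.
    """

    n_tips: int = 200
    birth_rate: float = 1.0
    death_rate: float = 0.0
    trait_sigma: float = 1.0
    regime: str = "neutral"
    regime_strength: float = 0.0
    n_samples: int = 5
    target_richness: int = 30
    sequencing_depths: tuple[int, ...] = (2000, 2000, 2000, 2000, 2000)
    abundance_shape: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 4:
            raise ValueError("n_tips must be at least 4")
        if self.target_richness > self.n_tips:
            raise ValueError("target_richness cannot exceed n_tips")
        if self.birth_rate <= 0 or self.trait_sigma <= 0 or self.abundance_shape <= 0:
            raise ValueError("rates must be positive")
        if self.death_rate < 0:
            raise ValueError("death_rate must be non-negative")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.regime_strength < 0:
            raise ValueError("regime_strength must be non-negative")
        if len(self.sequencing_depths) != self.n_samples:
            raise ValueError("need one sequencing depth per sample")


@dataclass
class SimulatedDataset:
    """A complete synthetic study with its ground truth."""

    tree: PhyloTree
    traits: dict[str, float]
    table: CommunityTable
    trait_table: TraitTable
    taxonomy: dict[str, str]
    truth: pd.DataFrame  # per sample: regime, strength


# ----------------------------------------------------------------- trees
def simulate_tree(
    n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0, seed: int = 0
) -> PhyloTree:
    """Simulate a rooted birth–death tree with exactly ``n_tips`` extant tips.

    Gillespie simulation from a crown pair of lineages, conditioned on
    reaching ``n_tips`` extant lineages without total extinction (extinct
    runs are restarted); extinct subtrees are pruned, so all branch lengths
    are positive. After the target is reached the tree is extended by the
    waiting time to the next (unrealized) event. Internal nodes carry
    bootstrap-like support values drawn uniformly on [0, 100]. Deterministic
    for a given seed. Tip labels are OTU0001, OTU0002, ...
    """
    if n_tips < 2:
        raise ValueError("n_tips must be at least 2")
    if birth_rate <= 0:
        raise ValueError("birth_rate must be positive")
    if death_rate < 0:
        raise ValueError("death_rate must be non-negative")
    rng = np.random.default_rng(seed)
    while True:
        nodes = _grow_birth_death(n_tips, birth_rate, death_rate, rng)
        if nodes is not None:
            break
    newick = _prune_to_newick(nodes, rng)
    return PhyloTree.from_newick(newick)


def _grow_birth_death(n_tips, birth_rate, death_rate, rng):
    # node: [parent, birth_time, end_time (None while active), children, alive]
    nodes = [
        [None, 0.0, None, [], True],
        [0, 0.0, None, [], True],
        [0, 0.0, None, [], True],
    ]
    nodes[0][2] = 0.0  # the crown root has zero age
    nodes[0][3] = [1, 2]
    nodes[0][4] = False
    active = [1, 2]
    t = 0.0
    total_rate = birth_rate + death_rate
    while len(active) < n_tips:
        if not active:
            return None  # extinct; restart
        t += rng.exponential(1.0 / (len(active) * total_rate))
        k = int(rng.integers(len(active)))
        node_id = active[k]
        if rng.random() < birth_rate / total_rate:
            nodes[node_id][2] = t
            nodes[node_id][4] = False
            for _ in range(2):
                nodes.append([node_id, t, None, [], True])
                nodes[node_id][3].append(len(nodes) - 1)
            active[k] = len(nodes) - 2
            active.append(len(nodes) - 1)
        else:
            nodes[node_id][2] = t
            nodes[node_id][4] = False
            active.pop(k)
    # observe the tree just before the next event would occur
    t += rng.exponential(1.0 / (len(active) * total_rate))
    for node_id in active:
        nodes[node_id][2] = t
    return nodes


def _prune_to_newick(nodes, rng) -> str:
    n_extant = sum(1 for nd in nodes if nd[4])
    width = max(4, len(str(n_extant)))
    counter = [0]

    def survives(i: int) -> bool:
        if nodes[i][4]:
            return True
        return any(survives(c) for c in nodes[i][3])

    def render(i: int, extra: float) -> str:
        parent, birth, end, children, alive = nodes[i]
        blen = (end - birth) + extra
        if alive:
            counter[0] += 1
            return f"OTU{counter[0]:0{width}d}:{blen!r}"
        kids = [c for c in children if survives(c)]
        if len(kids) == 1:  # suppress unifurcation, push length down
            return render(kids[0], extra + (end - birth))
        support = rng.uniform(0.0, 100.0)
        inner = ",".join(render(c, 0.0) for c in kids)
        return f"({inner}){support:.2f}:{blen!r}"

    root_kids = [c for c in nodes[0][3] if survives(c)]
    if len(root_kids) == 1:
        # one crown lineage died out entirely; its surviving sibling chain
        # becomes the root (depths measured from the original crown point)
        body = render(root_kids[0], 0.0)
        return f"({body});"
    inner = ",".join(render(c, 0.0) for c in root_kids)
    return f"({inner});"


# ----------------------------------------------------------------- traits
def evolve_trait(tree: PhyloTree, trait_sigma: float, seed: int = 0) -> dict[str, float]:
    """Brownian motion along branches from a root value of 0.

    The trait of a tip is N(0, trait_sigma² · T_i) with T_i its root-to-tip
    path length; sister tips on zero-length branches get identical values.
    """
    if trait_sigma <= 0:
        raise ValueError("trait_sigma must be positive")
    rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    values: dict[int, float] = {id(dtree.seed_node): 0.0}
    out: dict[str, float] = {}
    for nd in dtree.preorder_node_iter():
        if nd is dtree.seed_node:
            v = 0.0
            if nd.edge.length:
                v += rng.normal(0.0, trait_sigma * np.sqrt(nd.edge.length))
            values[id(nd)] = v
        else:
            elen = nd.edge.length
            if elen is None:
                raise ValueError("tree has a branch without a length")
            step = rng.normal(0.0, trait_sigma * np.sqrt(elen)) if elen > 0 else 0.0
            values[id(nd)] = values[id(nd.parent_node)] + step
        if nd.is_leaf():
            out[nd.taxon.label] = values[id(nd)]
    return out


# ------------------------------------------------------------ communities
def assemble_community(
    tree: PhyloTree,
    traits: dict[str, float],
    regime: str,
    regime_strength: float,
    target_richness: int,
    seed: int = 0,
    return_details: bool = False,
) -> list[str]:
    """Select ``target_richness`` taxa under an assembly regime.

    filtering: weighted sampling without replacement with weight
    exp(−strength · (trait − optimum)²), the optimum being the trait of a
    randomly chosen seed taxon (so different samples are filtered toward
    different clades). neutral: uniform. competition: greedy max–min
    cophenetic-distance selection from a random start; at each step the
    greedy pick is taken with probability 1 − exp(−strength), otherwise a
    uniform pick, so strength 0 is exactly neutral.

    With ``return_details`` a (taxa, info) pair is returned; for filtering,
    info records the seed taxon whose trait set the optimum.
    """
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    if regime_strength < 0:
        raise ValueError("regime_strength must be non-negative")
    labels = list(tree.tip_labels)
    n = len(labels)
    if not (1 <= target_richness <= n):
        raise ValueError("target_richness must be between 1 and the number of tips")
    rng = np.random.default_rng(seed)

    def result(indices, info):
        taxa = sorted(labels[i] for i in indices)
        return (taxa, info) if return_details else taxa

    if regime == "neutral" or regime_strength == 0:
        chosen = rng.choice(n, size=target_richness, replace=False)
        return result(chosen, {})
    if regime == "filtering":
        trait = np.array([traits[l] for l in labels])
        opt_idx = int(rng.integers(n))
        optimum = trait[opt_idx]
        logw = -regime_strength * (trait - optimum) ** 2
        # Gumbel top-k: weighted sampling without replacement
        scores = logw + rng.gumbel(size=n)
        chosen = np.argsort(scores)[-target_richness:]
        return result(chosen, {"optimum_taxon": labels[opt_idx], "optimum": float(optimum)})
    # competition
    d = tree.cophenetic_matrix().values
    p_greedy = 1.0 - np.exp(-regime_strength)
    selected = [int(rng.integers(n))]
    remaining = [i for i in range(n) if i != selected[0]]
    min_dist = d[selected[0], :].copy()
    while len(selected) < target_richness:
        if rng.random() < p_greedy:
            sub = np.array(remaining)
            pick = int(sub[np.argmax(min_dist[sub])])
        else:
            pick = remaining[int(rng.integers(len(remaining)))]
        selected.append(pick)
        remaining.remove(pick)
        min_dist = np.minimum(min_dist, d[pick, :])
    return result(selected, {"start_taxon": labels[selected[0]]})


def sample_counts(
    taxon_set, abundance_shape: float, depth: int, seed: int = 0
) -> pd.Series:
    """Emulate amplicon sequencing of a community.

    Relative abundances are drawn lognormal(0, abundance_shape) per taxon and
    normalized, then a single multinomial draw of ``depth`` sequences is
    taken; counts sum exactly to ``depth``.
    """
    taxa = list(taxon_set)
    if not taxa:
        raise ValueError("taxon set must be non-empty")
    if depth < 1:
        raise ValueError("depth must be at least 1")
    if abundance_shape <= 0:
        raise ValueError("abundance_shape must be positive")
    rng = np.random.default_rng(seed)
    rel = rng.lognormal(0.0, abundance_shape, size=len(taxa))
    p = rel / rel.sum()
    counts = rng.multinomial(depth, p)
    return pd.Series(counts, index=taxa)


# ----------------------------------------------------------- trait tables
def simulate_trait_table(
    n_samples: int,
    pool_size: int,
    category_map: dict[str, str] | None = None,
    per_sample_instances: int = 5000,
    enrichment: float = 1.0,
    enriched_category: str | None = None,
    sample_group_fractions=None,
    namespace: str = "KO",
    seed: int = 0,
) -> TraitTable:
    """Simulate an ortholog-group instance-count table.

    Each sample draws ``per_sample_instances`` gene instances from a shared
    pool of ``pool_size`` ortholog groups under a multinomial with uniform
    base weights; groups of ``enriched_category`` have their weight
    multiplied by ``enrichment`` (≥ 1). ``sample_group_fractions`` optionally
    restricts each sample to a random fraction of the pool's groups
    (one value in (0, 1] per sample), emulating functionally depleted layers.
    ``category_map`` maps group id → category; by default groups are assigned
    round-robin to the standard gene categories.
    """
    if enrichment < 1:
        raise ValueError("enrichment factor must be at least 1")
    if per_sample_instances < 1:
        raise ValueError("per_sample_instances must be at least 1")
    groups = [f"K{j + 1:05d}" for j in range(pool_size)]
    if category_map is None:
        cats = DEFAULT_TRAIT_CATEGORIES
        category_map = {g: cats[j % len(cats)] for j, g in enumerate(groups)}
    else:
        unknown = set(category_map) - set(groups)
        if unknown:
            raise ValueError(f"category map references unknown groups: {sorted(unknown)[:5]}")
    n_categories = len(set(category_map.values()))
    if pool_size < n_categories:
        raise ValueError("pool_size must be at least the number of categories")
    if sample_group_fractions is not None and len(sample_group_fractions) != n_samples:
        raise ValueError("need one group fraction per sample")
    rng = np.random.default_rng(seed)
    base = np.ones(pool_size)
    if enriched_category is not None:
        in_cat = np.array([category_map.get(g) == enriched_category for g in groups])
        base[in_cat] *= enrichment
    data = {}
    for s in range(n_samples):
        w = base.copy()
        if sample_group_fractions is not None:
            frac = float(sample_group_fractions[s])
            if not (0 < frac <= 1):
                raise ValueError("group fractions must lie in (0, 1]")
            k = max(1, int(round(frac * pool_size)))
            keep = rng.choice(pool_size, size=k, replace=False)
            mask = np.zeros(pool_size, dtype=bool)
            mask[keep] = True
            w[~mask] = 0.0
        data[f"S{s + 1:02d}"] = rng.multinomial(per_sample_instances, w / w.sum())
    counts = pd.DataFrame(data, index=groups)
    categories: dict[str, list[str]] = {}
    for g, c in category_map.items():
        categories.setdefault(c, []).append(g)
    return TraitTable(
        counts=counts,
        namespace=namespace,
        categories={c: tuple(sorted(gs)) for c, gs in categories.items()},
    )


# -------------------------------------------------------------- taxonomy
def assign_taxonomy(
    tree: PhyloTree, n_phyla: int = 6, n_orders_per_phylum: int = 3
) -> dict[str, str]:
    """Assign a synthetic lineage string to every tip by cutting the tree.

    The tree is split top-down into ``n_phyla`` monophyletic clades (always
    splitting the currently largest clade), and each phylum clade is split
    again into orders, yielding lineages like
    ``Bacteria;Phylum03;Order07``. Deterministic; no randomness involved.
    """
    dtree = tree.dendropy_tree

    def tips_below(node):
        return [lf.taxon.label for lf in node.leaf_iter()]

    def split(node_list, k):
        clades = list(node_list)
        while len(clades) < k:
            sizes = [len(tips_below(nd)) for nd in clades]
            j = int(np.argmax(sizes))
            nd = clades[j]
            kids = nd.child_nodes()
            if len(tips_below(nd)) < 2 or not kids:
                break
            clades.pop(j)
            clades.extend(kids)
        return clades

    phyla = split([dtree.seed_node], n_phyla)
    lineages: dict[str, str] = {}
    order_counter = 0
    for pi, pnode in enumerate(phyla, start=1):
        orders = split([pnode], n_orders_per_phylum)
        for onode in orders:
            order_counter += 1
            for tip in tips_below(onode):
                lineages[tip] = f"Bacteria;Phylum{pi:02d};Order{order_counter:02d}"
    return lineages


# ---------------------------------------------------------- full datasets
def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full study under one assembly regime for all samples."""
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4 + 2 * config.n_samples)]
    tree = simulate_tree(config.n_tips, config.birth_rate, config.death_rate, seeds[0])
    traits = evolve_trait(tree, config.trait_sigma, seeds[1])
    taxonomy = assign_taxonomy(tree)
    columns = {}
    truth_rows = []
    for s in range(config.n_samples):
        sample_id = f"S{s + 1:02d}"
        taxa = assemble_community(
            tree, traits, config.regime, config.regime_strength,
            config.target_richness, seeds[4 + 2 * s],
        )
        counts = sample_counts(
            taxa, config.abundance_shape, config.sequencing_depths[s], seeds[5 + 2 * s]
        )
        col = pd.Series(0, index=list(tree.tip_labels), dtype=np.int64)
        col[counts.index] = counts
        columns[sample_id] = col
        truth_rows.append(
            {"sample": sample_id, "regime": config.regime, "strength": config.regime_strength}
        )
    counts_df = pd.DataFrame(columns)
    metadata = pd.DataFrame(
        {
            "core": "C1",
            "year": 2010,
            "layer": [f"L{s + 1}" for s in range(config.n_samples)],
            "depth_top_mm": [2.0 * s for s in range(config.n_samples)],
            "depth_bottom_mm": [2.0 * (s + 1) for s in range(config.n_samples)],
        },
        index=list(columns),
    )
    table = CommunityTable(counts_df, metadata)
    trait_table = simulate_trait_table(
        n_samples=config.n_samples, pool_size=400, per_sample_instances=5000,
        seed=seeds[2],
    )
    trait_table.counts.columns = list(columns)
    return SimulatedDataset(
        tree=tree,
        traits=traits,
        table=table,
        trait_table=trait_table,
        taxonomy=taxonomy,
        truth=pd.DataFrame(truth_rows).set_index("sample"),
    )


#: Layer boundaries (mm) of the miniature study, mirroring a sectioned core.
_LAYERS = ((0.0, 2.0), (2.0, 5.0), (5.0, 8.0), (8.0, 10.0), (10.0, 15.0))


def simulate_mat_study(
    seed: int = 0,
    n_tips: int = 200,
    target_richness: int = 30,
    trait_sigma: float = 1.0,
    abundance_shape: float = 1.0,
) -> SimulatedDataset:
    """Miniature layered-mat study: 3 cores × 5 layers with depth-structured
    assembly.

    Two "old mat" cores (2010, 2011) and one "young mat" core (2010). The top
    layer assembles under mild competition and deeper layers under habitat
    filtering of increasing strength, emulating surface overdispersion over
    increasingly clustered deep layers; the young mat uses half-strength
    regimes. Sequencing depths are uneven with a smallest layer of 1071
    sequences.
    """
    ss = np.random.SeedSequence(seed)

    def next_seed():
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    tree = simulate_tree(n_tips, 1.0, 0.0, next_seed())
    traits = evolve_trait(tree, trait_sigma, next_seed())
    taxonomy = assign_taxonomy(tree)
    cores = (("OM-10", 2010, 1.0), ("YM-10", 2010, 0.5), ("OM-11", 2011, 1.0))
    regimes = (
        ("competition", 3.0),
        ("filtering", 3.0),
        ("filtering", 5.0),
        ("filtering", 8.0),
        ("filtering", 10.0),
    )
    depths = (5000, 4000, 3000, 2000, 1071)
    columns: dict[str, pd.Series] = {}
    meta_rows = []
    truth_rows = []
    for core, year, scale in cores:
        for li, ((top, bottom), (regime, strength), depth) in enumerate(
            zip(_LAYERS, regimes, depths), start=1
        ):
            sample_id = f"{core}_{int(top)}-{int(bottom)}mm"
            taxa = assemble_community(
                tree, traits, regime, strength * scale, target_richness, next_seed()
            )
            counts = sample_counts(taxa, abundance_shape, depth, next_seed())
            col = pd.Series(0, index=list(tree.tip_labels), dtype=np.int64)
            col[counts.index] = counts
            columns[sample_id] = col
            meta_rows.append(
                {
                    "sample": sample_id,
                    "core": core,
                    "year": year,
                    "layer": f"L{li}",
                    "depth_top_mm": top,
                    "depth_bottom_mm": bottom,
                }
            )
            truth_rows.append(
                {"sample": sample_id, "regime": regime, "strength": strength * scale}
            )
    counts_df = pd.DataFrame(columns)
    metadata = pd.DataFrame(meta_rows).set_index("sample")
    table = CommunityTable(counts_df, metadata)
    trait_table = simulate_trait_table(
        n_samples=len(_LAYERS),
        pool_size=600,
        per_sample_instances=8000,
        sample_group_fractions=(1.0, 0.8, 0.6, 0.5, 0.4),
        seed=next_seed(),
    )
    trait_table.counts.columns = [
        f"OM-10_{int(t)}-{int(b)}mm" for t, b in _LAYERS
    ]
    return SimulatedDataset(
        tree=tree,
        traits=traits,
        table=table,
        trait_table=trait_table,
        taxonomy=taxonomy,
        truth=pd.DataFrame(truth_rows).set_index("sample"),
    )
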