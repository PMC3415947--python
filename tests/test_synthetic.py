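"""The synthetic-data generator: trees, traits, communities, counts, traits
tables, and the regime calibration the dispersion tests rely on."""

import numpy as np
import pytest

from matdiv.synthetic import (
    SimulationConfig,
    assemble_community,
    assign_taxonomy,
    evolve_trait,
    sample_counts,
    simulate_dataset,
    simulate_mat_study,
    simulate_trait_table,
    simulate_tree,
)
from matdiv.tree import read_newick


def gillespie_depth_oracle(n_tips, birth, death, rng, n_reps):
    """Independent brute-force re-simulation of mean root-to-tip depth.

    Tracks only lineage counts and per-lineage origin times — no tree is
    built — and conditions on reaching n_tips without extinction exactly as
    the generator does (including the final waiting-time extension).
    """
    means = []
    total = birth + death
    while len(means) < n_reps:
        t, alive = 0.0, 2
        while 0 < alive < n_tips:
            t += rng.exponential(1.0 / (alive * total))
            alive += 1 if rng.random() < birth / total else -1
        if alive == 0:
            continue
        t += rng.exponential(1.0 / (alive * total))
        means.append(t)  # ultrametric in time: depth = elapsed time
    return np.array(means)


class TestSimulateTree:
    def test_smallest_valid_tree(self):
        tree = simulate_tree(2, 1.0, 0.0, seed=7)
        assert tree.n_tips == 2

    def test_seed_determinism(self):
        assert (
            simulate_tree(50, 1.0, 0.0, seed=7).to_newick()
            == simulate_tree(50, 1.0, 0.0, seed=7).to_newick()
        )

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, 1.0, 0.0, seed=0)

    def test_tip_count_supports_and_lengths(self):
        tree = simulate_tree(80, 1.0, 0.3, seed=2)
        assert tree.n_tips == 80
        lengths, _, depths = tree.branch_arrays()
        assert np.all(lengths > 0)
        assert np.all(depths > 0)
        sup = [s for s in tree.supports() if s is not None]
        assert sup and all(0 <= s <= 100 for s in sup)

    def test_birth_death_depth_matches_resimulation_oracle(self):
        """Mean root-to-tip depth of (200, λ=1, μ=0.5) trees against a
        1,000-replicate brute-force re-simulation, within 3 combined
        Monte-Carlo standard errors."""
        oracle = gillespie_depth_oracle(200, 1.0, 0.5, np.random.default_rng(0), 1000)
        sim = np.array(
            [simulate_tree(200, 1.0, 0.5, seed=3000 + i).tip_depths().mean() for i in range(40)]
        )
        se = np.sqrt(oracle.var() / oracle.size + sim.var() / sim.size)
        assert abs(sim.mean() - oracle.mean()) < 3 * se


class TestEvolveTrait:
    def test_star_tree_variance(self):
        """1,000 tips on unit branches, σ = 1: tip variance near 1."""
        newick = "(" + ",".join(f"T{i}:1" for i in range(1000)) + ");"
        traits = evolve_trait(read_newick(newick), 1.0, seed=1)
        assert 0.85 < np.var(list(traits.values())) < 1.15

    def test_zero_length_sisters_identical(self):
        tree = read_newick("((A:0,B:0):1,C:2);")
        traits = evolve_trait(tree, 1.0, seed=2)
        assert traits["A"] == traits["B"]

    def test_seed_determinism(self):
        tree = simulate_tree(30, 1.0, 0.0, seed=3)
        assert evolve_trait(tree, 1.0, seed=4) == evolve_trait(tree, 1.0, seed=4)

    def test_nonpositive_sigma_rejected(self):
        tree = simulate_tree(5, 1.0, 0.0, seed=0)
        with pytest.raises(ValueError):
            evolve_trait(tree, 0.0, seed=0)


class TestAssembleCommunity:
    def test_full_tip_set(self, tree200, traits200):
        out = assemble_community(tree200, traits200, "neutral", 0, 200, seed=0)
        assert out == sorted(tree200.tip_labels)

    def test_unknown_regime_rejected(self, tree200, traits200):
        with pytest.raises(ValueError):
            assemble_community(tree200, traits200, "mutualism", 1, 5, seed=0)

    @pytest.mark.parametrize("regime", ["filtering", "competition"])
    def test_zero_strength_is_distributionally_uniform(self, regime):
        """At strength 0 both structured regimes collapse to uniform: over
        2,000 draws each taxon's inclusion frequency stays within binomial
        99% bounds of richness/n_tips."""
        tree = simulate_tree(12, 1.0, 0.0, seed=5)
        traits = evolve_trait(tree, 1.0, seed=6)
        k, n = 4, 12
        counts = dict.fromkeys(tree.tip_labels, 0)
        for i in range(2000):
            for t in assemble_community(tree, traits, regime, 0, k, seed=i):
                counts[t] += 1
        p = k / n
        bound = 2.576 * np.sqrt(p * (1 - p) / 2000)
        for t, c in counts.items():
            assert abs(c / 2000 - p) < bound, t

    def test_regime_calibration_mean_level(self, tree200, traits200):
        """Filtering (strength 10) depresses mean MPD below the uniform-draw
        mean, competition raises it, neutral matches within 2 SEs; assessed
        over 100 replicates on a 200-tip tree."""
        d = tree200.cophenetic_matrix()
        rng = np.random.default_rng(7)

        def set_mpd(taxa):
            ix = d.index_of(taxa)
            sub = d.values[np.ix_(ix, ix)]
            return sub.sum() / (len(ix) * (len(ix) - 1))

        uniform = np.array(
            [set_mpd(rng.choice(d.labels, 30, replace=False)) for _ in range(400)]
        )
        results = {}
        for regime, strength in (("filtering", 10), ("competition", 10), ("neutral", 0)):
            vals = np.array(
                [
                    set_mpd(
                        assemble_community(tree200, traits200, regime, strength, 30, seed=i)
                    )
                    for i in range(100)
                ]
            )
            results[regime] = vals
        assert results["filtering"].mean() < uniform.mean()
        assert results["competition"].mean() > uniform.mean()
        se = np.sqrt(
            results["neutral"].var() / 100 + uniform.var() / uniform.size
        )
        assert abs(results["neutral"].mean() - uniform.mean()) < 2 * se


class TestSampleCounts:
    def test_single_taxon_gets_all_reads(self):
        out = sample_counts(["A"], 1.0, 500, seed=0)
        assert out["A"] == 500

    def test_counts_sum_to_depth_and_deterministic(self):
        a = sample_counts(list("ABCDE"), 1.0, 1234, seed=1)
        b = sample_counts(list("ABCDE"), 1.0, 1234, seed=1)
        assert a.sum() == 1234
        assert a.equals(b)

    def test_multinomial_frequencies_track_probabilities(self):
        """At depth 10⁶ the observed frequencies sit within 3 binomial SEs of
        the drawn relative abundances."""
        # recover the drawn abundances by replaying the generator's stream
        rng = np.random.default_rng(2)
        rel = rng.lognormal(0.0, 1.0, size=10)
        p = rel / rel.sum()
        out = sample_counts([f"T{i}" for i in range(10)], 1.0, 10**6, seed=2)
        freq = out.to_numpy() / 10**6
        se = np.sqrt(p * (1 - p) / 10**6)
        assert np.all(np.abs(freq - p) < 3 * se + 1e-12)

    def test_empty_taxon_set_rejected(self):
        with pytest.raises(ValueError):
            sample_counts([], 1.0, 10, seed=0)


class TestTraitTableSimulation:
    def test_unenriched_category_shares_match_pool(self):
        """With enrichment 1, each category's expected share of instances
        equals its share of the pool's groups (500 replicate tables)."""
        shares = []
        for rep in range(500):
            table = simulate_trait_table(
                n_samples=1, pool_size=50, per_sample_instances=200, seed=rep
            )
            counts = table.counts.iloc[:, 0]
            total = counts.sum()
            shares.append(
                {
                    c: counts.loc[list(groups)].sum() / total
                    for c, groups in table.categories.items()
                }
            )
        for cat in shares[0]:
            table = simulate_trait_table(n_samples=1, pool_size=50, per_sample_instances=200, seed=0)
            pool_share = len(table.categories[cat]) / 50
            mean_share = np.mean([s[cat] for s in shares])
            se = np.std([s[cat] for s in shares]) / np.sqrt(500)
            assert abs(mean_share - pool_share) < 4 * se + 1e-3

    def test_single_group_pool_richness_one(self):
        table = simulate_trait_table(
            n_samples=3, pool_size=1, category_map={"K00001": "photosynthesis"},
            per_sample_instances=100, seed=1,
        )
        assert ((table.counts > 0).sum(axis=0) == 1).all()

    def test_seed_determinism(self):
        a = simulate_trait_table(n_samples=2, pool_size=30, per_sample_instances=100, seed=2)
        b = simulate_trait_table(n_samples=2, pool_size=30, per_sample_instances=100, seed=2)
        assert a.counts.equals(b.counts)

    def test_enrichment_below_one_rejected(self):
        with pytest.raises(ValueError):
            simulate_trait_table(n_samples=1, pool_size=10, enrichment=0.5, seed=0)

    def test_enriched_category_overrepresented(self):
        table = simulate_trait_table(
            n_samples=1, pool_size=100, per_sample_instances=5000,
            enrichment=5.0, enriched_category="photosynthesis", seed=3,
        )
        counts = table.counts.iloc[:, 0]
        phot = counts.loc[list(table.categories["photosynthesis"])].sum()
        assert phot / counts.sum() > len(table.categories["photosynthesis"]) / 100


class TestDatasets:
    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_tips=3)
        with pytest.raises(ValueError):
            SimulationConfig(target_richness=300)
        with pytest.raises(ValueError):
            SimulationConfig(regime="weird")

    def test_dataset_conservation(self):
        cfg = SimulationConfig(
            n_tips=40, n_samples=3, target_richness=10,
            sequencing_depths=(500, 600, 700), seed=1,
        )
        ds = simulate_dataset(cfg)
        totals = ds.table.counts.sum(axis=0)
        np.testing.assert_array_equal(totals.to_numpy(), [500, 600, 700])
        present = set(ds.table.counts.index[(ds.table.counts > 0).any(axis=1)])
        assert present <= set(ds.tree.tip_labels)
        assert ((ds.table.counts > 0).sum(axis=0) <= 10).all()

    def test_mat_study_layout_and_determinism(self):
        a = simulate_mat_study(seed=5, n_tips=60, target_richness=12)
        b = simulate_mat_study(seed=5, n_tips=60, target_richness=12)
        assert a.table.counts.equals(b.table.counts)
        assert a.tree.to_newick() == b.tree.to_newick()
        assert len(a.table.sample_ids) == 15
        assert set(a.table.metadata["core"]) == {"OM-10", "YM-10", "OM-11"}
        assert int(a.table.counts.sum(axis=0).min()) == 1071
        assert set(a.truth["regime"]) == {"competition", "filtering"}

    def test_taxonomy_covers_all_tips(self, tree200):
        taxonomy = assign_taxonomy(tree200)
        assert set(taxonomy) == set(tree200.tip_labels)
        assert all(l.count(";") == 2 for l in taxonomy.values())
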