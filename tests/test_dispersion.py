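"""MPD, null models, standardized effect sizes, guild tests."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

from matdiv.dispersion import (
    SwapExhaustedWarning,
    guild_dispersion,
    guild_members,
    mpd,
    null_independent_swap,
    null_phylogeny_pool,
    null_taxa_labels,
    rank_test,
    ses_mpd,
)
from matdiv.synthetic import assign_taxonomy
from matdiv.tables import CommunityTable
from matdiv.tree import DistanceMatrix, read_newick

from conftest import make_study


def random_distance_matrix(n, rng, labels=None):
    x = rng.random((n, 2)) * 10
    d = np.hypot(*(x[:, None, :] - x[None, :, :]).transpose(2, 0, 1))
    labels = labels or tuple(f"T{i}" for i in range(n))
    return DistanceMatrix(tuple(labels), d)


class TestMPD:
    def test_single_pair(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 2.0], [2.0, 0.0]]))
        assert mpd(d, ["A", "B"]) == 2

    def test_equidistant_triple_both_weightings(self):
        d = DistanceMatrix(("A", "B", "C"), 5.0 * (1 - np.eye(3)))
        assert mpd(d, ["A", "B", "C"]) == 5
        assert mpd(d, {"A": 1, "B": 2, "C": 7}, "proportional") == pytest.approx(5)

    def test_proportional_equal_abundance_equals_presence(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            d = random_distance_matrix(20, rng)
            taxa = list(d.labels)[:12]
            equal = {t: 1.0 for t in taxa}
            assert mpd(d, equal, "proportional") == pytest.approx(
                mpd(d, taxa, "presence"), abs=1e-12
            )

    def test_fewer_than_two_taxa_rejected(self):
        d = DistanceMatrix(("A", "B"), np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValueError):
            mpd(d, ["A"])

    def test_matches_picante_oracle(self, tmp_path):
        """Cross-check against R picante::mpd.

        Presence weighting matches picante exactly. picante's abundance-
        weighted MPD averages over ordered pairs including self-pairs
        (denominator (Σn)²), while here self-pairs are excluded, so the two
        agree after multiplying picante's value by 1/(1 − Σp²).
        """
        rng = np.random.default_rng(3)
        d = random_distance_matrix(8, rng)
        counts = rng.integers(1, 20, 8)
        pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(tmp_path / "d.csv")
        pd.DataFrame([counts], columns=d.labels, index=["s1"]).to_csv(tmp_path / "c.csv")
        script = textwrap.dedent(
            """
            suppressMessages(library(picante))
            d <- as.matrix(read.csv(commandArgs(TRUE)[1], row.names=1))
            samp <- as.matrix(read.csv(commandArgs(TRUE)[2], row.names=1))
            cat(mpd(samp, d, abundance.weighted=FALSE), "\n")
            cat(mpd(samp, d, abundance.weighted=TRUE), "\n")
            """
        )
        (tmp_path / "mpd.R").write_text(script)
        out = subprocess.run(
            ["Rscript", str(tmp_path / "mpd.R"), str(tmp_path / "d.csv"), str(tmp_path / "c.csv")],
            capture_output=True, text=True, check=True,
        )
        r_presence, r_weighted = (float(x) for x in out.stdout.split())
        assert mpd(d, list(d.labels)) == pytest.approx(r_presence, rel=1e-6)
        p = counts / counts.sum()
        simpson = float(p @ p)
        abund = {t: int(c) for t, c in zip(d.labels, counts)}
        assert mpd(d, abund, "proportional") == pytest.approx(
            r_weighted / (1 - simpson), rel=1e-6
        )


class TestIndependentSwap:
    def test_only_checkerboard_swapped(self):
        out = null_independent_swap(np.array([[1, 0], [0, 1]]), 1, seed=0)
        np.testing.assert_array_equal(out, [[0, 1], [1, 0]])

    def test_no_checkerboard_warns_and_returns_input(self):
        with pytest.warns(SwapExhaustedWarning):
            out = null_independent_swap(np.array([[1, 1], [1, 1]]), 1, seed=0)
        np.testing.assert_array_equal(out, [[1, 1], [1, 1]])

    def test_margins_and_values_conserved(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            mat = rng.poisson(0.7, size=(rng.integers(3, 12), rng.integers(3, 12)))
            out = null_independent_swap(mat, 20, seed=rng)
            np.testing.assert_array_equal((out > 0).sum(0), (mat > 0).sum(0))
            np.testing.assert_array_equal((out > 0).sum(1), (mat > 0).sum(1))
            assert sorted(out.ravel()) == sorted(mat.ravel())


class TestTaxaLabels:
    def test_distance_multiset_invariant(self):
        rng = np.random.default_rng(2)
        d = random_distance_matrix(10, rng)
        out = null_taxa_labels(d, list(d.labels), seed=5)
        assert sorted(out.labels) == sorted(d.labels)
        np.testing.assert_array_equal(out.values, d.values)

    def test_pool_of_two(self):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(5, rng)
        out = null_taxa_labels(d, ["T0", "T1"], seed=1)
        assert out.labels[2:] == d.labels[2:]
        assert set(out.labels[:2]) == {"T0", "T1"}

    def test_permutations_uniform(self):
        """Each of the 24 permutations of a 4-label pool appears with
        frequency 1/24 within binomial 99% bounds over 24,000 draws."""
        rng = np.random.default_rng(4)
        d = random_distance_matrix(4, rng)
        from collections import Counter

        tally = Counter(
            null_taxa_labels(d, list(d.labels), rng).labels for _ in range(24000)
        )
        assert len(tally) == 24
        bound = 2.576 * np.sqrt((1 / 24) * (23 / 24) / 24000)
        for count in tally.values():
            assert abs(count / 24000 - 1 / 24) < bound


class TestPhylogenyPool:
    def test_richness_equal_pool_returns_pool(self):
        pool = [f"T{i}" for i in range(6)]
        out = null_phylogeny_pool(pool, pool, seed=0)
        assert sorted(out) == pool

    def test_single_draw_uniform(self):
        pool = [f"T{i}" for i in range(8)]
        rng = np.random.default_rng(1)
        from collections import Counter

        tally = Counter(null_phylogeny_pool(["T0"], pool, rng)[0] for _ in range(10000))
        bound = 2.576 * np.sqrt((1 / 8) * (7 / 8) / 10000)
        for t in pool:
            assert abs(tally[t] / 10000 - 1 / 8) < bound

    def test_deterministic_and_abundance_reassignment(self):
        pool = [f"T{i}" for i in range(10)]
        a = null_phylogeny_pool(["T0", "T3"], pool, 7, abundances={"T0": 5, "T3": 9})
        b = null_phylogeny_pool(["T0", "T3"], pool, 7, abundances={"T0": 5, "T3": 9})
        assert a == b
        assert sorted(a.values()) == [5, 9]


class TestRankTest:
    def test_printed_rank_convention(self):
        """An observed value ranked 15th among 999 nulls gives p = 0.015."""
        nulls = np.arange(1.0, 1000.0)
        rank, p_low, p_high = rank_test(14.5, nulls)
        assert rank == 15
        assert p_low == pytest.approx(0.015)
        assert p_high == pytest.approx((999 + 2 - 15) / 1000)

    def test_ties_mid_ranked(self):
        rank, p_low, _ = rank_test(5.0, np.array([1.0, 5.0, 5.0, 9.0]))
        assert rank == 1 + 1 + 1.0  # one below, two ties / 2
        assert p_low == pytest.approx(3 / 5)


class TestSesMPD:
    def test_sample_equal_to_pool_is_degenerate(self, tree200):
        labels = list(tree200.tip_labels)[:40]
        sub = tree200.prune_to_tips(labels)
        counts = pd.DataFrame({"S1": np.arange(1, 41)}, index=labels)
        meta = pd.DataFrame(
            {"core": "C", "year": 2010, "layer": "L1",
             "depth_top_mm": 0.0, "depth_bottom_mm": 2.0},
            index=["S1"],
        )
        res = ses_mpd(
            CommunityTable(counts, meta), sub, null_model="taxa_labels",
            n_null=99, seed=0,
        )
        assert bool(res["degenerate"].iloc[0])
        assert res["call"].iloc[0] == "degenerate"
        assert np.isnan(res["ses"].iloc[0])

    def test_filtering_detected_as_clustered(self, tree200, traits200):
        table = make_study(tree200, traits200, "filtering", 10, 6, seed=1)
        res = ses_mpd(table, tree200, null_model="taxa_labels", n_null=199, seed=2)
        assert res["ses"].mean() < 0

    def test_deterministic_given_seed(self, tree200, traits200):
        table = make_study(tree200, traits200, "neutral", 0, 3, seed=3)
        a = ses_mpd(table, tree200, null_model="phylogeny_pool", n_null=99, seed=5)
        b = ses_mpd(table, tree200, null_model="phylogeny_pool", n_null=99, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_rarefaction_inside_loop(self, tree200, traits200):
        table = make_study(tree200, traits200, "neutral", 0, 3, seed=4, depth=500)
        res = ses_mpd(
            table, tree200, null_model="taxa_labels", n_null=99,
            rarefy_depth="min", n_rarefactions=5, seed=6,
        )
        assert len(res) == 3
        assert np.isfinite(res["obs_mpd"]).all()

    def test_pool_scope_nesting(self, tree200, traits200):
        """Per-core pools are subsets of per-year pools which are subsets of
        the global pool."""
        table = make_study(tree200, traits200, "neutral", 0, 6, seed=7)
        meta = table.metadata.copy()
        meta["core"] = ["C1"] * 3 + ["C2"] * 3
        meta["year"] = [2010] * 6
        table = CommunityTable(table.counts, meta)
        pools = {
            scope: {g: set(pool) for g, _, pool in table.pool_groups(scope)}
            for scope in ("all", "per_year", "per_core")
        }
        for core_pool in pools["per_core"].values():
            assert core_pool <= pools["per_year"]["2010"] <= pools["all"]["all"]


class TestGuilds:
    def test_match_all_guild_equals_domain_result(self, tree200, traits200):
        table = make_study(tree200, traits200, "filtering", 5, 4, seed=8)
        taxonomy = assign_taxonomy(tree200)
        domain = ses_mpd(table, tree200, null_model="taxa_labels", n_null=99, seed=9)
        via_guild = guild_dispersion(
            table, tree200, taxonomy, {"everything": ("Bacteria",)},
            null_model="taxa_labels", n_null=99, seed=9,
        )
        pd.testing.assert_frame_equal(
            domain.drop(columns="guild"), via_guild.drop(columns="guild")
        )

    def test_disjoint_guilds_partition_taxa(self, tree200):
        taxonomy = assign_taxonomy(tree200)
        phyla = sorted({l.split(";")[1] for l in taxonomy.values()})
        members = [set(guild_members(taxonomy, [p], tree200.tip_labels)) for p in phyla]
        assert set().union(*members) == set(tree200.tip_labels)
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                assert not (members[i] & members[j])

    def test_guild_signal_weaker_than_domain(self):
        """Habitat filtering clusters the whole community, but within the
        guild (clade) that contains the filtering optimum the admitted
        members are close to a random draw from the guild's own pool, so
        guild-level SES sits nearer zero than domain-level SES."""
        from matdiv.synthetic import (
            assemble_community,
            evolve_trait,
            sample_counts,
            simulate_tree,
        )

        domain_ses, guild_ses = [], []
        for rep in range(12):
            tree = simulate_tree(200, 1.0, 0.0, seed=300 + rep)
            traits = evolve_trait(tree, 1.0, seed=400 + rep)
            taxonomy = assign_taxonomy(tree)
            cols, opt_phylum = {}, {}
            for s in range(4):
                taxa, info = assemble_community(
                    tree, traits, "filtering", 10, 30,
                    seed=rep * 10 + s, return_details=True,
                )
                counts = sample_counts(taxa, 1.0, 2000, seed=rep * 100 + s)
                col = pd.Series(0, index=list(tree.tip_labels), dtype=np.int64)
                col[counts.index] = counts
                sid = f"S{s}"
                cols[sid] = col
                opt_phylum[sid] = taxonomy[info["optimum_taxon"]].split(";")[1]
            meta = pd.DataFrame(
                {"core": "C", "year": 2010, "layer": [f"L{i}" for i in range(4)],
                 "depth_top_mm": np.arange(4.0), "depth_bottom_mm": np.arange(1.0, 5.0)},
                index=list(cols),
            )
            table = CommunityTable(pd.DataFrame(cols), meta)
            domain = ses_mpd(
                table, tree, null_model="taxa_labels", n_null=199, seed=rep
            ).set_index("sample")
            phyla = sorted(set(opt_phylum.values()))
            sub = guild_dispersion(
                table, tree, taxonomy, {p: (p,) for p in phyla},
                null_model="taxa_labels", n_null=199, seed=rep,
            )
            for sid, ph in opt_phylum.items():
                row = sub[(sub["sample"] == sid) & (sub["guild"] == ph)]
                if len(row) and not row["degenerate"].iloc[0]:
                    guild_ses.append(float(row["ses"].iloc[0]))
                    domain_ses.append(float(domain.loc[sid, "ses"]))
        assert np.mean(domain_ses) < 0
        assert abs(np.mean(guild_ses)) < abs(np.mean(domain_ses))
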