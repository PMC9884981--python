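"""OTU-table cleaning, rarefaction, filtering, Venn and aggregation."""

import numpy as np
import pandas as pd
import pytest

from rotipop import (
    OtuTable,
    abundance_filter,
    aggregate_taxonomy,
    rarefy,
    remove_chloroplast,
    remove_singletons,
    shared_fraction,
    top_k_taxa,
    venn_partition,
)


def tiny_table(counts, taxonomy=None, groups=None):
    """Build an OtuTable from a dict sample -> list of counts."""
    counts = pd.DataFrame(counts).T
    counts.columns = [f"OTU{i + 1}" for i in range(counts.shape[1])]
    n_otus = counts.shape[1]
    if taxonomy is None:
        taxonomy = [
            f"d__Bacteria;p__P;c__C;o__O{i};f__F{i};g__G{i};s__"
            for i in range(n_otus)
        ]
    meta = pd.DataFrame(
        {
            "group": groups or ["A"] * len(counts),
            "stage": "T1",
            "replicate": range(1, len(counts) + 1),
        },
        index=counts.index,
    )
    return OtuTable(
        counts=counts.astype(int),
        taxonomy=pd.Series(taxonomy, index=counts.columns),
        metadata=meta,
    )


CHLORO = "d__Bacteria;p__Cyanobacteria;c__Cyanophyceae;o__Chloroplast;f__;g__;s__"


class TestChloroplastFilter:
    def test_removes_lineage_with_token(self):
        t = tiny_table(
            {"s1": [5, 5, 5]},
            taxonomy=["d__B;p__;c__;o__X;f__;g__;s__", CHLORO,
                      "d__B;p__;c__;o__Y;f__;g__;s__"],
        )
        out, removed = remove_chloroplast(t)
        assert removed == ["OTU2"]
        assert out.otu_ids == ["OTU1", "OTU3"]

    def test_identity_when_no_chloroplast(self):
        t = tiny_table({"s1": [5, 5]})
        out, removed = remove_chloroplast(t)
        assert removed == [] and out.counts.equals(t.counts)

    def test_matches_generator_ground_truth(self, small_otu_table):
        table, truth = small_otu_table
        out, removed = remove_chloroplast(table)
        assert sorted(removed) == sorted(truth["chloroplast_otus"])

    def test_idempotent(self, small_otu_table):
        table, _ = small_otu_table
        once, _ = remove_chloroplast(table)
        twice, removed2 = remove_chloroplast(once)
        assert removed2 == [] and twice.counts.equals(once.counts)


class TestSingletonFilter:
    def test_total_of_one_removed_total_of_two_kept(self):
        t = tiny_table({"s1": [1, 2, 0], "s2": [0, 0, 1]})
        out, removed = remove_singletons(t)
        assert set(removed) == {"OTU1", "OTU3"}
        assert out.otu_ids == ["OTU2"]

    def test_matches_mask_by_total_oracle(self, small_otu_table, global_rng):
        table, _ = small_otu_table
        out, removed = remove_singletons(table)
        totals = table.counts.sum(axis=0)
        assert set(removed) == set(totals.index[totals == 1])

    def test_idempotent(self, small_otu_table):
        table, _ = small_otu_table
        once, _ = remove_singletons(table)
        twice, removed = remove_singletons(once)
        assert removed == []


class TestRarefaction:
    def test_every_sample_hits_exact_depth(self, small_otu_table):
        table, _ = small_otu_table
        out = rarefy(table, depth=1000, seed=1)
        assert (out.sample_totals == 1000).all()

    def test_auto_min_keeps_all_samples(self, small_otu_table):
        table, _ = small_otu_table
        out = rarefy(table, seed=1)
        assert set(out.sample_ids) == set(table.sample_ids)
        assert (out.sample_totals == int(table.sample_totals.min())).all()

    def test_sample_at_depth_unchanged(self):
        t = tiny_table({"s1": [3, 4, 3], "s2": [10, 5, 5]})
        out = rarefy(t, depth=10, seed=0)
        assert out.counts.loc["s1"].tolist() == [3, 4, 3]

    def test_explicit_depth_drops_shallow_samples_with_warning(self):
        t = tiny_table({"s1": [2, 2], "s2": [50, 50]})
        with pytest.warns(UserWarning, match="below depth"):
            out = rarefy(t, depth=20, seed=0)
        assert out.sample_ids == ["s2"]

    def test_hypergeometric_expectation(self):
        # E[rarefied count] = depth * count / total
        t = tiny_table({"s1": [60, 30, 10]})
        draws = np.array(
            [rarefy(t, depth=50, seed=s).counts.loc["s1"].to_numpy()
             for s in range(1000)]
        )
        mean = draws.mean(axis=0)
        expect = 50 * np.array([60, 30, 10]) / 100
        # hypergeometric SD with finite-population correction
        n_tot, d = 100, 50
        var = d * (np.array([60, 30, 10]) / n_tot) * (1 - np.array([60, 30, 10]) / n_tot) * (n_tot - d) / (n_tot - 1)
        se = np.sqrt(var / 1000)
        assert np.all(np.abs(mean - expect) < 3 * se)

    def test_seed_reproducible(self, small_otu_table):
        table, _ = small_otu_table
        a = rarefy(table, depth=1200, seed=7)
        b = rarefy(table, depth=1200, seed=7)
        assert a.counts.equals(b.counts)

    def test_nonpositive_depth_rejected(self, small_otu_table):
        table, _ = small_otu_table
        with pytest.raises(ValueError):
            rarefy(table, depth=0)


class TestAbundanceFilter:
    def test_below_threshold_everywhere_removed(self):
        # OTU2 at 0.5% in both samples
        t = tiny_table({"s1": [995, 5], "s2": [995, 5]})
        for mode in ("any-sample", "mean"):
            out = abundance_filter(t, threshold=0.01, mode=mode)
            assert out.otu_ids == ["OTU1"]

    def test_single_sample_spike_kept_in_any_sample_mode(self):
        t = tiny_table({"s1": [980, 20], "s2": [999, 1]})  # 2% then 0.1%
        assert "OTU2" in abundance_filter(t, 0.01, "any-sample").otu_ids
        # mean is (2% + 0.1%)/2 > 1% too; tighten to see the modes differ
        assert "OTU2" not in abundance_filter(t, 0.015, "mean").otu_ids
        assert "OTU2" in abundance_filter(t, 0.015, "any-sample").otu_ids

    def test_matches_brute_force_oracle(self, small_otu_table):
        table, _ = small_otu_table
        rel = table.counts.div(table.counts.sum(axis=1), axis=0)
        for mode, stat in (("any-sample", rel.max()), ("mean", rel.mean())):
            out = abundance_filter(table, 0.01, mode)
            assert set(out.otu_ids) == set(stat.index[stat > 0.01])

    def test_idempotent(self, small_otu_table):
        table, _ = small_otu_table
        once = abundance_filter(table, 0.01)
        twice = abundance_filter(once, 0.01)
        # a second pass can only re-evaluate on identical compositions
        assert twice.otu_ids == once.otu_ids


class TestVenn:
    def test_three_set_worked_example(self):
        # sets {a,b,c}, {b,c,d}, {c,e} by OTU presence
        counts = {
            "s1": [1, 1, 1, 0, 0],  # group A: a,b,c
            "s2": [0, 1, 1, 1, 0],  # group B: b,c,d
            "s3": [0, 0, 1, 0, 1],  # group C: c,e
        }
        t = tiny_table(counts, groups=["A", "B", "C"])
        regions = venn_partition(t, by="group")
        assert regions[frozenset(["A"])] == 1  # a
        assert regions[frozenset(["B"])] == 1  # d
        assert regions[frozenset(["C"])] == 1  # e
        assert regions[frozenset(["A", "B", "C"])] == 1  # c
        assert regions[frozenset(["A", "B"])] == 1  # b
        assert sum(regions.values()) == 5

    def test_identical_groups_all_shared(self):
        t = tiny_table({"s1": [1, 2], "s2": [3, 4]}, groups=["A", "B"])
        regions = venn_partition(t, by="group")
        assert regions[frozenset(["A", "B"])] == 2
        assert regions[frozenset(["A"])] == 0

    def test_matches_set_algebra_oracle(self, small_otu_table):
        table, _ = small_otu_table
        regions = venn_partition(table, by="group")
        sets = {}
        for g in table.metadata["group"].unique():
            samples = table.metadata.index[table.metadata["group"] == g]
            present = table.counts.loc[samples].sum(axis=0) > 0
            sets[g] = set(present.index[present])
        a, b, c = (sets[g] for g in sorted(sets))
        assert regions[frozenset([sorted(sets)[0]])] == len(a - b - c)
        assert regions[frozenset(sorted(sets))] == len(a & b & c)
        assert sum(regions.values()) == len(a | b | c)

    def test_region_counts_sum_to_union(self, small_otu_table):
        table, _ = small_otu_table
        regions = venn_partition(table, by="group")
        present_anywhere = (table.counts.sum(axis=0) > 0).sum()
        assert sum(regions.values()) == present_anywhere

    def test_more_than_three_levels_unsupported(self, small_otu_table):
        table, _ = small_otu_table
        with pytest.raises(ValueError, match="2-3 levels"):
            venn_partition(table, by="stage")


class TestSharedFraction:
    @pytest.mark.parametrize(
        "shared,total,expected",
        [(0, 50, 0.0), (50, 50, 100.0), (1, 3, 33.33)],
    )
    def test_values(self, shared, total, expected):
        assert shared_fraction(shared, total) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            shared_fraction(0, 0)


class TestTaxonomyAggregation:
    def test_same_family_otus_summed(self):
        tax = [
            "d__B;p__P;c__C;o__O;f__Fam1;g__Ga;s__",
            "d__B;p__P;c__C;o__O;f__Fam1;g__Gb;s__",
            "d__B;p__P;c__C;o__O;f__Fam2;g__Gc;s__",
        ]
        t = tiny_table({"s1": [3, 4, 5]}, taxonomy=tax)
        agg = aggregate_taxonomy(t, "family")
        assert agg.loc["s1", "Fam1"] == 7
        assert agg.loc["s1", "Fam2"] == 5

    def test_aggregation_conserves_sample_totals(self, small_otu_table):
        table, _ = small_otu_table
        for rank in ("phylum", "order", "genus"):
            agg = aggregate_taxonomy(table, rank)
            assert agg.sum(axis=1).equals(table.counts.sum(axis=1))

    def test_unresolved_rank_labelled_by_parent(self):
        tax = ["d__B;p__P;c__Alpha;o__;f__;g__;s__"]
        t = tiny_table({"s1": [9]}, taxonomy=tax)
        agg = aggregate_taxonomy(t, "order")
        assert list(agg.columns) == ["unclassified Alpha"]

    def test_unknown_rank_rejected(self, small_otu_table):
        table, _ = small_otu_table
        with pytest.raises(ValueError, match="rank"):
            aggregate_taxonomy(table, "kingdom")

    def test_top_k_matches_sort_oracle(self):
        counts = {"s1": [50, 30, 15, 5], "s2": [10, 60, 25, 5]}
        t = tiny_table(counts)
        agg = aggregate_taxonomy(t, "genus")
        rel = agg.div(agg.sum(axis=1), axis=0)
        order = rel.mean().sort_values(ascending=False)
        assert top_k_taxa(agg, k=2) == list(order.index[:2])

    def test_top_k_ties_break_lexicographically(self):
        t = tiny_table({"s1": [10, 10, 10]})
        agg = aggregate_taxonomy(t, "genus")
        assert top_k_taxa(agg, k=2) == ["G0", "G1"]
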