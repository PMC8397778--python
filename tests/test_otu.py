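"""zOTU -> OTU processing: distances, clustering, phylum mode, filters, rarefaction."""

import numpy as np
import pandas as pd
import pytest

from soilsdm.containers import DistanceMatrix, SimilarityScores, ZOtuTable
from soilsdm.otu import (
    aggregate_counts,
    assign_phylum,
    filter_low_count_zotus,
    filter_low_prevalence_otus,
    rarefy,
    similarity_to_distance,
    single_linkage_cluster,
)

from conftest import brute_force_single_linkage


def _sim(ids, mat):
    return SimilarityScores(ids=tuple(ids), sim=np.array(mat, dtype=float))


def _dist(ids, mat):
    return DistanceMatrix(ids=tuple(ids), dist=np.array(mat, dtype=float))


class TestSimilarityToDistance:
    def test_identical_sequences_are_at_distance_zero(self):
        sm = _sim("ab", [[80, 80], [80, 80]])
        assert similarity_to_distance(sm).dist[0, 1] == 0.0

    def test_hand_computed_example(self):
        sm = _sim("ab", [[100, 70], [70, 90]])
        d = similarity_to_distance(sm)
        # 100 + 90 - 2*70 = 50
        assert d.dist[0, 1] == 50.0
        assert d.dist[1, 0] == 50.0

    def test_diagonal_zero_and_symmetric_on_random_fixtures(self):
        from soilsdm.synthetic import generate_similarity_fixture

        _, sm = generate_similarity_fixture(10, seed=7)
        d = similarity_to_distance(sm)
        assert np.all(np.diag(d.dist) == 0.0)
        assert np.array_equal(d.dist, d.dist.T)

    def test_asymmetric_input_rejected_naming_pair(self):
        with pytest.raises(ValueError, match="asymmetric"):
            _sim("ab", [[100, 60], [70, 90]])


class TestSingleLinkage:
    def test_cutoff_below_all_distances_gives_singletons(self):
        d = _dist("abc", [[0, 10, 20], [10, 0, 30], [20, 30, 0]])
        part = single_linkage_cluster(d, cutoff=5)
        assert sorted(len(v) for v in part.values()) == [1, 1, 1]

    def test_chaining_merges_through_intermediate(self):
        d = _dist("ABC", [[0, 10, 30], [10, 0, 10], [30, 10, 0]])
        part = single_linkage_cluster(d, cutoff=15)
        assert len(part) == 1
        assert sorted(part["C001"]) == ["A", "B", "C"]

    def test_negative_cutoff_rejected(self):
        d = _dist("ab", [[0, 1], [1, 0]])
        with pytest.raises(ValueError, match="cutoff"):
            single_linkage_cluster(d, -1)

    def test_matches_brute_force_oracle_on_seeded_fixtures(
        self, random_distance_matrix_factory
    ):
        """100 random fixtures (<=12 items) x cutoffs 20/40/60 against an
        independent agglomerative implementation."""
        for seed in range(100):
            n = 3 + seed % 10
            dmat = random_distance_matrix_factory(n, seed)
            ids = tuple(f"z{i}" for i in range(n))
            d = DistanceMatrix(ids=ids, dist=dmat)
            for cutoff in (20.0, 40.0, 60.0):
                got = {frozenset(ids.index(m) for m in v)
                       for v in single_linkage_cluster(d, cutoff).values()}
                want = {frozenset(c) for c in brute_force_single_linkage(dmat, cutoff)}
                assert got == want, f"seed={seed} cutoff={cutoff}"

    def test_cluster_count_non_increasing_in_cutoff(self, random_distance_matrix_factory):
        for seed in range(20):
            dmat = random_distance_matrix_factory(10, seed + 500)
            d = DistanceMatrix(ids=tuple(f"z{i}" for i in range(10)), dist=dmat)
            ns = [len(single_linkage_cluster(d, c)) for c in (20.0, 40.0, 60.0)]
            assert ns[0] >= ns[1] >= ns[2]

    def test_zero_cutoff_all_distinct_gives_one_cluster_per_item(
        self, random_distance_matrix_factory
    ):
        dmat = random_distance_matrix_factory(8, 3)
        d = DistanceMatrix(ids=tuple(f"z{i}" for i in range(8)), dist=dmat)
        assert len(single_linkage_cluster(d, 0.0)) == 8


class TestAssignPhylum:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            (["Acidobacteria"] * 3 + ["Proteobacteria"], "Acidobacteria"),
            (["Acidobacteria", "Acidobacteria", "Firmicutes", "Firmicutes"], "Acidobacteria"),
            ([None, None], "Unclassified"),
            (["NotARealPhylum"], "Other"),
            (["NotARealPhylum", "NotARealPhylum", "Firmicutes"], "Other"),
        ],
    )
    def test_mode_with_tie_break_and_missing_rules(self, labels, expected):
        assert assign_phylum(labels) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            assign_phylum([])


def _zotu_table(counts, taxonomy=None, lib=None):
    counts = pd.DataFrame(counts)
    taxonomy = pd.Series(taxonomy if taxonomy is not None else "Firmicutes",
                         index=counts.index)
    lib = pd.Series(lib if lib is not None else counts.sum(axis=0) + 10,
                    index=counts.columns)
    return ZOtuTable(counts=counts, taxonomy=taxonomy, library_sizes=lib)


class TestAggregateCounts:
    def test_singleton_partition_is_identity(self):
        zt = _zotu_table({"s1": {"a": 3, "b": 2}, "s2": {"a": 0, "b": 5}})
        out = aggregate_counts(zt, {"a": ["a"], "b": ["b"]})
        assert out.counts.loc["a"].tolist() == zt.counts.loc["a"].tolist()

    def test_merging_sums_counts(self):
        zt = _zotu_table({"s1": {"a": 3, "b": 2}, "s2": {"a": 0, "b": 5}})
        out = aggregate_counts(zt, {"m": ["a", "b"]})
        assert out.counts.loc["m"].tolist() == [5, 5]

    def test_grand_total_conserved_under_any_partition(self, rng):
        counts = pd.DataFrame(rng.integers(0, 20, (6, 4)),
                              index=list("abcdef"), columns=[f"s{i}" for i in range(4)])
        zt = _zotu_table(counts)
        out = aggregate_counts(zt, {"g1": ["a", "c", "e"], "g2": ["b"], "g3": ["d", "f"]})
        assert out.counts.to_numpy().sum() == counts.to_numpy().sum()

    def test_partition_mismatch_rejected(self):
        zt = _zotu_table({"s1": {"a": 3, "b": 2}})
        with pytest.raises(ValueError, match="partition"):
            aggregate_counts(zt, {"m": ["a"]})


class TestFilters:
    def test_total_count_threshold_is_strict(self):
        counts = pd.DataFrame({"s1": {"lo": 99, "hi": 100}})
        zt = _zotu_table(counts, lib={"s1": 500})
        out = filter_low_count_zotus(zt, min_total=100)
        assert out.zotu_ids == ["hi"]
        # library sizes are pre-filter totals and stay unchanged
        assert out.library_sizes["s1"] == 500

    def test_zero_min_total_is_identity(self, small_dataset):
        zt = _zotu_table(pd.DataFrame({"s1": {"a": 0, "b": 1}}), lib={"s1": 5})
        assert filter_low_count_zotus(zt, min_total=0).zotu_ids == ["a", "b"]

    def test_prevalence_threshold_counts_sites_with_any_reads(self, small_dataset):
        otus = small_dataset.counts
        n_sites = len(otus.site_ids)
        present_20 = np.zeros(n_sites, dtype=int); present_20[:20] = 1
        present_21 = np.zeros(n_sites, dtype=int); present_21[:21] = 1
        counts = pd.DataFrame([present_20, present_21, np.zeros(n_sites, dtype=int)],
                              index=["p20", "p21", "absent"], columns=otus.site_ids)
        tab = type(otus)(counts=counts,
                         phylum=pd.Series("Firmicutes", index=counts.index),
                         library_sizes=otus.library_sizes)
        out = filter_low_prevalence_otus(tab, min_sites=21)
        assert out.otu_ids == ["p21"]

    def test_prevalence_filter_commutes_with_site_permutation(self, small_dataset):
        otus = small_dataset.counts
        kept = set(filter_low_prevalence_otus(otus, min_sites=5).otu_ids)
        perm = otus.counts.sample(frac=1, axis=1, random_state=1)
        shuffled = type(otus)(counts=perm, phylum=otus.phylum,
                              library_sizes=otus.library_sizes)
        assert set(filter_low_prevalence_otus(shuffled, min_sites=5).otu_ids) == kept


class TestRarefy:
    def test_columns_sum_to_depth_and_respect_originals(self):
        counts = pd.DataFrame({"s1": {"a": 4, "b": 6}, "s2": {"a": 50, "b": 70}})
        zt = _zotu_table(counts)
        out = rarefy(zt, depth=5, seed=0)
        assert (out.counts.sum(axis=0) == 5).all()
        assert (out.counts.to_numpy() <= counts.to_numpy()).all()

    def test_underdepth_sites_dropped(self):
        counts = pd.DataFrame({"deep": {"a": 40, "b": 60}, "shallow": {"a": 1, "b": 2}})
        zt = _zotu_table(counts)
        out = rarefy(zt, depth=10, seed=0)
        assert out.site_ids == ["deep"]

    def test_depth_exceeding_all_sites_errors(self):
        zt = _zotu_table(pd.DataFrame({"s1": {"a": 3}}), lib={"s1": 10})
        with pytest.raises(ValueError, match="depth"):
            rarefy(zt, depth=100, seed=0)

    def test_hypergeometric_mean_over_repeated_draws(self):
        # E[rarefied count] = depth * count / site_total
        counts = pd.DataFrame({"s1": {"a": 30, "b": 70}})
        zt = _zotu_table(counts, lib={"s1": 100})
        depth, n_rep = 40, 2000
        draws = np.array(
            [rarefy(zt, depth=depth, seed=k).counts.loc["a", "s1"] for k in range(n_rep)]
        )
        expect = depth * 30 / 100
        # hypergeometric variance with finite-population correction
        var = depth * 0.3 * 0.7 * (100 - depth) / (100 - 1)
        se = np.sqrt(var / n_rep)
        assert abs(draws.mean() - expect) < 3 * se
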