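"""Synthetic-data generator: determinism, ranges, and the stated noise model."""

import numpy as np
import pandas as pd
import pytest

import soilsdm as s
from soilsdm.schema import PH
from soilsdm.synthetic import (
    generate_env_table,
    generate_family_similarity,
    generate_library_sizes,
    generate_niche_params,
    generate_otu_counts,
    generate_resurvey_pairs,
    generate_similarity_fixture,
    generate_zotu_table,
)


class TestEnvTable:
    def test_values_respect_schema_ranges(self, schema):
        env = generate_env_table(schema, 255, seed=1)
        assert len(env) == 255
        for name in schema.names:
            low, high = schema.range_of(name)
            assert env[name].between(low, high).all()

    def test_seeded_determinism(self, schema):
        a = generate_env_table(schema, 50, seed=1)
        b = generate_env_table(schema, 50, seed=1)
        pd.testing.assert_frame_equal(a, b)
        c = generate_env_table(schema, 50, seed=2)
        assert not a.equals(c)

    def test_nonpositive_n_sites_rejected(self, schema):
        with pytest.raises(ValueError, match="n_sites"):
            generate_env_table(schema, 0, seed=1)

    def test_correlation_knob_couples_ph_to_temperature(self, schema):
        env = generate_env_table(schema, 500, seed=4, correlation=0.8)
        r = np.corrcoef(env[PH], env["T_coldQ"])[0, 1]
        assert r > 0.5


class TestOtuCounts:
    def test_flat_niche_mean_matches_closed_form(self, schema):
        """With huge breadths the rate is exp(baseline) everywhere; the
        empirical mean count over many sites must match library * rate."""
        n = 10_000
        env = generate_env_table(schema, n, seed=2)
        lib = pd.Series(1000, index=env.index)
        otus = ["OTU001"]
        truth = s.NicheParams(
            optimum=pd.DataFrame(5.0, index=otus, columns=list(schema.names)),
            breadth=pd.DataFrame(1e9, index=otus, columns=list(schema.names)),
            baseline=pd.Series(np.log(0.01), index=otus),
        )
        tab = generate_otu_counts(env, truth, lib, dispersion=1.0, seed=3)
        counts = tab.counts.loc["OTU001"].to_numpy()
        mean, expected = counts.mean(), 0.01 * 1000
        # NB variance = mu + mu^2/k with k = 1
        se = np.sqrt((expected + expected**2) / n)
        assert abs(mean - expected) < 3 * se

    def test_poisson_limit_variance_equals_mean(self, schema):
        env = generate_env_table(schema, 20_000, seed=5)
        lib = pd.Series(500, index=env.index)
        otus = ["OTU001"]
        truth = s.NicheParams(
            optimum=pd.DataFrame(5.0, index=otus, columns=list(schema.names)),
            breadth=pd.DataFrame(1e9, index=otus, columns=list(schema.names)),
            baseline=pd.Series(np.log(0.01), index=otus),
        )
        tab = generate_otu_counts(env, truth, lib, dispersion=1e12, seed=6)
        c = tab.counts.loc["OTU001"].to_numpy()
        assert abs(c.var() / c.mean() - 1.0) < 0.05

    def test_overdispersion_when_dispersion_finite(self, schema):
        env = generate_env_table(schema, 5_000, seed=7)
        lib = pd.Series(2000, index=env.index)
        otus = ["OTU001"]
        truth = s.NicheParams(
            optimum=pd.DataFrame(5.0, index=otus, columns=list(schema.names)),
            breadth=pd.DataFrame(1e9, index=otus, columns=list(schema.names)),
            baseline=pd.Series(np.log(0.05), index=otus),
        )
        tab = generate_otu_counts(env, truth, lib, dispersion=0.5, seed=8)
        c = tab.counts.loc["OTU001"].to_numpy()
        assert c.var() > 2 * c.mean()

    def test_conditioned_mode_column_sums_equal_library_sizes(self):
        ds = s.generate_dataset(n_sites=30, n_otus=5, seed=9, conditioned=True)
        assert (ds.counts.counts.sum(axis=0) == ds.library_sizes).all()

    def test_invalid_dispersion_and_library_rejected(self, schema):
        env = generate_env_table(schema, 10, seed=1)
        truth = generate_niche_params(schema, 2, seed=1)
        lib = pd.Series(100, index=env.index)
        with pytest.raises(ValueError, match="dispersion"):
            generate_otu_counts(env, truth, lib, dispersion=0.0, seed=1)
        lib_bad = lib.copy(); lib_bad.iloc[0] = 0
        with pytest.raises(ValueError, match="library"):
            generate_otu_counts(env, truth, lib_bad, dispersion=1.0, seed=1)

    def test_seeded_determinism(self):
        a = s.generate_dataset(n_sites=25, n_otus=4, seed=11)
        b = s.generate_dataset(n_sites=25, n_otus=4, seed=11)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)


class TestSimilarityFixture:
    def test_symmetric_and_self_score_maximal(self):
        _, sim = generate_similarity_fixture(10, seed=7)
        assert np.array_equal(sim.sim, sim.sim.T)
        assert (np.diag(sim.sim)[:, None] >= sim.sim - 1e-9).all()

    def test_identical_sequences_share_self_score(self):
        records, sim = generate_similarity_fixture(6, seed=1, mutation_rate=0.0)
        seqs = {}
        for i, (rid, seq) in enumerate(records):
            for j, other in seqs.items():
                if other == seq:
                    assert sim.sim[i, j] == sim.sim[i, i] == sim.sim[j, j]
            seqs[i] = seq

    def test_reproducible(self):
        r1, s1 = generate_similarity_fixture(10, seed=7)
        r2, s2 = generate_similarity_fixture(10, seed=7)
        assert r1 == r2
        assert np.array_equal(s1.sim, s2.sim)

    def test_family_similarity_recovers_membership_by_clustering(self):
        members = {"O1": ["O1_a", "O1_b", "O1_c"], "O2": ["O2_a", "O2_b"]}
        _, sim = generate_family_similarity(members, seed=4)
        from soilsdm.otu import similarity_to_distance, single_linkage_cluster

        for cutoff in (20.0, 40.0, 60.0):
            part = single_linkage_cluster(similarity_to_distance(sim), cutoff)
            got = {frozenset(v) for v in part.values()}
            assert got == {frozenset(v) for v in members.values()}


class TestResurveyPairs:
    def test_zero_slope_zero_noise_leaves_values_unchanged(self):
        pairs = generate_resurvey_pairs(0.0, 0.0, n_pairs=10, seed=1)
        assert np.allclose(pairs["value_new"], pairs["value_old"])

    def test_deterministic_slope_gives_exact_deltas(self):
        pairs = generate_resurvey_pairs(0.01, 0.0, n_pairs=112, seed=2)
        delta = pairs["value_new"] - pairs["value_old"]
        assert np.allclose(delta, 0.01 * 46)  # 1970 -> 2016

    def test_default_emulates_112_pairs(self):
        assert len(generate_resurvey_pairs(0.005, 0.1, seed=3)) == 112

    def test_bad_year_order_rejected(self):
        with pytest.raises(ValueError, match="year"):
            generate_resurvey_pairs(0.0, 0.0, n_pairs=5, year_old=2016, year_new=1970, seed=1)


class TestZotuSplit:
    def test_true_membership_aggregation_recovers_otu_table(self, small_dataset):
        zt, members = generate_zotu_table(small_dataset.counts, 3, seed=5)
        from soilsdm.otu import aggregate_counts

        back = aggregate_counts(zt, members)
        pd.testing.assert_frame_equal(
            back.counts.sort_index(), small_dataset.counts.counts.sort_index()
        )


def test_library_sizes_are_log_uniform_and_positive():
    lib = generate_library_sizes([f"s{i}" for i in range(500)], seed=1)
    assert (lib >= 50_000 * 0.99).all() and (lib <= 500_000 * 1.01).all()
    assert lib.nunique() > 400
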