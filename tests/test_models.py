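"""Abundance models: offset contracts, recovery, deviance descent, serialization."""

import numpy as np
import pandas as pd
import pytest

import soilsdm as s
from soilsdm.models import (
    ModelSpec,
    OffsetSpec,
    fit_gam,
    fit_gbm,
    model_from_json,
    model_to_json,
    poisson_deviance,
)


@pytest.fixture(scope="module")
def flat_env(schema):
    return s.generate_env_table(schema, 120, seed=31)


def test_model_spec_rejects_negbin_gbm():
    with pytest.raises(ValueError, match="negative-binomial"):
        ModelSpec(engine="gbm", family="negbin")


def test_offset_spec_rejects_nonpositive_libraries():
    with pytest.raises(ValueError, match="library"):
        OffsetSpec.per_site(pd.Series([100, 0], index=["a", "b"]))


class TestGam:
    def test_constant_counts_fit_constant_mean(self, flat_env):
        y = pd.Series(7, index=flat_env.index)
        off = OffsetSpec.fixed(10_000)
        m = fit_gam(y, flat_env, off, family="poisson")
        assert np.allclose(m.fitted, 7.0, rtol=1e-5)

    def test_all_zero_counts_rejected(self, flat_env):
        y = pd.Series(0, index=flat_env.index)
        with pytest.raises(ValueError, match="zero"):
            fit_gam(y, flat_env, OffsetSpec.fixed(1000), family="poisson")

    def test_single_predictor_slope_recovery(self, schema):
        """log-rate = 0.5 * pH with inert other predictors; the fitted
        partial effect must recover the slope within +-0.1."""
        rng = np.random.default_rng(17)
        env = s.generate_env_table(schema, 500, seed=17)
        lib = pd.Series(50_000, index=env.index)
        eta = np.log(2e-4) + 0.5 * (env["pH"].to_numpy() - 5.75)
        mu = np.exp(eta) * 50_000
        k = 1.0
        y = pd.Series(rng.negative_binomial(k, k / (k + mu)), index=env.index)
        m = fit_gam(y, env, OffsetSpec.per_site(lib), family="negbin")
        curve = s.response_curve(m, env, "pH", OffsetSpec.fixed(50_000), n_grid=50)
        # fitted slope of log-abundance across the central pH band
        sel = (curve.grid > 4) & (curve.grid < 7.5)
        slope = np.polyfit(curve.grid[sel], np.log(curve.abundance[sel]), 1)[0]
        assert abs(slope - 0.5) < 0.1

    def test_offset_invariance_of_rate_curves(self, flat_env):
        """Doubling every library (offset + log 2) with counts doubled leaves
        the fitted rate model unchanged."""
        rng = np.random.default_rng(5)
        lib1 = pd.Series(10_000, index=flat_env.index)
        y1 = pd.Series(rng.poisson(5.0, len(flat_env)), index=flat_env.index)
        m1 = fit_gam(y1, flat_env, OffsetSpec.per_site(lib1), family="poisson",
                     alpha_smooth=0.0)
        m2 = fit_gam(2 * y1, flat_env, OffsetSpec.per_site(2 * lib1), family="poisson",
                     alpha_smooth=0.0)
        r1 = m1.predict(flat_env, OffsetSpec.fixed(10_000))
        r2 = m2.predict(flat_env, OffsetSpec.fixed(10_000))
        assert np.allclose(r1, r2, rtol=1e-3)

    def test_prediction_scales_exactly_with_offset(self, flat_env, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[0]
        m = fit_gam(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), family="poisson",
                    alpha_smooth=1.0)
        p1 = m.predict(ds.env, OffsetSpec.fixed(100_000))
        p2 = m.predict(ds.env, OffsetSpec.fixed(200_000))
        assert np.allclose(p2 / p1, 2.0, rtol=1e-12)

    def test_prediction_row_order_invariant(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[1]
        m = fit_gam(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), family="poisson",
                    alpha_smooth=1.0)
        off = OffsetSpec.fixed(100_000)
        full = m.predict(ds.env, off)
        shuffled = m.predict(ds.env.iloc[::-1], off)
        assert np.allclose(full.loc[ds.env.index[5]], shuffled.loc[ds.env.index[5]])

    def test_schema_mismatch_rejected_with_names(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[0]
        m = fit_gam(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), family="poisson",
                    alpha_smooth=1.0)
        with pytest.raises(ValueError, match="pH"):
            m.predict(ds.env.drop(columns=["pH"]), OffsetSpec.fixed(1000))

    def test_negbin_dispersion_near_poisson_on_poisson_data(self, schema):
        """On Poisson counts the NB dispersion estimate must sit at the
        Poisson limit (small variance inflation)."""
        rng = np.random.default_rng(23)
        env = s.generate_env_table(schema, 400, seed=23)
        mu = 20.0 * np.exp(0.3 * (env["pH"].to_numpy() - 5.75))
        y = pd.Series(rng.poisson(mu), index=env.index)
        m = fit_gam(y, env, OffsetSpec.fixed(1000), family="negbin")
        # variance inflation at the typical mean stays below ~30 %
        assert m.nb_alpha * mu.mean() < 0.3

    def test_serialization_round_trip_is_exact(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[2]
        off = OffsetSpec.per_site(ds.library_sizes)
        m = fit_gam(ds.counts.counts.loc[otu], ds.env, off, family="negbin",
                    alpha_smooth=1.0)
        m2 = model_from_json(model_to_json(m))
        p1 = m.predict(ds.env, OffsetSpec.fixed(123_456))
        p2 = m2.predict(ds.env, OffsetSpec.fixed(123_456))
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())


class TestGbm:
    def test_constant_counts_predict_mean_rate(self, flat_env):
        y = pd.Series(9, index=flat_env.index)
        off = OffsetSpec.fixed(10_000)
        spec = ModelSpec(engine="gbm", family="poisson", n_trees=50)
        m = fit_gbm(y, flat_env, off, spec=spec, seed=0)
        assert np.allclose(m.fitted, 9.0, rtol=1e-9)

    def test_training_deviance_non_increasing_without_bagging(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[0]
        spec = ModelSpec(engine="gbm", family="poisson", n_trees=200, bag_fraction=1.0)
        m = fit_gbm(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), spec=spec, seed=0,
                    track_deviance=True)
        path = np.array(m.deviance_path)
        assert (np.diff(path) <= 1e-8).all()

    def test_step_function_rate_recovery(self, schema):
        """Rate 1 vs 10 per 1000 reads at a pH threshold: a tree-friendly
        signal recovered within +-20 % on each side."""
        rng = np.random.default_rng(41)
        env = s.generate_env_table(schema, 400, seed=41)
        rate = np.where(env["pH"].to_numpy() > 6.0, 10.0, 1.0)
        y = pd.Series(rng.poisson(rate), index=env.index)
        spec = ModelSpec(engine="gbm", family="poisson", n_trees=800)
        m = fit_gbm(y, env, OffsetSpec.fixed(1000), spec=spec, seed=1)
        pred = m.predict(env, OffsetSpec.fixed(1000))
        hi = pred[env["pH"] > 6.2].mean()
        lo = pred[env["pH"] < 5.8].mean()
        assert abs(hi - 10.0) / 10.0 < 0.2
        assert abs(lo - 1.0) / 1.0 < 0.2

    def test_offset_scaling_within_tolerance(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[0]
        spec = ModelSpec(engine="gbm", family="poisson", n_trees=100)
        m = fit_gbm(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), spec=spec, seed=0)
        p1 = m.predict(ds.env, OffsetSpec.fixed(50_000))
        p2 = m.predict(ds.env, OffsetSpec.fixed(100_000))
        assert np.allclose(p2 / p1, 2.0, rtol=1e-6)

    def test_serialization_round_trip_is_exact(self, medium_dataset):
        ds = medium_dataset
        otu = ds.counts.otu_ids[1]
        spec = ModelSpec(engine="gbm", family="poisson", n_trees=60)
        m = fit_gbm(ds.counts.counts.loc[otu], ds.env,
                    OffsetSpec.per_site(ds.library_sizes), spec=spec, seed=3)
        m2 = model_from_json(model_to_json(m))
        p1 = m.predict(ds.env, OffsetSpec.fixed(77_777))
        p2 = m2.predict(ds.env, OffsetSpec.fixed(77_777))
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())


def test_poisson_deviance_zero_at_saturation():
    y = np.array([0.0, 3.0, 10.0])
    assert poisson_deviance(y, np.maximum(y, 1e-10)) < 1e-6
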