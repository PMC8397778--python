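"""Per-OTU abundance models with sequencing-depth offsets.

Two engines model the expected read count of one OTU as a function of the
nine environmental predictors on a log link, with the natural log of the
site's total sequence count entering as a fixed offset — so the model
describes a *rate* (reads of the OTU per total reads) rather than raw counts:

* **GAM** — an additive model of penalized univariate cubic B-splines, with a
  Poisson or negative-binomial response.  Smoothing is chosen by generalized
  cross-validation over a shared penalty-weight grid; the NB dispersion is
  estimated by an outer profile likelihood around a method-of-moments start.
* **GBM** — stagewise gradient-boosted regression trees minimizing the
  Poisson deviance (2000 trees, interaction depth 3, shrinkage 0.01, bagging
  fraction 0.5), with terminal-node line-search updates on the log scale and
  the offset as a fixed additive term.  Trees may combine predictors, so
  interactions are captured automatically; only the Poisson response is
  available for this engine.

Both engines honour exact offset linearity: multiplying the offset's library
size by ``k`` multiplies every predicted count by ``k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

MEAN_FLOOR = 1e-10  # clamp on predicted means so deviances stay finite


# ---------------------------------------------------------------------------
# specs and offsets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """Engine and hyperparameters for one abundance model."""

    engine: str = "gam"          # "gam" | "gbm"
    family: str = "negbin"       # "poisson" | "negbin" (gbm: poisson only)
    # gam hyperparameters
    basis_df: int = 10
    alpha_grid: tuple[float, ...] = (0.1, 1.0, 10.0, 100.0, 1000.0)
    # gbm hyperparameters
    n_trees: int = 2000
    interaction_depth: int = 3
    shrinkage: float = 0.01
    bag_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.engine not in ("gam", "gbm"):
            raise ValueError(f"unknown engine {self.engine!r}")
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.engine == "gbm" and self.family != "poisson":
            raise ValueError("the negative-binomial family is not available for the gbm engine")


@dataclass(frozen=True)
class OffsetSpec:
    """Natural-log offsets derived from library sizes.

    ``per_site`` mode carries one log total per site; ``fixed_median`` mode
    applies the log of the median library size everywhere (the convention for
    projections onto new sites).
    """

    mode: str
    log_per_site: pd.Series | None = None
    log_fixed: float | None = None

    @classmethod
    def per_site(cls, library_sizes: pd.Series) -> "OffsetSpec":
        lib = pd.Series(library_sizes, dtype=float)
        if (lib < 1).any() or not np.isfinite(lib).all():
            raise ValueError("library sizes must be finite and >= 1")
        return cls(mode="per_site_log_total", log_per_site=np.log(lib))

    @classmethod
    def fixed_median(cls, library_sizes: pd.Series) -> "OffsetSpec":
        lib = pd.Series(library_sizes, dtype=float)
        if (lib < 1).any() or not np.isfinite(lib).all():
            raise ValueError("library sizes must be finite and >= 1")
        return cls(mode="fixed_log_median", log_fixed=float(np.log(np.median(lib))))

    @classmethod
    def fixed(cls, library_size: float) -> "OffsetSpec":
        if library_size < 1 or not np.isfinite(library_size):
            raise ValueError("library size must be finite and >= 1")
        return cls(mode="fixed_log_median", log_fixed=float(np.log(library_size)))

    def values_for(self, site_ids) -> np.ndarray:
        if self.mode == "per_site_log_total":
            vals = self.log_per_site.reindex(list(site_ids))
            if vals.isna().any():
                missing = vals.index[vals.isna()].tolist()
                raise ValueError(f"offset has no library size for sites: {missing}")
            return vals.to_numpy(dtype=float)
        return np.full(len(list(site_ids)), self.log_fixed, dtype=float)


def _validate_training_inputs(counts: pd.Series, env: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if not counts.index.equals(env.index):
        counts = counts.reindex(env.index)
    if counts.isna().any():
        raise ValueError("counts missing for some sites in the environmental table")
    y = counts.to_numpy(dtype=float)
    if (y < 0).any():
        raise ValueError("counts must be non-negative")
    if y.sum() == 0:
        raise ValueError("all-zero counts: the abundance model is degenerate")
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"missing predictor values in: {bad}")
    return y, env.to_numpy(dtype=float)


def _check_schema(env: pd.DataFrame, predictor_names) -> pd.DataFrame:
    missing = [n for n in predictor_names if n not in env.columns]
    if missing:
        extra = [c for c in env.columns if c not in predictor_names]
        raise ValueError(
            f"environment does not match the training schema; missing={missing}, extra={extra}"
        )
    return env[list(predictor_names)]


# ---------------------------------------------------------------------------
# GAM engine
# ---------------------------------------------------------------------------


def _make_smoother(z: np.ndarray, basis_df: int):
    from statsmodels.gam.api import BSplines

    k = z.shape[1]
    return BSplines(z, df=[basis_df] * k, degree=[3] * k, include_intercept=False)


class GamModel:
    """A fitted additive spline model for one OTU.

    Prediction evaluates the stored basis at (standardized, range-clamped)
    predictor values; values outside the training range are held at the
    boundary, i.e. the smooths extrapolate as constants.
    """

    def __init__(
        self,
        otu_id: str,
        spec: ModelSpec,
        predictor_names: tuple[str, ...],
        x_train: np.ndarray,
        params: np.ndarray,
        alpha_smooth: float,
        nb_alpha: float | None,
        fitted: pd.Series,
    ):
        self.otu_id = otu_id
        self.spec = spec
        self.predictor_names = tuple(predictor_names)
        # C-contiguous so axis reductions are bit-identical after a JSON round trip
        self.x_train = np.ascontiguousarray(x_train, dtype=float)
        self.params = np.asarray(params, dtype=float)
        self.alpha_smooth = float(alpha_smooth)
        self.nb_alpha = None if nb_alpha is None else float(nb_alpha)
        self.fitted = fitted
        self._mean = self.x_train.mean(axis=0)
        self._std = self.x_train.std(axis=0)
        self._std[self._std == 0] = 1.0
        self._z_train = (self.x_train - self._mean) / self._std
        self._smoother = _make_smoother(self._z_train, spec.basis_df)

    def _design(self, x: np.ndarray) -> np.ndarray:
        z = (x - self._mean) / self._std
        z = np.clip(z, self._z_train.min(axis=0), self._z_train.max(axis=0))
        basis = self._smoother.transform(z)
        if basis.ndim == 1:
            basis = basis[None, :]
        return np.column_stack([np.ones(len(z)), basis])

    def predict(self, env: pd.DataFrame, offset: OffsetSpec) -> pd.Series:
        env = _check_schema(env, self.predictor_names)
        eta = self._design(env.to_numpy(dtype=float)) @ self.params
        eta = eta + offset.values_for(env.index)
        mu = np.maximum(np.exp(eta), MEAN_FLOOR)
        return pd.Series(mu, index=env.index, name=self.otu_id)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "kind": "gam",
            "otu_id": self.otu_id,
            "spec": asdict(self.spec),
            "predictor_names": list(self.predictor_names),
            "x_train": self.x_train.tolist(),
            "params": self.params.tolist(),
            "alpha_smooth": self.alpha_smooth,
            "nb_alpha": self.nb_alpha,
            "fitted_index": list(self.fitted.index),
            "fitted_values": self.fitted.to_numpy().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GamModel":
        spec = d["spec"].copy()
        spec["alpha_grid"] = tuple(spec["alpha_grid"])
        return cls(
            otu_id=d["otu_id"],
            spec=ModelSpec(**spec),
            predictor_names=tuple(d["predictor_names"]),
            x_train=np.array(d["x_train"], dtype=float),
            params=np.array(d["params"], dtype=float),
            alpha_smooth=d["alpha_smooth"],
            nb_alpha=d["nb_alpha"],
            fitted=pd.Series(d["fitted_values"], index=d["fitted_index"], dtype=float),
        )


class _InterceptOnlyResult:
    """Stand-in result when the smooth fit is degenerate (e.g. the spline
    interpolates the data exactly and IRLS aborts): intercept-only model."""

    def __init__(self, y, offset, n_coef):
        exposure = np.exp(offset)
        intercept = float(np.log(y.sum() / exposure.sum()))
        self.params = np.zeros(n_coef)
        self.params[0] = intercept
        self.fittedvalues = np.exp(intercept + offset)
        mu = np.maximum(self.fittedvalues, MEAN_FLOOR)
        self.deviance = poisson_deviance(y, mu)
        self.edf = np.array([1.0])


def _fit_glmgam(y, z, offset, family, alpha, basis_df):
    from statsmodels.gam.api import GLMGam
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    smoother = _make_smoother(z, basis_df)
    exog = np.ones((len(y), 1))
    model = GLMGam(
        y, exog=exog, smoother=smoother, alpha=[alpha] * z.shape[1],
        family=family, offset=offset,
    )
    try:
        return model.fit(maxiter=100)
    except PerfectSeparationError:
        return _InterceptOnlyResult(y, offset, 1 + smoother.basis.shape[1])


def _gcv_score(res, n: int) -> float:
    edf = float(np.sum(res.edf))
    denom = max(n - edf, 1e-6)
    return n * float(res.deviance) / denom**2


def _nb_loglik(y, mu, alpha) -> float:
    import statsmodels.api as sm

    fam = sm.families.NegativeBinomial(alpha=alpha)
    return float(np.sum(fam.loglike_obs(y, np.maximum(mu, MEAN_FLOOR))))


def fit_gam(
    counts: pd.Series,
    env: pd.DataFrame,
    offset: OffsetSpec,
    family: str = "negbin",
    spec: ModelSpec | None = None,
    otu_id: str | None = None,
    alpha_smooth: float | None = None,
    nb_alpha: float | None = None,
) -> GamModel:
    """Fit the additive spline model for one OTU.

    ``log E[count_s] = offset_s + intercept + sum_v f_v(x_sv)`` with penalized
    cubic B-splines ``f_v``.  The penalty weight (shared across predictors on
    standardized inputs) is selected by GCV over ``spec.alpha_grid`` under the
    Poisson working family; for the negative-binomial family the dispersion is
    then profiled on an outer grid around the method-of-moments estimate.
    ``alpha_smooth`` / ``nb_alpha`` may be supplied to skip the searches (used
    by the repeated-split evaluation to hold tuning fixed across refits).
    """
    import statsmodels.api as sm

    spec = spec or ModelSpec(engine="gam", family=family)
    if spec.engine != "gam":
        raise ValueError("fit_gam requires a gam spec")
    family = spec.family if spec else family
    otu_id = otu_id or (counts.name if counts.name else "otu")
    counts = counts.reindex(env.index)
    y, x = _validate_training_inputs(counts, env)
    off = offset.values_for(env.index)

    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    z = (x - mean) / std

    # smoothing selection under the Poisson working family
    if alpha_smooth is None:
        best = None
        for a in spec.alpha_grid:
            res = _fit_glmgam(y, z, off, sm.families.Poisson(), a, spec.basis_df)
            score = _gcv_score(res, len(y))
            if best is None or score < best[0]:
                best = (score, a, res)
        _, alpha_smooth, res_pois = best
    else:
        res_pois = _fit_glmgam(y, z, off, sm.families.Poisson(), alpha_smooth, spec.basis_df)

    if family == "poisson":
        res = res_pois
        nb_alpha_out = None
    else:
        mu = np.maximum(res_pois.fittedvalues, MEAN_FLOOR)
        if nb_alpha is None:
            # method-of-moments start, then profile on a multiplicative grid
            mom = float(np.sum((y - mu) ** 2 - mu) / np.sum(mu**2))
            mom = min(max(mom, 1e-4), 1e3)
            best = None
            for mult in (0.25, 0.5, 1.0, 2.0, 4.0):
                a_disp = mom * mult
                r = _fit_glmgam(
                    y, z, off, sm.families.NegativeBinomial(alpha=a_disp),
                    alpha_smooth, spec.basis_df,
                )
                ll = _nb_loglik(y, r.fittedvalues, a_disp)
                if best is None or ll > best[0]:
                    best = (ll, a_disp, r)
            _, nb_alpha, res = best
        else:
            res = _fit_glmgam(
                y, z, off, sm.families.NegativeBinomial(alpha=nb_alpha),
                alpha_smooth, spec.basis_df,
            )
        nb_alpha_out = nb_alpha

    fitted = pd.Series(np.maximum(res.fittedvalues, MEAN_FLOOR), index=env.index, name=otu_id)
    model = GamModel(
        otu_id=otu_id,
        spec=ModelSpec(
            engine="gam", family=family, basis_df=spec.basis_df, alpha_grid=spec.alpha_grid,
        ),
        predictor_names=tuple(env.columns),
        x_train=x,
        params=np.asarray(res.params, dtype=float),
        alpha_smooth=alpha_smooth,
        nb_alpha=nb_alpha_out,
        fitted=fitted,
    )
    return model


# ---------------------------------------------------------------------------
# GBM engine (Poisson boosting with offset)
# ---------------------------------------------------------------------------

_GAMMA_CLIP = 4.0  # bound on a single terminal-node log-scale update


class GbmModel:
    """Boosted-tree Poisson rate model for one OTU.

    ``log E[count] = f0 + shrinkage * sum_m tree_m(x) + offset``; trees are
    stored as plain arrays so prediction and serialization are exact.
    """

    def __init__(
        self,
        otu_id: str,
        spec: ModelSpec,
        predictor_names: tuple[str, ...],
        f0: float,
        trees: list[dict],
        raw_importance: np.ndarray,
        fitted: pd.Series,
    ):
        self.otu_id = otu_id
        self.spec = spec
        self.predictor_names = tuple(predictor_names)
        self.f0 = float(f0)
        self.trees = trees
        self.raw_importance = np.asarray(raw_importance, dtype=float)
        self.fitted = fitted

    def decision_function(self, x: np.ndarray) -> np.ndarray:
        """Boosted log-rate score (before offset)."""
        f = np.full(len(x), self.f0)
        for t in self.trees:
            f += self.spec.shrinkage * _tree_apply(x, t)
        return f

    def predict(self, env: pd.DataFrame, offset: OffsetSpec) -> pd.Series:
        env = _check_schema(env, self.predictor_names)
        eta = self.decision_function(env.to_numpy(dtype=float))
        mu = np.maximum(np.exp(eta + offset.values_for(env.index)), MEAN_FLOOR)
        return pd.Series(mu, index=env.index, name=self.otu_id)

    def to_dict(self) -> dict:
        return {
            "kind": "gbm",
            "otu_id": self.otu_id,
            "spec": asdict(self.spec),
            "predictor_names": list(self.predictor_names),
            "f0": self.f0,
            "trees": [
                {k: np.asarray(v).tolist() for k, v in t.items()} for t in self.trees
            ],
            "raw_importance": self.raw_importance.tolist(),
            "fitted_index": list(self.fitted.index),
            "fitted_values": self.fitted.to_numpy().tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GbmModel":
        spec = d["spec"].copy()
        spec["alpha_grid"] = tuple(spec["alpha_grid"])
        trees = [
            {
                "children_left": np.array(t["children_left"], dtype=np.int64),
                "children_right": np.array(t["children_right"], dtype=np.int64),
                "feature": np.array(t["feature"], dtype=np.int64),
                "threshold": np.array(t["threshold"], dtype=float),
                "value": np.array(t["value"], dtype=float),
            }
            for t in d["trees"]
        ]
        return cls(
            otu_id=d["otu_id"],
            spec=ModelSpec(**spec),
            predictor_names=tuple(d["predictor_names"]),
            f0=d["f0"],
            trees=trees,
            raw_importance=np.array(d["raw_importance"], dtype=float),
            fitted=pd.Series(d["fitted_values"], index=d["fitted_index"], dtype=float),
        )


def _tree_apply(x: np.ndarray, tree: dict) -> np.ndarray:
    """Evaluate one stored tree (left branch when value <= threshold)."""
    cl, cr = tree["children_left"], tree["children_right"]
    feat, thr, val = tree["feature"], tree["threshold"], tree["value"]
    node = np.zeros(len(x), dtype=np.int64)
    active = cl[node] >= 0
    while active.any():
        idx = np.where(active)[0]
        nd = node[idx]
        go_left = x[idx, feat[nd]] <= thr[nd]
        node[idx] = np.where(go_left, cl[nd], cr[nd])
        active = cl[node] >= 0
    return val[node]


def poisson_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.maximum(mu, MEAN_FLOOR)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(y > 0, y * np.log(y / mu), 0.0)
    return float(2.0 * np.sum(term - (y - mu)))


def fit_gbm(
    counts: pd.Series,
    env: pd.DataFrame,
    offset: OffsetSpec,
    spec: ModelSpec | None = None,
    otu_id: str | None = None,
    seed: int = 0,
    track_deviance: bool = False,
) -> GbmModel:
    """Stagewise Poisson-deviance boosting with a fixed log-offset.

    The baseline is ``f0 = log(sum(y) / sum(exp(offset)))`` (the maximum
    likelihood constant rate).  Each stage fits a least-squares tree of depth
    ``interaction_depth`` to the current residuals ``y - mu`` on a seeded
    subsample, then replaces every terminal node's value by the Poisson
    line-search update ``log(sum y / sum mu)`` over the in-bag samples in that
    node, scaled by the shrinkage.  Per-predictor squared-error improvements
    are accumulated for the Friedman relative-influence summary.
    """
    from sklearn.tree import DecisionTreeRegressor

    spec = spec or ModelSpec(engine="gbm", family="poisson")
    if spec.engine != "gbm":
        raise ValueError("fit_gbm requires a gbm spec")
    otu_id = otu_id or (counts.name if counts.name else "otu")
    counts = counts.reindex(env.index)
    y, x = _validate_training_inputs(counts, env)
    off = offset.values_for(env.index)
    n, k = x.shape
    x32 = np.asfortranarray(x, dtype=np.float32)

    rng = np.random.default_rng(seed)
    f0 = float(np.log(y.sum() / np.sum(np.exp(off))))
    f = np.zeros(n)
    raw_imp = np.zeros(k)
    trees: list[dict] = []
    deviance_path: list[float] = []
    n_bag = max(2, int(round(spec.bag_fraction * n)))

    for _ in range(spec.n_trees):
        mu = np.exp(f0 + f + off)
        if track_deviance:
            deviance_path.append(poisson_deviance(y, mu))
        bag = (
            np.arange(n)
            if n_bag >= n
            else rng.choice(n, size=n_bag, replace=False)
        )
        resid = y - mu
        tree = DecisionTreeRegressor(max_depth=spec.interaction_depth)
        tree.fit(x32[bag], resid[bag], check_input=False)
        raw_imp += tree.tree_.compute_feature_importances(normalize=False)

        leaves_all = tree.apply(x32, check_input=False)
        leaves_bag = leaves_all[bag]
        n_nodes = tree.tree_.node_count
        sum_y = np.bincount(leaves_bag, weights=y[bag], minlength=n_nodes)
        sum_mu = np.bincount(leaves_bag, weights=mu[bag], minlength=n_nodes)
        with np.errstate(divide="ignore", invalid="ignore"):
            gamma = np.log((sum_y + MEAN_FLOOR) / (sum_mu + MEAN_FLOOR))
        gamma = np.clip(np.nan_to_num(gamma), -_GAMMA_CLIP, _GAMMA_CLIP)
        gamma[sum_mu == 0] = 0.0  # nodes with no in-bag samples contribute nothing

        f += spec.shrinkage * gamma[leaves_all]
        t = tree.tree_
        trees.append(
            {
                "children_left": t.children_left.copy(),
                "children_right": t.children_right.copy(),
                "feature": t.feature.copy(),
                "threshold": t.threshold.astype(float).copy(),
                "value": gamma,
            }
        )

    fitted = pd.Series(
        np.maximum(np.exp(f0 + f + off), MEAN_FLOOR), index=env.index, name=otu_id
    )
    model = GbmModel(
        otu_id=otu_id,
        spec=spec,
        predictor_names=tuple(env.columns),
        f0=f0,
        trees=trees,
        raw_importance=raw_imp,
        fitted=fitted,
    )
    if track_deviance:
        model.deviance_path = deviance_path
    return model


# ---------------------------------------------------------------------------
# dispatch and serialization
# ---------------------------------------------------------------------------


def fit_model(
    counts: pd.Series,
    env: pd.DataFrame,
    offset: OffsetSpec,
    spec: ModelSpec,
    seed: int = 0,
    **kwargs,
):
    """Fit one OTU under the given spec (gam -> :func:`fit_gam`, gbm -> :func:`fit_gbm`)."""
    if spec.engine == "gam":
        return fit_gam(counts, env, offset, family=spec.family, spec=spec, **kwargs)
    return fit_gbm(counts, env, offset, spec=spec, seed=seed, **kwargs)


def predict_abundance(model, env: pd.DataFrame, offset: OffsetSpec) -> pd.Series:
    """Expected counts for new sites (strictly positive; linear in offset scale)."""
    return model.predict(env, offset)


def model_to_json(model) -> str:
    return json.dumps(model.to_dict())


def model_from_json(payload: str):
    d = json.loads(payload)
    if d["kind"] == "gam":
        return GamModel.from_dict(d)
    if d["kind"] == "gbm":
        return GbmModel.from_dict(d)
    raise ValueError(f"unknown model kind {d['kind']!r}")


__all__ = [
    "GamModel",
    "GbmModel",
    "ModelSpec",
    "OffsetSpec",
    "fit_gam",
    "fit_gbm",
    "fit_model",
    "model_from_json",
    "model_to_json",
    "poisson_deviance",
    "predict_abundance",
]
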