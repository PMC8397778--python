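"""Model scoring and selection.

``cor_expl`` measures fit (observed vs fitted counts on the training sites);
``cor_pred`` measures predictive skill under ten repeated random 80/20
calibration/evaluation splits, correlating each site's observed count with
the mean of its held-out predictions (each site is evaluated on average
twice).  OTUs for which *both* correlations are weak (< 0.2) are excluded
from projections.  Variable importance comes from predictor shuffling for the
GAM engines and from Friedman's relative influence for the GBM engine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from .models import ModelSpec, OffsetSpec, fit_gam, fit_gbm

EXCLUSION_THRESHOLD = 0.2


def cor_expl(observed, fitted, method: str = "pearson") -> float:
    """Correlation between observed and fitted abundances (response scale).

    Returns NaN (flagged missing) when either vector is constant — an OTU
    with an undefined correlation then fails the retention test downstream.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    if len(obs) < 3:
        raise ValueError("correlation requires at least 3 sites")
    if np.ptp(obs) == 0 or np.ptp(fit) == 0:
        return float("nan")
    if method == "pearson":
        return float(pearsonr(obs, fit).statistic)
    if method == "spearman":
        return float(spearmanr(obs, fit).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


@dataclass(frozen=True)
class SplitPlan:
    """Repeated exact 80/20 site partitions for calibration/evaluation."""

    site_ids: tuple[str, ...]
    repeats: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]
    seed: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    def evaluation_uses(self) -> pd.Series:
        """Number of repeats in which each site sat in the evaluation set."""
        uses = pd.Series(0, index=list(self.site_ids), dtype=int)
        for _, ev in self.repeats:
            uses[list(ev)] += 1
        return uses


def make_split_plan(
    site_ids,
    seed: int,
    n_repeats: int = 10,
    calibration_fraction: float = 0.8,
) -> SplitPlan:
    """Draw ``n_repeats`` independent partitions with |calibration| = round(0.8 n).

    With ten exact 80/20 partitions each site is used on average eight times
    for calibration and twice for evaluation.
    """
    ids = [str(s) for s in site_ids]
    n = len(ids)
    if n < 10:
        raise ValueError(f"split plan requires at least 10 sites, got {n}")
    n_cal = round(calibration_fraction * n)
    rng = np.random.default_rng(seed)
    repeats = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        cal = tuple(ids[i] for i in sorted(perm[:n_cal]))
        ev = tuple(ids[i] for i in sorted(perm[n_cal:]))
        repeats.append((cal, ev))
    return SplitPlan(site_ids=tuple(ids), repeats=tuple(repeats), seed=seed)


def cor_pred(
    counts: pd.Series,
    env: pd.DataFrame,
    offset: OffsetSpec,
    spec: ModelSpec,
    plan: SplitPlan,
    seed: int = 0,
    method: str = "pearson",
    fixed_tuning: dict | None = None,
) -> float:
    """Predictive correlation under the repeated-split protocol.

    For every repeat the model is refit on the calibration sites and predicts
    the evaluation sites; per site the held-out predictions are averaged over
    the repeats that evaluated it, and the correlation of observed counts with
    those averages is returned.  Sites never used for evaluation are dropped.
    ``fixed_tuning`` may carry ``alpha_smooth`` / ``nb_alpha`` (GAM) estimated
    on the full data so split refits only re-estimate coefficients.
    """
    counts = counts.reindex(list(plan.site_ids))
    pred_sum = pd.Series(0.0, index=list(plan.site_ids))
    pred_n = pd.Series(0, index=list(plan.site_ids), dtype=int)
    fixed_tuning = fixed_tuning or {}
    for r, (cal, ev) in enumerate(plan.repeats):
        cal, ev = list(cal), list(ev)
        if spec.engine == "gam":
            m = fit_gam(
                counts.loc[cal], env.loc[cal], offset, family=spec.family, spec=spec,
                alpha_smooth=fixed_tuning.get("alpha_smooth"),
                nb_alpha=fixed_tuning.get("nb_alpha"),
            )
        else:
            m = fit_gbm(counts.loc[cal], env.loc[cal], offset, spec=spec, seed=seed + r)
        pred = m.predict(env.loc[ev], offset)
        pred_sum.loc[ev] += pred
        pred_n.loc[ev] += 1
    used = pred_n > 0
    if (~used).any():
        warnings.warn(
            f"{int((~used).sum())} site(s) never used for evaluation were dropped "
            "from cor_pred",
            stacklevel=2,
        )
    mean_pred = pred_sum[used] / pred_n[used]
    return cor_expl(counts[used], mean_pred, method=method)


@dataclass
class AssessmentRecord:
    """Scores and importances for one fitted OTU model."""

    otu_id: str
    engine: str
    family: str
    cor_expl: float
    cor_pred: float
    importance: pd.Series | None = None
    excluded: bool = False


def apply_exclusion(
    records: list[AssessmentRecord],
    threshold: float = EXCLUSION_THRESHOLD,
) -> tuple[list[AssessmentRecord], list[AssessmentRecord]]:
    """Partition records into (retained, excluded).

    Excluded iff *both* correlations are weak (< threshold, strict); an
    undefined (NaN) correlation counts as weak — conservative exclusion.
    """
    retained, excluded = [], []
    for rec in records:
        weak_expl = np.isnan(rec.cor_expl) or rec.cor_expl < threshold
        weak_pred = np.isnan(rec.cor_pred) or rec.cor_pred < threshold
        rec.excluded = bool(weak_expl and weak_pred)
        (excluded if rec.excluded else retained).append(rec)
    return retained, excluded


def importance_shuffle(
    model,
    env: pd.DataFrame,
    counts: pd.Series,
    offset: OffsetSpec,
    n_perms: int = 10,
    seed: int = 0,
    method: str = "pearson",
) -> pd.Series:
    """Permutation importance on a fitted model, as percentages summing to 100.

    Each predictor column is shuffled across sites ``n_perms`` times (seeded);
    the raw importance is the drop of the observed-vs-predicted correlation,
    floored at zero, then normalized over the predictors.  If every raw
    importance is zero the shares fall back to uniform with a warning.
    """
    if n_perms < 1:
        raise ValueError("n_perms must be >= 1")
    counts = counts.reindex(env.index)
    rng = np.random.default_rng(seed)
    names = list(model.predictor_names)
    n = len(env)
    # stack the original and every shuffled design into one prediction call;
    # this keeps tree-ensemble models affordable (one pass over the trees)
    blocks = [env]
    for name in names:
        for _ in range(n_perms):
            shuffled = env.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            blocks.append(shuffled)
    stacked = pd.concat(blocks, ignore_index=True)
    stacked.index = [f"r{i}" for i in range(len(stacked))]
    if offset.mode == "per_site_log_total":
        off_vals = np.tile(offset.values_for(env.index), len(blocks))
        stacked_offset = OffsetSpec(
            mode="per_site_log_total",
            log_per_site=pd.Series(off_vals, index=stacked.index),
        )
    else:
        stacked_offset = offset
    pred = model.predict(stacked, stacked_offset).to_numpy()
    base_cor = cor_expl(counts, pred[:n], method=method)
    raw = pd.Series(0.0, index=names)
    pos = n
    for name in names:
        cors = []
        for _ in range(n_perms):
            cors.append(cor_expl(counts, pred[pos : pos + n], method=method))
            pos += n
        raw[name] = max(0.0, base_cor - float(np.nanmean(cors)))
    total = raw.sum()
    if total <= 0 or np.isnan(total):
        warnings.warn(
            "all permutation importances are zero; returning uniform shares", stacklevel=2
        )
        return pd.Series(100.0 / len(names), index=names)
    return 100.0 * raw / total


def importance_gbm(model) -> pd.Series:
    """Friedman relative influence: squared split improvements, normalized to 100."""
    if not hasattr(model, "raw_importance"):
        raise ValueError("importance_gbm requires a fitted gbm model")
    raw = np.asarray(model.raw_importance, dtype=float)
    names = list(model.predictor_names)
    total = raw.sum()
    if total <= 0:
        return pd.Series(100.0 / len(names), index=names)
    return pd.Series(100.0 * raw / total, index=names)


def assessment_table(records: list[AssessmentRecord]) -> pd.DataFrame:
    """Tidy per-OTU assessment frame (one row per OTU)."""
    rows = []
    for rec in records:
        row = {
            "otu": rec.otu_id,
            "engine": rec.engine,
            "family": rec.family,
            "cor_expl": rec.cor_expl,
            "cor_pred": rec.cor_pred,
            "excluded": rec.excluded,
        }
        if rec.importance is not None:
            for name, val in rec.importance.items():
                row[f"imp_{name}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


__all__ = [
    "EXCLUSION_THRESHOLD",
    "AssessmentRecord",
    "SplitPlan",
    "apply_exclusion",
    "assessment_table",
    "cor_expl",
    "cor_pred",
    "importance_gbm",
    "importance_shuffle",
    "make_split_plan",
]
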