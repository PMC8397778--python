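"""Response curves, stacked community summaries and change maps.

A response curve slides one predictor from its training minimum to maximum
while holding the other eight at their training medians and the offset at the
median library size.  Stacking the per-OTU curves (or per-site projections)
gives community summaries at each evaluation point: the proportion of OTUs
above their own median abundance, the Shannon index (natural log) of the
relative abundances, and per-phylum relative abundance shares.  Comparing
current and scenario projections site by site yields change summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .models import OffsetSpec

EPSILON_REL = 1e-6  # relative change below which an OTU counts as unchanged


@dataclass
class ResponseCurve:
    """Predicted abundance of one OTU along one environmental gradient."""

    otu_id: str
    variable: str
    grid: np.ndarray
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)
        if not (np.diff(self.grid) > 0).all():
            raise ValueError("response-curve grid must be strictly increasing")
        if not (np.isfinite(self.abundance).all() and (self.abundance > 0).all()):
            raise ValueError("response-curve predictions must be positive and finite")

    @property
    def argmax(self) -> float:
        return float(self.grid[int(np.argmax(self.abundance))])


def response_curve(
    model,
    training_env: pd.DataFrame,
    variable: str,
    offset: OffsetSpec,
    n_grid: int = 100,
) -> ResponseCurve:
    """Abundance along one gradient, all other predictors at training medians."""
    if variable not in training_env.columns:
        raise ValueError(f"unknown variable {variable!r}")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    med = training_env.median(axis=0)
    grid = np.linspace(training_env[variable].min(), training_env[variable].max(), n_grid)
    frame = pd.DataFrame(
        {c: np.full(n_grid, med[c]) for c in training_env.columns},
        index=[f"g{i}" for i in range(n_grid)],
    )
    frame[variable] = grid
    pred = model.predict(frame, offset)
    return ResponseCurve(
        otu_id=model.otu_id, variable=variable, grid=grid, abundance=pred.to_numpy()
    )


def curves_frame(curves: list[ResponseCurve]) -> pd.DataFrame:
    """Long-format table (otu, variable, grid_value, abundance)."""
    rows = []
    for c in curves:
        for g, a in zip(c.grid, c.abundance):
            rows.append({"otu": c.otu_id, "variable": c.variable, "grid_value": g, "abundance": a})
    return pd.DataFrame(rows)


@dataclass
class CommunityProfile:
    """Stacked community summaries at each evaluation point.

    ``prop_above_median``: % of OTUs above their own median abundance across
    the evaluation points.  ``shannon``: H in nats.  ``phylum_shares``: % per
    phylum, rows = evaluation points, summing to 100.
    """

    points: pd.Index
    prop_above_median: pd.Series
    shannon: pd.Series
    phylum_shares: pd.DataFrame


def shannon_index(abundance: pd.DataFrame) -> pd.Series:
    """Shannon H (natural log) per column of an OTU × point abundance table."""
    total = abundance.sum(axis=0)
    h = pd.Series(np.nan, index=abundance.columns)
    ok = total > 0
    if ok.any():
        p = abundance.loc[:, ok] / total[ok]
        h[ok] = entropy(p.to_numpy(), base=np.e, axis=0)
    return h


def stack_profiles(abundance: pd.DataFrame, phylum: pd.Series) -> CommunityProfile:
    """Summarize an OTU × evaluation-point abundance table.

    Each OTU's reference is its own median across the evaluation points
    (strictly above counts); points with zero total abundance get NaN Shannon
    and phylum shares.
    """
    if abundance.empty:
        raise ValueError("no OTUs to stack")
    med = abundance.median(axis=1)
    above = abundance.gt(med, axis=0)
    prop = 100.0 * above.sum(axis=0) / len(abundance)
    h = shannon_index(abundance)
    phylum = phylum.reindex(abundance.index)
    by_phylum = abundance.groupby(phylum.fillna("Unclassified")).sum()
    total = by_phylum.sum(axis=0)
    shares = 100.0 * by_phylum.div(total.where(total > 0), axis=1)
    return CommunityProfile(
        points=abundance.columns,
        prop_above_median=prop,
        shannon=h,
        phylum_shares=shares.T,
    )


def project_sites(models: dict, env: pd.DataFrame, offset: OffsetSpec) -> pd.DataFrame:
    """Expected abundance (OTU × site) for the retained models only."""
    if not models:
        raise ValueError("no retained models to project")
    rows = {otu: m.predict(env, offset) for otu, m in models.items()}
    return pd.DataFrame(rows).T.reindex(list(models))


@dataclass
class ChangeSummary:
    """Per-site change between current and scenario projections."""

    pct_increased: pd.Series
    pct_decreased: pd.Series
    pct_unchanged: pd.Series
    delta_shannon: pd.Series
    delta_phylum_shares: pd.DataFrame
    analog: pd.Series | None = None

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "pct_increased": self.pct_increased,
                "pct_decreased": self.pct_decreased,
                "pct_unchanged": self.pct_unchanged,
                "delta_shannon": self.delta_shannon,
            }
        )
        for phyl in self.delta_phylum_shares.columns:
            out[f"dshare_{phyl}"] = self.delta_phylum_shares[phyl]
        if self.analog is not None:
            out["analog"] = self.analog
        return out


def change_summary(
    current: pd.DataFrame,
    future: pd.DataFrame,
    phylum: pd.Series,
    analog_flags: pd.Series | None = None,
    epsilon_rel: float = EPSILON_REL,
) -> ChangeSummary:
    """Compare scenario projections against current ones, site by site.

    An OTU counts as increased at a site when its relative change exceeds
    ``epsilon_rel``, decreased below ``-epsilon_rel``, else unchanged; the
    three percentages sum to 100.  Shannon and phylum-share deltas are
    future − current.  ``analog_flags`` (per-site bool, True = non-analog)
    are attached when given.
    """
    if not current.index.equals(future.index) or not current.columns.equals(future.columns):
        raise ValueError("current and future projections must share OTUs and sites")
    rel = (future - current) / current
    inc = rel.gt(epsilon_rel)
    dec = rel.lt(-epsilon_rel)
    n = len(current)
    pct_inc = 100.0 * inc.sum(axis=0) / n
    pct_dec = 100.0 * dec.sum(axis=0) / n
    pct_unch = 100.0 - pct_inc - pct_dec
    cur_prof = stack_profiles(current, phylum)
    fut_prof = stack_profiles(future, phylum)
    d_shares = fut_prof.phylum_shares - cur_prof.phylum_shares
    analog = None
    if analog_flags is not None:
        analog = ~analog_flags.reindex(current.columns).astype(bool)
    return ChangeSummary(
        pct_increased=pct_inc,
        pct_decreased=pct_dec,
        pct_unchanged=pct_unch,
        delta_shannon=fut_prof.shannon - cur_prof.shannon,
        delta_phylum_shares=d_shares,
        analog=analog,
    )


__all__ = [
    "EPSILON_REL",
    "ChangeSummary",
    "CommunityProfile",
    "ResponseCurve",
    "change_summary",
    "curves_frame",
    "project_sites",
    "response_curve",
    "shannon_index",
    "stack_profiles",
]
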