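"""Edaphic change scenarios and the climate × pH × TOC scenario grid.

Soil-change scenarios are sensitivity scenarios: mean per-year slopes of pH
and total organic carbon (TOC) estimated from paired resurvey measurements
are extrapolated from the measurement year to a target year (default 2060) to
give an "increase" shift; the "decrease" scenario inverts the sign and "now"
keeps current values.  Crossing the pH and TOC triples on top of a
future-climate table yields nine scenario environments; projection sites
whose values leave the training data's min-max envelope are flagged as
non-analogous (model extrapolation territory).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schema import CLIMATE_PREDICTORS, PH, TOC_LOG

#: Packaged default shifts: +-0.3 pH units and +-3.2 TOC percentage points
#: by 2060, the magnitudes implied by five decades of resurvey change.
DEFAULT_PH_SHIFT = 0.3
DEFAULT_TOC_SHIFT = 3.2

DIRECTIONS = ("inc", "now", "dec")
TOC_FLOOR = 0.01  # % — keeps the log defined under the decrease scenario


@dataclass(frozen=True)
class ScenarioShift:
    """One edaphic shift: variable, direction and magnitude.

    ``shift`` is in pH units or TOC percentage points; "now" always carries a
    zero shift and inc/dec are sign-inverted equal magnitudes by
    construction.
    """

    variable: str  # "pH" | "TOC"
    direction: str  # "inc" | "now" | "dec"
    shift: float
    provenance: str = "configured"  # "derived-from-slopes" | "configured"

    def __post_init__(self) -> None:
        if self.variable not in ("pH", "TOC"):
            raise ValueError(f"unknown scenario variable {self.variable!r}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.direction == "now" and self.shift != 0.0:
            raise ValueError("a 'now' scenario must carry a zero shift")


def estimate_mean_slope(pairs: pd.DataFrame, variable: str) -> float:
    """Mean per-pair slope (units/year) from resurvey records.

    Each record contributes ``(value_new - value_old) / (year_new - year_old)``.
    """
    sub = pairs[pairs["variable"] == variable]
    if len(sub) == 0:
        raise ValueError(f"no resurvey pairs for variable {variable!r}")
    dy = sub["year_new"].to_numpy() - sub["year_old"].to_numpy()
    if (dy <= 0).any():
        raise ValueError("every resurvey pair must have year_new > year_old")
    slopes = (sub["value_new"].to_numpy() - sub["value_old"].to_numpy()) / dy
    return float(slopes.mean())


def build_shift(
    slope: float,
    base_year: int,
    direction: str,
    target_year: int = 2060,
    variable: str = "pH",
) -> ScenarioShift:
    """Extrapolate a mean slope to the target year.

    shift = slope × (target_year − base_year) for "inc", negated for "dec",
    zero for "now".
    """
    if target_year <= base_year:
        raise ValueError(f"target_year ({target_year}) must be after base_year ({base_year})")
    if direction not in DIRECTIONS:
        raise ValueError(f"unknown direction {direction!r}")
    magnitude = slope * (target_year - base_year)
    shift = {"inc": magnitude, "dec": -magnitude, "now": 0.0}[direction]
    return ScenarioShift(
        variable=variable, direction=direction, shift=shift, provenance="derived-from-slopes"
    )


def default_shift_triple(variable: str) -> tuple[ScenarioShift, ScenarioShift, ScenarioShift]:
    """The packaged (inc, now, dec) triple: 0.3 pH units / 3.2 TOC points."""
    mag = DEFAULT_PH_SHIFT if variable == "pH" else DEFAULT_TOC_SHIFT
    return (
        ScenarioShift(variable, "inc", mag),
        ScenarioShift(variable, "now", 0.0),
        ScenarioShift(variable, "dec", -mag),
    )


def shift_triple_from_slope(
    slope: float, base_year: int, variable: str, target_year: int = 2060
) -> tuple[ScenarioShift, ScenarioShift, ScenarioShift]:
    return tuple(
        build_shift(slope, base_year, d, target_year=target_year, variable=variable)
        for d in DIRECTIONS
    )


@dataclass
class ScenarioGrid:
    """The nine scenario environments plus per-site non-analog flags.

    ``tables`` maps combination names ("pHinc_TOCdec", ...) to site ×
    predictor tables; ``flags`` maps the same names to per-site boolean
    frames (one column per predictor plus "any").
    """

    tables: dict[str, pd.DataFrame]
    flags: dict[str, pd.DataFrame]

    @property
    def names(self) -> list[str]:
        return list(self.tables)


def combination_name(ph_dir: str, toc_dir: str) -> str:
    return f"pH{ph_dir}_TOC{toc_dir}"


def apply_scenarios(
    env_current: pd.DataFrame,
    climate_future: pd.DataFrame,
    ph_shifts=None,
    toc_shifts=None,
    env_training: pd.DataFrame | None = None,
) -> ScenarioGrid:
    """Build the nine climate × pH × TOC scenario tables.

    In every combination the three climate columns are replaced by the future
    values; pH is shifted additively; TOC is shifted on the raw percentage
    scale (floored at 0.01 %) and re-logged into the modelling column;
    radiation, topography and clay stay at current values.  If
    ``env_training`` is given, non-analog flags are computed against it.
    """
    ph_shifts = ph_shifts or default_shift_triple("pH")
    toc_shifts = toc_shifts or default_shift_triple("TOC")
    missing = [c for c in CLIMATE_PREDICTORS if c not in climate_future.columns]
    if missing:
        raise ValueError(f"future-climate table lacks columns: {missing}")
    if not set(env_current.index) == set(climate_future.index):
        raise ValueError("current and future tables must cover the same site ids")
    climate_future = climate_future.reindex(env_current.index)

    _check_triple(ph_shifts, "pH")
    _check_triple(toc_shifts, "TOC")

    tables: dict[str, pd.DataFrame] = {}
    flags: dict[str, pd.DataFrame] = {}
    toc_pct_current = np.exp(env_current[TOC_LOG].to_numpy())
    for ph_s in ph_shifts:
        for toc_s in toc_shifts:
            name = combination_name(ph_s.direction, toc_s.direction)
            tab = env_current.copy()
            for col in CLIMATE_PREDICTORS:
                tab[col] = climate_future[col]
            tab[PH] = env_current[PH] + ph_s.shift
            if toc_s.shift != 0.0:  # zero shift keeps the column bit-identical
                toc_pct = np.maximum(toc_pct_current + toc_s.shift, TOC_FLOOR)
                tab[TOC_LOG] = np.log(toc_pct)
            if ((tab[PH] < 2) | (tab[PH] > 10)).any():
                warnings.warn(
                    f"scenario {name}: shifted pH leaves [2, 10] at some sites", stacklevel=2
                )
            tables[name] = tab
            if env_training is not None:
                flags[name] = flag_non_analog(tab, env_training)
    return ScenarioGrid(tables=tables, flags=flags)


def _check_triple(triple, variable: str) -> None:
    dirs = [s.direction for s in triple]
    if sorted(dirs) != sorted(DIRECTIONS):
        raise ValueError(f"{variable} shifts must be one each of inc/now/dec, got {dirs}")
    by_dir = {s.direction: s for s in triple}
    if not math.isclose(by_dir["inc"].shift, -by_dir["dec"].shift, abs_tol=1e-12):
        raise ValueError(f"{variable}: inc and dec shifts must be sign-inverted equal magnitudes")
    for s in triple:
        if s.variable != variable:
            raise ValueError(f"shift variable {s.variable!r} does not match {variable!r}")


def flag_non_analog(env_future: pd.DataFrame, env_training: pd.DataFrame) -> pd.DataFrame:
    """Flag values strictly outside the training min-max per variable.

    The closed training interval counts as analogous; the returned frame has
    one boolean column per shared variable plus an ``any`` column.
    """
    common = [c for c in env_training.columns if c in env_future.columns]
    if not common:
        raise ValueError("future and training tables share no variables")
    lo = env_training[common].min(axis=0)
    hi = env_training[common].max(axis=0)
    out = pd.DataFrame(index=env_future.index)
    for c in common:
        out[c] = (env_future[c] < lo[c]) | (env_future[c] > hi[c])
    out["any"] = out[common].any(axis=1)
    return out


__all__ = [
    "DEFAULT_PH_SHIFT",
    "DEFAULT_TOC_SHIFT",
    "DIRECTIONS",
    "ScenarioGrid",
    "ScenarioShift",
    "apply_scenarios",
    "build_shift",
    "combination_name",
    "default_shift_triple",
    "estimate_mean_slope",
    "flag_non_analog",
    "shift_triple_from_slope",
]
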