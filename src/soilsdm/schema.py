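"""Predictor schema: the nine environmental variables used by the abundance models.

The models relate OTU read counts to three climatic, three topographic and
three edaphic predictors.  A :class:`PredictorSchema` declares their names and
plausible ranges; the synthetic generator samples within the ranges and the
scenario engine uses the names to know which columns are climate, which is pH
and which is the log-carbon column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


#: Canonical predictor names, in the order used throughout the package.
PH = "pH"
TOC_LOG = "TOC_log"
CLAY = "clay"
T_COLDQ = "T_coldQ"
P_DRYM = "P_dryM"
T_RANGE = "T_range"
SRAD = "sRad"
TPI = "TPI"
SLOPE = "slope"

#: The three predictors that change under the future-climate table.
CLIMATE_PREDICTORS = (T_COLDQ, P_DRYM, T_RANGE)


@dataclass(frozen=True)
class PredictorSchema:
    """Ordered set of nine named predictors with per-predictor (low, high) bounds.

    Parameters
    ----------
    names
        Exactly nine unique predictor identifiers.
    ranges
        Mapping from each name to a ``(low, high)`` pair with ``low < high``.
    """

    names: tuple[str, ...]
    ranges: dict[str, tuple[float, float]] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.names) != 9:
            raise ValueError(f"schema requires exactly 9 predictors, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("predictor names must be unique")
        missing = [n for n in self.names if n not in self.ranges]
        if missing:
            raise ValueError(f"missing ranges for predictors: {missing}")
        for name in self.names:
            low, high = self.ranges[name]
            if not (math.isfinite(low) and math.isfinite(high) and low < high):
                raise ValueError(f"invalid range for {name!r}: ({low}, {high})")

    def range_of(self, name: str) -> tuple[float, float]:
        if name not in self.ranges:
            raise KeyError(f"unknown predictor {name!r}")
        return self.ranges[name]


def default_schema() -> PredictorSchema:
    """Schema emulating a temperate mountain study area.

    pH spans acid to alkaline topsoil (3-8.5), TOC covers 0.5-60 % on a natural
    log scale, and the climatic/topographic ranges are loosely calibrated to a
    425-3120 m elevation gradient.
    """
    return PredictorSchema(
        names=(PH, TOC_LOG, CLAY, T_COLDQ, P_DRYM, T_RANGE, SRAD, TPI, SLOPE),
        ranges={
            PH: (3.0, 8.5),
            TOC_LOG: (math.log(0.5), math.log(60.0)),  # TOC % on ln scale
            CLAY: (0.0, 50.0),      # %
            T_COLDQ: (-14.0, 1.0),  # degC, coldest quarter
            P_DRYM: (60.0, 180.0),  # mm, driest month
            T_RANGE: (16.0, 26.0),  # K, annual range
            SRAD: (300.0, 1300.0),  # kJ, potential annual radiation
            TPI: (-100.0, 100.0),   # valley bottoms to ridge tops
            SLOPE: (0.0, 60.0),     # degrees
        },
    )
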