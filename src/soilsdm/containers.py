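"""Core in-memory containers.

Conventions used across the package:

* **Environmental tables** are plain :class:`pandas.DataFrame` objects with
  one row per site (index = site ids) and one column per predictor, matching a
  :class:`~soilsdm.schema.PredictorSchema`.
* **Count tables** are wrapped in :class:`ZOtuTable` / :class:`OtuTable`:
  a counts DataFrame with taxa in rows and sites in columns, plus per-site
  library sizes (total sequence counts *before* any filtering — the offset
  basis) and taxonomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate taxon ids: {dup}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate site ids: {dup}")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


@dataclass
class ZOtuTable:
    """zOTU (unique dereplicated amplicon sequence) counts per site.

    Parameters
    ----------
    counts
        Integer DataFrame, zOTUs in rows, sites in columns.
    taxonomy
        Per-zOTU phylum label; missing labels are NaN/empty.
    library_sizes
        Per-site raw total sequence count (pre-filter), used as model offset.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    library_sizes: pd.Series

    def __post_init__(self) -> None:
        _check_counts(self.counts)
        self.taxonomy = self.taxonomy.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = self.library_sizes.index[self.library_sizes.isna()].tolist()
            raise ValueError(f"missing library sizes for sites: {missing}")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")

    @property
    def zotu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class OtuTable:
    """OTU counts after agglomerating zOTUs under a distance cutoff."""

    counts: pd.DataFrame
    phylum: pd.Series
    library_sizes: pd.Series
    #: member zOTU ids per OTU; empty when the table was built directly.
    members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_counts(self.counts)
        self.phylum = self.phylum.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.library_sizes <= 0).any() or self.library_sizes.isna().any():
            raise ValueError("library sizes must be positive for every site")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def site_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass(frozen=True)
class SimilarityScores:
    """Square table of pairwise alignment scores between zOTU sequences.

    Invariants: symmetric, and each self-score is maximal in its row
    (a sequence aligns to itself at least as well as to anything else).
    """

    ids: tuple[str, ...]
    sim: np.ndarray

    def __post_init__(self) -> None:
        sim = np.asarray(self.sim, dtype=float)
        n = len(self.ids)
        if sim.shape != (n, n):
            raise ValueError(f"similarity table shape {sim.shape} does not match {n} ids")
        asym = np.argwhere(~np.isclose(sim, sim.T, rtol=0, atol=1e-9))
        if len(asym):
            i, j = asym[0]
            raise ValueError(
                f"similarity table is asymmetric at pair ({self.ids[i]!r}, {self.ids[j]!r}): "
                f"{sim[i, j]} != {sim[j, i]}"
            )
        diag = np.diag(sim)
        if (sim > diag[:, None] + 1e-9).any():
            raise ValueError("self-score must be maximal in its row")
        object.__setattr__(self, "sim", sim)


@dataclass(frozen=True)
class DistanceMatrix:
    """Non-negative symmetric distances with a zero diagonal."""

    ids: tuple[str, ...]
    dist: np.ndarray

    def __post_init__(self) -> None:
        dist = np.asarray(self.dist, dtype=float)
        n = len(self.ids)
        if dist.shape != (n, n):
            raise ValueError(f"distance matrix shape {dist.shape} does not match {n} ids")
        if not np.allclose(dist, dist.T, rtol=0, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(dist), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        if (dist < -1e-9).any():
            raise ValueError("distances must be non-negative")
        object.__setattr__(self, "dist", dist)


def validate_env(env: pd.DataFrame, schema) -> None:
    """Check an environmental table against a predictor schema.

    Raises ``ValueError`` listing missing/extra predictor columns.
    """
    missing = [n for n in schema.names if n not in env.columns]
    extra = [c for c in env.columns if c not in schema.names]
    if missing or extra:
        raise ValueError(
            f"environmental table does not match schema; missing={missing}, extra={extra}"
        )
    if env.isna().any().any():
        bad = env.columns[env.isna().any()].tolist()
        raise ValueError(f"environmental table has missing values in: {bad}")
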