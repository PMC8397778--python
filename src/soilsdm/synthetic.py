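"""Synthetic study generator.

Emulates every input the pipeline consumes — site × predictor environmental
tables, niche-structured OTU count tables with library-size variation and
negative-binomial noise, zOTU sequence/similarity fixtures for the clustering
step, paired soil-resurvey measurements, and a future-climate table — with the
generating ("truth") parameters retained so recovery tests can compare fitted
response curves and importances against known niches.

The community model is deliberately simple: each OTU's expected relative
abundance is Gaussian on the log-rate scale in every predictor,

    E[count at site s] = L_s * exp(b_k - sum_v (x_sv - m_kv)^2 / (2 w_kv^2)),

with library size ``L_s``, per-OTU baseline ``b_k``, optimum ``m_kv`` and
breadth ``w_kv``.  Realized counts are negative binomial around that mean.
Soil pH is the dominant niche axis by default, with optima skewed toward
neutral-alkaline conditions, so that community diversity increases along the
pH gradient as observed in calcareous mountain regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import OtuTable, SimilarityScores, ZOtuTable
from .schema import CLIMATE_PREDICTORS, P_DRYM, PH, PredictorSchema, T_COLDQ, T_RANGE, default_schema

#: The ten globally most abundant soil phyla used for phylum labelling.
DEFAULT_TOP_PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Acidobacteria",
    "Planctomycetes",
    "Chloroflexi",
    "Verrucomicrobia",
    "Bacteroidetes",
    "Firmicutes",
    "Gemmatimonadetes",
    "Cyanobacteria",
)


@dataclass
class NicheParams:
    """Ground-truth Gaussian niche parameters for a synthetic community.

    ``optimum``/``breadth`` are OTU × predictor DataFrames (breadth strictly
    positive, predictor units); ``baseline`` is the per-OTU log expected
    relative abundance at the niche centre.
    """

    optimum: pd.DataFrame
    breadth: pd.DataFrame
    baseline: pd.Series

    def __post_init__(self) -> None:
        if not self.optimum.index.equals(self.breadth.index):
            raise ValueError("optimum and breadth must share OTU ids")
        if not self.optimum.columns.equals(self.breadth.columns):
            raise ValueError("optimum and breadth must share predictors")
        if (self.breadth.to_numpy() <= 0).any():
            raise ValueError("niche breadth must be strictly positive")
        for df in (self.optimum, self.breadth):
            if not np.isfinite(df.to_numpy()).all():
                raise ValueError("niche parameters must be finite")
        self.baseline = self.baseline.reindex(self.optimum.index)
        if not np.isfinite(self.baseline.to_numpy()).all():
            raise ValueError("baseline log-rates must be finite")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.optimum.index)

    def log_rate(self, env: pd.DataFrame) -> pd.DataFrame:
        """True log relative abundance (OTU × site) at the given conditions."""
        x = env[self.optimum.columns].to_numpy()          # sites × preds
        m = self.optimum.to_numpy()[:, None, :]           # otus × 1 × preds
        w = self.breadth.to_numpy()[:, None, :]
        pen = ((x[None, :, :] - m) ** 2 / (2.0 * w**2)).sum(axis=2)
        lr = self.baseline.to_numpy()[:, None] - pen
        return pd.DataFrame(lr, index=self.optimum.index, columns=env.index)


@dataclass
class SyntheticDataset:
    """A full synthetic study: environment, counts, truth and seed."""

    env: pd.DataFrame
    counts: OtuTable
    library_sizes: pd.Series
    truth: NicheParams
    dispersion: float
    seed: int


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def generate_env_table(
    schema: PredictorSchema,
    n_sites: int,
    seed: int,
    site_prefix: str = "S",
    correlation: float = 0.0,
) -> pd.DataFrame:
    """Sample a site × predictor table uniformly within the schema ranges.

    ``correlation`` (in [0, 1)) optionally couples pH to the coldest-quarter
    temperature through a Gaussian copula, mimicking the pH-elevation
    covariance of real mountain transects; the default is independence.
    """
    if n_sites < 2:
        raise ValueError(f"n_sites must be >= 2, got {n_sites}")
    if not 0.0 <= correlation < 1.0:
        raise ValueError(f"correlation must be in [0, 1), got {correlation}")
    rng = _rng(seed)
    from scipy.stats import norm

    cols = {}
    u = {name: rng.uniform(size=n_sites) for name in schema.names}
    if correlation > 0.0:
        z_t = norm.ppf(u[T_COLDQ])
        z_ph = correlation * z_t + np.sqrt(1 - correlation**2) * norm.ppf(u[PH])
        u[PH] = norm.cdf(z_ph)
    for name in schema.names:
        low, high = schema.range_of(name)
        cols[name] = low + (high - low) * u[name]
    index = [f"{site_prefix}{i + 1:03d}" for i in range(n_sites)]
    return pd.DataFrame(cols, index=index)[list(schema.names)]


def generate_library_sizes(
    site_ids,
    seed: int,
    low: int = 50_000,
    high: int = 500_000,
) -> pd.Series:
    """Log-uniform library sizes: tenfold depth variation between samples."""
    if low < 1 or high <= low:
        raise ValueError("library size bounds must satisfy 1 <= low < high")
    rng = _rng(seed)
    sizes = np.exp(rng.uniform(np.log(low), np.log(high), size=len(site_ids)))
    return pd.Series(np.round(sizes).astype(np.int64), index=list(site_ids), name="library_size")


def generate_niche_params(
    schema: PredictorSchema,
    n_otus: int,
    seed: int,
    ph_optimum_range: tuple[float, float] = (6.8, 8.2),
    ph_breadth_range: tuple[float, float] = (0.6, 1.0),
    other_effect_range: tuple[float, float] = (0.5, 1.5),
    baseline_log_range: tuple[float, float] = (np.log(1e-4), np.log(1e-3)),
) -> NicheParams:
    """Draw a pH-dominant synthetic community.

    pH optima sit in the neutral-alkaline band with niche breadths well inside
    the sampled 3-8.5 gradient, giving a maximal log-rate drop of ~4.5-6 across
    the gradient.  The eight remaining predictors get optima uniform in range
    and breadths chosen so their maximal drop is ``other_effect_range`` —
    several-fold weaker, so pH carries most of the signal.
    """
    if n_otus < 1:
        raise ValueError(f"n_otus must be >= 1, got {n_otus}")
    rng = _rng(seed)
    otus = [f"OTU{i + 1:03d}" for i in range(n_otus)]
    opt = pd.DataFrame(index=otus, columns=list(schema.names), dtype=float)
    brd = pd.DataFrame(index=otus, columns=list(schema.names), dtype=float)
    for name in schema.names:
        low, high = schema.range_of(name)
        if name == PH:
            opt[name] = rng.uniform(*ph_optimum_range, size=n_otus)
            brd[name] = rng.uniform(*ph_breadth_range, size=n_otus)
        else:
            opt[name] = rng.uniform(low, high, size=n_otus)
            # breadth chosen so the worst-case drop across the range is the
            # sampled effect size: drop = (range/ breadth)^2 / 2 at distance = range
            effect = rng.uniform(*other_effect_range, size=n_otus)
            brd[name] = (high - low) / np.sqrt(2.0 * effect)
    baseline = pd.Series(rng.uniform(*baseline_log_range, size=n_otus), index=otus)
    return NicheParams(optimum=opt, breadth=brd, baseline=baseline)


def assign_phyla(otu_ids, seed: int, phyla=DEFAULT_TOP_PHYLA) -> pd.Series:
    """Random phylum labels over the configured dominant phyla."""
    rng = _rng(seed)
    return pd.Series(rng.choice(list(phyla), size=len(otu_ids)), index=list(otu_ids), name="phylum")


def generate_otu_counts(
    env: pd.DataFrame,
    truth: NicheParams,
    library_sizes: pd.Series,
    dispersion: float,
    seed: int,
    conditioned: bool = False,
    phylum: pd.Series | None = None,
) -> OtuTable:
    """Draw an OTU × site count table from the Gaussian-niche rate model.

    ``dispersion`` is the negative-binomial size parameter (variance =
    mu + mu^2 / dispersion); values >= 1e8 are treated as the Poisson limit.
    With ``conditioned=True`` each site's counts are drawn multinomially with
    the site's library size as the total, so column sums match library sizes
    exactly (rates renormalized within the simulated community).
    """
    if dispersion <= 0:
        raise ValueError(f"dispersion must be positive, got {dispersion}")
    missing = [c for c in truth.optimum.columns if c not in env.columns]
    if missing:
        raise ValueError(f"environment lacks predictors required by the niche truth: {missing}")
    lib = library_sizes.reindex(env.index)
    if lib.isna().any() or (lib <= 0).any():
        raise ValueError("library sizes must be positive for every site")
    rng = _rng(seed)
    rate = np.exp(truth.log_rate(env).to_numpy())          # otus × sites
    if conditioned:
        counts = np.empty_like(rate, dtype=np.int64)
        p = rate / rate.sum(axis=0, keepdims=True)
        for j, L in enumerate(lib.to_numpy()):
            counts[:, j] = rng.multinomial(int(L), p[:, j])
    else:
        mu = rate * lib.to_numpy()[None, :]
        if dispersion >= 1e8:
            counts = rng.poisson(mu)
        else:
            p = dispersion / (dispersion + mu)
            counts = rng.negative_binomial(dispersion, p)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=truth.otu_ids, columns=env.index)
    if phylum is None:
        phylum = assign_phyla(truth.otu_ids, seed=seed + 1)
    return OtuTable(
        counts=counts_df,
        phylum=phylum,
        library_sizes=lib.astype(np.int64),
        members={o: [o] for o in truth.otu_ids},
    )


def generate_dataset(
    n_sites: int = 255,
    n_otus: int = 60,
    dispersion: float = 1.0,
    seed: int = 0,
    schema: PredictorSchema | None = None,
    conditioned: bool = False,
) -> SyntheticDataset:
    """One-call synthetic study at the default scale (255 sites, 60 OTUs)."""
    schema = schema or default_schema()
    env = generate_env_table(schema, n_sites, seed=seed)
    lib = generate_library_sizes(env.index, seed=seed + 1)
    truth = generate_niche_params(schema, n_otus, seed=seed + 2)
    counts = generate_otu_counts(
        env, truth, lib, dispersion=dispersion, seed=seed + 3, conditioned=conditioned
    )
    return SyntheticDataset(
        env=env, counts=counts, library_sizes=lib, truth=truth, dispersion=dispersion, seed=seed
    )


def generate_projection_env(
    schema: PredictorSchema | None = None,
    n_sites: int = 229,
    seed: int = 100,
) -> pd.DataFrame:
    """Independent projection-site environmental table (default 229 sites)."""
    schema = schema or default_schema()
    return generate_env_table(schema, n_sites, seed=seed, site_prefix="P")


def generate_future_climate(
    env: pd.DataFrame,
    seed: int = 0,
    warming_coldq: float = 2.5,
    precip_factor: float = 0.9,
    d_trange: float = 0.5,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Mid-century climate table for the projection sites.

    Applies a uniform warming of the coldest quarter, a fractional drop of
    driest-month precipitation and a small widening of the annual range, plus
    site-level noise — a stand-in for a downscaled emissions-scenario raster.
    """
    rng = _rng(seed)
    fut = env[list(CLIMATE_PREDICTORS)].copy()
    fut[T_COLDQ] = fut[T_COLDQ] + warming_coldq + rng.normal(0, noise_sd, len(fut))
    fut[P_DRYM] = fut[P_DRYM] * precip_factor + rng.normal(0, noise_sd * 10, len(fut))
    fut[T_RANGE] = fut[T_RANGE] + d_trange + rng.normal(0, noise_sd, len(fut))
    return fut


def generate_resurvey_pairs(
    true_slope: float,
    noise_sd: float,
    n_pairs: int = 112,
    year_old: int = 1970,
    year_new: int = 2016,
    seed: int = 0,
    variable: str = "pH",
    value_range: tuple[float, float] = (3.5, 8.0),
) -> pd.DataFrame:
    """Paired resurvey records: value_new = value_old + slope*(dt) + noise.

    The default pair count (112) and years (1970 -> 2016) match a typical
    five-decade soil resurvey campaign.
    """
    if year_new <= year_old:
        raise ValueError(f"year_new ({year_new}) must be after year_old ({year_old})")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = _rng(seed)
    old = rng.uniform(*value_range, size=n_pairs)
    new = old + true_slope * (year_new - year_old) + rng.normal(0.0, noise_sd, size=n_pairs)
    return pd.DataFrame(
        {
            "site": [f"R{i + 1:03d}" for i in range(n_pairs)],
            "variable": variable,
            "value_old": old,
            "year_old": year_old,
            "value_new": new,
            "year_new": year_new,
        }
    )


# ---------------------------------------------------------------------------
# sequence / similarity fixtures for the clustering step
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def generate_similarity_fixture(
    n_seqs: int,
    seed: int,
    length: int = 80,
    n_families: int | None = None,
    mutation_rate: float = 0.05,
):
    """Short nucleotide sequences plus their all-against-all alignment scores.

    Sequences are substitution-mutated copies of a few random ancestors, so
    the score matrix carries block structure for clustering tests.  Scores
    come from a global match/mismatch alignment (match +5, mismatch -4); with
    equal-length substitution-only variants the self-score is maximal by
    construction.  Returns ``(records, SimilarityScores)`` where records is a
    list of ``(id, sequence)`` pairs.
    """
    if n_seqs < 2:
        raise ValueError(f"n_seqs must be >= 2, got {n_seqs}")
    rng = _rng(seed)
    if n_families is None:
        n_families = max(1, n_seqs // 4)
    ancestors = [rng.integers(0, 4, size=length) for _ in range(n_families)]
    seqs = []
    for i in range(n_seqs):
        anc = ancestors[int(rng.integers(0, n_families))]
        seq = anc.copy()
        n_mut = rng.binomial(length, mutation_rate)
        pos = rng.choice(length, size=n_mut, replace=False)
        seq[pos] = (seq[pos] + rng.integers(1, 4, size=n_mut)) % 4
        seqs.append("".join(_BASES[seq]))
    ids = tuple(f"zOTU{i + 1:03d}" for i in range(n_seqs))

    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=5.0, mismatch_score=-4.0,
        open_gap_score=-10.0, extend_gap_score=-1.0,
    )
    sim = np.zeros((n_seqs, n_seqs))
    for i in range(n_seqs):
        for j in range(i, n_seqs):
            sim[i, j] = sim[j, i] = aligner.score(seqs[i], seqs[j])
    return list(zip(ids, seqs)), SimilarityScores(ids=ids, sim=sim)


def generate_family_similarity(
    members: dict[str, list[str]],
    seed: int,
    length: int = 80,
):
    """Sequences and similarity scores matching a known zOTU membership.

    Each family (future OTU) gets one random ancestor; the first member is
    the ancestor itself and the others carry a single substitution.  With the
    +5/-4 match/mismatch scoring this puts within-family distances at 18-36
    and between-family distances in the thousands, so single linkage at any
    of the standard cutoffs recovers the families exactly.  Returns
    ``(records, SimilarityScores)``.
    """
    rng = _rng(seed)
    ids, seqs = [], []
    for family, member_ids in members.items():
        anc = rng.integers(0, 4, size=length)
        for k, zid in enumerate(member_ids):
            seq = anc.copy()
            if k > 0:
                pos = int(rng.integers(0, length))
                seq[pos] = (seq[pos] + int(rng.integers(1, 4))) % 4
            ids.append(zid)
            seqs.append("".join(_BASES[seq]))

    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global", match_score=5.0, mismatch_score=-4.0,
        open_gap_score=-10.0, extend_gap_score=-1.0,
    )
    n = len(ids)
    sim = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            sim[i, j] = sim[j, i] = aligner.score(seqs[i], seqs[j])
    return list(zip(ids, seqs)), SimilarityScores(ids=tuple(ids), sim=sim)


def generate_zotu_table(
    otus: OtuTable,
    zotus_per_otu: int,
    seed: int,
    taxonomy: pd.Series | None = None,
) -> tuple[ZOtuTable, dict[str, list[str]]]:
    """Split each OTU's counts multinomially over member zOTUs.

    Produces a zOTU table whose agglomeration under the true membership
    recovers ``otus`` exactly; used to exercise clustering + aggregation.
    Returns the table and the true OTU -> member-zOTU mapping.
    """
    if zotus_per_otu < 1:
        raise ValueError("zotus_per_otu must be >= 1")
    rng = _rng(seed)
    rows, ids, members = [], [], {}
    for otu in otus.otu_ids:
        member_ids = [f"{otu}_z{k + 1}" for k in range(zotus_per_otu)]
        members[otu] = member_ids
        w = rng.dirichlet(np.ones(zotus_per_otu))
        for k, zid in enumerate(member_ids):
            ids.append(zid)
        counts = np.vstack(
            [rng.multinomial(int(c), w) for c in otus.counts.loc[otu].to_numpy()]
        ).T  # zotus × sites
        rows.append(counts)
    counts_df = pd.DataFrame(
        np.vstack(rows).astype(np.int64), index=ids, columns=otus.site_ids
    )
    if taxonomy is None:
        taxonomy = pd.Series(
            {z: otus.phylum[o] for o, zs in members.items() for z in zs}, name="phylum"
        )
    zt = ZOtuTable(counts=counts_df, taxonomy=taxonomy, library_sizes=otus.library_sizes)
    return zt, members


__all__ = [
    "DEFAULT_TOP_PHYLA",
    "NicheParams",
    "SyntheticDataset",
    "assign_phyla",
    "generate_dataset",
    "generate_env_table",
    "generate_family_similarity",
    "generate_future_climate",
    "generate_library_sizes",
    "generate_niche_params",
    "generate_otu_counts",
    "generate_projection_env",
    "generate_resurvey_pairs",
    "generate_similarity_fixture",
    "generate_zotu_table",
]
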