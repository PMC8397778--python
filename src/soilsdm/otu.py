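"""zOTU -> OTU processing.

Converts pairwise alignment scores to distances, agglomerates zOTUs into OTUs
by single linkage at a distance cutoff, assigns each OTU the modal phylum of
its members, applies the total-count and prevalence filters, and offers
rarefaction to a common depth as the alternative normalization.
"""

from __future__ import annotations

import collections

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import DistanceMatrix, OtuTable, SimilarityScores, ZOtuTable
from .synthetic import DEFAULT_TOP_PHYLA

MISSING_PHYLUM = "Unclassified"
OTHER_PHYLUM = "Other"


def similarity_to_distance(sim: SimilarityScores) -> DistanceMatrix:
    """dist[i, j] = sim[i, i] + sim[j, j] - 2 sim[i, j].

    A score-based squared-distance analogue: identical sequences (whose cross
    score equals both self scores) are at distance zero, and the further the
    cross alignment falls below the self alignments the larger the distance.
    """
    s = sim.sim
    diag = np.diag(s)
    dist = diag[:, None] + diag[None, :] - 2.0 * s
    np.fill_diagonal(dist, 0.0)
    # self-score maximality guarantees non-negativity up to float noise
    dist = np.maximum(dist, 0.0)
    return DistanceMatrix(ids=sim.ids, dist=dist)


def single_linkage_cluster(dist: DistanceMatrix, cutoff: float) -> dict[str, list[str]]:
    """Cut the single-linkage dendrogram at ``cutoff`` (merge when dist <= cutoff).

    Equivalent to the connected components of the graph joining every pair at
    distance <= cutoff.  Returns a mapping from cluster label ("C001", ...) to
    member ids; clusters are numbered by order of their first member.
    """
    if cutoff < 0:
        raise ValueError(f"cutoff must be non-negative, got {cutoff}")
    n = len(dist.ids)
    if n == 1:
        return {"C001": [dist.ids[0]]}
    condensed = squareform(dist.dist, checks=False)
    z = linkage(condensed, method="single")
    labels = fcluster(z, t=cutoff, criterion="distance")
    clusters: dict[int, list[str]] = collections.defaultdict(list)
    for idx, lab in zip(dist.ids, labels):
        clusters[lab].append(idx)
    ordered = sorted(clusters.values(), key=lambda ms: dist.ids.index(ms[0]))
    return {f"C{i + 1:03d}": members for i, members in enumerate(ordered)}


def assign_phylum(
    member_labels,
    top_phyla=DEFAULT_TOP_PHYLA,
) -> str:
    """Modal phylum of the member zOTUs.

    Labels outside the configured ten globally dominant phyla are first mapped
    to "Other"; missing labels do not vote.  Ties break lexicographically and
    an all-missing member set yields "Unclassified".
    """
    labels = list(member_labels)
    if not labels:
        raise ValueError("assign_phylum requires at least one member label")
    top = set(top_phyla)
    votes = [
        (lab if lab in top else OTHER_PHYLUM)
        for lab in labels
        if isinstance(lab, str) and lab.strip()
    ]
    if not votes:
        return MISSING_PHYLUM
    counts = collections.Counter(votes)
    best = max(counts.values())
    return min(lab for lab, c in counts.items() if c == best)


def aggregate_counts(
    zotus: ZOtuTable,
    partition: dict[str, list[str]],
    top_phyla=DEFAULT_TOP_PHYLA,
) -> OtuTable:
    """Sum member zOTU counts into OTU counts; phylum = mode of member phyla."""
    covered = [z for members in partition.values() for z in members]
    if sorted(covered) != sorted(zotus.zotu_ids):
        missing = set(zotus.zotu_ids) - set(covered)
        extra = set(covered) - set(zotus.zotu_ids)
        raise ValueError(
            f"partition does not cover the table exactly; missing={sorted(missing)}, "
            f"unknown={sorted(extra)}"
        )
    rows, phyla = [], {}
    for otu, members in partition.items():
        rows.append(zotus.counts.loc[members].sum(axis=0))
        phyla[otu] = assign_phylum(zotus.taxonomy.loc[members], top_phyla=top_phyla)
    counts = pd.DataFrame(rows, index=list(partition)).astype(np.int64)
    return OtuTable(
        counts=counts,
        phylum=pd.Series(phyla, name="phylum"),
        library_sizes=zotus.library_sizes,
        members={k: list(v) for k, v in partition.items()},
    )


def filter_low_count_zotus(zotus: ZOtuTable, min_total: int = 100) -> ZOtuTable:
    """Drop zOTUs whose total count across all sites is below ``min_total``.

    Library sizes are pre-filter totals and stay unchanged.
    """
    keep = zotus.counts.sum(axis=1) >= min_total
    return ZOtuTable(
        counts=zotus.counts.loc[keep],
        taxonomy=zotus.taxonomy.loc[keep],
        library_sizes=zotus.library_sizes,
    )


def filter_low_prevalence_otus(otus: OtuTable, min_sites: int = 21) -> OtuTable:
    """Keep OTUs present (count >= 1) in at least ``min_sites`` sites."""
    keep = (otus.counts >= 1).sum(axis=1) >= min_sites
    kept = otus.counts.index[keep]
    return OtuTable(
        counts=otus.counts.loc[keep],
        phylum=otus.phylum.loc[keep],
        library_sizes=otus.library_sizes,
        members={k: v for k, v in otus.members.items() if k in set(kept)},
    )


def rarefy(zotus: ZOtuTable, depth: int, seed: int) -> ZOtuTable:
    """Subsample each site to ``depth`` reads without replacement.

    One multivariate-hypergeometric draw per site; sites with fewer than
    ``depth`` total reads are dropped.  After rarefaction the library size of
    a retained site is the common depth.
    """
    if depth < 1:
        raise ValueError(f"depth must be >= 1, got {depth}")
    totals = zotus.counts.sum(axis=0)
    keep_sites = totals.index[totals >= depth]
    if len(keep_sites) == 0:
        raise ValueError(
            f"rarefaction depth {depth} exceeds every site total (max {int(totals.max())})"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for site in keep_sites:
        col = zotus.counts[site].to_numpy()
        out[site] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=zotus.counts.index).astype(np.int64)
    lib = pd.Series(depth, index=keep_sites, dtype=np.int64, name="library_size")
    return ZOtuTable(counts=counts, taxonomy=zotus.taxonomy, library_sizes=lib)


def cluster_zotus(
    zotus: ZOtuTable,
    sim: SimilarityScores,
    cutoff: float,
    top_phyla=DEFAULT_TOP_PHYLA,
) -> OtuTable:
    """Distance conversion + single linkage + aggregation in one call."""
    dist = similarity_to_distance(sim)
    partition = single_linkage_cluster(dist, cutoff)
    return aggregate_counts(zotus, partition, top_phyla=top_phyla)


__all__ = [
    "MISSING_PHYLUM",
    "OTHER_PHYLUM",
    "aggregate_counts",
    "assign_phylum",
    "cluster_zotus",
    "filter_low_count_zotus",
    "filter_low_prevalence_otus",
    "rarefy",
    "similarity_to_distance",
    "single_linkage_cluster",
]
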