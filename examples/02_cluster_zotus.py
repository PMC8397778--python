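"""Cluster zOTU sequences into OTUs from pairwise alignment scores.

Similarity scores are converted to distances via
dist[i,j] = sim[i,i] + sim[j,j] - 2 sim[i,j], then single-linkage clusters
are cut at distances 20, 40 and 60.  Coarser cutoffs can only merge
clusters, so the OTU count is non-increasing.
"""

import soilsdm as s

records, sim = s.generate_similarity_fixture(n_seqs=30, seed=7)
print("sequences:", len(records), "x", len(records[0][1]), "nt")

dist = s.similarity_to_distance(sim)
print("distance matrix: diagonal max %.1f (identical sequences are at 0)"
      % abs(dist.dist.diagonal()).max())

for cutoff in (20.0, 40.0, 60.0):
    part = s.single_linkage_cluster(dist, cutoff)
    sizes = sorted((len(v) for v in part.values()), reverse=True)
    print(f"cutoff {cutoff:>4}: {len(part):2d} OTUs, largest {sizes[0]} members")

print("\nFewer, larger OTUs at coarser cutoffs — the clustering-resolution "
      "axis of the analysis.")
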