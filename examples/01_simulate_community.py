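"""Generate the default synthetic study and inspect its structure.

Builds a 255-site environmental table over nine predictors, a pH-dominant
Gaussian-niche community of 60 OTUs, log-uniform library sizes (tenfold
depth variation) and negative-binomial counts (dispersion 1).
"""

import numpy as np

import soilsdm as s

ds = s.generate_dataset(n_sites=255, n_otus=60, dispersion=1.0, seed=0)

print("environment:", ds.env.shape, "sites x predictors")
print("pH range: %.2f - %.2f" % (ds.env["pH"].min(), ds.env["pH"].max()))
print("library sizes: %d - %d reads" % (ds.library_sizes.min(), ds.library_sizes.max()))
print("counts:", ds.counts.counts.shape, "OTUs x sites,",
      "total reads %.2g" % ds.counts.counts.to_numpy().sum())

occ = (ds.counts.counts >= 1).sum(axis=1)
print("OTU prevalence: median %d sites, %d OTUs pass the >=21-site filter"
      % (occ.median(), (occ >= 21).sum()))

print("\ntrue pH niche (first 5 OTUs):")
print(ds.truth.optimum["pH"].head().round(2).to_string())
print("\nThese optima are the ground truth that response-curve recovery "
      "tests compare against.")
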