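# soilsdm

Abundance-based species distribution modelling (SDM) of soil bacterial OTUs,
with library-size offsets and projection of community change under crossed
climate × soil-pH × soil-carbon scenarios.

## The problem

Soil bacterial communities are driven foremost by soil pH, together with
organic carbon, texture, climate and topography. Sequencing surveys deliver
per-site read counts of thousands of taxa, but raw counts are not comparable
across samples: total library size varies by an order of magnitude. This
package implements an SDM workflow adapted to such relative-abundance data:

1. **OTU construction** — pairwise alignment scores between unique amplicon
   sequences (zOTUs) are converted to distances,
   `dist[i,j] = sim[i,i] + sim[j,j] − 2·sim[i,j]`, and single-linkage
   clusters are cut at distances 20/40/60; OTU counts are member-wise sums,
   the OTU phylum is the mode of member phyla. Rare zOTUs (total < 100 reads)
   and sparse OTUs (< 21 occupied sites) are removed; rarefaction without
   replacement is available as the alternative normalization.
2. **Abundance models** — for each OTU,
   `log E[count_s] = log L_s + Σ_v f_v(x_sv)`, where `L_s` is the site's
   total read count (offset) and `f_v` are penalized cubic splines over nine
   environmental predictors; the response is Poisson (GAMp) or negative
   binomial (GAMnb, dispersion estimated by profile likelihood). A Poisson
   gradient-boosting engine (GBM: 2000 trees, interaction depth 3, shrinkage
   0.01) captures predictor interactions.
3. **Assessment** — fit quality `cor_expl` (observed vs fitted Pearson
   correlation) and predictive skill `cor_pred` (ten random 80/20
   calibration/evaluation splits; each site is evaluated on average twice and
   its held-out predictions are averaged). OTUs with both correlations < 0.2
   are excluded from projections. Predictor importance by permutation
   (correlation drop under column shuffling) or Friedman relative influence.
4. **Scenarios and projection** — mean per-year slopes from paired soil
   resurveys are extrapolated to 2060 (defaults: ±0.3 pH units, ±3.2 TOC
   percentage points), crossed with a future-climate table into nine
   scenario environments; projection sites outside the training min–max
   envelope are flagged non-analogous. Stacked per-OTU projections yield
   community summaries: proportion of OTUs above their median abundance,
   Shannon index `H = −Σ p ln p`, and per-phylum relative abundance.

A first-class synthetic-data generator emulates the study design (255
training sites, 229 projection sites, nine predictors, pH-dominant Gaussian
niches on the log-rate scale, negative-binomial noise, tenfold library-size
variation) with known ground truth, so niche recovery and the direction of
projected change are testable end to end.

## Worked example

Fit one OTU's negative-binomial spline model and recover its niche
(`examples/03_fit_abundance_model.py`):

```text
OTU006: 1002 reads over 105 sites
smoothing penalty (GCV-selected): 0.1
NB dispersion alpha (profile): 0.386
cor_expl (observed vs fitted): 0.824
pH response-curve argmax: 7.44  (true optimum 7.34)
```

The nine predictors explain most of this OTU's count variation
(`cor_expl = 0.82`), and the pH response curve peaks within 0.1 units of the
simulated niche optimum. Scoring the same community
(`examples/04_assess_models.py`):

```text
split plan: 10 repeats, 204 calibration / 51 evaluation sites
cor_expl = 0.888, cor_pred = 0.671
retained for projections: True (excluded only when BOTH are < 0.2)

permutation importance (%):
pH         67.5
T_coldQ    14.4
P_dryM      8.9
...
```

pH dominates the importance ranking, as simulated. Projecting the pH
scenarios (`examples/05_project_scenarios.py`) shows the expected direction
of community change:

```text
pHinc_TOCnow: mean Shannon 1.757
pHnow_TOCnow: mean Shannon 1.728
pHdec_TOCnow: mean Shannon 1.695
```

Acidification lowers projected diversity relative to alkalinisation at most
projection sites. The other examples cover simulation, clustering, and the
end-to-end pipeline driver (also available as a CLI:
`soilsdm all --seed 1 --output-dir run/`).

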