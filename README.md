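# cohesion-delim

Cohesion species delimitation as a reusable, tested pipeline. The package
covers the two cohesion mechanisms end to end:

- **Ecological interchangeability** — presence-background maximum-entropy-style
  species distribution models (candidate grid of feature classes x
  regularization multipliers, AICc selection), Schoener's D niche overlap,
  one-tailed niche **equivalency** (identity) randomization tests, two-tailed
  niche **similarity** (background) tests, and three background-region
  constructions (occurrence convex hull, suitability > 0.5, suitability
  > 0.75) whose choice is known to swing similarity inference.
- **Genetic exchangeability** — replicate single-SNP-per-locus matrices from
  phased per-locus alignments, one-hot encoding, a 2-D-latent variational
  autoencoder (NumPy) plus PCA for morphology, and a quantitative
  separate/overlapping cluster verdict (silhouette + adjusted Rand index).
- **Decision engine** — explicit, configurable rejection rules for genetic
  exchangeability (geography + barrier + clustering) and ecological
  interchangeability (equivalency AND all-direction divergence), combined
  under a `conservative_both` or `flowchart_either` policy, with full
  evidence trails and a summary table.
- **Synthetic data** — spatially autocorrelated, optionally inter-correlated
  climate layers; Gaussian-niche occurrence sampling; an F-model (Balding–
  Nichols) simulator for phased locus alignments with controllable
  completeness; log-normal trait tables. Every downstream stage is testable
  with known ground truth and no external downloads.

Module map: `synthetic_data`, `climate_prep`, `sdm`, `backgrounds`,
`niche_tests`, `genetic_clustering`, `decision_engine` under
`src/cohesion_delim/`.

Raster stacks are stored as plain-text directories (`stack.json` + one
`.asc` grid per layer) so all artifacts are diffable text.

## CLI

```sh
cohesion-delim simulate --preset three-lineage --seed 1 --out data/
cohesion-delim prep --stack data/stack --corr-threshold 0.8 --out prepped/
cohesion-delim sdm --occ data/occurrences.csv --stack prepped/stack \
    --lineage North --fc L,LQ,H,LQH,LQP,LQPH --rm 0.5,1,2,3,4 --seed 1 --out sdm_out/
cohesion-delim nichetests --config nichetests.yaml --reps 99 --seed 1 --out tests.csv
cohesion-delim cluster --loci data/loci --lineage-map inds.csv --sets 5 --reps 3 \
    --seed 1 --out cluster_out/
cohesion-delim decide --assessments assessments.yaml --policy conservative_both \
    --background thresh75 --out table.csv
```

## Notes

- Replicate fits inside the randomization tests reuse the feature class and
  regularization multiplier selected for the observed models
  (`FitConfig.reselect_per_rep=True` restores full per-replicate selection).
- Schoener's D is always computed on raw (sum-to-one) surfaces; the logistic
  view is used for display and for the 0.5/0.75 background thresholds.
- Detecting niche *divergence* with a similarity test requires a background
  region containing environments shared between the lineages (e.g. the
  occurrence convex hull); a lineage's own suitability-thresholded region
  biases the test toward conservatism.
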