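# storystates

Context-modulated brain-state dynamics during naturalistic story listening,
as a tested, reusable pipeline:

- **Gaussian-HMM brain states** on network-level fMRI time series
  (dwell-time-prior initialization, 5 seeded restarts, identity-plus-ridge
  covariances, Viterbi/posterior decoding, leave-one-subject-out CV,
  Hungarian state matching across models);
- **state reliability screening** (activation > 0.1, bootstrap CI width
  < 0.3, split-half reliability > 0.5) and **Jaccard consensus clustering**
  of reliable states pooled across groups and model sizes (average linkage,
  similarity threshold 0.8 with a 0.6–0.9 stability sweep, occupancy-ordered
  cluster IDs, 50%-consensus binary patterns, context-provenance labels,
  representative-state selection from combined-group models);
- **MAP Bayesian logistic mixed models** linking per-TR story annotations to
  brain-state occupancy and to behavioral button presses (deviation-coded
  group, feature×group interactions, AR(2) outcome lags, subject random
  intercepts, Laplace posterior SDs, direction probabilities, Bayesian FDR,
  odds-ratio decomposition into group-specific effects);
- **permutation tests** of group occupancy-time-course differences
  (group-size-preserving random participant splits, add-one p-values);
- a **synthetic-data generator** (Markov state paths with Gaussian network
  emissions, bursty binary annotation streams, logistic occupancy/press
  generation with random intercepts) providing ground truth for every stage.

## CLI

```bash
storystates run-all --out runs/demo --seed 1            # full pipeline
storystates simulate --out runs/sim --seed 1            # synthetic data only
storystates prep --in raw/ --out prepped/               # shift/trim/z-score
storystates fit-hmm --series-dir runs/sim/series --k 4 --out hmm.json
storystates cv --series-dir runs/sim/series --k 4 --out cv.json
storystates filter-states --series-dir runs/sim/series --k-min 2 --k-max 5 --out patterns.tsv
storystates cluster-states --patterns patterns.tsv --threshold 0.8 \
    --sweep 0.6:0.9:0.05 --out clusters.json
storystates glmm-brain --features features.tsv --occupancy occ.tsv --out brain.tsv
storystates glmm-behavior --features features.tsv --presses presses.tsv --out beh.tsv
storystates permute --occupancy occ.tsv --n-perm 10000 --seed 1 --out perm.json
```

All commands accept `--config run.json` (see `storystates.config.RunConfig`
for the schema and defaults) and `--seed`; every output embeds the config
hash and seed for provenance. Tabular interchange is TSV; nested results are
JSON.

## Layout

```
src/storystates/
  simulate.py      synthetic Markov-Gaussian series, annotations, presses
  prep.py          shift/trim, parcel->network averaging, z-score, concat
  hmm.py           Gaussian HMM fitting, decoding, LOOCV, state matching
  reliability.py   occupancy, bootstrap CIs, split-half, state filters
  clustering.py    Jaccard consensus clustering and cluster reporting
  annotations.py   per-TR feature schema, composites, event rasterization
  glmm.py          MAP logistic mixed models, direction probs, Bayesian FDR
  behavior.py      press alignment and group agreement
  permutation.py   group-difference permutation tests
  config.py/io.py/pipeline.py/cli.py   configuration, formats, driver, CLI
```
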