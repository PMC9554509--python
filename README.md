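# lohmil

Estimation of tumor homologous-recombination-deficiency (HRD) status from
loss-of-heterozygosity (LOH) segment tables, using a multi-instance
learning model with K learned "target concept" points.

Each tumor sample is a *bag* whose instances are the LOH segments called by
an allele-specific copy-number caller (FACETS-style `*_cncf` TSV tables).
Only the sample carries an HRD label. Training alternates an E-step
(select one representative segment per sample per concept, with a
reliability threshold `Pro`) and an M-step (quasi-Newton re-optimisation of
each concept over its reliable representatives), minimising a negative log
diverse-density objective. At prediction time every segment is scored by
its mean squared-exponential affinity to the K concepts; a sample's HRD
score is its best segment score, and the sample is called positive when
that score reaches the learned threshold.

## Layout

| module | contents |
| --- | --- |
| `lohmil.facets_io` | cncf TSV parsing/writing, 9-feature extraction, min-max normalisation, bag assembly |
| `lohmil.mil` | similarity/diverse-density primitives, E/M steps, the trainer, model (de)serialisation |
| `lohmil.scoring` | per-segment scores, sample-level HRD score and status call, prediction output |
| `lohmil.feature_select` | noisy-OR boosting feature importance and the feature-count ablation study |
| `lohmil.evaluate` | precision/sensitivity/F1, stratified k-fold CV, nested CV, bootstrap |
| `lohmil.synthetic` | generator of labeled bags with planted concepts, and FACETS-dialect table emission |

## Command-line usage

```sh
# generate a synthetic cohort (per-sample *_cncf.tsv + labels.tsv + truth.json)
lohmil simulate --out data/ --n-pos 28 --n-neg 28 --seed 7

# fit a K=3 model
lohmil train --data data/ --out model.json -k 3 --pro 0.9 --seed 0

# score samples (optional per-segment audit file)
lohmil predict --model model.json --data data/ --out predictions.tsv \
    --per-instance segments.tsv

# cross-validate / bootstrap
lohmil evaluate --data data/ --mode kfold --folds 10 --out report
lohmil evaluate --data data/ --mode bootstrap --replicates 500 --out report

# feature importance and ablation
lohmil select-features --data data/ --importance-out importance.tsv
```

Input conventions: a dataset directory holds one `<sample>_cncf.tsv` per
sample (14 FACETS columns, dotted or underscore headers) and a two-column
`labels.tsv` (`sample_id<TAB>label`, labels `1`/`-1` or `pos`/`neg`).
Prediction output is `sample_id<TAB>hrd_score<TAB>hrd_status`.

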