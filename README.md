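# pepregex

Genetic programming over regular expressions for peptide
sequence–function modelling, applied to the design of CEST MRI
contrast-agent peptides.

## The problem

Chemical exchange saturation transfer (CEST) MRI detects peptides whose
exchangeable protons (amide, amine, hydroxyl, guanidine — abundant in
K, R, S, T) transfer saturation to water; the read-out is the
magnetization transfer ratio asymmetry at ±3.6 ppm,
MTRasym = (S(−3.6 ppm) − S(+3.6 ppm)) / S0.  Finding peptides with high
CEST contrast is a search over 20ⁿ sequences guided by small labelled
panels (order 10² peptides), far too little data for deep models.

`pepregex` addresses this with an explicit, interpretable model: an
individual is an ordered list of rules, each rule a regular expression
over the amino-acid alphabet with a real weight.  A peptide's predicted
score is the sum of the weights of the rules that match it.  Weights
are not free parameters: they are set deterministically from a motif
database (every 1–6-mer of the training peptides, classed above/below
the poly-L-lysine threshold T = 12.5 and priced by the "occurrence"
method), via

    w(rule) = Σ over matches m  ± cest(m) · |m|,   + if cest(m) ≥ T, − otherwise.

A genetic-programming loop (tournament selection k = 5, one-point
rule-list crossover p = 0.9, list- and tree-level mutations p = 0.1,
elitism, μ+λ reduction) evolves the rule lists; fitness is the Pearson
correlation r between predicted scores and measured CEST, estimated by
6-fold cross-validation with per-fold retraining.  A trained model then
drives in-silico directed evolution: a 1000-peptide random library is
iterated through mutate–score–select cycles, filtered for
hydrophilicity (Hopp–Woods sums > 0), and the top 20 candidates are
reported.  A `random_weights` ablation mode (weights random, never
trained) isolates the contribution of the training step.

See `docs/methods.md` for the full model description, parameter
defaults, and known limitations.

## Worked example

Everything runs from synthetic data with planted ground truth, so no
download is needed:

```sh
pepregex fixtures --n 158 --seed 7 --out demo.csv
# wrote 158 peptides to demo.csv

pepregex train --train demo.csv --out-dir run \
    --population-size 60 --generations 15 --seed 7
# best fitness 0.6102 (eval 0.6168), 26 rules -> run/model.tsv

pepregex evolve --model run/model.tsv --cycles 100 \
    --library-size 1000 --top 5 --seed 7 --out candidates.csv
# 5 candidates -> candidates.csv

pepregex stats --data demo.csv --out-prefix report
# 12403 pairs; 0.06% above 50% identity
```

The training line reports the cross-validated fitness of the best
evolved model: mean training-fold Pearson r = 0.61 and mean held-out
r = 0.62 between predicted scores and the (synthetic) CEST contrasts —
on this noisy 158-peptide panel the model explains a substantial part
of the contrast variance without overfitting (train ≈ held-out).
`candidates.csv` ranks hydrophilic designed peptides by model score:

```
rank,sequence,score,hydrophilicity
1,GRRNNQNKKFGR,-32691.43,13.30
2,RNQGGKRNQMKN,-32691.43,11.70
```

Scores are raw weight sums: their scale is arbitrary (only the ranking
and the correlation with contrast are meaningful), and with small
training runs they can be negative overall; the hydrophilicity column
is the Hopp–Woods sum, positive for every reported candidate.  Model
files (`run/model.tsv`) are plain TSV with one `id  pattern  weight`
row per rule plus the serialized tree, so models are fully inspectable.

The library surface mirrors the CLI: `make_synthetic_dataset`,
`build_mdb`, `run_evolution`, `run_directed_evolution`, and the data
utilities (`split_dataset`, `pairwise_identity`, `composition_stats`,
`mtr_asym`) are all importable from `pepregex`.

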