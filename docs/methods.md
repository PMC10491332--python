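# Methods

`pepregex` learns peptide → CEST-contrast models from small labelled
peptide panels and uses them to design new candidate contrast-agent
peptides.  This note describes the model, the algorithms, the synthetic
data the package is validated against, and the numerical and design
choices a user should know about.

## The problem and the data

Chemical exchange saturation transfer (CEST) MRI detects peptides whose
exchangeable protons (amide, amine, hydroxyl, guanidine) transfer
saturation to water.  The quantitative read-out is the magnetization
transfer ratio asymmetry at ±3.6 ppm,

    MTRasym = (S(−3.6 ppm) − S(+3.6 ppm)) / S0,

exposed as a standalone utility (`peptide_data.mtr_asym`).  The input to
the learning pipeline is a table of short peptides (typically 10–13
residues over the 20 standard amino acids) each labelled with its
measured CEST contrast at 3.6 ppm, in percent.  Panels of this kind are
small (order 10²), which rules out data-hungry learners and motivates a
genetic-programming approach with an explicit, interpretable model.

## The motif database and the occurrence method

Every substring of length 1–6 of the training peptides is a motif.  A
training sequence is *class 1* when its CEST is at or above the class
threshold `T` and *class 0* otherwise; `T` defaults to 12.5, the
contrast of the poly-L-lysine gold standard K12.  (The boundary case
CEST = T is class 1, consistent with the `≥ T` branch of the weight
equation below.)  Each motif is assigned

* the class in which its *window instances* are more numerous (a motif
  occurring twice in one sequence counts twice; ties go to class 1), and
* the mean CEST of the winning class's sequences that contain it.

Lookups are exact-string; nothing longer than 6 residues is stored.
The conventional "database size" report counts motifs of length 2–6,
although single residues are stored and used.

## The model: weighted lists of regular expressions

A model (an *individual* in the evolutionary search) is an ordered list
of up to 30 rules, each rule a regular expression with a real weight.
Patterns are binary trees over seven operators — concatenation,
alternation `|`, `+`, fixed repetition `{n}` with n ∈ [2, 6], character
class `[...]`, negated class `[^...]` (restricted to the 20-letter
alphabet) and grouping `(...)` — with leaves holding 1–6 amino-acid
letters.  A leaf under a class node is a character set; elsewhere it is
a literal run.  Trees are stored in the implicit-array layout (children
of node *i* at 2*i*+1, 2*i*+2) with a depth cap of 6, which keeps
patterns cheap to match against 10–13-mers.  Rendering is deterministic
in-order emission; an operand that already ends in a quantifier is
parenthesised before another quantifier is applied, so every rendered
pattern compiles and none can match the empty string.

Matching uses leftmost-longest non-overlapping semantics: the scanner
finds the leftmost feasible start, takes the longest match anchored
there, and resumes after it.  (Backtracking engines natively return the
*first* alternative, not the longest; the package anchors candidate ends
explicitly so that `(K|KK)` on `"KK"` yields one two-letter match.)

### Weight training

Rule weights start at 0 and are set deterministically from the data:
for each rule, every match in every training sequence is looked up in
the motif database and contributes

    + cest(motif) × len(motif)   if cest(motif) ≥ T
    − cest(motif) × len(motif)   otherwise,

summed over all matches.  Matches absent from the database (longer than
6 residues, or unseen substrings) contribute 0 and are counted in a
diagnostic.  Weights are the raw sums by default; a mean-per-sequence
normalization (`train_weights(..., normalize=True)`) is available for
cross-dataset comparability but off by default.

A consequence worth knowing: weight *sign* comes from the matched
motif's database CEST value, i.e. from the mean contrast of the motif's
majority class.  A motif that genuinely raises contrast but whose
supporting sequences mostly sit below `T` trains to a *negative* weight.
The synthetic-data tests exhibit exactly this on a planted motif whose
contribution (+4) leaves single-motif sequences below the threshold.

### Scoring and fitness

A peptide's predicted score is the sum of the weights of the rules that
match it at least once (a rule matching three times still counts once).
Fitness is the Pearson correlation between predicted scores and
measured CEST, estimated by k-fold cross-validation with k = 6: for
each fold the motif database and all weights are rebuilt from the other
k−1 folds (the stricter no-leakage reading), giving a training-folds
correlation `r_train` and a held-out correlation `r_eval` on the ~16%
fold.  Fitness is the mean `r_train`; the mean `r_eval` monitors
overfitting.  Pearson on a constant vector is defined as 0 so that
every candidate has a defined, totally ordered fitness.

## The evolutionary search

A generational μ+λ loop with μ = λ = `population_size`:

* **Initialisation** — individuals hold 1–8 rules with weight 0; trees
  come from ramped half-and-half over depths 2–6 (depths cycle, grow
  and full alternate).
* **Selection** — tournaments of k = 5 drawn with replacement; ties
  break toward fewer rules, then the lower (earlier) individual id, so
  runs are bit-reproducible.
* **Crossover** (p = 0.9) — one-point cuts in each parent's rule list
  (ends allowed); offspring are head₁+tail₂ and head₂+tail₁, truncated
  to 30 rules; an empty child receives one fresh rule.  Non-crossover
  pairs are cloned so mutation still applies.
* **Mutation** (p = 0.1) — list level: add / replace / delete a rule
  (add suppressed at the 30-rule cap, delete below 2 rules); tree
  level, per rule at p = 0.1: branch replacement, node inversion
  (concat↔alt, class↔negated class, leaf-letter or repeat-count
  resample), subtree deletion (replaced by a fresh leaf — the array
  layout and arities stay intact), or appending 1–4 letters to a leaf
  (capped at 6).
* **Elitism and reduction** — the pre-variation best is carried over
  unchanged; the next generation is the best `population_size` of
  parents ∪ offspring ∪ elite, so best-so-far fitness is monotone.
* **Stopping** — a fixed generation budget; an optional plateau stop
  (`plateau_patience`) is off by default.

Full-scale defaults mirror the canonical configuration (population
1000, 300 generations, 30 rules, crossover 0.9, mutation 0.1, depth 6,
tournament 5).  The test suite and the acceptance script run the same
loop at population 100 × 30 generations on 150-peptide synthetic data,
a size chosen so the whole validation completes on one CPU in minutes;
per-individual evaluation is independent, and the engine memoises
per-pattern fold weights and match masks, which is numerically
identical to plain per-fold retraining (asserted in the tests).

### The random-weight ablation

`mode="random_weights"` isolates the value of weight training: weights
are drawn uniformly from [−100, 100] at initialisation (range
configurable; no distribution is canonical), change only through
mutation (resampling at p = 0.1), and the training step never runs —
instrumentation counters assert this.  On the noise-free synthetic
data the *mean* held-out correlation of trained runs exceeds the
ablation's across 10 paired seeds, echoing the direction of the
original comparison; per-seed win counts are noisier, because with a
small, noise-free dataset the ablation's freedom to tune weights by
selection partly compensates for its uninformed initialisation,
whereas equation-trained weights can be badly scaled (a catch-all rule
can train to |w| ~ 10⁴ while an informative rule sits near 10²).

## Directed evolution of candidate peptides

Given a trained model, a library of `library_size` (default 1000)
random 12-mers is evolved for a chosen number of cycles (10 / 100 /
1000 span the diversity–convergence trade-off): each cycle substitutes
one uniformly chosen residue per peptide and keeps the mutant only if
its score strictly increases, so per-peptide score trajectories are
non-decreasing and library size is constant.  Afterwards peptides whose
summed per-residue hydropathy values are ≤ 0 are discarded (solubility
proxy) and the `top_k` (default 20) by score are reported, ties
preferring higher hydrophilicity then lexicographic order.  The shipped
default scale is Hopp–Woods; it is a synthetic stand-in for the
measured scale used with the original wet-lab data, and is a required,
swappable input.

## The synthetic-data generator

`synthetic.make_synthetic_dataset` emulates the study-shaped data: 158
peptides (default), lengths uniform on 10–13, residues drawn with a
composition bias giving K+R+S+T ≈ 45% and W ≈ 5% of residues, and

    CEST = base + Σ_m contribution_m × count(m, sequence) + N(0, noise_sd),

clipped at 0, with default base 7.0, noise 1.5 and planted motifs
KK (+4), QSL (+5), RS (+3).  Each planted motif is additionally written
into a `plant_rate` = 0.35 fraction of sequences so its prevalence does
not depend on composition chance alone.  The additive form matches the
additive weight-training rule, so learnability of the ground truth is
analytically clear.  An optional `max_motif_occurrences=1` rejection
cap yields data on which presence-based scoring is *exactly* linear in
CEST; on that fixture the hand-built model whose rules are the planted
motifs with weights equal to their contributions attains Pearson r = 1
exactly — the end-to-end correctness oracle.

What the generator does **not** emulate: real CEST chemistry (context
effects, pH/temperature dependence, saturation-power dependence),
correlated measurement error, or the composition quirks of any real
panel.  Passing tests therefore demonstrate that the algorithms are
implemented correctly and can recover planted structure — not that the
method attains any particular accuracy on laboratory data.

## Numerical and degenerate-input conventions

* Sequence identity between two peptides is ungapped: identical letters
  at aligned positions from position 1, divided by the *longer* length
  (×100).  No alignment is attempted; for equal-length pairs the
  denominator choice is moot.
* Train/test splitting takes `ceil(fraction × n)` records for the train
  part (an 80% split of 158 gives the conventional 127/31).
* Pearson on fewer than 2 points is an error; on a constant vector it
  is 0 by convention.
* Class-boundary CEST = T is class 1.  Class-count ties go to class 1
  (biasing search toward positive motifs; configurable at the call
  site by the threshold choice).
* The random-weight range, repeat-count range [2, 6] and leaf length
  cap 6 are stated in `regex_tree`/`gp_engine` constants.
* All randomness flows from explicit `numpy.random.Generator` objects;
  the CLI derives every module's generator from one run seed.

## Known limitations

* Weight magnitudes are unnormalised equation sums and can differ by
  orders of magnitude between rules; Pearson fitness is scale-free per
  model, but reported weights are not comparable across training sets
  unless `normalize=True` is used.
* The occurrence method's sign convention can invert the weight of a
  genuinely positive motif whose supporting sequences sit below the
  class threshold (see above).
* Matching is leftmost-longest and non-overlapping; overlapping
  occurrences are not double-counted, and a rule contributes its weight
  at most once per peptide when scoring.
* The hydropathy scale shipped as default is a literature scale, not
  the one used to filter the original wet-lab candidates; reported
  hydrophilicity values are therefore not comparable to those published
  with the original data.
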