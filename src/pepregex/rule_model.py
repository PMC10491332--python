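"""Weighted rule lists: the evolvable protein-function model.

An individual is an ordered list of rules, each rule a regular-expression
tree with a real weight.  Training sets each rule's weight from the motif
database: every match of the rule in every training sequence contributes
``+cest * len(motif)`` when the matched motif's database CEST value is at
or above the class threshold and ``-cest * len(motif)`` below it.  A
peptide's predicted score is the sum of the weights of the rules that
match it (each matching rule counted once).  Fitness is the Pearson
correlation between predicted scores and measured CEST values, estimated
by k-fold cross-validation with per-fold retraining.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif_db import MotifDB, build_mdb
from .peptide_data import Dataset
from .regex_tree import (
    RegexTree,
    compile_pattern,
    extract_matches_pattern,
    ramped_half_and_half,
)

DEFAULT_THRESHOLD = 12.5
DEFAULT_KFOLD = 6
MAX_RULES = 30

# instrumentation: how many times weight training has run (the
# random-weight ablation must never touch it)
_counters = {"train_weights_calls": 0, "rule_weight_calls": 0}


def counter(name: str) -> int:
    return _counters[name]


def reset_counters() -> None:
    for k in _counters:
        _counters[k] = 0


@dataclass
class Rule:
    """(id, regular-expression tree, weight)."""

    id: int
    tree: RegexTree
    weight: float = 0.0

    @property
    def pattern(self) -> str:
        return self.tree.pattern

    def copy(self) -> "Rule":
        return Rule(id=self.id, tree=self.tree.copy(), weight=self.weight)


@dataclass
class Individual:
    """An ordered rule list with (optionally) a cross-validated fitness.

    ``fitness`` is the mean training-fold Pearson r, ``eval_r`` the mean
    held-out-fold Pearson r.  ``uid`` is a run-unique identifier used for
    deterministic tie-breaking during selection and reduction.
    """

    rules: list[Rule]
    fitness: float | None = None
    eval_r: float | None = None
    uid: int = -1
    n_unmatched: int = 0

    def __post_init__(self) -> None:
        if not self.rules:
            raise ValueError("an individual needs at least one rule")
        ids = [r.id for r in self.rules]
        if len(set(ids)) != len(ids):
            raise ValueError("rule ids must be unique within an individual")

    def __len__(self) -> int:
        return len(self.rules)

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.rules], dtype=float)

    def copy(self) -> "Individual":
        return Individual(
            rules=[r.copy() for r in self.rules],
            fitness=self.fitness,
            eval_r=self.eval_r,
            uid=self.uid,
            n_unmatched=self.n_unmatched,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.rules],
                "pattern": [r.pattern for r in self.rules],
                "weight": [r.weight for r in self.rules],
                "tree": [r.tree.serialize() for r in self.rules],
            }
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "Individual":
        frame = pd.read_csv(path, sep="\t", dtype={"pattern": str, "tree": str})
        rules = [
            Rule(
                id=int(row["id"]),
                tree=RegexTree.deserialize(str(row["tree"])),
                weight=float(row["weight"]),
            )
            for row in frame.to_dict("records")
        ]
        return cls(rules=rules)


def renumber_rules(rules: list[Rule]) -> list[Rule]:
    """Reassign sequential ids 0..n-1, preserving order."""
    return [Rule(id=i, tree=r.tree, weight=r.weight) for i, r in enumerate(rules)]


def new_individual(
    rng,
    min_rules: int = 1,
    max_rules_init: int = 8,
    depth_range: tuple[int, int] = (2, 6),
) -> Individual:
    """Fresh individual: 1-8 ramped-half-and-half trees, all weights 0."""
    if not 1 <= min_rules <= max_rules_init:
        raise ValueError("need 1 <= min_rules <= max_rules_init")
    n = int(rng.integers(min_rules, max_rules_init + 1))
    trees = ramped_half_and_half(n, depth_range, rng)
    return Individual(rules=[Rule(id=i, tree=t) for i, t in enumerate(trees)])


def rule_weight(
    pattern: str,
    train: Dataset,
    db: MotifDB,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[float, int]:
    """Final weight of one rule on a training set.

    Sums ``±cest * len(motif)`` over every non-overlapping match in every
    training sequence, with the sign set by the matched motif's database
    CEST value against the threshold.  Matches absent from the database
    contribute 0; their count is returned as a diagnostic.
    """
    _counters["rule_weight_calls"] += 1
    weight = 0.0
    unmatched = 0
    for rec in train.records:
        for motif in extract_matches_pattern(pattern, rec.sequence):
            entry = db.lookup(motif)
            if entry is None:
                unmatched += 1
                continue
            term = entry.cest * len(motif)
            weight += term if entry.cest >= threshold else -term
    return weight, unmatched


def train_weights(
    ind: Individual,
    train: Dataset,
    db: MotifDB,
    threshold: float = DEFAULT_THRESHOLD,
    normalize: bool = False,
) -> Individual:
    """Set every rule's weight from the training data (in place).

    Each rule is trained independently; rules that never match keep
    weight 0.  With ``normalize=True`` each weight is divided by the
    number of training sequences (a mean-per-sequence scale that keeps
    weights comparable across training-set sizes); the raw equation sum
    is the default.  Returns the same individual for chaining.
    """
    if len(train) == 0:
        raise ValueError("cannot train on an empty dataset")
    _counters["train_weights_calls"] += 1
    total_unmatched = 0
    for rule in ind.rules:
        rule.weight, unmatched = rule_weight(rule.pattern, train, db, threshold)
        if normalize:
            rule.weight /= len(train)
        total_unmatched += unmatched
    ind.n_unmatched = total_unmatched
    return ind


def predict_score(ind: Individual, sequence: str) -> float:
    """Sum of the weights of the rules that match the sequence.

    A rule matching several times still contributes its weight once.
    """
    score = 0.0
    for rule in ind.rules:
        if compile_pattern(rule.pattern).search(sequence) is not None:
            score += rule.weight
    return score


def predict_scores(ind: Individual, ds: Dataset) -> np.ndarray:
    return np.array([predict_score(ind, r.sequence) for r in ds.records])


def pearson(x, y) -> float:
    """Product-moment correlation in [-1, 1].

    Degenerate (constant) inputs return 0 so that every candidate model
    has a defined, totally ordered fitness.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("pearson needs at least 2 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    sx = x - x.mean()
    sy = y - y.mean()
    r = float(np.dot(sx, sy) / np.sqrt(np.dot(sx, sx) * np.dot(sy, sy)))
    return max(-1.0, min(1.0, r))


def model_correlation(ind: Individual, ds: Dataset) -> float:
    """Pearson r between the model's scores and measured CEST values."""
    return pearson(predict_scores(ind, ds), ds.cest_values)


def kfold_indices(n: int, k: int, rng) -> list[np.ndarray]:
    """Seeded partition of range(n) into k near-equal folds."""
    if n < k:
        raise ValueError(f"need at least k={k} records, got {n}")
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]


def evaluate_fitness(
    ind: Individual,
    train: Dataset,
    db_builder=build_mdb,
    threshold: float = DEFAULT_THRESHOLD,
    k: int = DEFAULT_KFOLD,
    rng=None,
    folds: list[np.ndarray] | None = None,
    retrain: bool = True,
) -> tuple[float, float]:
    """k-fold cross-validated fitness of an individual.

    For each fold, the motif database and the rule weights are rebuilt
    from the k-1 training folds only (no leakage into the held-out
    ~1/k of the data); ``fitness`` is the mean Pearson r on the training
    folds and ``eval_r`` the mean on the held-out folds.  With
    ``retrain=False`` (the random-weight ablation) the individual's
    stored weights are used unchanged in every fold.

    Sets ``ind.fitness`` / ``ind.eval_r`` and returns them.  The
    individual's stored weights are not modified by retraining.
    """
    n = len(train)
    if folds is None:
        if rng is None:
            raise ValueError("either rng or precomputed folds are required")
        folds = kfold_indices(n, k, rng)
    r_train_vals = []
    r_eval_vals = []
    for held_out in folds:
        held_set = set(int(i) for i in held_out)
        fit_idx = [i for i in range(n) if i not in held_set]
        fit_ds = train.subset(fit_idx)
        eval_ds = train.subset(sorted(held_set))
        scratch = ind.copy()
        if retrain:
            db = db_builder(fit_ds, threshold)
            train_weights(scratch, fit_ds, db, threshold)
        r_train_vals.append(
            pearson(predict_scores(scratch, fit_ds), fit_ds.cest_values)
        )
        r_eval_vals.append(
            pearson(predict_scores(scratch, eval_ds), eval_ds.cest_values)
        )
    ind.fitness = float(np.mean(r_train_vals))
    ind.eval_r = float(np.mean(r_eval_vals))
    return ind.fitness, ind.eval_r
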