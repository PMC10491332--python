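"""The generational genetic-programming loop.

Mu+lambda evolution of rule-list individuals: tournament selection
(k=5), one-point crossover on rule lists, two groups of mutations (rule
add/replace/delete on the list; branch replacement, node inversion,
subtree deletion and leaf extension on trees), elitism, and reduction to
the best ``population_size`` of parents, offspring and the elite.
Fitness is the k-fold cross-validated Pearson correlation from
:mod:`pepregex.rule_model`.

The ``random_weights`` mode is the ablation control: rule weights are
drawn uniformly at initialisation, are only changed by mutation, and
weight training is never run — it isolates the contribution of the
training step.

Evaluation uses an internal cache keyed by pattern string: the per-fold
trained weight and the per-sequence match mask of a pattern depend only
on the pattern and the (fixed) fold partition, so clones and elites
carried across generations cost nothing to re-evaluate.  Cached results
are bit-identical to the plain :func:`pepregex.rule_model.evaluate_fitness`
path on the same folds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motif_db import MotifDB, build_mdb
from .peptide_data import Dataset
from .regex_tree import (
    MUTATION_KINDS,
    extract_matches_pattern,
    generate_tree,
    mutate_tree,
)
from .rule_model import (
    Individual,
    Rule,
    new_individual,
    pearson,
    renumber_rules,
    rule_weight,
    kfold_indices,
)
from . import rule_model

DEFAULT_RANDOM_WEIGHT_RANGE = (-100.0, 100.0)


@dataclass
class EvolutionConfig:
    """Hyper-parameters of an evolution run (defaults are the full-scale
    study conditions; tests and examples scale population/generations
    down)."""

    population_size: int = 1000
    generations: int = 300
    max_rules: int = 30
    p_crossover: float = 0.9
    p_mutation: float = 0.1
    tree_depth: int = 6
    tournament_k: int = 5
    kfold: int = 6
    threshold: float = 12.5
    mode: str = "trained"  # or "random_weights"
    seed: int = 0
    min_rules_init: int = 1
    max_rules_init: int = 8
    random_weight_range: tuple[float, float] = DEFAULT_RANDOM_WEIGHT_RANGE
    plateau_patience: int | None = None  # optional early stop, off by default

    def validate(self) -> None:
        if self.population_size < 1 or self.generations < 1:
            raise ValueError("population_size and generations must be >= 1")
        if not 0 <= self.p_crossover <= 1 or not 0 <= self.p_mutation <= 1:
            raise ValueError("probabilities must be in [0, 1]")
        if self.max_rules < 1 or self.tournament_k < 1 or self.kfold < 2:
            raise ValueError("max_rules, tournament_k >= 1 and kfold >= 2")
        if not 1 <= self.min_rules_init <= self.max_rules_init <= self.max_rules:
            raise ValueError(
                "need 1 <= min_rules_init <= max_rules_init <= max_rules"
            )
        if self.mode not in ("trained", "random_weights"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 1 <= self.tree_depth <= 6:
            raise ValueError("tree_depth must be in [1, 6]")

    def to_dict(self) -> dict:
        return {
            "population_size": self.population_size,
            "generations": self.generations,
            "max_rules": self.max_rules,
            "p_crossover": self.p_crossover,
            "p_mutation": self.p_mutation,
            "tree_depth": self.tree_depth,
            "tournament_k": self.tournament_k,
            "kfold": self.kfold,
            "threshold": self.threshold,
            "mode": self.mode,
            "seed": self.seed,
        }


@dataclass
class GenerationStats:
    generation: int
    best_fitness: float
    mean_fitness: float
    mean_eval_r: float


@dataclass
class EvolutionResult:
    best: Individual
    history: list[GenerationStats]
    config: EvolutionConfig
    counters: dict[str, int]

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": [h.generation for h in self.history],
                "best_fitness": [h.best_fitness for h in self.history],
                "mean_fitness": [h.mean_fitness for h in self.history],
                "mean_eval_r": [h.mean_eval_r for h in self.history],
            }
        )


# ---------------------------------------------------------------------------
# variation operators
# ---------------------------------------------------------------------------

def _rank_key(ind: Individual):
    # higher fitness first; ties: fewer rules, then lower uid
    return (-ind.fitness, len(ind.rules), ind.uid)


def tournament_select(pop: list[Individual], k: int, rng) -> Individual:
    """k-entrant tournament with replacement; best fitness wins, ties
    broken by fewer rules then lower uid."""
    if not pop:
        raise ValueError("cannot select from an empty population")
    if k < 1:
        raise ValueError("tournament size must be >= 1")
    entrants = [pop[int(rng.integers(len(pop)))] for _ in range(k)]
    return min(entrants, key=_rank_key)


def crossover(
    p1: Individual,
    p2: Individual,
    max_rules: int,
    rng,
    fresh_rule=None,
) -> tuple[Individual, Individual]:
    """One-point crossover on rule lists.

    Independent uniform cut points (list ends allowed) split each parent
    into a head and a tail; offspring are head1+tail2 and head2+tail1,
    truncated from the tail to ``max_rules``.  An empty child receives
    one fresh random rule (``fresh_rule(rng) -> Rule``).
    """
    c1 = int(rng.integers(0, len(p1.rules) + 1))
    c2 = int(rng.integers(0, len(p2.rules) + 1))
    rules_a = [r.copy() for r in p1.rules[:c1]] + [r.copy() for r in p2.rules[c2:]]
    rules_b = [r.copy() for r in p2.rules[:c2]] + [r.copy() for r in p1.rules[c1:]]
    out = []
    for rules in (rules_a, rules_b):
        rules = rules[:max_rules]
        if not rules:
            if fresh_rule is None:
                raise ValueError("empty child and no fresh_rule factory given")
            rules = [fresh_rule(rng)]
        out.append(Individual(rules=renumber_rules(rules)))
    return out[0], out[1]


def _fresh_rule(rng, tree_depth: int = 6) -> Rule:
    depth = int(rng.integers(2, tree_depth + 1)) if tree_depth >= 2 else 1
    mode = "grow" if rng.random() < 0.5 else "full"
    return Rule(id=0, tree=generate_tree(depth, mode, rng))


def mutate_individual(ind: Individual, cfg: EvolutionConfig, rng) -> Individual:
    """Apply list-level (Group I) and tree-level (Group II) mutations.

    With probability ``p_mutation`` one list action runs — add a rule
    (only below ``max_rules``), replace a rule, or delete a rule (only
    with two or more rules).  Independently each rule's tree mutates
    with probability ``p_mutation`` by one uniformly chosen tree
    operator.  In ``random_weights`` mode each weight additionally
    resamples with probability ``p_mutation``.
    """
    out = ind.copy()
    out.fitness = None
    out.eval_r = None

    if rng.random() < cfg.p_mutation:
        actions = ["replace"]
        if len(out.rules) < cfg.max_rules:
            actions.append("add")
        if len(out.rules) >= 2:
            actions.append("delete")
        action = actions[int(rng.integers(len(actions)))]
        if action == "add":
            out.rules.append(_fresh_rule(rng, cfg.tree_depth))
        elif action == "replace":
            i = int(rng.integers(len(out.rules)))
            out.rules[i] = _fresh_rule(rng, cfg.tree_depth)
        else:
            i = int(rng.integers(len(out.rules)))
            del out.rules[i]

    for i, rule in enumerate(out.rules):
        if rng.random() < cfg.p_mutation:
            kind = MUTATION_KINDS[int(rng.integers(len(MUTATION_KINDS)))]
            new_tree, _applied = mutate_tree(rule.tree, kind, rng)
            out.rules[i] = Rule(id=rule.id, tree=new_tree, weight=rule.weight)

    if cfg.mode == "random_weights":
        lo, hi = cfg.random_weight_range
        for i, rule in enumerate(out.rules):
            if rng.random() < cfg.p_mutation:
                out.rules[i] = Rule(
                    id=rule.id, tree=rule.tree, weight=float(rng.uniform(lo, hi))
                )

    out.rules = renumber_rules(out.rules)
    return out


# ---------------------------------------------------------------------------
# cached evaluation
# ---------------------------------------------------------------------------

class CachedEvaluator:
    """Shared-fold, pattern-memoised fitness evaluation.

    The fold partition is drawn once; per-fold motif databases are built
    once.  For each distinct pattern string the per-fold trained weight
    and the per-sequence match mask are computed once and reused for
    every individual containing that pattern.
    """

    def __init__(self, train: Dataset, cfg: EvolutionConfig, rng):
        cfg.validate()
        self.train = train
        self.cfg = cfg
        n = len(train)
        self.folds = kfold_indices(n, cfg.kfold, rng)
        self.fold_fit_idx: list[np.ndarray] = []
        self.fold_dbs: list[MotifDB] = []
        self.fold_cest: list[np.ndarray] = []
        self.eval_cest: list[np.ndarray] = []
        cest = train.cest_values
        for held in self.folds:
            held_set = set(int(i) for i in held)
            fit_idx = np.array(
                [i for i in range(n) if i not in held_set], dtype=int
            )
            self.fold_fit_idx.append(fit_idx)
            fit_ds = train.subset(fit_idx.tolist())
            self.fold_dbs.append(build_mdb(fit_ds, cfg.threshold))
            self.fold_cest.append(cest[fit_idx])
            self.eval_cest.append(cest[sorted(held_set)])
        self.full_db = build_mdb(train, cfg.threshold)
        self._cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._full_weight_cache: dict[str, float] = {}
        self.n_evaluations = 0

    def _pattern_stats(self, pattern: str) -> tuple[np.ndarray, np.ndarray]:
        """(per-fold trained weights, per-sequence match mask).

        Matches are extracted once per pattern; per-fold weights then
        only re-price the same matches against each fold's motif
        database, which is algebraically identical to retraining the
        rule on the fold (matches do not depend on the fold).
        """
        hit = self._cache.get(pattern)
        if hit is not None:
            return hit
        matches = [
            extract_matches_pattern(pattern, s) for s in self.train.sequences
        ]
        mask = np.array([len(m) > 0 for m in matches], dtype=bool)
        weights = np.zeros(len(self.folds))
        if self.cfg.mode == "trained":
            rule_model._counters["rule_weight_calls"] += len(self.folds)
            for f, fit_idx in enumerate(self.fold_fit_idx):
                db = self.fold_dbs[f]
                w = 0.0
                for i in fit_idx:
                    for motif in matches[i]:
                        entry = db.lookup(motif)
                        if entry is None:
                            continue
                        term = entry.cest * len(motif)
                        w += term if entry.cest >= self.cfg.threshold else -term
                weights[f] = w
        result = (weights, mask)
        self._cache[pattern] = result
        return result

    def evaluate(self, ind: Individual) -> None:
        """Set ``ind.fitness`` and ``ind.eval_r`` (idempotent)."""
        if ind.fitness is not None:
            return
        self.n_evaluations += 1
        patterns = [r.pattern for r in ind.rules]
        stats = [self._pattern_stats(p) for p in patterns]
        mask = np.stack([s[1] for s in stats])  # rules x sequences
        r_train_vals = []
        r_eval_vals = []
        for f, (fit_idx, held) in enumerate(zip(self.fold_fit_idx, self.folds)):
            if self.cfg.mode == "trained":
                w = np.array([s[0][f] for s in stats])
            else:
                w = ind.weights
            eval_idx = np.array(sorted(int(i) for i in held), dtype=int)
            preds_fit = w @ mask[:, fit_idx]
            preds_eval = w @ mask[:, eval_idx]
            r_train_vals.append(pearson(preds_fit, self.fold_cest[f]))
            r_eval_vals.append(pearson(preds_eval, self.eval_cest[f]))
        ind.fitness = float(np.mean(r_train_vals))
        ind.eval_r = float(np.mean(r_eval_vals))

    def train_full(self, ind: Individual) -> Individual:
        """Set the individual's stored weights from the full training set
        (the deployable model)."""
        for rule in ind.rules:
            w = self._full_weight_cache.get(rule.pattern)
            if w is None:
                w, _ = rule_weight(
                    rule.pattern, self.train, self.full_db, self.cfg.threshold
                )
                self._full_weight_cache[rule.pattern] = w
            rule.weight = w
        return ind


# ---------------------------------------------------------------------------
# the loop
# ---------------------------------------------------------------------------

def run_evolution(
    cfg: EvolutionConfig, train: Dataset, rng=None, progress=None
) -> EvolutionResult:
    """Run the full generational loop and return the best individual.

    Per generation: snapshot the elite; draw ``population_size``
    offspring from tournament-selected parent pairs (crossover with
    probability ``p_crossover``, otherwise cloned parents), mutate and
    evaluate them; then keep the best ``population_size`` of parents,
    offspring and the elite.  Best-so-far fitness is therefore monotone
    non-decreasing.  In trained mode the returned best individual's
    weights are trained on the full training set.
    """
    cfg.validate()
    if len(train) < cfg.kfold:
        raise ValueError(
            f"training set ({len(train)}) smaller than kfold ({cfg.kfold})"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    rule_model.reset_counters()
    evaluator = CachedEvaluator(train, cfg, rng)

    uid_counter = 0

    def next_uid() -> int:
        nonlocal uid_counter
        uid_counter += 1
        return uid_counter

    lo, hi = cfg.random_weight_range
    population: list[Individual] = []
    for _ in range(cfg.population_size):
        ind = new_individual(
            rng,
            cfg.min_rules_init,
            cfg.max_rules_init,
            depth_range=(min(2, cfg.tree_depth), cfg.tree_depth),
        )
        if cfg.mode == "random_weights":
            for rule in ind.rules:
                rule.weight = float(rng.uniform(lo, hi))
        ind.uid = next_uid()
        population.append(ind)
    for ind in population:
        evaluator.evaluate(ind)

    history: list[GenerationStats] = []
    best_so_far = min(population, key=_rank_key).copy()
    plateau = 0

    for gen in range(1, cfg.generations + 1):
        elite = min(population, key=_rank_key).copy()

        offspring: list[Individual] = []
        while len(offspring) < cfg.population_size:
            p1 = tournament_select(population, cfg.tournament_k, rng)
            p2 = tournament_select(population, cfg.tournament_k, rng)
            if rng.random() < cfg.p_crossover:
                c1, c2 = crossover(
                    p1,
                    p2,
                    cfg.max_rules,
                    rng,
                    fresh_rule=lambda r: _fresh_rule(r, cfg.tree_depth),
                )
            else:
                c1, c2 = p1.copy(), p2.copy()
            for child in (c1, c2):
                child = mutate_individual(child, cfg, rng)
                child.uid = next_uid()
                offspring.append(child)
        offspring = offspring[: cfg.population_size]

        for child in offspring:
            evaluator.evaluate(child)

        pool = population + offspring + [elite]
        pool.sort(key=_rank_key)
        # drop duplicate uids (the elite is already in the parent pool)
        seen: set[int] = set()
        population = []
        for ind in pool:
            if ind.uid in seen:
                continue
            seen.add(ind.uid)
            population.append(ind)
            if len(population) == cfg.population_size:
                break

        gen_best = population[0]
        if _rank_key(gen_best) < _rank_key(best_so_far):
            best_so_far = gen_best.copy()
            plateau = 0
        else:
            plateau += 1
        stats = GenerationStats(
            generation=gen,
            best_fitness=gen_best.fitness,
            mean_fitness=float(np.mean([i.fitness for i in population])),
            mean_eval_r=float(np.mean([i.eval_r for i in population])),
        )
        history.append(stats)
        if progress is not None:
            progress(stats)
        if cfg.plateau_patience is not None and plateau >= cfg.plateau_patience:
            break

    best = best_so_far.copy()
    if cfg.mode == "trained":
        evaluator.train_full(best)
    counters = {
        "train_weights_calls": rule_model.counter("train_weights_calls"),
        "rule_weight_calls": rule_model.counter("rule_weight_calls"),
        "evaluations": evaluator.n_evaluations,
    }
    return EvolutionResult(
        best=best, history=history, config=cfg, counters=counters
    )
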