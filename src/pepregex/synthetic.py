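"""Synthetic peptide/CEST datasets with known ground truth.

The generator emulates the shape of the curated CEST peptide data the
package is built for: short peptides (10-13 residues) with a residue
composition biased toward the CEST-active amino acids K, R, S and T, and
a contrast value produced by an additive planted-motif model

    CEST = base + sum_m contribution_m * count(m, sequence) + noise,

clipped at zero.  The additive form mirrors the additive weight-training
rule of the model, so the learnability of the planted ground truth is
analytically clear.  Planted motifs are also explicitly written into a
fraction of the sequences (``plant_rate``) so their prevalence does not
depend solely on composition chance.

The generator is first-class, tested code: the whole pipeline (database
construction, training, evolution, directed evolution) is exercised end
to end against data whose generative truth is known.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .peptide_data import AMINO_ACIDS, Dataset, PeptideRecord

#: Default residue weights: K+R+S+T carry ~45% of the mass, W ~5%,
#: the remaining 15 residues share the rest — the qualitative
#: composition of CEST-selected peptide panels.
DEFAULT_COMPOSITION_BIAS = {
    **{aa: 0.50 / 15 for aa in AMINO_ACIDS if aa not in "KRSTW"},
    "K": 0.17,
    "R": 0.10,
    "S": 0.10,
    "T": 0.08,
    "W": 0.05,
}

#: Default planted motifs (motif, additive CEST contribution in percent).
DEFAULT_PLANTED_MOTIFS = (("KK", 4.0), ("QSL", 5.0), ("RS", 3.0))


@dataclass
class SyntheticSpec:
    """Study-shaped synthetic data: 158 peptides of 10-13 residues."""

    n_peptides: int = 158
    length_range: tuple[int, int] = (10, 13)
    composition_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_BIAS)
    )
    planted_motifs: tuple[tuple[str, float], ...] = DEFAULT_PLANTED_MOTIFS
    base_cest: float = 7.0
    noise_sd: float = 1.5
    seed: int = 0
    #: fraction of sequences into which each planted motif is written
    plant_rate: float = 0.35
    #: when set, sequences are redrawn until no planted motif occurs more
    #: often than this (used by noise-free oracle fixtures)
    max_motif_occurrences: int | None = None

    def validate(self) -> None:
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.plant_rate <= 1:
            raise ValueError("plant_rate must be in [0, 1]")
        lo, hi = self.length_range
        if not 1 <= lo <= hi:
            raise ValueError(f"bad length_range {self.length_range}")
        for motif, contribution in self.planted_motifs:
            if any(c not in AMINO_ACIDS for c in motif):
                raise ValueError(f"planted motif {motif!r} has bad letters")
            if not np.isfinite(contribution):
                raise ValueError(f"contribution for {motif!r} must be finite")
            if len(motif) > hi:
                raise ValueError(f"motif {motif!r} longer than max length")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, for parameter-recovery checks."""

    planted_motifs: tuple[tuple[str, float], ...]
    base_cest: float
    noise_sd: float
    seed: int
    motif_counts: tuple[tuple[int, ...], ...]  # per record, per motif

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_motifs": [list(m) for m in self.planted_motifs],
                "base_cest": self.base_cest,
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            },
            indent=2,
        )


def _count(sequence: str, motif: str) -> int:
    w = len(motif)
    return sum(
        1 for i in range(len(sequence) - w + 1) if sequence[i:i + w] == motif
    )


def _draw_sequence(spec: SyntheticSpec, letters, probs, rng) -> str:
    length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
    seq = list(rng.choice(letters, size=length, p=probs))
    for motif, _contribution in spec.planted_motifs:
        if rng.random() < spec.plant_rate and len(motif) <= length:
            start = int(rng.integers(length - len(motif) + 1))
            seq[start:start + len(motif)] = list(motif)
    return "".join(seq)


def make_synthetic_dataset(spec: SyntheticSpec) -> tuple[Dataset, GroundTruth]:
    """Draw a dataset from the planted-motif additive model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.composition_bias.keys()))
    probs = np.array(list(spec.composition_bias.values()), dtype=float)
    probs = probs / probs.sum()

    records = []
    all_counts = []
    for _ in range(spec.n_peptides):
        for _attempt in range(1000):
            seq = _draw_sequence(spec, letters, probs, rng)
            counts = [_count(seq, m) for m, _c in spec.planted_motifs]
            if spec.max_motif_occurrences is None or all(
                c <= spec.max_motif_occurrences for c in counts
            ):
                break
        else:
            raise RuntimeError(
                "could not draw a sequence satisfying max_motif_occurrences"
            )
        cest = spec.base_cest + sum(
            contribution * c
            for (_m, contribution), c in zip(spec.planted_motifs, counts)
        )
        if spec.noise_sd > 0:
            cest += rng.normal(0.0, spec.noise_sd)
        records.append(PeptideRecord(seq, max(0.0, float(cest))))
        all_counts.append(tuple(counts))

    truth = GroundTruth(
        planted_motifs=tuple(spec.planted_motifs),
        base_cest=spec.base_cest,
        noise_sd=spec.noise_sd,
        seed=spec.seed,
        motif_counts=tuple(all_counts),
    )
    return Dataset(records, name=f"synthetic-{spec.seed}"), truth
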