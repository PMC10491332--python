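"""In-silico directed evolution of a peptide library.

A library of random peptides is iterated through mutate-score-select
cycles: each cycle substitutes one residue per peptide and keeps the
mutant only when the trained model scores it strictly higher.  After the
requested number of cycles the library is filtered to hydrophilic
peptides (summed per-residue hydropathy values > 0, a proxy for the
water solubility CEST agents require) and the top-scoring candidates are
reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .peptide_data import AMINO_ACIDS
from .rule_model import Individual, predict_score

#: Hopp-Woods hydrophilicity values (positive = hydrophilic).  The scale
#: is a swappable input; any AA -> value map covering the 20 standard
#: residues can be passed instead.
HOPP_WOODS = {
    "A": -0.5, "R": 3.0, "N": 0.2, "D": 3.0, "C": -1.0,
    "Q": 0.2, "E": 3.0, "G": 0.0, "H": -0.5, "I": -1.8,
    "L": -1.8, "K": 3.0, "M": -1.3, "F": -2.5, "P": 0.0,
    "S": 0.3, "T": -0.4, "W": -3.4, "Y": -2.3, "V": -1.5,
}


@dataclass
class DEConfig:
    """Directed-evolution settings.

    ``cycles`` of 10, 100 and 1000 span the exploration/convergence
    trade-off: few cycles keep the library diverse, many cycles converge
    it onto similar high-scoring peptides.
    """

    library_size: int = 1000
    peptide_length: int = 12
    cycles: int = 100
    top_k: int = 20
    hydro_scale: dict[str, float] = field(default_factory=lambda: dict(HOPP_WOODS))
    seed: int = 0

    def validate(self) -> None:
        if min(self.library_size, self.peptide_length, self.cycles, self.top_k) < 1:
            raise ValueError("all DE counts must be >= 1")
        missing = set(AMINO_ACIDS) - set(self.hydro_scale)
        if missing:
            raise ValueError(
                f"hydro_scale missing amino acid(s): {''.join(sorted(missing))}"
            )


@dataclass(frozen=True)
class ScoredPeptide:
    sequence: str
    score: float
    hydrophilicity: float


def hydrophilicity(peptide: str, scale: dict[str, float]) -> float:
    """Sum of per-residue scale values; raises on letters the scale lacks."""
    try:
        return sum(scale[c] for c in peptide)
    except KeyError as exc:
        raise ValueError(f"hydropathy scale missing letter {exc.args[0]!r}") from exc


def init_library(cfg: DEConfig, rng) -> list[str]:
    """``library_size`` random peptides, letters uniform over the 20 AAs."""
    cfg.validate()
    return [
        "".join(
            AMINO_ACIDS[int(i)]
            for i in rng.integers(len(AMINO_ACIDS), size=cfg.peptide_length)
        )
        for _ in range(cfg.library_size)
    ]


def de_cycle(library: list[str], model: Individual, rng) -> list[str]:
    """One mutate-score-select pass over the library.

    Each peptide gets one substitution at a uniform position to a
    uniformly chosen different residue; the mutant replaces the original
    only when its model score is strictly higher.
    """
    out = []
    for peptide in library:
        pos = int(rng.integers(len(peptide)))
        alternatives = [c for c in AMINO_ACIDS if c != peptide[pos]]
        mutant = (
            peptide[:pos]
            + alternatives[int(rng.integers(len(alternatives)))]
            + peptide[pos + 1:]
        )
        if predict_score(model, mutant) > predict_score(model, peptide):
            out.append(mutant)
        else:
            out.append(peptide)
    return out


def run_directed_evolution(
    model: Individual, cfg: DEConfig, rng
) -> list[ScoredPeptide]:
    """Full DE run: init -> cycles -> hydrophilicity filter -> top-k.

    Candidates are ranked by score descending; ties prefer higher
    hydrophilicity, then lexicographic order.  Returns at most ``top_k``
    peptides, all with hydrophilicity > 0; an empty list (with a
    warning) when the filter removes everything.
    """
    cfg.validate()
    library = init_library(cfg, rng)
    for _ in range(cfg.cycles):
        library = de_cycle(library, model, rng)
    scored = [
        ScoredPeptide(
            sequence=p,
            score=predict_score(model, p),
            hydrophilicity=hydrophilicity(p, cfg.hydro_scale),
        )
        for p in library
    ]
    kept = [s for s in scored if s.hydrophilicity > 0]
    if not kept:
        warnings.warn("all peptides were filtered out as non-hydrophilic")
        return []
    kept.sort(key=lambda s: (-s.score, -s.hydrophilicity, s.sequence))
    return kept[: cfg.top_k]


def candidates_frame(candidates: list[ScoredPeptide]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(candidates) + 1),
            "sequence": [c.sequence for c in candidates],
            "score": [c.score for c in candidates],
            "hydrophilicity": [c.hydrophilicity for c in candidates],
        }
    )
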