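"""Motif database (MDB) construction via the occurrence method.

Every substring of length 1-6 of the training peptides is a motif.  A
training sequence is class 1 when its CEST contrast is at or above the
class threshold (12.5, the contrast of the poly-L-lysine gold standard
K12) and class 0 below it.  Each motif is assigned the class in which its
window occurrences are more numerous, and the mean CEST of that class's
supporting sequences — the "occurrence" method.  The resulting lookup
table is the source of the per-motif CEST values used when training rule
weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .peptide_data import Dataset

DEFAULT_THRESHOLD = 12.5
DEFAULT_MIN_LEN = 1
DEFAULT_MAX_LEN = 6


@dataclass(frozen=True)
class MotifEntry:
    """One motif with its class and occurrence-method CEST value.

    ``count_class1``/``count_class0`` are window-instance counts (a motif
    occurring twice in one sequence counts 2).  ``cest`` is the mean CEST
    of the winning class's sequences that contain the motif.
    """

    motif: str
    cls: int
    cest: float
    count_class1: int
    count_class0: int


@dataclass
class MotifDB:
    """Exact-string motif lookup table built from training data."""

    entries: dict[str, MotifEntry]
    threshold: float
    min_len: int = DEFAULT_MIN_LEN
    max_len: int = DEFAULT_MAX_LEN

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, motif: str) -> MotifEntry | None:
        return self.entries.get(motif)

    def size(self, min_len: int = 2, max_len: int = 6) -> int:
        """Number of stored motifs with length in [min_len, max_len].

        The conventional MDB-size report counts lengths 2-6 even though
        single residues are stored as well.
        """
        return sum(1 for m in self.entries if min_len <= len(m) <= max_len)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.motif, e.cls, e.cest, e.count_class1, e.count_class0)
            for e in sorted(self.entries.values(), key=lambda e: e.motif)
        ]
        return pd.DataFrame(
            rows, columns=["motif", "class", "cest", "n_class1", "n_class0"]
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path, threshold: float = DEFAULT_THRESHOLD) -> "MotifDB":
        frame = pd.read_csv(path, sep="\t", dtype={"motif": str})
        entries = {}
        for row in frame.to_dict("records"):
            motif = str(row["motif"])
            entries[motif] = MotifEntry(
                motif,
                int(row["class"]),
                float(row["cest"]),
                int(row["n_class1"]),
                int(row["n_class0"]),
            )
        return cls(entries=entries, threshold=threshold)


def extract_motifs(
    sequence: str,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[tuple[str, int]]:
    """All substrings of each length in [min_len, max_len], with 0-based
    start positions, in scan order (by length, then position)."""
    if not sequence:
        raise ValueError("cannot extract motifs from an empty sequence")
    if not 1 <= min_len <= max_len:
        raise ValueError(f"invalid window range [{min_len}, {max_len}]")
    out = []
    for w in range(min_len, max_len + 1):
        for start in range(len(sequence) - w + 1):
            out.append((sequence[start:start + w], start))
    return out


def _count_occurrences(sequence: str, motif: str) -> int:
    """Window instances of ``motif`` in ``sequence`` (overlaps counted)."""
    w = len(motif)
    return sum(
        1 for i in range(len(sequence) - w + 1) if sequence[i:i + w] == motif
    )


def occurrence_cest(
    motif: str, train: Dataset, threshold: float = DEFAULT_THRESHOLD
) -> MotifEntry:
    """Occurrence-method class and CEST value for one motif.

    Training sequences with CEST >= threshold are class 1, the rest class
    0.  Window instances of the motif are counted per class; the class
    with more instances wins (ties go to class 1), and the motif's CEST is
    the mean CEST of the winning class's sequences that contain it.
    """
    counts = {0: 0, 1: 0}
    support = {0: [], 1: []}
    for rec in train.records:
        c = _count_occurrences(rec.sequence, motif)
        if c == 0:
            continue
        cls = 1 if rec.cest >= threshold else 0
        counts[cls] += c
        support[cls].append(rec.cest)
    if counts[0] == 0 and counts[1] == 0:
        raise ValueError(f"motif {motif!r} absent from the training data")
    winner = 1 if counts[1] >= counts[0] else 0
    cest = sum(support[winner]) / len(support[winner])
    return MotifEntry(
        motif=motif,
        cls=winner,
        cest=cest,
        count_class1=counts[1],
        count_class0=counts[0],
    )


def build_mdb(
    train: Dataset,
    threshold: float = DEFAULT_THRESHOLD,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> MotifDB:
    """Build the motif database from training data.

    One :class:`MotifEntry` per distinct substring of length in
    [min_len, max_len]; deterministic for fixed input.
    """
    if len(train) == 0:
        raise ValueError("cannot build a motif database from an empty dataset")
    # accumulate per motif: instance counts per class and supporting CEST sums
    counts1: dict[str, int] = {}
    counts0: dict[str, int] = {}
    sum1: dict[str, float] = {}
    n1: dict[str, int] = {}
    sum0: dict[str, float] = {}
    n0: dict[str, int] = {}
    for rec in train.records:
        cls1 = rec.cest >= threshold
        per_seq: dict[str, int] = {}
        for motif, _pos in extract_motifs(rec.sequence, min_len, max_len):
            per_seq[motif] = per_seq.get(motif, 0) + 1
        for motif, c in per_seq.items():
            if cls1:
                counts1[motif] = counts1.get(motif, 0) + c
                sum1[motif] = sum1.get(motif, 0.0) + rec.cest
                n1[motif] = n1.get(motif, 0) + 1
            else:
                counts0[motif] = counts0.get(motif, 0) + c
                sum0[motif] = sum0.get(motif, 0.0) + rec.cest
                n0[motif] = n0.get(motif, 0) + 1
    entries: dict[str, MotifEntry] = {}
    for motif in set(counts1) | set(counts0):
        c1 = counts1.get(motif, 0)
        c0 = counts0.get(motif, 0)
        if c1 >= c0:
            cest = sum1[motif] / n1[motif]
            cls = 1
        else:
            cest = sum0[motif] / n0[motif]
            cls = 0
        entries[motif] = MotifEntry(motif, cls, cest, c1, c0)
    return MotifDB(
        entries=entries, threshold=threshold, min_len=min_len, max_len=max_len
    )


def mdb_lookup(db: MotifDB, motif: str) -> MotifEntry | None:
    """Exact-string lookup; returns None when the motif is absent."""
    return db.lookup(motif)
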