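"""Peptide datasets and their descriptive statistics.

This module holds the basic data types of the package: a peptide sequence
paired with its measured CEST contrast (the MTRasym value at 3.6 ppm, in
percent), collections of such records, readers/writers for the two on-disk
formats (CSV and annotated FASTA), train/test splitting, ungapped pairwise
sequence identity, amino-acid composition statistics, and the MTRasym
ratio as a standalone utility for z-spectral amplitudes.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class DataFormatError(ValueError):
    """A record or file violates the expected peptide-table format."""


@dataclass(frozen=True)
class PeptideRecord:
    """One peptide with its measured (or synthetic) CEST contrast.

    Parameters
    ----------
    sequence
        Uppercase string over the 20-letter standard amino-acid alphabet.
        Lengths of 10-13 residues are typical but not enforced.
    cest
        CEST contrast at 3.6 ppm, percent units, non-negative.
    """

    sequence: str
    cest: float

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataFormatError("peptide sequence must be non-empty")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise DataFormatError(
                f"sequence {self.sequence!r} contains non-standard "
                f"letter(s) {''.join(sorted(bad))!r}"
            )
        if not np.isfinite(self.cest) or self.cest < 0:
            raise DataFormatError(
                f"cest value {self.cest!r} for {self.sequence!r} must be "
                "finite and >= 0"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Dataset:
    """An ordered collection of :class:`PeptideRecord`."""

    records: list[PeptideRecord]
    name: str = ""

    def __post_init__(self) -> None:
        dups = self.duplicate_sequences()
        if dups:
            warnings.warn(
                f"dataset {self.name or '<unnamed>'} contains duplicate "
                f"sequence(s): {', '.join(sorted(dups)[:5])}",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def cest_values(self) -> np.ndarray:
        return np.array([r.cest for r in self.records], dtype=float)

    def duplicate_sequences(self) -> list[str]:
        counts = Counter(r.sequence for r in self.records)
        return [s for s, c in counts.items() if c > 1]

    def subset(self, indices, name: str = "") -> "Dataset":
        return Dataset([self.records[i] for i in indices], name=name or self.name)


@dataclass(frozen=True)
class ZSpectrumPoint:
    """Z-spectral amplitudes at +/-3.6 ppm plus the unsaturated reference.

    ``s_neg`` and ``s_pos`` are the signal amplitudes at -3.6 and +3.6 ppm,
    ``s0`` the reference amplitude acquired at zero saturation power.
    """

    s_neg: float
    s_pos: float
    s0: float

    def __post_init__(self) -> None:
        if not self.s0 > 0:
            raise ValueError(f"reference amplitude s0 must be > 0, got {self.s0}")


def mtr_asym(z: ZSpectrumPoint) -> float:
    """Magnetization transfer ratio asymmetry ``(S(-3.6) - S(+3.6)) / S0``."""
    return (z.s_neg - z.s_pos) / z.s0


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".fa", ".fasta", ".faa"}:
        return "fasta"
    return "csv"


def read_peptide_table(path, format: str | None = None) -> Dataset:
    """Read a labelled peptide table from CSV or annotated FASTA.

    CSV files need ``sequence`` and ``cest`` columns; FASTA descriptions
    need a ``cest=<float>`` token.  Records whose sequence contains a
    non-standard letter are rejected with an error naming the record.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        records = _read_csv(path)
    elif fmt == "fasta":
        records = _read_fasta(path)
    else:
        raise ValueError(f"unknown peptide-table format {fmt!r}")
    return Dataset(records, name=path.stem)


def _read_csv(path: Path) -> list[PeptideRecord]:
    frame = pd.read_csv(path, dtype={"sequence": str})
    missing = {"sequence", "cest"} - set(frame.columns)
    if missing:
        raise DataFormatError(
            f"{path}: missing required column(s) {', '.join(sorted(missing))}"
        )
    records = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            cest = float(row.cest)
        except (TypeError, ValueError) as exc:
            raise DataFormatError(
                f"{path}: row {row_number}: non-numeric cest value {row.cest!r}"
            ) from exc
        try:
            records.append(PeptideRecord(str(row.sequence), cest))
        except DataFormatError as exc:
            raise DataFormatError(f"{path}: row {row_number}: {exc}") from exc
    return records


def _read_fasta(path: Path) -> list[PeptideRecord]:
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        cest = None
        for token in rec.description.split():
            if token.startswith("cest="):
                try:
                    cest = float(token[len("cest="):])
                except ValueError as exc:
                    raise DataFormatError(
                        f"{path}: record {rec.id}: non-numeric cest "
                        f"annotation {token!r}"
                    ) from exc
        if cest is None:
            raise DataFormatError(
                f"{path}: record {i} ({rec.id}): missing 'cest=<float>' "
                "annotation in the description line"
            )
        try:
            records.append(PeptideRecord(str(rec.seq).upper(), cest))
        except DataFormatError as exc:
            raise DataFormatError(f"{path}: record {rec.id}: {exc}") from exc
    return records


def write_peptide_table(ds: Dataset, path, format: str | None = None) -> None:
    """Write a dataset as CSV (``sequence,cest``) or annotated FASTA."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "csv":
        pd.DataFrame(
            {"sequence": ds.sequences, "cest": ds.cest_values}
        ).to_csv(path, index=False)
    elif fmt == "fasta":
        seq_records = [
            SeqRecord(Seq(r.sequence), id=f"p{i}", description=f"cest={r.cest:g}")
            for i, r in enumerate(ds.records, start=1)
        ]
        SeqIO.write(seq_records, str(path), "fasta")
    else:
        raise ValueError(f"unknown peptide-table format {fmt!r}")


# ---------------------------------------------------------------------------
# splitting and statistics
# ---------------------------------------------------------------------------

def split_dataset(
    ds: Dataset, train_fraction: float, seed: int
) -> tuple[Dataset, Dataset]:
    """Random disjoint train/test partition, reproducible from ``seed``.

    The train part has ``ceil(train_fraction * n)`` records (so an 80%
    split of 158 peptides gives the conventional 127/31); relative file
    order is preserved within each part.
    """
    n = len(ds)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    n_train = int(np.ceil(train_fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction {train_fraction} would leave an empty part "
            f"for n={n}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    train_idx = sorted(perm[:n_train].tolist())
    test_idx = sorted(perm[n_train:].tolist())
    return (
        ds.subset(train_idx, name=f"{ds.name}/train"),
        ds.subset(test_idx, name=f"{ds.name}/test"),
    )


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped percent identity between two sequences.

    Positionwise identical letters are counted from position 1 over the
    shorter length; the denominator is the longer length, so the result is
    in [0, 100] and symmetric.  No alignment is performed.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    identical = sum(x == y for x, y in zip(a, b))
    return 100.0 * identical / max(len(a), len(b))


@dataclass(frozen=True)
class IdentityDistribution:
    """Binned pairwise-identity fractions over all unordered pairs."""

    bin_edges: np.ndarray
    fractions: np.ndarray
    fraction_above: float
    high_threshold: float
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "fraction": self.fractions,
            }
        )


def identity_distribution(
    ds: Dataset, bin_width: float = 10.0, high_threshold: float = 50.0
) -> IdentityDistribution:
    """Pairwise identity over all unordered pairs, binned by ``bin_width``.

    Returns per-bin fractions (summing to 1) and the fraction of pairs
    strictly above ``high_threshold`` percent identity.
    """
    if len(ds) < 2:
        raise ValueError("identity_distribution needs at least 2 records")
    seqs = ds.sequences
    values = [
        pairwise_identity(seqs[i], seqs[j])
        for i in range(len(seqs))
        for j in range(i + 1, len(seqs))
    ]
    values = np.asarray(values)
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    return IdentityDistribution(
        bin_edges=edges,
        fractions=counts / values.size,
        fraction_above=float(np.mean(values > high_threshold)),
        high_threshold=high_threshold,
        n_pairs=values.size,
    )


def composition_stats(ds: Dataset) -> pd.Series:
    """Per-amino-acid frequency over all residues; sums to 1."""
    if len(ds) == 0:
        raise ValueError("composition_stats needs a non-empty dataset")
    counts = Counter()
    for r in ds.records:
        counts.update(r.sequence)
    total = sum(counts.values())
    return pd.Series(
        {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}, name="frequency"
    )


def per_aa_occurrence_cest(ds: Dataset, threshold: float = 12.5) -> pd.Series:
    """Occurrence-method CEST value for each single amino acid.

    Convenience wrapper used by the dataset-analysis report: delegates to
    the motif database's occurrence rule with single-letter motifs.
    Letters absent from the dataset get NaN.
    """
    from .motif_db import occurrence_cest  # local import to avoid a cycle

    out = {}
    present = set("".join(ds.sequences))
    for aa in AMINO_ACIDS:
        if aa in present:
            out[aa] = occurrence_cest(aa, ds, threshold).cest
        else:
            out[aa] = np.nan
    return pd.Series(out, name="occurrence_cest")
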