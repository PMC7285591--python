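"""Sequence and pair-table I/O.

Reads and writes multi-record FASTA (via Biopython), validates sequences
against their declared molecular alphabet, loads delimited protein-aptamer
pair tables, and applies the problematic-sequence filter that removes
nucleotide entries containing B, N, or a mixture of U and T.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")
DNA_ALPHABET = frozenset("ACGT")
RNA_ALPHABET = frozenset("ACGU")

_ALPHABETS = {
    "protein": PROTEIN_ALPHABET,
    "DNA": DNA_ALPHABET,
    "RNA": RNA_ALPHABET,
}

MOLECULES = ("protein", "DNA", "RNA")


class AlphabetError(ValueError):
    """Sequence contains letters outside its declared alphabet."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence with a declared molecule kind.

    ``residues`` are stored upper-case exactly as given (RNA keeps U, DNA
    keeps T); encoders canonicalize internally where needed.
    """

    name: str
    residues: str
    molecule: str  # "protein" | "DNA" | "RNA"

    def __post_init__(self) -> None:
        if self.molecule not in _ALPHABETS:
            raise ValueError(f"unknown molecule kind: {self.molecule!r}")
        if len(self.residues) < 1:
            raise ValueError(f"empty sequence for record {self.name!r}")
        object.__setattr__(self, "residues", self.residues.upper())

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def is_nucleotide(self) -> bool:
        return self.molecule in ("DNA", "RNA")

    def validate(self) -> "SequenceRecord":
        """Raise :class:`AlphabetError` if residues fall outside the alphabet."""
        bad = set(self.residues) - _ALPHABETS[self.molecule]
        if bad:
            raise AlphabetError(
                f"record {self.name!r} ({self.molecule}) contains invalid "
                f"letters: {''.join(sorted(bad))}"
            )
        return self


@dataclass(frozen=True)
class PairRecord:
    """A protein-aptamer pair with a binary interaction label (1 = interacting)."""

    protein: SequenceRecord
    aptamer: SequenceRecord
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")
        if self.protein.molecule != "protein":
            raise ValueError("pair protein member is not a protein record")
        if not self.aptamer.is_nucleotide:
            raise ValueError("pair aptamer member is not a nucleotide record")


def read_fasta(path: str | os.PathLike, molecule: str) -> list[SequenceRecord]:
    """Read a FASTA file into validated-shape records.

    Header text after the first whitespace is ignored; wrapped and
    unwrapped bodies are both accepted; lower-case input is up-cased.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = str(entry.seq)
        if not seq:
            raise ValueError(f"empty sequence for FASTA entry {entry.id!r}")
        records.append(SequenceRecord(entry.id, seq, molecule))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    bio = [_BioRecord(Seq(r.residues), id=r.name, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def problematic_reason(record: SequenceRecord) -> str | None:
    """Reason a nucleotide sequence is problematic, or None if clean.

    A sequence is problematic when it contains the letter B, the letter N,
    or both U and T (an ambiguous DNA/RNA mixture).
    """
    s = record.residues
    if "B" in s:
        return "contains B"
    if "N" in s:
        return "contains N"
    if "U" in s and "T" in s:
        return "mixed U/T"
    return None


def filter_problematic(
    records: Sequence[SequenceRecord], *, include_proteins: bool = False
) -> tuple[list[SequenceRecord], list[tuple[SequenceRecord, str]]]:
    """Partition records into (kept, discarded-with-reason).

    By default only nucleotide records are screened; proteins pass through
    (B is a legitimate ambiguity code only in extended protein alphabets,
    and the filter's U/T clause is meaningless for proteins).  Set
    ``include_proteins=True`` to screen everything.
    """
    kept: list[SequenceRecord] = []
    discarded: list[tuple[SequenceRecord, str]] = []
    for rec in records:
        if rec.is_nucleotide or include_proteins:
            reason = problematic_reason(rec)
            if reason is not None:
                discarded.append((rec, reason))
                continue
        kept.append(rec)
    return kept, discarded


def write_discard_report(
    discarded: Sequence[tuple[SequenceRecord, str]], path: str | os.PathLike
) -> None:
    pd.DataFrame(
        [(r.name, reason) for r, reason in discarded], columns=["name", "reason"]
    ).to_csv(path, sep="\t", index=False)


#: default column mapping for pair tables
PAIR_COLUMNS = {
    "protein_id": "protein_id",
    "protein_seq": "protein_seq",
    "aptamer_id": "aptamer_id",
    "aptamer_seq": "aptamer_seq",
    "label": "label",
}

_LABEL_TOKENS = {
    "1": 1, "0": 0, "yes": 1, "no": 0, "true": 1, "false": 0,
    "positive": 1, "negative": 0, "interacting": 1, "non-interacting": 0,
}


def load_pair_dataset(
    path: str | os.PathLike,
    *,
    aptamer_molecule: str = "DNA",
    columns: dict[str, str] | None = None,
    sep: str | None = None,
) -> list[PairRecord]:
    """Load a delimited pair table into :class:`PairRecord` objects.

    The table must have a header row with (configurable) columns for
    protein id/sequence, aptamer id/sequence and label.  Labels are coerced
    to {0, 1}; unknown tokens raise with the offending row number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cols = dict(PAIR_COLUMNS)
    if columns:
        cols.update(columns)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"pair table {path} missing columns: {missing}")
    pairs: list[PairRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        row = row._asdict()
        raw_label = str(row[cols["label"]]).strip().lower()
        if raw_label not in _LABEL_TOKENS:
            raise ValueError(f"row {i}: unknown label token {raw_label!r}")
        try:
            protein = SequenceRecord(
                str(row[cols["protein_id"]]), str(row[cols["protein_seq"]]), "protein"
            )
            aptamer = SequenceRecord(
                str(row[cols["aptamer_id"]]), str(row[cols["aptamer_seq"]]),
                aptamer_molecule,
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        pairs.append(PairRecord(protein, aptamer, _LABEL_TOKENS[raw_label]))
    return pairs


def filter_pair_dataset(
    pairs: Sequence[PairRecord],
) -> tuple[list[PairRecord], list[tuple[PairRecord, str]]]:
    """Apply the problematic-sequence filter to the aptamer member of each pair."""
    kept, discarded = [], []
    for p in pairs:
        reason = problematic_reason(p.aptamer)
        if reason is None:
            kept.append(p)
        else:
            discarded.append((p, reason))
    return kept, discarded
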