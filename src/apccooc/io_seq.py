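"""Sequence input/output and the core sequence container.

The pipeline operates on a set of homologous protein sequences over the
20-letter amino-acid alphabet.  Residue positions are 0-based half-open
internally; every user-facing report converts to 1-based inclusive
coordinates, matching the residue-numbering convention of the structural
biology literature (Lys48, Gly76, ...).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetically.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

GAP = "-"
WILDCARD = "*"


class SequenceError(ValueError):
    """Raised for malformed or inconsistent sequence input."""


@dataclass(frozen=True)
class SequenceRecord:
    """One protein sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a :class:`SequenceSet`.
    residues : str
        Uppercase string over the 20 standard amino acids.
    description : str
        Free-text description (FASTA header remainder).
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.residues):
            if ch not in _AA_SET:
                raise SequenceError(
                    f"illegal residue {ch!r} in sequence {self.id!r} at position "
                    f"{pos + 1} (1-based); expected one of {AMINO_ACIDS}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class SequenceSet:
    """Ordered collection of :class:`SequenceRecord` with background frequencies.

    The maximum-likelihood residue frequencies f(sigma) over all residues of
    the set are used as the order-0 background model for pattern significance.
    """

    records: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise SequenceError(f"duplicate identifier {rec.id!r}")
            seen.add(rec.id)
        self._by_id = {rec.id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.records)

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self._by_id[seq_id]

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [rec.id for rec in self.records]

    def total_residues(self) -> int:
        return sum(len(rec) for rec in self.records)

    def frequencies(self) -> dict[str, float]:
        """Maximum-likelihood background frequency of each amino acid.

        Sums to 1 for a non-empty set; residues absent from the set get 0.
        """
        counts = Counter()
        for rec in self.records:
            counts.update(rec.residues)
        total = sum(counts.values())
        if total == 0:
            return {aa: 0.0 for aa in AMINO_ACIDS}
        return {aa: counts.get(aa, 0) / total for aa in AMINO_ACIDS}


def read_fasta(path: str | Path, skip_bad_records: bool = False) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    Parameters
    ----------
    path : path-like
        Multi-record FASTA, wrapped or unwrapped.
    skip_bad_records : bool
        When True, records containing non-standard residues (B, J, O, U, X, Z
        or anything outside the 20-letter alphabet) are dropped with a
        warning instead of aborting the whole read.  Pattern statistics
        assume a 20-letter alphabet, so the default is to abort.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        try:
            records.append(
                SequenceRecord(id=rec.id, residues=residues, description=rec.description)
            )
        except SequenceError:
            if skip_bad_records:
                warnings.warn(f"skipping record {rec.id!r}: non-standard residue")
                continue
            raise
    if not records:
        raise SequenceError(f"no sequences in {path}")
    return SequenceSet(records)


def write_fasta(seqs: SequenceSet | Iterable[SequenceRecord], path: str | Path,
                width: int = 60) -> None:
    """Write sequences as uppercase FASTA wrapped at ``width`` columns."""
    bio_records = [
        SeqRecord(Seq(rec.residues), id=rec.id, description=rec.description)
        for rec in seqs
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(bio_records)
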