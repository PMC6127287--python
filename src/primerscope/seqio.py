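"""Sequence I/O and the IUPAC nucleotide algebra.

Every other module builds on the primitives here: the IUPAC ambiguity
table (one letter -> set of concrete bases), degenerate matching,
expansion, degeneracy counting, and reverse complementation, plus
FASTA/FASTQ/TSV readers that normalize records into :class:`SequenceRecord`.

Conventions
-----------
* Residues are uppercase; ``U`` is silently mapped to ``T`` (16S data is
  sometimes RNA-coded); any other non-IUPAC letter is a hard error.
* The only gap character is ``-``; ``.`` in input alignments is
  normalized to ``-``.
* Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

__all__ = [
    "IUPAC_BASES",
    "IUPAC_COMPLEMENT",
    "SequenceError",
    "SequenceRecord",
    "is_degenerate",
    "iupac_match",
    "expand_degenerate",
    "count_degeneracy",
    "reverse_complement",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "read_primer_tsv",
    "write_primer_tsv",
    "smallest_code_for",
]

#: IUPAC nucleotide ambiguity codes -> the set of concrete bases they denote.
IUPAC_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Reverse lookup: frozenset of bases -> the unique IUPAC letter covering exactly them.
_CODE_FOR_BASES: dict[frozenset[str], str] = {v: k for k, v in IUPAC_BASES.items()}

#: IUPAC-aware complement (comp(R)=Y, comp(D)=H, comp(N)=N, ...).
IUPAC_COMPLEMENT: dict[str, str] = {
    code: _CODE_FOR_BASES[frozenset({"A": "T", "C": "G", "G": "C", "T": "A"}[b] for b in bases)]
    for code, bases in IUPAC_BASES.items()
}

GAP = "-"


class SequenceError(ValueError):
    """Raised for malformed sequences, records, or sequence files."""


def _check_letter(letter: str) -> frozenset[str]:
    try:
        return IUPAC_BASES[letter]
    except KeyError:
        raise SequenceError(f"invalid IUPAC nucleotide letter: {letter!r}") from None


def is_degenerate(letter: str) -> bool:
    """True iff *letter* denotes more than one concrete base."""
    return len(_check_letter(letter)) > 1


def iupac_match(a: str, b: str) -> bool:
    """Degenerate-aware base match: true iff bases(a) and bases(b) intersect.

    Symmetric and reflexive; for concrete bases this is plain equality.
    Gaps are not allowed.
    """
    return not _check_letter(a).isdisjoint(_check_letter(b))


def count_degeneracy(seq: str) -> tuple[int, int]:
    """Return ``(n_degenerate_positions, fold_degeneracy)`` for an IUPAC string.

    ``fold_degeneracy`` is the product of per-position base-set sizes, i.e.
    the number of concrete sequences the string denotes.
    """
    n_deg = 0
    fold = 1
    for letter in seq:
        k = len(_check_letter(letter))
        if k > 1:
            n_deg += 1
        fold *= k
    return n_deg, fold


def expand_degenerate(seq: str, cap: int = 1024) -> set[str]:
    """Enumerate all concrete ACGT sequences an IUPAC string denotes.

    Parameters
    ----------
    seq : IUPAC string without gaps.
    cap : refuse to expand beyond this many sequences (bounds the
        brute-force oracle; default 1024).
    """
    _, fold = count_degeneracy(seq)
    if fold > cap:
        raise SequenceError(
            f"degenerate expansion of {seq!r} has cardinality {fold} > cap {cap}"
        )
    pools = [sorted(IUPAC_BASES[letter]) for letter in seq]
    return {"".join(combo) for combo in itertools.product(*pools)}


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement; an involution on valid strings."""
    _validate(seq, allow_gaps=False)
    return "".join(IUPAC_COMPLEMENT[letter] for letter in reversed(seq))


def smallest_code_for(bases: Iterable[str]) -> str:
    """The unique IUPAC letter whose base set is exactly the given bases."""
    key = frozenset(bases)
    try:
        return _CODE_FOR_BASES[key]
    except KeyError:
        raise SequenceError(f"no IUPAC code for base set {sorted(key)}") from None


def _validate(seq: str, allow_gaps: bool = False) -> bool:
    for i, letter in enumerate(seq):
        if letter == GAP:
            if allow_gaps:
                continue
            raise SequenceError(f"gap character at position {i} not allowed here")
        if letter not in IUPAC_BASES:
            raise SequenceError(f"non-IUPAC character {letter!r} at position {i}")
    return True


def normalize_residues(raw: str, *, context: str = "") -> str:
    """Uppercase, map U->T and .->-, and validate against the IUPAC alphabet.

    Raises :class:`SequenceError` naming the offending position otherwise.
    """
    s = raw.upper().replace("U", "T").replace(".", GAP)
    for i, letter in enumerate(s):
        if letter != GAP and letter not in IUPAC_BASES:
            where = f" in {context}" if context else ""
            raise SequenceError(f"non-IUPAC character {letter!r} at position {i}{where}")
    return s


@dataclass(frozen=True)
class SequenceRecord:
    """A named IUPAC nucleotide sequence, possibly gapped when aligned."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise SequenceError(f"record id must be a non-empty token, got {self.id!r}")
        object.__setattr__(self, "residues", normalize_residues(self.residues, context=self.id))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def without_gaps(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.ungapped, self.description)


def _check_unique_ids(records: Sequence[SequenceRecord], source: str) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r} in {source}")
        seen.add(rec.id)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-line) FASTA file into normalized records.

    Order is preserved; duplicate ids and non-IUPAC characters are hard
    errors; an empty file yields an empty list with a warning.
    """
    path = Path(path)
    records = [
        SequenceRecord(r.id, str(r.seq), r.description[len(r.id):].strip())
        for r in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    _check_unique_ids(records, str(path))
    return records


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read FASTQ; qualities are parsed and discarded."""
    path = Path(path)
    records = [
        SequenceRecord(r.id, str(r.seq), r.description[len(r.id):].strip())
        for r in SeqIO.parse(str(path), "fastq")
    ]
    if not records:
        warnings.warn(f"no sequences found in {path}", stacklevel=2)
    _check_unique_ids(records, str(path))
    return records


def read_sequences(path: str | Path) -> list[SequenceRecord]:
    """Dispatch on extension: .fastq/.fq -> FASTQ, anything else FASTA."""
    suffix = Path(path).suffix.lower()
    if suffix in {".fastq", ".fq"}:
        return read_fastq(path)
    return read_fasta(path)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA wrapped at *width* columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_primer_tsv(path: str | Path) -> list[SequenceRecord]:
    """Read primers from a 2-column TSV (name, IUPAC sequence).

    Lines starting with ``#`` and a header line whose second column is not
    a valid IUPAC string are skipped.
    """
    records: list[SequenceRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise SequenceError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            name, seq = parts[0].strip(), parts[1].strip()
            try:
                records.append(SequenceRecord(name, seq))
            except SequenceError:
                if lineno == 1:  # tolerate a header row
                    continue
                raise
    _check_unique_ids(records, str(path))
    return records


def write_primer_tsv(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\tsequence\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.residues}\n")
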