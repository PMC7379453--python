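"""FASTA input/output for prolamin sequence sets.

Reads the header dialects encountered in curated seed-storage-protein
databases (UniProt ``sp|``/``tr|`` pipe headers, NCBI ``gi|``/versioned
accessions, and plain-token headers) into validated
:class:`SequenceRecord` objects, and writes them back deterministically.

The amino-acid alphabet is the 20 standard residues plus the ambiguity
letters ``X``, ``B``, ``Z``, ``J``.  Ambiguous records are *readable* —
the curation stage needs to see them in order to remove them — whereas
selenocysteine (``U``), pyrrolysine (``O``) and stop characters are hard
read errors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
AMBIGUITY_LETTERS = frozenset("XBZJ")
ALLOWED_LETTERS = STANDARD_RESIDUES | AMBIGUITY_LETTERS

_OS_RE = re.compile(r"\s*OS=(.+?)(?=\s+[A-Z]{2}=|$)")
_NCBI_VERSIONED = re.compile(r"^[A-Za-z0-9_]+\.\d+$")


class FastaError(ValueError):
    """Raised for malformed FASTA input (bad header, bad residue, empty file)."""


class Source(str, Enum):
    """Origin dialect of a sequence record."""

    uniprot_sp = "uniprot_sp"
    uniprot_tr = "uniprot_tr"
    ncbi = "ncbi"
    other = "other"


@dataclass
class SequenceRecord:
    """One protein sequence with its provenance.

    Parameters
    ----------
    accession : str
        Non-empty identifier, unique within a curated set.
    source : Source
        Header dialect the record was read from.
    description : str
        Free text after the accession token (``OS=`` species field removed).
    species : str
        Organism name from the ``OS=`` field; empty when absent.
    sequence : str
        Upper-case amino acids; standard residues plus X/B/Z/J.
    signal_len : int
        Residues of N-terminal signal peptide, 0 = unknown/none.  Not
        serialized to FASTA.
    """

    accession: str
    source: Source = Source.other
    description: str = ""
    species: str = ""
    sequence: str = ""
    signal_len: int = 0

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.accession}: sequence must be non-empty")
        if self.sequence != self.sequence.upper():
            raise ValueError(f"{self.accession}: sequence must be upper-case")
        bad = set(self.sequence) - ALLOWED_LETTERS
        if bad:
            pos = next(i for i, c in enumerate(self.sequence, start=1) if c in bad)
            raise ValueError(
                f"{self.accession}: disallowed residue {self.sequence[pos - 1]!r} "
                f"at position {pos}"
            )
        if not 0 <= self.signal_len < len(self.sequence):
            raise ValueError(f"{self.accession}: signal_len must be in [0, L)")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mature_sequence(self) -> str:
        """Sequence with the signal peptide (if annotated) removed."""
        return self.sequence[self.signal_len :]


def parse_header(header: str) -> tuple[str, Source, str, str]:
    """Split a FASTA definition line (text after ``>``) into fields.

    Returns ``(accession, source, description, species)``.  The species
    is taken from a UniProt-style ``OS=`` field when present and that
    field is removed from the returned description, so the description +
    species pair round-trips through :func:`write_fasta`.
    """
    header = header.strip()
    if not header:
        raise FastaError("empty FASTA header")
    token, _, rest = header.partition(" ")
    rest = rest.strip()

    if token.startswith("sp|") or token.startswith("tr|"):
        fields = token.split("|")
        if len(fields) < 2 or not fields[1]:
            raise FastaError(f"UniProt header with no accession: {header!r}")
        accession = fields[1]
        source = Source.uniprot_sp if token.startswith("sp|") else Source.uniprot_tr
    elif token.startswith("gi|"):
        fields = [f for f in token.split("|") if f]
        # gi|number|db|accession| style: prefer the trailing accession
        accession = fields[3] if len(fields) >= 4 else fields[1]
        source = Source.ncbi
    elif _NCBI_VERSIONED.match(token):
        accession = token
        source = Source.ncbi
    else:
        accession = token
        source = Source.other
    if not accession:
        raise FastaError(f"header with no accession token: {header!r}")

    species = ""
    m = _OS_RE.search(rest)
    if m:
        species = m.group(1).strip()
        rest = (rest[: m.start()] + rest[m.end() :]).strip()
    return accession, source, rest, species


def _format_header(rec: SequenceRecord) -> str:
    if rec.source is Source.uniprot_sp:
        head = f"sp|{rec.accession}|{rec.accession}"
    elif rec.source is Source.uniprot_tr:
        head = f"tr|{rec.accession}|{rec.accession}"
    else:
        head = rec.accession
    parts = [head]
    if rec.description:
        parts.append(rec.description)
    if rec.species:
        parts.append(f"OS={rec.species}")
    return " ".join(parts)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into an ordered list of records.

    Whitespace and digits are stripped from sequence lines and letters
    upper-cased.  An empty file, a residue outside the allowed alphabet,
    or a header without an accession token raise :class:`FastaError`.
    """
    path = Path(path)
    if not path.is_file():
        raise FastaError(f"no such FASTA file: {path}")
    records: list[SequenceRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        accession, source, description, species = parse_header(entry.description)
        raw = str(entry.seq)
        seq = re.sub(r"[\s\d]", "", raw).upper()
        if not seq:
            raise FastaError(f"{accession}: empty sequence")
        for i, c in enumerate(seq, start=1):
            if c not in ALLOWED_LETTERS:
                raise FastaError(
                    f"record {accession}: disallowed residue {c!r} at position {i}"
                )
        records.append(
            SequenceRecord(
                accession=accession,
                source=source,
                description=description,
                species=species,
                sequence=seq,
            )
        )
    if not records:
        raise FastaError(f"no FASTA records in {path}")
    return records


def write_fasta(
    records: Iterable[SequenceRecord], path: str | Path, wrap: int = 60
) -> None:
    """Write records to ``path``, wrapping sequence lines at ``wrap`` residues.

    Output is deterministic; headers are rebuilt in the record's own
    dialect so that ``read_fasta(write_fasta(x)) == x`` field-for-field
    (``signal_len`` excepted — FASTA carries no signal annotation).
    An empty collection yields an empty file.
    """
    if wrap < 1:
        raise ValueError("wrap must be a positive integer")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_format_header(rec)}\n")
            for i in range(0, len(rec.sequence), wrap):
                fh.write(rec.sequence[i : i + wrap] + "\n")


def check_unique_accessions(records: Sequence[SequenceRecord]) -> None:
    """Raise ``ValueError`` if any accession occurs more than once."""
    seen: set[str] = set()
    for rec in records:
        if rec.accession in seen:
            raise ValueError(f"duplicate accession {rec.accession}")
        seen.add(rec.accession)
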