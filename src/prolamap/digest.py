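"""In-silico chymotryptic digestion and marker-peptide selection.

Chymotrypsin specificity follows the rule used in gluten proteomics
searches: cleavage after Y, W, F or L unless the next residue is
proline, with up to two missed cleavages.  Peptides carry parent
coordinates, a missed-cleavage count and a monoisotopic mass (with
optional fixed carbamidomethylation of cysteine, +57.021464 Da per C).

Marker candidates for targeted quantitation are peptides that are
unique to one database protein, at least 5 residues long, and above the
750 Da precursor cut-off applied during MS processing (applied here to
the neutral monoisotopic peptide mass — a documented approximation,
since charge states are out of scope).  Because mass spectrometry
cannot distinguish isoleucine from leucine, uniqueness may optionally
merge I and L.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from pyteomics import mass as _pmass

from .motifmap import MotifPanel, find_hits
from .seqio import STANDARD_RESIDUES, SequenceRecord

CLEAVAGE_RESIDUES = frozenset("YWFL")
WATER_MONO = 18.010565
CAM_DELTA = 57.021464


@dataclass(frozen=True)
class Peptide:
    sequence: str
    parent: str
    start: int  # 1-based inclusive, parent coordinates
    end: int
    missed_cleavages: int
    mono_mass: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span does not match its length")


@dataclass(frozen=True)
class MarkerCandidate:
    peptide: Peptide
    unique: bool
    n_parent_proteins: int
    overlaps_motif: bool
    passes_filters: bool


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions i such that cleavage occurs between i and i+1:
    sequence[i] in Y/W/F/L and sequence[i+1] exists and is not P."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in CLEAVAGE_RESIDUES and sequence[i + 1] != "P"
    ]


def chymotryptic_digest(
    sequence: str, parent: str = "", max_missed: int = 2
) -> list[Peptide]:
    """All chymotryptic peptides with 0..max_missed missed cleavages.

    Zero-missed peptides are the fragments between consecutive cleavage
    sites (termini included) and tile the parent exactly; a peptide with
    j missed cleavages concatenates j+1 consecutive fragments.  Masses
    are not filled in (see :func:`monoisotopic_mass`).
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    sites = cleavage_sites(sequence)
    bounds = [0] + [s + 1 for s in sites] + [len(sequence)]
    fragments = [
        (bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1)
    ]  # half-open 0-based
    peptides: list[Peptide] = []
    nfrag = len(fragments)
    for missed in range(0, min(max_missed, nfrag - 1) + 1):
        for i in range(nfrag - missed):
            lo = fragments[i][0]
            hi = fragments[i + missed][1]
            peptides.append(
                Peptide(
                    sequence=sequence[lo:hi],
                    parent=parent,
                    start=lo + 1,
                    end=hi,
                    missed_cleavages=missed,
                )
            )
    return peptides


def monoisotopic_mass(peptide_sequence: str, fixed_cam: bool = False) -> float:
    """Neutral monoisotopic peptide mass in Da (residues + water), with
    optional fixed carbamidomethyl-C.  Ambiguity letters are rejected."""
    if not peptide_sequence:
        raise ValueError("cannot compute the mass of an empty peptide")
    bad = set(peptide_sequence) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"non-standard residues in peptide: {sorted(bad)}")
    m = _pmass.fast_mass(peptide_sequence)
    if fixed_cam:
        m += CAM_DELTA * peptide_sequence.count("C")
    return m


def _uniqueness_key(seq: str, ileq: bool) -> str:
    return seq.replace("I", "L") if ileq else seq


def peptide_uniqueness(
    records: Sequence[SequenceRecord],
    max_missed: int = 2,
    ileq: bool = False,
) -> dict[str, set[str]]:
    """Map each digestion peptide (key; I/L merged when ``ileq``) to the
    set of parent accessions producing it.  A peptide is unique iff its
    parent set has size 1."""
    if not records:
        raise ValueError("peptide_uniqueness needs at least one record")
    parents: dict[str, set[str]] = {}
    for rec in records:
        for pep in chymotryptic_digest(rec.sequence, rec.accession, max_missed):
            parents.setdefault(_uniqueness_key(pep.sequence, ileq), set()).add(
                rec.accession
            )
    return parents


def select_markers(
    records: Sequence[SequenceRecord],
    panel: MotifPanel | None = None,
    min_len: int = 5,
    min_mass: float = 750.0,
    max_missed: int = 2,
    ileq: bool = False,
    fixed_cam: bool = False,
    require_motif_overlap: bool = False,
) -> list[MarkerCandidate]:
    """Database-unique marker peptides passing the length and mass filters.

    A candidate's ``overlaps_motif`` is true iff its parent-coordinate
    interval intersects any motif hit on that parent.  Candidates are
    sorted by (parent accession, start, end).
    """
    if require_motif_overlap and (panel is None or len(panel) == 0):
        raise ValueError("require_motif_overlap needs a non-empty motif panel")
    parents = peptide_uniqueness(records, max_missed=max_missed, ileq=ileq)

    motif_spans: dict[str, list[tuple[int, int]]] = {}
    if panel is not None and len(panel) > 0:
        for rec in records:
            motif_spans[rec.accession] = [
                (h.start, h.end) for h in find_hits(rec.sequence, panel)
            ]

    seen: set[tuple[str, int, int]] = set()
    candidates: list[MarkerCandidate] = []
    for rec in records:
        for pep in chymotryptic_digest(rec.sequence, rec.accession, max_missed):
            coord = (pep.parent, pep.start, pep.end)
            if coord in seen:
                continue
            seen.add(coord)
            owners = parents[_uniqueness_key(pep.sequence, ileq)]
            if len(owners) != 1 or len(pep.sequence) < min_len:
                continue
            m = monoisotopic_mass(pep.sequence, fixed_cam=fixed_cam)
            if m < min_mass:
                continue
            spans = motif_spans.get(pep.parent, [])
            overlaps = any(s <= pep.end and pep.start <= e for s, e in spans)
            if require_motif_overlap and not overlaps:
                continue
            candidates.append(
                MarkerCandidate(
                    peptide=replace(pep, mono_mass=m),
                    unique=True,
                    n_parent_proteins=1,
                    overlaps_motif=overlaps,
                    passes_filters=True,
                )
            )
    candidates.sort(key=lambda c: (c.peptide.parent, c.peptide.start, c.peptide.end))
    return candidates
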