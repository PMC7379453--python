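"""Prolamin group classification.

A sequence is assigned to a protein group (alpha/gamma/delta/omega-type
prolamin, LMW/HMW glutenin subunit, avenin A/B/C, avenin-like a/b, ...)
from four lines of evidence:

* global percent identity to per-group *master* sequences — the primary
  signal; assignment goes to the group of the best-identity master when
  that identity clears a floor (default 30%, the homology level used to
  recover candidate prolamins in database construction),
* proline + glutamine composition,
* the cysteine count (the conserved prolamin skeleton holds eight
  cysteines, nine in polymeric A-avenins, none in the sulphur-poor
  omega-type prolamins),
* repeat-motif grammar hits (e.g. ``PFM`` followed by 1–5 glutamines in
  A-avenins, the ``VFQPQLQQ`` / ``FFQPQMQQ`` / ``VTQG`` literals of B-
  and C-avenins).

Cysteine and repeat evidence break ties between equally good masters
and are reported alongside the assignment.

Alignments are global (end-to-end) Needleman–Wunsch with BLOSUM62 and
affine gap costs (open 10, extend 0.5 by default); identity is counted
over all alignment columns, gap columns included in the denominator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .curation import pq_content
from .seqio import SequenceRecord


@dataclass(frozen=True)
class RepeatPattern:
    """A repeat-unit grammar: a literal prefix optionally followed by a
    glutamine run of bounded length.  ``q_run_min == q_run_max == 0``
    denotes a literal-only pattern."""

    prefix: str
    q_run_min: int = 0
    q_run_max: int = 0

    def __post_init__(self) -> None:
        if not self.prefix:
            raise ValueError("repeat prefix must be non-empty")
        if not 0 <= self.q_run_min <= self.q_run_max:
            raise ValueError("require 0 <= q_run_min <= q_run_max")

    @property
    def is_literal(self) -> bool:
        return self.q_run_max == 0


@dataclass
class GroupTemplate:
    group_name: str
    repeat_patterns: tuple[RepeatPattern, ...] = ()
    expected_cys: int = 0
    master_accessions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.expected_cys < 0:
            raise ValueError("expected_cys must be >= 0")


@dataclass
class ClassificationResult:
    accession: str
    assigned_group: str
    pq_percent: float
    cys_count: int
    repeat_hits: list[tuple[RepeatPattern, int, int]]
    best_master: tuple[str, float]  # (master accession, identity percent)


@dataclass
class AlignmentParams:
    """Global-alignment scoring used for every identity in the pipeline."""

    matrix_name: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def count_cysteines(sequence: str) -> int:
    """Number of cysteine residues — the skeleton fingerprint."""
    return sequence.count("C")


def find_repeats(sequence: str, pattern: RepeatPattern) -> list[tuple[int, int]]:
    """All (possibly overlapping) occurrences of a repeat pattern.

    Returns 1-based inclusive ``(start, end)`` spans.  The glutamine run
    after the prefix is matched greedily and capped at ``q_run_max``;
    literal patterns match the prefix exactly.
    """
    hits: list[tuple[int, int]] = []
    p = len(pattern.prefix)
    for i in range(len(sequence) - p + 1):
        if sequence[i : i + p] != pattern.prefix:
            continue
        if pattern.is_literal:
            hits.append((i + 1, i + p))
            continue
        run = 0
        j = i + p
        while j < len(sequence) and sequence[j] == "Q" and run < pattern.q_run_max:
            run += 1
            j += 1
        if run >= pattern.q_run_min:
            hits.append((i + 1, i + p + run))
    return hits


def pairwise_identity(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> float:
    """Global percent identity between two sequences.

    Identity = 100 x identical aligned pairs / alignment columns (gap
    columns count in the denominator), reported to 2 decimals.  The pair
    is canonically ordered before aligning so the result is symmetric
    even when several alignments are co-optimal.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    params = params or AlignmentParams()
    a, b = sorted((seq_a, seq_b))
    alignment = params.make_aligner().align(a, b)[0]
    identities = alignment.counts().identities
    return round(100.0 * identities / alignment.length, 2)


def identity_matrix(
    records: Sequence[SequenceRecord], params: AlignmentParams | None = None
) -> tuple[list[str], "list[list[float]]"]:
    """All-against-all identity matrix (symmetric, 100 on the diagonal)."""
    params = params or AlignmentParams()
    n = len(records)
    mat = [[100.0] * n for _ in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        ident = pairwise_identity(records[i].sequence, records[j].sequence, params)
        mat[i][j] = mat[j][i] = ident
    return [r.accession for r in records], mat


def group_homology(
    records: Sequence[SequenceRecord],
    groups: Mapping[str, str],
    params: AlignmentParams | None = None,
) -> dict[str, float]:
    """Mean pairwise identity within each group (all unordered pairs).

    ``groups`` maps accession -> group name; every group must contain at
    least two records.
    """
    params = params or AlignmentParams()
    members: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.accession in groups:
            members.setdefault(groups[rec.accession], []).append(rec)
    out: dict[str, float] = {}
    for name, recs in members.items():
        if len(recs) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 records")
        idents = [
            pairwise_identity(a.sequence, b.sequence, params)
            for a, b in itertools.combinations(recs, 2)
        ]
        out[name] = round(sum(idents) / len(idents), 2)
    return out


def classify_record(
    record: SequenceRecord,
    templates: Sequence[GroupTemplate],
    masters: Mapping[str, SequenceRecord],
    identity_floor: float = 30.0,
    params: AlignmentParams | None = None,
) -> ClassificationResult:
    """Classify one record against group templates and master sequences.

    ``masters`` maps master accession -> record; each master accession
    must be claimed by exactly one template.  The record takes the group
    of its best-identity master when identity >= ``identity_floor``;
    ties are broken by more repeat-pattern hits for the tied group, then
    by template order.  Otherwise the record is "unclassified".
    """
    if not templates:
        raise ValueError("templates must be non-empty")
    params = params or AlignmentParams()

    group_of_master: dict[str, str] = {}
    template_rank = {t.group_name: k for k, t in enumerate(templates)}
    by_name = {t.group_name: t for t in templates}
    for t in templates:
        for acc in t.master_accessions:
            group_of_master[acc] = t.group_name

    repeat_hits: list[tuple[RepeatPattern, int, int]] = []
    hits_per_group: dict[str, int] = {}
    for t in templates:
        n = 0
        for pat in t.repeat_patterns:
            for start, end in find_repeats(record.sequence, pat):
                repeat_hits.append((pat, start, end))
                n += 1
        hits_per_group[t.group_name] = n

    best: tuple[float, int, int, str] | None = None  # (-identity proxies via compare)
    best_master = ("", 0.0)
    for acc, master in masters.items():
        if acc not in group_of_master:
            raise ValueError(f"master {acc} is not claimed by any template")
        ident = pairwise_identity(record.sequence, master.sequence, params)
        group = group_of_master[acc]
        key = (-ident, -hits_per_group[group], template_rank[group], acc)
        if best is None or key < best:
            best = key
            best_master = (acc, ident)

    assigned = "unclassified"
    if best_master[0] and best_master[1] >= identity_floor:
        assigned = group_of_master[best_master[0]]

    return ClassificationResult(
        accession=record.accession,
        assigned_group=assigned,
        pq_percent=pq_content(record.sequence),
        cys_count=count_cysteines(record.sequence),
        repeat_hits=repeat_hits,
        best_master=best_master,
    )


def classify_records(
    records: Iterable[SequenceRecord],
    templates: Sequence[GroupTemplate],
    masters: Mapping[str, SequenceRecord],
    identity_floor: float = 30.0,
    params: AlignmentParams | None = None,
) -> list[ClassificationResult]:
    return [
        classify_record(r, templates, masters, identity_floor, params) for r in records
    ]
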