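"""Stage-I style curation of prolamin sequence sets.

Downloaded seed-storage-protein sets are dominated by redundancy: the
same protein is returned by several search terms and deposited under
several accessions, so raw downloads collapse to a few percent of their
original size once duplicates are removed.  This module makes that
manual clean-up deterministic and auditable:

* exact duplicate sequences are collapsed with UniProt accessions
  preferentially retained,
* records sharing an accession are collapsed to the first occurrence,
* sequences containing ambiguity letters (X and friends) are removed,
* likely partial sequences are removed on three explicit, configurable
  signals (length floor, missing initiator methionine, header keywords
  such as "(Fragment)"),
* a proline + glutamine content below the prolamin-confirmation
  threshold (default 30%) is *reported* as a warning, never removed —
  genuine prolamins (notably avenins and some avenin-like proteins)
  fall in the 22–35% range.

Every removal is logged with exactly one (first-triggered) reason so
that ``n_input == n_kept + len(removals)`` always holds.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .seqio import AMBIGUITY_LETTERS, SequenceRecord, Source


class RemovalReason(str, Enum):
    duplicate_sequence = "duplicate_sequence"
    duplicate_accession = "duplicate_accession"
    ambiguous_residue = "ambiguous_residue"
    partial_sequence = "partial_sequence"
    low_pq = "low_pq"  # reported as warning only, never a removal


@dataclass(frozen=True)
class Removal:
    accession: str
    reason: RemovalReason
    detail: str = ""


DEFAULT_SOURCE_PREFERENCE: tuple[Source, ...] = (
    Source.uniprot_sp,
    Source.uniprot_tr,
    Source.ncbi,
    Source.other,
)


@dataclass
class CurationConfig:
    """Tunable rules for the curation pass.

    ``pq_threshold_percent`` is the proline + glutamine percentage below
    which a record is flagged (not removed) as a doubtful prolamin.
    ``source_preference`` must be a total order over :class:`Source`.
    """

    ambiguous_letters: frozenset[str] = AMBIGUITY_LETTERS
    min_length: int = 50
    require_initiator_met: bool = True
    pq_threshold_percent: float = 30.0
    partial_keywords: tuple[str, ...] = ("partial", "fragment", "(Fragment)")
    source_preference: tuple[Source, ...] = DEFAULT_SOURCE_PREFERENCE

    def __post_init__(self) -> None:
        if not 0.0 <= self.pq_threshold_percent <= 100.0:
            raise ValueError("pq_threshold_percent must be in [0, 100]")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if set(self.source_preference) != set(Source):
            raise ValueError("source_preference must totally order Source")

    def source_rank(self, source: Source) -> int:
        return self.source_preference.index(source)


@dataclass
class CurationReport:
    n_input: int = 0
    n_kept: int = 0
    removals: list[Removal] = field(default_factory=list)
    low_pq_warnings: list[tuple[str, float]] = field(default_factory=list)

    @property
    def tallies(self) -> Counter:
        """Per-reason removal counts."""
        return Counter(r.reason for r in self.removals)

    def validate(self) -> None:
        if self.n_input != self.n_kept + len(self.removals):
            raise AssertionError("curation report violates count conservation")
        accs = [r.accession for r in self.removals]
        if len(accs) != len(set(accs)):
            raise AssertionError("a removed accession appears more than once")


def pq_content(sequence: str) -> float:
    """Percent of residues that are proline or glutamine, to 2 decimals."""
    if not sequence:
        raise ValueError("pq_content of an empty sequence is undefined")
    return round(100.0 * (sequence.count("P") + sequence.count("Q")) / len(sequence), 2)


def flag_ambiguous(record: SequenceRecord, config: CurationConfig | None = None) -> bool:
    """True iff the sequence contains any configured ambiguity letter."""
    config = config or CurationConfig()
    return any(c in config.ambiguous_letters for c in record.sequence)


def flag_partial(record: SequenceRecord, config: CurationConfig | None = None) -> bool:
    """Heuristic partial-sequence flag.

    True iff the sequence is shorter than ``min_length``, or lacks an
    initiator methionine (when required and no signal peptide is
    annotated), or the description contains a partial keyword
    (case-insensitive).
    """
    config = config or CurationConfig()
    if len(record.sequence) < config.min_length:
        return True
    if (
        config.require_initiator_met
        and record.signal_len == 0
        and record.sequence[0] != "M"
    ):
        return True
    desc = record.description.lower()
    return any(kw.lower() in desc for kw in config.partial_keywords)


def deduplicate(
    records: Sequence[SequenceRecord], config: CurationConfig | None = None
) -> tuple[list[SequenceRecord], list[Removal]]:
    """Collapse duplicate accessions and duplicate sequences.

    Records sharing an accession keep the first occurrence.  Exact
    duplicate sequences keep one representative chosen by source
    preference (UniProt Swiss-Prot first), ties broken by input order.
    Survivors keep input order.
    """
    config = config or CurationConfig()
    removals: list[Removal] = []

    by_accession: dict[str, SequenceRecord] = {}
    stage1: list[SequenceRecord] = []
    for rec in records:
        if rec.accession in by_accession:
            removals.append(
                Removal(rec.accession, RemovalReason.duplicate_accession,
                        "accession seen earlier in input")
            )
        else:
            by_accession[rec.accession] = rec
            stage1.append(rec)

    # representative per sequence: best (preference rank, input index)
    best_for_seq: dict[str, tuple[tuple[int, int], SequenceRecord]] = {}
    for idx, rec in enumerate(stage1):
        key = (config.source_rank(rec.source), idx)
        if rec.sequence not in best_for_seq or key < best_for_seq[rec.sequence][0]:
            best_for_seq[rec.sequence] = (key, rec)
    winners = {id(v[1]) for v in best_for_seq.values()}

    kept: list[SequenceRecord] = []
    for rec in stage1:
        if id(rec) in winners:
            kept.append(rec)
        else:
            rep = best_for_seq[rec.sequence][1]
            removals.append(
                Removal(rec.accession, RemovalReason.duplicate_sequence,
                        f"identical to {rep.accession}")
            )
    return kept, removals


def curate(
    records: Sequence[SequenceRecord], config: CurationConfig | None = None
) -> tuple[list[SequenceRecord], CurationReport]:
    """Apply the full curation pass: deduplicate, then remove ambiguous
    and partial records; flag (never remove) low-P+Q survivors.

    Duplicate checks run before content checks so that the retained
    representative, not a discarded copy, is the one content-checked.
    Idempotent: curating curated output removes nothing further.
    """
    config = config or CurationConfig()
    report = CurationReport(n_input=len(records))

    deduped, dup_removals = deduplicate(records, config)
    report.removals.extend(dup_removals)

    kept: list[SequenceRecord] = []
    for rec in deduped:
        if flag_ambiguous(rec, config):
            letters = sorted(set(rec.sequence) & set(config.ambiguous_letters))
            report.removals.append(
                Removal(rec.accession, RemovalReason.ambiguous_residue,
                        f"contains {','.join(letters)}")
            )
        elif flag_partial(rec, config):
            report.removals.append(
                Removal(rec.accession, RemovalReason.partial_sequence, "")
            )
        else:
            kept.append(rec)
            pq = pq_content(rec.sequence)
            if pq <= config.pq_threshold_percent:
                report.low_pq_warnings.append((rec.accession, pq))

    report.n_kept = len(kept)
    report.validate()
    return kept, report
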