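"""Synthetic prolamin families with exact ground truth.

Real prolamin databases cannot be redistributed inside a test suite, so
this module generates families that *structurally* mimic them: each
group has a signal peptide, an N-terminal domain, a repetitive domain
built from a group-specific repeat unit (e.g. ``PFM`` + glutamine run
for A-avenin-like groups), and a C-terminal domain carrying a fixed
cysteine skeleton (eight or nine cysteines; none for the sulphur-poor
omega-type group).  The residue background is glutamine/proline rich
(default 35% Q, 15% P) to mimic prolamin composition.

Ground truth stays exact by construction:

* motifs are spliced in at recorded coordinates,
* point mutations never touch the initiator Met, embedded motif spans
  or skeleton cysteines (the background alphabet excludes C, so the
  cysteine count equals the skeleton size whenever the mutation rate
  leaves C positions alone — which it always does),
* expected motif statistics are computed *after* assembly by an
  independent brute-force per-residue oracle, so incidental matches
  created by the repetitive background are included — repetitive
  prolamin-like backgrounds do create accidental motif matches, and the
  mapped statistics count them.

Corrupted records for curation testing are appended after the clean
ones: NCBI-sourced exact duplicates, records with an injected ``X``,
and truncated "(Fragment)" records.

What the generator does *not* emulate: realistic evolutionary
divergence (mutations are i.i.d. point substitutions), indels, allelic
series, or any mass-spectrometric noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import GroupTemplate, RepeatPattern
from .motifmap import MotifMetrics, MotifPanel, write_panel
from .seqio import SequenceRecord, Source, write_fasta

BACKGROUND_ALPHABET = tuple("ADEFGHIKLMNPQRSTVWY")  # standard residues minus C
SIGNAL_ALPHABET = tuple("ASTVGIKRNQPEDH")  # no C, no Y/W/F/L


@dataclass(frozen=True)
class GroupSpec:
    """Template for one synthetic prolamin group."""

    name: str
    n_records: int
    signal: str
    nterm: str
    repeat_unit: str
    repeat_count_range: tuple[int, int]
    cterm: str  # carries the fixed cysteine skeleton
    patterns: tuple[RepeatPattern, ...]

    @property
    def n_cys(self) -> int:
        return self.cterm.count("C")


@dataclass(frozen=True)
class PanelSpec:
    n_motifs: int = 25
    length_range: tuple[int, int] = (6, 10)
    nested_fraction: float = 0.2  # fraction that are fragments of other motifs

    def __post_init__(self) -> None:
        if self.length_range[0] < 4:
            raise ValueError("motif lengths must be >= 4")


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int = 1
    groups: tuple[GroupSpec, ...] = ()
    panel: PanelSpec = field(default_factory=PanelSpec)
    embeddings_per_record: tuple[int, int] = (1, 3)
    mutation_rate: float = 0.0
    n_duplicates: int = 3
    n_ambiguous: int = 2
    n_partial: int = 2
    partial_length: int = 40

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        for n in (self.n_duplicates, self.n_ambiguous, self.n_partial):
            if n < 0:
                raise ValueError("corruption counts must be >= 0")


@dataclass
class GroundTruthRecord:
    accession: str
    group: str
    corruption: str  # clean | duplicate | ambiguous | partial
    embedded: tuple[tuple[str, int, int], ...]
    m: int
    density: float
    coverage_pct: float


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    records: list[SequenceRecord]
    truth: list[GroundTruthRecord]
    panel: MotifPanel
    templates: list[GroupTemplate]
    masters: dict[str, SequenceRecord]

    @property
    def clean_records(self) -> list[SequenceRecord]:
        clean = {t.accession for t in self.truth if t.corruption == "clean"}
        return [r for r in self.records if r.accession in clean]

    def groups_of(self) -> dict[str, str]:
        return {t.accession: t.group for t in self.truth}


# ---------------------------------------------------------------------------
# independent brute-force oracle

def oracle_metrics(sequence: str, panel: MotifPanel, accession: str = "") -> MotifMetrics:
    """Per-residue boolean-marking oracle for the three motif statistics.

    Deliberately naive (O(L x |panel| x motif length)) and independent
    of the interval-union implementation; used for ground truth and in
    oracle-equivalence tests.
    """
    L = len(sequence)
    marked = [False] * L
    present: set[str] = set()
    for motif in panel:
        w = len(motif)
        for i in range(L - w + 1):
            if sequence[i : i + w] == motif:
                present.add(motif)
                for j in range(i, i + w):
                    marked[j] = True
    m = len(present)
    return MotifMetrics(
        accession=accession,
        length=L,
        unique_count=m,
        density=m / L,
        density_per100=round(100.0 * m / L, 4),
        coverage_percent=round(100.0 * sum(marked) / L, 2),
    )


# ---------------------------------------------------------------------------
# building blocks

def _background(rng: np.random.Generator, n: int, q: float = 0.35, p: float = 0.15) -> str:
    probs = np.full(len(BACKGROUND_ALPHABET), (1.0 - q - p) / (len(BACKGROUND_ALPHABET) - 2))
    probs[BACKGROUND_ALPHABET.index("Q")] = q
    probs[BACKGROUND_ALPHABET.index("P")] = p
    return "".join(rng.choice(BACKGROUND_ALPHABET, size=n, p=probs))


def _signal(rng: np.random.Generator, n: int = 20) -> str:
    return "M" + "".join(rng.choice(SIGNAL_ALPHABET, size=n - 1))


def _realize_unit(rng: np.random.Generator, pattern: RepeatPattern, spacer: int = 5) -> str:
    if pattern.is_literal:
        core = pattern.prefix
    else:
        q = int(rng.integers(pattern.q_run_min, pattern.q_run_max + 1))
        core = pattern.prefix + "Q" * q
    return core + _background(rng, spacer)


def _cterm(rng: np.random.Generator, length: int, n_cys: int) -> str:
    body = list(_background(rng, length))
    if n_cys:
        offsets = sorted(rng.choice(np.arange(2, length - 2), size=n_cys, replace=False))
        for off in offsets:
            body[off] = "C"
    return "".join(body)


_DEFAULT_GROUP_PLAN: tuple[tuple[str, int, RepeatPattern, int], ...] = (
    # (name, n_records, defining repeat pattern, skeleton cysteines)
    ("alpha", 6, RepeatPattern("QPQPFP"), 8),
    ("gamma", 5, RepeatPattern("QPQQPFP"), 8),
    ("omega", 5, RepeatPattern("PQQPF"), 0),
    ("hmw_gs", 4, RepeatPattern("PGQGQQ"), 4),
    ("avenin_A", 5, RepeatPattern("PFM", 1, 5), 9),
    ("avenin_B", 5, RepeatPattern("MLL", 3, 6), 8),
)


def toy_glupro_spec(seed: int = 1, mutation_rate: float = 0.0) -> SyntheticSpec:
    """The default repository fixture: 6 groups, 30 clean sequences, a
    25-motif panel with 20% nested fragments, plus 3 duplicate, 2
    ambiguous and 2 partial corrupted records."""
    rng = np.random.default_rng(seed)
    groups = []
    for name, n_rec, pattern, n_cys in _DEFAULT_GROUP_PLAN:
        groups.append(
            GroupSpec(
                name=name,
                n_records=n_rec,
                signal=_signal(rng),
                nterm=_background(rng, 30),
                repeat_unit=_realize_unit(rng, pattern),
                repeat_count_range=(3, 9),
                cterm=_cterm(rng, 60, n_cys),
                patterns=(pattern,),
            )
        )
    return SyntheticSpec(seed=seed, groups=tuple(groups), mutation_rate=mutation_rate)


def _make_panel(rng: np.random.Generator, spec: PanelSpec) -> MotifPanel:
    lo, hi = spec.length_range
    n_nested = int(round(spec.n_motifs * spec.nested_fraction))
    motifs: list[str] = []
    seen: set[str] = set()
    while len(motifs) < spec.n_motifs - n_nested:
        m = _background(rng, int(rng.integers(lo, hi + 1)))
        if m not in seen:
            motifs.append(m)
            seen.add(m)
    bases = list(motifs)
    while len(motifs) < spec.n_motifs:
        base = bases[int(rng.integers(len(bases)))]
        if len(base) <= 4:
            continue
        w = int(rng.integers(4, len(base)))
        start = int(rng.integers(0, len(base) - w + 1))
        frag = base[start : start + w]
        if frag not in seen:
            motifs.append(frag)
            seen.add(frag)
    return MotifPanel(motifs, name="synthetic-panel",
                      source_note="generated coeliac-toxic-motif stand-in panel")


def _assemble(rng: np.random.Generator, g: GroupSpec, k: int) -> str:
    return g.signal + g.nterm + g.repeat_unit * k + g.cterm


def _embed_motifs(
    rng: np.random.Generator,
    sequence: str,
    region: tuple[int, int],
    panel: MotifPanel,
    n_embed: int,
) -> tuple[str, list[tuple[str, int, int]]]:
    """Splice ``n_embed`` distinct panel motifs into ``region`` (0-based
    half-open) without overlapping one another."""
    lo, hi = region
    chosen = [
        str(m)
        for m in rng.choice(panel.motifs, size=min(n_embed, len(panel)), replace=False)
    ]
    spans: list[tuple[int, int]] = []  # 0-based half-open
    placed: list[tuple[str, int, int]] = []
    seq = sequence
    for motif in chosen:
        if len(motif) > hi - lo:
            raise ValueError(f"motif {motif!r} longer than the embedding region")
        for _ in range(60):
            start = int(rng.integers(lo, hi - len(motif) + 1))
            stop = start + len(motif)
            if all(stop <= s or start >= e for s, e in spans):
                seq = seq[:start] + motif + seq[stop:]
                spans.append((start, stop))
                placed.append((motif, start + 1, stop))
                break
    placed.sort(key=lambda t: t[1])
    return seq, placed


def _mutate(
    rng: np.random.Generator,
    sequence: str,
    rate: float,
    protected: set[int],
) -> str:
    """i.i.d. point substitutions outside protected positions; never
    introduces or destroys a cysteine."""
    if rate == 0.0:
        return sequence
    body = list(sequence)
    for i in range(len(body)):
        if i in protected or body[i] == "C":
            continue
        if rng.random() < rate:
            repl = body[i]
            while repl == body[i]:
                repl = str(rng.choice(BACKGROUND_ALPHABET))
            body[i] = repl
    return "".join(body)


# ---------------------------------------------------------------------------
# generation

def generate(spec: SyntheticSpec | None = None) -> SyntheticDataset:
    """Generate the full dataset: FASTA records, ground truth, motif
    panel, classification templates and master sequences.

    Pure function of ``spec`` (including its seed): the same spec yields
    byte-identical output.
    """
    spec = spec or toy_glupro_spec()
    if not spec.groups:
        spec = toy_glupro_spec(spec.seed, spec.mutation_rate)
    rng = np.random.default_rng(spec.seed)

    panel = _make_panel(rng, spec.panel)

    records: list[SequenceRecord] = []
    truth: list[GroundTruthRecord] = []
    templates: list[GroupTemplate] = []
    masters: dict[str, SequenceRecord] = {}
    used_sequences: set[str] = set()

    for g in spec.groups:
        gtag = g.name.upper().replace("_", "")
        master_acc = f"MST{gtag}"
        k_mid = (g.repeat_count_range[0] + g.repeat_count_range[1]) // 2
        master_seq = _assemble(rng, g, k_mid)
        masters[master_acc] = SequenceRecord(
            accession=master_acc,
            source=Source.other,
            description=f"synthetic {g.name} master",
            sequence=master_seq,
            signal_len=len(g.signal),
        )
        templates.append(
            GroupTemplate(
                group_name=g.name,
                repeat_patterns=g.patterns,
                expected_cys=g.n_cys,
                master_accessions=(master_acc,),
            )
        )

        for j in range(g.n_records):
            accession = f"SYN{gtag}{j + 1:02d}"
            for _attempt in range(40):
                k = int(rng.integers(*g.repeat_count_range, endpoint=True))
                seq = _assemble(rng, g, k)
                region = (len(g.signal) + len(g.nterm), len(seq) - len(g.cterm))
                n_embed = int(rng.integers(*spec.embeddings_per_record, endpoint=True))
                seq, placed = _embed_motifs(rng, seq, region, panel, n_embed)
                protected = {0}
                for _, s1, e1 in placed:
                    protected.update(range(s1 - 1, e1))
                seq = _mutate(rng, seq, spec.mutation_rate, protected)
                if seq not in used_sequences:
                    break
            used_sequences.add(seq)
            om = oracle_metrics(seq, panel, accession)
            records.append(
                SequenceRecord(
                    accession=accession,
                    source=Source.uniprot_sp,
                    description=f"synthetic {g.name} prolamin",
                    species="Synthetica cerealis",
                    sequence=seq,
                    signal_len=len(g.signal),
                )
            )
            truth.append(
                GroundTruthRecord(
                    accession=accession,
                    group=g.name,
                    corruption="clean",
                    embedded=tuple(placed),
                    m=om.unique_count,
                    density=om.density,
                    coverage_pct=om.coverage_percent,
                )
            )

    clean = list(records)

    # corrupted extras: duplicates (same sequence, NCBI source), ambiguous
    # (injected X), partials (truncated + "(Fragment)" keyword)
    dup_sources = rng.choice(len(clean), size=min(spec.n_duplicates, len(clean)),
                             replace=False)
    for i, src_idx in enumerate(dup_sources):
        src = clean[int(src_idx)]
        acc = f"DUPNC{i + 1}.1"
        records.append(
            SequenceRecord(
                accession=acc,
                source=Source.ncbi,
                description=f"re-deposited copy of {src.accession}",
                sequence=src.sequence,
            )
        )
        truth.append(GroundTruthRecord(acc, _group_of(truth, src.accession),
                                       "duplicate", (), 0, 0.0, 0.0))

    for i in range(spec.n_ambiguous):
        g = spec.groups[int(rng.integers(len(spec.groups)))]
        while True:
            seq = _assemble(rng, g, int(rng.integers(*g.repeat_count_range, endpoint=True)))
            pos = int(rng.integers(len(g.signal), len(seq) - len(g.cterm)))
            seq = seq[:pos] + "X" + seq[pos + 1 :]
            if seq not in used_sequences:
                break
        used_sequences.add(seq)
        acc = f"AMBIG{i + 1}"
        records.append(
            SequenceRecord(
                accession=acc,
                source=Source.uniprot_tr,
                description=f"synthetic {g.name} prolamin, low-quality read",
                sequence=seq,
            )
        )
        truth.append(GroundTruthRecord(acc, g.name, "ambiguous", (), 0, 0.0, 0.0))

    part_sources = rng.choice(len(clean), size=min(spec.n_partial, len(clean)),
                              replace=False)
    for i, src_idx in enumerate(part_sources):
        src = clean[int(src_idx)]
        # staggered lengths: records of one group share their N-terminal
        # prefix, so equal-length truncations could collide as duplicates
        seq = src.sequence[: spec.partial_length - i]
        acc = f"PART{i + 1}"
        records.append(
            SequenceRecord(
                accession=acc,
                source=Source.uniprot_tr,
                description=f"synthetic prolamin (Fragment) of {src.accession}",
                sequence=seq,
            )
        )
        truth.append(GroundTruthRecord(acc, _group_of(truth, src.accession),
                                       "partial", (), 0, 0.0, 0.0))

    return SyntheticDataset(
        spec=spec, records=records, truth=truth, panel=panel,
        templates=templates, masters=masters,
    )


def _group_of(truth: Sequence[GroundTruthRecord], accession: str) -> str:
    return next(t.group for t in truth if t.accession == accession)


# ---------------------------------------------------------------------------
# serialization

def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Emit FASTA, panel, masters FASTA, templates JSON and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "sequences.fasta",
        "panel": out / "motifs.txt",
        "masters": out / "masters.fasta",
        "templates": out / "templates.json",
        "truth": out / "ground_truth.tsv",
    }
    write_fasta(dataset.records, paths["fasta"])
    write_panel(dataset.panel, paths["panel"])
    write_fasta(dataset.masters.values(), paths["masters"])
    paths["templates"].write_text(json.dumps(
        [
            {
                "group_name": t.group_name,
                "expected_cys": t.expected_cys,
                "master_accessions": list(t.master_accessions),
                "repeat_patterns": [
                    {"prefix": p.prefix, "q_run_min": p.q_run_min,
                     "q_run_max": p.q_run_max}
                    for p in t.repeat_patterns
                ],
            }
            for t in dataset.templates
        ],
        indent=2,
    ) + "\n")
    with open(paths["truth"], "w") as fh:
        fh.write("accession\tgroup\tcorruption\tembedded\tm\tdensity\tcoverage_pct\n")
        for t in dataset.truth:
            emb = ";".join(f"{m}@{s}-{e}" for m, s, e in t.embedded)
            fh.write(f"{t.accession}\t{t.group}\t{t.corruption}\t{emb}\t"
                     f"{t.m}\t{t.density:.6f}\t{t.coverage_pct:.2f}\n")
    return paths


def load_templates(path: str | Path) -> list[GroupTemplate]:
    """Read a templates JSON file (the schema written by write_dataset)."""
    data = json.loads(Path(path).read_text())
    return [
        GroupTemplate(
            group_name=t["group_name"],
            expected_cys=t["expected_cys"],
            master_accessions=tuple(t["master_accessions"]),
            repeat_patterns=tuple(
                RepeatPattern(p["prefix"], p["q_run_min"], p["q_run_max"])
                for p in t["repeat_patterns"]
            ),
        )
        for t in data
    ]
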