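"""Coeliac-toxic-motif mapping statistics.

A motif panel is a list of short peptides (T-cell epitope cores and
related fragments, in real use the ~1,013-peptide coeliac-disease panel
of AllergenOnline).  Each motif is matched against each protein as an
exact, case-sensitive substring — overlapping occurrences and motifs
that are fragments of other motifs all count.  Three statistics are
reported per sequence:

* ``m`` — the number of *distinct* panel motifs present at least once
  (a motif occurring five times still counts once; nested fragments
  count separately),
* density — ``m / L`` motifs per residue (a per-100-residue column is
  emitted alongside for readability),
* coverage — percent of residues lying under the union of all motif
  hit intervals.

Matching is on the plain sequence; deamidation-aware (Q->E) variants
are out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import STANDARD_RESIDUES, SequenceRecord


@dataclass
class MotifPanel:
    """Ordered collection of unique motif peptides."""

    motifs: list[str]
    name: str = "panel"
    source_note: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique: list[str] = []
        for m in self.motifs:
            if not m:
                raise ValueError("motifs must be non-empty")
            bad = set(m) - STANDARD_RESIDUES
            if bad:
                raise ValueError(f"motif {m!r} contains non-standard residue {bad}")
            if m in seen:
                warnings.warn(f"duplicate motif {m!r} collapsed", stacklevel=2)
                continue
            seen.add(m)
            unique.append(m)
        self.motifs = unique

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)


def load_panel(path: str | Path, name: str | None = None) -> MotifPanel:
    """Read a plain-text panel: one peptide per line, '#' comments."""
    path = Path(path)
    motifs: list[str] = []
    for line in path.read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            motifs.append(line.upper())
    return MotifPanel(motifs, name=name or path.stem)


def write_panel(panel: MotifPanel, path: str | Path) -> None:
    Path(path).write_text("".join(f"{m}\n" for m in panel.motifs))


@dataclass(frozen=True)
class MotifHit:
    motif: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif):
            raise ValueError("hit span does not match motif length")


@dataclass
class MotifMetrics:
    accession: str
    length: int
    unique_count: int
    density: float
    density_per100: float
    coverage_percent: float


def find_hits(sequence: str, panel: MotifPanel) -> list[MotifHit]:
    """Every exact occurrence of every panel motif, overlapping included,
    sorted by (start, end)."""
    hits: list[MotifHit] = []
    for motif in panel:
        start = sequence.find(motif)
        while start != -1:
            hits.append(MotifHit(motif, start + 1, start + len(motif)))
            start = sequence.find(motif, start + 1)
    hits.sort(key=lambda h: (h.start, h.end))
    return hits


def _union_length(intervals: Iterable[tuple[int, int]]) -> int:
    total = 0
    cur_start = cur_end = None
    for s, e in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = s, e
        elif s <= cur_end + 1:
            cur_end = max(cur_end, e)
        else:
            total += cur_end - cur_start + 1
            cur_start, cur_end = s, e
    if cur_end is not None:
        total += cur_end - cur_start + 1
    return total


def motif_metrics(
    sequence: str, panel: MotifPanel, accession: str = ""
) -> MotifMetrics:
    """The three per-sequence statistics (unique count, density, coverage)."""
    hits = find_hits(sequence, panel)
    L = len(sequence)
    m = len({h.motif for h in hits})
    covered = _union_length((h.start, h.end) for h in hits)
    return MotifMetrics(
        accession=accession,
        length=L,
        unique_count=m,
        density=m / L,
        density_per100=round(100.0 * m / L, 4),
        coverage_percent=round(100.0 * covered / L, 2),
    )


def map_database(
    records: Sequence[SequenceRecord], panel: MotifPanel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Motif metrics for every record (input order) plus the full hit list.

    Returns ``(metrics, hits)`` DataFrames; deterministic.
    """
    metric_rows = []
    hit_rows = []
    for rec in records:
        mm = motif_metrics(rec.sequence, panel, accession=rec.accession)
        metric_rows.append(
            {
                "accession": mm.accession,
                "L": mm.length,
                "m": mm.unique_count,
                "density": mm.density,
                "density_per100": mm.density_per100,
                "coverage_pct": mm.coverage_percent,
            }
        )
        for h in find_hits(rec.sequence, panel):
            hit_rows.append(
                {"accession": rec.accession, "motif": h.motif,
                 "start": h.start, "end": h.end}
            )
    metrics = pd.DataFrame(
        metric_rows,
        columns=["accession", "L", "m", "density", "density_per100", "coverage_pct"],
    )
    hits = pd.DataFrame(hit_rows, columns=["accession", "motif", "start", "end"])
    return metrics, hits


STATISTICS = ("m", "density", "coverage_pct")


def summarize_by_group(
    metrics: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Five-number summary + mean per group for each statistic.

    ``groups`` maps accession -> group label and must cover every row.
    Quartiles use linear interpolation.  One row per (group, statistic)
    with columns min, q1, median, q3, max, mean, n.
    """
    unknown = set(metrics["accession"]) - set(groups)
    if unknown:
        raise ValueError(f"accessions without a group: {sorted(unknown)}")
    tagged = metrics.assign(group=metrics["accession"].map(groups))
    rows = []
    for group, sub in tagged.groupby("group", sort=False):
        for stat in STATISTICS:
            v = sub[stat].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "group": group, "statistic": stat, "n": len(v),
                    "min": v.min(), "q1": q1, "median": med, "q3": q3,
                    "max": v.max(), "mean": v.mean(),
                }
            )
    return pd.DataFrame(
        rows, columns=["group", "statistic", "n", "min", "q1", "median", "q3", "max", "mean"]
    )
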