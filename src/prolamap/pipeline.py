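"""End-to-end pipeline: curate -> classify -> tree -> map-motifs -> markers.

One config drives the whole chain; every stage writes TSV (or Newick /
FASTA) into the output directory and the run report keeps the stage
counts chained (classification input equals curation survivors, motif
rows equal classification rows) so the bookkeeping of a run is
auditable after the fact.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import classify as _classify
from . import curation as _curation
from . import motifmap as _motifmap
from . import phylo as _phylo
from . import digest as _digest
from .seqio import read_fasta, write_fasta
from .synthetic import load_templates
from .motifmap import load_panel

logger = logging.getLogger("prolamap")


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (exit code 2)."""


class DataError(ValueError):
    """Invalid input data encountered mid-run (exit code 3)."""


@dataclass
class RunConfig:
    input_fasta: Path
    out_dir: Path
    panel_path: Path | None = None
    templates_path: Path | None = None
    masters_path: Path | None = None
    curation: _curation.CurationConfig = field(default_factory=_curation.CurationConfig)
    alignment: _classify.AlignmentParams = field(default_factory=_classify.AlignmentParams)
    identity_floor: float = 30.0
    tree_cut_height: float | None = None
    marker_min_len: int = 5
    marker_min_mass: float = 750.0
    max_missed: int = 2
    ileq: bool = False
    fixed_cam: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            raw: dict[str, Any] = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        try:
            cfg = cls(
                input_fasta=Path(raw["input_fasta"]),
                out_dir=Path(raw["out_dir"]),
                panel_path=Path(raw["panel"]) if raw.get("panel") else None,
                templates_path=Path(raw["templates"]) if raw.get("templates") else None,
                masters_path=Path(raw["masters"]) if raw.get("masters") else None,
                identity_floor=float(raw.get("identity_floor", 30.0)),
                tree_cut_height=raw.get("tree_cut_height"),
                marker_min_len=int(raw.get("marker_min_len", 5)),
                marker_min_mass=float(raw.get("marker_min_mass", 750.0)),
                max_missed=int(raw.get("max_missed", 2)),
                ileq=bool(raw.get("ileq", False)),
                fixed_cam=bool(raw.get("fixed_cam", False)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"bad config field: {exc}") from exc
        if "curation" in raw:
            cfg.curation = _curation.CurationConfig(**raw["curation"])
        return cfg

    def validate(self) -> None:
        if not self.input_fasta.exists():
            raise ConfigError(f"input FASTA not found: {self.input_fasta}")
        for p in (self.panel_path, self.templates_path, self.masters_path):
            if p is not None and not p.exists():
                raise ConfigError(f"configured path not found: {p}")


@dataclass
class RunReport:
    stages: dict[str, dict[str, Any]] = field(default_factory=dict)
    curation_report: _curation.CurationReport | None = None

    def record(self, stage: str, **info: Any) -> None:
        self.stages[stage] = info

    def to_json(self) -> str:
        payload: dict[str, Any] = {"stages": self.stages}
        if self.curation_report is not None:
            cr = self.curation_report
            payload["curation"] = {
                "n_input": cr.n_input,
                "n_kept": cr.n_kept,
                "tallies": {k.value: v for k, v in cr.tallies.items()},
                "low_pq_warnings": cr.low_pq_warnings,
            }
        return json.dumps(payload, indent=2, default=str)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all configured stages in fixed order; deterministic given
    inputs and config.  Stages needing a missing optional input (panel,
    templates) are skipped and noted in the report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    def timed(stage: str):
        t0 = time.perf_counter()
        return lambda **info: report.record(
            stage, wall_seconds=round(time.perf_counter() - t0, 3), **info
        )

    # --- curate ---
    done = timed("curate")
    try:
        records = read_fasta(config.input_fasta)
    except ValueError as exc:
        raise DataError(str(exc)) from exc
    kept, curation_report = _curation.curate(records, config.curation)
    report.curation_report = curation_report
    write_fasta(kept, out / "curated.fasta")
    rep_rows = [
        {"accession": r.accession, "reason": r.reason.value, "detail": r.detail}
        for r in curation_report.removals
    ]
    pd.DataFrame(rep_rows, columns=["accession", "reason", "detail"]).to_csv(
        out / "curation_report.tsv", sep="\t", index=False
    )
    done(n_input=curation_report.n_input, n_kept=curation_report.n_kept)
    logger.info("curate: %d -> %d records", curation_report.n_input,
                curation_report.n_kept)

    # --- classify ---
    groups: dict[str, str] = {}
    if config.templates_path and config.masters_path:
        done = timed("classify")
        templates = load_templates(config.templates_path)
        master_records = {r.accession: r for r in read_fasta(config.masters_path)}
        results = _classify.classify_records(
            kept, templates, master_records, config.identity_floor, config.alignment
        )
        rows = [
            {
                "accession": r.accession, "group": r.assigned_group,
                "pq": r.pq_percent, "cys": r.cys_count,
                "n_repeat_hits": len(r.repeat_hits),
                "best_master": r.best_master[0], "identity": r.best_master[1],
            }
            for r in results
        ]
        pd.DataFrame(rows).to_csv(out / "classes.tsv", sep="\t", index=False)
        groups = {r.accession: r.assigned_group for r in results}
        done(n_classified=len(results))
    else:
        report.record("classify", skipped="no templates/masters configured")

    # --- tree ---
    if len(kept) >= 2:
        done = timed("tree")
        labels, ident = _classify.identity_matrix(kept, config.alignment)
        dm = _phylo.distances_from_identity(labels, np.array(ident))
        tree = _phylo.upgma(dm)
        (out / "tree.nwk").write_text(_phylo.to_newick(tree) + "\n")
        info: dict[str, Any] = {"n_leaves": len(labels)}
        if config.tree_cut_height is not None:
            clusters = _phylo.cut_clusters(tree, config.tree_cut_height)
            with open(out / "tree_clusters.tsv", "w") as fh:
                fh.write("cluster\taccession\n")
                for ci, cluster in enumerate(clusters, start=1):
                    for acc in cluster:
                        fh.write(f"{ci}\t{acc}\n")
            info["n_clusters"] = len(clusters)
        done(**info)
    else:
        report.record("tree", skipped="fewer than 2 curated records")

    # --- map-motifs ---
    panel = None
    if config.panel_path:
        done = timed("map_motifs")
        panel = load_panel(config.panel_path)
        metrics, hits = _motifmap.map_database(kept, panel)
        metrics.to_csv(out / "motif_metrics.tsv", sep="\t", index=False)
        hits.to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        if groups:
            summary = _motifmap.summarize_by_group(metrics, groups)
            summary.to_csv(out / "motif_summary.tsv", sep="\t", index=False)
        done(n_rows=len(metrics), n_hits=len(hits))
    else:
        report.record("map_motifs", skipped="no motif panel configured")

    # --- markers ---
    done = timed("markers")
    markers = _digest.select_markers(
        kept, panel=panel, min_len=config.marker_min_len,
        min_mass=config.marker_min_mass, max_missed=config.max_missed,
        ileq=config.ileq, fixed_cam=config.fixed_cam,
    )
    mrows = [
        {
            "accession": c.peptide.parent, "peptide": c.peptide.sequence,
            "start": c.peptide.start, "end": c.peptide.end,
            "missed": c.peptide.missed_cleavages,
            "mass": round(c.peptide.mono_mass, 5),
            "unique": c.unique, "parents": c.n_parent_proteins,
            "overlaps_motif": c.overlaps_motif,
        }
        for c in markers
    ]
    pd.DataFrame(
        mrows,
        columns=["accession", "peptide", "start", "end", "missed", "mass",
                 "unique", "parents", "overlaps_motif"],
    ).to_csv(out / "markers.tsv", sep="\t", index=False)
    done(n_markers=len(markers))

    (out / "run_report.json").write_text(report.to_json() + "\n")
    return report
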