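"""Differential-expression integration: DEG filtering and DELG reports.

The differential-expression table (a DESeq2-style export) is consumed as
given; genes passing ``|log2FC| >= 0.58 and p <= 0.05`` (both inclusive)
are differentially expressed genes (DEGs).  Strengthened looping genes
that are also DEGs are differentially expressed looping genes (DELGs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from loopdiff.errors import MalformedInputError, ValidationError
from loopdiff.loop_scoring import LoopingGeneTable, SLGResult, gene_vppm_table

DEFAULT_MIN_ABS_LFC = 0.58
DEFAULT_MAX_P = 0.05

# DESeq2 export column names, matched case-insensitively
_GENE_COLS = ("gene_id", "gene", "id", "row.names")
_LFC_COLS = ("log2foldchange", "log2fc", "lfc")
_P_COLS = ("pvalue", "p_value", "p")


@dataclass(frozen=True)
class DEGRecord:
    gene_id: str
    log2_fold_change: float
    p_value: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.log2_fold_change):
            raise ValidationError(f"{self.gene_id}: non-finite log2 fold change")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"{self.gene_id}: p-value outside [0, 1]")


def read_deg_table(path) -> list[DEGRecord]:
    """Read a DEG TSV with gene, log2 fold change and p-value columns."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    lower = {c.lower(): c for c in df.columns}

    def pick(candidates, what):
        for cand in candidates:
            if cand in lower:
                return lower[cand]
        raise MalformedInputError(f"{path}: no {what} column among {list(df.columns)}")

    gcol = pick(_GENE_COLS, "gene id")
    lcol = pick(_LFC_COLS, "log2 fold change")
    pcol = pick(_P_COLS, "p-value")
    return [
        DEGRecord(str(r[gcol]), float(r[lcol]), float(r[pcol]))
        for _, r in df.iterrows()
    ]


def filter_degs(
    records: list[DEGRecord],
    min_abs_lfc: float = DEFAULT_MIN_ABS_LFC,
    max_p: float = DEFAULT_MAX_P,
) -> set[str]:
    """Genes with |log2FC| >= ``min_abs_lfc`` and p <= ``max_p`` (inclusive)."""
    return {
        r.gene_id for r in records
        if abs(r.log2_fold_change) >= min_abs_lfc and r.p_value <= max_p
    }


@dataclass
class DELGReport:
    condition: str
    delg_ids: set[str]
    table: pd.DataFrame  # per-gene vppm_a, vppm_b, diff, score, lfc, p


def intersect_delgs(
    slg: SLGResult,
    degs: set[str],
    a: LoopingGeneTable | None = None,
    b: LoopingGeneTable | None = None,
    deg_records: list[DEGRecord] | None = None,
) -> tuple[DELGReport, DELGReport]:
    """Intersect each condition's SLG set with the DEG set.

    Returns one report per condition (A first).  The optional tables and
    DEG records populate the per-gene columns of the report.
    """
    va = gene_vppm_table(a) if a is not None else {}
    vb = gene_vppm_table(b) if b is not None else {}
    by_gene = {r.gene_id: r for r in deg_records} if deg_records else {}

    def build(condition: str, slg_ids: set[str]) -> DELGReport:
        ids = slg_ids & degs
        rows = []
        for g in sorted(ids):
            rec = by_gene.get(g)
            rows.append({
                "gene_id": g,
                "vppm_a": va.get(g, 0.0),
                "vppm_b": vb.get(g, 0.0),
                "diff": slg.diffs.get(g, 0.0),
                "score": slg.normalized_scores.get(g, 0.0),
                "lfc": rec.log2_fold_change if rec else np.nan,
                "p": rec.p_value if rec else np.nan,
            })
        cols = ["gene_id", "vppm_a", "vppm_b", "diff", "score", "lfc", "p"]
        return DELGReport(condition, ids, pd.DataFrame(rows, columns=cols))

    return build(slg.condition_a, slg.slg_a), build(slg.condition_b, slg.slg_b)


REPORT_SCHEMA_VERSION = 1


def build_run_report(
    parameters: dict | None = None,
    seed: int | None = None,
    tad_summary=None,
    loop_partition=None,
    slg: SLGResult | None = None,
    delg_a: DELGReport | None = None,
    delg_b: DELGReport | None = None,
    n_degs: int | None = None,
    version: str | None = None,
) -> dict:
    """Assemble one deterministic, JSON-serializable run summary.

    Sections for stages that did not run are zeroed, never omitted, so
    the schema is stable across partial pipelines.  No timestamps are
    recorded: identical inputs give byte-identical JSON.
    """
    from loopdiff import __version__

    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "tool_version": version or __version__,
        "seed": seed,
        "parameters": dict(sorted((parameters or {}).items())),
        "tads": {"n_events": 0, "counts": {}, "fractions": {},
                 "rc_fraction": 0.0, "dc_fraction": 0.0},
        "loops": {"unique_a": 0, "common": 0, "unique_b": 0},
        "slg": {"n_slg_a": 0, "n_slg_b": 0, "cutoff": None},
        "deg": {"n_degs": n_degs or 0},
        "delg": {"n_delg_a": 0, "n_delg_b": 0},
    }
    if tad_summary is not None:
        report["tads"] = {
            "n_events": tad_summary.n_events,
            "counts": dict(sorted(tad_summary.counts.items())),
            "fractions": dict(sorted(tad_summary.fractions.items())),
            "rc_fraction": tad_summary.rc_fraction,
            "dc_fraction": tad_summary.dc_fraction,
        }
    if loop_partition is not None:
        report["loops"] = {
            "unique_a": len(loop_partition.unique_a),
            "common": loop_partition.n_common,
            "unique_b": len(loop_partition.unique_b),
        }
    if slg is not None:
        report["slg"] = {"n_slg_a": len(slg.slg_a), "n_slg_b": len(slg.slg_b),
                         "cutoff": slg.cutoff}
    if delg_a is not None or delg_b is not None:
        report["delg"] = {
            "n_delg_a": len(delg_a.delg_ids) if delg_a else 0,
            "n_delg_b": len(delg_b.delg_ids) if delg_b else 0,
        }
    return report


def validate_report(report: dict) -> None:
    """Check the fixed report schema; raises on violation."""
    required = {"schema_version", "tool_version", "seed", "parameters",
                "tads", "loops", "slg", "deg", "delg"}
    missing = required - set(report)
    if missing:
        raise ValidationError(f"report missing sections: {sorted(missing)}")
    if report["schema_version"] != REPORT_SCHEMA_VERSION:
        raise ValidationError("unknown report schema version")
    for key, fields in [("tads", {"n_events", "counts", "fractions", "rc_fraction", "dc_fraction"}),
                        ("loops", {"unique_a", "common", "unique_b"}),
                        ("slg", {"n_slg_a", "n_slg_b", "cutoff"}),
                        ("deg", {"n_degs"}),
                        ("delg", {"n_delg_a", "n_delg_b"})]:
        if set(report[key]) != fields:
            raise ValidationError(f"report section {key!r} has fields {sorted(report[key])}")
    json.dumps(report)  # must be serializable


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
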