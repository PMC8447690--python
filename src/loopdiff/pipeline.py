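"""End-to-end pipeline driver and configuration.

The configuration carries every analysis parameter with its standard
default (300 kb conserve bound, -4 kb/+1 kb promoter, 10-100 kb distal,
FDR <= 0.1 SIF filter, 0.15 SLG cutoff, |log2FC| >= 0.58 and p <= 0.05
DEG filter) plus the synthetic-scenario knobs.  ``run_all`` generates the
scenario, re-reads every emitted file through the public parsers, runs
each stage, and writes a deterministic JSON report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from loopdiff import expression, hic_matrix, loop_scoring, tad_changes
from loopdiff.errors import ParameterError
from loopdiff.synth import ScenarioSpec, write_scenario

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "loopdiff_out"
    # TAD-change classification
    conserve_max_delta: int = 300_000
    identity_tolerance: int = 40_000
    min_overlap: int = 1
    # matrix normalization
    smoothing_fraction: float = 0.3
    pseudocount: float = 1.0
    # loop scoring
    max_fdr: float = 0.1
    slg_cutoff: float = 0.15
    # DEG filter
    min_abs_lfc: float = 0.58
    max_p: float = 0.05
    # synthetic scenario overrides (ScenarioSpec field -> value)
    scenario: dict = field(default_factory=dict)

    _SCHEMA = {
        "seed": int, "outdir": str,
        "conserve_max_delta": int, "identity_tolerance": int, "min_overlap": int,
        "smoothing_fraction": float, "pseudocount": float,
        "max_fdr": float, "slg_cutoff": float,
        "min_abs_lfc": float, "max_p": float,
        "scenario": dict,
    }

    def validate(self) -> None:
        errors = []
        if self.conserve_max_delta <= 0:
            errors.append("conserve_max_delta must be positive")
        if self.identity_tolerance < 0:
            errors.append("identity_tolerance must be >= 0")
        if not 0.0 < self.smoothing_fraction <= 1.0:
            errors.append("smoothing_fraction must be in (0, 1]")
        if not 0.0 <= self.max_fdr <= 1.0:
            errors.append("max_fdr must be in [0, 1]")
        if not 0.0 <= self.slg_cutoff <= 1.0:
            errors.append("slg_cutoff must be in [0, 1]")
        if self.min_abs_lfc < 0:
            errors.append("min_abs_lfc must be >= 0")
        if not 0.0 <= self.max_p <= 1.0:
            errors.append("max_p must be in [0, 1]")
        unknown = set(self.scenario) - {f.name for f in dataclasses.fields(ScenarioSpec)}
        if unknown:
            errors.append(f"unknown scenario keys: {sorted(unknown)}")
        if errors:
            raise ParameterError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls._SCHEMA)
        if unknown:
            raise ParameterError(f"invalid config: unknown keys {sorted(unknown)}")
        for key, typ in cls._SCHEMA.items():
            if key in raw and typ is float and isinstance(raw[key], int):
                raw[key] = float(raw[key])
            if key in raw and not isinstance(raw[key], typ):
                raise ParameterError(
                    f"invalid config: {key} must be {typ.__name__}, "
                    f"got {type(raw[key]).__name__}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def scenario_spec(self) -> ScenarioSpec:
        return ScenarioSpec(**{"seed": self.seed, **self.scenario})

    def params_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("scenario")
        d.pop("outdir")
        return d


def run_all(config: PipelineConfig, outdir=None) -> dict:
    """Simulate the configured scenario and run every analysis stage.

    Every stage consumes the files the generator wrote (not in-memory
    objects), so the run also exercises all parsers.  Returns the report
    dict; writes ``report.json`` and per-stage tables under ``outdir``.
    """
    config.validate()
    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    scen_dir = out / "scenario"
    spec = config.scenario_spec()
    truth = write_scenario(spec, scen_dir)
    logger.info("scenario written to %s", scen_dir)

    # --- matrix normalization diagnostics ---------------------------------
    mat_a = hic_matrix.read_hicpro_matrix(
        scen_dir / "condA_abs.bed", scen_dir / "condA.matrix", scen_dir / "condA.stats")
    mat_b = hic_matrix.read_hicpro_matrix(
        scen_dir / "condB_abs.bed", scen_dir / "condB.matrix", scen_dir / "condB.stats")
    curve = hic_matrix.fit_lowess_bias(
        mat_a, mat_b, smoothing_fraction=config.smoothing_fraction,
        pseudocount=config.pseudocount)
    corrected = hic_matrix.apply_bias_correction(mat_a, curve)
    hic_matrix.write_hicpro_matrix(
        corrected, out / "condA_corrected_abs.bed", out / "condA_corrected.matrix")

    # --- TAD changes ------------------------------------------------------
    dom_a = tad_changes.read_topdom(scen_dir / "condA_domains.tsv", mat_a.layout)
    dom_b = tad_changes.read_topdom(scen_dir / "condB_domains.tsv", mat_b.layout)
    events = tad_changes.classify_changes(
        dom_a, dom_b,
        conserve_max_delta=config.conserve_max_delta,
        identity_tolerance=config.identity_tolerance,
        min_overlap=config.min_overlap)
    summary = tad_changes.summarize_changes(events)
    tad_changes.events_to_frame(events).to_csv(out / "tad_events.tsv", sep="\t", index=False)
    (out / "tad_summary.json").write_text(summary.to_json())

    # --- loops and SLGs ---------------------------------------------------
    genes = loop_scoring.read_genes_bed6(scen_dir / "genes.bed")
    sifs_a = loop_scoring.filter_sifs(
        loop_scoring.read_sifs(scen_dir / "condA_sifs.tsv"), config.max_fdr)
    sifs_b = loop_scoring.filter_sifs(
        loop_scoring.read_sifs(scen_dir / "condB_sifs.tsv"), config.max_fdr)
    table_a = loop_scoring.call_p1d1_loops(
        sifs_a, genes, int(mat_a.total_valid_pairs), sample_id="condA")
    table_b = loop_scoring.call_p1d1_loops(
        sifs_b, genes, int(mat_b.total_valid_pairs), sample_id="condB")
    loop_scoring.loops_to_bedpe(table_a).to_csv(out / "condA_loops.bedpe", sep="\t", index=False)
    loop_scoring.loops_to_bedpe(table_b).to_csv(out / "condB_loops.bedpe", sep="\t", index=False)
    partition = loop_scoring.partition_loops(table_a, table_b)
    slg = loop_scoring.strengthened_looping_genes(table_a, table_b, cutoff=config.slg_cutoff)
    slg.to_frame().to_csv(out / "slg.tsv", sep="\t", index=False)

    # --- DEG / DELG -------------------------------------------------------
    deg_records = expression.read_deg_table(scen_dir / "deg.tsv")
    degs = expression.filter_degs(deg_records, config.min_abs_lfc, config.max_p)
    delg_a, delg_b = expression.intersect_delgs(
        slg, degs, a=table_a, b=table_b, deg_records=deg_records)
    delg_a.table.to_csv(out / "delg_a.tsv", sep="\t", index=False)
    delg_b.table.to_csv(out / "delg_b.tsv", sep="\t", index=False)

    report = expression.build_run_report(
        parameters=config.params_dict(), seed=config.seed,
        tad_summary=summary, loop_partition=partition, slg=slg,
        delg_a=delg_a, delg_b=delg_b, n_degs=len(degs))
    expression.validate_report(report)
    (out / "report.json").write_text(expression.report_to_json(report))
    return report
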