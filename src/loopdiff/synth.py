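"""Synthetic two-condition Hi-C scenarios with known ground truth.

Every pipeline input can be generated here with its answer key: a genome
layout with annotated genes, two domain tilings related by a planted set
of TAD-change events, distance-decaying contact matrices with TAD-block
enrichment, SIF tables carrying planted promoter-distal loops of
controlled strength, and a differential-expression table with planted
effects.  The generators emit exactly the dialects the analysis modules
consume, so each planted object is recoverable by an independent parser.

The stated world is desk-scale: one 20 Mb chromosome at 40 kb bins,
~16 TADs of median size 800 kb separated by 400 kb spacers (wide enough
that every planted change event is unambiguous under the 300 kb
classification rules), 60 genes at >= 250 kb spacing, a library depth of
2e6 valid pairs, contact decay exponent 1.0 with 3x within-TAD
enrichment, 5% of genes loop-strengthened 5-fold in condition B, and 30%
of genes differentially expressed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from loopdiff.errors import ParameterError
from loopdiff.hic_matrix import ContactMatrix, GenomeLayout, write_hicpro_matrix
from loopdiff.tad_changes import ChangeEvent, DomainCall, DomainCallSet, write_topdom
from loopdiff.loop_scoring import (
    SIF,
    GeneRecord,
    distal_windows,
    make_sif,
    promoter_window,
    write_sifs,
)

# distinct child-stream ids so the five generators draw independently
_S_GENOME, _S_DOMAIN, _S_CONTACT, _S_SIF, _S_DEG = 11, 13, 17, 19, 23

GENE_MIN_SPACING = 250_000
_GENE_MARGIN = 150_000


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic two-condition scenario."""

    # genome layout
    n_chrom: int = 1
    chrom_length: int = 20_000_000
    bin_size: int = 40_000
    # TAD tiling
    tad_size_median: int = 800_000
    tad_size_sigma: float = 0.4
    spacer_bp: int = 400_000          # inter-TAD spacer; > conserve_max_delta
    gap_fraction: float = 0.7         # fraction of each spacer emitted as gap
    # planted change plan (counts per type; unlisted types default to 0;
    # TADs not consumed by the plan become no_change events)
    change_counts: dict = field(default_factory=lambda: {
        "conserve_expand": 1, "conserve_shrink": 1, "shift": 1,
        "split": 1, "fuse": 1, "neo": 1, "del": 1,
    })
    # contact model
    decay_alpha: float = 1.0
    tad_beta: float = 3.0
    depth: int = 2_000_000
    # genes and loops
    n_genes: int = 60
    loops_per_gene_lambda: float = 0.8   # loops per gene = 1 + Poisson(lambda)
    loop_strength_median: float = 100.0  # valid pairs per planted loop
    loop_strength_sigma: float = 0.35
    frac_strengthened: float = 0.05
    effect_size: float = 5.0
    # fraction of non-strengthened planted loops present in only one
    # condition (split evenly A-only/B-only); 0 keeps every loop shared so
    # the strengthened-gene truth set stays exact
    frac_condition_unique: float = 0.0
    n_decoys: int = 30
    # differential expression
    frac_de: float = 0.3
    de_lfc_scale: float = 0.6            # |lfc| = 0.58 + Exponential(scale)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gap_fraction", "frac_strengthened", "frac_de",
                     "frac_condition_unique"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.decay_alpha <= 0:
            raise ParameterError("decay_alpha must be positive")
        if self.tad_beta < 1:
            raise ParameterError("tad_beta must be >= 1")
        if self.depth <= 0:
            raise ParameterError("depth must be positive")

    def replace(self, **kw) -> "ScenarioSpec":
        return dataclasses.replace(self, **kw)

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            tuple((f"chr{i + 1}", self.chrom_length) for i in range(self.n_chrom)),
            self.bin_size,
        )


@dataclass
class GroundTruth:
    """Answer key for one scenario."""

    domains_a: DomainCallSet | None = None
    domains_b: DomainCallSet | None = None
    events: list[ChangeEvent] = field(default_factory=list)
    loops_a: list[dict] = field(default_factory=list)
    loops_b: list[dict] = field(default_factory=list)
    strengthened_genes: set[str] = field(default_factory=set)
    deg_genes: set[str] = field(default_factory=set)

    def event_type_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for e in self.events:
            out[e.change_type] = out.get(e.change_type, 0) + 1
        return out


def _rng(spec: ScenarioSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


# ---------------------------------------------------------------------------
# Genome and genes
# ---------------------------------------------------------------------------

def simulate_genome(spec: ScenarioSpec) -> tuple[GenomeLayout, list[GeneRecord]]:
    """Place genes uniformly with >= 250 kb spacing on both strands.

    The spacing guarantees that promoter and distal windows of distinct
    genes never overlap and leaves a window-free zone between consecutive
    genes for decoy anchors.
    """
    layout = spec.layout()
    rng = _rng(spec, _S_GENOME)
    per_chrom = [spec.n_genes // spec.n_chrom] * spec.n_chrom
    for i in range(spec.n_genes % spec.n_chrom):
        per_chrom[i] += 1
    genes: list[GeneRecord] = []
    gid = 0
    for (chrom, length), n in zip(layout.chromosomes, per_chrom):
        if n == 0:
            continue
        usable = length - 2 * _GENE_MARGIN - (n - 1) * GENE_MIN_SPACING
        if usable < 0:
            raise ParameterError(
                f"{n} genes at {GENE_MIN_SPACING} bp spacing do not fit on "
                f"{chrom} ({length} bp)")
        offsets = np.sort(rng.uniform(0, usable, size=n))
        for k in range(n):
            tss = int(_GENE_MARGIN + offsets[k] + k * GENE_MIN_SPACING)
            strand = "+" if rng.random() < 0.5 else "-"
            gid += 1
            genes.append(GeneRecord(f"g{gid:04d}", chrom, tss, strand))
    return layout, genes


def write_genes_bed6(genes: list[GeneRecord], path) -> None:
    """BED6 with TSS = start on +, end-1 on - (2 kb nominal gene body)."""
    with open(path, "w") as fh:
        for g in genes:
            if g.strand == "+":
                start, end = g.tss, g.tss + 2000
            else:
                start, end = g.tss - 1999, g.tss + 1
            fh.write(f"{g.chrom}\t{start}\t{end}\t{g.gene_id}\t0\t{g.strand}\n")


# ---------------------------------------------------------------------------
# Domain pair with planted change events
# ---------------------------------------------------------------------------

def _tile_condition_a(spec: ScenarioSpec, rng: np.random.Generator):
    """Tile each chromosome as [spacer][TAD][spacer][TAD]...[spacer].

    Returns per-chromosome A calls plus the TAD list and the spacer
    interval following each TAD.
    """
    bs = spec.bin_size
    spacer_bins = max(3, spec.spacer_bp // bs)
    min_tad_bins = max(3, int(np.ceil(480_000 / bs)))
    max_tad_bins = max(min_tad_bins + 1, int(2_000_000 / bs))
    calls: dict[str, list[DomainCall]] = {}
    tads: list[tuple[str, int, int]] = []
    spacer_after: list[tuple[int, int]] = []

    def emit_spacer(chrom: str, start: int, end: int) -> None:
        # a 1-bin boundary on each side of a central gap keeps all three
        # TopDom states present in the tiling
        if end - start >= 3 * bs and rng.random() < spec.gap_fraction:
            calls[chrom].append(DomainCall(chrom, start, start + bs, "boundary"))
            calls[chrom].append(DomainCall(chrom, start + bs, end - bs, "gap"))
            calls[chrom].append(DomainCall(chrom, end - bs, end, "boundary"))
        else:
            calls[chrom].append(DomainCall(chrom, start, end, "gap"))

    for chrom, length in spec.layout().chromosomes:
        calls[chrom] = []
        pos = 0
        emit_spacer(chrom, 0, spacer_bins * bs)
        pos = spacer_bins * bs
        while True:
            size_bp = rng.lognormal(np.log(spec.tad_size_median), spec.tad_size_sigma)
            tad_bins = int(np.clip(round(size_bp / bs), min_tad_bins, max_tad_bins))
            end = pos + tad_bins * bs
            if end + spacer_bins * bs > length:
                break
            calls[chrom].append(DomainCall(chrom, pos, end, "tad"))
            tads.append((chrom, pos, end))
            emit_spacer(chrom, end, end + spacer_bins * bs)
            spacer_after.append((end, end + spacer_bins * bs))
            pos = end + spacer_bins * bs
        if pos < length:
            calls[chrom].append(DomainCall(chrom, pos, length, "gap"))
    return calls, tads, spacer_after


def simulate_domain_pair(
    spec: ScenarioSpec,
) -> tuple[DomainCallSet, DomainCallSet, list[ChangeEvent]]:
    """Generate condition-A/B domain tilings with a planted event list.

    Modifications stay within each TAD and its following spacer, and
    spacers exceed the 300 kb conserve bound, so every planted event is
    unambiguous to the classifier.  The truth list covers every TAD of
    both conditions (unconsumed TADs are no_change events).
    """
    bs = spec.bin_size
    if spec.spacer_bp <= 300_000:
        raise ParameterError("spacer_bp must exceed 300000 for unambiguous events")
    rng = _rng(spec, _S_DOMAIN)
    calls_a, tads, spacer_after = _tile_condition_a(spec, rng)

    plan: list[str] = []
    for t, n in sorted(spec.change_counts.items()):
        if t not in ("no_change", "conserve_expand", "conserve_shrink", "shift",
                     "split", "fuse", "neo", "del"):
            raise ParameterError(f"unknown change type in plan: {t!r}")
        plan.extend([t] * int(n))
    rng.shuffle(plan)

    needed = sum(2 if t == "fuse" else 1 for t in plan)
    if needed > len(tads):
        raise ParameterError(
            f"change plan consumes {needed} TADs but the scenario tiles only "
            f"{len(tads)}; enlarge chrom_length or shrink the plan")

    b_tads: list[tuple[str, int, int]] = []
    events: list[ChangeEvent] = []

    def tad_call(chrom, s, e):
        return DomainCall(chrom, s, e, "tad")

    i = 0
    for t in plan:
        chrom, s, e = tads[i]
        if t == "no_change":
            b_tads.append((chrom, s, e))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, s, e)], "no_change", 0, 0))
            i += 1
        elif t == "conserve_expand":
            e2 = e + 2 * bs  # +80 kb into the spacer: > tolerance, <= 300 kb
            b_tads.append((chrom, s, e2))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, s, e2)], "conserve_expand",
                                      e2 - e, e2 - e))
            i += 1
        elif t == "conserve_shrink":
            e2 = e - 2 * bs
            b_tads.append((chrom, s, e2))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, s, e2)], "conserve_shrink",
                                      e2 - e, e - e2))
            i += 1
        elif t == "shift":
            d = 9 * bs  # 360 kb > 300 kb, still overlapping (TADs >= 480 kb)
            b_tads.append((chrom, s + d, e + d))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, s + d, e + d)], "shift", 0, d))
            i += 1
        elif t == "split":
            mid = s + ((e - s) // (2 * bs)) * bs
            b1, b2 = (s, mid), (mid + bs, e)
            b_tads.extend([(chrom, *b1), (chrom, *b2)])
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, *b1), tad_call(chrom, *b2)],
                                      "split", -bs, 0))
            i += 1
        elif t == "fuse":
            # the fused pair must sit on one chromosome; skip a straddling
            # position by emitting the stranded TAD unchanged
            while i + 1 < len(tads) and tads[i + 1][0] != tads[i][0]:
                chrom, s, e = tads[i]
                b_tads.append((chrom, s, e))
                events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                          [tad_call(chrom, s, e)], "no_change", 0, 0))
                i += 1
            if i + 1 >= len(tads):
                raise ParameterError("no adjacent TAD pair left for a planted fuse")
            chrom, s, e = tads[i]
            chrom2, s2, e2 = tads[i + 1]
            b_tads.append((chrom, s, e2))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e), tad_call(chrom2, s2, e2)],
                                      [tad_call(chrom, s, e2)], "fuse",
                                      (e2 - s) - (e - s) - (e2 - s2), 0))
            i += 2
        elif t == "del":
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)], [], "del",
                                      -(e - s), 0))
            i += 1
        elif t == "neo":
            # the TAD itself stays untouched (no_change); the new TAD goes
            # in the spacer after it, one bin clear of both neighbours
            b_tads.append((chrom, s, e))
            events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                      [tad_call(chrom, s, e)], "no_change", 0, 0))
            sp_s, sp_e = spacer_after[i]
            ns, ne = sp_s + bs, sp_e - bs
            b_tads.append((chrom, ns, ne))
            events.append(ChangeEvent(chrom, [], [tad_call(chrom, ns, ne)], "neo",
                                      ne - ns, 0))
            i += 1
    for chrom, s, e in tads[i:]:
        b_tads.append((chrom, s, e))
        events.append(ChangeEvent(chrom, [tad_call(chrom, s, e)],
                                  [tad_call(chrom, s, e)], "no_change", 0, 0))

    # assemble the B tiling: TADs plus gap-filled complement
    calls_b: dict[str, list[DomainCall]] = {}
    layout = spec.layout()
    for chrom, length in layout.chromosomes:
        ivs = sorted([(s, e) for c, s, e in b_tads if c == chrom])
        out: list[DomainCall] = []
        pos = 0
        for s, e in ivs:
            if s > pos:
                out.append(DomainCall(chrom, pos, s, "gap"))
            out.append(DomainCall(chrom, s, e, "tad"))
            pos = e
        if pos < length:
            out.append(DomainCall(chrom, pos, length, "gap"))
        calls_b[chrom] = out
    return (DomainCallSet(layout, calls_a), DomainCallSet(layout, calls_b), events)


# ---------------------------------------------------------------------------
# Contact matrix
# ---------------------------------------------------------------------------

def simulate_contact_matrix(
    layout: GenomeLayout,
    domains: DomainCallSet | None,
    spec: ScenarioSpec,
    seed_offset: int = 0,
) -> ContactMatrix:
    """Poisson contact counts with power-law decay and TAD-block enrichment.

    The expected count at bin distance k is proportional to
    ``max(k, 1) ** -alpha``, multiplied by ``beta`` when both bins fall in
    the same TAD, scaled so the expected total equals ``spec.depth``.
    """
    rng = np.random.default_rng([spec.seed, _S_CONTACT, seed_offset])
    per_chrom = []
    total_weight = 0.0
    for ci, (chrom, length) in enumerate(layout.chromosomes):
        n = layout.n_bins(chrom)
        iu, ju = np.triu_indices(n)
        k = ju - iu
        w = np.maximum(k, 1).astype(np.float64) ** (-spec.decay_alpha)
        if domains is not None and spec.tad_beta != 1.0:
            tad_id = np.full(n, -1, dtype=np.int64)
            for t, call in enumerate(domains.tads(chrom)):
                b0 = call.start // layout.bin_size
                b1 = -(-call.end // layout.bin_size)
                tad_id[b0:b1] = t
            same = (tad_id[iu] >= 0) & (tad_id[iu] == tad_id[ju])
            w = np.where(same, w * spec.tad_beta, w)
        per_chrom.append((chrom, iu, ju, w))
        total_weight += w.sum()
    scale = spec.depth / total_weight
    offsets = layout.bin_offsets()
    b1_all, b2_all, c_all = [], [], []
    for chrom, iu, ju, w in per_chrom:
        counts = rng.poisson(scale * w)
        nz = counts > 0
        off = offsets[chrom]
        b1_all.append(iu[nz] + off)
        b2_all.append(ju[nz] + off)
        c_all.append(counts[nz].astype(np.float64))
    b1 = np.concatenate(b1_all) if b1_all else np.array([], dtype=np.int64)
    b2 = np.concatenate(b2_all) if b2_all else np.array([], dtype=np.int64)
    c = np.concatenate(c_all) if c_all else np.array([], dtype=np.float64)
    return ContactMatrix(layout, b1, b2, c, float(c.sum()))


# ---------------------------------------------------------------------------
# SIF tables with planted P1D1 loops
# ---------------------------------------------------------------------------

def _sub_interval(rng, window: tuple[int, int], width: int) -> tuple[int, int]:
    lo, hi = window
    width = min(width, hi - lo)
    start = int(rng.integers(lo, hi - width + 1))
    return start, start + width


def simulate_sif_tables(
    genes: list[GeneRecord],
    spec: ScenarioSpec,
) -> tuple[list[SIF], list[SIF], GroundTruth]:
    """Two-condition SIF lists with planted promoter-distal loops.

    Each planted loop anchors a 1 kb promoter fragment to a 2 kb distal
    fragment of the same gene; its valid-pair count is Poisson around a
    per-gene base strength, multiplied by the effect size in condition B
    for the planted strengthened genes.  Decoy SIFs with non-P1D1
    geometry (distal-distal, cross-gene promoter-promoter, window-free
    anchors) are mixed in with FDR ~ Uniform[0, 1]; planted loops get
    FDR ~ Uniform[0, 0.1].
    """
    rng = _rng(spec, _S_SIF)
    n_str = int(round(spec.frac_strengthened * len(genes)))
    strengthened = set(
        rng.choice([g.gene_id for g in genes], size=n_str, replace=False).tolist()
    ) if n_str else set()
    truth = GroundTruth(strengthened_genes=strengthened)
    sifs_a: list[SIF] = []
    sifs_b: list[SIF] = []
    for g in genes:
        prom = promoter_window(g, spec.chrom_length)
        up, down = distal_windows(g, spec.chrom_length)
        windows = [w for w in (up, down) if w[1] - w[0] >= 2000]
        n_loops = 1 + int(rng.poisson(spec.loops_per_gene_lambda))
        # the lognormal draw is the gene's total looping budget, divided
        # over its loops, so the planted effect size acts on the gene-level
        # VPPM regardless of loop count
        base = rng.lognormal(np.log(spec.loop_strength_median),
                             spec.loop_strength_sigma) / n_loops
        for _ in range(n_loops):
            p_anchor = _sub_interval(rng, prom, 1000)
            d_anchor = _sub_interval(rng, windows[int(rng.integers(len(windows)))], 2000)
            vp_a = max(1, int(rng.poisson(base)))
            mult = spec.effect_size if g.gene_id in strengthened else 1.0
            vp_b = max(1, int(rng.poisson(base * mult)))
            fdr_a = float(rng.uniform(0, 0.1))
            fdr_b = float(rng.uniform(0, 0.1))
            presence = "both"
            if spec.frac_condition_unique and g.gene_id not in strengthened:
                u = rng.random()
                if u < spec.frac_condition_unique / 2:
                    presence = "a_only"
                elif u < spec.frac_condition_unique:
                    presence = "b_only"
            rec = {"gene_id": g.gene_id, "promoter_anchor": list(p_anchor),
                   "distal_anchor": list(d_anchor)}
            if presence != "b_only":
                sifs_a.append(make_sif(g.chrom, *p_anchor, *d_anchor, vp_a, fdr_a))
                truth.loops_a.append({**rec, "valid_pairs": vp_a})
            if presence != "a_only":
                sifs_b.append(make_sif(g.chrom, *p_anchor, *d_anchor, vp_b, fdr_b))
                truth.loops_b.append({**rec, "valid_pairs": vp_b})
    # decoys: identical geometry in both conditions, independent counts
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.tss)
    kinds = ["distal_distal", "promoter_promoter", "window_free"]
    made = 0
    while made < spec.n_decoys:
        kind = kinds[made % len(kinds)]
        chrom = genes[int(rng.integers(len(genes)))].chrom
        lst = by_chrom[chrom]
        gi = int(rng.integers(len(lst)))
        g = lst[gi]
        up, down = distal_windows(g, spec.chrom_length)
        if kind == "distal_distal":
            if up[1] - up[0] < 2000 or down[1] - down[0] < 2000:
                continue
            a1, a2 = _sub_interval(rng, up, 2000), _sub_interval(rng, down, 2000)
        elif kind == "promoter_promoter":
            if gi + 1 >= len(lst):
                continue
            g2 = lst[gi + 1]
            a1 = _sub_interval(rng, promoter_window(g, spec.chrom_length), 1000)
            a2 = _sub_interval(rng, promoter_window(g2, spec.chrom_length), 1000)
        else:  # window_free: anchors in the >= 50 kb dead zone past +100 kb
            if gi + 1 >= len(lst):
                continue
            g2 = lst[gi + 1]
            zone = (g.tss + 105_000, min(g2.tss - 105_000, g.tss + 145_000))
            if zone[1] - zone[0] < 6000:
                continue
            a1 = _sub_interval(rng, (zone[0], zone[0] + 3000), 1000)
            a2 = _sub_interval(rng, (zone[1] - 3000, zone[1]), 1000)
        for sifs in (sifs_a, sifs_b):
            vp = max(1, int(rng.poisson(spec.loop_strength_median)))
            sifs.append(make_sif(chrom, *a1, *a2, vp, float(rng.uniform(0, 1))))
        made += 1
    return sifs_a, sifs_b, truth


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def simulate_deg_table(
    genes: list[GeneRecord],
    spec: ScenarioSpec,
) -> tuple[list[tuple[str, float, float]], set[str]]:
    """DEG rows (gene_id, log2FC, p) with a guaranteed-recoverable truth set.

    DE genes draw ``|lfc| = 0.58 + Exponential(scale)`` with random sign
    and ``p ~ Uniform[0, 0.05]``; null genes fail at least one criterion
    by construction (truncated |lfc| < 0.58, or p strictly above 0.05).
    """
    rng = _rng(spec, _S_DEG)
    n_de = int(round(spec.frac_de * len(genes)))
    de_ids = set(
        rng.choice([g.gene_id for g in genes], size=n_de, replace=False).tolist()
    ) if n_de else set()
    rows = []
    for g in genes:
        if g.gene_id in de_ids:
            lfc = (0.58 + rng.exponential(spec.de_lfc_scale)) * (1 if rng.random() < 0.5 else -1)
            p = float(rng.uniform(0, 0.05))
        elif rng.random() < 0.5:
            lfc = float(np.clip(rng.normal(0, 0.2), -0.5799, 0.5799))
            p = float(rng.uniform(0, 1))
        else:
            lfc = float(rng.normal(0, 0.8))
            p = float(np.nextafter(0.05, 1) + rng.uniform(0, 1) * (1 - 0.06))
        rows.append((g.gene_id, float(lfc), float(p)))
    return rows, de_ids


def write_deg_table(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tlog2FoldChange\tpvalue\n")
        for gid, lfc, p in rows:
            fh.write(f"{gid}\t{lfc!r}\t{p!r}\n")


# ---------------------------------------------------------------------------
# Full scenario emission
# ---------------------------------------------------------------------------

def write_scenario(spec: ScenarioSpec, outdir) -> GroundTruth:
    """Generate and write every pipeline input plus ``truth.json``.

    Emits HiC-Pro bins+matrix per condition, TopDom TSVs, SIF TSVs, BED6
    genes and a DEG TSV, in exactly the dialects the analysis modules
    read.  Byte-identical for identical specs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, genes = simulate_genome(spec)
    dom_a, dom_b, events = simulate_domain_pair(spec)
    mat_a = simulate_contact_matrix(layout, dom_a, spec, seed_offset=0)
    mat_b = simulate_contact_matrix(layout, dom_b, spec, seed_offset=1)
    sifs_a, sifs_b, truth = simulate_sif_tables(genes, spec)
    deg_rows, deg_ids = simulate_deg_table(genes, spec)
    truth.domains_a, truth.domains_b, truth.events = dom_a, dom_b, events
    truth.deg_genes = deg_ids

    write_hicpro_matrix(mat_a, outdir / "condA_abs.bed", outdir / "condA.matrix")
    write_hicpro_matrix(mat_b, outdir / "condB_abs.bed", outdir / "condB.matrix")
    for name, mat in (("condA", mat_a), ("condB", mat_b)):
        with open(outdir / f"{name}.stats", "w") as fh:
            fh.write(f"valid_interaction_rmdup={int(mat.total_valid_pairs)}\n")
    write_topdom(dom_a, outdir / "condA_domains.tsv")
    write_topdom(dom_b, outdir / "condB_domains.tsv")
    write_sifs(sifs_a, outdir / "condA_sifs.tsv")
    write_sifs(sifs_b, outdir / "condB_sifs.tsv")
    write_genes_bed6(genes, outdir / "genes.bed")
    write_deg_table(deg_rows, outdir / "deg.tsv")

    truth_doc = {
        "spec": dataclasses.asdict(spec),
        "event_types": sorted(e.change_type for e in events),
        "strengthened_genes": sorted(truth.strengthened_genes),
        "deg_genes": sorted(truth.deg_genes),
        "n_loops_a": len(truth.loops_a),
        "n_loops_b": len(truth.loops_b),
        "loops_a": truth.loops_a,
        "loops_b": truth.loops_b,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth_doc, fh, indent=2, sort_keys=True)
    return truth
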