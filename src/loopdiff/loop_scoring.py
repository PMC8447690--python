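"""Promoter-distal (P1D1) loop assignment and VPPM strength scoring.

A significant interaction fragment (SIF) becomes a P1D1 loop of gene *g*
when one anchor overlaps *g*'s promoter window (4 kb upstream to 1 kb
downstream of the 5'TSS, following transcription direction) and the other
anchor overlaps one of *g*'s distal windows (10-100 kb up- or downstream
of the 5'TSS).  Anchors touching any promoter are assigned promoter
priority: their distal roles are discarded.

Loop strength is measured in Valid Pairs Per Million::

    VPPM = valid pairs within the loop / total library valid pairs * 1e6

and summed per gene.  Strengthened looping genes (SLGs) between two
samples are called from the per-gene VPPM difference: z-scored, min-max
scaled to [0, 1] within the positive-difference subset, and thresholded
at 0.15 by default (symmetric on the negated negative subset for the
other condition), so a gene can be strengthened in at most one condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _stats

from loopdiff.errors import (
    DegenerateInputError,
    InsufficientDataError,
    MalformedInputError,
    ParameterError,
    ValidationError,
)

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 4_000
PROMOTER_DOWNSTREAM = 1_000
DISTAL_NEAR = 10_000
DISTAL_FAR = 100_000
DEFAULT_SLG_CUTOFF = 0.15
DEFAULT_MAX_FDR = 0.1


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene reduced to its 5'TSS and strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValidationError(f"{self.gene_id}: negative TSS")


@dataclass(frozen=True)
class SIF:
    """One significant interaction: two ordered anchors on one chromosome."""

    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]
    valid_pairs: int
    fdr: float

    def __post_init__(self) -> None:
        a1, a2 = self.anchor1, self.anchor2
        if a1[1] <= a1[0] or a2[1] <= a2[0]:
            raise ValidationError("anchor intervals must be non-empty")
        if a1[0] > a2[0]:
            raise ValidationError("anchors must be ordered by start")
        if a1[1] > a2[0]:
            raise ValidationError("anchors must not overlap")
        if self.valid_pairs <= 0:
            raise ValidationError(f"valid_pairs must be positive, got {self.valid_pairs}")
        if not 0.0 <= self.fdr <= 1.0:
            raise ValidationError(f"fdr must be in [0, 1], got {self.fdr}")


def make_sif(chrom, start1, end1, start2, end2, valid_pairs, fdr) -> SIF:
    """Build a SIF, ordering the anchors by start coordinate."""
    a1, a2 = (int(start1), int(end1)), (int(start2), int(end2))
    if a1[0] > a2[0]:
        a1, a2 = a2, a1
    return SIF(str(chrom), a1, a2, int(valid_pairs), float(fdr))


# ---------------------------------------------------------------------------
# SIF I/O and filtering
# ---------------------------------------------------------------------------

_SIF_COLS = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "valid_pairs", "fdr"]


def read_sifs(path) -> list[SIF]:
    """Read a SIF TSV (chrom1,start1,end1,chrom2,start2,end2,valid_pairs,fdr).

    Inter-chromosomal rows are dropped with a logged count; anchors are
    reordered by start where needed.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str, 3: str}, float_precision="round_trip")
    cols = [c.lower() for c in df.columns]
    if cols[: len(_SIF_COLS)] != _SIF_COLS:
        # headerless files are accepted too
        df = pd.read_csv(path, sep="\t", header=None, names=_SIF_COLS,
                         dtype={"chrom1": str, "chrom2": str},
                         float_precision="round_trip")
    out: list[SIF] = []
    n_inter = 0
    for row in df.itertuples(index=False):
        if str(row.chrom1) != str(row.chrom2):
            n_inter += 1
            continue
        out.append(make_sif(row.chrom1, row.start1, row.end1, row.start2, row.end2,
                            row.valid_pairs, row.fdr))
    if n_inter:
        logger.warning("dropped %d inter-chromosomal SIFs from %s", n_inter, path)
    return out


def write_sifs(sifs: list[SIF], path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SIF_COLS) + "\n")
        for s in sifs:
            fh.write(f"{s.chrom}\t{s.anchor1[0]}\t{s.anchor1[1]}\t{s.chrom}\t"
                     f"{s.anchor2[0]}\t{s.anchor2[1]}\t{s.valid_pairs}\t{s.fdr!r}\n")


def filter_sifs(sifs: list[SIF], max_fdr: float = DEFAULT_MAX_FDR) -> list[SIF]:
    """Keep SIFs with FDR <= ``max_fdr`` (inclusive), preserving order."""
    return [s for s in sifs if s.fdr <= max_fdr]


def read_genes_bed6(path, chrom_lengths: dict[str, int] | None = None) -> list[GeneRecord]:
    """Read gene annotation as 6-column BED; TSS = start on +, end-1 on -."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene_id", "score", "strand"],
                     dtype={"chrom": str, "gene_id": str, "strand": str})
    genes = []
    for row in df.itertuples(index=False):
        tss = int(row.start) if row.strand == "+" else int(row.end) - 1
        genes.append(GeneRecord(str(row.gene_id), str(row.chrom), tss, str(row.strand)))
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise MalformedInputError(f"{path}: duplicate gene ids")
    if chrom_lengths:
        for g in genes:
            if g.chrom in chrom_lengths and g.tss >= chrom_lengths[g.chrom]:
                raise ValidationError(f"{g.gene_id}: TSS beyond chromosome end")
    return genes


# ---------------------------------------------------------------------------
# Promoter / distal windows and anchor assignment
# ---------------------------------------------------------------------------

def promoter_window(gene: GeneRecord, chrom_length: int | None = None) -> tuple[int, int]:
    """Strand-aware promoter window: 4 kb upstream to 1 kb downstream of 5'TSS."""
    if gene.strand == "+":
        start, end = gene.tss - PROMOTER_UPSTREAM, gene.tss + PROMOTER_DOWNSTREAM
    else:
        start, end = gene.tss - PROMOTER_DOWNSTREAM, gene.tss + PROMOTER_UPSTREAM
    start = max(0, start)
    if chrom_length is not None:
        end = min(end, chrom_length)
    return start, end


def distal_windows(gene: GeneRecord, chrom_length: int | None = None) -> tuple[tuple[int, int], tuple[int, int]]:
    """Strand-aware distal windows: (upstream, downstream), each 10-100 kb
    from the 5'TSS, clipped to chromosome bounds (may be empty intervals)."""
    left = (gene.tss - DISTAL_FAR, gene.tss - DISTAL_NEAR)
    right = (gene.tss + DISTAL_NEAR, gene.tss + DISTAL_FAR)
    up, down = (left, right) if gene.strand == "+" else (right, left)

    def clip(iv):
        s, e = max(0, iv[0]), iv[1]
        if chrom_length is not None:
            e = min(e, chrom_length)
        return (s, max(s, e))

    return clip(up), clip(down)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return min(a[1], b[1]) - max(a[0], b[0]) >= 1


class GeneIndex:
    """Per-chromosome gene lookup with precomputed windows."""

    def __init__(self, genes: list[GeneRecord], chrom_lengths: dict[str, int] | None = None):
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValidationError("duplicate gene ids")
        self.by_chrom: dict[str, list[GeneRecord]] = {}
        self.windows: dict[str, tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
            cl = (chrom_lengths or {}).get(g.chrom)
            self.windows[g.gene_id] = (
                promoter_window(g, cl), *distal_windows(g, cl))


def assign_anchor(anchor: tuple[int, int], chrom: str, index: GeneIndex) -> set[tuple[str, str]]:
    """All (gene_id, role) pairs for one anchor, with promoter priority.

    A role needs at least 1 bp of window overlap.  If the anchor touches
    any promoter window, every distal role is discarded (the priority rule
    demotes distal, not competing promoters).
    """
    roles: set[tuple[str, str]] = set()
    for g in index.by_chrom.get(chrom, ()):
        prom, up, down = index.windows[g.gene_id]
        if _overlaps(anchor, prom):
            roles.add((g.gene_id, "promoter"))
        if _overlaps(anchor, up) or _overlaps(anchor, down):
            roles.add((g.gene_id, "distal"))
    if any(r == "promoter" for _, r in roles):
        roles = {(g, r) for g, r in roles if r == "promoter"}
    return roles


# ---------------------------------------------------------------------------
# P1D1 loop calling and gene-level VPPM
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class P1D1Loop:
    gene_id: str
    chrom: str
    promoter_anchor: tuple[int, int]
    distal_anchor: tuple[int, int]
    valid_pairs: int
    vppm: float


@dataclass
class LoopingGeneTable:
    """All P1D1 loops of one sample, grouped by gene."""

    sample_id: str
    total_valid_pairs: int
    loops: dict[str, list[P1D1Loop]]  # gene_id -> loops

    def gene_vppm(self, gene_id: str) -> float:
        return sum(l.vppm for l in self.loops.get(gene_id, ()))

    @property
    def gene_ids(self) -> set[str]:
        return set(self.loops)

    @property
    def n_loops(self) -> int:
        return sum(len(v) for v in self.loops.values())

    def all_loops(self) -> list[P1D1Loop]:
        return [l for g in sorted(self.loops) for l in self.loops[g]]


def call_p1d1_loops(
    sifs: list[SIF],
    genes: list[GeneRecord] | GeneIndex,
    total_valid_pairs: int,
    sample_id: str = "sample",
    chrom_lengths: dict[str, int] | None = None,
) -> LoopingGeneTable:
    """Assign FDR-filtered SIFs to genes as P1D1 loops and score them.

    For each SIF and each gene *g* with one anchor carrying role
    promoter(*g*) and the other distal(*g*), one loop is emitted with
    ``vppm = valid_pairs / total_valid_pairs * 1e6``.  Genes without
    loops are absent from the table.
    """
    if total_valid_pairs <= 0:
        raise ParameterError(f"total_valid_pairs must be positive, got {total_valid_pairs}")
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes, chrom_lengths)
    table: dict[str, list[P1D1Loop]] = {}
    for sif in sifs:
        r1 = assign_anchor(sif.anchor1, sif.chrom, index)
        r2 = assign_anchor(sif.anchor2, sif.chrom, index)
        genes1 = {g: r for g, r in r1}
        genes2 = {g: r for g, r in r2}
        for g in set(genes1) & set(genes2):
            roles = (genes1[g], genes2[g])
            if roles == ("promoter", "distal"):
                prom, dist = sif.anchor1, sif.anchor2
            elif roles == ("distal", "promoter"):
                prom, dist = sif.anchor2, sif.anchor1
            else:
                continue
            vppm = sif.valid_pairs / total_valid_pairs * 1e6
            table.setdefault(g, []).append(
                P1D1Loop(g, sif.chrom, prom, dist, sif.valid_pairs, vppm))
    return LoopingGeneTable(sample_id, int(total_valid_pairs), table)


def gene_vppm_table(table: LoopingGeneTable) -> dict[str, float]:
    """Per-gene looping strength: the sum of member-loop VPPMs."""
    return {g: sum(l.vppm for l in loops) for g, loops in table.loops.items()}


# ---------------------------------------------------------------------------
# Strengthened looping genes
# ---------------------------------------------------------------------------

@dataclass
class SLGResult:
    condition_a: str
    condition_b: str
    diffs: dict[str, float]              # gene -> VPPM_b - VPPM_a
    normalized_scores: dict[str, float]  # gene -> score in [0, 1] on its own sign side
    slg_b: set[str]
    slg_a: set[str]
    cutoff: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.diffs):
            side = "b" if g in self.slg_b else ("a" if g in self.slg_a else "")
            rows.append({"gene_id": g, "diff": self.diffs[g],
                         "score": self.normalized_scores.get(g, 0.0), "slg_in": side})
        return pd.DataFrame(rows, columns=["gene_id", "diff", "score", "slg_in"])


def _positive_side_scores(diffs: dict[str, float], zscores: dict[str, float]) -> dict[str, float]:
    """Min-max scale the z-scores of positive-diff genes to [0, 1]."""
    pos = {g: zscores[g] for g, d in diffs.items() if d > 0}
    if not pos:
        return {}
    zmin, zmax = min(pos.values()), max(pos.values())
    if zmax == zmin:
        return {g: 1.0 for g in pos}
    return {g: (z - zmin) / (zmax - zmin) for g, z in pos.items()}


def strengthened_looping_genes(
    a: LoopingGeneTable,
    b: LoopingGeneTable,
    cutoff: float = DEFAULT_SLG_CUTOFF,
    normalization: str = "minmax_of_z_pos_neg",
) -> SLGResult:
    """Call strengthened looping genes from the per-gene VPPM difference.

    Over the union of looping genes (a gene absent from one table has
    VPPM 0 there), ``diff = VPPM_b - VPPM_a`` is z-scored; for condition B
    the z-scores of positive diffs are min-max scaled to [0, 1] within
    that subset and genes scoring at or above the cutoff are returned.
    Condition-A SLGs apply the identical procedure to the negated diffs,
    so swapping the tables swaps the two sets exactly, and a gene can be
    strengthened in at most one condition.
    """
    if normalization not in ("minmax_of_z_pos_neg", "minmax_of_z_joint"):
        raise ParameterError(f"unknown normalization policy {normalization!r}")
    if not 0.0 <= cutoff <= 1.0:
        raise ParameterError(f"cutoff must be in [0, 1], got {cutoff}")
    va, vb = gene_vppm_table(a), gene_vppm_table(b)
    union = sorted(set(va) | set(vb))
    if len(union) < 3:
        raise InsufficientDataError("need at least 3 looping genes across both samples")
    diffs = {g: vb.get(g, 0.0) - va.get(g, 0.0) for g in union}
    arr = np.array([diffs[g] for g in union])
    sd = float(arr.std(ddof=0))
    if sd == 0.0:
        raise DegenerateInputError("zero variance of VPPM differences; no SLGs definable")
    mean = float(arr.mean())
    # Min-max scaling within a sign subset is invariant to any affine
    # transform of the diffs, so z-scoring jointly or per sign yields the
    # same scores; both policy names are accepted and share one code path.
    # The z-step still guards against a degenerate zero-variance input.
    z_all = {g: (diffs[g] - mean) / sd for g in union}
    zneg = {g: -z for g, z in z_all.items()}
    scores_b = _positive_side_scores(diffs, z_all)
    scores_a = _positive_side_scores({g: -d for g, d in diffs.items()}, zneg)
    slg_b = {g for g, s in scores_b.items() if s >= cutoff}
    slg_a = {g for g, s in scores_a.items() if s >= cutoff}
    normalized = dict(scores_b)
    normalized.update(scores_a)
    return SLGResult(a.sample_id, b.sample_id, diffs, normalized, slg_b, slg_a, cutoff)


# ---------------------------------------------------------------------------
# Loop partitioning and strength distributions
# ---------------------------------------------------------------------------

@dataclass
class LoopPartition:
    unique_a: list[P1D1Loop]
    common_a: list[P1D1Loop]
    common_b: list[P1D1Loop]
    unique_b: list[P1D1Loop]

    @property
    def n_common(self) -> int:
        """Matched loops counted on the A side (Venn intersection size)."""
        return len(self.common_a)


def partition_loops(a: LoopingGeneTable, b: LoopingGeneTable) -> LoopPartition:
    """Split two samples' loops into unique and common classes.

    Two loops match when they belong to the same gene and their distal
    anchors overlap by at least 1 bp (restriction-fragment identity is
    not assumed).
    """
    unique_a, common_a = [], []
    matched_b: set[int] = set()
    for g, loops_a in a.loops.items():
        loops_b = b.loops.get(g, [])
        for la in loops_a:
            hit = False
            for k, lb in enumerate(loops_b):
                if _overlaps(la.distal_anchor, lb.distal_anchor):
                    hit = True
                    matched_b.add(id(lb))
            (common_a if hit else unique_a).append(la)
    common_b, unique_b = [], []
    for g, loops_b in b.loops.items():
        for lb in loops_b:
            (common_b if id(lb) in matched_b else unique_b).append(lb)
    return LoopPartition(unique_a, common_a, common_b, unique_b)


def strength_distributions(partition: LoopPartition, a: LoopingGeneTable, b: LoopingGeneTable):
    """Gene-level VPPM samples per partition class plus rank-sum p-values.

    Returns ``(groups, pvalues)`` where groups maps class name to an array
    of per-gene VPPM sums (restricted to that class's loops) and pvalues
    holds two-sided Wilcoxon rank-sum p-values for the standard contrasts.
    """
    def gene_sums(loops: list[P1D1Loop]) -> np.ndarray:
        per_gene: dict[str, float] = {}
        for l in loops:
            per_gene[l.gene_id] = per_gene.get(l.gene_id, 0.0) + l.vppm
        return np.array(sorted(per_gene.values()))

    groups = {
        "unique_a": gene_sums(partition.unique_a),
        "common_a": gene_sums(partition.common_a),
        "common_b": gene_sums(partition.common_b),
        "unique_b": gene_sums(partition.unique_b),
    }
    for name, vals in groups.items():
        if len(vals) == 0:
            raise DegenerateInputError(f"empty loop class {name!r}")
    contrasts = [("unique_a", "unique_b"), ("unique_a", "common_a"),
                 ("unique_b", "common_b"), ("common_a", "common_b")]
    pvalues = {}
    for g1, g2 in contrasts:
        stat = _stats.ranksums(groups[g1], groups[g2])
        pvalues[(g1, g2)] = float(stat.pvalue)
    return groups, pvalues


def loops_to_bedpe(table: LoopingGeneTable) -> pd.DataFrame:
    """Flatten a looping-gene table to BEDPE-style rows."""
    rows = []
    for loop in table.all_loops():
        p, d = sorted([loop.promoter_anchor, loop.distal_anchor])
        rows.append((loop.chrom, p[0], p[1], loop.chrom, d[0], d[1],
                     loop.gene_id, loop.valid_pairs, loop.vppm))
    return pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2", "start2",
                                       "end2", "gene_id", "valid_pairs", "vppm"])
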