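"""Binned Hi-C contact matrices: HiC-Pro dialect I/O, down-sampling,
distance-decay diagnostics, and inter-sample LOWESS bias normalization.

The matrix model is intra-chromosomal only: contacts between chromosomes
are dropped on read (with a logged count).  Coordinates are 0-based
half-open throughout; a genomic position maps to bin ``floor(start /
bin_size)``.  Only the upper triangle (``bin_i <= bin_j``) is stored.

The normalization removes a smooth, distance-dependent log-ratio bias of
one library relative to another.  For every stored position present in
either matrix we form ``M = log2((target + pc) / (reference + pc))`` and
fit a LOWESS curve of M against log10(genomic distance), pooled over all
chromosomes; dividing the target by ``2**curve(d)`` flattens the
inter-sample trend while leaving within-distance structure (TADs, loops)
untouched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from loopdiff.errors import (
    InsufficientDataError,
    LayoutError,
    MalformedInputError,
    ParameterError,
)

logger = logging.getLogger(__name__)

STATS_TOTAL_KEY = "valid_interaction_rmdup"


@dataclass(frozen=True)
class GenomeLayout:
    """A fixed binning of an ordered set of chromosomes.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length_bp)`` pairs.
    bin_size
        Bin width in base pairs; the terminal bin of each chromosome may
        be shorter.
    """

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chromosomes", tuple((str(c), int(l)) for c, l in self.chromosomes))
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise LayoutError("duplicate chromosome names")
        if any(l <= 0 for _, l in self.chromosomes):
            raise LayoutError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise LayoutError("bin_size must be positive")

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def chrom_length(self, name: str) -> int:
        for c, l in self.chromosomes:
            if c == name:
                return l
        raise LayoutError(f"unknown chromosome {name!r}")

    def n_bins(self, name: str) -> int:
        return -(-self.chrom_length(name) // self.bin_size)

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chrom_names)

    def bin_offsets(self) -> dict[str, int]:
        """Global index of each chromosome's first bin."""
        out, off = {}, 0
        for c, _ in self.chromosomes:
            out[c] = off
            off += self.n_bins(c)
        return out

    def bin_chrom(self) -> np.ndarray:
        """Chromosome ordinal of every global bin."""
        return np.repeat(
            np.arange(len(self.chromosomes)),
            [self.n_bins(c) for c in self.chrom_names],
        )


@dataclass
class ContactMatrix:
    """Sparse intra-chromosomal contact counts over a :class:`GenomeLayout`.

    ``bin1``/``bin2`` are global 0-based bin indices with ``bin1 <= bin2``
    (upper triangle only); ``count`` may be real-valued for balanced
    (iced) matrices.  ``total_valid_pairs`` is the library-wide valid-pair
    count used as the VPPM denominator downstream.
    """

    layout: GenomeLayout
    bin1: np.ndarray
    bin2: np.ndarray
    count: np.ndarray
    total_valid_pairs: float

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.count = np.asarray(self.count, dtype=np.float64)
        if not (len(self.bin1) == len(self.bin2) == len(self.count)):
            raise ValueError("bin1, bin2 and count must have equal length")
        if np.any(self.bin1 > self.bin2):
            raise ValueError("entries must satisfy bin1 <= bin2")
        if np.any(self.count < 0):
            raise ValueError("counts must be non-negative")
        n = self.layout.total_bins
        if len(self.bin1) and (self.bin1.min() < 0 or self.bin2.max() >= n):
            raise ValueError("bin index outside layout")
        chrom_of = self.layout.bin_chrom()
        if len(self.bin1) and np.any(chrom_of[self.bin1] != chrom_of[self.bin2]):
            raise ValueError("inter-chromosomal entry in ContactMatrix")
        # canonical order for reproducible I/O and comparisons
        order = np.lexsort((self.bin2, self.bin1))
        self.bin1, self.bin2, self.count = self.bin1[order], self.bin2[order], self.count[order]

    @property
    def n_entries(self) -> int:
        return len(self.count)

    def distances(self) -> np.ndarray:
        """Genomic distance (bp) of each stored entry."""
        return (self.bin2 - self.bin1) * self.layout.bin_size

    def sum(self) -> float:
        return float(self.count.sum())

    def has_integer_counts(self) -> bool:
        return bool(np.all(self.count == np.round(self.count)))

    def to_dict(self) -> dict[tuple[int, int], float]:
        return {(int(i), int(j)): float(c) for i, j, c in zip(self.bin1, self.bin2, self.count)}


# ---------------------------------------------------------------------------
# HiC-Pro dialect I/O
# ---------------------------------------------------------------------------

def _read_bins_bed(bins_path) -> tuple[GenomeLayout, dict[int, int]]:
    """Parse ``<prefix>_abs.bed`` into a layout and file-id -> global-bin map."""
    bed = pd.read_csv(
        bins_path, sep=r"\s+", header=None,
        names=["chrom", "start", "end", "bin_id"],
        dtype={"chrom": str},
    )
    if bed.empty:
        raise MalformedInputError(f"{bins_path}: empty bins file")
    chroms: list[tuple[str, int]] = []
    widths = set()
    for chrom, grp in bed.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        w = (grp["end"] - grp["start"]).to_numpy()
        if len(w) > 1:
            widths.update(np.unique(w[:-1]).tolist())
        else:
            widths.add(int(w[0]))
        chroms.append((str(chrom), int(grp["end"].max())))
    non_terminal = {int(w) for w in widths}
    if len(non_terminal) > 1:
        raise LayoutError(f"{bins_path}: inconsistent bin widths {sorted(non_terminal)}")
    bin_size = non_terminal.pop()
    layout = GenomeLayout(tuple(chroms), bin_size)
    offsets = layout.bin_offsets()
    id_map = {}
    for row in bed.itertuples(index=False):
        id_map[int(row.bin_id)] = offsets[str(row.chrom)] + int(row.start) // bin_size
    return layout, id_map


def _read_sidecar_total(stats_path) -> float | None:
    with open(stats_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            if not value:
                # HiC-Pro stat files are also commonly TAB-separated
                parts = line.split()
                if len(parts) >= 2:
                    key, value = parts[0], parts[1]
            if key.strip() == STATS_TOTAL_KEY:
                return float(value.strip())
    return None


def read_hicpro_matrix(bins_path, matrix_path, stats_path=None) -> ContactMatrix:
    """Read a HiC-Pro bins BED + sparse triplet matrix pair.

    Inter-chromosomal triplets are dropped (their number is logged).
    ``total_valid_pairs`` comes from the optional key=value sidecar
    (key ``valid_interaction_rmdup``); absent that, it defaults to the
    sum of the retained counts.
    """
    layout, id_map = _read_bins_bed(bins_path)
    chrom_of = layout.bin_chrom()
    b1, b2, cnt = [], [], []
    n_inter = 0
    with open(matrix_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise MalformedInputError(f"{matrix_path}:{lineno}: expected 3 fields, got {len(parts)}")
            try:
                i, j, c = int(parts[0]), int(parts[1]), float(parts[2])
            except ValueError as exc:
                raise MalformedInputError(f"{matrix_path}:{lineno}: {exc}") from exc
            if i not in id_map or j not in id_map:
                missing = i if i not in id_map else j
                raise MalformedInputError(f"{matrix_path}:{lineno}: unknown bin id {missing}")
            gi, gj = id_map[i], id_map[j]
            if chrom_of[gi] != chrom_of[gj]:
                n_inter += 1
                continue
            if gi > gj:
                gi, gj = gj, gi
            b1.append(gi)
            b2.append(gj)
            cnt.append(c)
    if n_inter:
        logger.info("dropped %d inter-chromosomal triplets from %s", n_inter, matrix_path)
    total = None
    if stats_path is not None:
        total = _read_sidecar_total(stats_path)
    if total is None:
        total = float(np.sum(cnt)) if cnt else 0.0
    return ContactMatrix(layout, np.array(b1, dtype=np.int64), np.array(b2, dtype=np.int64),
                         np.array(cnt, dtype=np.float64), total)


def write_hicpro_matrix(matrix: ContactMatrix, bins_path, matrix_path) -> None:
    """Write a matrix in the HiC-Pro dialect (1-based sequential bin ids).

    Integer counts round-trip bit-exactly; real counts are written with
    ``repr`` precision.
    """
    layout = matrix.layout
    with open(bins_path, "w") as fh:
        bin_id = 1
        for chrom, length in layout.chromosomes:
            for start in range(0, length, layout.bin_size):
                end = min(start + layout.bin_size, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{bin_id}\n")
                bin_id += 1
    with open(matrix_path, "w") as fh:
        for i, j, c in zip(matrix.bin1, matrix.bin2, matrix.count):
            c_str = str(int(c)) if c == int(c) else repr(float(c))
            fh.write(f"{i + 1}\t{j + 1}\t{c_str}\n")


# ---------------------------------------------------------------------------
# Down-sampling and diagnostics
# ---------------------------------------------------------------------------

def downsample_pairs(matrix: ContactMatrix, fraction: float, seed: int) -> ContactMatrix:
    """Binomially thin every valid pair with retention probability ``fraction``.

    Requires raw integer counts.  ``total_valid_pairs`` is set to the
    realized retained count: thinned matrix entries plus a thinned draw of
    the library pairs not represented in the matrix (e.g. inter-chromosomal
    or filtered pairs counted in the sidecar total).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ParameterError(f"fraction must be in [0, 1], got {fraction}")
    if not matrix.has_integer_counts():
        raise ParameterError("downsampling requires raw integer counts")
    rng = np.random.default_rng(seed)
    if fraction == 1.0:
        return ContactMatrix(matrix.layout, matrix.bin1.copy(), matrix.bin2.copy(),
                             matrix.count.copy(), matrix.total_valid_pairs)
    kept = rng.binomial(matrix.count.astype(np.int64), fraction).astype(np.float64)
    extra = max(0, int(round(matrix.total_valid_pairs)) - int(matrix.count.sum()))
    kept_extra = int(rng.binomial(extra, fraction)) if extra else 0
    keep = kept > 0
    return ContactMatrix(matrix.layout, matrix.bin1[keep], matrix.bin2[keep], kept[keep],
                         float(kept.sum() + kept_extra))


def distance_decay_profile(matrix: ContactMatrix) -> dict[int, float]:
    """Mean contact count per genomic distance.

    The mean at distance ``d`` is the total stored count at ``d`` divided
    by the number of intra-chromosomal bin pairs at that distance in the
    layout (pairs with no stored entry contribute zero).  Distances with
    no stored entry are omitted.
    """
    if matrix.n_entries == 0:
        return {}
    bin_size = matrix.layout.bin_size
    k = matrix.bin2 - matrix.bin1  # bin-distance of each entry
    sums: dict[int, float] = {}
    for kk, c in zip(k, matrix.count):
        sums[int(kk)] = sums.get(int(kk), 0.0) + float(c)
    # number of possible pairs per bin-distance, summed over chromosomes
    n_per_chrom = [matrix.layout.n_bins(c) for c in matrix.layout.chrom_names]
    out = {}
    for kk, s in sorted(sums.items()):
        npairs = sum(max(0, n - kk) for n in n_per_chrom)
        out[kk * bin_size] = s / npairs
    return out


def matrix_correlation(a: ContactMatrix, b: ContactMatrix, method: str = "pearson") -> float:
    """Correlation of two matrices over the union of stored positions.

    Positions present in only one matrix are imputed as zero in the other.
    """
    from scipy import stats

    if a.layout != b.layout:
        raise LayoutError("matrix layouts differ")
    da, db = a.to_dict(), b.to_dict()
    keys = sorted(set(da) | set(db))
    if len(keys) < 2:
        raise InsufficientDataError("need at least 2 positions to correlate")
    xa = np.array([da.get(k, 0.0) for k in keys])
    xb = np.array([db.get(k, 0.0) for k in keys])
    if method == "pearson":
        r = stats.pearsonr(xa, xb).statistic
    elif method == "spearman":
        r = stats.spearmanr(xa, xb).statistic
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(r)


# ---------------------------------------------------------------------------
# LOWESS inter-sample bias normalization
# ---------------------------------------------------------------------------

@dataclass
class BiasCurve:
    """A smooth log2 bias of one library relative to another, as a function
    of genomic distance.  Evaluated by linear interpolation on the grid,
    constant beyond its ends."""

    distance_grid: np.ndarray
    log2_bias: np.ndarray
    smoothing_fraction: float

    def __post_init__(self) -> None:
        self.distance_grid = np.asarray(self.distance_grid, dtype=np.float64)
        self.log2_bias = np.asarray(self.log2_bias, dtype=np.float64)
        if np.any(np.diff(self.distance_grid) <= 0):
            raise ValueError("distance grid must be strictly increasing")
        if not np.all(np.isfinite(self.log2_bias)):
            raise ValueError("bias values must be finite")

    def __call__(self, distance) -> np.ndarray:
        return np.interp(np.asarray(distance, dtype=np.float64),
                         self.distance_grid, self.log2_bias)


def _union_counts(target: ContactMatrix, reference: ContactMatrix):
    dt, dr = target.to_dict(), reference.to_dict()
    keys = sorted(set(dt) | set(dr))
    i = np.array([k[0] for k in keys], dtype=np.int64)
    j = np.array([k[1] for k in keys], dtype=np.int64)
    t = np.array([dt.get(k, 0.0) for k in keys])
    r = np.array([dr.get(k, 0.0) for k in keys])
    return i, j, t, r


def fit_lowess_bias(
    target: ContactMatrix,
    reference: ContactMatrix,
    smoothing_fraction: float = 0.3,
    pseudocount: float = 1.0,
) -> BiasCurve:
    """Fit the distance-dependent log2 bias of ``target`` vs ``reference``.

    M = log2((target + pc) / (reference + pc)) at every position stored in
    either matrix is regressed on log10(distance) with LOWESS, pooled over
    all chromosomes.  Diagonal entries (distance 0) are excluded from the
    fit; the curve covers [bin_size, max observed distance].
    """
    if target.layout != reference.layout:
        raise LayoutError("matrix layouts differ")
    if not 0.0 < smoothing_fraction <= 1.0:
        raise ParameterError("smoothing_fraction must be in (0, 1]")
    i, j, t, r = _union_counts(target, reference)
    d = (j - i) * target.layout.bin_size
    off = d > 0
    if off.sum() < 3:
        raise InsufficientDataError("too few off-diagonal positions to fit a bias curve")
    m = np.log2((t[off] + pseudocount) / (r[off] + pseudocount))
    x = np.log10(d[off].astype(np.float64))
    # delta keeps LOWESS linear-time on dense distance strata without
    # changing the pooled-fit semantics
    delta = 0.005 * (x.max() - x.min())
    fitted = _sm_lowess(m, x, frac=smoothing_fraction, delta=delta, return_sorted=True)
    grid_x, grid_y = fitted[:, 0], fitted[:, 1]
    grid_x, uniq = np.unique(grid_x, return_index=True)
    grid_y = grid_y[uniq]
    # express the grid in bp
    distance_grid = 10.0 ** grid_x
    # snap endpoints so the grid covers [bin_size, max distance] exactly
    distance_grid[0] = min(distance_grid[0], target.layout.bin_size)
    return BiasCurve(distance_grid, grid_y, smoothing_fraction)


def apply_bias_correction(target: ContactMatrix, curve: BiasCurve) -> ContactMatrix:
    """Divide every count by ``2**curve(distance)``.

    The curve is linearly interpolated between grid points and held
    constant beyond them (diagonal entries use the near-end value).
    ``total_valid_pairs`` is left unchanged.
    """
    d = target.distances().astype(np.float64)
    factor = 2.0 ** curve(d)
    return ContactMatrix(target.layout, target.bin1.copy(), target.bin2.copy(),
                         target.count / factor, target.total_valid_pairs)
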