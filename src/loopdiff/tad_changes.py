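"""Domain call sets and eight-type TAD-change classification.

Two TopDom-style three-state tilings (TAD / boundary / gap) of the same
genome are compared by matching TADs that overlap between conditions and
classifying every matched component into one of eight change types:

========================  ====================================================
``no_change``             both boundaries move by at most the identity
                          tolerance (default: one bin)
``conserve_expand``       1-1 match, length grows by at most 300 kb and no
                          boundary moves more than 300 kb
``conserve_shrink``       as above with the length shrinking
``shift``                 1-1 match moving or resizing by more than 300 kb
``split``                 one condition-A TAD covered by two or more B TADs
``fuse``                  two or more A TADs covered by one B TAD
``neo``                   boundary/gap space in A becomes a TAD in B
``del``                   an A TAD becomes boundary/gap space in B
========================  ====================================================

The first three types are grouped as relatively conserved (RC), the rest
as drastically changed (DC).  The unit of counting is the overlap-graph
component: every TAD of either condition belongs to exactly one event.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from loopdiff.errors import LayoutError, MalformedInputError, ValidationError
from loopdiff.hic_matrix import GenomeLayout

CHANGE_TYPES = (
    "no_change", "conserve_expand", "conserve_shrink", "shift",
    "split", "fuse", "neo", "del",
)
RC_TYPES = ("no_change", "conserve_expand", "conserve_shrink")
DC_TYPES = ("shift", "split", "fuse", "neo", "del")

_TAG_MAP = {"domain": "tad", "tad": "tad", "boundary": "boundary", "gap": "gap"}


@dataclass(frozen=True, order=True)
class DomainCall:
    chrom: str
    start: int
    end: int
    state: str  # tad | boundary | gap

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(f"{self.chrom}:{self.start}-{self.end}: end must exceed start")
        if self.state not in ("tad", "boundary", "gap"):
            raise ValidationError(f"unknown state {self.state!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DomainCallSet:
    """Sorted, non-overlapping calls per chromosome.  Uncovered space is
    implicitly treated as gap."""

    layout: GenomeLayout | None
    calls: dict[str, list[DomainCall]]

    def __post_init__(self) -> None:
        for chrom, lst in self.calls.items():
            lst.sort(key=lambda c: (c.start, c.end))
            for prev, cur in zip(lst, lst[1:]):
                if cur.start < prev.end:
                    raise ValidationError(
                        f"overlapping calls on {chrom}: "
                        f"{prev.start}-{prev.end} and {cur.start}-{cur.end}"
                    )

    def tads(self, chrom: str | None = None) -> list[DomainCall]:
        chroms = [chrom] if chrom is not None else sorted(self.calls)
        return [c for ch in chroms for c in self.calls.get(ch, []) if c.state == "tad"]

    @property
    def n_tads(self) -> int:
        return len(self.tads())

    def state_counts(self) -> Counter:
        return Counter(c.state for ch in self.calls.values() for c in ch)


def read_topdom(path, layout: GenomeLayout | None = None) -> DomainCallSet:
    """Read a TopDom-style TSV (chrom, start, end, tag).

    The tag column is case-insensitive; ``domain`` maps to ``tad``.  A
    header row is detected and skipped.  Overlapping calls raise a
    validation error naming the offending coordinates.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 4:
        raise MalformedInputError(f"{path}: expected >= 4 columns, got {df.shape[1]}")
    first = df.iloc[0]
    try:
        int(first.iloc[1]), int(first.iloc[2])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    calls: dict[str, list[DomainCall]] = {}
    for lineno, row in enumerate(df.itertuples(index=False), start=1):
        tag = str(row[3]).strip().lower()
        if tag not in _TAG_MAP:
            raise MalformedInputError(f"{path}:{lineno}: unknown tag {row[3]!r}")
        call = DomainCall(str(row[0]), int(row[1]), int(row[2]), _TAG_MAP[tag])
        calls.setdefault(call.chrom, []).append(call)
    return DomainCallSet(layout, calls)


def write_topdom(cs: DomainCallSet, path) -> None:
    tag_out = {"tad": "domain", "boundary": "boundary", "gap": "gap"}
    with open(path, "w") as fh:
        for chrom in sorted(cs.calls):
            for c in cs.calls[chrom]:
                fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{tag_out[c.state]}\n")


# ---------------------------------------------------------------------------
# Overlap graph and classification
# ---------------------------------------------------------------------------

@dataclass
class OverlapComponent:
    chrom: str
    members_a: list[DomainCall]
    members_b: list[DomainCall]


def _overlap(a: DomainCall, b: DomainCall) -> int:
    return min(a.end, b.end) - max(a.start, b.start)


def build_overlap_graph(a: DomainCallSet, b: DomainCallSet, min_overlap: int = 1) -> list[OverlapComponent]:
    """Connected components of the bipartite TAD overlap graph.

    Edges join an A-TAD and a B-TAD overlapping by at least ``min_overlap``
    bp.  Unmatched TADs of either side come back as singleton components.
    """
    if a.layout is not None and b.layout is not None and a.layout != b.layout:
        raise LayoutError("domain call sets have different layouts")
    components: list[OverlapComponent] = []
    for chrom in sorted(set(a.calls) | set(b.calls)):
        ta, tb = a.tads(chrom), b.tads(chrom)
        # union-find over A-nodes (0..len(ta)) and B-nodes (len(ta)..)
        parent = list(range(len(ta) + len(tb)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        def union(x: int, y: int) -> None:
            rx, ry = find(x), find(y)
            if rx != ry:
                parent[ry] = rx

        jb = 0
        for ia, ca in enumerate(ta):
            while jb < len(tb) and tb[jb].end <= ca.start:
                jb += 1
            k = jb
            while k < len(tb) and tb[k].start < ca.end:
                if _overlap(ca, tb[k]) >= min_overlap:
                    union(ia, len(ta) + k)
                k += 1
        groups: dict[int, OverlapComponent] = {}
        for ia, ca in enumerate(ta):
            groups.setdefault(find(ia), OverlapComponent(chrom, [], [])).members_a.append(ca)
        for ib, cb in enumerate(tb):
            groups.setdefault(find(len(ta) + ib), OverlapComponent(chrom, [], [])).members_b.append(cb)
        components.extend(
            groups[k] for k in sorted(
                groups,
                key=lambda k: min(
                    [c.start for c in groups[k].members_a] + [c.start for c in groups[k].members_b]
                ),
            )
        )
    return components


@dataclass
class ChangeEvent:
    chrom: str
    members_a: list[DomainCall]
    members_b: list[DomainCall]
    change_type: str
    length_delta: int  # total B length minus total A length, bp
    max_boundary_displacement: int  # bp; 0 where undefined (neo/del)

    def __post_init__(self) -> None:
        if self.change_type not in CHANGE_TYPES:
            raise ValidationError(f"unknown change type {self.change_type!r}")


def _classify_one_to_one(a: DomainCall, b: DomainCall, conserve_max_delta: int,
                         identity_tolerance: int, chrom: str) -> ChangeEvent:
    start_disp = abs(a.start - b.start)
    end_disp = abs(a.end - b.end)
    max_disp = max(start_disp, end_disp)
    delta = b.length - a.length
    if max_disp <= identity_tolerance:
        ctype = "no_change"
    elif delta != 0 and abs(delta) <= conserve_max_delta and max_disp <= conserve_max_delta:
        ctype = "conserve_expand" if delta > 0 else "conserve_shrink"
    else:
        # pure translation (delta == 0 beyond tolerance) or any move past
        # the conserve bound is a shift; keeps A/B swap anti-symmetric
        ctype = "shift"
    return ChangeEvent(chrom, [a], [b], ctype, delta, max_disp)


def _decompose_many_to_many(comp: OverlapComponent) -> list[tuple[list[DomainCall], list[DomainCall]]]:
    """Greedy star decomposition of a many-to-many component.

    Edges are visited by decreasing overlap (leftmost-coordinate
    tie-break).  An edge seeds a new sub-event when both ends are free;
    otherwise the free end joins the assigned end's sub-event only while
    the assigned side of that sub-event is still a singleton (so every
    sub-event stays a star: one-to-one, one-to-many, or many-to-one).
    TADs left unassigned after all edges become singleton sub-events.
    """
    edges = []
    for ia, ca in enumerate(comp.members_a):
        for ib, cb in enumerate(comp.members_b):
            ov = _overlap(ca, cb)
            if ov > 0:
                # tie-break is invariant under swapping the two conditions
                edges.append((-ov, min(ca.start, cb.start), max(ca.start, cb.start), ia, ib))
    edges.sort()
    sub: list[tuple[list[int], list[int]]] = []
    a_of: dict[int, int] = {}
    b_of: dict[int, int] = {}
    for _, _, _, ia, ib in edges:
        in_a, in_b = ia in a_of, ib in b_of
        if not in_a and not in_b:
            sub.append(([ia], [ib]))
            a_of[ia] = b_of[ib] = len(sub) - 1
        elif in_a and not in_b:
            s = a_of[ia]
            if len(sub[s][0]) == 1:  # A-side still singleton: grows a split
                sub[s][1].append(ib)
                b_of[ib] = s
        elif in_b and not in_a:
            s = b_of[ib]
            if len(sub[s][1]) == 1:  # B-side still singleton: grows a fuse
                sub[s][0].append(ia)
                a_of[ia] = s
        # both assigned: edge is redundant
    for ia in range(len(comp.members_a)):
        if ia not in a_of:
            sub.append(([ia], []))
    for ib in range(len(comp.members_b)):
        if ib not in b_of:
            sub.append(([], [ib]))
    return [
        (sorted((comp.members_a[i] for i in sa), key=lambda c: c.start),
         sorted((comp.members_b[i] for i in sb), key=lambda c: c.start))
        for sa, sb in sub
    ]


def _event_from_members(chrom: str, ma: list[DomainCall], mb: list[DomainCall],
                        conserve_max_delta: int, identity_tolerance: int) -> ChangeEvent:
    if not ma:
        return ChangeEvent(chrom, [], mb, "neo", sum(c.length for c in mb), 0)
    if not mb:
        return ChangeEvent(chrom, ma, [], "del", -sum(c.length for c in ma), 0)
    if len(ma) == 1 and len(mb) == 1:
        return _classify_one_to_one(ma[0], mb[0], conserve_max_delta, identity_tolerance, chrom)
    delta = sum(c.length for c in mb) - sum(c.length for c in ma)
    span_disp = max(
        abs(min(c.start for c in ma) - min(c.start for c in mb)),
        abs(max(c.end for c in ma) - max(c.end for c in mb)),
    )
    if len(ma) == 1:
        return ChangeEvent(chrom, ma, mb, "split", delta, span_disp)
    return ChangeEvent(chrom, ma, mb, "fuse", delta, span_disp)


def classify_changes(
    a: DomainCallSet,
    b: DomainCallSet,
    conserve_max_delta: int = 300_000,
    identity_tolerance: int = 40_000,
    min_overlap: int = 1,
) -> list[ChangeEvent]:
    """Classify every TAD change between condition A and condition B.

    Every TAD of either condition appears in exactly one returned event.
    Many-to-many overlap components are decomposed greedily into split and
    fuse sub-events by maximal pairwise overlap (leftmost tie-break).
    """
    events: list[ChangeEvent] = []
    for comp in build_overlap_graph(a, b, min_overlap=min_overlap):
        na, nb = len(comp.members_a), len(comp.members_b)
        if na > 1 and nb > 1:
            for ma, mb in _decompose_many_to_many(comp):
                events.append(_event_from_members(comp.chrom, ma, mb,
                                                  conserve_max_delta, identity_tolerance))
        else:
            events.append(_event_from_members(comp.chrom, comp.members_a, comp.members_b,
                                              conserve_max_delta, identity_tolerance))
    return events


@dataclass
class ChangeSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    rc_fraction: float
    dc_fraction: float
    n_events: int

    def to_json(self) -> str:
        return json.dumps(
            {"counts": self.counts, "fractions": self.fractions,
             "rc_fraction": self.rc_fraction, "dc_fraction": self.dc_fraction,
             "n_events": self.n_events},
            indent=2, sort_keys=True,
        )


def summarize_changes(events: list[ChangeEvent]) -> ChangeSummary:
    """Counts and fractions per change type, plus the RC/DC split."""
    counts = {t: 0 for t in CHANGE_TYPES}
    for e in events:
        counts[e.change_type] += 1
    n = len(events)
    fractions = {t: (counts[t] / n if n else 0.0) for t in CHANGE_TYPES}
    rc = sum(fractions[t] for t in RC_TYPES)
    dc = sum(fractions[t] for t in DC_TYPES)
    return ChangeSummary(counts, fractions, rc, dc, n)


def tad_size_distribution(cs: DomainCallSet, edges) -> np.ndarray:
    """Histogram of TAD lengths over the given bin edges (bp).

    Boundaries and gaps are excluded.  Lengths outside the edges are not
    counted, matching :func:`numpy.histogram` semantics.
    """
    sizes = [c.length for c in cs.tads()]
    counts, _ = np.histogram(sizes, bins=np.asarray(edges, dtype=np.float64))
    return counts


def events_to_frame(events: list[ChangeEvent]) -> pd.DataFrame:
    """Flatten events to a table (one row per event) for TSV export."""
    rows = []
    for e in events:
        rows.append({
            "chrom": e.chrom,
            "a_members": ";".join(f"{c.start}-{c.end}" for c in e.members_a),
            "b_members": ";".join(f"{c.start}-{c.end}" for c in e.members_b),
            "type": e.change_type,
            "length_delta": e.length_delta,
            "max_displacement": e.max_boundary_displacement,
        })
    return pd.DataFrame(rows, columns=["chrom", "a_members", "b_members", "type",
                                       "length_delta", "max_displacement"])
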