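"""Independent brute-force reference implementations used only by tests.

These re-derive the classification and assignment rules with plain,
unoptimized code (all-pairs scans, explicit BFS) so the fast package
implementations can be checked against them on random instances.
"""

from __future__ import annotations

from collections import deque


# ---------------------------------------------------------------------------
# TAD-change classification oracle
# ---------------------------------------------------------------------------

def _ov(a, b):
    return min(a[1], b[1]) - max(a[0], b[0])


def brute_force_classify(tads_a, tads_b, conserve_max_delta=300_000,
                         identity_tolerance=40_000, min_overlap=1):
    """Classify changes between two TAD interval lists of one chromosome.

    ``tads_a``/``tads_b`` are lists of (start, end).  Returns a list of
    (members_a, members_b, type) with members as sorted interval lists.
    Applies the same rules as the package classifier: components of the
    >= min_overlap bipartite overlap graph; star decomposition of
    many-to-many components by greedy maximal overlap with a
    swap-invariant leftmost tie-break; 1-1 rules with the 300 kb
    conserve bound and the identity tolerance.
    """
    tads_a = sorted(tads_a)
    tads_b = sorted(tads_b)
    # all-pairs edges, then BFS components over a bipartite adjacency
    edges = [(ia, ib) for ia, a in enumerate(tads_a) for ib, b in enumerate(tads_b)
             if _ov(a, b) >= min_overlap]
    adj_a = {ia: [] for ia in range(len(tads_a))}
    adj_b = {ib: [] for ib in range(len(tads_b))}
    for ia, ib in edges:
        adj_a[ia].append(ib)
        adj_b[ib].append(ia)
    seen_a, seen_b = set(), set()
    components = []
    for start in range(len(tads_a)):
        if start in seen_a:
            continue
        ca, cb = set(), set()
        queue = deque([("a", start)])
        while queue:
            side, idx = queue.popleft()
            if side == "a":
                if idx in seen_a:
                    continue
                seen_a.add(idx)
                ca.add(idx)
                queue.extend(("b", j) for j in adj_a[idx])
            else:
                if idx in seen_b:
                    continue
                seen_b.add(idx)
                cb.add(idx)
                queue.extend(("a", j) for j in adj_b[idx])
        components.append((sorted(ca), sorted(cb)))
    for ib in range(len(tads_b)):
        if ib not in seen_b:
            components.append(([], [ib]))
    components.sort(key=lambda c: min([tads_a[i][0] for i in c[0]]
                                      + [tads_b[i][0] for i in c[1]]))

    def one_to_one(a, b):
        disp = max(abs(a[0] - b[0]), abs(a[1] - b[1]))
        delta = (b[1] - b[0]) - (a[1] - a[0])
        if disp <= identity_tolerance:
            return "no_change"
        if delta != 0 and abs(delta) <= conserve_max_delta and disp <= conserve_max_delta:
            return "conserve_expand" if delta > 0 else "conserve_shrink"
        return "shift"

    def emit(ma_idx, mb_idx):
        ma = sorted(tads_a[i] for i in ma_idx)
        mb = sorted(tads_b[i] for i in mb_idx)
        if not ma:
            return (ma, mb, "neo")
        if not mb:
            return (ma, mb, "del")
        if len(ma) == 1 and len(mb) == 1:
            return (ma, mb, one_to_one(ma[0], mb[0]))
        return (ma, mb, "split" if len(ma) == 1 else "fuse")

    events = []
    for ca, cb in components:
        if len(ca) > 1 and len(cb) > 1:
            comp_edges = []
            for ia in ca:
                for ib in cb:
                    ov = _ov(tads_a[ia], tads_b[ib])
                    if ov > 0:
                        sa, sb = tads_a[ia][0], tads_b[ib][0]
                        comp_edges.append((-ov, min(sa, sb), max(sa, sb),
                                           ca.index(ia), cb.index(ib), ia, ib))
            comp_edges.sort()
            sub = []
            a_of, b_of = {}, {}
            for _, _, _, _, _, ia, ib in comp_edges:
                if ia not in a_of and ib not in b_of:
                    sub.append(([ia], [ib]))
                    a_of[ia] = b_of[ib] = len(sub) - 1
                elif ia in a_of and ib not in b_of:
                    s = a_of[ia]
                    if len(sub[s][0]) == 1:
                        sub[s][1].append(ib)
                        b_of[ib] = s
                elif ib in b_of and ia not in a_of:
                    s = b_of[ib]
                    if len(sub[s][1]) == 1:
                        sub[s][0].append(ia)
                        a_of[ia] = s
            for ia in ca:
                if ia not in a_of:
                    sub.append(([ia], []))
            for ib in cb:
                if ib not in b_of:
                    sub.append(([], [ib]))
            events.extend(emit(sa, sb) for sa, sb in sub)
        else:
            events.append(emit(ca, cb))
    return events


# ---------------------------------------------------------------------------
# P1D1 loop-calling oracle
# ---------------------------------------------------------------------------

def brute_force_p1d1(sifs, genes, total_valid_pairs, chrom_length=None):
    """All-pairs promoter/distal scan re-deriving the windows from scratch.

    ``sifs`` are (chrom, a1, a2, valid_pairs) tuples (already filtered);
    ``genes`` are (gene_id, chrom, tss, strand).  Returns a set of
    (gene_id, promoter_anchor, distal_anchor, valid_pairs, round(vppm, 9)).
    """
    def windows(tss, strand):
        if strand == "+":
            prom = (tss - 4000, tss + 1000)
            dist = [(tss - 100_000, tss - 10_000), (tss + 10_000, tss + 100_000)]
        else:
            prom = (tss - 1000, tss + 4000)
            dist = [(tss + 10_000, tss + 100_000), (tss - 100_000, tss - 10_000)]
        def clip(iv):
            s = max(0, iv[0])
            e = iv[1] if chrom_length is None else min(iv[1], chrom_length)
            return (s, max(s, e))
        return clip(prom), [clip(d) for d in dist]

    def hits(anchor, iv):
        return min(anchor[1], iv[1]) - max(anchor[0], iv[0]) >= 1

    loops = set()
    for chrom, a1, a2, vp in sifs:
        # roles of each anchor over every gene, with promoter demotion
        roles = []
        for anchor in (a1, a2):
            r = set()
            for gid, gchrom, tss, strand in genes:
                if gchrom != chrom:
                    continue
                prom, dist = windows(tss, strand)
                if hits(anchor, prom):
                    r.add((gid, "promoter"))
                if any(hits(anchor, d) for d in dist):
                    r.add((gid, "distal"))
            if any(role == "promoter" for _, role in r):
                r = {(g, role) for g, role in r if role == "promoter"}
            roles.append(r)
        for gid, _, _, _ in genes:
            for prom_anchor, dist_anchor, rp, rd in ((a1, a2, roles[0], roles[1]),
                                                     (a2, a1, roles[1], roles[0])):
                if (gid, "promoter") in rp and (gid, "distal") in rd:
                    vppm = vp / total_valid_pairs * 1e6
                    loops.add((gid, prom_anchor, dist_anchor, vp, round(vppm, 9)))
    return loops
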