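"""P1D1 loop assignment, VPPM scoring and strengthened looping genes."""

import numpy as np
import pytest

from _oracles import brute_force_p1d1
from loopdiff.errors import (
    DegenerateInputError,
    ParameterError,
    ValidationError,
)
from loopdiff.loop_scoring import (
    GeneIndex,
    GeneRecord,
    LoopingGeneTable,
    P1D1Loop,
    assign_anchor,
    call_p1d1_loops,
    distal_windows,
    filter_sifs,
    gene_vppm_table,
    make_sif,
    partition_loops,
    promoter_window,
    read_sifs,
    strength_distributions,
    strengthened_looping_genes,
    write_sifs,
)


def gene(gid="g1", chrom="chr1", tss=500_000, strand="+"):
    return GeneRecord(gid, chrom, tss, strand)


def random_sifs(rng, n, chrom="chr1", span=10_000_000):
    out = []
    for _ in range(n):
        s1 = int(rng.integers(0, span - 300_000))
        w1 = int(rng.integers(500, 5000))
        gap = int(rng.integers(1, 200_000))
        s2 = s1 + w1 + gap
        w2 = int(rng.integers(500, 5000))
        out.append(make_sif(chrom, s1, s1 + w1, s2, s2 + w2,
                            int(rng.integers(1, 500)), float(rng.uniform(0, 0.1))))
    return out


class TestSifIO:
    def test_single_row(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tvalid_pairs\tfdr\n"
                     "chr1\t100\t200\tchr1\t5000\t5100\t10\t0.05\n")
        sifs = read_sifs(p)
        assert len(sifs) == 1 and sifs[0].valid_pairs == 10

    def test_inter_chromosomal_dropped(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tvalid_pairs\tfdr\n"
                     "chr1\t100\t200\tchr2\t5000\t5100\t10\t0.05\n")
        assert read_sifs(p) == []

    def test_invalid_fdr_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tvalid_pairs\tfdr\n"
                     "chr1\t100\t200\tchr1\t5000\t5100\t10\t1.5\n")
        with pytest.raises(ValidationError):
            read_sifs(p)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_round_trip_100_random(self, tmp_path, seed):
        sifs = random_sifs(np.random.default_rng(seed), 100)
        write_sifs(sifs, tmp_path / "rt.tsv")
        assert read_sifs(tmp_path / "rt.tsv") == sifs

    @pytest.mark.parametrize("fdr,kept", [(0.05, True), (0.10, True), (0.2, False)])
    def test_fdr_filter_inclusive(self, fdr, kept):
        s = make_sif("chr1", 0, 100, 5000, 5100, 5, fdr)
        assert (filter_sifs([s]) == [s]) is kept


class TestWindows:
    def test_promoter_plus_strand(self):
        assert promoter_window(gene(tss=100_000, strand="+")) == (96_000, 101_000)

    def test_promoter_minus_strand(self):
        assert promoter_window(gene(tss=100_000, strand="-")) == (99_000, 104_000)

    def test_promoter_clipped(self):
        assert promoter_window(gene(tss=2_000, strand="+")) == (0, 3_000)

    def test_distal_plus_strand(self):
        up, down = distal_windows(gene(tss=500_000, strand="+"))
        assert up == (400_000, 490_000)
        assert down == (510_000, 600_000)

    def test_distal_minus_strand_mirrored(self):
        up, down = distal_windows(gene(tss=500_000, strand="-"))
        assert up == (510_000, 600_000)
        assert down == (400_000, 490_000)

    def test_distal_clipping(self):
        up, down = distal_windows(gene(tss=50_000, strand="+"))
        assert up == (0, 40_000)
        assert down == (60_000, 150_000)


class TestAssignAnchor:
    def test_promoter_only(self):
        idx = GeneIndex([gene()])
        assert assign_anchor((498_000, 499_000), "chr1", idx) == {("g1", "promoter")}

    def test_promoter_priority_demotes_distal(self):
        # anchor sits in g2's promoter and in g1's downstream distal window
        g1 = gene("g1", tss=500_000)
        g2 = gene("g2", tss=560_000)
        idx = GeneIndex([g1, g2])
        roles = assign_anchor((555_500, 556_500), "chr1", idx)
        assert roles == {("g2", "promoter")}

    def test_two_distal_roles_kept(self):
        # anchor falls in g1's downstream and g3's upstream distal windows
        g1 = gene("g1", tss=500_000)
        g3 = gene("g3", tss=690_000)
        idx = GeneIndex([g1, g3])
        roles = assign_anchor((592_000, 593_000), "chr1", idx)
        assert roles == {("g1", "distal"), ("g3", "distal")}


class TestCallLoops:
    def test_vppm_arithmetic(self):
        g = gene()
        sif = make_sif("chr1", 497_000, 498_000, 520_000, 522_000, 100, 0.01)
        table = call_p1d1_loops([sif], [g], 50_000_000)
        (loop,) = table.loops["g1"]
        assert loop.vppm == pytest.approx(2.0)
        assert loop.promoter_anchor == (497_000, 498_000)

    def test_cross_gene_pair_yields_nothing(self):
        g1 = gene("g1", tss=500_000)
        g2 = gene("g2", tss=5_000_000)
        sif = make_sif("chr1", 497_000, 498_000, 5_020_000, 5_022_000, 100, 0.01)
        assert call_p1d1_loops([sif], [g1, g2], 1_000_000).loops == {}

    def test_total_must_be_positive(self):
        with pytest.raises(ParameterError):
            call_p1d1_loops([], [gene()], 0)

    @pytest.mark.parametrize("seed", range(100))
    def test_oracle_equivalence_random(self, seed):
        """Loop calling equals the exhaustive all-pairs window scan."""
        rng = np.random.default_rng(seed)
        n_genes, n_sifs = 30, 60
        genes = [GeneRecord(f"g{k}", "chr1", int(rng.integers(120_000, 9_000_000)),
                            "+" if rng.random() < 0.5 else "-")
                 for k in range(n_genes)]
        sifs = random_sifs(rng, n_sifs)
        total = 1_000_000
        table = call_p1d1_loops(sifs, genes, total)
        got = {(l.gene_id, l.promoter_anchor, l.distal_anchor, l.valid_pairs,
                round(l.vppm, 9))
               for loops in table.loops.values() for l in loops}
        want = brute_force_p1d1(
            [(s.chrom, s.anchor1, s.anchor2, s.valid_pairs) for s in sifs],
            [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes], total)
        assert got == want

    def test_oracle_equivalence_large(self):
        rng = np.random.default_rng(424242)
        genes = [GeneRecord(f"g{k}", "chr1", int(rng.integers(120_000, 49_000_000)),
                            "+" if rng.random() < 0.5 else "-")
                 for k in range(200)]
        sifs = random_sifs(rng, 500, span=50_000_000)
        table = call_p1d1_loops(sifs, genes, 2_000_000)
        got = {(l.gene_id, l.promoter_anchor, l.distal_anchor, l.valid_pairs,
                round(l.vppm, 9))
               for loops in table.loops.values() for l in loops}
        want = brute_force_p1d1(
            [(s.chrom, s.anchor1, s.anchor2, s.valid_pairs) for s in sifs],
            [(g.gene_id, g.chrom, g.tss, g.strand) for g in genes], 2_000_000)
        assert got == want

    def test_strand_reflection_invariance(self):
        """Reflecting all coordinates and flipping strands preserves loops."""
        L = 10_000_000
        genes = [gene("g1", tss=500_000, strand="+"), gene("g2", tss=2_000_000, strand="-")]
        sifs = [make_sif("chr1", 497_000, 498_000, 520_000, 522_000, 50, 0.01),
                make_sif("chr1", 1_905_000, 1_907_000, 2_000_500, 2_001_500, 70, 0.01)]
        table = call_p1d1_loops(sifs, genes, 1_000_000)

        def refl(iv):
            return (L - iv[1], L - iv[0])

        genes_r = [GeneRecord(g.gene_id, g.chrom, L - 1 - g.tss,
                              "-" if g.strand == "+" else "+") for g in genes]
        sifs_r = [make_sif("chr1", *refl(s.anchor1), *refl(s.anchor2),
                           s.valid_pairs, s.fdr) for s in sifs]
        table_r = call_p1d1_loops(sifs_r, genes_r, 1_000_000)
        assert set(table.loops) == set(table_r.loops)
        assert table.n_loops == table_r.n_loops

    def test_promoter_priority_invariant(self):
        """No anchor contributes both promoter and distal roles to the loop set."""
        rng = np.random.default_rng(9)
        genes = [GeneRecord(f"g{k}", "chr1", int(rng.integers(120_000, 9_000_000)), "+")
                 for k in range(40)]
        idx = GeneIndex(genes)
        for s in random_sifs(rng, 100):
            for anchor in (s.anchor1, s.anchor2):
                roles = {r for _, r in assign_anchor(anchor, "chr1", idx)}
                assert roles != {"promoter", "distal"}


def table_from(vppms: dict[str, float], sample="s", total=1_000_000) -> LoopingGeneTable:
    loops = {}
    for g, v in vppms.items():
        vp = max(1, int(round(v * total / 1e6)))
        loops[g] = [P1D1Loop(g, "chr1", (0, 1000), (20_000, 22_000), vp, v)]
    return LoopingGeneTable(sample, total, loops)


class TestGeneVppm:
    def test_sum_of_member_loops(self):
        t = LoopingGeneTable("s", 10, {
            "g1": [P1D1Loop("g1", "chr1", (0, 1), (2, 3), 1, 2.0),
                   P1D1Loop("g1", "chr1", (0, 1), (4, 5), 1, 3.5)]})
        assert gene_vppm_table(t) == {"g1": 5.5}

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        loops = {}
        for k in range(rng.integers(1, 20)):
            loops[f"g{k}"] = [
                P1D1Loop(f"g{k}", "chr1", (0, 1), (2, 3), 1, float(rng.uniform(0, 5)))
                for _ in range(rng.integers(1, 5))]
        t = LoopingGeneTable("s", 100, loops)
        got = gene_vppm_table(t)
        for g, loops_g in loops.items():
            assert got[g] == pytest.approx(sum(l.vppm for l in loops_g))

    def test_vppm_bounds(self):
        loop = P1D1Loop("g", "chr1", (0, 1), (2, 3), 1_000, 1e6)
        assert 0 <= loop.vppm <= 1e6
        sif = make_sif("chr1", 497_000, 498_000, 520_000, 522_000, 1_000, 0.0)
        table = call_p1d1_loops([sif], [gene()], 1_000)
        assert table.loops["g1"][0].vppm == pytest.approx(1e6)


class TestSLG:
    def test_degenerate_then_single_perturbation(self):
        a = table_from({"g1": 1.0, "g2": 1.0, "g3": 1.0})
        with pytest.raises(DegenerateInputError):
            strengthened_looping_genes(a, a)
        b = table_from({"g1": 1.0, "g2": 1.0, "g3": 2.0})
        res = strengthened_looping_genes(a, b)
        assert res.slg_b == {"g3"} and res.slg_a == set()

    def test_planted_bulk_recovery(self):
        rng = np.random.default_rng(17)
        base = {f"g{k}": 10.0 for k in range(1000)}
        diffs = rng.normal(0, 0.1, 1000)
        b_vals = {g: max(0.01, 10.0 + d) for g, d in zip(base, diffs)}
        planted = [f"g{k}" for k in range(0, 1000, 20)]  # 50 genes
        for g in planted:
            b_vals[g] = 15.0
        res = strengthened_looping_genes(table_from(base, "a"), table_from(b_vals, "b"))
        assert set(planted) <= res.slg_b
        assert not (set(planted) & res.slg_a)

    @pytest.mark.parametrize("seed", range(50))
    def test_monotonicity(self, seed):
        """Raising a gene's VPPM in b never expels it from slg_b."""
        rng = np.random.default_rng(seed)
        genes = [f"g{k}" for k in range(20)]
        va = {g: float(rng.uniform(0, 10)) for g in genes}
        vb = {g: float(rng.uniform(0, 10)) for g in genes}
        res = strengthened_looping_genes(table_from(va, "a"), table_from(vb, "b"))
        if not res.slg_b:
            return
        g = sorted(res.slg_b)[0]
        vb2 = dict(vb)
        vb2[g] += float(rng.uniform(0.1, 5))
        res2 = strengthened_looping_genes(table_from(va, "a"), table_from(vb2, "b"))
        assert g in res2.slg_b

    @pytest.mark.parametrize("seed", range(20))
    def test_anti_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        genes = [f"g{k}" for k in range(15)]
        va = {g: float(rng.uniform(0, 10)) for g in genes}
        vb = {g: float(rng.uniform(0, 10)) for g in genes}
        fwd = strengthened_looping_genes(table_from(va, "a"), table_from(vb, "b"))
        rev = strengthened_looping_genes(table_from(vb, "b"), table_from(va, "a"))
        assert fwd.slg_b == rev.slg_a
        assert fwd.slg_a == rev.slg_b

    def test_absent_gene_counts_as_zero(self):
        a = table_from({"g1": 1.0, "g2": 1.0})
        b = table_from({"g2": 1.0, "g3": 4.0})
        res = strengthened_looping_genes(a, b)
        assert res.diffs["g3"] == pytest.approx(4.0)
        assert res.diffs["g1"] == pytest.approx(-1.0)


class TestPartitionAndDistributions:
    def test_identical_tables_all_common(self):
        t = table_from({"g1": 2.0, "g2": 3.0})
        p = partition_loops(t, t)
        assert not p.unique_a and not p.unique_b
        assert p.n_common == 2

    def test_disjoint_gene_sets(self):
        p = partition_loops(table_from({"g1": 2.0}), table_from({"g2": 2.0}))
        assert len(p.unique_a) == 1 and len(p.unique_b) == 1 and p.n_common == 0

    def test_planted_overlap_counts(self):
        common = {f"c{k}": 1.0 for k in range(60)}
        only_a = {f"a{k}": 1.0 for k in range(40)}
        only_b = {f"b{k}": 1.0 for k in range(40)}
        p = partition_loops(table_from({**common, **only_a}),
                            table_from({**common, **only_b}))
        assert p.n_common == 60
        assert len(p.unique_a) == len(p.unique_b) == 40

    def test_same_gene_disjoint_distal_anchors_are_unique(self):
        la = LoopingGeneTable("a", 100, {"g1": [
            P1D1Loop("g1", "chr1", (0, 1000), (20_000, 22_000), 1, 1.0)]})
        lb = LoopingGeneTable("b", 100, {"g1": [
            P1D1Loop("g1", "chr1", (0, 1000), (50_000, 52_000), 1, 1.0)]})
        p = partition_loops(la, lb)
        assert len(p.unique_a) == len(p.unique_b) == 1 and p.n_common == 0

    def test_rank_sum_null_and_shift(self):
        rng = np.random.default_rng(5)
        common = {f"c{k}": float(rng.uniform(1, 3)) for k in range(200)}
        ua = {f"a{k}": float(rng.uniform(1, 3)) for k in range(200)}
        ub = {f"b{k}": float(rng.uniform(1, 3)) + 10.0 for k in range(200)}
        p = partition_loops(table_from({**common, **ua}), table_from({**common, **ub}))
        groups, pv = strength_distributions(
            p, table_from({**common, **ua}), table_from({**common, **ub}))
        assert pv[("common_a", "common_b")] > 0.5  # identical groups
        assert pv[("unique_a", "unique_b")] < 1e-6  # +10 VPPM shift

    def test_empty_group_errors(self):
        t = table_from({"g1": 2.0})
        p = partition_loops(t, t)  # unique classes empty
        with pytest.raises(DegenerateInputError):
            strength_distributions(p, t, t)
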