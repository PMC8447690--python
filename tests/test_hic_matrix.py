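"""Contact-matrix I/O, down-sampling, diagnostics and LOWESS normalization."""

import numpy as np
import pytest

from conftest import random_matrix
from loopdiff.errors import LayoutError, MalformedInputError, ParameterError
from loopdiff.hic_matrix import (
    ContactMatrix,
    GenomeLayout,
    BiasCurve,
    apply_bias_correction,
    distance_decay_profile,
    downsample_pairs,
    fit_lowess_bias,
    matrix_correlation,
    read_hicpro_matrix,
    write_hicpro_matrix,
)
from loopdiff.synth import ScenarioSpec, simulate_contact_matrix, simulate_domain_pair


def write_pair(tmp_path, bins_lines, matrix_lines, stats=None):
    bins = tmp_path / "t_abs.bed"
    mat = tmp_path / "t.matrix"
    bins.write_text("".join(l + "\n" for l in bins_lines))
    mat.write_text("".join(l + "\n" for l in matrix_lines))
    stats_path = None
    if stats is not None:
        stats_path = tmp_path / "t.stats"
        stats_path.write_text(stats)
    return bins, mat, stats_path


class TestHicProIO:
    def test_two_bin_parse(self, tmp_path):
        bins, mat, _ = write_pair(
            tmp_path,
            ["chr1\t0\t40000\t1", "chr1\t40000\t80000\t2"],
            ["1\t1\t10", "1\t2\t4", "2\t2\t8"],
        )
        m = read_hicpro_matrix(bins, mat)
        assert m.n_entries == 3
        assert m.sum() == 22
        assert m.total_valid_pairs == 22  # defaults to count sum

    def test_empty_matrix_is_not_an_error(self, tmp_path):
        bins, mat, _ = write_pair(tmp_path, ["chr1\t0\t40000\t1"], [])
        m = read_hicpro_matrix(bins, mat)
        assert m.n_entries == 0

    def test_sidecar_total(self, tmp_path):
        bins, mat, stats = write_pair(
            tmp_path, ["chr1\t0\t40000\t1"], ["1\t1\t5"],
            stats="valid_interaction_rmdup=1000\n")
        assert read_hicpro_matrix(bins, mat, stats).total_valid_pairs == 1000

    def test_inter_chromosomal_dropped(self, tmp_path):
        bins, mat, _ = write_pair(
            tmp_path,
            ["chr1\t0\t40000\t1", "chr2\t0\t40000\t2"],
            ["1\t2\t7", "1\t1\t3"],
        )
        m = read_hicpro_matrix(bins, mat)
        assert m.n_entries == 1 and m.sum() == 3

    def test_unknown_bin_id_names_line(self, tmp_path):
        bins, mat, _ = write_pair(tmp_path, ["chr1\t0\t40000\t1"], ["1\t9\t3"])
        with pytest.raises(MalformedInputError, match=":1"):
            read_hicpro_matrix(bins, mat)

    def test_inconsistent_bin_width(self, tmp_path):
        bins, mat, _ = write_pair(
            tmp_path,
            ["chr1\t0\t40000\t1", "chr1\t40000\t60000\t2", "chr1\t60000\t100000\t3"],
            [],
        )
        with pytest.raises(LayoutError):
            read_hicpro_matrix(bins, mat)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_round_trip_random_matrix(self, tmp_path, layout_50, seed):
        rng = np.random.default_rng(seed)
        m = random_matrix(layout_50, rng)
        write_hicpro_matrix(m, tmp_path / "rt_abs.bed", tmp_path / "rt.matrix")
        m2 = read_hicpro_matrix(tmp_path / "rt_abs.bed", tmp_path / "rt.matrix")
        assert m2.layout == m.layout
        assert m2.to_dict() == m.to_dict()


class TestDownsample:
    def test_fraction_one_is_identity(self, layout_50):
        m = random_matrix(layout_50, np.random.default_rng(3))
        d = downsample_pairs(m, 1.0, seed=1)
        assert d.to_dict() == m.to_dict()
        assert d.total_valid_pairs == m.total_valid_pairs

    def test_fraction_zero_empties(self, layout_50):
        m = random_matrix(layout_50, np.random.default_rng(3))
        d = downsample_pairs(m, 0.0, seed=1)
        assert d.n_entries == 0 and d.total_valid_pairs == 0

    def test_binomial_tail_bound(self, layout_50):
        m = ContactMatrix(layout_50, [0], [1], [10_000.0], 10_000)
        d = downsample_pairs(m, 0.5, seed=11)
        sd = np.sqrt(10_000 * 0.25)
        assert abs(d.sum() - 5_000) < 4 * sd

    def test_deterministic_given_seed(self, layout_50):
        m = random_matrix(layout_50, np.random.default_rng(4))
        assert downsample_pairs(m, 0.3, 5).to_dict() == downsample_pairs(m, 0.3, 5).to_dict()

    def test_fraction_out_of_range(self, layout_50):
        m = random_matrix(layout_50, np.random.default_rng(3))
        with pytest.raises(ParameterError):
            downsample_pairs(m, 1.5, 0)

    def test_real_counts_rejected(self, layout_50):
        m = ContactMatrix(layout_50, [0], [1], [2.5], 10)
        with pytest.raises(ParameterError):
            downsample_pairs(m, 0.5, 0)

    def test_decay_shape_preserved_at_half(self, default_spec):
        """Down-sampling to 50% keeps the distance-decay profile intact."""
        dom_a, _, _ = simulate_domain_pair(default_spec)
        m = simulate_contact_matrix(default_spec.layout(), dom_a, default_spec)
        d = downsample_pairs(m, 0.5, seed=2)
        p0, p1 = distance_decay_profile(m), distance_decay_profile(d)
        common = sorted(set(p0) & set(p1))
        r = np.corrcoef([p0[k] for k in common], [p1[k] for k in common])[0, 1]
        assert r >= 0.95


class TestDiagnostics:
    def test_uniform_counts_constant_profile(self, layout_50):
        n = layout_50.total_bins
        iu, ju = np.triu_indices(n)
        m = ContactMatrix(layout_50, iu, ju, np.full(len(iu), 7.0), 1)
        prof = distance_decay_profile(m)
        assert all(abs(v - 7.0) < 1e-12 for v in prof.values())

    def test_planted_inverse_distance(self, layout_50):
        n = layout_50.total_bins
        iu, ju = np.triu_indices(n)
        off = ju > iu
        iu, ju = iu[off], ju[off]
        counts = 100.0 / (ju - iu)
        m = ContactMatrix(layout_50, iu, ju, counts, 1)
        prof = distance_decay_profile(m)
        for d, v in prof.items():
            assert v == pytest.approx(100.0 / (d // layout_50.bin_size))

    def test_single_entry_and_empty(self, layout_50):
        m = ContactMatrix(layout_50, [2], [5], [9.0], 9)
        prof = distance_decay_profile(m)
        assert list(prof) == [3 * 40_000]
        empty = ContactMatrix(layout_50, [], [], [], 0)
        assert distance_decay_profile(empty) == {}

    def test_correlation_self_and_scale(self, layout_50):
        m = random_matrix(layout_50, np.random.default_rng(5))
        m2 = ContactMatrix(layout_50, m.bin1, m.bin2, m.count * 2, m.total_valid_pairs)
        assert matrix_correlation(m, m, "pearson") == pytest.approx(1.0)
        assert matrix_correlation(m, m2, "pearson") == pytest.approx(1.0)
        assert matrix_correlation(m, m2, "spearman") == pytest.approx(1.0)

    def test_independent_matrices_near_zero(self):
        # ~1000 dense positions with independent counts: r should vanish
        layout = GenomeLayout((("chr1", 1_800_000),), 40_000)
        rng = np.random.default_rng(6)
        a = random_matrix(layout, rng, density=1.0)
        b = random_matrix(layout, rng, density=1.0)
        assert abs(matrix_correlation(a, b, "pearson")) < 0.15

    def test_layout_mismatch(self, layout_50):
        other = GenomeLayout((("chr1", 4_000_000),), 40_000)
        with pytest.raises(LayoutError):
            matrix_correlation(random_matrix(layout_50, np.random.default_rng(0)),
                               random_matrix(other, np.random.default_rng(0)))


@pytest.fixture(scope="module")
def synthetic_reference():
    spec = ScenarioSpec(seed=19)
    dom, _, _ = simulate_domain_pair(spec)
    return simulate_contact_matrix(spec.layout(), dom, spec)


class TestLowessBias:
    def test_self_comparison_is_flat(self, synthetic_reference):
        curve = fit_lowess_bias(synthetic_reference, synthetic_reference)
        assert np.max(np.abs(curve.log2_bias)) < 1e-6

    def test_constant_bias_recovered(self, synthetic_reference):
        ref = synthetic_reference
        target = ContactMatrix(ref.layout, ref.bin1, ref.bin2,
                               ref.count * 2 ** 0.5, ref.total_valid_pairs)
        curve = fit_lowess_bias(target, ref, pseudocount=0.0)
        assert np.max(np.abs(curve.log2_bias - 0.5)) < 0.02

    def test_monotone_bias_gives_monotone_curve(self, synthetic_reference):
        ref = synthetic_reference
        k = (ref.bin2 - ref.bin1).astype(float)
        target = ContactMatrix(ref.layout, ref.bin1, ref.bin2,
                               ref.count * 2 ** (0.001 * k * 40), ref.total_valid_pairs)
        curve = fit_lowess_bias(target, ref, pseudocount=0.0)
        # fitted log-ratio must rise with distance overall and locally
        assert curve.log2_bias[-1] > curve.log2_bias[0]
        assert np.all(np.diff(curve.log2_bias) > -0.02)

    def test_smooth_bias_recovery_bounded(self, synthetic_reference):
        """Median |fit - truth| <= 0.05 log2 units for a smooth |g| <= 1 bias."""
        ref = synthetic_reference
        d = ref.distances().astype(float)
        g = np.sin(d / d.max() * np.pi)  # smooth, bounded by 1 in log2 units
        target = ContactMatrix(ref.layout, ref.bin1, ref.bin2,
                               ref.count * 2 ** g, ref.total_valid_pairs)
        curve = fit_lowess_bias(target, ref, smoothing_fraction=0.15, pseudocount=0.0)
        fitted = curve(d[d > 0])
        truth = np.sin(d[d > 0] / d.max() * np.pi)
        assert np.median(np.abs(fitted - truth)) <= 0.05

    def test_apply_zero_curve_is_identity(self, synthetic_reference):
        curve = BiasCurve([40_000.0, 1e6], [0.0, 0.0], 0.3)
        out = apply_bias_correction(synthetic_reference, curve)
        assert np.allclose(out.count, synthetic_reference.count)

    def test_apply_constant_one_halves(self, synthetic_reference):
        curve = BiasCurve([40_000.0, 1e6], [1.0, 1.0], 0.3)
        out = apply_bias_correction(synthetic_reference, curve)
        assert np.allclose(out.count, synthetic_reference.count / 2)
        assert out.total_valid_pairs == synthetic_reference.total_valid_pairs

    def test_correction_is_idempotent(self, synthetic_reference):
        """Refit after correction leaves < 0.05 log2 residual bias."""
        ref = synthetic_reference
        d = ref.distances().astype(float)
        target = ContactMatrix(ref.layout, ref.bin1, ref.bin2,
                               ref.count * 2 ** (0.3 + 0.4 * d / d.max()),
                               ref.total_valid_pairs)
        curve = fit_lowess_bias(target, ref, pseudocount=0.0)
        corrected = apply_bias_correction(target, curve)
        refit = fit_lowess_bias(corrected, ref, pseudocount=0.0)
        assert np.max(np.abs(refit.log2_bias)) < 0.05

    def test_insufficient_overlap(self, layout_50):
        a = ContactMatrix(layout_50, [0], [1], [5.0], 5)
        b = ContactMatrix(layout_50, [0], [1], [5.0], 5)
        with pytest.raises(Exception):
            fit_lowess_bias(a, b)
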