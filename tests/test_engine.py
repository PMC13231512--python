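import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from deltapcc import ExpressionMatrix, delta_pcc_all, delta_pcc_sample, pcc_matrix, precompute_normal_stats

from conftest import make_matrix


def _pair(x, y):
    """One-RNA, one-miRNA matrices over shared samples."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    samples = [f"S{i:03d}" for i in range(x.shape[1])]
    rna = ExpressionMatrix(x, ["X"], samples, "TPM")
    mirna = ExpressionMatrix(y, ["Y"], samples, "CPM")
    return rna, mirna, samples


def brute_delta(rna, mirna, normal_ids, tumour_id):
    """Oracle: dPCC by definition, two brute-force correlations."""
    before, _, _ = pcc_matrix(rna, mirna, normal_ids)
    after, _, _ = pcc_matrix(rna, mirna, list(normal_ids) + [tumour_id])
    return after - before


class TestPccMatrix:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [1, 2, 3, 0], -0.2),
        ],
    )
    def test_known_values(self, x, y, expected):
        rna, mirna, samples = _pair(x, y)
        pcc, _, _ = pcc_matrix(rna, mirna, samples)
        assert pcc.shape == (1, 1)
        assert pcc[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_feature_named(self):
        rna, mirna, samples = _pair([2, 2, 2], [1, 2, 3])
        with pytest.raises(ValueError, match="X"):
            pcc_matrix(rna, mirna, samples)

    def test_needs_two_samples(self):
        rna, mirna, _ = _pair([1, 2], [1, 2])
        with pytest.raises(ValueError, match="at least 2"):
            pcc_matrix(rna, mirna, ["S000"])


class TestPrecompute:
    def test_sufficient_statistics_values(self):
        rna, mirna, samples = _pair([1, 2, 3], [1, 2, 3])
        stats = precompute_normal_stats(rna, mirna, samples)
        assert stats.n == 3
        assert stats.rna_mean[0] == pytest.approx(2.0)
        assert stats.rna_ss[0] == pytest.approx(2.0)
        assert stats.cn[0, 0] == pytest.approx(2.0)
        assert stats.pcc_n[0, 0] == pytest.approx(1.0)

    def test_baseline_consistent_with_brute_force(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        brute, _, _ = pcc_matrix(rna, mirna, normal_ids)
        np.testing.assert_allclose(stats.pcc_n, brute, atol=1e-12)

    def test_constant_feature_rejected(self):
        rna, mirna, samples = _pair([5, 5, 5], [1, 2, 3])
        with pytest.raises(ValueError, match="zero-variance"):
            precompute_normal_stats(rna, mirna, samples)


class TestDeltaPccSample:
    def test_micro_example_exact(self):
        rna, mirna, _ = _pair([1, 2, 3, 4], [1, 2, 3, 0])
        stats = precompute_normal_stats(rna, mirna, ["S000", "S001", "S002"])
        delta = delta_pcc_sample(stats, np.array([4.0]), np.array([0.0]))
        # PCC over 4 points is -0.2, baseline is 1, so dPCC = -1.2
        assert (delta + stats.pcc_n)[0, 0] == pytest.approx(-0.2, abs=1e-12)
        assert delta[0, 0] == pytest.approx(-1.2, abs=1e-12)

    def test_printed_variant_differs_from_brute_force(self):
        rna, mirna, _ = _pair([1, 2, 3, 4], [1, 2, 3, 0])
        stats = precompute_normal_stats(rna, mirna, ["S000", "S001", "S002"])
        printed = delta_pcc_sample(stats, np.array([4.0]), np.array([0.0]), as_printed=True)
        assert (printed + stats.pcc_n)[0, 0] == pytest.approx(-0.4, abs=1e-12)

    def test_mean_point_gives_zero(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        delta = delta_pcc_sample(stats, stats.rna_mean.copy(), stats.mirna_mean.copy())
        np.testing.assert_allclose(delta, 0.0, atol=1e-12)

    def test_perfectly_anticorrelated_baseline_can_only_rise(self):
        rna, mirna, samples = _pair([1, 2, 3], [3, 2, 1])
        stats = precompute_normal_stats(rna, mirna, samples)
        for x, y in [(0.5, 0.5), (10, 0.1), (2, 9)]:
            delta = delta_pcc_sample(stats, np.array([x]), np.array([y]))
            assert delta[0, 0] >= -1e-12

    def test_misaligned_feature_order_rejected(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        with pytest.raises(ValueError, match="order"):
            delta_pcc_sample(stats, stats.rna_mean, stats.mirna_mean,
                             rna_ids=list(reversed(stats.rna_ids)))

    def test_non_finite_input_rejected(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        bad = stats.rna_mean.copy()
        bad[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            delta_pcc_sample(stats, bad, stats.mirna_mean)

    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        n_rna, n_mirna = rng.integers(1, 6), rng.integers(1, 5)
        n = int(rng.integers(2, 12))
        vals_x = np.exp(rng.standard_normal((n_rna, n + 1)))
        vals_y = np.exp(rng.standard_normal((n_mirna, n + 1)))
        samples = [f"S{i:03d}" for i in range(n + 1)]
        rna = ExpressionMatrix(vals_x, [f"R{i}" for i in range(n_rna)], samples, "TPM")
        mirna = ExpressionMatrix(vals_y, [f"M{i}" for i in range(n_mirna)], samples, "CPM")
        stats = precompute_normal_stats(rna, mirna, samples[:n])
        fast = delta_pcc_sample(stats, rna.column(samples[n])[np.argsort(rna.feature_ids)],
                                mirna.column(samples[n])[np.argsort(mirna.feature_ids)])
        slow = brute_delta(rna, mirna, samples[:n], samples[n])
        np.testing.assert_allclose(fast, slow, atol=1e-10)

    @given(st.floats(0.1, 50.0), st.floats(0.0, 20.0), st.integers(0, 2**31 - 1))
    def test_affine_invariance(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.standard_normal(7))
        y = np.exp(rng.standard_normal(7))
        rna1, mirna1, samples = _pair(x, y)
        rna2, _, _ = _pair(a * x + b, y)
        s1 = precompute_normal_stats(rna1, mirna1, samples[:6])
        s2 = precompute_normal_stats(rna2, mirna1, samples[:6])
        d1 = delta_pcc_sample(s1, x[[6]], y[[6]])
        d2 = delta_pcc_sample(s2, a * x[[6]] + b, y[[6]])
        np.testing.assert_allclose(s1.pcc_n, s2.pcc_n, atol=1e-10)
        np.testing.assert_allclose(d1, d2, atol=1e-10)

    @given(st.integers(0, 2**31 - 1))
    def test_symmetric_in_pair_roles(self, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.standard_normal(8))
        y = np.exp(rng.standard_normal(8))
        rna_xy, mirna_xy, samples = _pair(x, y)
        rna_yx, mirna_yx, _ = _pair(y, x)
        sa = precompute_normal_stats(rna_xy, mirna_xy, samples[:7])
        sb = precompute_normal_stats(rna_yx, mirna_yx, samples[:7])
        da = delta_pcc_sample(sa, x[[7]], y[[7]])
        db = delta_pcc_sample(sb, y[[7]], x[[7]])
        np.testing.assert_allclose(da, db.T, atol=1e-12)

    @given(st.integers(0, 2**31 - 1))
    def test_range_bounds(self, seed):
        rng = np.random.default_rng(seed)
        x = np.exp(2 * rng.standard_normal(6))
        y = np.exp(2 * rng.standard_normal(6))
        rna, mirna, samples = _pair(x, y)
        stats = precompute_normal_stats(rna, mirna, samples[:5])
        delta = delta_pcc_sample(stats, x[[5]], y[[5]])
        assert np.abs(stats.pcc_n).max() <= 1 + 1e-12
        assert np.abs(delta + stats.pcc_n).max() <= 1 + 1e-12
        assert np.abs(delta).max() <= 2 + 1e-12


class TestDeltaPccAll:
    def test_empty_tumour_set(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        tensor = delta_pcc_all(stats, rna, mirna, [])
        assert tensor.values.shape == (stats.n_pairs, 0)

    def test_single_sample_matches_delta_pcc_sample(self, random_cohort):
        rna, mirna, normal_ids, tumour_ids = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        tensor = delta_pcc_all(stats, rna, mirna, tumour_ids[:1])
        order_r = np.argsort(rna.feature_ids)
        order_m = np.argsort(mirna.feature_ids)
        single = delta_pcc_sample(stats, rna.column(tumour_ids[0])[order_r],
                                  mirna.column(tumour_ids[0])[order_m])
        np.testing.assert_array_equal(tensor.values[:, 0], single.ravel())

    def test_matches_brute_force_per_sample(self, rng):
        n_rna, n_mirna, n_normal, n_tumour = 20, 10, 15, 5
        total = n_normal + n_tumour
        rna = make_matrix(np.exp(rng.standard_normal((n_rna, total))), "RNA")
        mirna = make_matrix(np.exp(rng.standard_normal((n_mirna, total))), "MIR", unit="CPM")
        normal_ids = rna.sample_ids[:n_normal]
        tumour_ids = rna.sample_ids[n_normal:]
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        tensor = delta_pcc_all(stats, rna, mirna, tumour_ids)
        for j, t in enumerate(tumour_ids):
            slow = brute_delta(rna, mirna, normal_ids, t)
            np.testing.assert_allclose(tensor.values[:, j].reshape(n_rna, n_mirna), slow, atol=1e-10)

    def test_missing_sample_error(self, random_cohort):
        rna, mirna, normal_ids, _ = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        with pytest.raises(KeyError, match="missing"):
            delta_pcc_all(stats, rna, mirna, ["NOPE"])

    def test_row_lookup(self, random_cohort):
        rna, mirna, normal_ids, tumour_ids = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        tensor = delta_pcc_all(stats, rna, mirna, tumour_ids)
        pair = tensor.pair_index[3]
        assert tensor.row(*pair).shape == (len(tumour_ids),)
        with pytest.raises(KeyError):
            tensor.row("nope", "nope")


class TestStateContract:
    def test_state_size_independent_of_n(self):
        sizes = []
        for n in (10, 100, 1000):
            rng = np.random.default_rng(n)
            rna = make_matrix(np.exp(rng.standard_normal((8, n))), "RNA")
            mirna = make_matrix(np.exp(rng.standard_normal((5, n))), "MIR", unit="CPM")
            stats = precompute_normal_stats(rna, mirna, rna.sample_ids)
            sizes.append(stats.nbytes())
        assert len(set(sizes)) == 1

    def test_delta_computable_after_normals_deleted(self, random_cohort):
        rna, mirna, normal_ids, tumour_ids = random_cohort
        stats = precompute_normal_stats(rna, mirna, normal_ids)
        tumour_rna = rna.subset_samples(tumour_ids)
        tumour_mirna = mirna.subset_samples(tumour_ids)
        del rna, mirna  # engine state must suffice from here on
        tensor = delta_pcc_all(stats, tumour_rna, tumour_mirna, tumour_ids)
        assert tensor.values.shape == (stats.n_pairs, len(tumour_ids))
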