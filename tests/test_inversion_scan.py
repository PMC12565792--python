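import numpy as np
import pytest

from invscan.inversion_scan import (InsufficientResolutionError, WindowStat,
                                    chromosome_pca, detect_candidate_regions,
                                    standardize, windowed_weight_variance)
from tests.conftest import make_gm


class TestStandardize:
    def test_closed_form_p_half(self):
        # (d - 2p)/sqrt(2p(1-p)) at p = 0.5: scale is sqrt(0.5)
        gm = make_gm(np.array([[0, 0], [1, 1], [2, 2]]))
        z, kept = standardize(gm, "1")
        s = np.sqrt(2.0)
        np.testing.assert_allclose(z[:, 0], [-s, 0, s])
        assert list(kept) == [0, 1]

    def test_closed_form_homozygote_split(self):
        gm = make_gm(np.array([[0, 0], [0, 1], [2, 2], [2, 1]]))
        z, _ = standardize(gm, "1")
        s = np.sqrt(2.0)
        np.testing.assert_allclose(z[:, 0], [-s, -s, s, s])

    def test_zero_variance_heterozygous_column_dropped(self):
        # p = 0.5 but every sample heterozygous: no information, dropped
        gm = make_gm(np.array([[1, 0], [1, 1], [1, 2], [1, 2]]))
        z, kept = standardize(gm, "1")
        assert z.shape[1] == 1
        assert list(kept) == [1]

    def test_missing_centered_to_zero(self):
        gm = make_gm(np.array([[0, 0], [-1, 1], [2, 2], [2, 1]]))
        z, _ = standardize(gm, "1")
        assert z[1, 0] == 0.0

    def test_all_degenerate_is_fatal(self):
        gm = make_gm(np.ones((4, 2), dtype=np.int8))
        with pytest.raises(ValueError, match="degenerate"):
            standardize(gm, "1")


def brute_force_pca(z):
    """Oracle: explicit eigendecomposition of the SNP covariance matrix."""
    cov = z.T @ z / (z.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestChromosomePCA:
    def test_two_anticorrelated_snps(self):
        # one SNP the complement of the other: PC1 carries all variance
        col = np.array([0, 0, 1, 1, 2, 2, 0, 2], dtype=np.int8)
        gm = make_gm(np.column_stack([col, 2 - col]))
        pca = chromosome_pca(gm, "1", n_components=2)
        assert pca.eigenvalues[0] > 0
        assert pca.eigenvalues[1] == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(np.abs(pca.weights[:, 0]),
                                   [np.sqrt(0.5)] * 2, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_covariance_eigendecomposition(self, seed):
        rng = np.random.default_rng(seed)
        gm = make_gm(rng.integers(0, 3, size=(15, 12)).astype(np.int8))
        pca = chromosome_pca(gm, "1", n_components=5)
        z, _ = standardize(gm, "1")
        evals, evecs = brute_force_pca(z)
        np.testing.assert_allclose(pca.eigenvalues, evals[:5], atol=1e-8)
        for k in range(5):
            dot = abs(evecs[:, k] @ pca.weights[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_weight_columns_orthonormal(self):
        rng = np.random.default_rng(11)
        gm = make_gm(rng.integers(0, 3, size=(30, 40)).astype(np.int8))
        pca = chromosome_pca(gm, "1")
        gram = pca.weights.T @ pca.weights
        np.testing.assert_allclose(gram, np.eye(pca.n_components), atol=1e-8)

    def test_score_variance_equals_eigenvalue(self):
        rng = np.random.default_rng(12)
        gm = make_gm(rng.integers(0, 3, size=(25, 30)).astype(np.int8))
        pca = chromosome_pca(gm, "1")
        np.testing.assert_allclose(np.var(pca.scores, axis=0, ddof=1),
                                   pca.eigenvalues, rtol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(13)
        gm = make_gm(rng.integers(0, 3, size=(20, 25)).astype(np.int8))
        a = chromosome_pca(gm, "1")
        b = chromosome_pca(gm, "1")
        np.testing.assert_array_equal(a.weights, b.weights)
        for k in range(a.n_components):
            i = np.argmax(np.abs(a.weights[:, k]))
            assert a.weights[i, k] > 0

    def test_duplicated_samples_leave_weights_unchanged(self):
        rng = np.random.default_rng(14)
        d = rng.integers(0, 3, size=(12, 20)).astype(np.int8)
        gm1 = make_gm(d)
        gm2 = make_gm(np.vstack([d, d]),
                      sample_ids=[f"T{i}" for i in range(24)])
        p1 = chromosome_pca(gm1, "1", 3)
        p2 = chromosome_pca(gm2, "1", 3)
        np.testing.assert_allclose(np.abs(p1.weights), np.abs(p2.weights),
                                   atol=1e-8)

    def test_no_dominant_component_in_pure_noise(self):
        # i.i.d. genotypes: eigenvalue spectrum has no isolated leader
        ratios = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            gm = make_gm(rng.binomial(2, 0.5, size=(100, 50)).astype(np.int8))
            pca = chromosome_pca(gm, "1", 2)
            ratios.append(pca.eigenvalues[0] / pca.eigenvalues[1])
        assert np.mean(np.array(ratios) < 2.0) >= 0.95


class TestWindowedWeightVariance:
    def test_constant_weights_zero_variance(self):
        pca = _fake_pca(weights=np.full(6, 0.2), pos=np.arange(6) * 1000 + 1)
        ws = windowed_weight_variance(pca, 1, window_bp=10_000, step_bp=7_500)
        assert ws[0].value == pytest.approx(0.0)

    def test_closed_form_three_weights(self):
        pca = _fake_pca(weights=np.array([0.1, 0.2, 0.3]),
                        pos=np.array([1000, 2000, 3000]))
        ws = windowed_weight_variance(pca, 1, window_bp=10_000, step_bp=7_500)
        assert ws[0].value == pytest.approx(0.01)

    def test_small_windows_carry_no_value(self):
        pca = _fake_pca(weights=np.array([0.1, 0.2]),
                        pos=np.array([1000, 2000]))
        ws = windowed_weight_variance(pca, 1, window_bp=5_000, step_bp=5_000,
                                      min_snps=3)
        assert all(w.value is None for w in ws)

    def test_matches_naive_per_window_loop(self):
        rng = np.random.default_rng(21)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 1000, replace=False))
        w = rng.normal(size=1000)
        pca = _fake_pca(weights=w, pos=pos)
        ws = windowed_weight_variance(pca, 1, 10_000, 7_500, min_snps=3)
        for stat in ws:
            inside = w[(pos >= stat.start) & (pos < stat.end)]
            assert stat.n_snps == len(inside)
            if len(inside) >= 3:
                assert stat.value == pytest.approx(np.var(inside, ddof=1))
            else:
                assert stat.value is None


def _fake_pca(weights, pos):
    from invscan.inversion_scan import PCAResult
    w = np.asarray(weights, dtype=float).reshape(-1, 1)
    return PCAResult(chrom="1", scores=np.zeros((3, 1)), weights=w,
                     eigenvalues=np.array([1.0]),
                     snp_index=np.arange(len(pos)),
                     pos=np.asarray(pos, dtype=np.int64))


def _windows(values, start=1, width=100):
    out = []
    for i, v in enumerate(values):
        out.append(WindowStat(chrom="1", component=1, start=start + i * width,
                              end=start + i * width + width, value=v,
                              n_snps=5))
    return out


class TestDetectCandidateRegions:
    def test_flat_profile_yields_no_region(self):
        ws = _windows([1.0] * 50)
        assert detect_candidate_regions(ws) == []

    def test_single_block_detected_with_correct_span(self):
        values = [1.0] * 100 + [10.0] * 50 + [1.0] * 100
        ws = _windows(values)
        regions = detect_candidate_regions(ws)
        assert len(regions) == 1
        r = regions[0]
        assert r.n_windows == 50
        # block occupies windows 100..149 (1-based bp grid, width 100)
        assert r.start == ws[100].start
        assert r.end == ws[149].end

    def test_two_separated_blocks_give_two_regions(self):
        values = [1.0] * 50 + [10.0] * 30 + [1.0] * 20 + [10.0] * 30 + [1.0] * 50
        regions = detect_candidate_regions(_windows(values))
        assert len(regions) == 2

    def test_short_run_below_min_run_ignored(self):
        values = [1.0] * 100 + [10.0] * 5 + [1.0] * 100
        assert detect_candidate_regions(_windows(values), min_run=10) == []

    def test_gap_tolerance_bridges_small_dips(self):
        values = ([1.0] * 50 + [10.0] * 20 + [1.0] * 2 + [10.0] * 20
                  + [1.0] * 50)
        regions = detect_candidate_regions(_windows(values), max_gap=2)
        assert len(regions) == 1
        assert regions[0].n_windows == 40

    def test_regions_never_overlap(self):
        rng = np.random.default_rng(31)
        values = list(rng.exponential(1.0, size=200))
        values[40:70] = [50.0] * 30
        values[100:130] = [40.0] * 30
        regions = detect_candidate_regions(_windows(values))
        spans = sorted((r.start, r.end) for r in regions)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            assert e1 <= s2

    def test_too_few_valued_windows_fatal(self):
        with pytest.raises(InsufficientResolutionError):
            detect_candidate_regions(_windows([1.0] * 10))
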