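import numpy as np
import pytest

from invscan.genotype_io import MISSING
from invscan.inversion_scan import PCAResult, chromosome_pca
from invscan.karyotyping import (call_karyotypes, classical_mds, fuzzy_cmeans,
                                 ibs_matrix, inversion_summary,
                                 karyotype_component, select_top_weight_snps)
from tests.conftest import make_gm


def _pca_with_weights(weights, pos=None):
    w = np.asarray(weights, dtype=float).reshape(-1, 1)
    if pos is None:
        pos = np.arange(1, len(w) + 1) * 100
    return PCAResult(chrom="1", scores=np.zeros((3, 1)), weights=w,
                     eigenvalues=np.array([1.0]),
                     snp_index=np.arange(len(w)),
                     pos=np.asarray(pos, dtype=np.int64))


class TestSelectTopWeightSnps:
    def test_ceiling_rule(self):
        rng = np.random.default_rng(0)
        assert len(select_top_weight_snps(
            _pca_with_weights(rng.normal(size=200)), 1, 0.01)) == 2
        assert len(select_top_weight_snps(
            _pca_with_weights(rng.normal(size=250)), 1, 0.01)) == 3

    def test_largest_absolute_weights_chosen(self):
        w = np.array([0.1, -0.9, 0.2, 0.8, -0.05] + [0.01] * 195)
        idx = select_top_weight_snps(_pca_with_weights(w), 1, 0.01)
        assert set(idx) == {1, 3}

    def test_tie_broken_by_lower_position(self):
        w = np.array([0.5, 0.5, 0.5, 0.5] + [0.01] * 296)
        idx = select_top_weight_snps(_pca_with_weights(w), 1, 0.01)
        assert set(idx) == {0, 1, 2}          # ceil(3.0) = 3, lowest positions


class TestIbsMatrix:
    @pytest.mark.parametrize("a,b,expected", [
        ([0, 1, 2, 1], [0, 1, 2, 1], 1.0),      # identical
        ([0, 0, 0, 0], [2, 2, 2, 2], 0.0),      # opposite homozygotes
        ([0, 0, 0, 0], [1, 1, 1, 1], 0.5),      # one shared allele
    ])
    def test_closed_forms(self, a, b, expected):
        gm = make_gm(np.array([a, b]))
        ibs = ibs_matrix(gm, np.arange(4))
        assert ibs[0, 1] == pytest.approx(expected)
        assert ibs[0, 0] == 1.0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(20, 50)).astype(np.int8)
        d[rng.random(d.shape) < 0.1] = MISSING
        gm = make_gm(d)
        subset = np.arange(50)
        ibs = ibs_matrix(gm, subset)
        for i in range(20):
            for j in range(20):
                num = cnt = 0
                for k in range(50):
                    if d[i, k] != MISSING and d[j, k] != MISSING:
                        num += (2 - abs(int(d[i, k]) - int(d[j, k]))) / 2
                        cnt += 1
                expected = 1.0 if i == j else num / cnt
                assert ibs[i, j] == pytest.approx(expected)

    def test_zero_shared_snps_fatal(self):
        d = np.array([[0, MISSING], [MISSING, 2]], dtype=np.int8)
        with pytest.raises(ValueError, match="zero non-missing"):
            ibs_matrix(make_gm(d), np.arange(2))


class TestClassicalMds:
    def test_collinear_points_recovered_exactly(self):
        # three points on a line at 0, 0.1, 0.3 -> distances reproduced
        x = np.array([0.0, 0.1, 0.3])
        d = np.abs(x[:, None] - x[None, :])
        coords = classical_mds(1.0 - d, k=1)[:, 0]
        rec = np.abs(coords[:, None] - coords[None, :])
        np.testing.assert_allclose(rec, d, atol=1e-8)

    def test_identical_samples_identical_coordinates(self):
        sim = np.array([[1.0, 1.0, 0.4],
                        [1.0, 1.0, 0.4],
                        [0.4, 0.4, 1.0]])
        coords = classical_mds(sim, k=1)
        assert coords[0, 0] == pytest.approx(coords[1, 0], abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_embedding_never_stretches_distances(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(10, 3))
        d = np.linalg.norm(x[:, None] - x[None, :], axis=-1)
        d /= d.max()
        coords = classical_mds(1.0 - d, k=2)
        emb = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        assert (emb <= d + 1e-8).all()

    def test_axis_sign_deterministic(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        d = np.abs(x[:, None] - x[None, :])
        coords = classical_mds(1.0 - d / d.max(), k=1)
        i = np.argmax(np.abs(coords[:, 0]))
        assert coords[i, 0] > 0


class TestFuzzyCmeans:
    def test_three_tight_groups_recovered(self):
        rng = np.random.default_rng(5)
        coords = np.concatenate([rng.normal(c, 0.005, 30)
                                 for c in (-0.25, 0.0, 0.25)])
        u, centers = fuzzy_cmeans(coords, seed=5)
        np.testing.assert_allclose(centers, [-0.25, 0.0, 0.25], atol=0.01)
        assert u.max(axis=1).min() > 0.95

    def test_point_at_center_gets_crisp_membership(self):
        coords = np.array([-1.0, -1.0, -0.9, 0.0, 0.05, 1.0, 1.1, 0.95])
        u, centers = fuzzy_cmeans(coords, seed=0)
        # after convergence, feed a point exactly at a center
        from invscan.karyotyping import _fcm_memberships
        u2 = _fcm_memberships(np.array([centers[0]]), centers, 2.0)
        assert u2[0, 0] == pytest.approx(1.0)
        assert u2[0, 1:].sum() == pytest.approx(0.0)

    def test_duplicated_dataset_same_centers(self):
        rng = np.random.default_rng(6)
        coords = np.concatenate([rng.normal(c, 0.01, 20)
                                 for c in (-0.3, 0.0, 0.3)])
        _, c1 = fuzzy_cmeans(coords, seed=0)
        _, c2 = fuzzy_cmeans(np.concatenate([coords, coords]), seed=0)
        np.testing.assert_allclose(c1, c2, atol=1e-6)

    def test_memberships_sum_to_one(self):
        rng = np.random.default_rng(7)
        u, _ = fuzzy_cmeans(rng.normal(size=50), seed=7)
        np.testing.assert_allclose(u.sum(axis=1), 1.0, atol=1e-8)

    def test_skewed_cluster_sizes_still_found(self):
        # majority cluster holds > 50% of points: the quantile start alone
        # would trap two centers inside it
        rng = np.random.default_rng(8)
        coords = np.concatenate([rng.normal(-0.15, 0.01, 110),
                                 rng.normal(0.15, 0.01, 80),
                                 rng.normal(0.45, 0.01, 10)])
        _, centers = fuzzy_cmeans(coords, seed=8)
        np.testing.assert_allclose(centers, [-0.15, 0.15, 0.45], atol=0.02)

    def test_too_few_distinct_values_fatal(self):
        with pytest.raises(ValueError, match="distinct"):
            fuzzy_cmeans(np.array([1.0, 1.0, 2.0, 2.0]))


def _crisp_memberships(labels):
    u = np.zeros((len(labels), 3))
    u[np.arange(len(labels)), labels] = 1.0
    return u


class TestCallKaryotypes:
    def test_orientation_larger_homozygote_cluster_is_aa(self):
        labels = np.array([0] * 150 + [1] * 60 + [2] * 10)
        u = _crisp_memberships(labels)
        centers = np.array([-0.5, 0.0, 0.5])
        coords = centers[labels]
        ids = [f"S{i}" for i in range(220)]
        calls, retained, reason = call_karyotypes(ids, "1:C1", u, centers,
                                                  coords)
        assert retained and reason == ""
        assert calls[0].genotype == "AA"
        assert calls[219].genotype == "BB"

    def test_orientation_flips_when_minor_cluster_is_low(self):
        labels = np.array([0] * 10 + [1] * 60 + [2] * 150)
        u = _crisp_memberships(labels)
        centers = np.array([-0.5, 0.0, 0.5])
        calls, retained, _ = call_karyotypes(
            [f"S{i}" for i in range(220)], "1:C1", u, centers, centers[labels])
        assert retained
        assert calls[0].genotype == "BB"       # low cluster is the minor one
        assert calls[219].genotype == "AA"

    def test_empty_cluster_rejected(self):
        labels = np.array([0] * 100 + [2] * 100)
        u = _crisp_memberships(labels)
        centers = np.array([-0.5, 0.0, 0.5])
        _, retained, reason = call_karyotypes(
            [f"S{i}" for i in range(200)], "1:C1", u, centers, centers[labels])
        assert not retained and reason == "cluster size"

    def test_bad_center_spacing_rejected(self):
        labels = np.array([0] * 100 + [1] * 50 + [2] * 50)
        u = _crisp_memberships(labels)
        centers = np.array([-0.5, -0.4, 0.5])  # relative position 0.1
        _, retained, reason = call_karyotypes(
            [f"S{i}" for i in range(200)], "1:C1", u, centers, centers[labels])
        assert not retained and reason == "center spacing"

    def test_weak_memberships_rejected(self):
        u = np.full((90, 3), 1 / 3.0)
        u[:30, 0] += 0.02
        u[30:60, 1] += 0.02
        u[60:, 2] += 0.02
        u /= u.sum(axis=1, keepdims=True)
        centers = np.array([-0.5, 0.0, 0.5])
        coords = np.repeat(centers, 30)
        _, retained, reason = call_karyotypes(
            [f"S{i}" for i in range(90)], "1:C1", u, centers, coords)
        assert not retained and reason == "mean membership"


class TestInversionSummary:
    @pytest.mark.parametrize("counts,q,f", [
        ((81, 18, 1), 0.10, 0.0),
        ((50, 0, 50), 0.50, 1.0),
        ((0, 100, 0), 0.50, -1.0),
    ])
    def test_hardy_weinberg_closed_forms(self, counts, q, f):
        from invscan.karyotyping import KaryotypeCall
        calls = []
        for geno, n in zip(("AA", "AB", "BB"), counts):
            calls += [KaryotypeCall(f"S{len(calls) + i}", "x", geno,
                                    np.ones(3) / 3, 0.0) for i in range(n)]
        inv_maf, f_index = inversion_summary(calls)
        assert inv_maf == pytest.approx(q)
        assert f_index == pytest.approx(f)


class TestKaryotypeComponent:
    def test_recovers_simulated_karyotypes(self, small_sim):
        gm, truth, _, cfg = small_sim
        from invscan.variant_filtering import filter_variants, ld_prune
        from invscan.evaluation import karyotype_concordance
        pruned = ld_prune(filter_variants(gm))
        pca = chromosome_pca(pruned, cfg.chrom)
        inv = karyotype_component(pruned, pca, 1, seed=1)
        assert inv.retained, inv.reason
        conc = karyotype_concordance(inv, truth.karyotypes[0],
                                     pruned.sample_ids)
        assert conc >= 0.95
        assert 0.0 <= inv.inv_maf <= 0.5
        assert -1.0 <= inv.f_index <= 1.0
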