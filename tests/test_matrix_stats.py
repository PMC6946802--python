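import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix

from phylosym import matrix_stats as ms
from tests.conftest import random_distance_matrix


def brute_force_mantel(x, y):
    """Independent oracle: enumerate all label permutations of y, count r >= obs."""
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    tx = x[iu]
    r_obs = np.corrcoef(tx, y[iu])[0, 1]
    hits = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = np.corrcoef(tx, y[np.ix_(p, p)][iu])[0, 1]
        hits += r >= r_obs - 1e-12
        total += 1
    return r_obs, hits / total


class TestMantel:
    def test_identity_gives_r_one(self):
        dm = random_distance_matrix(np.random.default_rng(0), 6)
        res = ms.mantel(dm, dm, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_affine_reversal_gives_minus_one(self):
        rng = np.random.default_rng(1)
        dx = random_distance_matrix(rng, 6)
        c = dx.data.max() + 1.0
        rev = c - dx.data
        np.fill_diagonal(rev, 0.0)
        dy = DistanceMatrix(rev, ids=dx.ids)
        assert ms.mantel(dx, dy, n_perm=99, seed=1).r == pytest.approx(-1.0)

    def test_exhaustive_p_matches_enumeration_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            dx = random_distance_matrix(rng, 4)
            dy = random_distance_matrix(rng, 4, ids=list(dx.ids))
            res = ms.mantel(dx, dy, exhaustive=True)
            r_want, p_want = brute_force_mantel(dx.data, dy.data)
            assert res.r == pytest.approx(r_want, abs=1e-12)
            assert res.p == pytest.approx(p_want, abs=0)
            assert res.n_perm == 24

    def test_symmetry_in_r(self):
        rng = np.random.default_rng(3)
        dx = random_distance_matrix(rng, 8)
        dy = random_distance_matrix(rng, 8, ids=list(dx.ids))
        assert ms.mantel(dx, dy, n_perm=9, seed=0).r == pytest.approx(
            ms.mantel(dy, dx, n_perm=9, seed=0).r, abs=1e-12
        )

    def test_label_order_invariance(self):
        rng = np.random.default_rng(4)
        dx = random_distance_matrix(rng, 7)
        dy = random_distance_matrix(rng, 7, ids=list(dx.ids))
        shuffled_ids = list(dy.ids)[::-1]
        dy_shuffled = dy.filter(shuffled_ids)
        assert ms.mantel(dx, dy_shuffled, n_perm=99, seed=5).r == pytest.approx(
            ms.mantel(dx, dy, n_perm=99, seed=5).r, abs=1e-12
        )

    def test_constant_triangle_rejected(self):
        flat = DistanceMatrix(1 - np.eye(4), ids=list("abcd"))
        dm = random_distance_matrix(np.random.default_rng(0), 4, ids=list("abcd"))
        with pytest.raises(ValueError, match="undefined correlation"):
            ms.mantel(flat, dm, n_perm=9, seed=0)

    def test_p_floor_is_one_over_nperm_plus_one(self):
        dm = random_distance_matrix(np.random.default_rng(0), 10)
        res = ms.mantel(dm, dm, n_perm=99, seed=2)
        assert res.p >= 1 / 100
    def test_agrees_with_skbio_r(self):
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(11)
        dx = random_distance_matrix(rng, 12)
        dy = random_distance_matrix(rng, 12, ids=list(dx.ids))
        r_ref, _, _ = skbio_mantel(dx, dy, permutations=0)
        assert ms.mantel(dx, dy, n_perm=9, seed=0).r == pytest.approx(r_ref, abs=1e-12)


class TestPartialMantel:
    def test_matches_closed_form_partial_correlation(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            dx = random_distance_matrix(rng, 4)
            dy = random_distance_matrix(rng, 4, ids=list(dx.ids))
            dz = random_distance_matrix(rng, 4, ids=list(dx.ids))
            iu = np.triu_indices(4, k=1)
            r_xy = np.corrcoef(dx.data[iu], dy.data[iu])[0, 1]
            r_xz = np.corrcoef(dx.data[iu], dz.data[iu])[0, 1]
            r_yz = np.corrcoef(dy.data[iu], dz.data[iu])[0, 1]
            want = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
            got = ms.partial_mantel(dx, dy, dz, n_perm=9, seed=0).r
            assert got == pytest.approx(want, abs=1e-10)

    def test_conditioning_on_dy_itself_kills_signal(self):
        rng = np.random.default_rng(22)
        dx = random_distance_matrix(rng, 10)
        dy = random_distance_matrix(rng, 10, ids=list(dx.ids))
        res = ms.partial_mantel(dx, dy, dy, n_perm=9, seed=0)
        assert abs(res.r) < 1e-10

    def test_independent_conditioner_leaves_r_nearly_unchanged(self):
        rng = np.random.default_rng(23)
        deltas = []
        for _ in range(10):
            dx = random_distance_matrix(rng, 30)
            dy = random_distance_matrix(rng, 30, ids=list(dx.ids))
            dz = random_distance_matrix(rng, 30, ids=list(dx.ids))
            simple = ms.mantel(dx, dy, n_perm=9, seed=0).r
            partial = ms.partial_mantel(dx, dy, dz, n_perm=9, seed=0).r
            deltas.append(abs(simple - partial))
        assert np.median(deltas) < 0.05


class TestMrm:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(31)
        dx = random_distance_matrix(rng, 8)
        dy = DistanceMatrix(2.0 * dx.data, ids=dx.ids)
        res = ms.mrm(dy, [dx], n_perm=9, seed=0)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)
        assert res.coefficients[1] == pytest.approx(2.0, abs=1e-10)

    def test_single_predictor_r2_equals_mantel_r_squared(self):
        rng = np.random.default_rng(32)
        dx = random_distance_matrix(rng, 15)
        dy = random_distance_matrix(rng, 15, ids=list(dx.ids))
        r = ms.mantel(dx, dy, n_perm=9, seed=0).r
        r2 = ms.mrm(dy, [dx], n_perm=9, seed=0).r2
        assert r2 == pytest.approx(r**2, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(33)
        dx = random_distance_matrix(rng, 8)
        dx2 = DistanceMatrix(3.0 * dx.data, ids=dx.ids)
        dy = random_distance_matrix(rng, 8, ids=list(dx.ids))
        with pytest.raises(ValueError, match="collinear"):
            ms.mrm(dy, [dx, dx2], n_perm=9, seed=0)

    def test_null_type_one_error_rate_calibrated(self):
        """dy independent of dx: p_overall rejects ~5% at alpha=0.05."""
        rng = np.random.default_rng(34)
        n_reps, hits = 500, 0
        for rep in range(n_reps):
            dx = random_distance_matrix(rng, 30)
            dy = random_distance_matrix(rng, 30, ids=list(dx.ids))
            res = ms.mrm(dy, [dx], n_perm=199, seed=int(rng.integers(2**31)))
            hits += res.p_overall <= 0.05
        assert 0.03 <= hits / n_reps <= 0.07

    def test_noise_predictor_usually_nonsignificant(self):
        rng = np.random.default_rng(35)
        nonsig = 0
        n_reps = 50
        for rep in range(n_reps):
            dx1 = random_distance_matrix(rng, 20)
            noise = random_distance_matrix(rng, 20, ids=list(dx1.ids))
            jitter = random_distance_matrix(rng, 20, ids=list(dx1.ids))
            dy = DistanceMatrix(dx1.data + 0.05 * jitter.data, ids=dx1.ids)
            res = ms.mrm(dy, [dx1, noise], n_perm=199, seed=rep)
            nonsig += res.p_coefficients[1] > 0.05
        assert nonsig / n_reps >= 0.9


class TestPermanova:
    def test_toy_pseudo_f_matches_direct_formula(self):
        d = np.array(
            [
                [0.0, 0.1, 1.0, 1.0],
                [0.1, 0.0, 1.0, 1.0],
                [1.0, 1.0, 0.0, 0.1],
                [1.0, 1.0, 0.1, 0.0],
            ]
        )
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = ms.permanova(dm, ["g1", "g1", "g2", "g2"], n_perm=9, seed=0)
        assert res.pseudo_f == pytest.approx(199.0, abs=1e-9)

    def test_agrees_with_skbio_f(self):
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(41)
        dm = random_distance_matrix(rng, 12)
        groups = ["a"] * 6 + ["b"] * 6
        ref = skbio_permanova(dm, grouping=groups, permutations=0)
        res = ms.permanova(dm, groups, n_perm=9, seed=0)
        assert res.pseudo_f == pytest.approx(ref["test statistic"], abs=1e-10)

    def test_null_type_one_error_rate_calibrated(self):
        rng = np.random.default_rng(42)
        n_reps, hits = 500, 0
        for rep in range(n_reps):
            dm = random_distance_matrix(rng, 20)
            groups = list(rng.permutation(["a"] * 10 + ["b"] * 10))
            res = ms.permanova(dm, groups, n_perm=199, seed=int(rng.integers(2**31)))
            hits += res.p <= 0.05
        assert 0.03 <= hits / n_reps <= 0.07

    def test_equal_distances_flagged_degenerate(self):
        dm = DistanceMatrix(1 - np.eye(6), ids=list("abcdef"))
        res = ms.permanova(dm, ["a"] * 3 + ["b"] * 3, n_perm=9, seed=0)
        assert res.degenerate

    def test_single_group_rejected(self):
        dm = random_distance_matrix(np.random.default_rng(0), 4)
        with pytest.raises(ValueError, match="2 groups"):
            ms.permanova(dm, ["g"] * 4, n_perm=9, seed=0)
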