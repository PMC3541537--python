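"""Univariate rules and the projection-based bivariate detector."""

import numpy as np
import pytest
from scipy import stats

from robustcorr import (bivariate_outliers, boxplot_outliers, carling_k,
                        ideal_fourths, madmedian_outliers, project_distances,
                        s_outliers)
from robustcorr.outliers import GATE_0975


class TestIdealFourths:
    def test_hand_evaluation_1_to_11(self):
        # j = 3, g ~ 0.1667: q1 = 0.8333*3 + 0.1667*4
        q1, q3 = ideal_fourths(np.arange(1.0, 12.0))
        assert q1 == pytest.approx(3 + 1 / 6, abs=1e-10)
        assert q3 == pytest.approx(9 - 1 / 6, abs=1e-10)

    def test_constant_vector(self):
        q1, q3 = ideal_fourths(np.full(10, 7.0))
        assert q1 == q3 == 7.0

    def test_symmetric_sample_centered_on_median(self, rng):
        v = rng.standard_normal(51)
        v = np.concatenate([v, -v])  # exactly symmetric about 0
        q1, q3 = ideal_fourths(v)
        assert q1 + q3 == pytest.approx(2 * np.median(v), abs=1e-10)

    def test_too_few(self):
        with pytest.raises(ValueError):
            ideal_fourths([1.0, 2.0, 3.0])


class TestCarling:
    def test_n20(self):
        assert carling_k(20) == pytest.approx((352.6 - 23.64) / (154.8 - 3.71))

    def test_limit(self):
        assert carling_k(10 ** 9) == pytest.approx(17.63 / 7.74, rel=1e-6)

    def test_small_n_positive(self):
        assert carling_k(4) > 0


class TestUnivariateRules:
    def test_boxplot_flags_obvious_outlier(self):
        v = np.concatenate([np.arange(1.0, 10.0), [1000.0]])
        rep = boxplot_outliers(v)
        assert np.where(rep.flags)[0].tolist() == [9]

    def test_boxplot_anscombe(self, quartet):
        x1, y1 = quartet[0]
        assert boxplot_outliers(x1).n_flagged == 0
        assert boxplot_outliers(y1).n_flagged == 0
        x3, y3 = quartet[2]
        rep = boxplot_outliers(y3)
        assert y3[rep.flags].tolist() == [12.74]

    def test_boxplot_degenerate_iqr(self):
        rep = boxplot_outliers(np.full(10, 2.0))
        assert rep.degenerate and rep.n_flagged == 0

    def test_madmedian_hand_trace(self):
        rep = madmedian_outliers(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert np.where(rep.flags)[0].tolist() == [4]

    def test_madmedian_anscombe_pair2_y(self, quartet):
        _, y2 = quartet[1]
        rep = madmedian_outliers(y2)
        assert sorted(y2[rep.flags].tolist()) == [3.10, 4.74]

    def test_madmedian_constant_degenerate(self):
        assert madmedian_outliers(np.full(8, 1.0)).degenerate

    def test_s_outliers_hand_trace(self):
        rep = s_outliers(np.array([1.0, 2.0, 3.0, 4.0, 100.0]))
        assert np.where(rep.flags)[0].tolist() == [4]

    def test_s_outliers_constant_degenerate(self):
        assert s_outliers(np.full(6, 3.0)).degenerate

    def test_s_outliers_normal_flag_rate(self, rng):
        v = rng.standard_normal(1000)
        rate = s_outliers(v).n_flagged / 1000
        # nominal two-sided tail mass of the 2.2414 gate is ~2.5%
        assert 0.005 < rate < 0.06

    def test_no_rule_flags_mid_range_values(self, rng):
        v = rng.uniform(-0.4, 0.4, 50)  # everything well inside median +/- IQR/2
        for fn in (boxplot_outliers, madmedian_outliers, s_outliers):
            assert fn(v).n_flagged == 0


class TestProjectDistances:
    def test_self_projection_is_distance_to_center(self, rng):
        P = rng.standard_normal((8, 2))
        c = np.array([0.3, -0.2])
        D = project_distances(P[:, 0], P[:, 1], c)
        np.testing.assert_allclose(np.diag(D),
                                   np.linalg.norm(P - c, axis=1), atol=1e-12)

    def test_translation_invariance(self, rng):
        P = rng.standard_normal((9, 2))
        c = P.mean(axis=0)
        D1 = project_distances(P[:, 0], P[:, 1], c)
        Q = P + [100.0, -50.0]
        D2 = project_distances(Q[:, 0], Q[:, 1], c + [100.0, -50.0])
        np.testing.assert_allclose(D1, D2, atol=1e-9)

    def test_rotation_invariance(self, rng):
        P = rng.standard_normal((9, 2))
        th = 0.7
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        c = np.array([0.1, 0.2])
        D1 = project_distances(P[:, 0], P[:, 1], c)
        Q = P @ R.T
        D2 = project_distances(Q[:, 0], Q[:, 1], R @ c)
        np.testing.assert_allclose(D1, D2, atol=1e-10)

    def test_matches_bruteforce_loop(self, rng):
        P = rng.standard_normal((8, 2))
        c = np.array([0.5, 0.5])
        D = project_distances(P[:, 0], P[:, 1], c, signed=True)
        for i in range(8):
            B = P[i] - c
            bot = B @ B
            for j in range(8):
                w = (P[j] - c) @ B / bot
                assert D[i, j] == pytest.approx(w * np.sqrt(bot), abs=1e-12)

    def test_zero_direction_rows_are_zero(self):
        P = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 0.0], [0.0, 2.0], [3.0, 3.0]])
        D = project_distances(P[:, 0], P[:, 1], np.zeros(2))
        assert (D[0] == 0).all()


class TestBivariateOutliers:
    def test_anscombe_pair4_flags_exactly_the_outlier(self, quartet):
        x4, y4 = quartet[3]
        rep = bivariate_outliers(x4, y4)
        assert np.where(rep.flags)[0].tolist() == [7]
        assert (x4[7], y4[7]) == (19.0, 12.5)

    def test_anscombe_pairs_123_unflagged(self, quartet):
        for x, y in quartet[:3]:
            assert bivariate_outliers(x, y).n_flagged == 0

    def test_translation_invariance(self, quartet):
        x4, y4 = quartet[3]
        rep1 = bivariate_outliers(x4, y4)
        rep2 = bivariate_outliers(x4 + 37.0, y4 - 11.0)
        np.testing.assert_array_equal(rep1.flags, rep2.flags)

    def test_monotone_in_distance_along_ray(self, rng):
        """Pushing a flagged point further from the center keeps it flagged."""
        P = rng.standard_normal((19, 2))
        P = np.vstack([P, [6.0, 6.0]])
        rep = bivariate_outliers(P[:, 0], P[:, 1], seed=1)
        assert rep.flags[-1]
        center = rep.thresholds["center"]
        for factor in (2.0, 5.0, 20.0):
            Q = P.copy()
            Q[-1] = center + factor * (P[-1] - center)
            rep2 = bivariate_outliers(Q[:, 0], Q[:, 1], seed=1)
            assert rep2.flags[-1]

    def test_gate_default(self, quartet):
        x, y = quartet[0]
        rep = bivariate_outliers(x, y)
        assert rep.gate_constant == pytest.approx(
            np.sqrt(stats.chi2.ppf(0.975, 1)))
        assert GATE_0975 == pytest.approx(2.2414, abs=5e-4)

    def test_madmedian_variant_flags_at_least_boxplot_on_average(self, rng):
        """The MAD-median projection rule is the less specific one."""
        n_box = n_mad = 0
        for i in range(30):
            r = np.random.default_rng(i)
            P = r.standard_normal((10, 2))
            n_box += bivariate_outliers(P[:, 0], P[:, 1], rule="boxplot").n_flagged
            n_mad += bivariate_outliers(P[:, 0], P[:, 1], rule="madmedian").n_flagged
        assert n_mad > n_box
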