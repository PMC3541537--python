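"""Population generators, the Monte-Carlo harness and the worked examples."""

import numpy as np
import pytest

from robustcorr import (N_GRID_FULL, PopulationSpec,
                        compare_methods_median_diff, effect_size_bias,
                        gen_bivariate_normal, gen_contaminated,
                        rotating_outlier_demo, run_fpr_power, schwarzkopf_sim,
                        skipped)
from robustcorr.simulation import _batch_skipped


class TestGenerators:
    def test_rho_one_perfect_line(self):
        x, y = gen_bivariate_normal(50, 1.0, seed=0)
        np.testing.assert_allclose(x, y, atol=1e-12)

    def test_rho_zero_large_sample(self):
        x, y = gen_bivariate_normal(100_000, 0.0, seed=1)
        assert abs(np.corrcoef(x, y)[0, 1]) < 3 / np.sqrt(100_000)

    def test_rho_half_large_sample(self):
        rho = 0.5
        x, y = gen_bivariate_normal(100_000, rho, seed=2)
        tol = 3 * (1 - rho ** 2) / np.sqrt(100_000)
        assert abs(np.corrcoef(x, y)[0, 1] - rho) < tol

    def test_seed_determinism(self):
        a = gen_bivariate_normal(20, 0.3, seed=5)
        b = gen_bivariate_normal(20, 0.3, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_contaminated_prop_zero_equals_clean(self):
        spec = PopulationSpec(0.4, "none")
        a = gen_contaminated(30, spec, seed=3)
        b = gen_bivariate_normal(30, 0.4, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_bivariate_mixture_moments(self):
        """Population correlation of the 10% [6,6] mixture at rho = 0.

        Closed form: E[XY] = 0.9*0 + 0.1*36 = 3.6, E[X] = E[Y] = 0.6,
        Var = 1 + 0.1*36 - 0.36 = 4.24, so corr = 3.24/4.24 ~ 0.764.
        """
        spec = PopulationSpec(0.0, "bivariate")
        x, y = gen_contaminated(200_000, spec, seed=4)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(3.24 / 4.24, abs=0.01)

    def test_marginal_mixture_uncorrelated(self):
        spec = PopulationSpec(0.0, "marginal")
        x, y = gen_contaminated(200_000, spec, seed=5)
        assert abs(np.corrcoef(x, y)[0, 1]) < 0.01

    def test_outlier_count_is_round_prop_n(self):
        spec = PopulationSpec(0.0, "bivariate")
        x, y = gen_contaminated(50, spec, seed=6)
        # outliers sit near [6, 6]; with the bulk at the origin a 3-sigma
        # cut on x + y separates them
        assert int(np.sum(x + y > 6)) == 5

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec(1.5, "none")
        with pytest.raises(ValueError):
            PopulationSpec(0.0, "weird")


class TestHarness:
    def test_rho_one_always_rejected(self):
        res = run_fpr_power(PopulationSpec(1.0, "none"), methods=("pearson",),
                            n_grid=(10, 30), n_reps=200, seed=0)
        assert (res.table.rejection_rate == 1.0).all()

    def test_replicates_shared_across_methods(self):
        res = run_fpr_power(PopulationSpec(0.5, "none"),
                            methods=("pearson", "skipped-pearson"),
                            n_grid=(15,), n_reps=150, seed=1,
                            keep_replicates=True)
        rp = res.replicates[(15, "pearson")]
        rs = res.replicates[(15, "skipped-pearson")]
        # same draws: on replicates where nothing was removed the two agree
        same = np.isfinite(rs) & (np.abs(rp - rs) < 1e-12)
        assert same.mean() > 0.3

    def test_power_nondecreasing_in_n(self):
        res = run_fpr_power(PopulationSpec(0.5, "none"), methods=("pearson",),
                            n_grid=(10, 20, 50, 100), n_reps=1000, seed=2)
        rates = res.table.sort_values("n").rejection_rate.to_numpy()
        assert np.all(np.diff(rates) > -0.04)

    def test_batch_skipped_matches_single_sample_api(self, rng):
        for n in (10, 16):
            S = rng.standard_normal((25, n, 2))
            r, rej, _ = _batch_skipped(S, np.random.default_rng(0))
            for i in range(25):
                res = skipped(S[i, :, 0], S[i, :, 1], seed=0)
                if np.isnan(res.r):
                    assert np.isnan(r[i])
                else:
                    assert res.r == pytest.approx(r[i], abs=1e-10)
                    assert res.h == int(rej[i])


class TestEffectSizeAndComparison:
    def test_bias_ci_degenerate(self):
        from robustcorr import SimulationGridResult
        import pandas as pd
        res = SimulationGridResult(pd.DataFrame(),
                                   {(10, "pearson"): np.full(500, 0.5)})
        df = effect_size_bias(res, 0.5)
        assert df.ci_lower[0] == df.ci_upper[0] == 0.0
        assert df.estimates_rho[0]

    def test_gaussian_bias_cis_cover_zero(self):
        res = run_fpr_power(PopulationSpec(0.0, "none"),
                            methods=("pearson", "bend"),
                            n_grid=(20, 50), n_reps=1000, seed=3,
                            keep_replicates=True)
        df = effect_size_bias(res, 0.0)
        assert df.estimates_rho.all()

    def test_median_diff_identical_inputs(self):
        r = np.random.default_rng(0).uniform(-1, 1, 500)
        lo, hi, h = compare_methods_median_diff(r, r, seed=0)
        assert lo == hi == 0.0 and h == 0

    def test_median_diff_constant_shift(self):
        r = np.random.default_rng(1).uniform(-0.5, 0.5, 500)
        lo, hi, h = compare_methods_median_diff(r + 0.01, r, seed=1)
        assert lo == pytest.approx(0.01, abs=1e-9)
        assert hi == pytest.approx(0.01, abs=1e-9)
        assert h == 1


class TestSchwarzkopf:
    def test_control_run_near_nominal(self):
        df = schwarzkopf_sim("control", n_reps=2000, seed=0)
        rates = df.set_index("method").type_I
        # no contamination: Pearson exact 5%; skipped/box-plot close to it
        assert rates["pearson"] == pytest.approx(0.05, abs=0.02)
        assert rates["skipped-boxplot"] == pytest.approx(0.05, abs=0.025)

    def test_output_shape(self):
        df = schwarzkopf_sim("univariate", n_reps=300, seed=1)
        assert set(df.method) == {"pearson", "pearson-mcd-removal",
                                  "skipped-boxplot", "skipped-madmedian"}
        assert ((df.type_I >= 0) & (df.type_I <= 1)).all()

    def test_invalid_kind(self):
        with pytest.raises(ValueError):
            schwarzkopf_sim("other")


class TestRotatingOutlier:
    def test_angle_zero_perfect_correlation(self):
        _, _, pr, _ = rotating_outlier_demo(0.2, 0.0)
        assert pr.r == pytest.approx(1.0, abs=1e-12)

    def test_slope02_angle80(self):
        x, y, pr, sk = rotating_outlier_demo(0.2, 80.0)
        assert x[-1] == 9.0
        assert -394.0 < y[-1] < -393.0
        assert pr.r == pytest.approx(-0.51, abs=0.01)
        assert sk.r == pytest.approx(1.0, abs=1e-9)
        assert sk.h == 1 and sk.n_used == 9

    def test_vertical_rotation_rejected(self):
        with pytest.raises(ValueError, match="vertical"):
            rotating_outlier_demo(1.0, 45.0)


class TestAnscombeFixture:
    def test_shared_first_order_statistics(self, quartet):
        for x, y in quartet:
            assert np.mean(x) == pytest.approx(9.0)
            assert np.mean(y) == pytest.approx(7.5, abs=0.005)
            assert np.var(x, ddof=1) == pytest.approx(11.0)
            assert np.var(y, ddof=1) == pytest.approx(4.12, abs=0.01)

    def test_pair4_structure(self, quartet):
        x4, _ = quartet[3]
        assert np.sum(x4 == 8.0) == 10 and np.sum(x4 == 19.0) == 1

    def test_grid_matches_study(self):
        assert len(N_GRID_FULL) == 14
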