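import subprocess

import numpy as np
import pytest

from eegwmnet.stats import (
    bh_adjust,
    fit_age_gam,
    partial_corr,
    screen_correlations,
)
from oracles import partial_corr_identity


class TestGamFit:
    def test_penalty_shrinks_linear_data_to_one_edf(self):
        rng = np.random.default_rng(0)
        age = np.sort(rng.uniform(20, 81, 200))
        y = 3.0 + 0.05 * age + rng.normal(0, 0.01, 200)
        fit = fit_age_gam(y, age, k=10)
        assert 1.0 <= fit.edf <= 1.2

    def test_large_penalty_reduces_to_least_squares_line(self):
        """With the penalty sent to infinity the fit is the OLS straight line."""
        rng = np.random.default_rng(1)
        age = np.sort(rng.uniform(20, 81, 60))
        y = 10.0 - 0.2 * age + rng.normal(0, 1.0, 60)
        fit = fit_age_gam(y, age, k=10, smoothing_parameter=1e15)
        design = np.column_stack([np.ones(60), age])
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(fit.fitted, design @ coef, atol=1e-6)
        assert fit.edf == pytest.approx(1.0, abs=1e-6)

    def test_matches_mgcv_on_shared_dataset(self, tmp_path):
        """R mgcv (independent reference implementation) must agree."""
        rng = np.random.default_rng(7)
        age = np.sort(rng.uniform(20, 81, 39))
        y = 90 - 0.1 * (age - 20) - 0.4 * np.maximum(age - 50, 0) + rng.normal(0, 3, 39)
        dat = tmp_path / "dat.csv"
        np.savetxt(dat, np.column_stack([age, y]), delimiter=",",
                   header="age,y", comments="")
        fit = fit_age_gam(y, age, k=12)
        script = (
            f"d <- read.csv('{dat}'); library(mgcv); "
            "m <- gam(y ~ s(age, bs='cr', k=12), data=d, method='REML'); "
            "s <- summary(m); "
            "cat(s$s.table[1,1], s$s.table[1,2], s$s.table[1,3], "
            "s$p.table[1,1], s$p.table[1,2], sep=',')"
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        edf_r, refdf_r, f_r, b0_r, se_r = map(float, out.stdout.strip().split(","))
        assert fit.edf == pytest.approx(edf_r, abs=0.02)
        assert fit.ref_df == pytest.approx(refdf_r, abs=0.02)
        assert fit.f_stat == pytest.approx(f_r, rel=0.02)
        assert fit.intercept_estimate == pytest.approx(b0_r, abs=1e-3)
        assert fit.intercept_se == pytest.approx(se_r, abs=1e-3)

    def test_edf_bounded_by_basis_dimension(self):
        rng = np.random.default_rng(2)
        age = rng.uniform(20, 81, 100)
        y = np.sin(age / 5.0) + rng.normal(0, 0.05, 100)
        fit = fit_age_gam(y, age, k=12)
        assert 0 < fit.edf <= 11
        assert 0 <= fit.p_smooth <= 1 and 0 <= fit.intercept_p <= 1

    def test_guards(self):
        rng = np.random.default_rng(3)
        age = rng.uniform(20, 81, 8)
        with pytest.raises(ValueError):
            fit_age_gam(rng.standard_normal(8), age, k=10)  # n < k
        age = rng.uniform(20, 81, 50)
        with pytest.raises(ValueError):
            fit_age_gam(np.full(50, 3.0), age, k=10)  # constant outcome

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(4)
        age = rng.uniform(20, 81, 60)
        y = 0.1 * age + rng.normal(0, 1, 60)
        y[5] = np.nan
        fit = fit_age_gam(y, age, k=10)
        assert fit.n == 59


class TestPartialCorrelation:
    def test_matches_closed_form_identity(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            z = rng.standard_normal(50)
            x = 0.5 * z + rng.standard_normal(50)
            y = -0.3 * z + rng.standard_normal(50)
            pc = partial_corr(x, y, z)
            assert pc.r == pytest.approx(partial_corr_identity(x, y, z), abs=1e-12)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(6)
        z = rng.uniform(20, 81, 40)
        x = 0.02 * z + rng.standard_normal(40)
        y = -0.01 * z + 0.5 * x + rng.standard_normal(40)
        pc = partial_corr(x, y, z)
        ref = pg.partial_corr(
            pd.DataFrame({"x": x, "y": y, "z": z}), x="x", y="y", covar="z"
        )
        assert pc.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert pc.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_true_null_partial_correlation_vanishes_at_large_n(self):
        rng = np.random.default_rng(7)
        n = 5000
        age = rng.uniform(20, 81, n)
        x = 0.05 * age + rng.standard_normal(n)
        y = -0.03 * age + rng.standard_normal(n)
        pc = partial_corr(x, y, age)
        assert abs(pc.r) < 0.05

    def test_identical_vectors_give_unit_correlation(self):
        rng = np.random.default_rng(8)
        z = rng.uniform(20, 81, 30)
        x = 0.1 * z + rng.standard_normal(30)
        pc = partial_corr(x, x.copy(), z)
        assert pc.r == pytest.approx(1.0)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(9)
        z = rng.uniform(20, 81, 40)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        r1 = partial_corr(x, y, z).r
        assert partial_corr(y, x, z).r == pytest.approx(r1, abs=1e-12)
        assert partial_corr(3 * x - 2, 0.5 * y + 7, -2 * z + 1).r == pytest.approx(
            r1, abs=1e-12
        )

    def test_degenerate_inputs_raise(self):
        z = np.linspace(20, 81, 20)
        with pytest.raises(ValueError):
            partial_corr(2 * z + 1, np.random.default_rng(0).standard_normal(20), z)
        with pytest.raises(ValueError):
            partial_corr(np.ones(3), np.ones(3), np.ones(3))


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        adj, rej = bh_adjust([0.01, 0.02, 0.04, 0.5], q=0.05)
        # step-up: 0.04 > 3*0.05/4 = 0.0375, so only the first two reject
        np.testing.assert_array_equal(rej, [True, True, False, False])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_all_zero_p_all_rejected(self):
        _, rej = bh_adjust(np.zeros(7), q=0.05)
        assert rej.all()

    def test_single_test_is_plain_alpha(self):
        adj, rej = bh_adjust([0.049], q=0.05)
        assert rej[0] and adj[0] == pytest.approx(0.049)

    def test_adjustment_preserves_order(self):
        rng = np.random.default_rng(10)
        p = rng.uniform(0, 1, 50)
        adj, _ = bh_adjust(p)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestScreen:
    @staticmethod
    def _screen_once(rng, n=39, n_null=20, true_r=0.7):
        age = rng.uniform(20, 81, n)
        e1 = rng.standard_normal(n)
        x = 0.02 * age + e1
        y = -0.01 * age + true_r * e1 + np.sqrt(1 - true_r**2) * rng.standard_normal(n)
        pairs = [("signal", x, "score", y, "integration")]
        for i in range(n_null):
            pairs.append(
                (f"null{i}", 0.02 * age + rng.standard_normal(n), "score",
                 -0.01 * age + rng.standard_normal(n), "integration")
            )
        return screen_correlations(pairs, age)

    def test_strong_pair_reported_among_nulls(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            df = self._screen_once(rng)
            reported = set(df[df.passes_screen].metric)
            hits += "signal" in reported
        assert hits >= 0.90 * 200

    def test_all_null_pairs_rarely_reported(self):
        rng = np.random.default_rng(12)
        total = 0
        reps = 100
        for _ in range(reps):
            age = rng.uniform(20, 81, 39)
            pairs = [
                (f"m{i}", rng.standard_normal(39), "score",
                 rng.standard_normal(39), "segregation")
                for i in range(100)
            ]
            df = screen_correlations(pairs, age)
            total += int(df.passes_screen.sum())
        assert total / reps < 0.3  # joint screen is far stricter than FDR alone

    def test_moderate_filter_boundary(self):
        # sample r below 0.400 is never reported regardless of significance
        rng = np.random.default_rng(13)
        n = 500
        age = rng.uniform(20, 81, n)
        e1 = rng.standard_normal(n)
        x = e1
        y = 0.35 * e1 + np.sqrt(1 - 0.35**2) * rng.standard_normal(n)
        df = screen_correlations([("m", x, "s", y, "global")], age)
        assert df.p.iloc[0] < 0.001
        if abs(df.r.iloc[0]) <= 0.400:
            assert not df.passes_screen.iloc[0]

    def test_gam_prefilter_restricts_candidates(self):
        rng = np.random.default_rng(14)
        age = rng.uniform(20, 81, 39)
        x = rng.standard_normal(39)
        y = rng.standard_normal(39)
        df = screen_correlations(
            [("a", x, "s", y, "global"), ("b", x, "s", y, "global")],
            age,
            gam_pvalues={"a": 0.001, "b": 0.5},
        )
        assert set(df.metric) == {"a"}

    def test_empty_candidate_set_is_empty_frame(self):
        df = screen_correlations([], np.linspace(20, 81, 10))
        assert df.empty and "passes_screen" in df.columns

    def test_sorted_by_absolute_r(self):
        rng = np.random.default_rng(15)
        df = self._screen_once(rng)
        assert np.all(np.diff(df.r.abs().to_numpy()) <= 1e-15)
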