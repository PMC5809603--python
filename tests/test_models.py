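import math

import numpy as np
import pytest

from fertresp import (
    FertilizerTrial,
    NSFMParameters,
    QPFMParameters,
    fit_nsfm,
    fit_qpfm,
    fit_statistics,
    marginal_series,
    fit_marginal_linear,
    predict_nsfm,
    predict_qpfm,
    taylor_qpfm_of_nsfm,
    to_nutrient_basis,
)


class TestPredict:
    @pytest.mark.parametrize(
        "params,x,expected",
        [
            (QPFMParameters(5087.6, 22.273, -0.065), 0, 5087.6),
            (QPFMParameters(5087.6, 22.273, -0.065), 100, 6664.9),
            (QPFMParameters(0, 0, 0), 123.4, 0.0),
        ],
    )
    def test_quadratic(self, params, x, expected):
        assert predict_qpfm(params, x) == pytest.approx(expected)

    def test_exponential_at_zero_is_A_s0(self):
        p = NSFMParameters(A=47.596, c=3.74e-3, s0=105.12)
        assert predict_nsfm(p, 0) == pytest.approx(p.A * p.s0)

    def test_exponential_mid_range_value(self):
        p = NSFMParameters(A=47.596, c=3.740e-3, s0=105.12)
        assert predict_nsfm(p, 150) == pytest.approx(6928, abs=2)

    def test_small_c_limit_is_linear(self):
        p = NSFMParameters(A=1.0, c=1e-12, s0=0.0)
        assert predict_nsfm(p, 5.0) == pytest.approx(5.0)

    def test_positive_c_required(self):
        with pytest.raises(ValueError):
            NSFMParameters(A=1.0, c=0.0, s0=0.0)


class TestFitQpfm:
    def test_reproduces_published_rice_n(self, datian_n):
        params, stats = fit_qpfm(datian_n)
        assert params.b1 == pytest.approx(22.273, rel=5e-3)
        assert params.b2 == pytest.approx(-0.065, rel=5e-3)
        assert stats.r2 == pytest.approx(0.981, rel=5e-3)

    def test_reproduces_published_wheat_1(self, wheat_trials):
        params, _ = fit_qpfm(wheat_trials["W1"])
        assert params.b1 == pytest.approx(40.684, rel=5e-3)
        assert params.b2 == pytest.approx(-0.1326, rel=5e-3)

    def test_exact_quadratic_recovery(self):
        x = np.array([0.0, 25, 50, 100, 150])
        y = 10 + 2 * x - 0.01 * x**2
        trial = FertilizerTrial(
            "q", "s", "other", "N", tuple(x), tuple(y)
        )
        params, stats = fit_qpfm(trial)
        assert params.b0 == pytest.approx(10, rel=1e-9)
        assert params.b1 == pytest.approx(2, rel=1e-9)
        assert params.b2 == pytest.approx(-0.01, rel=1e-9)
        assert stats.r2 == pytest.approx(1.0)
        assert stats.s == pytest.approx(0.0, abs=1e-9)


class TestFitNsfm:
    def test_reproduces_published_rice_n(self, datian_n):
        params, stats = fit_nsfm(datian_n)
        assert params.A == pytest.approx(47.596, rel=0.01)
        assert params.c == pytest.approx(3.740e-3, rel=0.02)
        assert params.s0 == pytest.approx(105.12, rel=0.01)
        assert stats.r2 == pytest.approx(0.990, rel=0.01)

    def test_reproduces_published_rice_p(self, nanan_p):
        params, stats = fit_nsfm(nanan_p)
        assert params.s0 == pytest.approx(106.79, rel=0.01)
        assert stats.r2 == pytest.approx(0.998, rel=0.01)

    def test_noiseless_exact_recovery(self):
        true = NSFMParameters(A=60.0, c=0.005, s0=90.0)
        x = np.arange(0.0, 8 * 30, 30)
        y = predict_nsfm(true, x)
        trial = FertilizerTrial("g", "s", "other", "N", tuple(x), tuple(y))
        params, stats = fit_nsfm(trial)
        assert params.A == pytest.approx(true.A, rel=1e-6)
        assert params.c == pytest.approx(true.c, rel=1e-6)
        assert params.s0 == pytest.approx(true.s0, rel=1e-6)
        assert stats.sse <= 1e-8 * stats.sst

    def test_exponential_fits_rice_better_than_quadratic(self, rice_trials):
        for trial in rice_trials.values():
            _, nstats = fit_nsfm(trial)
            _, qstats = fit_qpfm(trial)
            assert nstats.sse < qstats.sse

    def test_wheat_fits_on_nutrient_basis_match_published(
        self, wheat_trials, pub_wheat
    ):
        """All nine historical wheat trials reproduce the published
        coefficient table once product-dosed rates are nutrient-converted."""
        pub = pub_wheat.set_index("trial_id")
        for tid, trial in wheat_trials.items():
            t = to_nutrient_basis(trial)
            nparams, _ = fit_nsfm(t)
            qparams, _ = fit_qpfm(t)
            row = pub.loc[tid]
            assert nparams.A == pytest.approx(row.A, rel=0.01), tid
            assert nparams.c * 1e3 == pytest.approx(row.c_e3, rel=0.02), tid
            assert nparams.s0 == pytest.approx(row.s0, rel=0.01), tid
            assert qparams.b1 == pytest.approx(row.b1, rel=0.005), tid
            assert qparams.b2 == pytest.approx(row.b2, rel=0.005), tid

    def test_unique_interior_maximum(self):
        p = NSFMParameters(A=47.596, c=3.74e-3, s0=105.12)
        x_star = 1 / p.c - p.s0
        grid = np.linspace(0, 2 * x_star, 20001)
        y = predict_nsfm(p, grid)
        assert grid[np.argmax(y)] == pytest.approx(
            x_star, abs=2 * (grid[1] - grid[0])
        )


class TestFitStatistics:
    def test_perfect_fit(self):
        y = [1.0, 2.0, 3.0, 4.0]
        st = fit_statistics(y, y, p=2)
        assert st.r2 == 1.0 and st.sse == 0.0 and st.s == 0.0

    def test_published_marginal_line_statistics(self, datian_n):
        fit = fit_marginal_linear(marginal_series(datian_n))
        st = fit.stats
        assert st.n == 7 and st.p == 2
        assert st.s == pytest.approx(3.765, rel=5e-3)
        assert st.f == pytest.approx(40.28, rel=5e-3)

    def test_f_identity_from_r2(self):
        # closed form: R2=0.93, n=7, p=3 -> F = (0.93/0.07) * 2
        r2, n, p = 0.93, 7, 3
        f = (r2 / (1 - r2)) * (n - p) / (p - 1)
        assert f == pytest.approx(26.57, abs=0.01)

    def test_requires_residual_df(self):
        with pytest.raises(ValueError):
            fit_statistics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], p=3)


class TestTaylorMap:
    def test_maps_parameters_to_quadratic(self):
        p = NSFMParameters(A=47.596, c=3.740e-3, s0=105.12)
        q = taylor_qpfm_of_nsfm(p)
        assert q.b0 == pytest.approx(5003.3, abs=0.5)
        assert q.b1 == pytest.approx(28.88, abs=0.02)
        assert q.b2 == pytest.approx(-0.178, abs=0.001)

    def test_unit_case(self):
        q = taylor_qpfm_of_nsfm(NSFMParameters(A=1.0, c=1.0, s0=1.0))
        assert (q.b0, q.b1, q.b2) == (1.0, 0.0, -1.0)

    def test_vanishing_c_limit_is_line(self):
        q = taylor_qpfm_of_nsfm(NSFMParameters(A=2.0, c=1e-15, s0=50.0))
        assert q.b0 == pytest.approx(100.0)
        assert q.b1 == pytest.approx(2.0)
        assert q.b2 == pytest.approx(0.0, abs=1e-12)

    def test_quadratic_fit_converges_to_series_as_curvature_vanishes(self):
        """Fitting the quadratic to noiseless exponential-model yields
        approaches the analytic second-order series as c X_max -> 0 with
        A c (hence b2) held fixed."""
        x = np.linspace(0, 200, 9)
        Ac = 0.25
        errs = []
        for c in (2e-3, 2e-4, 2e-5):
            p = NSFMParameters(A=Ac / c, c=c, s0=100.0)
            trial = FertilizerTrial(
                "t", "s", "other", "N", tuple(x), tuple(predict_nsfm(p, x))
            )
            qfit, _ = fit_qpfm(trial)
            qser = taylor_qpfm_of_nsfm(p)
            errs.append(
                max(
                    abs(qfit.b0 - qser.b0) / abs(qser.b0),
                    abs(qfit.b1 - qser.b1) / abs(qser.b1),
                    abs(qfit.b2 - qser.b2) / abs(qser.b2),
                )
            )
        assert errs[0] > errs[1] > errs[2]
        assert errs[-1] < 5e-3
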