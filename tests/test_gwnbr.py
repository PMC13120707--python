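import numpy as np
import pytest

import gwcrash as gw
from gwcrash import GWCrashError, KernelSpec, LocalFitState
from gwcrash.simulate import constant_surface, sar_covariates

from conftest import nb_logpmf_oracle


def _state_from(units, w):
    return LocalFitState(
        focal=0,
        y=units.response_vector(),
        X=units.design_matrix(),
        log_t=units.log_offset(),
        w=w,
    )


class TestLocalLoglikelihood:
    def test_unit_weights_recover_the_global_loglik(self, gradient12):
        units = gradient12.units
        state = _state_from(units, np.ones(units.n))
        beta = np.array([2.5, 0.2])
        mu = np.exp(units.design_matrix() @ beta)
        expected = gw.nb2_loglik(units.response_vector(), mu, 0.7)
        assert gw.local_loglikelihood(state, beta, 0.7) == pytest.approx(
            expected, abs=1e-10
        )

    def test_zero_count_term_reduces_to_log_survival(self):
        import pandas as pd

        df = pd.DataFrame({"x": [0.0], "y": [0.0], "cnt": [0]},
                          index=pd.Index(["a"], name="unit_id"))
        units = gw.SpatialUnitTable(data=df, response="cnt")
        state = _state_from(units, np.ones(1))
        beta, alpha = np.array([1.3]), 0.6
        mu = np.exp(1.3)
        assert gw.local_loglikelihood(state, beta, alpha) == pytest.approx(
            -(1 / alpha) * np.log1p(alpha * mu), abs=1e-12
        )

    def test_matches_independent_pmf_oracle_on_fixture(self):
        """Weighted local likelihood agrees with scipy's NB pmf to 1e-9."""
        rng = np.random.default_rng(30)
        import pandas as pd

        n = 30
        df = pd.DataFrame(
            {
                "x": rng.uniform(0, 10, n),
                "y": rng.uniform(0, 10, n),
                "x1": rng.standard_normal(n),
                "cnt": rng.integers(0, 40, n),
            },
            index=pd.Index([f"u{i}" for i in range(n)], name="unit_id"),
        )
        units = gw.SpatialUnitTable(data=df, response="cnt", covariates=["x1"])
        w = rng.uniform(0, 1, n)
        state = _state_from(units, w)
        for _ in range(5):
            beta = rng.normal(0, 0.5, 2) + np.array([2.0, 0.0])
            alpha = float(rng.uniform(0.05, 2.0))
            mu = np.exp(units.design_matrix() @ beta)
            oracle = float(np.sum(w * nb_logpmf_oracle(df["cnt"].to_numpy(), mu, alpha)))
            assert gw.local_loglikelihood(state, beta, alpha) == pytest.approx(
                oracle, abs=1e-9 * max(1.0, abs(oracle))
            )

    def test_nonfinite_mean_reported(self, gradient12):
        state = _state_from(gradient12.units, np.ones(gradient12.units.n))
        with pytest.raises(GWCrashError, match="non-positive|non-finite"):
            gw.local_loglikelihood(state, np.array([np.inf, 0.0]), 0.5)


class TestFitLocal:
    def test_uniform_weights_reproduce_global_negbin(self, gradient12):
        units = gradient12.units
        res = gw.fit_local(_state_from(units, np.ones(units.n)))
        nb = gw.fit_negbin(units)
        assert np.allclose(res.beta, nb.params, atol=1e-6)
        assert res.alpha == pytest.approx(nb.alpha, abs=1e-5)

    def test_monotone_ascent_of_weighted_loglik(self, gradient12):
        units = gradient12.units
        w = gw.kernel_weight_vector(units, 60, KernelSpec("adaptive_bisquare", 40))
        state = LocalFitState(focal=60, y=units.response_vector(),
                              X=units.design_matrix(), log_t=units.log_offset(), w=w)
        res = gw.fit_local(state, beta0=None, alpha0=0.3)
        diffs = np.diff(res.ll_trace)
        assert np.all(diffs >= -1e-10)
        assert res.converged

    def test_too_few_positive_weights_is_locally_unidentified(self, gradient12):
        units = gradient12.units
        w = np.zeros(units.n)
        w[:3] = 1.0  # p + 2 = 4 needed
        with pytest.raises(GWCrashError, match="locally unidentified"):
            gw.fit_local(_state_from(units, w))

    def test_constant_surface_recovered_within_three_local_se(self):
        lattice = gw.generate_lattice(12, 10.0, seed=21)
        units = sar_covariates(lattice, {"x1": 0.5}, 21)
        st = gw.simulate_gwnbr_counts(
            units,
            {"Intercept": constant_surface(np.log(16.0)),
             "x1": constant_surface(0.4)},
            alpha=0.3, seed=21,
        )
        fit = gw.fit_gwnbr(st.units, kernel=KernelSpec("adaptive_bisquare", 72))
        truth = np.array([np.log(16.0), 0.4])
        within = np.abs(fit.local_beta - truth) < 3 * fit.local_se
        assert within.all(axis=1).mean() >= 0.9


class TestFitGWNBR:
    def test_uniform_kernel_collapses_to_global_fit(self, gradient12):
        units = gradient12.units
        fit = gw.fit_gwnbr(units, kernel=KernelSpec("uniform", 1))
        nb = gw.fit_negbin(units)
        assert np.max(np.abs(fit.local_beta - nb.params)) < 1e-5
        assert np.max(np.abs(fit.local_alpha - nb.alpha)) < 1e-4

    def test_gradient_surface_recovered(self, gradient12):
        fit = gw.fit_gwnbr(gradient12.units,
                           kernel=KernelSpec("adaptive_bisquare", 50))
        true_b1 = gradient12.true_beta["x1"].to_numpy()
        corr = np.corrcoef(true_b1, fit.local_beta[:, 1])[0, 1]
        assert corr >= 0.8

    def test_median_local_coefficient_sign_matches_offset_ramp(self):
        # a ramp with a clearly signed median (0.1 .. 0.9)
        st = gw.gradient_study(seed=4, n_side=10, beta1_range=(0.1, 0.9))
        fit = gw.fit_gwnbr(st.units, kernel=KernelSpec("adaptive_bisquare", 40))
        assert np.median(fit.local_beta[:, 1]) > 0

    def test_effective_params_decrease_with_bandwidth(self, gradient12):
        ks = [20, 50, 100, 144]
        effs = [
            gw.fit_gwnbr(gradient12.units,
                         kernel=KernelSpec("adaptive_bisquare", b)).effective_params
            for b in ks
        ]
        assert np.all(np.diff(effs) < 0.5)  # monotone within evaluation noise
        p = 2
        assert all(p <= e <= gradient12.units.n * p + 1 for e in effs)

    def test_five_number_summary_layout(self, gradient12):
        fit = gw.fit_gwnbr(gradient12.units,
                           kernel=KernelSpec("adaptive_bisquare", 60))
        summ = fit.local_summary()
        assert list(summ.columns) == ["Min", "LQ", "Median", "UQ", "Max"]
        assert list(summ.index) == ["Intercept", "x1"]
        assert (summ["Min"] <= summ["LQ"]).all() and (summ["UQ"] <= summ["Max"]).all()

    def test_bandwidth_below_identifiability_rejected(self, gradient12):
        with pytest.raises(GWCrashError, match="p \\+ 2"):
            gw.fit_gwnbr(gradient12.units, kernel=KernelSpec("adaptive_bisquare", 3))

    def test_residual_autocorrelation_lower_than_global_nb(self, paper_like):
        units = paper_like.units
        wm = gw.row_standardize(gw.contiguity_weights(units, "queen"))
        nb = gw.fit_negbin(units)
        fit = gw.fit_gwnbr(units, kernel=KernelSpec("adaptive_bisquare", 60))
        i_nb = gw.global_moran(nb.residuals(), wm).I
        i_gw = gw.global_moran(fit.residuals(), wm).I
        assert i_gw <= i_nb

    def test_global_alpha_mode_holds_dispersion_fixed(self, gradient12):
        fit = gw.fit_gwnbr(gradient12.units,
                           kernel=KernelSpec("adaptive_bisquare", 60),
                           global_alpha=True)
        assert np.ptp(fit.local_alpha) == 0.0


class TestGoldenSection:
    def test_quadratic_minimum_found(self):
        res = gw.golden_section_search(lambda b: (b - 100.0) ** 2, 10, 197)
        assert res.optimum == 100

    def test_monotone_decreasing_objective_selects_upper_bound(self):
        res = gw.golden_section_search(lambda b: -b, 10, 197)
        assert res.optimum == 197

    @pytest.mark.parametrize("target", [23.4, 57.3, 150.0, 11.0, 196.0])
    def test_matches_exhaustive_integer_grid(self, target):
        f = lambda b: np.cosh((b - target) / 40.0)
        res = gw.golden_section_search(f, 10, 197)
        grid = {b: f(b) for b in range(10, 198)}
        assert f(res.optimum) == pytest.approx(min(grid.values()), abs=1e-12)

    def test_optimum_never_worse_than_any_probe(self):
        res = gw.golden_section_search(lambda b: (b - 44.0) ** 2 + 3.0, 10, 120)
        best = min(s for _, s in res.evaluated)
        assert dict(res.evaluated)[res.optimum] == best

    def test_invalid_bounds_rejected(self):
        with pytest.raises(GWCrashError, match="bounds"):
            gw.golden_section_search(lambda b: b, 50, 50)


class TestSelectBandwidth:
    def test_spatially_varying_data_select_interior_bandwidth(self, gradient12):
        res = gw.select_bandwidth(gradient12.units, criterion="aic")
        assert res.optimum < gradient12.units.n

    def test_constant_data_statistically_global(self):
        lattice = gw.generate_lattice(12, 10.0, seed=0)
        units = sar_covariates(lattice, {"x1": 0.5}, 0)
        st = gw.simulate_gwnbr_counts(
            units,
            {"Intercept": constant_surface(np.log(16.0)),
             "x1": constant_surface(0.4)},
            alpha=0.5, seed=0,
        )
        res = gw.select_bandwidth(st.units, criterion="aic", global_alpha=True)
        scores = dict(res.evaluated)
        at_n = gw.fit_gwnbr(
            st.units, kernel=KernelSpec("adaptive_bisquare", st.units.n),
            global_alpha=True,
        ).aic
        # the global model is statistically indistinguishable from the optimum
        assert at_n - scores[res.optimum] < 5.0

    def test_cv_criterion_runs_and_respects_bounds(self, gradient12):
        res = gw.select_bandwidth(gradient12.units, criterion="cv",
                                  bounds=(20, 144))
        assert res.criterion == "cv"
        assert 20 <= res.optimum <= 144

    def test_out_of_range_bounds_rejected(self, gradient12):
        with pytest.raises(GWCrashError, match="bounds"):
            gw.select_bandwidth(gradient12.units, bounds=(2, 144))
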