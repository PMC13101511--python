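"""Global least-squares fitting: recovery, goodness of fit, edge cases."""

import numpy as np
import pandas as pd
import pytest

import pahkin as pk
from conftest import random_valid_params

DAYS = [0.0, 1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0, 15.0]


def make_data(params, times=DAYS, replicates=1, sigma=(0.0, 0.0), seed=0, lod=0.0):
    design = pk.DesignSpec(
        sample_times=tuple(times),
        n_replicates=replicates,
        noise_sigma_parent=sigma[0],
        noise_sigma_intermediate=sigma[1],
        lod_parent=lod,
        lod_intermediate=lod,
        seed=seed,
    )
    return pk.simulate_timecourse(params, design)


class TestBranchedFit:
    def test_exact_recovery_noiseless(self, study_params, noiseless_data):
        fit = pk.fit_branched_model(noiseless_data)
        p = fit.params_hat
        assert p.k_tot == pytest.approx(study_params.k_tot, rel=1e-6)
        assert p.f == pytest.approx(study_params.f, rel=1e-6)
        assert p.k2 == pytest.approx(study_params.k2, rel=1e-6)
        assert p.S0 == pytest.approx(study_params.S0, rel=1e-6)
        assert fit.converged and fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_exact_recovery_random_truths(self):
        """Noiseless least squares recovers randomized admissible truths."""
        rng = np.random.default_rng(17)
        checked = 0
        while checked < 20:
            truth = random_valid_params(rng)
            # identifiable interior truths only: formation signal and P0=0 design
            if not (0.05 <= truth.f <= 0.95 and truth.k2 > 0.01 and abs(truth.k2 - truth.k_tot) > 1e-3):
                continue
            truth = pk.KineticParams(truth.k_tot, truth.f, truth.k2, truth.S0, 0.0)
            fit = pk.fit_branched_model(make_data(truth))
            p = fit.params_hat
            for name in ("k_tot", "f", "k2", "S0"):
                assert getattr(p, name) == pytest.approx(getattr(truth, name), rel=1e-5), name
            checked += 1

    def test_zero_intermediate_drives_f_to_zero(self):
        truth = pk.KineticParams(k_tot=0.2, f=0.0, k2=0.1, S0=100.0)
        fit = pk.fit_branched_model(make_data(truth))
        assert fit.params_hat.f < 1e-6
        assert fit.params_hat.k_tot == pytest.approx(0.2, rel=1e-6)

    def test_parent_only_exponential_matches_log_linear_oracle(self):
        """k_tot from the global fit equals the log-linear regression slope."""
        truth = pk.KineticParams(k_tot=0.2, f=0.0, k2=0.1, S0=100.0)
        data = make_data(truth)
        fit = pk.fit_branched_model(data)
        par = data.series(pk.PARENT)
        slope = np.polyfit(par["time_d"], np.log(par["conc_mg_per_L"]), 1)[0]
        assert fit.params_hat.k_tot == pytest.approx(-slope, rel=1e-6)

    def test_k_a_is_exactly_f_times_k_tot(self, noisy_data):
        fit = pk.fit_branched_model(noisy_data)
        assert fit.k_a_hat == fit.params_hat.f * fit.params_hat.k_tot

    def test_objective_invariant_to_record_order(self, noisy_data):
        shuffled = pk.TimeCourseData(
            noisy_data.table.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        a = pk.fit_branched_model(noisy_data)
        b = pk.fit_branched_model(shuffled)
        assert a.objective_value == pytest.approx(b.objective_value, rel=1e-12)
        assert a.params_hat.k_tot == pytest.approx(b.params_hat.k_tot, rel=1e-12)

    def test_refit_from_fitted_point_is_fixed_point(self, noisy_data):
        first = pk.fit_branched_model(noisy_data)
        second = pk.fit_branched_model(noisy_data, init=first.params_hat)
        for name in ("k_tot", "f", "k2", "S0"):
            assert getattr(second.params_hat, name) == pytest.approx(
                getattr(first.params_hat, name), rel=1e-6
            ), name

    def test_error_shrinks_with_noise(self, study_params):
        """Median |relative error| of the rate estimates falls when sigma halves."""
        def median_err(sigma, n=15):
            errs = []
            for seed in range(n):
                data = make_data(study_params, replicates=3, sigma=(sigma, sigma / 2), seed=seed)
                fit = pk.fit_branched_model(data)
                errs.append(abs(fit.params_hat.k_tot - study_params.k_tot) / study_params.k_tot)
            return float(np.median(errs))

        assert median_err(1.0) > median_err(0.5)

    def test_fix_S0(self, noisy_data):
        init = pk.KineticParams(k_tot=0.1, f=0.5, k2=0.1, S0=60.0)
        fit = pk.fit_branched_model(noisy_data, init=init, fix_S0=True)
        assert fit.params_hat.S0 == 60.0

    def test_inverse_variance_weighting_runs(self, noisy_data):
        fit = pk.fit_branched_model(noisy_data, weighting="inverse_variance")
        assert fit.converged
        assert fit.params_hat.k_tot == pytest.approx(0.142, rel=0.3)

    def test_too_few_observations_rejected(self):
        df = pd.DataFrame(
            {
                "time_d": [0.0, 1.0, 0.0, 1.0],
                "compound": ["parent", "parent", "intermediate", "intermediate"],
                "replicate": ["r1"] * 4,
                "conc_mg_per_L": [60.0, 50.0, 0.0, 3.0],
            }
        )
        with pytest.raises(pk.FittingError, match="distinct time"):
            pk.fit_branched_model(pk.TimeCourseData(df))

    def test_fully_censored_series_rejected(self, study_params):
        data = make_data(study_params, replicates=1, lod=1000.0)
        with pytest.raises(pk.FittingError, match="censored|usable"):
            pk.fit_branched_model(data)

    def test_half_lod_policy_substitutes(self, study_params):
        data = make_data(study_params, replicates=1, lod=5.0)
        fit = pk.fit_branched_model(data, lod_policy="half_lod")
        obs = fit.residuals
        assert (obs["observed"] == 2.5).any()  # LOD/2 imputed rows included

    def test_replicate_means_option(self, study_params):
        data = make_data(study_params, replicates=3, sigma=(2.0, 1.0), seed=1)
        fit_all = pk.fit_branched_model(data)
        fit_mean = pk.fit_branched_model(data, use_replicate_means=True)
        assert fit_mean.n_obs == fit_all.n_obs // 3
        assert fit_mean.params_hat.k_tot == pytest.approx(fit_all.params_hat.k_tot, rel=0.1)


class TestSingleFirstOrder:
    def test_noiseless_recovery(self):
        truth = pk.KineticParams(k_tot=0.5, f=0.0, k2=0.0, S0=50.0)
        fit = pk.fit_single_first_order(make_data(truth))
        assert fit.params_hat.k_tot == pytest.approx(0.5, rel=1e-6)
        assert fit.params_hat.S0 == pytest.approx(50.0, rel=1e-6)

    def test_constant_series_gives_zero_rate(self):
        df = pd.DataFrame(
            {
                "time_d": DAYS,
                "compound": ["parent"] * len(DAYS),
                "replicate": ["r1"] * len(DAYS),
                "conc_mg_per_L": [42.0] * len(DAYS),
            }
        )
        fit = pk.fit_single_first_order(pk.TimeCourseData(df))
        assert fit.params_hat.k_tot < 1e-8

    def test_half_life_composition(self):
        truth = pk.KineticParams(k_tot=np.log(2), f=0.0, k2=0.0, S0=10.0)
        fit = pk.fit_single_first_order(make_data(truth, times=[0, 0.5, 1, 1.5, 2, 3]))
        assert pk.half_life(fit.params_hat.k_tot) == pytest.approx(1.0, rel=1e-6)


class TestGoodnessOfFit:
    def test_noiseless_r2_is_one(self, noiseless_data):
        fit = pk.fit_branched_model(noiseless_data)
        assert pk.goodness_of_fit(fit) == pytest.approx(1.0, abs=1e-12)

    def test_mean_predictor_r2_is_zero(self, noisy_data):
        fit = pk.fit_branched_model(noisy_data)
        table = fit.residuals.copy()
        table["predicted"] = table.groupby("compound")["observed"].transform("mean")
        table["residual"] = table["observed"] - table["predicted"]
        degenerate = pk.FitResult(
            params_hat=fit.params_hat,
            residuals=table,
            r_squared=float("nan"),
            r_squared_by_series={},
            sigma_hat=fit.sigma_hat,
            converged=True,
            n_obs=fit.n_obs,
            objective_value=float("nan"),
        )
        assert pk.goodness_of_fit(degenerate) == pytest.approx(0.0, abs=1e-12)

    def test_matches_manual_pooled_computation(self, study_params):
        """R^2 equals a spreadsheet-style 1 - SSR/SST on the same numbers."""
        data = pk.simulate_timecourse(
            study_params, pk.DesignSpec(noise_sigma_parent=2.0, noise_sigma_intermediate=2.0, seed=99)
        )
        fit = pk.fit_branched_model(data)
        ssr = sst = 0.0
        for compound in (pk.PARENT, pk.INTERMEDIATE):
            sub = fit.residuals[fit.residuals["compound"] == compound]
            ssr += ((sub["observed"] - sub["predicted"]) ** 2).sum()
            sst += ((sub["observed"] - sub["observed"].mean()) ** 2).sum()
        assert fit.r_squared == pytest.approx(1 - ssr / sst, rel=1e-12)
        assert pk.goodness_of_fit(fit) == pytest.approx(1 - ssr / sst, rel=1e-12)

    def test_identical_observations_undefined(self):
        df = pd.DataFrame(
            {
                "time_d": DAYS,
                "compound": ["parent"] * len(DAYS),
                "replicate": ["r1"] * len(DAYS),
                "conc_mg_per_L": [42.0] * len(DAYS),
            }
        )
        fit = pk.fit_single_first_order(pk.TimeCourseData(df))
        with pytest.raises(pk.ValidationError, match="undefined"):
            pk.goodness_of_fit(fit)


class TestPercentDegraded:
    @pytest.mark.parametrize(
        "initial,residual,expected",
        [(100.0, 25.0, 75.0), (50.0, 50.0, 0.0), (50.0, 2.45, 95.1), (50.0, 60.0, 0.0)],
    )
    def test_values(self, initial, residual, expected):
        assert pk.percent_degraded(initial, residual) == pytest.approx(expected, abs=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(pk.ValidationError):
            pk.percent_degraded(0.0, 1.0)
        with pytest.raises(pk.ValidationError):
            pk.percent_degraded(10.0, -1.0)
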