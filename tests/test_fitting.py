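"""Fitting-layer tests: merit function, estimation, CIs, model selection,
sensitivity scan and growth-curve alignment."""

import numpy as np
import pandas as pd
import pytest

from phybdyn.fitting import (
    ExperimentDataset,
    FitConfig,
    align_growth_curves,
    chi_square,
    confidence_intervals,
    information_criteria,
    multi_experiment_fit,
    sensitivity_scan,
    with_pooled_se,
)
from phybdyn.growth import GrowthParameters, dark_growth_length
from phybdyn.model import PHOTOCHEMISTRY_ONLY, WITH_DARK_REVERSION, ModelVariant
from phybdyn.synth import SyntheticSpec, generate_seedling_panel, generate_timeseries

ACCUM_FREE = {"t_syn": (0.0, 2000.0), "k_dr": (1e-4, 1e-2), "z": (0.5, 10.0)}


def accumulation_fit(seed: int, n_starts: int = 1):
    spec = SyntheticSpec(seed=seed)
    ds = with_pooled_se(generate_timeseries(spec, "accumulation"))
    cfg = FitConfig(free=ACCUM_FREE, seed=seed, n_starts=n_starts)
    return multi_experiment_fit([ds], cfg), ds


class TestChiSquare:
    def setup_method(self):
        self.ds = ExperimentDataset(
            "degradation", [0.0, 10.0], [1.0, 2.0], [1.0, 1.0]
        )

    def test_perfect_fit_zero(self):
        assert chi_square(self.ds, [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        # residuals (1, 2) with unit SEs: chi2 = 1 + 4 = 5
        assert chi_square(self.ds, [0.0, 0.0]) == 5.0

    def test_halving_se_quadruples(self):
        halved = ExperimentDataset(
            "degradation", [0.0, 10.0], [1.0, 2.0], [0.5, 0.5]
        )
        assert chi_square(halved, [0.0, 0.0]) == 4 * chi_square(
            self.ds, [0.0, 0.0]
        )

    def test_nonpositive_se_rejected(self):
        ds = ExperimentDataset("degradation", [0.0, 10.0], [1.0, 2.0],
                               [0.0, 1.0])
        with pytest.raises(ValueError):
            chi_square(ds, [1.0, 2.0])


class TestMultiExperimentFit:
    def test_zero_noise_recovers_ground_truth(self):
        """Noise-free synthetic FRAP + reversion + degradation data return
        the generating rates to within 1 %."""
        spec = SyntheticSpec(seed=0, noise={})
        datasets = [
            generate_timeseries(spec, k)
            for k in ("frap", "dark_reversion", "degradation")
        ]
        cfg = FitConfig(
            free={"k_3": (0.1, 10.0), "k_4": (0.1, 10.0),
                  "k_r": (0.001, 0.1), "k_dfr": (0.00061, 0.00305)},
            seed=0, n_starts=2,
        )
        fit = multi_experiment_fit(datasets, cfg)
        truth = {"k_3": 3.98, "k_4": 1.51, "k_r": 0.0321, "k_dfr": 0.0024}
        for name, value in truth.items():
            assert fit.estimates[name] == pytest.approx(value, rel=0.01)
        assert fit.chi2_total < 1e-10

    def test_dataset_order_invariance(self):
        spec = SyntheticSpec(seed=3)
        a = with_pooled_se(generate_timeseries(spec, "accumulation"))
        b = with_pooled_se(generate_timeseries(spec, "degradation"))
        cfg = FitConfig(free=ACCUM_FREE, seed=3, n_starts=1)
        fwd = multi_experiment_fit([a, b], cfg)
        rev = multi_experiment_fit([b, a], cfg)
        assert fwd.chi2_total == pytest.approx(rev.chi2_total, rel=1e-9)
        for name in ACCUM_FREE:
            assert fwd.estimates[name] == pytest.approx(
                rev.estimates[name], rel=1e-6
            )

    def test_chi2_identity(self):
        """Reported total chi2 equals an independent re-evaluation of the
        merit function at the returned estimates."""
        fit, ds = accumulation_fit(seed=4)
        from phybdyn.experiments import accumulation_curve
        from phybdyn.model import RateConstants

        rc = RateConstants(z=fit.estimates["z"], k_dr=fit.estimates["k_dr"])
        model = accumulation_curve(rc, ds.times,
                                   t_syn=fit.estimates["t_syn"])
        assert fit.chi2_total == pytest.approx(
            chi_square(ds, model["value"].to_numpy()), rel=1e-9
        )

    def test_determinism(self):
        one, _ = accumulation_fit(seed=5, n_starts=2)
        two, _ = accumulation_fit(seed=5, n_starts=2)
        assert one.estimates == two.estimates
        assert one.chi2_total == two.chi2_total


class TestConfidenceIntervals:
    def test_linearized_matches_fisher_oracle(self):
        """Linearised CI vs an independent finite-difference Fisher matrix
        of the closed-form accumulation model."""
        fit, ds = accumulation_fit(seed=6)
        est = fit.estimates

        def model(t_syn, k_dr, z):
            tau = np.clip(ds.times - t_syn, 0.0, None)
            return z * (1.0 - np.exp(-k_dr * tau))

        p0 = np.array([est["t_syn"], est["k_dr"], est["z"]])
        J = np.empty((len(ds.times), 3))
        for j in range(3):
            h = 1e-6 * max(abs(p0[j]), 1e-12)
            up, dn = p0.copy(), p0.copy()
            up[j] += h
            dn[j] -= h
            J[:, j] = (model(*up) - model(*dn)) / (2 * h) / ds.se
        cov = np.linalg.inv(J.T @ J)
        sd_oracle = np.sqrt(np.diag(cov))
        assert fit.stderr["t_syn"] == pytest.approx(sd_oracle[0], rel=0.05)
        assert fit.stderr["z"] == pytest.approx(sd_oracle[2], rel=0.05)

    def test_zero_noise_intervals_collapse(self):
        spec = SyntheticSpec(seed=0, noise={})
        ds = generate_timeseries(spec, "accumulation")
        cfg = FitConfig(free=ACCUM_FREE, seed=0, n_starts=1)
        fit = multi_experiment_fit([ds], cfg)
        lo, hi = fit.ci95["t_syn"]
        assert hi - lo < 1e-2  # width shrinks toward zero with the residuals

    def test_coverage_near_95_percent(self):
        """200 seeded replicates at the default noise: the 95 % linearised
        intervals cover the generating values about 95 % of the time."""
        hits_t, hits_z = 0, 0
        for rep in range(200):
            fit, _ = accumulation_fit(seed=20000 + rep)
            lo, hi = fit.ci95["t_syn"]
            hits_t += lo <= 648.0 <= hi
            lo, hi = fit.ci95["z"]
            hits_z += lo <= 3.8 <= hi
        assert 0.90 <= hits_t / 200 <= 1.0
        assert 0.90 <= hits_z / 200 <= 1.0

    def test_profile_brackets_linearized(self):
        fit, _ = accumulation_fit(seed=7)
        prof = confidence_intervals(fit, method="profile")
        lin = confidence_intervals(fit, method="linearized")
        for name in ("t_syn", "z"):
            # near-quadratic likelihood: the two intervals agree broadly
            assert prof[name][0] == pytest.approx(lin[name][0], rel=0.2)
            assert prof[name][1] == pytest.approx(lin[name][1], rel=0.2)


class TestInformationCriteria:
    def test_fewer_parameters_win_at_equal_chi2(self):
        fit, ds = accumulation_fit(seed=8)
        import copy

        slim = copy.copy(fit)
        slim.n_free = fit.n_free - 1
        table = information_criteria({"full": fit, "slim": slim})
        assert table.iloc[0]["model"] == "slim"
        assert (table["bic"].iloc[0] < table[table.model == "full"]["bic"]).all()

    def test_dark_reversion_submodel_recovered(self):
        """Fluence-response data carry a reversion signature: the submodel
        with dark reversion beats pure photochemistry by AIC and BIC."""
        spec = SyntheticSpec(seed=7)
        ds = generate_timeseries(spec, "fluence_response")
        fits = {
            "photochemistry_only": multi_experiment_fit(
                [ds], FitConfig(free={"K_prime": (0.01, 1e4)}, seed=7,
                                n_starts=3),
                variant=PHOTOCHEMISTRY_ONLY,
            ),
            "with_dark_reversion": multi_experiment_fit(
                [ds], FitConfig(free={"K_prime": (0.01, 1e4),
                                      "k_r": (0.001, 0.1)}, seed=7,
                                n_starts=3),
                variant=WITH_DARK_REVERSION,
            ),
        }
        table = information_criteria(fits)
        assert table.iloc[0]["model"] == "with_dark_reversion"
        assert table["delta_aic"].iloc[1] > 10

    def test_cytosolic_signaling_excluded(self):
        """Data generated with nuclear signalling reject a cytosolic-Pfr
        readout decisively."""
        spec = SyntheticSpec(seed=5)
        ds = generate_timeseries(spec, "fluence_response")
        fits = {}
        for sel in ("pfr_nuclear_sum", "pfr_cytosolic"):
            fits[sel] = multi_experiment_fit(
                [ds], FitConfig(free={"K_prime": (0.1, 1e4)}, seed=5,
                                n_starts=3),
                variant=ModelVariant("full", sel),
            )
        table = information_criteria(fits)
        assert table.iloc[0]["model"] == "pfr_nuclear_sum"
        assert table["delta_aic"].iloc[1] > 10

    def test_mismatched_data_rejected(self):
        fit_a, _ = accumulation_fit(seed=8)
        spec = SyntheticSpec(seed=8)
        ds = generate_timeseries(spec, "degradation")
        fit_b = multi_experiment_fit(
            [ds], FitConfig(free={"k_dfr": (0.00061, 0.00305)}, seed=8,
                            n_starts=1)
        )
        with pytest.raises(ValueError):
            information_criteria([fit_a, fit_b])


class TestSensitivityScan:
    def test_unit_factor_is_baseline(self, rc, gp):
        for name in ("k_3", "k_4", "k_r", "z", "k_dfr", "alpha0_beta", "K"):
            scan = sensitivity_scan(rc, gp, name, factors=(1.0,))
            assert scan["value"].iloc[0] == pytest.approx(1.0)

    def test_nb_exchange_antagonism_under_diffuse_signaling(self, rc, gp):
        """With the diffuse nucleoplasmic pool as read-out, NB association
        (k_3) lengthens and dissociation (k_4) shortens the hypocotyl."""
        diffuse = ModelVariant("full", "pfr_n_diffuse")
        facs = (0.1, 0.5, 1.0, 2.0, 10.0)
        k3 = sensitivity_scan(rc, gp, "k_3", facs, variant=diffuse)["value"]
        k4 = sensitivity_scan(rc, gp, "k_4", facs, variant=diffuse)["value"]
        assert np.all(np.diff(k3) > 0)
        assert np.all(np.diff(k4) < 0)

    def test_abundance_and_degradation_antagonism(self, rc, gp):
        facs = (0.1, 0.5, 1.0, 2.0, 10.0)
        z = sensitivity_scan(rc, gp, "z", facs)["value"]
        kdfr = sensitivity_scan(rc, gp, "k_dfr", facs)["value"]
        assert np.all(np.diff(z) < 0)
        assert np.all(np.diff(kdfr) > 0)

    def test_weak_parameters_near_flat(self, rc, gp):
        """k_5, k_r and k_in barely move the read-out at saturating red;
        k_1 and k_2 stay an order of magnitude weaker than the abundance
        class, though the reconstructed cross-sections leave them a mild
        residual effect at the band edges."""
        facs = (0.1, 0.5, 1.0, 2.0, 10.0)
        for name in ("k_5", "k_r", "k_in"):
            v = sensitivity_scan(rc, gp, name, facs)["value"].to_numpy()
            assert v.max() - v.min() < 0.06, name
        for name in ("k_1", "k_2"):
            v = sensitivity_scan(rc, gp, name, facs)["value"].to_numpy()
            assert v.max() / v.min() < 2.1, name
        for name in ("z", "k_dfr", "alpha0_beta", "K"):
            v = sensitivity_scan(rc, gp, name, facs)["value"].to_numpy()
            assert v.max() / v.min() > 10, name


class TestAlignGrowthCurves:
    @staticmethod
    def _noise_free_curve(gp, t_growth, t_end=8640.0):
        t = np.arange(0.0, t_end + 1.0, 60.0)
        L = dark_growth_length(t, gp.with_(t_growth=t_growth))
        return pd.DataFrame({"time_min": t, "length_mm": L})

    def test_identical_curves_mean_is_curve(self, gp):
        curves = [self._noise_free_curve(gp, 2000.0) for _ in range(5)]
        out = align_growth_curves(curves)
        interp = np.interp(
            out.grid["time_min"] + out.crossing_times[0],
            curves[0]["time_min"], curves[0]["length_mm"],
        )
        assert np.allclose(out.grid["mean_mm"], interp, rtol=1e-9)
        assert np.allclose(out.grid["se_mm"], 0.0)

    def test_pure_time_shifts_removed(self, gp):
        # whole-hour shifts keep the sampling phase identical, so the
        # alignment must remove the shifts exactly
        shifts = np.array([1800.0, 2100.0, 2400.0, 2700.0])
        curves = [self._noise_free_curve(gp, tg, t_end=10080.0)
                  for tg in shifts]
        out = align_growth_curves(curves)
        # after alignment all curves coincide, so the pointwise SE vanishes
        assert np.allclose(out.grid["se_mm"], 0.0, atol=1e-9)
        spread = np.ptp(out.crossing_times - shifts)
        assert spread < 1e-6  # shifts recovered up to a common offset

    def test_jittered_panel_recovers_generating_mean(self):
        """Crossing-time estimate lands within 2 SE of the panel's own
        mean initiation time."""
        spec = SyntheticSpec(seed=11)
        curves, truth = generate_seedling_panel(spec)
        out = align_growth_curves(curves)
        draw_mean = truth["t_growth_draws"].mean()
        sd = np.hypot(out.t_growth_se, 30.0)  # alignment noise floor
        assert abs(out.t_growth_mean - draw_mean) < 2 * sd

    def test_non_crossing_curve_excluded_with_warning(self, gp):
        flat = pd.DataFrame({
            "time_min": np.arange(0.0, 8641.0, 60.0),
            "length_mm": np.full(145, 0.3),
        })
        curves = [self._noise_free_curve(gp, 2000.0) for _ in range(3)] + [flat]
        with pytest.warns(UserWarning):
            out = align_growth_curves(curves)
        assert out.n_used == 3
        assert out.n_excluded == 1


class TestPooledSe:
    def test_rms_pooling(self):
        ds = ExperimentDataset("degradation", [0.0, 10.0], [1.0, 0.9],
                               [0.1, 0.3])
        pooled = with_pooled_se(ds)
        assert np.allclose(pooled.se, np.sqrt((0.01 + 0.09) / 2))

    def test_zero_noise_passthrough(self):
        ds = ExperimentDataset("degradation", [0.0, 10.0], [1.0, 0.9],
                               [0.0, 0.0])
        assert with_pooled_se(ds) is ds
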