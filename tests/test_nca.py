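import numpy as np
import pytest
from scipy.integrate import quad

import glycopk as g
import glycopk.io as gio
from glycopk.model import AnalysisConfig, ConcentrationSeries, SampleProfile, SchemaError
from glycopk.nca import (
    GlycoformConcSeries,
    auc_trapezoid,
    estimate_lambda_z,
    nca_study,
    normalize_to_reference,
    split_concentrations,
)


def series(times, concs, route="IV", glycoform="G0F"):
    return GlycoformConcSeries("A1", "G", glycoform, np.asarray(times, float), np.asarray(concs, float), route)


class TestSplitConcentrations:
    def profile(self, time_h, fractions, animal="A1", group="G"):
        return SampleProfile(animal, group, "IV", time_h, fractions)

    def test_fraction_times_total(self):
        profiles = [self.profile(24.0, {"G0F": 0.6, "G1F": 0.4}), self.profile(48.0, {"G0F": 0.6, "G1F": 0.4})]
        conc = [ConcentrationSeries("A1", "G", [24.0, 48.0], [5.0, 2.5], [False, False])]
        split = {s.glycoform: s for s in split_concentrations(profiles, conc)}
        assert split["G0F"].conc_ug_ml.tolist() == [3.0, 1.5]
        assert split["G1F"].conc_ug_ml.tolist() == [2.0, 1.0]

    def test_points_beyond_analysis_window_dropped(self):
        profiles = [self.profile(t, {"G0F": 1.0}) for t in (24.0, 240.0, 264.0)]
        conc = [ConcentrationSeries("A1", "G", [24.0, 240.0, 264.0], [5, 2, 1], [False] * 3)]
        split = {s.glycoform: s for s in split_concentrations(profiles, conc)}
        assert split["G0F"].times_h.tolist() == [24.0, 240.0]

    def test_bloq_totals_dropped(self):
        profiles = [self.profile(t, {"G0F": 1.0}) for t in (24.0, 168.0)]
        conc = [ConcentrationSeries("A1", "G", [24.0, 168.0], [5.0, 0.005], [False, True])]
        split = {s.glycoform: s for s in split_concentrations(profiles, conc)}
        assert split["G0F"].times_h.tolist() == [24.0]

    def test_conservation_sum_equals_total(self, make_study):
        _, _, study = make_study(seed=9)
        profiles = gio.profiles_from_frame(study.profiles, g.default_registry())
        conc = gio.concentrations_from_frame(study.concentrations)
        split = split_concentrations(profiles, conc)
        by_animal = {}
        for s in split:
            by_animal.setdefault(s.animal_id, {})[s.glycoform] = s
        for animal, d in by_animal.items():
            total = d.pop("Total")
            summed = np.sum([s.conc_ug_ml for s in d.values()], axis=0)
            np.testing.assert_allclose(summed, total.conc_ug_ml, rtol=0, atol=1e-12)

    def test_no_common_points_names_animal(self):
        profiles = [self.profile(96.0, {"G0F": 1.0})]
        conc = [ConcentrationSeries("A7", "G", [24.0], [5.0], [False])]
        with pytest.raises(SchemaError, match="A7"):
            split_concentrations(profiles, conc)


class TestLambdaZ:
    def test_exact_halving_series(self):
        fit = estimate_lambda_z(series([48, 72, 96], [4, 2, 1]))
        assert fit.lambda_z_per_h == pytest.approx(np.log(2) / 24, rel=1e-12)
        assert fit.half_life_h == pytest.approx(24.0)
        assert fit.n_points == 3

    def test_perfect_exponential_uses_all_points_with_r2_one(self):
        t = np.array([0.08, 1, 7, 24, 48, 72, 96, 168.0])
        fit = estimate_lambda_z(series(t, 10 * np.exp(-0.01 * t)))
        assert fit.r2adj == pytest.approx(1.0)
        assert fit.n_points == len(t)  # ties resolved toward more points
        assert fit.lambda_z_per_h == pytest.approx(0.01, rel=1e-10)

    def test_sc_excludes_tmax_itself(self):
        t = np.array([2, 7, 24, 48, 72, 96.0])
        c = np.array([2.0, 4.0, 3.0, 2.0, 1.4, 1.0])
        fit = estimate_lambda_z(series(t, c, route="SC"))
        assert fit.n_points <= 4  # only points after the 7 h peak are candidates

    def test_too_few_points_not_estimable(self):
        fit = estimate_lambda_z(series([24, 48], [4, 2]))
        assert not fit.estimable
        assert np.isnan(fit.lambda_z_per_h)

    def test_nonpositive_concentrations_excluded(self):
        fit = estimate_lambda_z(series([24, 48, 72, 96], [8, 4, 2, 0.0]))
        assert fit.estimable
        assert fit.lambda_z_per_h == pytest.approx(np.log(2) / 24, rel=1e-12)

    def test_median_bias_small_under_noise(self):
        """Log-linear best fit recovers a known slope with <2% median bias
        at 5% proportional noise."""
        rng = np.random.default_rng(123)
        k = 17.0 / 50 / 24
        times = np.array([0.08, 1, 7, 24, 48, 72, 96, 168.0])
        sigma = np.sqrt(np.log(1 + 0.05**2))
        estimates = []
        for _ in range(1000):
            c = 10 * np.exp(-k * times) * np.exp(rng.normal(-sigma**2 / 2, sigma, times.size))
            fit = estimate_lambda_z(series(times, c))
            if fit.estimable:
                estimates.append(fit.lambda_z_per_h)
        assert len(estimates) > 990
        assert abs(np.median(estimates) / k - 1) < 0.02


class TestAUC:
    def test_hand_trapezoid_and_extrapolation(self):
        s = series([0, 24, 48, 72], [10, 5, 2.5, 1.25])
        lz = np.log(2) / 24
        auc = auc_trapezoid(s, lz)
        assert auc.auc_last == pytest.approx(315.0)
        assert auc.auc_inf == pytest.approx(315.0 + 1.25 / lz, rel=1e-12)
        assert auc.auc_inf == pytest.approx(358.28, abs=0.005)
        assert auc.extrap_percent == pytest.approx(100 * (auc.auc_inf - 315) / auc.auc_inf)

    def test_constant_segment(self):
        auc = auc_trapezoid(series([0, 48], [3.0, 3.0]), None)
        assert auc.auc_last == pytest.approx(144.0)
        assert np.isnan(auc.auc_inf)

    def test_halving_intervals_converges_to_quadrature(self):
        f = lambda t: 10 * np.exp(-0.01 * t)  # noqa: E731
        exact, _ = quad(f, 0, 100)
        errors = []
        for n in (8, 16, 32):
            t = np.linspace(0, 100, n + 1)
            auc = auc_trapezoid(series(t, f(t)), None)
            errors.append(abs(auc.auc_last - exact))
        assert errors[1] < errors[0] / 3.5  # ~4x per halving for trapezoid
        assert errors[2] < errors[1] / 3.5

    def test_lin_up_log_down_below_linear_on_decay(self):
        config = AnalysisConfig(trapezoid_rule="lin-up-log-down")
        s = series([0, 24, 48], [10, 5, 2.5])
        assert auc_trapezoid(s, None, config).auc_last < auc_trapezoid(s, None).auc_last

    def test_high_extrapolation_warns(self):
        s = series([0, 24, 48], [10, 9.9, 9.8])
        with pytest.warns(UserWarning, match="extrapolated"):
            auc_trapezoid(s, 0.0001)


def monoexponential_study(k_per_day, fractions, dose_mg_kg=0.5, v_ml_kg=50.0,
                          times=(0.08, 1, 7, 24, 48, 72, 96, 168.0), group="G"):
    """Noise-free study with one shared elimination rate for every glycoform."""
    times = np.asarray(times, float)
    conc = dose_mg_kg * 1000 / v_ml_kg * np.exp(-k_per_day * times / 24.0)
    profiles = [SampleProfile("A1", group, "IV", t, dict(fractions)) for t in times]
    series_ = [ConcentrationSeries("A1", group, times, conc, np.zeros(times.size, bool))]
    return profiles, series_


class TestNCAStudy:
    def test_closed_form_clearance_recovery(self, registry):
        """Monoexponential IV series with V=50 mL/kg, k=0.018/day: true
        CL = 0.9 mL/day/kg, recovered within trapezoid discretization error."""
        profiles, conc = monoexponential_study(0.018, {"G0F": 1.0})
        dose = g.DoseSpec("G", 0.5, "IV", SampleProfile("std", "G", "STD", 0.0, {"G0F": 1.0}))
        nca = nca_study(profiles, conc, dose).set_index("glycoform")
        assert nca.loc["G0F", "clearance_ml_day_kg"] == pytest.approx(0.9, rel=0.03)
        assert nca.loc["G0F", "cl_label"] == "CL"

    def test_standard_fraction_scales_dose_and_clearance(self):
        profiles, conc = monoexponential_study(0.3, {"G0F": 0.5, "G1F": 0.5})
        std_even = SampleProfile("std", "G", "STD", 0.0, {"G0F": 0.5, "G1F": 0.5})
        std_quarter = SampleProfile("std", "G", "STD", 0.0, {"G0F": 0.25, "G1F": 0.75})
        nca_even = nca_study(profiles, conc, g.DoseSpec("G", 0.5, "IV", std_even)).set_index("glycoform")
        nca_quart = nca_study(profiles, conc, g.DoseSpec("G", 0.5, "IV", std_quarter)).set_index("glycoform")
        assert nca_quart.loc["G0F", "dose_ug_kg"] == pytest.approx(
            0.5 * nca_even.loc["G0F", "dose_ug_kg"]
        )
        assert nca_quart.loc["G0F", "clearance_ml_day_kg"] == pytest.approx(
            0.5 * nca_even.loc["G0F", "clearance_ml_day_kg"]
        )

    def test_glycoform_missing_from_standard_rejected(self):
        profiles, conc = monoexponential_study(0.3, {"G0F": 0.5, "G1F": 0.5})
        std = SampleProfile("std", "G", "STD", 0.0, {"G0F": 1.0})
        with pytest.raises(SchemaError, match="G1F"):
            nca_study(profiles, conc, g.DoseSpec("G", 0.5, "IV", std))

    def test_dose_conservation(self, make_study):
        design, _, study = make_study(seed=1)
        total = sum(
            design.dose.dose_ug_per_kg(gl) for gl in design.dose.standard_profile.fractions
        )
        assert total == pytest.approx(design.dose.nominal_dose_mg_per_kg * 1000, rel=1e-12)

    def test_auc_additivity_across_glycoforms(self, make_study, registry):
        _, _, study = make_study(seed=6)
        profiles = gio.profiles_from_frame(study.profiles, registry)
        conc = gio.concentrations_from_frame(study.concentrations)
        design = g.default_study_design("IV")
        nca = nca_study(profiles, conc, design.dose)
        for animal, sub in nca.groupby("animal_id"):
            total = sub.loc[sub["glycoform"] == "Total", "auc_last_ug_h_ml"].item()
            parts = sub.loc[sub["glycoform"] != "Total", "auc_last_ug_h_ml"].sum()
            assert parts == pytest.approx(total, rel=1e-12)

    def test_clearance_invariant_to_uniform_rescaling(self):
        profiles, conc = monoexponential_study(0.3, {"G0F": 1.0})
        std = SampleProfile("std", "G", "STD", 0.0, {"G0F": 1.0})
        base = nca_study(profiles, conc, g.DoseSpec("G", 0.5, "IV", std)).set_index("glycoform")
        scaled_conc = [
            ConcentrationSeries(s.animal_id, s.group, s.times_h, 10 * s.conc_ug_ml, s.bloq)
            for s in conc
        ]
        scaled = nca_study(profiles, scaled_conc, g.DoseSpec("G", 5.0, "IV", std)).set_index("glycoform")
        assert scaled.loc["G0F", "clearance_ml_day_kg"] == pytest.approx(
            base.loc["G0F", "clearance_ml_day_kg"], rel=1e-12
        )

    def test_noise_free_rank_order_matches_planted_multipliers(self, make_study, registry):
        design, params, study = make_study(seed=3, noise=g.NoiseModel(seed=3).silent())
        profiles = gio.profiles_from_frame(study.profiles, registry)
        conc = gio.concentrations_from_frame(study.concentrations)
        nca = nca_study(profiles, conc, design.dose)
        means = (
            nca[nca["glycoform"] != "Total"]
            .groupby("glycoform")["clearance_ml_day_kg"]
            .mean()
            .sort_values(ascending=False)
        )
        assert list(means.index) == ["Man5", "G0F-N", "G0F", "G1F", "G2F"]


class TestNormalizeToReference:
    def test_reference_ratio_exactly_one(self, make_study, registry):
        design, _, study = make_study(seed=2)
        profiles = gio.profiles_from_frame(study.profiles, registry)
        conc = gio.concentrations_from_frame(study.concentrations)
        nca = nca_study(profiles, conc, design.dose)
        tidy, summary = normalize_to_reference(nca, "G0F")
        ref = tidy[tidy["glycoform"] == "G0F"]["ratio"]
        assert (ref == 1.0).all()
        assert summary.set_index("glycoform").loc["G0F", "sd"] == 0.0

    def test_printed_mean_arithmetic(self):
        # an animal with CL_Man5 = 1.04 and CL_G0F = 0.88 has ratio ~1.182
        assert 1.04 / 0.88 == pytest.approx(1.182, abs=5e-4)

    def test_noise_free_ratios_equal_planted_multipliers(self, make_study, registry):
        design, params, study = make_study(seed=8, noise=g.NoiseModel(seed=8).silent())
        profiles = gio.profiles_from_frame(study.profiles, registry)
        conc = gio.concentrations_from_frame(study.concentrations)
        nca = nca_study(profiles, conc, design.dose)
        _, summary = normalize_to_reference(nca, "G0F")
        for _, row in summary.iterrows():
            assert row["mean"] == pytest.approx(
                params.cl_multipliers[row["glycoform"]], rel=5e-3
            )

    def test_missing_reference_animal_excluded_with_warning(self, caplog):
        import pandas as pd

        results = pd.DataFrame(
            {
                "animal_id": ["A1", "A1", "A2"],
                "glycoform": ["G0F", "Man5", "Man5"],
                "clearance_ml_day_kg": [0.88, 1.04, 1.10],
            }
        )
        with caplog.at_level("WARNING"):
            tidy, _ = normalize_to_reference(results, "G0F")
        assert set(tidy["animal_id"]) == {"A1"}
        assert any("A2" in r.message for r in caplog.records)
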