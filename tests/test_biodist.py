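"""Dose accounting, excretion curves, group comparison, method agreement."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from pdtrace import biodist, icpms
from pdtrace.biodist import (
    StudyLedger,
    compare_groups,
    cumulative_excretion,
    fit_transit_rates,
    method_agreement,
    np_count_from_mass,
    pd_dose_from_np_mass,
    percent_of_dose,
    total_recovery,
)
from pdtrace.synthetic import (
    ACUTE_REGIMEN,
    TransitRates,
    generate_icpms_batch,
    simulate_biodistribution,
)


class TestDoseArithmetic:
    def test_full_dose_is_100_percent(self):
        assert percent_of_dose(9.976, 9.976) == pytest.approx(100.0)

    def test_zero_mass_zero_percent(self):
        assert percent_of_dose(0.0, 9.976) == 0.0

    def test_above_100_percent_legal_but_flagged(self):
        with pytest.warns(UserWarning):
            pct = percent_of_dose(12.53, 9.976)
        assert pct == pytest.approx(125.6, abs=0.1)

    def test_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            percent_of_dose(1.0, 0.0)

    def test_acute_dose_pair_self_consistent(self):
        """3.3817 mg NPs at the acute Pd fraction gives back 9.976 ug Pd."""
        fraction = 9.976 / 3381.7
        assert pd_dose_from_np_mass(3.3817, fraction) == pytest.approx(9.976)

    def test_simple_fraction(self):
        assert pd_dose_from_np_mass(1.0, 0.003) == pytest.approx(3.0)

    def test_subacute_dose_close_to_printed_value(self):
        """0.99 mg at the acute-derived fraction lands within 1% of 2.91 ug."""
        fraction = 9.976 / 3381.7
        dose = pd_dose_from_np_mass(0.99, fraction)
        assert dose == pytest.approx(2.92, abs=0.01)
        assert abs(dose - 2.91) / 2.91 <= 0.01

    def test_particle_count_inverse_of_single_particle_mass(self):
        d_cm = 200e-7
        single_mass_mg = 1.05 * math.pi / 6 * d_cm**3 * 1000.0
        assert np_count_from_mass(single_mass_mg, 200.0, 1.05) == pytest.approx(1.0)

    def test_particle_count_linear_in_mass(self):
        assert np_count_from_mass(2.0) == pytest.approx(2 * np_count_from_mass(1.0))

    def test_acute_dose_particle_count_matches_geometry_oracle(self):
        """3.3817 mg at d=200 nm, rho=1.05: count = m / (pi/6 d^3 rho)."""
        volume_cm3 = math.pi / 6.0 * (200e-7) ** 3
        expected = 3.3817e-3 / (volume_cm3 * 1.05)
        assert np_count_from_mass(3.3817) == pytest.approx(expected, rel=1e-12)


class TestCumulativeExcretion:
    def test_single_interval_reaches_100(self):
        series = pd.DataFrame({"time_h": [4.0], "pd_mass_ug": [9.976]})
        curve = cumulative_excretion(series, 9.976)
        assert curve["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_all_zero_series_flat(self):
        series = pd.DataFrame({"time_h": [1.0, 2.0, 3.0], "pd_mass_ug": [0.0, 0.0, 0.0]})
        assert (cumulative_excretion(series, 1.0)["cumulative_pct"] == 0).all()

    def test_unsorted_times_rejected(self):
        series = pd.DataFrame({"time_h": [2.0, 1.0], "pd_mass_ug": [1.0, 1.0]})
        with pytest.raises(ValueError):
            cumulative_excretion(series, 1.0)

    def test_curve_non_decreasing(self):
        series = pd.DataFrame({"time_h": [1, 2, 3, 4], "pd_mass_ug": [0.5, 1.0, 0.2, 0.0]})
        curve = cumulative_excretion(series, 9.976)
        assert (np.diff(curve["cumulative_pct"]) >= 0).all()

    def test_censored_rows_contribute_per_rules(self):
        series = pd.DataFrame(
            {
                "time_h": [1.0, 2.0],
                "pd_mass_ug": [1.0, 0.5],
                "status": [icpms.STATUS_BDL, icpms.STATUS_BETWEEN],
            }
        )
        curve = cumulative_excretion(series, 10.0)
        assert curve["cumulative_pct"].iloc[0] == 0.0  # bdl contributes nothing
        assert curve["cumulative_pct"].iloc[1] == pytest.approx(5.0)
        assert curve["censored"].all()

    def test_no_uptake_long_horizon_excretes_everything(self):
        """With zero uptake the whole dose ends up excreted (conservation)."""
        study = simulate_biodistribution(
            ACUTE_REGIMEN, uptake_fraction=0.0, times_h=np.arange(1.0, 120.0, 4.0)
        )
        feces = study.pd_mass_ug["feces"].to_numpy()
        intervals = np.diff(np.concatenate([[0.0], feces]))
        series = pd.DataFrame({"time_h": study.times_h, "pd_mass_ug": intervals})
        curve = cumulative_excretion(series, 9.976)
        assert curve["cumulative_pct"].iloc[-1] == pytest.approx(100.0, abs=0.01)


def _ledger():
    organs = pd.DataFrame(
        {
            "mouse": ["m1"] * 3 + ["m2"],
            "organ": ["liver", "kidney", "colon", "liver"],
            "method": ["ICPMS"] * 4,
            "mass": [0.9976, 1.4964, 0.0, 0.5],
            "unit": ["ug"] * 4,
            "status": ["", "", icpms.STATUS_BDL, ""],
        }
    )
    return StudyLedger(applied_dose_ug=9.976, organ_masses=organs)


class TestTotalRecovery:
    def test_organ_percentages_add(self):
        """Organs at 10% and 15% of dose total 25%."""
        pct, n_censored = total_recovery(_ledger(), "m1")
        assert pct == pytest.approx(25.0)
        assert n_censored == 1

    def test_all_bdl_mouse_reports_zero_with_note(self):
        organs = pd.DataFrame(
            {
                "mouse": ["m3", "m3"],
                "organ": ["liver", "kidney"],
                "method": ["ICPMS"] * 2,
                "mass": [0.0, 0.0],
                "unit": ["ng"] * 2,
                "status": [icpms.STATUS_BDL] * 2,
            }
        )
        ledger = StudyLedger(applied_dose_ug=9.976, organ_masses=organs)
        pct, n_censored = total_recovery(ledger, "m3")
        assert pct == 0.0
        assert n_censored == 2

    def test_mixed_units_rejected(self):
        organs = _ledger().organ_masses.copy()
        organs.loc[organs.index[0], "unit"] = "ng"
        ledger = StudyLedger(applied_dose_ug=9.976, organ_masses=organs)
        with pytest.raises(ValueError):
            total_recovery(ledger, "m1")

    def test_recovery_from_virtual_icpms_matches_ground_truth(self):
        """Recovered systemic+GI fraction agrees with simulation truth."""
        study = simulate_biodistribution(ACUTE_REGIMEN, uptake_fraction=0.05, times_h=[8.0])
        masses = study.pd_mass_ug.iloc[0]
        organs = [c for c in study.compartments if c != "feces"]
        dil, vol = 100.0, 3.0
        concs = [float(masses[o]) * 1000.0 / (dil * vol) for o in organs]
        batch = generate_icpms_batch(concs, dilution_factor=dil, digest_volume_ml=vol, seed=17)
        result = icpms.quantify_batch(batch)
        rows = []
        for organ, (_, r) in zip(organs, result.iterrows()):
            mass_ng = 0.0 if r["status"] == icpms.STATUS_BDL else r["mass_ng"]
            rows.append(
                {"mouse": "m1", "organ": organ, "method": "ICPMS", "mass": mass_ng,
                 "unit": "ng", "status": r["status"] if r["status"] != icpms.STATUS_QUANTIFIED else ""}
            )
        ledger = StudyLedger(applied_dose_ug=9.976, organ_masses=pd.DataFrame(rows))
        pct, _ = total_recovery(ledger, "m1")
        truth_pct = 100.0 * sum(float(masses[o]) for o in organs) / 9.976
        # 3 sigma of propagated intensity noise on the summed masses
        sigma_pct = 3 * math.sqrt(len(organs)) * (40.0 / 5000.0) * dil * vol / 1000.0 / 9.976 * 100.0
        assert abs(pct - truth_pct) <= sigma_pct


class TestGroupComparison:
    def test_identical_groups_t0_p1(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_equal_constant_groups(self):
        t, p = compare_groups([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)

    def test_textbook_dataset_matches_closed_form(self):
        """{1,2,3} vs {4,5,6}: pooled t = -3/sqrt(2/3), df = 4."""
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        t, p = compare_groups(a, b)
        sp2 = (np.var(a, ddof=1) * 2 + np.var(b, ddof=1) * 2) / 4
        t_expected = (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (2 / 3))
        assert t == pytest.approx(t_expected, rel=1e-12)
        from scipy.stats import t as t_dist

        assert p == pytest.approx(2 * t_dist.sf(abs(t_expected), df=4), rel=1e-12)

    def test_agrees_with_permutation_oracle(self):
        """Two-sided pooled t-test p matches the exact permutation p-value."""
        a = [1.1, 2.0, 2.9, 3.5]
        b = [4.2, 5.1, 5.9, 7.0]
        _, p = compare_groups(a, b)
        pooled = np.array(a + b)
        observed = abs(np.mean(a) - np.mean(b))
        count = 0
        total = 0
        for idx in itertools.combinations(range(8), 4):
            ga = pooled[list(idx)]
            gb = pooled[[i for i in range(8) if i not in idx]]
            if abs(ga.mean() - gb.mean()) >= observed - 1e-12:
                count += 1
            total += 1
        p_perm = count / total
        assert abs(p - p_perm) <= 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestMethodAgreement:
    def _paired(self, factor=1.0):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        return pd.DataFrame({"sample": list("abcd"), "mass_a": a, "mass_b": factor * a})

    def test_identical_columns(self):
        stats = method_agreement(self._paired())
        assert stats.slope_through_origin == pytest.approx(1.0)
        assert stats.mean_relative_difference == pytest.approx(0.0)

    def test_proportional_bias_recovered_in_slope(self):
        stats = method_agreement(self._paired(0.8))
        assert stats.slope_through_origin == pytest.approx(0.8)

    def test_censored_pairs_excluded_with_note(self):
        df = self._paired()
        df["status_a"] = ["", icpms.STATUS_BDL, "", ""]
        stats = method_agreement(df)
        assert stats.n_pairs == 3
        assert stats.n_excluded_censored == 1

    def test_simulated_paired_outputs_agree(self):
        """Virtual XFI vs ICP-MS organ masses: slope within 3 sigma of 1."""
        rng = np.random.default_rng(5)
        truth = np.array([0.5, 1.0, 1.5, 2.0, 3.0, 4.0])
        rel_sd = 0.03
        slopes = []
        for _ in range(50):
            a = truth * (1 + rng.normal(0, rel_sd, truth.size))
            b = truth * (1 + rng.normal(0, rel_sd, truth.size))
            df = pd.DataFrame({"sample": range(6), "mass_a": a, "mass_b": b})
            slopes.append(method_agreement(df).slope_through_origin)
        se = np.std(slopes, ddof=1) / math.sqrt(len(slopes))
        assert abs(np.mean(slopes) - 1.0) <= 3 * se


class TestTransitRateRecovery:
    def test_rates_recovered_from_noisy_organ_time_courses(self):
        """ICP-MS-noise compartment sampling recovers each rate within 10%."""
        true = TransitRates()
        times = [1, 2, 4, 6, 8, 12]
        study = simulate_biodistribution(ACUTE_REGIMEN, rates=true, uptake_fraction=0.0, times_h=times)
        cols = ["stomach", "small_intestine", "cecum", "colon", "feces"]
        truth = study.pd_mass_ug[cols]
        dil, vol = 100.0, 3.0
        concs = (truth.to_numpy().ravel() * 1000.0 / (dil * vol)).tolist()
        batch = generate_icpms_batch(concs, dilution_factor=dil, digest_volume_ml=vol, seed=7)
        result = icpms.quantify_batch(batch)
        measured = result["mass_ng"].to_numpy() / 1000.0
        measured = np.nan_to_num(measured).reshape(truth.shape)
        observed = pd.DataFrame(measured, index=truth.index, columns=cols)
        fitted = fit_transit_rates(observed, ACUTE_REGIMEN, uptake_fraction=0.0)
        for name, k_true in true.as_dict().items():
            assert getattr(fitted, name) == pytest.approx(k_true, rel=0.10), name
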