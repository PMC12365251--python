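"""Generator checks: transit dynamics, virtual instruments, titration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pdtrace import synthetic as syn
from pdtrace.constants import PD_ISOTOPE_ABUNDANCE
from pdtrace.synthetic import (
    ACUTE_REGIMEN,
    DoseRegimen,
    ParticleBatch,
    TransitRates,
    generate_icpms_batch,
    generate_imc_roi,
    generate_titration_series,
    generate_xfi_scan,
    simulate_biodistribution,
)
from pdtrace.xfi import DetectorGeometry


class TestDomainTypes:
    def test_particle_batch_rejects_bad_fraction(self):
        with pytest.raises(ValueError):
            ParticleBatch(pd_mass_fraction=1.5)
        with pytest.raises(ValueError):
            ParticleBatch(diameter_nm=-1)

    def test_regimen_schedule_must_increase(self):
        with pytest.raises(ValueError):
            DoseRegimen(daily_np_mass_mg=1.0, daily_pd_mass_ug=3.0, schedule_h=(0.0, 0.0))

    def test_regimen_consistency_with_batch(self):
        batch = ParticleBatch()
        ACUTE_REGIMEN.check_consistency(batch, rtol=0.01)
        bad = DoseRegimen(daily_np_mass_mg=3.3817, daily_pd_mass_ug=5.0)
        with pytest.raises(ValueError):
            bad.check_consistency(batch, rtol=0.01)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            TransitRates(stomach_to_si=-0.1)


class TestTransitSimulation:
    def test_no_transfer_identity(self, acute_regimen):
        """With all rates zero the bolus stays in the stomach."""
        rates = TransitRates(0.0, 0.0, 0.0, 0.0)
        study = simulate_biodistribution(
            acute_regimen, rates=rates, uptake_fraction=0.0, times_h=[1, 4, 24]
        )
        assert np.allclose(study.pd_mass_ug["stomach"], 9.976)
        assert np.allclose(study.pd_mass_ug["feces"], 0.0)

    def test_fast_rates_limit(self, acute_regimen):
        """Very large rates flush >=99.9% of the dose to feces+systemic by 24 h."""
        rates = TransitRates(1e3, 1e3, 1e3, 1e3)
        study = simulate_biodistribution(
            acute_regimen, rates=rates, uptake_fraction=0.02, times_h=[24]
        )
        out = study.pd_mass_ug[["feces", "systemic"]].iloc[0].sum()
        assert out >= 0.999 * 9.976

    def test_feces_matches_independent_ode_oracle(self, acute_regimen):
        """Closed-form propagation agrees with a tightly tolerated ODE solve.

        Chain 1.5/0.8/0.5/0.6 per hour, no uptake, single dose: the fecal
        mass at 4 h is computed independently by scipy's stiff integrator
        on the same 5-state linear system.
        """
        k = (1.5, 0.8, 0.5, 0.6)

        def rhs(_t, y):
            s, si, c, co, f = y
            return [
                -k[0] * s,
                k[0] * s - k[1] * si,
                k[1] * si - k[2] * c,
                k[2] * c - k[3] * co,
                k[3] * co,
            ]

        sol = solve_ivp(rhs, (0, 4), [9.976, 0, 0, 0, 0], rtol=1e-11, atol=1e-12)
        expected_feces = sol.y[4, -1]

        study = simulate_biodistribution(
            acute_regimen, rates=TransitRates(*k), uptake_fraction=0.0, times_h=[4]
        )
        assert study.pd_mass_ug["feces"].iloc[0] == pytest.approx(expected_feces, rel=1e-8)

    @given(
        k=st.tuples(*[st.floats(0.0, 5.0) for _ in range(4)]),
        uptake=st.floats(0.0, 1.0),
    )
    def test_mass_conservation(self, k, uptake):
        """Administered dose equals compartment sum at every output time."""
        study = simulate_biodistribution(
            ACUTE_REGIMEN, rates=TransitRates(*k), uptake_fraction=uptake, times_h=[0.5, 3, 10]
        )
        assert study.mass_balance_error() <= 1e-9
        assert (study.pd_mass_ug.to_numpy() >= -1e-12).all()

    def test_multi_dose_superposition(self):
        regimen = DoseRegimen(
            daily_np_mass_mg=0.99, daily_pd_mass_ug=2.91, schedule_h=(0.0, 24.0, 48.0)
        )
        study = simulate_biodistribution(regimen, times_h=[12, 36, 60])
        assert study.administered_ug(36) == pytest.approx(2 * 2.91)
        assert study.mass_balance_error() <= 1e-9

    def test_rejects_unsorted_times(self, acute_regimen):
        with pytest.raises(ValueError):
            simulate_biodistribution(acute_regimen, times_h=[4, 2])

    def test_deterministic_given_seed(self, acute_regimen):
        a = simulate_biodistribution(acute_regimen, times_h=[1, 2], seed=5)
        b = simulate_biodistribution(acute_regimen, times_h=[1, 2], seed=5)
        assert a.pd_mass_ug.equals(b.pd_mass_ug)


class TestXfiGenerator:
    def test_zero_mass_zero_background_gives_empty_spectra(self):
        scan = generate_xfi_scan(
            np.zeros((2, 2)), background_rate=0.0, reference_areal_masses_ug_cm2=(), seed=0
        )
        assert np.all(scan.counts == 0)

    def test_noise_free_linearity_in_mass(self):
        """Doubling the pixel mass exactly doubles the expected line counts."""
        s1 = generate_xfi_scan(np.array([[1.0]]), background_rate=0.0, poisson=False,
                               reference_areal_masses_ug_cm2=())
        s2 = generate_xfi_scan(np.array([[2.0]]), background_rate=0.0, poisson=False,
                               reference_areal_masses_ug_cm2=())
        assert np.allclose(s2.counts, 2.0 * s1.counts, rtol=1e-12)

    def test_solid_angle_fraction_matches_numeric_integration(self):
        """Flat-disc formula vs brute-force integration over the detector disc."""
        det = DetectorGeometry()  # 10 x 0.5 cm^2 at 6 cm
        radius = math.sqrt(det.area_cm2 / math.pi)
        n = 400
        xs = np.linspace(-radius, radius, n)
        xx, yy = np.meshgrid(xs, xs)
        inside = xx**2 + yy**2 <= radius**2
        da = (xs[1] - xs[0]) ** 2
        r2 = det.distance_cm**2 + xx**2 + yy**2
        omega_one = np.sum((det.distance_cm / np.sqrt(r2) / r2)[inside]) * da
        numeric_fraction = det.n_detectors * omega_one / (4 * math.pi)
        assert det.solid_angle_fraction == pytest.approx(numeric_fraction, rel=0.01)
        assert det.solid_angle_fraction == pytest.approx(10 * 0.5 / (4 * math.pi * 36), rel=1e-12)

    def test_rejects_negative_truth(self):
        with pytest.raises(ValueError):
            generate_xfi_scan(np.array([[-1.0]]))

    def test_scan_deterministic_given_seed(self):
        a = generate_xfi_scan(np.ones((2, 2)), seed=11)
        b = generate_xfi_scan(np.ones((2, 2)), seed=11)
        assert np.array_equal(a.counts, b.counts)


class TestIcpmsGenerator:
    def test_exact_intensities_without_noise_or_drift(self):
        batch = generate_icpms_batch([2.0], slope=100.0, intercept=7.0, blank_sd=0.0, drift=0.0)
        sample = batch.samples.iloc[0]
        assert sample["intensity_106"] == pytest.approx(100.0 * 2.0 + 7.0)

    def test_internal_standard_decays_by_drift(self):
        batch = generate_icpms_batch([1.0], blank_sd=0.0, drift=0.10)
        is_channel = batch.records.sort_values("order")["intensity_IS"]
        assert is_channel.iloc[-1] / is_channel.iloc[0] == pytest.approx(0.90)

    def test_standards_sit_on_calibration_grid(self):
        batch = generate_icpms_batch([], blank_sd=0.0)
        assert list(batch.standards["nominal_conc"]) == [0, 0.1, 0.5, 1.0, 2.5, 5.0, 12.5, 25.0]


class TestImcGenerator:
    def test_pure_noise_stays_below_one_dual_count(self):
        roi = generate_imc_roi(30, 30, [], noise_max=1.0, seed=2)
        for grid in roi.channels.values():
            assert np.all(grid <= 1.0)

    def test_out_of_grid_particle_rejected(self):
        with pytest.raises(ValueError):
            generate_imc_roi(10, 10, [(10, 0, 1)])

    def test_single_particle_signal_has_poisson_mean_one(self):
        """Summed-channel ion count at a 1-particle pixel averages 1 over seeds."""
        n = 10_000
        rng = np.random.default_rng(123)
        seeds = rng.integers(0, 2**31, size=n)
        totals = np.empty(n)
        for i, s in enumerate(seeds):
            roi = generate_imc_roi(1, 1, [(0, 0, 1)], ions_per_particle=1.0, noise_max=0.0, seed=int(s))
            totals[i] = sum(g[0, 0] for g in roi.channels.values())
        se = totals.std(ddof=1) / math.sqrt(n)
        assert abs(totals.mean() - 1.0) <= 3 * se

    def test_channel_shares_follow_natural_abundance(self):
        """Many ions split with 106Pd and 108Pd as the top non-105 channels."""
        roi = generate_imc_roi(
            1, 1, [(0, 0, 20_000)], ions_per_particle=1.0, noise_max=0.0, seed=9
        )
        shares = {ch: g[0, 0] for ch, g in roi.channels.items()}
        total = sum(shares.values())
        for mass, abundance in PD_ISOTOPE_ABUNDANCE.items():
            assert shares[f"Pd{mass}"] / total == pytest.approx(abundance, abs=0.02)
        non105 = {ch: v for ch, v in shares.items() if ch != "Pd105"}
        top_two = sorted(non105, key=non105.get, reverse=True)[:2]
        assert set(top_two) == {"Pd106", "Pd108"}


class TestTitrationGenerator:
    def test_spot_one_mass_from_stock(self):
        series = generate_titration_series(91.0, n_dilutions=39, spot_volume_ul=0.2)
        assert series.spots[0].pd_mass_ng == pytest.approx(18.2)

    def test_single_spot_when_no_dilutions(self):
        series = generate_titration_series(50.0, n_dilutions=0, factor_convention="spot1")
        assert len(series.spots) == 1
        assert series.spots[0].dilution_factor == 1

    def test_cumulative_factor_is_exact_power_of_two(self):
        """After 40 two-fold dilution steps the factor is exactly 2^40."""
        series = generate_titration_series(91.0, n_dilutions=39)
        assert series.spots[39].dilution_factor == 2**40 == 1099511627776
        spot1_convention = generate_titration_series(91.0, n_dilutions=39, factor_convention="spot1")
        assert spot1_convention.spots[39].dilution_factor == 2**39

    def test_masses_strictly_halve(self):
        series = generate_titration_series(10.0, n_dilutions=12)
        masses = np.array([s.pd_mass_ng for s in series.spots])
        assert np.allclose(masses[1:] / masses[:-1], 0.5)
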