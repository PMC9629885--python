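"""Simulator: dose design, exact mass balance, oracle equivalence,
depletion bias, and the default maturation scenario's ground truth."""

import numpy as np
import pytest

import ada_affinity as aa
from ada_affinity.fit import fit_monophasic
from ada_affinity.simulate import PatientPlan


def bisect_free_ligand(l_tot, site_tot, kd, iters=200):
    """Independent brute-force bisection on the monotone mass balance."""
    lo, hi = 0.0, l_tot
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if mid + site_tot * mid / (kd + mid) < l_tot:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestDoseSeries:
    def test_default_assay_design(self):
        ds = aa.make_dose_series()
        assert len(ds.doses) == 8
        assert ds.doses_source[0] == 1000.0
        # 1000 / 5**7 = 0.0128 ng/mL, printed as "0.01" at display rounding
        assert ds.doses_source[-1] == pytest.approx(0.0128, rel=1e-12)

    def test_two_point_series(self):
        ds = aa.make_dose_series(top=7.0, fold=2.0, n=2, unit="M")
        np.testing.assert_allclose(ds.doses_molar, [7.0, 3.5])

    def test_powers_of_ten(self):
        ds = aa.make_dose_series(top=100.0, fold=10.0, n=4, unit="M")
        np.testing.assert_allclose(ds.doses_molar, [100.0, 10.0, 1.0, 0.1])

    def test_preconditions(self):
        with pytest.raises(ValueError):
            aa.make_dose_series(top=0.0)
        with pytest.raises(ValueError):
            aa.make_dose_series(fold=1.0)
        with pytest.raises(ValueError):
            aa.make_dose_series(n=1)


class TestFreeLigand:
    def test_no_sites_returns_total(self):
        assert aa.free_ligand(1e-9, 0.0, 1e-12) == 1e-9

    def test_zero_ligand(self):
        assert aa.free_ligand(0.0, 1e-9, 1e-12) == 0.0

    @pytest.mark.parametrize(
        "l_tot,site,kd",
        [(1e-9, 1e-9, 1e-9), (5e-12, 1e-10, 2e-12), (1e-7, 1e-9, 1e-12)],
    )
    def test_matches_independent_bisection(self, l_tot, site, kd):
        got = aa.free_ligand(l_tot, site, kd)
        assert got == pytest.approx(bisect_free_ligand(l_tot, site, kd), rel=1e-12)

    def test_equal_concentrations_golden_ratio(self):
        # l_tot = site = kd reduces the balance to l^2 + l - 1 = 0 in kd
        # units: free fraction is (sqrt(5)-1)/2
        L = aa.free_ligand(1e-9, 1e-9, 1e-9)
        assert L == pytest.approx(1e-9 * (np.sqrt(5) - 1) / 2, rel=1e-12)

    def test_mass_conservation(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            l_tot = 10.0 ** rng.uniform(-13, -7)
            site = 10.0 ** rng.uniform(-15, -8)
            kd = 10.0 ** rng.uniform(-13, -8)
            L = aa.free_ligand(l_tot, site, kd)
            bound = site * L / (kd + L)
            assert L + bound == pytest.approx(l_tot, rel=1e-10)

    def test_multi_clone_pool(self):
        sites = np.array([1e-10, 2e-10])
        kds = np.array([1e-12, 1e-9])
        L = aa.free_ligand(1e-9, sites, kds)
        total = L + float(np.sum(sites * L / (kds + L)))
        assert total == pytest.approx(1e-9, rel=1e-10)


class TestDetectableFraction:
    def test_no_occupancy(self):
        assert aa.detectable_fraction(0.0, 1e-12) == 1.0

    def test_half_occupancy(self):
        # theta = 1/2 -> 1 - 1/4
        assert aa.detectable_fraction(1e-12, 1e-12) == 0.75

    def test_high_occupancy_hand_value(self):
        kd = 1e-12
        assert aa.detectable_fraction(99 * kd, kd) == pytest.approx(0.0199, rel=1e-12)


class TestSimulateCurve:
    def test_excess_ligand_matches_closed_form(self, dose_series):
        # dilute sites: simulation must converge to the analytic model
        kd = 2e-12
        site = 8e-16  # <= kd/100 and <= min dose/100
        clone = aa.ClonePopulation(site_conc=site, kd=kd)
        noise = aa.AssayNoiseModel(cv=0.0, background=0.0, seed=0)
        curve = aa.simulate_curve(dose_series, [clone], scale=1e18, noise=noise)
        expected = aa.response_mono(
            dose_series.doses_molar, aa.BindingParamsMono(1e18 * site / 2, kd)
        )
        np.testing.assert_allclose(curve.signals, expected, rtol=1e-3)

    def test_excess_ligand_biphasic(self, dose_series):
        clones = [
            aa.ClonePopulation(4e-16, 1e-12),
            aa.ClonePopulation(4e-16, 1e-9),
        ]
        noise = aa.AssayNoiseModel(cv=0.0, background=0.0, seed=0)
        curve = aa.simulate_curve(dose_series, clones, scale=1e18, noise=noise)
        expected = aa.response_bi(
            dose_series.doses_molar,
            aa.BindingParamsBi(1e18 * 2e-16, 1e-12, 1e18 * 2e-16, 1e-9),
        )
        np.testing.assert_allclose(curve.signals, expected, rtol=1e-2)

    def test_point_count_and_determinism(self, dose_series):
        clone = aa.ClonePopulation(2e-14, 2e-12)
        noise = aa.AssayNoiseModel(cv=0.1, background=20.0, seed=7)
        c1 = aa.simulate_curve(dose_series, [clone], 1e18, noise)
        c2 = aa.simulate_curve(dose_series, [clone], 1e18, noise)
        assert len(c1) == 8
        np.testing.assert_array_equal(c1.signals, c2.signals)

    def test_depletion_shifts_apparent_kd_right(self, dose_series):
        # when sites >> kd the ligand pool is depleted and the fitted
        # (apparent) K_D exceeds the true per-site constant
        kd = 1e-12
        clone = aa.ClonePopulation(site_conc=1e-10, kd=kd)
        noise = aa.AssayNoiseModel(cv=0.0, background=0.0, seed=0)
        curve = aa.simulate_curve(dose_series, [clone], 1e18, noise)
        # the depleted shoulder sits near the site concentration, well
        # above K_D; the raw-signal fit tracks it
        fit = fit_monophasic(curve, weights="unweighted")
        assert fit.params.kd > 2 * kd
        # the relative-weighted fit tracks the tail but never shifts left
        fit_rel = fit_monophasic(curve)
        assert fit_rel.params.kd >= kd


class TestStudyScenario:
    def test_single_point_scenario(self, dose_series):
        plan = PatientPlan("X", (30,), 1e-10, 1e-10, 0.5, 0.5)
        scen = aa.StudyScenario(patients=(plan,), dose_spec=dose_series)
        curves, truth = aa.simulate_study(scen)
        assert len(curves) == 1 and len(truth) == 1

    def test_default_truth_decreasing_kd(self, default_study):
        truth = default_study["truth"]
        by_patient = {}
        for t in truth:
            by_patient.setdefault(t["patient_id"], []).append((t["day"], t["kd_geo"]))
        assert len(by_patient) == 7
        for days_kds in by_patient.values():
            kds = [k for _, k in sorted(days_kds)]
            assert all(a > b for a, b in zip(kds, kds[1:]))  # strictly maturing

    def test_default_fold_changes_in_design_bounds(self, default_study):
        by_patient = {}
        for t in default_study["truth"]:
            by_patient.setdefault(t["patient_id"], []).append((t["day"], t["kd_geo"]))
        for days_kds in by_patient.values():
            kds = [k for _, k in sorted(days_kds)]
            fold = kds[0] / kds[-1]
            assert 20 <= fold <= 10_000

    def test_study_determinism(self, dose_series):
        scen = aa.default_scenario(seed=5)
        c1, _ = aa.simulate_study(scen)
        c2, _ = aa.simulate_study(aa.default_scenario(seed=5))
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.signals, b.signals)
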