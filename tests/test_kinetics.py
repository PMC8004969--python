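"""Michaelis–Menten fitting, catalytic efficiency, SEC calibration."""

import numpy as np
import pandas as pd
import pytest

from loxmd.errors import FitError, InputError
from loxmd.kinetics import (
    MichaelisMenten,
    calibrate_sec,
    catalytic_efficiency,
    efficiency_fold_change,
    estimate_rh,
    kav,
    read_kinetics_csv,
    read_sec_csv,
)
from loxmd.refdata import load_reference_kinetics
from loxmd.synth import gen_mm_data, gen_sec_standards
from loxmd.util import round_half_up

S_GRID = np.array([2.0, 5.0, 10.0, 20.0, 40.0, 80.0, 160.0])


class TestMichaelisMenten:
    def test_noiseless_recovery_is_exact(self):
        kcat, km = 47.2, 21.4
        v = kcat * S_GRID / (km + S_GRID)
        fit = MichaelisMenten(S_GRID, v).fit()
        assert fit.kcat == pytest.approx(kcat, rel=1e-6)
        assert fit.KM == pytest.approx(km, rel=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)
        assert fit.efficiency == pytest.approx(kcat / km, rel=1e-12)

    def test_all_zero_rates_degenerate(self):
        with pytest.raises(FitError):
            MichaelisMenten(S_GRID, np.zeros_like(S_GRID)).fit()

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(InputError):
            MichaelisMenten([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])

    def test_noisy_monte_carlo_recovery(self):
        """>= 90% of noisy fits land within 10% of the generating parameters.

        The generator's noise is proportional to the rate, so the fit uses
        relative weighting (the matching maximum-likelihood estimator).
        """
        hits = 0
        n_rep = 100
        for i in range(n_rep):
            dataset, spec = gen_mm_data(noise_cv=0.05, replicates=3, seed=1000 + i)
            fit = MichaelisMenten.from_dataset(dataset, weights="relative").fit()
            ok_kcat = abs(fit.kcat - spec.ground_truth["kcat"]) / spec.ground_truth["kcat"] <= 0.10
            ok_km = abs(fit.KM - spec.ground_truth["KM"]) / spec.ground_truth["KM"] <= 0.10
            hits += ok_kcat and ok_km
        assert hits >= 90

    def test_rate_scaling_scales_kcat_only(self):
        v = 30.0 * S_GRID / (12.0 + S_GRID)
        f1 = MichaelisMenten(S_GRID, v).fit()
        f2 = MichaelisMenten(S_GRID, 3.0 * v).fit()
        assert f2.kcat == pytest.approx(3.0 * f1.kcat, rel=1e-8)
        assert f2.KM == pytest.approx(f1.KM, rel=1e-8)

    def test_summary_mentions_estimates(self):
        v = 10.0 * S_GRID / (5.0 + S_GRID)
        fit = MichaelisMenten(S_GRID, v, substrate="LA").fit()
        text = fit.summary()
        assert "kcat" in text and "LA" in text

    def test_csv_round_trip(self, tmp_path):
        dataset, _ = gen_mm_data(noise_cv=0.0, seed=0, substrate="AA")
        path = tmp_path / "kin.csv"
        dataset.points.assign(substrate="AA").to_csv(path, index=False)
        loaded = read_kinetics_csv(path)
        assert set(loaded) == {"AA"}
        fit = MichaelisMenten.from_dataset(loaded["AA"]).fit()
        assert fit.kcat == pytest.approx(47.2, rel=1e-6)


class TestEfficiency:
    @pytest.mark.parametrize(
        "kcat,km,display",
        [(47.2, 21.4, 2.2), (15.8, 4.9, 3.2), (39.8, 24.7, 1.6), (0.0, 5.0, 0.0)],
    )
    def test_display_rounding(self, kcat, km, display):
        assert round_half_up(catalytic_efficiency(kcat, km), 1) == pytest.approx(display)

    def test_reference_table_efficiencies(self):
        """Recomputed kcat/KM matches the published one-decimal cells."""
        expected = {
            ("WT", "LA"): 2.2, ("WT", "AA"): 1.4,
            ("His585Glu", "LA"): 1.1, ("His585Glu", "AA"): 3.2,
            ("Trp181Glu", "LA"): 1.6, ("Trp181Glu", "AA"): 8.2,
        }
        ref = load_reference_kinetics()
        for _, row in ref.iterrows():
            eff = catalytic_efficiency(row["kcat_per_s"], row["KM_uM"])
            assert round_half_up(eff, 1) == pytest.approx(
                expected[(row["enzyme"], row["substrate"])]
            ), (row["enzyme"], row["substrate"])

    def test_fold_change(self):
        assert round_half_up(efficiency_fold_change(8.3, 1.4), 1) == pytest.approx(5.9)
        assert efficiency_fold_change(2.0, 2.0) == pytest.approx(1.0)
        assert round_half_up(efficiency_fold_change(3.2, 1.4), 1) == pytest.approx(2.3)
        with pytest.raises(InputError):
            efficiency_fold_change(1.0, 0.0)

    def test_invalid_km_rejected(self):
        with pytest.raises(InputError):
            catalytic_efficiency(10.0, 0.0)


class TestKav:
    def test_boundaries(self):
        assert kav(8.0, 8.0, 24.0) == pytest.approx(0.0)
        assert kav(24.0, 8.0, 24.0) == pytest.approx(1.0)
        assert kav(16.0, 8.0, 24.0) == pytest.approx(0.5)

    def test_ordering_violations(self):
        with pytest.raises(InputError):
            kav(7.0, 8.0, 24.0)
        with pytest.raises(InputError):
            kav(25.0, 8.0, 24.0)
        with pytest.raises(InputError):
            kav(10.0, 24.0, 8.0)


class TestSEC:
    def test_forward_model_identity(self):
        standards, spec = gen_sec_standards(slope=0.02, intercept=0.1, Vo=8.0, Vt=24.0)
        cal = calibrate_sec(standards, Vo=8.0, Vt=24.0)
        assert cal.r_squared == pytest.approx(1.0, abs=1e-12)
        assert cal.slope == pytest.approx(0.02, abs=1e-12)
        assert cal.intercept == pytest.approx(0.1, abs=1e-10)
        for s in standards:
            assert estimate_rh(cal, s.Ve_mL) == pytest.approx(s.Rh_A, abs=1e-9)

    def test_standard_radii_fixture_present(self):
        standards, spec = gen_sec_standards()
        assert [s.Rh_A for s in standards] == [20.9, 35.5, 52.2]
        assert spec.parameters["radii"] == [20.9, 35.5, 52.2]

    def test_two_standards_rejected(self):
        standards, _ = gen_sec_standards()
        with pytest.raises(InputError):
            calibrate_sec(standards[:2], Vo=8.0, Vt=24.0)

    def test_void_elution_query_rejected(self):
        standards, _ = gen_sec_standards()
        cal = calibrate_sec(standards, Vo=8.0, Vt=24.0)
        with pytest.raises(InputError):
            estimate_rh(cal, 8.0)  # Kav = 0, log undefined

    def test_zero_slope_generator_rejected(self):
        with pytest.raises(InputError):
            gen_sec_standards(slope=0.0)

    def test_round_trip_over_parameter_grid(self):
        for slope in (0.01, 0.02, 0.04):
            for intercept in (0.0, 0.1, 0.3):
                standards, _ = gen_sec_standards(slope=slope, intercept=intercept)
                cal = calibrate_sec(standards, Vo=8.0, Vt=24.0)
                query_ve = (standards[0].Ve_mL + standards[1].Ve_mL) / 2
                rh = estimate_rh(cal, query_ve)
                y = np.sqrt(-np.log10(kav(query_ve, 8.0, 24.0)))
                assert rh == pytest.approx((y - intercept) / slope, abs=1e-9)

    def test_csv_round_trip(self, tmp_path):
        standards, _ = gen_sec_standards()
        path = tmp_path / "sec.csv"
        pd.DataFrame(
            [{"name": s.name, "Rh_A": s.Rh_A, "Ve_mL": s.Ve_mL} for s in standards]
        ).to_csv(path, index=False)
        loaded = read_sec_csv(path)
        assert [s.name for s in loaded] == [s.name for s in standards]
        for got, want in zip(loaded, standards):
            assert got.Rh_A == pytest.approx(want.Rh_A, abs=1e-12)
            assert got.Ve_mL == pytest.approx(want.Ve_mL, abs=1e-9)
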