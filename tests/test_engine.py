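"""Deterministic risk-engine arithmetic: dilution, doses, risks, totals."""

import numpy as np
import pytest

import frackrisk as fr
from frackrisk.engine import PathwayResult, totals


@pytest.fixture
def factors():
    return fr.drinking_water_factors()


@pytest.fixture
def scenario():
    return fr.drinking_water_scenario()


class TestDilute:
    def test_barium_median_spill(self):
        """164 mg/L carried by a 128 L spill into a 44e6 L reservoir."""
        assert fr.dilute(164.0, 128.0, 44_000_000.0) == pytest.approx(4.771e-4, rel=1e-3)

    def test_zero_spill_gives_zero(self):
        assert fr.dilute(100.0, 0.0, 44e6) == 0.0

    def test_linear_in_spill_volume(self):
        assert fr.dilute(10.0, 200.0, 44e6) == pytest.approx(2 * fr.dilute(10.0, 100.0, 44e6))

    def test_nonpositive_pond_rejected(self):
        with pytest.raises(ValueError):
            fr.dilute(1.0, 1.0, 0.0)


class TestDoses:
    def test_ingestion_reference_value(self, factors, scenario):
        """2.5 L/day of 4.771e-4 mg/L, 350 d/y for 30 y, 70 kg, lifetime AT."""
        dose = fr.ingestion_dose(4.771e-4, factors, scenario, cancer=True)
        assert dose == pytest.approx(7.00e-6, rel=1e-3)

    def test_zero_concentration(self, factors, scenario):
        assert fr.ingestion_dose(0.0, factors, scenario) == 0.0

    def test_halving_averaging_time_doubles_dose(self, factors, scenario):
        import dataclasses

        short = dataclasses.replace(factors, averaging_time_cancer=factors.averaging_time_cancer / 2)
        assert fr.ingestion_dose(1.0, short, scenario) == pytest.approx(
            2 * fr.ingestion_dose(1.0, factors, scenario)
        )

    def test_air_concentration_default_factor(self, factors):
        """The shipped volatilization factor is 0.0005 x 1000 L/m3 = 0.5 L/m3."""
        assert factors.volatilization_factor == 0.5
        assert fr.air_concentration(0.17, factors) == pytest.approx(0.085)
        assert fr.air_concentration(0.0, factors) == 0.0

    def test_inhalation_reference_value(self, factors, scenario):
        dose = fr.inhalation_dose(0.085, factors, scenario, cancer=True)
        assert dose == pytest.approx(7.49e-3, rel=1e-3)

    def test_dermal_event_dose_benzene(self):
        """Kp 0.015 cm/h on 0.17 mg/L for a 43-minute event."""
        da = fr.dermal_event_dose(0.17, 0.015, 43.0 / 60.0)
        assert da == pytest.approx(1.8275e-6, rel=1e-4)

    def test_dermal_dose_scales_with_surface_area(self, factors, scenario, registry):
        import dataclasses

        benzene = registry["Benzene"]
        double = dataclasses.replace(factors, skin_surface_area=2 * factors.skin_surface_area)
        assert fr.dermal_dose(0.17, benzene, double, scenario) == pytest.approx(
            2 * fr.dermal_dose(0.17, benzene, factors, scenario)
        )

    def test_missing_permeability_disables_dermal(self, factors, scenario, registry):
        import dataclasses

        lead = registry["Lead"]
        no_kp = dataclasses.replace(lead, dermal_permeability=None)
        assert fr.dermal_dose(0.1, no_kp, factors, scenario) is None


class TestChemicalMetrics:
    def test_risk_is_dose_times_slope_factor(self, registry, factors):
        arsenic = registry["Arsenic"]
        out = fr.chemical_metrics({"ingestion": 1e-3}, arsenic, "cancer", factors)
        (r,) = out
        assert r.cancer_risk == pytest.approx(1e-3 * 1.5)

    def test_hq_is_dose_over_rfd(self, registry, factors):
        barium = registry["Barium"]
        out = fr.chemical_metrics({"ingestion": 0.5}, barium, "noncancer", factors)
        (r,) = out
        assert r.hazard_quotient == pytest.approx(0.5 / 0.2)

    def test_dermal_slope_factor_equals_oral_when_fully_absorbed(self, registry, factors):
        benzene = registry["Benzene"]  # GI absorption fraction 1
        out = {r.pathway: r for r in fr.chemical_metrics(
            {"ingestion": 1e-3, "dermal": 1e-3}, benzene, "cancer", factors)}
        assert out["dermal"].cancer_risk == pytest.approx(out["ingestion"].cancer_risk)

    def test_dermal_rfd_uses_gi_absorption(self, registry, factors):
        barium = registry["Barium"]  # GI absorption 0.07
        out = {r.pathway: r for r in fr.chemical_metrics(
            {"ingestion": 1e-2, "dermal": 1e-2}, barium, "noncancer", factors)}
        assert out["dermal"].hazard_quotient == pytest.approx(
            out["ingestion"].hazard_quotient / 0.07
        )

    def test_risk_clipped_at_one(self, registry, factors):
        arsenic = registry["Arsenic"]
        (r,) = fr.chemical_metrics({"ingestion": 10.0}, arsenic, "cancer", factors)
        assert r.cancer_risk == 1.0

    def test_unit_consistency_microgram_formulation(self, registry, factors, scenario):
        """Recomputing with ug/L concentrations and per-ug slope factors
        reproduces the mg-based risk exactly (dimensional audit)."""
        arsenic = registry["Arsenic"]
        dose_mg = fr.ingestion_dose(4.771e-4, factors, scenario, cancer=True)
        risk_mg = dose_mg * arsenic.oral_slope_factor
        dose_ug = fr.ingestion_dose(4.771e-4 * 1e3, factors, scenario, cancer=True)
        risk_ug = dose_ug * (arsenic.oral_slope_factor / 1e3)
        assert risk_ug == pytest.approx(risk_mg, rel=1e-12)


class TestRadionuclides:
    def test_ingestion_intake_accumulation(self, registry, factors, scenario):
        """1.3 pCi/L at 2.5 L/day, 350 d/y, 30 y -> 34,125 pCi of intake."""
        ra = registry["Radium-226"]
        out = {r.pathway: r for r in fr.radionuclide_metrics(1.3, ra, factors, scenario)}
        assert out["ingestion"].dose == pytest.approx(34_125.0)
        assert out["ingestion"].cancer_risk == pytest.approx(34_125.0 * ra.rad_ingestion_sf)

    def test_zero_concentration_zero_risk(self, registry, factors, scenario):
        ra = registry["Radium-228"]
        for r in fr.radionuclide_metrics(0.0, ra, factors, scenario):
            assert r.cancer_risk == 0.0

    def test_inhalation_dominates_at_median_inputs(self, registry, factors, scenario):
        """For both radium isotopes the inhalation pathway carries the
        largest risk at median concentrations."""
        for name in ("Radium-226", "Radium-228"):
            ra = registry[name]
            c_w = fr.dilute(ra.concentration_dist.median, 128.0, 44e6)
            out = {r.pathway: r.cancer_risk for r in
                   fr.radionuclide_metrics(c_w, ra, factors, scenario)}
            assert out["inhalation"] > out["ingestion"]
            assert out["inhalation"] > out["dermal"]

    def test_chemical_analyte_rejected(self, registry, factors, scenario):
        with pytest.raises(ValueError, match="not a radionuclide"):
            fr.radionuclide_metrics(1.0, registry["Benzene"], factors, scenario)


class TestAssessAndTotals:
    def test_nonvolatile_has_no_inhalation_pathway(self, registry, factors, scenario):
        out = fr.assess_contaminant(registry["Arsenic"], 1e-3, factors, scenario)
        assert {r.pathway for r in out} == {"ingestion", "dermal"}

    def test_volatile_has_inhalation_pathway(self, registry, factors, scenario):
        out = fr.assess_contaminant(registry["Benzene"], 1e-3, factors, scenario)
        assert {r.pathway for r in out} == {"ingestion", "dermal", "inhalation"}

    def test_empty_totals(self):
        assert totals([]) == (0.0, 0.0, 0.0)

    def test_pathway_additivity(self):
        rs = [
            PathwayResult("X", "ingestion", 0.0, cancer_risk=1e-7),
            PathwayResult("X", "inhalation", 0.0, cancer_risk=2e-7),
            PathwayResult("X", "dermal", 0.0, cancer_risk=3e-7),
        ]
        t_cancer, t_hi, t_rad = totals(rs)
        assert t_cancer == pytest.approx(6e-7)
        assert t_hi == 0.0 and t_rad == 0.0

    def test_radionuclide_total_kept_separate(self):
        rs = [
            PathwayResult("Benzene", "ingestion", 0.0, cancer_risk=1e-7),
            PathwayResult("Radium-226", "inhalation", 0.0, cancer_risk=5e-6),
        ]
        t_cancer, _, t_rad = totals(rs, radionuclide_names={"Radium-226"})
        assert t_cancer == pytest.approx(1e-7)
        assert t_rad == pytest.approx(5e-6)

    @pytest.mark.parametrize("scale", [2.0, 10.0])
    def test_risk_linear_in_concentration_and_duration(
        self, registry, factors, scenario, scale
    ):
        """Unclipped chemical risk scales linearly with flowback
        concentration and with exposure duration."""
        benzene = registry["Benzene"]

        def risk(c_w, ed):
            rs = fr.assess_contaminant(
                benzene, c_w, factors, scenario, ed_years=ed, clip=False
            )
            return sum(r.cancer_risk for r in rs)

        base = risk(1e-4, 30.0)
        assert risk(scale * 1e-4, 30.0) == pytest.approx(scale * base, rel=1e-12)
        assert risk(1e-4, scale * 30.0) == pytest.approx(scale * base, rel=1e-12)

    def test_vectorized_matches_scalar(self, registry, factors, scenario):
        benzene = registry["Benzene"]
        c = np.array([1e-5, 2e-4, 3e-3])
        vec = fr.assess_contaminant(benzene, c, factors, scenario)
        for i, ci in enumerate(c):
            scal = fr.assess_contaminant(benzene, float(ci), factors, scenario)
            for rv, rsc in zip(vec, scal):
                assert rv.cancer_risk[i] == pytest.approx(rsc.cancer_risk)


class TestSwimmingScenario:
    def test_swim_ingestion_uses_incidental_rate(self, registry):
        f = fr.swimming_factors()
        swim = fr.swimming_scenario()
        dose = fr.ingestion_dose(1.0, f, swim, cancer=True)
        drink = fr.ingestion_dose(1.0, f, fr.drinking_water_scenario(), cancer=True)
        # 0.05 L/h x 1 h vs 2.5 L/day
        assert dose / drink == pytest.approx(0.05 / 2.5)

    def test_swim_inhalation_prorated_over_event(self, registry):
        f = fr.swimming_factors()
        dose_swim = fr.inhalation_dose(1.0, f, fr.swimming_scenario(), cancer=True)
        dose_drink = fr.inhalation_dose(1.0, f, fr.drinking_water_scenario(), cancer=True)
        assert dose_swim / dose_drink == pytest.approx(1.0 / 24.0)
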