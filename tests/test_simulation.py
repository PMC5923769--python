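"""Monte Carlo driver, summaries, Spearman sensitivity, prioritization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import frackrisk as fr
from frackrisk.simulate import (
    prioritization_comparison,
    run_monte_carlo,
    spearman_sensitivity,
    summarize,
)


class TestRunMonteCarlo:
    def test_trial_count_and_shapes(self, drinking_run, registry):
        assert drinking_run.n_trials == 1000
        assert len(drinking_run.inputs) == 1000
        assert set(drinking_run.inputs.columns) == {"spill_volume", *registry.names()}

    def test_same_seed_bit_identical(self, registry, drinking_run):
        again = run_monte_carlo(
            registry, fr.drinking_water_scenario(), fr.drinking_water_factors(),
            n_trials=1000, seed=17,
        )
        pd.testing.assert_frame_equal(again.inputs, drinking_run.inputs)
        pd.testing.assert_frame_equal(again.totals, drinking_run.totals)
        pd.testing.assert_frame_equal(again.pathway_values, drinking_run.pathway_values)

    def test_totals_equal_sum_of_parts(self, drinking_run, registry):
        """Per trial, each total is exactly the sum of its pathway terms
        over the documented partition."""
        pv = drinking_run.pathway_values
        rad = {c.name for c in registry.radionuclides}
        is_risk = pv["metric"] == "cancer_risk"
        chem = pv[is_risk & ~pv["analyte"].isin(rad)].groupby("trial")["value"].sum()
        np.testing.assert_allclose(
            chem.to_numpy(), drinking_run.totals["total_cancer_risk"].to_numpy(), rtol=1e-12
        )
        radsum = pv[is_risk & pv["analyte"].isin(rad)].groupby("trial")["value"].sum()
        np.testing.assert_allclose(
            radsum.to_numpy(),
            drinking_run.totals["total_radionuclide_risk"].to_numpy(),
            rtol=1e-12,
        )

    def test_radionuclides_absent_from_chemical_total(self, drinking_run, registry):
        pv = drinking_run.pathway_values
        rad = {c.name for c in registry.radionuclides}
        assert not pv[(pv["metric"] == "hazard_quotient") & pv["analyte"].isin(rad)].shape[0]

    def test_trials_materialization(self, registry):
        small = run_monte_carlo(
            registry, fr.drinking_water_scenario(), fr.drinking_water_factors(),
            n_trials=5, seed=1,
        )
        trials = small.trials()
        assert len(trials) == 5
        t = trials[0]
        assert t.total_cancer_risk == pytest.approx(
            sum(r.cancer_risk for r in t.pathway_results
                if r.cancer_risk is not None and not r.analyte.startswith("Radium"))
        )


class TestSummarize:
    def test_order_statistics_ordered(self, drinking_run):
        s = summarize(drinking_run)
        t = s.table
        assert (t["min"] <= t["q25"]).all()
        assert (t["q25"] <= t["median"]).all()
        assert (t["median"] <= t["q75"]).all()
        assert (t["q75"] <= t["p95"]).all()
        assert (t["p95"] <= t["max"]).all()
        assert s.n_trials == 1000

    def test_linear_interpolation_quantiles(self):
        """trials 1..1000 -> median 500.5 and p95 950.05 under linear
        interpolation (closed-form order statistics)."""
        x = np.arange(1, 1001, dtype=float)
        assert np.quantile(x, 0.5, method="linear") == pytest.approx(500.5)
        assert np.quantile(x, 0.95, method="linear") == pytest.approx(950.05)

    def test_constant_metric_collapses(self, registry):
        r = run_monte_carlo(
            registry, fr.drinking_water_scenario(), fr.drinking_water_factors(),
            n_trials=3, seed=2,
        )
        # force a constant column and re-summarize
        r.totals["total_cancer_risk"] = 1.0
        s = summarize(r)
        row = s.totals_table.loc["total_cancer_risk"]
        assert row["min"] == row["max"] == row["median"] == 1.0


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        from scipy.stats import spearmanr

        x = np.arange(50.0)
        assert spearmanr(x, np.exp(x / 10)).statistic == pytest.approx(1.0)
        assert spearmanr(x, -np.exp(x / 10)).statistic == pytest.approx(-1.0)

    def test_frozen_concentrations_give_rho_one(self, registry):
        """With concentrations frozen at their 95th percentiles the total is
        an exact monotone (linear) function of spill volume, so
        rho(spill volume, total risk) = 1."""
        from scipy.stats import spearmanr

        from frackrisk.thresholds import metric_value

        vols = np.linspace(100, 1e5, 25)
        risks = [
            metric_value(
                "total_cancer", registry, fr.drinking_water_factors(),
                fr.drinking_water_scenario(), spill_volume=v,
            )
            for v in vols
        ]
        assert spearmanr(vols, risks).statistic == pytest.approx(1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5), scale=st.floats(0.1, 10))
    def test_invariance_under_monotone_transforms(self, shift, scale):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        base = spearmanr(x, y).statistic
        assert spearmanr(np.exp(scale * x + shift), y).statistic == pytest.approx(base)

    def test_sensitivity_table_structure(self, drinking_run, registry):
        sens = spearman_sensitivity(drinking_run)
        assert set(sens["output"]) == {
            "total_cancer_risk", "total_hazard_index", "total_radionuclide_risk",
        }
        spill = sens[sens["input"] == "spill_volume"]
        assert len(spill) == 3
        assert (spill["rho"] > 0.7).all()  # spill volume dominates all totals
        assert (spill["significance"] == "**").all()

    def test_too_few_trials_rejected(self, registry):
        tiny = run_monte_carlo(
            registry, fr.drinking_water_scenario(), fr.drinking_water_factors(),
            n_trials=5, seed=4,
        )
        with pytest.raises(ValueError, match="at least 10"):
            spearman_sensitivity(tiny)


class TestPrioritization:
    def test_collinear_points_r2_one(self):
        from scipy import stats

        xs = np.array([1.0, 2.0, 3.0, 4.0])
        ys = 2 * xs + 1
        assert stats.linregress(xs, ys).rvalue ** 2 == pytest.approx(1.0)

    def test_uncorrelated_pairs_r2_near_zero(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        x, y = rng.normal(size=1000), rng.normal(size=1000)
        assert stats.linregress(x, y).rvalue ** 2 < 0.02

    def test_default_run_cancer_beats_hi(self, drinking_run):
        """The scenario-based prioritization tracks concentration/MCL better
        for cancer risk than for hazard index."""
        r2_cancer, r2_hi = prioritization_comparison(drinking_run, fr.load_mcl_table())
        assert 0.0 <= r2_hi <= r2_cancer <= 1.0

    def test_too_few_mcls_rejected(self, drinking_run):
        with pytest.raises(ValueError, match="at least 3"):
            prioritization_comparison(drinking_run, {"Arsenic": 0.01})


class TestMonotoneDilution:
    def test_p95_total_risk_monotone_in_pond_dilution(self, registry):
        """Across paired seeded runs, a smaller pond (less dilution) cannot
        lower the 95th-percentile total risk."""
        p95s = []
        for pond in (88e6, 44e6, 11e6):
            r = run_monte_carlo(
                registry, fr.drinking_water_scenario(pond_volume=pond),
                fr.drinking_water_factors(), n_trials=300, seed=6,
            )
            p95s.append(np.quantile(r.totals["total_cancer_risk"], 0.95))
        assert p95s[0] <= p95s[1] <= p95s[2]
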