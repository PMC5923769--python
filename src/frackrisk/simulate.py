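"""Monte Carlo driver, distributional summaries, rank-correlation
sensitivity, and the risk-vs-(concentration/MCL) prioritization comparison.

Each trial draws one spill volume (shared by all analytes — they co-occur in
the same spill) and one flowback concentration per analyte (independent
draws; no correlation structure is imposed), dilutes into the scenario's
reservoir, and pushes the result through the deterministic risk engine.
Everything is reproducible from (seed, n_trials, configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import sample
from .engine import (
    SPILL_MAX_L,
    ExposureFactors,
    ScenarioConfig,
    TrialResult,
    PathwayResult,
    assess_contaminant,
    dilute,
)
from .registry import ContaminantRegistry

__all__ = [
    "MonteCarloResult",
    "RiskSummary",
    "run_monte_carlo",
    "summarize",
    "spearman_sensitivity",
    "prioritization_comparison",
]

_QUANTS = {"min": 0.0, "q25": 0.25, "median": 0.5, "q75": 0.75, "p95": 0.95, "max": 1.0}


@dataclass
class MonteCarloResult:
    """All trial-level outputs of one seeded Monte Carlo run.

    ``inputs``: one row per trial (spill volume + flowback concentration per
    analyte).  ``pathway_values``: tidy frame (trial, analyte, pathway,
    metric, value).  ``totals``: per-trial partitioned sums.
    """

    registry: ContaminantRegistry
    scenario: ScenarioConfig
    factors: ExposureFactors
    n_trials: int
    seed: int
    inputs: pd.DataFrame
    pathway_values: pd.DataFrame
    totals: pd.DataFrame

    def per_analyte_totals(self, metric: str) -> pd.DataFrame:
        """Per-trial totals across pathways for each analyte (per-analyte view)."""
        sub = self.pathway_values[self.pathway_values["metric"] == metric]
        return sub.pivot_table(
            index="trial", columns="analyte", values="value", aggfunc="sum"
        )

    def per_pathway_totals(self, metric: str) -> pd.DataFrame:
        """Per-trial totals across analytes for each pathway (per-pathway view)."""
        sub = self.pathway_values[self.pathway_values["metric"] == metric]
        return sub.pivot_table(
            index="trial", columns="pathway", values="value", aggfunc="sum"
        )

    def trials(self) -> list[TrialResult]:
        """Materialise per-trial objects (small runs / inspection)."""
        out = []
        by_trial = dict(tuple(self.pathway_values.groupby("trial")))
        for i in range(self.n_trials):
            rows = by_trial.get(i)
            results = []
            if rows is not None:
                for r in rows.itertuples():
                    results.append(
                        PathwayResult(
                            analyte=r.analyte,
                            pathway=r.pathway,
                            dose=r.dose,
                            cancer_risk=r.value if r.metric == "cancer_risk" else None,
                            hazard_quotient=r.value if r.metric == "hazard_quotient" else None,
                        )
                    )
            t = self.totals.iloc[i]
            conc = self.inputs.iloc[i].drop("spill_volume").to_dict()
            out.append(
                TrialResult(
                    spill_volume=float(self.inputs.iloc[i]["spill_volume"]),
                    concentrations=conc,
                    pathway_results=results,
                    total_cancer_risk=float(t["total_cancer_risk"]),
                    total_hazard_index=float(t["total_hazard_index"]),
                    total_radionuclide_risk=float(t["total_radionuclide_risk"]),
                )
            )
        return out


def run_monte_carlo(
    registry: ContaminantRegistry,
    scenario: ScenarioConfig,
    factors: ExposureFactors,
    n_trials: int = 1000,
    seed: int = 17,
) -> MonteCarloResult:
    """Propagate spill-volume and concentration uncertainty through the engine."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(registry) + 1)
    spill = sample(
        scenario.spill_dist,
        n_trials,
        np.random.default_rng(children[0]),
        nonnegative=True,
        upper=SPILL_MAX_L,
    )

    inputs = {"spill_volume": spill}
    frames = []
    names = registry.names()
    rad_names = {c.name for c in registry.radionuclides}
    for c, child in zip(registry, children[1:]):
        conc = sample(
            c.concentration_dist, n_trials, np.random.default_rng(child), nonnegative=True
        )
        inputs[c.name] = conc
        c_w = dilute(conc, spill, scenario.pond_volume)
        for pr in assess_contaminant(c, c_w, factors, scenario):
            if pr.cancer_risk is not None:
                metric, value = "cancer_risk", pr.cancer_risk
            else:
                metric, value = "hazard_quotient", pr.hazard_quotient
            frames.append(
                pd.DataFrame(
                    {
                        "trial": np.arange(n_trials),
                        "analyte": pr.analyte,
                        "pathway": pr.pathway,
                        "metric": metric,
                        "dose": np.asarray(pr.dose, dtype=float),
                        "value": np.asarray(value, dtype=float),
                    }
                )
            )

    pathway_values = pd.concat(frames, ignore_index=True)
    is_rad = pathway_values["analyte"].isin(rad_names)
    is_risk = pathway_values["metric"] == "cancer_risk"
    totals = pd.DataFrame(index=np.arange(n_trials))
    totals["total_cancer_risk"] = (
        pathway_values[is_risk & ~is_rad].groupby("trial")["value"].sum()
        .reindex(totals.index, fill_value=0.0)
    )
    totals["total_hazard_index"] = (
        pathway_values[~is_risk].groupby("trial")["value"].sum()
        .reindex(totals.index, fill_value=0.0)
    )
    totals["total_radionuclide_risk"] = (
        pathway_values[is_risk & is_rad].groupby("trial")["value"].sum()
        .reindex(totals.index, fill_value=0.0)
    )
    return MonteCarloResult(
        registry=registry,
        scenario=scenario,
        factors=factors,
        n_trials=n_trials,
        seed=seed,
        inputs=pd.DataFrame(inputs),
        pathway_values=pathway_values,
        totals=totals,
    )


@dataclass
class RiskSummary:
    """Order statistics (linear-interpolation quantiles) over trials."""

    table: pd.DataFrame  # index (analyte, pathway, metric); cols min..max
    totals_table: pd.DataFrame  # index metric name; cols min..max
    n_trials: int


def _row_stats(x: np.ndarray) -> dict[str, float]:
    return {k: float(np.quantile(x, q, method="linear")) for k, q in _QUANTS.items()}


def summarize(result: MonteCarloResult) -> RiskSummary:
    """Six-number summaries per analyte x pathway x metric and for the totals."""
    if result.n_trials < 1 or result.pathway_values.empty:
        raise ValueError("cannot summarize an empty run")
    rows = {}
    for key, grp in result.pathway_values.groupby(["analyte", "pathway", "metric"]):
        rows[key] = _row_stats(grp["value"].to_numpy())
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index = pd.MultiIndex.from_tuples(table.index, names=["analyte", "pathway", "metric"])
    trows = {col: _row_stats(result.totals[col].to_numpy()) for col in result.totals.columns}
    return RiskSummary(
        table=table.sort_index(),
        totals_table=pd.DataFrame.from_dict(trows, orient="index"),
        n_trials=result.n_trials,
    )


def _one_tailed_p(rho: float, n: int) -> float:
    """One-tailed significance via the t-approximation for Spearman's rho."""
    if abs(rho) >= 1.0:
        return 0.0
    t = abs(rho) * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(stats.t.sf(t, df=n - 2))


def spearman_sensitivity(result: MonteCarloResult) -> pd.DataFrame:
    """Spearman rank correlation of every sampled input against each total.

    Ties are mid-ranked (scipy convention).  Chemical concentrations are
    correlated with the chemical totals, radionuclide concentrations with
    the radionuclide total, and the shared spill volume with all three.
    Constant inputs yield missing rho.
    """
    if result.n_trials < 10:
        raise ValueError("need at least 10 trials for a rank correlation")
    rad_names = {c.name for c in result.registry.radionuclides}
    rows = []
    outputs = {
        "total_cancer_risk": result.totals["total_cancer_risk"].to_numpy(),
        "total_hazard_index": result.totals["total_hazard_index"].to_numpy(),
        "total_radionuclide_risk": result.totals["total_radionuclide_risk"].to_numpy(),
    }
    for col in result.inputs.columns:
        x = result.inputs[col].to_numpy()
        if col == "spill_volume":
            targets = list(outputs)
        elif col in rad_names:
            targets = ["total_radionuclide_risk"]
        else:
            targets = ["total_cancer_risk", "total_hazard_index"]
        for out_name in targets:
            y = outputs[out_name]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rho, p = float("nan"), float("nan")
            else:
                rho = float(stats.spearmanr(x, y).statistic)
                p = _one_tailed_p(rho, result.n_trials)
            stars = "" if math.isnan(p) else ("**" if p < 0.01 else "*" if p < 0.05 else "")
            rows.append(
                {
                    "input": col,
                    "output": out_name,
                    "rho": rho,
                    "p_one_tailed": p,
                    "significance": stars,
                }
            )
    return pd.DataFrame(rows)


def prioritization_comparison(
    result: MonteCarloResult,
    mcl_table: dict[str, float],
    *,
    log_scale: bool = True,
) -> tuple[float, float]:
    """R-squared of mean risk (and mean HI) against mean concentration / MCL.

    Compares the scenario-based prioritization with the simple
    concentration-to-standard ratio across analytes, via ordinary least
    squares on log10 scales (the quantities span orders of magnitude).
    Returns (r2 for cancer risk over carcinogens, r2 for HI over
    non-carcinogens); radionuclides are included with the carcinogen set
    through their separate risk metric.
    """
    risk_means = (
        result.pathway_values[result.pathway_values["metric"] == "cancer_risk"]
        .groupby(["trial", "analyte"])["value"].sum()
        .groupby("analyte").mean()
    )
    hi_means = (
        result.pathway_values[result.pathway_values["metric"] == "hazard_quotient"]
        .groupby(["trial", "analyte"])["value"].sum()
        .groupby("analyte").mean()
    )
    conc_means = result.inputs.drop(columns="spill_volume").mean()

    def r2(metric_means: pd.Series) -> float:
        xs, ys = [], []
        for analyte, m in metric_means.items():
            mcl = mcl_table.get(analyte)
            if mcl is None or not m > 0:
                continue
            ratio = conc_means[analyte] / mcl
            if not ratio > 0:
                continue
            if log_scale:
                xs.append(math.log10(ratio))
                ys.append(math.log10(m))
            else:
                xs.append(ratio)
                ys.append(m)
        if len(xs) < 3:
            raise ValueError("need MCLs for at least 3 analytes")
        fit = stats.linregress(xs, ys)
        return float(fit.rvalue**2)

    return r2(risk_means), r2(hi_means)
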