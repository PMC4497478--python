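"""CO2-response experiment protocol.

Long-term runs optimize the six constant vegetation parameters with SCE at
each CO2 level; medium-term runs freeze those constants at the baseline-CO2
optimum and let only the daily/hourly properties adapt. Summaries aggregate
the last N simulation years; sensitivities are relative change per relative
change in CO2.
"""
from __future__ import annotations

import dataclasses
import math
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, VomError
from .forcing import generate_synthetic_daily, hourly_forcing_arrays
from .presets import SyntheticSite, default_bounds
from .sce import LongTermParams, SCEConfig, SCEResult, sce_maximize
from .simulate import (SimResult, SimulationConfig, run_from_arrays,
                       water_balance_residual)

#: mol of water per mm depth per m^2
MOL_PER_MM = 1000.0 / 18.0

CA_LEVELS_PPM = (317.0, 350.0, 380.0)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """One simulation scenario on one site."""

    site: SyntheticSite
    c_a_ppm: float
    mode: str = "long"                      # "long" | "medium"
    frozen_params: Optional[LongTermParams] = None
    n_years: int = 6
    summary_years: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.c_a_ppm <= 0:
            raise ConfigurationError("c_a_ppm must be > 0")
        if self.mode not in ("long", "medium"):
            raise ConfigurationError("mode must be 'long' or 'medium'")
        if self.mode == "medium" and self.frozen_params is None:
            raise ConfigurationError(
                "medium-term scenarios require frozen_params")
        if self.summary_years > self.n_years:
            raise ConfigurationError("summary window exceeds simulation length")


@dataclasses.dataclass(frozen=True)
class SummaryTable:
    """Aggregates over the summary window (per-year fluxes; medians for
    lambda). Units follow the reporting conventions: mm yr^-1 water fluxes,
    mmol s^-1 conductances (per leaf area), mmol d^-1 assimilation (per
    ground area), mmol mol^-1 WUE, umol mol^-1 iWUE."""

    p: float
    q: float
    e_t_total: float
    e_t_p: float
    e_t_s: float
    e_s: float
    g_s_p: float
    g_s_s: float
    m_a_p: float
    m_a_s: float
    a_g_p: float
    a_g_s: float
    wue_p: float
    wue_s: float
    iwue_p: float
    iwue_s: float
    j_max25_p: float
    j_max25_s: float
    lambda_p_median: float
    lambda_s_median: float
    rai_p: float
    rai_s: float
    theta_1: float
    av_theta: float
    d_storage: float
    balance_residual: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def scenario_config(site: SyntheticSite) -> SimulationConfig:
    return SimulationConfig(soil=site.soil, geometry=site.geometry,
                            latitude_deg=site.latitude_deg)


def scenario_forcing(scenario: ScenarioSpec):
    """(daily series, hourly arrays) for a scenario; seeded and reusable
    across CO2 levels."""
    climate = dataclasses.replace(scenario.site.climate,
                                  rng_seed=scenario.rng_seed)
    days = generate_synthetic_daily(climate, scenario.n_years)
    arrays = hourly_forcing_arrays(days, scenario.site.latitude_deg,
                                   scenario.c_a_ppm)
    return days, arrays


def summarize(result: SimResult, last_n_years: int = 5) -> SummaryTable:
    """Aggregate a run's logs over its final ``last_n_years``.

    Fluxes are annual means, lambda entries are medians, soil saturations
    are means; the water-balance identity P = Q + E_T + d(storage) is
    evaluated over the whole run and reported as a residual.
    """
    d = result.daily
    n_days = last_n_years * 365
    if n_days > len(d):
        raise VomError("summary window longer than the simulation")
    w = d.iloc[-n_days:]
    yrs = float(last_n_years)

    e_t_p = float(w["e_t_p"].sum()) / yrs
    e_t_s = float(w["e_t_s"].sum()) / yrs
    e_s = float(w["e_s"].sum()) / yrs
    a_g_p = float(w["a_g_p"].mean())  # mol m^-2 ground d^-1
    a_g_s = float(w["a_g_s"].mean())

    def wue(ag_col, et_col):
        ag = float(w[ag_col].sum())               # mol CO2
        et_mol = float(w[et_col].sum()) * MOL_PER_MM
        return 1000.0 * ag / et_mol if et_mol > 0 else math.nan

    audit = water_balance_residual(result)
    return SummaryTable(
        p=float(w["rain"].sum()) / yrs,
        q=float(w["drainage"].sum() + w["runoff"].sum()) / yrs,
        e_t_total=e_t_p + e_t_s + e_s,
        e_t_p=e_t_p, e_t_s=e_t_s, e_s=e_s,
        g_s_p=float(w["g_s_p"].mean()) * 1000.0,
        g_s_s=float(w["g_s_s"].mean()) * 1000.0,
        m_a_p=float(w["m_a_p"].mean()),
        m_a_s=float(w["m_a_s"].mean()),
        a_g_p=a_g_p * 1000.0,
        a_g_s=a_g_s * 1000.0,
        wue_p=wue("a_g_p", "e_t_p"),
        wue_s=wue("a_g_s", "e_t_s"),
        iwue_p=float(w["iwue_p"].mean()),
        iwue_s=float(w["iwue_s"].mean()),
        j_max25_p=float(w["j_max25_p"].mean()),
        j_max25_s=float(w["j_max25_s"].mean()),
        lambda_p_median=float(w["lambda_p"].median()),
        lambda_s_median=float(w["lambda_s"].median()),
        rai_p=float(w["rai_p"].mean()),
        rai_s=float(w["rai_s"].mean()),
        theta_1=float(w["theta_1"].mean()),
        av_theta=float(w["av_theta"].mean()),
        d_storage=audit["d_storage"],
        balance_residual=audit["residual"])


class LongTermResult(NamedTuple):
    params: LongTermParams
    summary: SummaryTable
    result: SimResult
    sce: SCEResult


def _snap_transform(z_surface: float):
    def snap(x: np.ndarray) -> np.ndarray:
        x = x.copy()
        x[1] = min(max(0.5, round(x[1] / 0.5) * 0.5), z_surface)
        return x
    return snap


def run_long_term(scenario: ScenarioSpec, sce_config: SCEConfig = SCEConfig(),
                  bounds: Optional[Sequence[tuple[float, float]]] = None,
                  initial_points: Optional[Sequence[Sequence[float]]] = None,
                  cfg: Optional[SimulationConfig] = None) -> LongTermResult:
    """SCE search of the six constants maximizing total NCP, followed by a
    final run and summary with the incumbent."""
    if scenario.mode != "long":
        raise ConfigurationError("run_long_term requires mode='long'")
    cfg = cfg or scenario_config(scenario.site)
    days, arrays = scenario_forcing(scenario)
    dates = [d.date for d in days]
    z = scenario.site.geometry.z_surface
    bounds = list(bounds) if bounds is not None else default_bounds(z)

    def objective(x: np.ndarray) -> float:
        lt = LongTermParams.from_array(x)
        res = run_from_arrays(arrays, dates, lt, scenario.c_a_ppm, cfg)
        return res.ncp

    sce_res = sce_maximize(objective, bounds, config=sce_config,
                           transform=_snap_transform(z),
                           initial_points=initial_points)
    best = LongTermParams.from_array(sce_res.x).snapped(z)
    final = run_from_arrays(arrays, dates, best, scenario.c_a_ppm, cfg)
    return LongTermResult(params=best,
                          summary=summarize(final, scenario.summary_years),
                          result=final, sce=sce_res)


def run_medium_term(scenario: ScenarioSpec,
                    cfg: Optional[SimulationConfig] = None) -> tuple[SummaryTable, SimResult]:
    """Re-run with the six constants frozen at the baseline-CO2 optimum;
    only the daily/hourly vegetation properties adapt."""
    if scenario.mode != "medium":
        raise ConfigurationError("run_medium_term requires mode='medium'")
    if scenario.frozen_params is None:
        raise ConfigurationError("frozen_params required")
    cfg = cfg or scenario_config(scenario.site)
    days, arrays = scenario_forcing(scenario)
    dates = [d.date for d in days]
    res = run_from_arrays(arrays, dates, scenario.frozen_params,
                          scenario.c_a_ppm, cfg)
    return summarize(res, scenario.summary_years), res


def relative_sensitivity(v_ref: float, v_new: float, c_a_ref: float,
                         c_a_new: float) -> Optional[float]:
    """Relative change of a variable per relative change in CO2:
    (v_new/v_ref - 1) / (c_a_new/c_a_ref - 1). None when undefined."""
    if c_a_ref == 0 or c_a_new == c_a_ref:
        raise ConfigurationError("need c_a_ref != 0 and c_a_new != c_a_ref")
    if v_ref == 0:
        return None
    return (v_new / v_ref - 1.0) / (c_a_new / c_a_ref - 1.0)


def relative_ca_change(c_a_new: float, c_a_ref: float) -> float:
    """Normalized CO2 enrichment step, e.g. 580/380 - 1 = 0.5."""
    if c_a_ref == 0:
        raise ConfigurationError("c_a_ref must be non-zero")
    return c_a_new / c_a_ref - 1.0


def percent_response(sensitivity: float, relative_ca: float) -> float:
    """Percent response implied by a sensitivity, e.g. 0.7 x 20 % = 14 %."""
    return sensitivity * relative_ca * 100.0


# ---------------------------------------------------------------------------
# full protocol

@dataclasses.dataclass(frozen=True)
class ExperimentProtocol:
    sites: Sequence[SyntheticSite]
    ca_levels: Sequence[float] = CA_LEVELS_PPM
    n_years: int = 6
    summary_years: int = 2
    sce: SCEConfig = SCEConfig(max_evaluations=300)
    rng_seed: int = 0


class SiteExperiment(NamedTuple):
    site: str
    long_term: dict      # ca -> LongTermResult
    medium_term: dict    # ca -> SummaryTable


def run_site_experiment(site: SyntheticSite,
                        protocol: ExperimentProtocol) -> SiteExperiment:
    """Long-term adaptation at each CO2 level plus medium-term re-runs with
    the baseline incumbent frozen. The long-term populations at elevated
    CO2 are seeded with the baseline incumbent, which also guarantees the
    long >= medium NCP dominance up to optimizer determinism."""
    ca0 = protocol.ca_levels[0]

    def scen(ca, mode, frozen=None):
        return ScenarioSpec(site=site, c_a_ppm=ca, mode=mode,
                            frozen_params=frozen, n_years=protocol.n_years,
                            summary_years=protocol.summary_years,
                            rng_seed=protocol.rng_seed)

    base = run_long_term(scen(ca0, "long"), sce_config=protocol.sce)
    long_term = {ca0: base}
    medium = {ca0: base.summary}
    seed_pt = base.params.to_array()
    for ca in protocol.ca_levels[1:]:
        long_term[ca] = run_long_term(scen(ca, "long"),
                                      sce_config=protocol.sce,
                                      initial_points=[seed_pt])
        medium[ca], _ = run_medium_term(scen(ca, "medium",
                                             frozen=base.params))
    return SiteExperiment(site=site.name, long_term=long_term,
                          medium_term=medium)


_TABLE_VARS = ("p", "q", "e_t_total", "e_t_p", "e_t_s", "e_s", "g_s_p",
               "g_s_s", "m_a_p", "m_a_s", "a_g_p", "a_g_s", "wue_p", "wue_s",
               "iwue_p", "iwue_s", "j_max25_p", "j_max25_s",
               "lambda_p_median", "lambda_s_median", "rai_p", "rai_s",
               "theta_1", "av_theta")


def summary_matrix(exp: SiteExperiment) -> pd.DataFrame:
    """Absolute values at the baseline CO2 and percent deviations at the
    elevated levels, for both response modes."""
    cas = sorted(exp.medium_term.keys())
    ca0 = cas[0]
    rows = []
    for mode, tables in (("medium", exp.medium_term),
                         ("long", {ca: r.summary
                                   for ca, r in exp.long_term.items()})):
        base = tables[ca0].as_dict()
        for var in _TABLE_VARS:
            row = {"mode": mode, "variable": var, f"abs_{ca0:g}": base[var]}
            for ca in cas[1:]:
                v = tables[ca].as_dict()[var]
                row[f"pct_{ca:g}"] = (100.0 * (v / base[var] - 1.0)
                                      if base[var] != 0 else math.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def sensitivity_matrix(exp: SiteExperiment) -> pd.DataFrame:
    """Relative CO2 sensitivities between the lowest and highest CO2 level
    for both response modes."""
    cas = sorted(exp.medium_term.keys())
    ca0, ca1 = cas[0], cas[-1]
    rows = []
    for var in _TABLE_VARS:
        row = {"variable": var}
        for mode, tables in (("medium", exp.medium_term),
                             ("long", {ca: r.summary
                                       for ca, r in exp.long_term.items()})):
            v0 = tables[ca0].as_dict()[var]
            v1 = tables[ca1].as_dict()[var]
            s = relative_sensitivity(v0, v1, ca0, ca1) if v0 != 0 else None
            row[mode] = math.nan if s is None else s
        rows.append(row)
    return pd.DataFrame(rows)
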