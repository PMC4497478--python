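"""Coupled multi-year simulation driver.

Wires the hourly forcing arrays, the soil column, the root network and the
two-big-leaf canopy into the compiled day loop, and returns tidy daily
(and optionally hourly) logs.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from . import _kernels as _k
from .canopy import PhysiologyParams
from .errors import ConfigurationError
from .forcing import DailyWeather, hourly_forcing_arrays
from .ncp import CostParams, DailyState
from .roots import RootHydraulics
from .sce import LongTermParams
from .soilwater import (CatchmentGeometry, SoilHydraulicParams,
                        soil_param_vector)


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Everything except forcing and the six long-term constants."""

    soil: SoilHydraulicParams
    geometry: CatchmentGeometry
    latitude_deg: float
    phys: PhysiologyParams = PhysiologyParams()
    costs: CostParams = CostParams()
    root_hydraulics: RootHydraulics = RootHydraulics()
    initial_se: float = 0.5
    initial_j_max25: float = 150.0   # umol m^-2 s^-1
    initial_m_a_s: float = 0.1
    initial_s_ar: float = 0.5        # m2 m^-3 in rooted layers

    def phys_vector(self) -> np.ndarray:
        pp = self.phys.as_vector()
        rh = self.root_hydraulics
        pp[_k.PP_PSI_MIN] = rh.psi_min
        pp[_k.PP_KRAD] = rh.k_radial
        pp[_k.PP_CSR] = rh.c_soil
        return pp


class SimResult(NamedTuple):
    daily: pd.DataFrame
    hourly: Optional[pd.DataFrame]
    final_theta: np.ndarray
    final_state: DailyState
    long_term: LongTermParams
    c_a_ppm: float
    initial_storage_mm: float

    @property
    def ncp(self) -> float:
        return float(self.daily["ncp"].sum())


def initial_daily_state(cfg: SimulationConfig,
                        lt: LongTermParams) -> DailyState:
    nl = cfg.geometry.n_layers
    i_r_p = min(int(round(lt.y_r_p / cfg.geometry.layer_thickness)), nl)
    i_r_s = min(2, nl)
    s_p = np.zeros(nl)
    s_p[:i_r_p] = cfg.initial_s_ar
    s_s = np.zeros(nl)
    s_s[:i_r_s] = cfg.initial_s_ar
    return DailyState(j_max25_p=cfg.initial_j_max25,
                      j_max25_s=cfg.initial_j_max25,
                      m_a_s=min(cfg.initial_m_a_s, 1.0 - lt.m_a_p),
                      s_ar_p=s_p, s_ar_s=s_s)


def run_simulation(days: Sequence[DailyWeather], lt: LongTermParams,
                   c_a_ppm: float, cfg: SimulationConfig,
                   init: Optional[DailyState] = None,
                   theta0: Optional[np.ndarray] = None,
                   adapt: bool = True,
                   log_hourly: bool = False) -> SimResult:
    """Run the coupled model over a daily weather series."""
    arrays = hourly_forcing_arrays(days, cfg.latitude_deg, c_a_ppm)
    dates = [d.date for d in days]
    return run_from_arrays(arrays, dates, lt, c_a_ppm, cfg, init=init,
                           theta0=theta0, adapt=adapt, log_hourly=log_hourly)


def run_from_arrays(arrays, dates, lt: LongTermParams,
                    c_a_ppm: float, cfg: SimulationConfig,
                    init: Optional[DailyState] = None,
                    theta0: Optional[np.ndarray] = None,
                    adapt: bool = True,
                    log_hourly: bool = False) -> SimResult:
    """Run on precomputed hourly forcing arrays (CO2-independent, so the
    same arrays can be reused across CO2 levels and optimizer evaluations).
    """
    if lt.m_a_p > 1.0:
        raise ConfigurationError("m_a_p must be <= 1")
    lt = lt.snapped(cfg.geometry.z_surface)
    nl = cfg.geometry.n_layers
    i_a, t_a, d_v, rain, ig_w = arrays
    sp = soil_param_vector(cfg.soil, cfg.geometry)
    pp = cfg.phys_vector()
    cp = cfg.costs.as_vector()
    vc = np.array([lt.m_a_p, lt.y_r_p, lt.c_lambda_f_p, lt.c_lambda_e_p,
                   lt.c_lambda_f_s, lt.c_lambda_e_s])

    if theta0 is None:
        theta = np.full(nl, cfg.soil.theta_r
                        + cfg.initial_se * (cfg.soil.theta_s - cfg.soil.theta_r))
    else:
        theta = np.asarray(theta0, dtype=float).copy()
    state = (init or initial_daily_state(cfg, lt)).copy()
    dyn = np.array([state.j_max25_p * 1e-6, state.j_max25_s * 1e-6,
                    min(state.m_a_s, 1.0 - lt.m_a_p)])
    sar_p = state.s_ar_p.copy()
    sar_s = state.s_ar_s.copy()

    init_storage = float(np.sum(theta) * cfg.geometry.layer_thickness * 1000.0)
    n_days = len(dates)
    daily = np.zeros((n_days, len(_k.DAILY_COLUMNS)))
    hourly = (np.zeros((n_days * 24, len(_k.HOURLY_COLUMNS)))
              if log_hourly else np.zeros((0, len(_k.HOURLY_COLUMNS))))
    _k.run_core(i_a, t_a, d_v, rain, ig_w, float(c_a_ppm),
                sp, pp, cp, vc, theta, sar_p, sar_s, dyn,
                daily, hourly, adapt)

    frame = pd.DataFrame(daily, columns=list(_k.DAILY_COLUMNS))
    frame["j_max25_p"] *= 1e6
    frame["j_max25_s"] *= 1e6
    frame["iwue_p"] *= 1e6   # A_g/g_s in umol CO2 per mol air
    frame["iwue_s"] *= 1e6
    frame.insert(0, "date", dates)
    frame["m_a_p"] = lt.m_a_p
    hframe = None
    if log_hourly:
        hframe = pd.DataFrame(hourly, columns=list(_k.HOURLY_COLUMNS))
    final_state = DailyState(j_max25_p=dyn[0] * 1e6, j_max25_s=dyn[1] * 1e6,
                             m_a_s=dyn[2], s_ar_p=sar_p, s_ar_s=sar_s)
    return SimResult(daily=frame, hourly=hframe, final_theta=theta,
                     final_state=final_state, long_term=lt, c_a_ppm=c_a_ppm,
                     initial_storage_mm=init_storage)


def water_balance_residual(result: SimResult) -> dict:
    """Audit: P - Q - E_T - d(storage); Q includes runoff and drainage."""
    d = result.daily
    p = float(d["rain"].sum())
    q = float(d["drainage"].sum() + d["runoff"].sum())
    e_t = float(d["e_t_p"].sum() + d["e_t_s"].sum() + d["e_s"].sum())
    dstore = float(d["storage"].iloc[-1]) - result.initial_storage_mm
    return {"P": p, "Q": q, "E_T": e_t, "d_storage": dstore,
            "residual": p - q - e_t - dstore}
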