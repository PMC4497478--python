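"""Net-carbon-profit accounting and day-by-day vegetation adjustment.

NCP = daily CO2 uptake minus maintenance/turnover costs of foliage, wood and
roots. The fast vegetation properties (electron transport capacities,
seasonal cover, per-layer root surface areas) climb the NCP gradient one
bounded multiplicative step per day, using finite-difference sensitivities
evaluated on a replay of the previous day.

Cost coefficients are order-of-magnitude closures exposed in configuration;
carbon is in mol CO2 m^-2 ground, aggregated at local midnight.
"""
from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import _kernels as _k
from .errors import ConfigurationError, VomError
from .sce import LongTermParams

LAYER_THICKNESS = 0.5


@dataclasses.dataclass(frozen=True)
class CostParams:
    """Respiration/turnover coefficients (mol C m^-2 ground d^-1 scale)."""

    foliage_cost_coeff: float = 0.004        # per unit M_A
    photosynthetic_capacity_cost_coeff: float = 600.0  # per (mol e- s^-1) per M_A
    root_cost_coeff: float = 0.002           # per m2 root area per day
    wood_cost_coeff: float = 0.004           # per unit M_A,p
    wood_depth_factor: float = 0.3           # relative cost per m rooting depth
    probe_rel_step: float = 0.05             # finite-difference probe size
    adjust_rel_step: float = 0.05            # daily multiplicative step
    j_max25_min: float = 1.0                 # umol m^-2 s^-1
    j_max25_max: float = 2000.0
    m_a_s_min: float = 0.001
    s_ar_min: float = 1e-4                   # m2 m^-3; floor allows regrowth
    s_ar_max: float = 20.0

    def __post_init__(self) -> None:
        if min(self.foliage_cost_coeff, self.photosynthetic_capacity_cost_coeff,
               self.root_cost_coeff, self.wood_cost_coeff,
               self.wood_depth_factor) < 0:
            raise ConfigurationError("cost coefficients must be >= 0")

    def as_vector(self) -> np.ndarray:
        cp = np.zeros(12)
        cp[_k.CP_FOLIAGE] = self.foliage_cost_coeff
        cp[_k.CP_CAPACITY] = self.photosynthetic_capacity_cost_coeff
        cp[_k.CP_ROOT] = self.root_cost_coeff
        cp[_k.CP_WOOD] = self.wood_cost_coeff
        cp[_k.CP_WOOD_DEPTH] = self.wood_depth_factor
        cp[_k.CP_PROBE] = self.probe_rel_step
        cp[_k.CP_STEP] = self.adjust_rel_step
        cp[_k.CP_JMAX_MIN] = self.j_max25_min * 1e-6
        cp[_k.CP_JMAX_MAX] = self.j_max25_max * 1e-6
        cp[_k.CP_MAS_MIN] = self.m_a_s_min
        cp[_k.CP_SAR_MIN] = self.s_ar_min
        cp[_k.CP_SAR_MAX] = self.s_ar_max
        return cp


@dataclasses.dataclass
class DailyState:
    """Day-varying vegetation properties (J_max25 in umol m^-2 s^-1)."""

    j_max25_p: float
    j_max25_s: float
    m_a_s: float
    s_ar_p: np.ndarray
    s_ar_s: np.ndarray

    def __post_init__(self) -> None:
        self.s_ar_p = np.asarray(self.s_ar_p, dtype=float)
        self.s_ar_s = np.asarray(self.s_ar_s, dtype=float)
        if (min(self.j_max25_p, self.j_max25_s, self.m_a_s) < 0
                or np.any(self.s_ar_p < 0) or np.any(self.s_ar_s < 0)):
            raise ConfigurationError("daily state fields must be >= 0")

    def copy(self) -> "DailyState":
        return DailyState(self.j_max25_p, self.j_max25_s, self.m_a_s,
                          self.s_ar_p.copy(), self.s_ar_s.copy())


@dataclasses.dataclass(frozen=True)
class CarbonAccount:
    a_g_total: float
    r_foliage: float
    r_roots: float
    r_wood: float

    @property
    def ncp_day(self) -> float:
        return self.a_g_total - (self.r_foliage + self.r_roots + self.r_wood)


def daily_costs(state: DailyState, long_term: LongTermParams,
                costs: CostParams) -> tuple[float, float, float]:
    """(R_foliage, R_roots, R_wood) in mol C m^-2 ground d^-1.

    Foliage cost is linear in cover and in cover x capacity; root cost is
    linear in total root area; wood cost scales with perennial cover and
    rooting depth.
    """
    ma_p = long_term.m_a_p
    r_fol = (costs.foliage_cost_coeff * (ma_p + state.m_a_s)
             + costs.photosynthetic_capacity_cost_coeff
             * (ma_p * state.j_max25_p + state.m_a_s * state.j_max25_s) * 1e-6)
    r_roots = costs.root_cost_coeff * float(
        np.sum(state.s_ar_p) + np.sum(state.s_ar_s)) * LAYER_THICKNESS
    r_wood = (costs.wood_cost_coeff * ma_p
              * (1.0 + costs.wood_depth_factor * long_term.y_r_p))
    return r_fol, r_roots, r_wood


def ncp_total(flux_log: pd.Series, cost_log: pd.Series) -> float:
    """Total NCP = sum over days of (A_g_total - R_total).

    The two logs must share an identical index (one entry per day).
    """
    if len(flux_log) != len(cost_log) or not flux_log.index.equals(cost_log.index):
        raise VomError("flux and cost logs are misaligned")
    return float((flux_log - cost_log).sum())


_SCALAR_VARS = ("j_max25_p", "j_max25_s", "m_a_s")


def marginal_ncp(state: DailyState,
                 replay: Callable[[DailyState], float],
                 probe_rel_step: float = 0.05,
                 abs_floor: float = 1e-6) -> dict:
    """Finite-difference NCP sensitivities of every dynamic variable.

    ``replay`` re-evaluates yesterday's NCP for a perturbed state. Each
    sensitivity is the NCP difference for a relative increase of
    ``probe_rel_step`` (plus a small absolute floor so zero-valued variables
    can be probed); a zero step gives all-zero sensitivities.
    """
    out: dict = {}
    if probe_rel_step == 0.0:
        out.update({v: 0.0 for v in _SCALAR_VARS})
        out["s_ar_p"] = np.zeros_like(state.s_ar_p)
        out["s_ar_s"] = np.zeros_like(state.s_ar_s)
        return out
    base = replay(state)
    for var in _SCALAR_VARS:
        probe = state.copy()
        setattr(probe, var,
                getattr(state, var) * (1.0 + probe_rel_step) + abs_floor)
        out[var] = replay(probe) - base
    for var in ("s_ar_p", "s_ar_s"):
        arr = getattr(state, var)
        sens = np.zeros_like(arr)
        for i in range(arr.size):
            probe = state.copy()
            getattr(probe, var)[i] = arr[i] * (1.0 + probe_rel_step) + abs_floor
            sens[i] = replay(probe) - base
        out[var] = sens
    return out


def daily_adjust(state: DailyState, marginal_gains: dict, m_a_p: float,
                 costs: CostParams = CostParams()) -> DailyState:
    """One bounded multiplicative hill-climbing step per dynamic variable.

    Variables with positive marginal NCP grow by ``adjust_rel_step``,
    negative ones shrink; zero gains leave the variable unchanged. The
    cover constraint M_A,s <= 1 - M_A,p and all floors/caps are enforced.
    """
    step = costs.adjust_rel_step
    new = state.copy()

    def move(x, gain, lo, hi, floor_kick=0.0):
        if gain > 0:
            x = x * (1.0 + step) + floor_kick
        elif gain < 0:
            x = x * (1.0 - step)
        else:
            return min(x, hi)  # no gradient: only re-impose hard constraints
        return min(max(x, lo), hi)

    new.j_max25_p = move(state.j_max25_p, marginal_gains["j_max25_p"],
                         costs.j_max25_min, costs.j_max25_max)
    new.j_max25_s = move(state.j_max25_s, marginal_gains["j_max25_s"],
                         costs.j_max25_min, costs.j_max25_max)
    new.m_a_s = move(state.m_a_s, marginal_gains["m_a_s"],
                     costs.m_a_s_min, 1.0 - m_a_p, floor_kick=1e-6)
    for var in ("s_ar_p", "s_ar_s"):
        arr = getattr(new, var)
        gains = marginal_gains[var]
        for i in range(arr.size):
            arr[i] = move(arr[i], gains[i], costs.s_ar_min, costs.s_ar_max,
                          floor_kick=1e-6)
    return new
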