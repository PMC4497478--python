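"""Two-big-leaf canopy gas exchange under hourly stomatal optimality.

Photosynthesis is electron-transport limited:
    A_g = (J/4) (C_i - Gamma*) / (C_i + 2 Gamma*),
coupled to the diffusive supply A_g = g_s (C_a - C_i) and transpiration
E_t = 1.6 g_s D_v. Each hour the stomatal conductance of each big leaf is
chosen so that the marginal water cost dE_t/dA_g equals the day's lambda,
i.e. g_s maximizes A_g - E_t/lambda, subject to a root-supply cap on E_t.

Internally CO2 is in mol mol^-1; the public API takes ppm. lambda carries
units of mol H2O per mol CO2.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import _kernels as _k
from .errors import DomainError, InvariantError

#: H2O:CO2 stomatal diffusivity ratio
DIFFUSIVITY_RATIO = 1.6
#: default CO2 compensation point in the absence of dark respiration (ppm)
GAMMA_STAR_PPM = 40.0


@dataclasses.dataclass(frozen=True)
class PhysiologyParams:
    """Leaf-level closure constants shared by both big leaves."""

    gamma_star_ppm: float = GAMMA_STAR_PPM
    alpha_q: float = 0.3        # quantum yield, mol e- per mol quanta
    theta_j: float = 0.9        # light-response curvature (0 = rectangular)
    g_s_max: float = 10.0       # upper bound on stomatal conductance
    t_opt: float = 30.0         # temperature optimum of J_max (degC)
    t_omega: float = 15.0       # breadth of the temperature response (degC)
    lambda_max: float = 1.0e6
    lambda_alt_grouping: bool = False
    c_soil_evap: float = 1.0

    def as_vector(self) -> np.ndarray:
        pp = np.zeros(_k.PP_SIZE)
        pp[_k.PP_GAMMA_STAR] = self.gamma_star_ppm * 1e-6
        pp[_k.PP_ALPHA_Q] = self.alpha_q
        pp[_k.PP_GSMAX] = self.g_s_max
        pp[_k.PP_TOPT] = self.t_opt
        pp[_k.PP_TOMEGA] = self.t_omega
        pp[_k.PP_LAMBDA_MAX] = self.lambda_max
        pp[_k.PP_LAMBDA_ALT] = 1.0 if self.lambda_alt_grouping else 0.0
        pp[_k.PP_CSE] = self.c_soil_evap
        pp[_k.PP_THETA_J] = self.theta_j
        return pp


@dataclasses.dataclass(frozen=True)
class BigLeafConfig:
    """State of one big leaf for a flux evaluation."""

    component: str               # "perennial" | "seasonal"
    m_a: float                   # fractional ground cover
    j_max25: float               # umol m^-2 s^-1, per leaf area
    c_lambda_f: float
    c_lambda_e: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_a <= 1.0:
            raise DomainError("m_a must be in [0, 1]")
        if self.j_max25 <= 0.0:
            raise DomainError("j_max25 must be > 0")


@dataclasses.dataclass(frozen=True)
class GasExchangeEnv:
    """Hourly environment of a leaf."""

    i_a: float               # PPFD, mol m^-2 s^-1
    t_a: float               # degC
    d_v: float               # vapour mole fraction deficit, mol mol^-1
    c_a: float               # ppm
    gamma_star: float = GAMMA_STAR_PPM  # ppm

    def __post_init__(self) -> None:
        if min(self.i_a, self.d_v, self.c_a) < 0 or self.gamma_star < 0:
            raise DomainError("environment fields must be >= 0")


class GasExchangeResult(NamedTuple):
    g_s: float          # mol CO2 m^-2 s^-1 per leaf area
    c_i: float          # ppm
    a_g: float          # umol CO2 m^-2 s^-1 per leaf area
    e_t: float          # mol H2O m^-2 s^-1 per leaf area
    lambda_used: float  # dE_t/dA_g at the operating point (mol/mol)
    supply_limited: bool = False


class CanopyFluxes(NamedTuple):
    """Hourly per-ground-area totals of the two big leaves."""

    e_t_p: float
    e_t_s: float
    a_g_p: float
    a_g_s: float
    g_s_p: float
    g_s_s: float
    perennial: GasExchangeResult
    seasonal: GasExchangeResult


def electron_transport(i_a: float, j_max_t: float, alpha_q: float = 0.3,
                       curvature: float = 0.0) -> float:
    """Saturating light response of electron transport.

    The default ``curvature = 0`` is the rectangular hyperbola
    J = alpha_q I_a J_max / (alpha_q I_a + J_max); positive curvature gives
    the non-rectangular form with a sharper knee (the coupled simulator
    defaults to 0.9, see PhysiologyParams).
    """
    if i_a < 0 or j_max_t <= 0:
        raise DomainError("need i_a >= 0 and j_max_t > 0")
    return float(_k.electron_transport_rate(i_a, j_max_t, alpha_q, curvature))


def jmax_at_temperature(j_max25: float, t_a: float, t_opt: float = 30.0,
                        t_omega: float = 15.0) -> float:
    """Gaussian temperature response anchored at 25 degC."""
    if not -10.0 < t_a < 60.0:
        raise DomainError("air temperature outside (-10, 60) degC")
    return float(_k.jmax_at_temp(j_max25, t_a, t_opt, t_omega))


def assimilation(g_s: float, env: GasExchangeEnv, j: float):
    """(A_g, C_i) from supply/demand balance at fixed stomatal conductance.

    ``j`` in umol e- m^-2 s^-1; returns A_g in umol m^-2 s^-1, C_i in ppm.
    """
    if g_s < 0:
        raise DomainError("g_s must be >= 0")
    # the kernel is unit-agnostic as long as C and J/4 share a scale; use
    # ppm and umol throughout (g_s in mol m^-2 s^-1 keeps A in umol)
    c_i = float(_k.ci_from_gs(g_s, env.c_a, env.gamma_star, j))
    return g_s * (env.c_a - c_i), c_i


def transpiration(g_s: float, d_v: float) -> float:
    """E_t = 1.6 g_s D_v (mol H2O m^-2 s^-1 per leaf area)."""
    if g_s < 0 or d_v < 0:
        raise DomainError("g_s and d_v must be >= 0")
    return DIFFUSIVITY_RATIO * g_s * d_v


def lambda_from_suction(c_f: float, c_e: float, h_layers: Sequence[float],
                        i_r: int, alt_grouping: bool = False,
                        lambda_max: float = 1.0e6) -> float:
    """Water-use function: lambda = c_f (sum_{i<=i_r} h_i)^c_e.

    The alternative reading c_f * sum(h_i^c_e) is selectable. A zero suction
    sum with a negative exponent returns the configured lambda_max.
    """
    h = np.asarray(h_layers, dtype=float)
    if np.any(h < 0):
        raise DomainError("suction heads must be >= 0")
    if not 1 <= i_r <= h.size:
        raise DomainError("i_r must index a rooted layer")
    return float(_k.lambda_value(c_f, c_e, h, i_r,
                                 1.0 if alt_grouping else 0.0, lambda_max))


def _slope_de_da(g_s: float, env: GasExchangeEnv, j: float,
                 rel: float = 1e-4) -> float:
    """Numerical dE_t/dA_g along the g_s axis (mol H2O per mol CO2)."""
    dg = max(g_s * rel, 1e-9)
    a1, _ = assimilation(g_s - dg, env, j)
    a2, _ = assimilation(g_s + dg, env, j)
    da = (a2 - a1) * 1e-6  # umol -> mol
    de = DIFFUSIVITY_RATIO * 2.0 * dg * env.d_v
    return de / da if da != 0 else np.inf


def optimal_gs(env: GasExchangeEnv, j_max25: float, lam: float,
               supply_cap: float = np.inf,
               phys: Optional[PhysiologyParams] = None) -> GasExchangeResult:
    """Hourly stomatal optimum for one big leaf.

    Maximizes A_g - E_t/lambda over g_s in [0, g_s_max]; at an interior
    optimum the slope dE_t/dA_g equals lambda. E_t never exceeds
    ``supply_cap`` (mol H2O m^-2 s^-1 per leaf area); when the cap binds the
    result is flagged.
    """
    if lam <= 0:
        raise DomainError("lambda must be > 0")
    phys = phys or PhysiologyParams(gamma_star_ppm=env.gamma_star)
    pp = phys.as_vector()
    pp[_k.PP_GAMMA_STAR] = env.gamma_star * 1e-6
    e_cap = supply_cap if np.isfinite(supply_cap) else 1e30
    g, ci_mf, a_mol, e_t, limited = _k.optimal_gas_exchange(
        env.i_a, env.t_a, env.d_v, env.c_a * 1e-6, j_max25 * 1e-6, lam,
        e_cap, pp)
    lam_used = lam
    if g <= 0 or limited:
        j_t = _k.jmax_at_temp(j_max25, env.t_a, phys.t_opt, phys.t_omega)
        j = _k.electron_transport_rate(env.i_a, j_t, phys.alpha_q,
                                       phys.theta_j)
        lam_used = _slope_de_da(g, env, j) if g > 0 else np.inf
    return GasExchangeResult(g_s=float(g), c_i=float(ci_mf * 1e6),
                             a_g=float(a_mol * 1e6), e_t=float(e_t),
                             lambda_used=float(lam_used),
                             supply_limited=bool(limited))


def canopy_fluxes(perennial: BigLeafConfig, seasonal: BigLeafConfig,
                  env: GasExchangeEnv, lambda_p: float, lambda_s: float,
                  supply_cap_p: float = np.inf,
                  supply_cap_s: float = np.inf,
                  phys: Optional[PhysiologyParams] = None) -> CanopyFluxes:
    """Hourly canopy totals per ground area for both big leaves.

    Ground-area fluxes are leaf-area fluxes scaled by each leaf's cover;
    the opaque big leaves must not overlap (M_A,s + M_A,p <= 1). Supply
    caps are per ground area (mol H2O m^-2 ground s^-1).
    """
    if perennial.m_a + seasonal.m_a > 1.0 + 1e-12:
        raise InvariantError(
            f"cover constraint violated: {perennial.m_a} + {seasonal.m_a} > 1")
    zero = GasExchangeResult(0.0, env.gamma_star, 0.0, 0.0, np.inf, False)
    res_p = zero
    res_s = zero
    if perennial.m_a > 0:
        res_p = optimal_gs(env, perennial.j_max25, lambda_p,
                           supply_cap=supply_cap_p / perennial.m_a, phys=phys)
    if seasonal.m_a > 0:
        res_s = optimal_gs(env, seasonal.j_max25, lambda_s,
                           supply_cap=supply_cap_s / seasonal.m_a, phys=phys)
    return CanopyFluxes(
        e_t_p=res_p.e_t * perennial.m_a, e_t_s=res_s.e_t * seasonal.m_a,
        a_g_p=res_p.a_g * perennial.m_a, a_g_s=res_s.a_g * seasonal.m_a,
        g_s_p=res_p.g_s * perennial.m_a, g_s_s=res_s.g_s * seasonal.m_a,
        perennial=res_p, seasonal=res_s)
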