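"""Multi-layer soil water balance of a rectangular soil block.

Van Genuchten-Mualem hydraulics, explicit Darcy redistribution, infiltration
with saturation-excess runoff, Dupuit-style lateral drainage above the
channel elevation, and a radiation-driven soil evaporation closure.

Layers are 0.5 m thick, indexed from the surface down (layer 0 = top).
Suction heads are positive (m); elevations are positive upward from bedrock.
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple, Optional, Sequence

import numpy as np

from . import _kernels as _k
from .errors import ConfigurationError, DomainError

LAYER_THICKNESS = 0.5


@dataclasses.dataclass(frozen=True)
class SoilHydraulicParams:
    """Van Genuchten-Mualem parameter set for one soil texture."""

    theta_r: float
    theta_s: float
    alpha_vg: float  # m^-1
    n_vg: float
    k_sat: float     # m s^-1

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_r < self.theta_s <= 1.0:
            raise ConfigurationError("need 0 <= theta_r < theta_s <= 1")
        if self.n_vg <= 1.0 or self.alpha_vg <= 0.0 or self.k_sat <= 0.0:
            raise ConfigurationError("need n_vg > 1, alpha_vg > 0, k_sat > 0")


#: soil texture presets
SOIL_TEXTURES = {
    "sandy loam": SoilHydraulicParams(0.065, 0.41, 7.5, 1.89, 1.228e-5),
    "loam": SoilHydraulicParams(0.078, 0.43, 3.6, 1.56, 2.889e-6),
    "sandy clay loam": SoilHydraulicParams(0.10, 0.39, 5.9, 1.48, 3.639e-6),
}


@dataclasses.dataclass(frozen=True)
class CatchmentGeometry:
    """Rectangular soil block above impermeable bedrock."""

    z_surface: float     # soil surface elevation above bedrock (m)
    z_channel: float     # drainage channel elevation above bedrock (m)
    slope_deg: float     # slope angle near the channel
    drain_length: float = 100.0   # effective lateral flow length (m)
    drain_coeff: float = 1.0      # dimensionless drainage closure scale
    layer_thickness: float = LAYER_THICKNESS

    def __post_init__(self) -> None:
        if not self.z_surface > self.z_channel >= 0:
            raise ConfigurationError("need z_surface > z_channel >= 0")
        if not 0.0 < self.slope_deg < 90.0:
            raise ConfigurationError("slope_deg must be in (0, 90)")
        n = self.z_surface / self.layer_thickness
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "z_surface must be an integer multiple of the layer thickness")

    @property
    def n_layers(self) -> int:
        return int(round(self.z_surface / self.layer_thickness))


#: site geometry/soil presets
SITE_PRESETS = {
    "VIR": ("sandy loam", CatchmentGeometry(15.0, 5.0, 2.0)),
    "HS": ("sandy loam", CatchmentGeometry(15.0, 10.0, 2.0)),
    "TUM": ("loam", CatchmentGeometry(30.0, 5.0, 11.5)),
    "CT": ("sandy clay loam", CatchmentGeometry(15.0, 5.0, 2.0)),
}


@dataclasses.dataclass
class SoilColumnState:
    """Per-layer volumetric water content; suction and water table derived."""

    theta: np.ndarray

    def copy(self) -> "SoilColumnState":
        return SoilColumnState(theta=self.theta.copy())


class StepResult(NamedTuple):
    state: SoilColumnState
    runoff: float      # mm over the step
    drainage: float    # mm over the step
    infiltration: float
    e_s: float
    uptake: np.ndarray  # mm per layer actually extracted
    shortfall: float    # demanded but unavailable sink water (mm)


def soil_param_vector(p: SoilHydraulicParams, geom: CatchmentGeometry) -> np.ndarray:
    """Flat parameter vector consumed by the numba kernels."""
    sp = np.zeros(10)
    sp[_k.SP_THETA_R] = p.theta_r
    sp[_k.SP_THETA_S] = p.theta_s
    sp[_k.SP_ALPHA] = p.alpha_vg
    sp[_k.SP_N] = p.n_vg
    sp[_k.SP_KSAT] = p.k_sat
    sp[_k.SP_DZ] = geom.layer_thickness
    sp[_k.SP_ZR] = geom.z_channel
    sp[_k.SP_SINGAMMA] = np.sin(np.deg2rad(geom.slope_deg))
    sp[_k.SP_DRAIN_LEN] = geom.drain_length
    sp[_k.SP_CDRAIN] = geom.drain_coeff
    return sp


# ---------------------------------------------------------------------------
# retention / conductivity curves

def vg_saturation(h, p: SoilHydraulicParams):
    """Effective saturation Theta(h) = [1 + (alpha h)^n]^(-m), m = 1 - 1/n."""
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 0):
        raise DomainError("suction head must be >= 0")
    m = 1.0 - 1.0 / p.n_vg
    out = (1.0 + (p.alpha_vg * h_arr) ** p.n_vg) ** (-m)
    return float(out) if out.ndim == 0 else out


def vg_water_content(h, p: SoilHydraulicParams):
    """Volumetric water content theta(h)."""
    return p.theta_r + vg_saturation(h, p) * (p.theta_s - p.theta_r)


def vg_suction_from_saturation(se, p: SoilHydraulicParams):
    """Closed-form inverse of the retention curve (m)."""
    se_arr = np.asarray(se, dtype=float)
    if np.any((se_arr < 0) | (se_arr > 1)):
        raise DomainError("effective saturation must be in [0, 1]")
    out = np.asarray([_k.vg_head_from_sat(float(s), p.alpha_vg, p.n_vg)
                      for s in np.atleast_1d(se_arr)])
    return float(out[0]) if np.ndim(se) == 0 else out.reshape(np.shape(se))


def vg_conductivity(se, p: SoilHydraulicParams):
    """Mualem conductivity K(Theta) = Ksat Theta^0.5 [1-(1-Theta^(1/m))^m]^2."""
    se_arr = np.asarray(se, dtype=float)
    if np.any((se_arr < 0) | (se_arr > 1)):
        raise DomainError("effective saturation must be in [0, 1]")
    m = 1.0 - 1.0 / p.n_vg
    with np.errstate(invalid="ignore"):
        t = 1.0 - (1.0 - se_arr ** (1.0 / m)) ** m
        out = p.k_sat * np.sqrt(se_arr) * t * t
    out = np.where(se_arr <= 0.0, 0.0, out)
    out = np.where(se_arr >= 1.0, p.k_sat, out)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# column state helpers

def uniform_state(se: float, p: SoilHydraulicParams,
                  geom: CatchmentGeometry) -> SoilColumnState:
    theta = np.full(geom.n_layers,
                    p.theta_r + se * (p.theta_s - p.theta_r))
    return SoilColumnState(theta=theta)


def hydrostatic_state(z_w: float, p: SoilHydraulicParams,
                      geom: CatchmentGeometry) -> SoilColumnState:
    """Equilibrium profile for a given water-table elevation: suction equals
    height above the water table."""
    nl = geom.n_layers
    theta = np.empty(nl)
    for i in range(nl):
        z_mid = geom.z_surface - (i + 0.5) * geom.layer_thickness
        h = max(0.0, z_mid - z_w)
        theta[i] = vg_water_content(h, p)
    return SoilColumnState(theta=theta)


def suction_heads(state: SoilColumnState, p: SoilHydraulicParams) -> np.ndarray:
    """Per-layer suction head (m), capped at the kernel head ceiling."""
    se = (state.theta - p.theta_r) / (p.theta_s - p.theta_r)
    return np.array([_k.vg_head_from_sat(float(s), p.alpha_vg, p.n_vg)
                     for s in se])


def water_table(state: SoilColumnState, p: SoilHydraulicParams,
                geom: CatchmentGeometry) -> float:
    return float(_k.water_table_elev(state.theta, soil_param_vector(p, geom)))


def storage_mm(state: SoilColumnState, geom: CatchmentGeometry) -> float:
    return float(np.sum(state.theta) * geom.layer_thickness * 1000.0)


# ---------------------------------------------------------------------------
# fluxes

def drainage_flux(state: SoilColumnState, geom: CatchmentGeometry,
                  p: SoilHydraulicParams) -> float:
    """Lateral outflow (mm h^-1 per unit catchment area); zero at or below
    the channel elevation, strictly increasing above it."""
    sp = soil_param_vector(p, geom)
    zw = _k.water_table_elev(state.theta, sp)
    return float(_k.drainage_rate(zw, sp))


def drainage_flux_at(z_w: float, geom: CatchmentGeometry,
                     p: SoilHydraulicParams) -> float:
    """Drainage rate for an externally supplied water-table elevation."""
    return float(_k.drainage_rate(z_w, soil_param_vector(p, geom)))


def soil_evaporation(state: SoilColumnState, i_g_w: float, t_a: float,
                     total_fpc: float, p: SoilHydraulicParams,
                     c_se: float = 1.0) -> float:
    """Soil evaporation (mm h^-1): exposed-fraction x top-layer saturation x
    equilibrium radiation-driven rate."""
    if not 0.0 <= total_fpc <= 1.0:
        raise DomainError("total_fpc must be in [0, 1]")
    se1 = (state.theta[0] - p.theta_r) / (p.theta_s - p.theta_r)
    return float(_k.soil_evap_rate(i_g_w, t_a, max(0.0, se1), total_fpc, c_se))


def step_soil_water(state: SoilColumnState, rain_mm: float,
                    uptake_per_layer: Sequence[float], e_s_demand: float,
                    dt: float, p: SoilHydraulicParams,
                    geom: CatchmentGeometry) -> StepResult:
    """Advance the column by one step of length ``dt`` hours.

    Sinks are capped at extractable water (never negative storage); the cap
    shortfall is reported. Water mass is conserved exactly:
    d(storage) = infiltration - uptake - E_s - drainage.
    """
    if dt <= 0:
        raise DomainError("dt must be > 0")
    uptake_req = np.asarray(uptake_per_layer, dtype=float)
    if uptake_req.shape != (geom.n_layers,):
        raise DomainError("uptake_per_layer must have one entry per layer")
    if np.any(uptake_req < 0) or e_s_demand < 0 or rain_mm < 0:
        raise DomainError("rain and sink demands must be >= 0")
    sp = soil_param_vector(p, geom)
    theta = state.theta.copy()
    dzmm = geom.layer_thickness * 1000.0

    # sinks, capped at extractable water
    shortfall = 0.0
    uptake = np.empty_like(uptake_req)
    for i in range(theta.size):
        avail = (theta[i] - p.theta_r) * dzmm
        take = min(uptake_req[i], avail)
        uptake[i] = take
        shortfall += uptake_req[i] - take
        theta[i] -= take / dzmm
    avail0 = (theta[0] - p.theta_r) * dzmm
    e_s = min(e_s_demand, avail0)
    shortfall += e_s_demand - e_s
    theta[0] -= e_s / dzmm

    infil, runoff = _k.infiltrate(theta, sp, rain_mm)
    _k.redistribute(theta, sp, dt)
    zw = _k.water_table_elev(theta, sp)
    q_mm = float(_k.drainage_rate(zw, sp)) * dt
    q_mm = float(_k.apply_drainage(theta, sp, q_mm))
    return StepResult(state=SoilColumnState(theta=theta),
                      runoff=float(runoff), drainage=q_mm,
                      infiltration=float(infil), e_s=float(e_s),
                      uptake=uptake, shortfall=float(shortfall))
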