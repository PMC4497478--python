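"""Root profiles and water extraction through a soil-to-root resistance
network.

Each rooted layer contributes a conductance proportional to its fine-root
surface area, with the soil pathway (scaling with unsaturated conductivity)
and a constant radial root pathway in series. A single root-collar potential
is solved per step so that total extraction meets transpiration demand
(steady-state plant water balance: hourly uptake equals hourly
transpiration).
"""
from __future__ import annotations

import dataclasses
from typing import NamedTuple

import numpy as np

from . import _kernels as _k
from .errors import ConfigurationError, DomainError
from .soilwater import (CatchmentGeometry, SoilColumnState,
                        SoilHydraulicParams, soil_param_vector)

SEASONAL_ROOTING_DEPTH = 1.0  # m, fixed


@dataclasses.dataclass(frozen=True)
class RootHydraulics:
    """Closure coefficients of the uptake resistance network."""

    psi_min: float = -300.0   # minimum root water potential (m head)
    k_radial: float = 1.0e-5  # radial conductivity per root area (m h^-1 m^-1)
    c_soil: float = 1.0       # scale on the soil-pathway conductivity

    def as_phys_vector(self) -> np.ndarray:
        pp = np.zeros(_k.PP_SIZE)
        pp[_k.PP_PSI_MIN] = self.psi_min
        pp[_k.PP_KRAD] = self.k_radial
        pp[_k.PP_CSR] = self.c_soil
        return pp


@dataclasses.dataclass
class RootProfile:
    """Vertical fine-root surface-area profile of one vegetation component.

    ``s_ar`` is fine-root surface area per soil volume (m2 m^-3) per layer;
    entries below the maximum rooting depth are forced to zero.
    """

    s_ar: np.ndarray
    y_r: float
    layer_thickness: float = 0.5

    def __post_init__(self) -> None:
        self.s_ar = np.asarray(self.s_ar, dtype=float)
        if np.any(self.s_ar < 0):
            raise ConfigurationError("root surface areas must be >= 0")
        if self.y_r < self.layer_thickness:
            raise ConfigurationError("rooting depth must cover >= 1 layer")
        self.s_ar = self.s_ar.copy()
        self.s_ar[self.i_r:] = 0.0

    @property
    def i_r(self) -> int:
        """Index one past the deepest rooted layer (number of rooted layers)."""
        return min(int(round(self.y_r / self.layer_thickness)), self.s_ar.size)


def perennial_profile(s_ar_value: float, y_r_p: float,
                      n_layers: int) -> RootProfile:
    s = np.zeros(n_layers)
    i_r = min(int(round(y_r_p / 0.5)), n_layers)
    s[:i_r] = s_ar_value
    return RootProfile(s_ar=s, y_r=y_r_p)


def seasonal_profile(s_ar_value: float, n_layers: int) -> RootProfile:
    s = np.zeros(n_layers)
    i_r = min(int(round(SEASONAL_ROOTING_DEPTH / 0.5)), n_layers)
    s[:i_r] = s_ar_value
    return RootProfile(s_ar=s, y_r=SEASONAL_ROOTING_DEPTH)


class UptakeResult(NamedTuple):
    uptake: np.ndarray  # mm h^-1 per layer
    total: float
    limited: bool


def _network(state: SoilColumnState, profile: RootProfile,
             p: SoilHydraulicParams, geom: CatchmentGeometry,
             hyd: RootHydraulics):
    sp = soil_param_vector(p, geom)
    pp = hyd.as_phys_vector()
    nl = state.theta.size
    g = np.empty(nl)
    psi = np.empty(nl)
    cap = np.empty(nl)
    _k.root_conductances(state.theta, profile.s_ar, profile.i_r, sp, pp, g, psi)
    total = _k.supply_caps(state.theta, g, psi, profile.i_r, sp, pp, cap)
    return g, psi, cap, float(total)


def max_supply(state: SoilColumnState, profile: RootProfile,
               p: SoilHydraulicParams, geom: CatchmentGeometry,
               hyd: RootHydraulics = RootHydraulics()) -> float:
    """Maximum extraction rate (mm h^-1) with the collar at psi_min,
    additionally capped by extractable layer water."""
    return _network(state, profile, p, geom, hyd)[3]


def root_water_uptake(state: SoilColumnState, profile: RootProfile,
                      demand: float, p: SoilHydraulicParams,
                      geom: CatchmentGeometry,
                      hyd: RootHydraulics = RootHydraulics()) -> UptakeResult:
    """Distribute a transpiration demand (mm h^-1) over the rooted layers.

    The root-collar potential is solved so the summed layer fluxes equal the
    demand; when the network cannot supply it, extraction saturates at the
    per-layer caps and the result is flagged as limited.
    """
    if demand < 0:
        raise DomainError("demand must be >= 0")
    g, psi, cap, supply = _network(state, profile, p, geom, hyd)
    uptake = np.zeros_like(g)
    total = float(_k.solve_uptake(g, psi, cap, demand, hyd.psi_min, uptake))
    return UptakeResult(uptake=uptake, total=total,
                        limited=bool(demand > supply + 1e-12))


def root_area_index(profile: RootProfile) -> float:
    """RAI (m2 root per m2 ground) = sum_i S_Ar,i * layer thickness."""
    return float(np.sum(profile.s_ar) * profile.layer_thickness)
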