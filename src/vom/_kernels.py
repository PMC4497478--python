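"""Numba-compiled numerical core shared by the public modules.

Scalar primitives (retention curve, leaf gas exchange, root uptake) are
exposed as plain functions so the public API and the fused multi-year
simulation loop use the *same* compiled code paths.

Unit conventions inside the kernels:
  - lengths/heads in m, layer fluxes in mm h^-1, time step 1 h
  - CO2/H2O mole fractions in mol mol^-1 (ppm * 1e-6)
  - electron transport / assimilation in mol m^-2 s^-1 (per leaf area)
  - carbon accounting in mol CO2 m^-2 ground d^-1
"""
from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap

# ---------------------------------------------------------------------------
# parameter-vector layouts (kept flat for numba friendliness)

# soil/geometry vector
SP_THETA_R, SP_THETA_S, SP_ALPHA, SP_N, SP_KSAT, SP_DZ, SP_ZR, SP_SINGAMMA, \
    SP_DRAIN_LEN, SP_CDRAIN = range(10)

# physiology / closure vector
PP_GAMMA_STAR, PP_ALPHA_Q, PP_GSMAX, PP_TOPT, PP_TOMEGA, PP_PSI_MIN, \
    PP_KRAD, PP_CSR, PP_CSE, PP_LAMBDA_MAX, PP_LAMBDA_ALT, PP_THETA_J = range(12)
PP_SIZE = 12

# carbon cost / adaptation vector
CP_FOLIAGE, CP_CAPACITY, CP_ROOT, CP_WOOD, CP_WOOD_DEPTH, CP_PROBE, \
    CP_STEP, CP_JMAX_MIN, CP_JMAX_MAX, CP_MAS_MIN, CP_SAR_MIN, CP_SAR_MAX = range(12)

# long-term (constant) vegetation vector
VC_MAP, VC_YRP, VC_CFP, VC_CEP, VC_CFS, VC_CES = range(6)

DAILY_COLUMNS = (
    "rain", "runoff", "drainage", "e_s", "e_t_p", "e_t_s",
    "a_g_p", "a_g_s", "g_s_p", "g_s_s", "iwue_p", "iwue_s",
    "lambda_p", "lambda_s", "j_max25_p", "j_max25_s", "m_a_s",
    "rai_p", "rai_s", "theta_1", "av_theta", "ncp", "storage", "cost",
)
(D_RAIN, D_RUNOFF, D_DRAIN, D_ES, D_ETP, D_ETS, D_AGP, D_AGS, D_GSP, D_GSS,
 D_IWUEP, D_IWUES, D_LAMP, D_LAMS, D_JMAXP, D_JMAXS, D_MAS, D_RAIP, D_RAIS,
 D_TH1, D_AVTH, D_NCP, D_STORAGE, D_COST) = range(len(DAILY_COLUMNS))

HOURLY_COLUMNS = (
    "rain", "infiltration", "runoff", "drainage", "e_s", "e_t_p", "e_t_s",
    "g_s_p", "g_s_s", "a_g_p", "a_g_s", "storage",
)

H_MAX = 1.0e4          # suction-head cap (m); far beyond any wilting point
MM_PER_MOL = 0.018 * 3600.0 * 1.0  # mol H2O m^-2 s^-1 -> mm h^-1 (= 64.8)


# ---------------------------------------------------------------------------
# van Genuchten / Mualem primitives

@njit(cache=True)
def vg_sat_from_head(h, alpha, n):
    """Effective saturation from suction head (h >= 0, m)."""
    m = 1.0 - 1.0 / n
    return (1.0 + (alpha * h) ** n) ** (-m)


@njit(cache=True)
def vg_head_from_sat(se, alpha, n):
    """Closed-form inverse retention curve, capped at H_MAX."""
    if se >= 1.0:
        return 0.0
    if se < 1e-12:
        se = 1e-12
    m = 1.0 - 1.0 / n
    h = ((se ** (-1.0 / m)) - 1.0) ** (1.0 / n) / alpha
    if h > H_MAX:
        h = H_MAX
    return h


@njit(cache=True)
def vg_cond_from_sat(se, ksat, n):
    """Mualem conductivity K(Theta) = Ksat * Th^0.5 * [1-(1-Th^(1/m))^m]^2."""
    if se <= 0.0:
        return 0.0
    if se >= 1.0:
        return ksat
    m = 1.0 - 1.0 / n
    t = 1.0 - (1.0 - se ** (1.0 / m)) ** m
    return ksat * np.sqrt(se) * t * t


# ---------------------------------------------------------------------------
# soil column mechanics

@njit(cache=True)
def water_table_elev(theta, sp):
    """Water-table elevation above bedrock (m): contiguous saturated stack
    from the bottom, plus a continuous partial fill from the layer above
    once it is nearly saturated (keeps drainage continuous and monotone
    without counting held unsaturated water as table)."""
    nl = theta.size
    ts = sp[SP_THETA_S]
    tr = sp[SP_THETA_R]
    dz = sp[SP_DZ]
    se0 = 0.9  # effective saturation where a layer starts to count as table
    nsat = 0
    for i in range(nl - 1, -1, -1):
        if theta[i] >= ts - 1e-9:
            nsat += 1
        else:
            break
    zw = nsat * dz
    if nsat < nl:
        i = nl - 1 - nsat
        se = (theta[i] - tr) / (ts - tr)
        if se > se0:
            zw += dz * (se - se0) / (1.0 - se0)
    return zw


@njit(cache=True)
def drainage_rate(zw, sp):
    """Dupuit-style lateral outflow (mm h^-1 per unit catchment area)."""
    head = zw - sp[SP_ZR]
    if head <= 0.0:
        return 0.0
    ks_mh = sp[SP_KSAT] * 3600.0
    return sp[SP_CDRAIN] * ks_mh * sp[SP_SINGAMMA] * head / sp[SP_DRAIN_LEN] * 1000.0


@njit(cache=True)
def apply_drainage(theta, sp, q_mm):
    """Remove q_mm from the saturated stack (top of stack downward).
    Returns the amount actually removed."""
    nl = theta.size
    ts = sp[SP_THETA_S]
    tr = sp[SP_THETA_R]
    dz = sp[SP_DZ]
    nsat = 0
    for i in range(nl - 1, -1, -1):
        if theta[i] >= ts - 1e-9:
            nsat += 1
        else:
            break
    removed = 0.0
    start = nl - 1 - nsat
    if start < 0:
        start = 0
    for i in range(start, nl):
        if removed >= q_mm:
            break
        avail = (theta[i] - tr) * dz * 1000.0
        take = q_mm - removed
        if take > avail:
            take = avail
        theta[i] -= take / (dz * 1000.0)
        removed += take
    return removed


@njit(cache=True)
def infiltrate(theta, sp, rain_mm):
    """Add rain at the surface limited by Ksat and available pore space.
    Returns (infiltrated_mm, runoff_mm)."""
    nl = theta.size
    ts = sp[SP_THETA_S]
    dz = sp[SP_DZ]
    cap = sp[SP_KSAT] * 3600.0 * 1000.0  # mm h^-1
    amount = rain_mm if rain_mm < cap else cap
    added = 0.0
    for i in range(nl):
        if added >= amount:
            break
        room = (ts - theta[i]) * dz * 1000.0
        take = amount - added
        if take > room:
            take = room
        theta[i] += take / (dz * 1000.0)
        added += take
    return added, rain_mm - added


@njit(cache=True)
def redistribute(theta, sp, dt):
    """Explicit Darcy redistribution between adjacent layers with adaptive
    sub-stepping; geometric-mean interface conductivity; impermeable top and
    bottom for this operator. Mass-conserving by construction."""
    nl = theta.size
    tr = sp[SP_THETA_R]
    ts = sp[SP_THETA_S]
    al = sp[SP_ALPHA]
    vn = sp[SP_N]
    ks_mh = sp[SP_KSAT] * 3600.0
    dz = sp[SP_DZ]
    q = np.empty(nl - 1)
    remaining = dt
    it = 0
    while remaining > 1e-12 and it < 400:
        it += 1
        qmax = 1e-30
        for i in range(nl - 1):
            se_u = (theta[i] - tr) / (ts - tr)
            se_l = (theta[i + 1] - tr) / (ts - tr)
            h_u = vg_head_from_sat(se_u, al, vn)
            h_l = vg_head_from_sat(se_l, al, vn)
            k_u = vg_cond_from_sat(se_u, ks_mh, vn)
            k_l = vg_cond_from_sat(se_l, ks_mh, vn)
            kbar = np.sqrt(k_u * k_l)
            # total head H = z - h; downward-positive gradient
            q[i] = kbar * (1.0 + (h_l - h_u) / dz)
            if abs(q[i]) > qmax:
                qmax = abs(q[i])
        dts = 0.1 * (ts - tr) * dz / qmax
        if dts > remaining:
            dts = remaining
        for i in range(nl - 1):
            qi = q[i] * dts  # m of water, positive downward
            if qi > 0.0:
                lim1 = (theta[i] - tr) * dz
                lim2 = (ts - theta[i + 1]) * dz
                if qi > lim1:
                    qi = lim1
                if qi > lim2:
                    qi = lim2
            else:
                lim1 = (theta[i + 1] - tr) * dz
                lim2 = (ts - theta[i]) * dz
                if -qi > lim1:
                    qi = -lim1
                if -qi > lim2:
                    qi = -lim2
            theta[i] -= qi / dz
            theta[i + 1] += qi / dz
        remaining -= dts


@njit(cache=True)
def soil_evap_rate(ig_w, t_a, theta1_se, total_fpc, c_se):
    """Equilibrium-radiation soil evaporation (mm h^-1), scaled by exposed
    ground fraction and top-layer effective saturation."""
    if ig_w <= 0.0 or theta1_se <= 0.0 or total_fpc >= 1.0:
        return 0.0
    es = 0.6108 * np.exp(17.27 * t_a / (t_a + 237.3))
    delta = 4098.0 * es / ((t_a + 237.3) ** 2)
    eq = delta / (delta + 0.0665) * ig_w * 3600.0 / 2.45e6  # mm h^-1
    return c_se * (1.0 - total_fpc) * theta1_se * eq


# ---------------------------------------------------------------------------
# root resistance network

@njit(cache=True)
def root_conductances(theta, sar, i_r, sp, pp, g_out, psi_out):
    """Per-layer conductance (mm h^-1 per m head) and soil water potential
    (m, matric only). Soil and radial pathway in series."""
    nl = theta.size
    tr = sp[SP_THETA_R]
    ts = sp[SP_THETA_S]
    dz = sp[SP_DZ]
    krad = pp[PP_KRAD]
    csr = pp[PP_CSR]
    for i in range(nl):
        if i < i_r and sar[i] > 0.0:
            se = (theta[i] - tr) / (ts - tr)
            if se < 0.0:
                se = 0.0
            h = vg_head_from_sat(se, sp[SP_ALPHA], sp[SP_N])
            k_mh = vg_cond_from_sat(se, sp[SP_KSAT] * 3600.0, sp[SP_N])
            ksoil = csr * k_mh
            if ksoil < 1e-30:
                kcomb = 0.0
            else:
                kcomb = 1.0 / (1.0 / ksoil + 1.0 / krad)
            g_out[i] = sar[i] * dz * kcomb * 1000.0
            psi_out[i] = -h
        else:
            g_out[i] = 0.0
            psi_out[i] = 0.0


@njit(cache=True)
def supply_caps(theta, g_cond, psi, i_r, sp, pp, cap_out):
    """Per-layer maximum extraction (mm over one hour), limited by the
    resistance network at psi_min and by extractable water."""
    nl = theta.size
    tr = sp[SP_THETA_R]
    dz = sp[SP_DZ]
    psi_min = pp[PP_PSI_MIN]
    total = 0.0
    for i in range(nl):
        if g_cond[i] > 0.0:
            s = g_cond[i] * (psi[i] - psi_min)
            if s < 0.0:
                s = 0.0
            avail = 0.9 * (theta[i] - tr) * dz * 1000.0
            if s > avail:
                s = avail
            cap_out[i] = s
            total += s
        else:
            cap_out[i] = 0.0
    return total


@njit(cache=True)
def solve_uptake(g_cond, psi, cap, demand, psi_min, uptake_out):
    """Root-collar potential solve: sum_i min(G_i*max(0, psi_i - psi_r),
    cap_i) = demand, by bisection on psi_r. Returns total extracted."""
    nl = g_cond.size
    total_cap = 0.0
    psi_hi = psi_min
    for i in range(nl):
        total_cap += cap[i]
        if g_cond[i] > 0.0 and psi[i] > psi_hi:
            psi_hi = psi[i]
    if demand <= 0.0:
        for i in range(nl):
            uptake_out[i] = 0.0
        return 0.0
    if demand >= total_cap:
        for i in range(nl):
            uptake_out[i] = cap[i]
        return total_cap
    lo = psi_min
    hi = psi_hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        tot = 0.0
        for i in range(nl):
            if g_cond[i] > 0.0:
                u = g_cond[i] * (psi[i] - mid)
                if u < 0.0:
                    u = 0.0
                if u > cap[i]:
                    u = cap[i]
                tot += u
        if tot > demand:
            lo = mid
        else:
            hi = mid
    psi_r = 0.5 * (lo + hi)
    total = 0.0
    for i in range(nl):
        u = 0.0
        if g_cond[i] > 0.0:
            u = g_cond[i] * (psi[i] - psi_r)
            if u < 0.0:
                u = 0.0
            if u > cap[i]:
                u = cap[i]
        uptake_out[i] = u
        total += u
    # rescale residual bisection error onto the active layers
    if total > 0.0 and demand < total_cap:
        f = demand / total
        if f < 2.0:
            for i in range(nl):
                uptake_out[i] *= f
            total = demand
    return total


# ---------------------------------------------------------------------------
# leaf gas exchange

@njit(cache=True)
def jmax_at_temp(jmax25, t_a, t_opt, t_omega):
    """Gaussian temperature response anchored so that f(25 C) = jmax25."""
    x = (t_a - t_opt) / t_omega
    x25 = (25.0 - t_opt) / t_omega
    return jmax25 * np.exp(-x * x + x25 * x25)


@njit(cache=True)
def electron_transport_rate(i_a, jmax_t, alpha_q, theta_j):
    """Hyperbolic light response (mol e- m^-2 s^-1): rectangular for
    theta_j = 0, non-rectangular (sharper knee) for 0 < theta_j < 1."""
    if i_a <= 0.0 or jmax_t <= 0.0:
        return 0.0
    q = alpha_q * i_a
    if theta_j <= 0.0:
        return q * jmax_t / (q + jmax_t)
    s = q + jmax_t
    return (s - np.sqrt(s * s - 4.0 * theta_j * q * jmax_t)) / (2.0 * theta_j)


@njit(cache=True)
def ci_from_gs(g_s, c_a, gamma_star, j):
    """Leaf-internal CO2 from the supply/demand balance
    g_s (c_a - c_i) = (j/4)(c_i - G*)/(c_i + 2 G*)."""
    if g_s <= 0.0 or j <= 0.0:
        return gamma_star
    b = j / 4.0 - g_s * (c_a - 2.0 * gamma_star)
    c = gamma_star * (2.0 * g_s * c_a + j / 4.0)
    return (-b + np.sqrt(b * b + 4.0 * g_s * c)) / (2.0 * g_s)


@njit(cache=True)
def optimal_gas_exchange(i_a, t_a, d_v, c_a, jmax25, lam, e_cap, pp):
    """Hourly stomatal optimum: maximize A - E/lam subject to E <= e_cap.

    Interior candidates come from the closed-form stationarity quadratic in
    c_i; boundary candidates are g=0 and g=gmax. Returns
    (g_s, c_i, a_g, e_t, limited_flag). All in mol units per leaf area.
    """
    gstar = pp[PP_GAMMA_STAR]
    gmax = pp[PP_GSMAX]
    if i_a <= 0.0 or jmax25 <= 0.0 or c_a <= gstar:
        return 0.0, gstar, 0.0, 0.0, 0.0
    jm = jmax_at_temp(jmax25, t_a, pp[PP_TOPT], pp[PP_TOMEGA])
    j = electron_transport_rate(i_a, jm, pp[PP_ALPHA_Q], pp[PP_THETA_J])
    if j <= 0.0:
        return 0.0, gstar, 0.0, 0.0, 0.0
    if d_v <= 0.0:
        # water costs nothing; fully open within the supply-independent bound
        g = gmax
        ci = ci_from_gs(g, c_a, gstar, j)
        return g, ci, g * (c_a - ci), 0.0, 0.0
    k = 1.6 * d_v / lam
    a2 = 3.0 * gstar - k
    b2 = 2.0 * k * gstar - 6.0 * gstar * c_a
    c2 = 3.0 * gstar * c_a * c_a - 3.0 * gstar * k * c_a + 2.0 * k * gstar * gstar
    best_f = 0.0
    best_g = 0.0
    n_cand = 0
    cand = np.empty(2)
    if abs(a2) < 1e-30:
        if b2 != 0.0:
            cand[0] = -c2 / b2
            n_cand = 1
    else:
        disc = b2 * b2 - 4.0 * a2 * c2
        if disc >= 0.0:
            sq = np.sqrt(disc)
            cand[0] = (-b2 - sq) / (2.0 * a2)
            cand[1] = (-b2 + sq) / (2.0 * a2)
            n_cand = 2
    for ic in range(n_cand):
        ci = cand[ic]
        if ci <= gstar or ci >= c_a:
            continue
        g = (j / 4.0) * (ci - gstar) / ((ci + 2.0 * gstar) * (c_a - ci))
        if g <= 0.0:
            continue
        if g > gmax:
            g = gmax
            ci = ci_from_gs(g, c_a, gstar, j)
        f = g * (c_a - ci) - 1.6 * g * d_v / lam
        if f > best_f:
            best_f = f
            best_g = g
    ci = ci_from_gs(gmax, c_a, gstar, j)
    f = gmax * (c_a - ci) - 1.6 * gmax * d_v / lam
    if f > best_f:
        best_f = f
        best_g = gmax
    g = best_g
    limited = 0.0
    e = 1.6 * g * d_v
    if e > e_cap:
        g = e_cap / (1.6 * d_v)
        limited = 1.0
    ci = ci_from_gs(g, c_a, gstar, j)
    a = g * (c_a - ci)
    e = 1.6 * g * d_v
    return g, ci, a, e, limited


@njit(cache=True)
def lambda_value(c_f, c_e, h_layers, i_r, alt_grouping, lam_max):
    """Water-use function lambda = c_f (sum h_i)^c_e over the rooted layers;
    alternative grouping c_f sum(h_i^c_e) selectable."""
    if alt_grouping != 0.0:
        s = 0.0
        for i in range(i_r):
            hi = h_layers[i]
            if hi <= 0.0:
                s += lam_max / c_f if c_e < 0.0 else 0.0
            else:
                s += hi ** c_e
        lam = c_f * s
    else:
        s = 0.0
        for i in range(i_r):
            s += h_layers[i]
        if s <= 0.0:
            lam = lam_max if c_e < 0.0 else (c_f if c_e == 0.0 else 0.0)
        else:
            lam = c_f * s ** c_e
    if lam > lam_max:
        lam = lam_max
    if lam < 1e-12:
        lam = 1e-12
    return lam


# ---------------------------------------------------------------------------
# daily carbon accounting and the finite-difference day replay

@njit(cache=True)
def component_costs(is_perennial, ma, jmax25, sar, dz, y_r, cp):
    """Maintenance/turnover cost of one big leaf + its root system
    (mol C m^-2 ground d^-1)."""
    r_fol = cp[CP_FOLIAGE] * ma + cp[CP_CAPACITY] * ma * jmax25
    r_root = 0.0
    for i in range(sar.size):
        r_root += sar[i] * dz
    r_root *= cp[CP_ROOT]
    r_wood = 0.0
    if is_perennial:
        r_wood = cp[CP_WOOD] * ma * (1.0 + cp[CP_WOOD_DEPTH] * y_r)
    return r_fol + r_root + r_wood


@njit(cache=True)
def replay_component_ncp(is_perennial, ma, jmax25, sar, i_r, lam, y_r,
                         h_day, ia_day, ta_day, dv_day, c_a_mf,
                         sp, pp, cp):
    """NCP contribution of one big leaf for a stored day, holding the soil
    suction trajectory fixed (the 'would it have paid off yesterday' probe).
    """
    nl = sar.size
    dz = sp[SP_DZ]
    tr = sp[SP_THETA_R]
    ts = sp[SP_THETA_S]
    krad = pp[PP_KRAD]
    csr = pp[PP_CSR]
    psi_min = pp[PP_PSI_MIN]
    a_sum = 0.0
    for hh in range(24):
        ia = ia_day[hh]
        if ia <= 0.0 or ma <= 0.0:
            continue
        supply = 0.0
        for i in range(i_r):
            if sar[i] > 0.0:
                h = h_day[hh, i]
                se = vg_sat_from_head(h, sp[SP_ALPHA], sp[SP_N])
                k_mh = vg_cond_from_sat(se, sp[SP_KSAT] * 3600.0, sp[SP_N])
                ksoil = csr * k_mh
                if ksoil > 1e-30:
                    kcomb = 1.0 / (1.0 / ksoil + 1.0 / krad)
                    s = sar[i] * dz * kcomb * 1000.0 * (-h - psi_min)
                    if s > 0.0:
                        avail = 0.9 * (ts - tr) * se * dz * 1000.0
                        if s > avail:
                            s = avail
                        supply += s
        e_cap = supply / (ma * MM_PER_MOL)
        g, ci, a, e, lim = optimal_gas_exchange(
            ia, ta_day[hh], dv_day[hh], c_a_mf, jmax25, lam, e_cap, pp)
        a_sum += a * ma * 3600.0
    return a_sum - component_costs(is_perennial, ma, jmax25, sar, dz, y_r, cp)


# ---------------------------------------------------------------------------
# fused multi-year simulation

@njit(cache=True)
def run_core(ia, ta, dv, rain, ig_w, c_a_ppm,
             sp, pp, cp, vc,
             theta, sar_p, sar_s, dyn,
             daily_out, hourly_out, adapt):
    """Hourly water balance + two-big-leaf gas exchange with day-by-day
    adjustment of the fast vegetation properties.

    dyn = [j_max25_p, j_max25_s, m_a_s] (mol units for J). Arrays theta,
    sar_p, sar_s and dyn are advanced in place; daily_out (n_days x NCOLS)
    is filled. hourly_out may be a (0, x) array to skip hourly logging.
    """
    nl = theta.size
    dz = sp[SP_DZ]
    tr = sp[SP_THETA_R]
    ts = sp[SP_THETA_S]
    n_hours = ia.size
    n_days = n_hours // 24
    c_a_mf = c_a_ppm * 1e-6
    ma_p = vc[VC_MAP]
    y_r_p = vc[VC_YRP]
    y_r_s = 1.0
    i_r_p = int(round(y_r_p / dz))
    if i_r_p < 1:
        i_r_p = 1
    if i_r_p > nl:
        i_r_p = nl
    i_r_s = int(round(y_r_s / dz))
    if i_r_s > nl:
        i_r_s = nl
    for i in range(i_r_p, nl):
        sar_p[i] = 0.0
    for i in range(i_r_s, nl):
        sar_s[i] = 0.0

    h_lay = np.empty(nl)
    g_p = np.empty(nl)
    psi_p = np.empty(nl)
    cap_p = np.empty(nl)
    g_s_ = np.empty(nl)
    psi_s = np.empty(nl)
    cap_s = np.empty(nl)
    upt_p = np.empty(nl)
    upt_s = np.empty(nl)
    h_day = np.empty((24, nl))
    ia_day = np.empty(24)
    ta_day = np.empty(24)
    dv_day = np.empty(24)
    sar_probe = np.empty(nl)
    log_hourly = hourly_out.shape[0] > 0

    for d in range(n_days):
        # --- daily water-use parameter from the midnight soil state
        for i in range(nl):
            se = (theta[i] - tr) / (ts - tr)
            h_lay[i] = vg_head_from_sat(se, sp[SP_ALPHA], sp[SP_N])
        lam_p = lambda_value(vc[VC_CFP], vc[VC_CEP], h_lay, i_r_p,
                             pp[PP_LAMBDA_ALT], pp[PP_LAMBDA_MAX])
        lam_s = lambda_value(vc[VC_CFS], vc[VC_CES], h_lay, i_r_s,
                             pp[PP_LAMBDA_ALT], pp[PP_LAMBDA_MAX])
        ma_s = dyn[2]
        jp = dyn[0]
        js = dyn[1]
        fpc = ma_p + ma_s

        agp = 0.0
        ags = 0.0
        etp = 0.0
        ets = 0.0
        es_tot = 0.0
        q_tot = 0.0
        ro_tot = 0.0
        rain_tot = 0.0
        gsp_sum = 0.0
        gss_sum = 0.0
        iwp_sum = 0.0
        iws_sum = 0.0
        n_day_p = 0
        n_day_s = 0
        th1_sum = 0.0
        avth_sum = 0.0

        for hh in range(24):
            t = d * 24 + hh
            ia_day[hh] = ia[t]
            ta_day[hh] = ta[t]
            dv_day[hh] = dv[t]
            for i in range(nl):
                se = (theta[i] - tr) / (ts - tr)
                h_day[hh, i] = vg_head_from_sat(se, sp[SP_ALPHA], sp[SP_N])

            # roots: conductances and supply caps
            root_conductances(theta, sar_p, i_r_p, sp, pp, g_p, psi_p)
            root_conductances(theta, sar_s, i_r_s, sp, pp, g_s_, psi_s)
            sup_p = supply_caps(theta, g_p, psi_p, i_r_p, sp, pp, cap_p)
            sup_s = supply_caps(theta, g_s_, psi_s, i_r_s, sp, pp, cap_s)

            # canopy
            e_dem_p = 0.0
            e_dem_s = 0.0
            a_p = 0.0
            a_s = 0.0
            gs_p_h = 0.0
            gs_s_h = 0.0
            if ma_p > 0.0:
                ecl = sup_p / (ma_p * MM_PER_MOL)
                g1, ci1, a1, e1, l1 = optimal_gas_exchange(
                    ia[t], ta[t], dv[t], c_a_mf, jp, lam_p, ecl, pp)
                e_dem_p = e1 * ma_p * MM_PER_MOL
                a_p = a1 * ma_p * 3600.0
                gs_p_h = g1
                if ia[t] > 0.0:
                    gsp_sum += g1
                    if g1 > 1e-9:
                        iwp_sum += a1 / g1
                    n_day_p += 1
            if ma_s > 0.0:
                ecl = sup_s / (ma_s * MM_PER_MOL)
                g2, ci2, a2c, e2, l2 = optimal_gas_exchange(
                    ia[t], ta[t], dv[t], c_a_mf, js, lam_s, ecl, pp)
                e_dem_s = e2 * ma_s * MM_PER_MOL
                a_s = a2c * ma_s * 3600.0
                gs_s_h = g2
                if ia[t] > 0.0:
                    gss_sum += g2
                    if g2 > 1e-9:
                        iws_sum += a2c / g2
                    n_day_s += 1
            agp += a_p
            ags += a_s

            # extract transpiration water
            tot_p = solve_uptake(g_p, psi_p, cap_p, e_dem_p, pp[PP_PSI_MIN], upt_p)
            tot_s = solve_uptake(g_s_, psi_s, cap_s, e_dem_s, pp[PP_PSI_MIN], upt_s)
            for i in range(nl):
                theta[i] -= (upt_p[i] + upt_s[i]) / (dz * 1000.0)
            etp += tot_p
            ets += tot_s

            # soil evaporation from the top layer
            se1 = (theta[0] - tr) / (ts - tr)
            if se1 < 0.0:
                se1 = 0.0
            es_rate = soil_evap_rate(ig_w[t], ta[t], se1, fpc, pp[PP_CSE])
            avail1 = (theta[0] - tr) * dz * 1000.0
            if es_rate > avail1:
                es_rate = avail1
            theta[0] -= es_rate / (dz * 1000.0)
            es_tot += es_rate

            # infiltration and runoff
            infil, runoff = infiltrate(theta, sp, rain[t])
            rain_tot += rain[t]
            ro_tot += runoff

            # vertical redistribution and lateral drainage
            redistribute(theta, sp, 1.0)
            zw = water_table_elev(theta, sp)
            q_mm = drainage_rate(zw, sp)
            q_mm = apply_drainage(theta, sp, q_mm)
            q_tot += q_mm

            th1_sum += se1
            av = 0.0
            for i in range(i_r_p):
                sei = (theta[i] - tr) / (ts - tr)
                if sei < 0.0:
                    sei = 0.0
                av += sei
            avth_sum += av / i_r_p

            if log_hourly:
                st = 0.0
                for i in range(nl):
                    st += theta[i] * dz * 1000.0
                hourly_out[t, 0] = rain[t]
                hourly_out[t, 1] = infil
                hourly_out[t, 2] = runoff
                hourly_out[t, 3] = q_mm
                hourly_out[t, 4] = es_rate
                hourly_out[t, 5] = tot_p
                hourly_out[t, 6] = tot_s
                hourly_out[t, 7] = gs_p_h
                hourly_out[t, 8] = gs_s_h
                hourly_out[t, 9] = a_p
                hourly_out[t, 10] = a_s
                hourly_out[t, 11] = st

        # --- daily carbon account
        cost_p = component_costs(True, ma_p, jp, sar_p, dz, y_r_p, cp)
        cost_s = component_costs(False, ma_s, js, sar_s, dz, y_r_s, cp)
        ncp_day = (agp + ags) - (cost_p + cost_s)

        storage = 0.0
        for i in range(nl):
            storage += theta[i] * dz * 1000.0
        rai_p = 0.0
        rai_s = 0.0
        for i in range(nl):
            rai_p += sar_p[i] * dz
            rai_s += sar_s[i] * dz

        daily_out[d, D_RAIN] = rain_tot
        daily_out[d, D_RUNOFF] = ro_tot
        daily_out[d, D_DRAIN] = q_tot
        daily_out[d, D_ES] = es_tot
        daily_out[d, D_ETP] = etp
        daily_out[d, D_ETS] = ets
        daily_out[d, D_AGP] = agp
        daily_out[d, D_AGS] = ags
        daily_out[d, D_GSP] = gsp_sum / n_day_p if n_day_p > 0 else 0.0
        daily_out[d, D_GSS] = gss_sum / n_day_s if n_day_s > 0 else 0.0
        daily_out[d, D_IWUEP] = iwp_sum / n_day_p if n_day_p > 0 else 0.0
        daily_out[d, D_IWUES] = iws_sum / n_day_s if n_day_s > 0 else 0.0
        daily_out[d, D_LAMP] = lam_p
        daily_out[d, D_LAMS] = lam_s
        daily_out[d, D_JMAXP] = jp
        daily_out[d, D_JMAXS] = js
        daily_out[d, D_MAS] = ma_s
        daily_out[d, D_RAIP] = rai_p
        daily_out[d, D_RAIS] = rai_s
        daily_out[d, D_TH1] = th1_sum / 24.0
        daily_out[d, D_AVTH] = avth_sum / 24.0
        daily_out[d, D_NCP] = ncp_day
        daily_out[d, D_STORAGE] = storage
        daily_out[d, D_COST] = cost_p + cost_s

        # --- day-by-day adjustment from finite-difference replay
        if adapt:
            probe = cp[CP_PROBE]
            step = cp[CP_STEP]

            # perennial: J_max25 and root profile
            base_p = replay_component_ncp(True, ma_p, jp, sar_p, i_r_p, lam_p,
                                          y_r_p, h_day, ia_day, ta_day,
                                          dv_day, c_a_mf, sp, pp, cp)
            up = replay_component_ncp(True, ma_p, jp * (1.0 + probe), sar_p,
                                      i_r_p, lam_p, y_r_p, h_day, ia_day,
                                      ta_day, dv_day, c_a_mf, sp, pp, cp)
            jp = jp * (1.0 + step) if up > base_p else jp * (1.0 - step)
            if jp < cp[CP_JMAX_MIN]:
                jp = cp[CP_JMAX_MIN]
            if jp > cp[CP_JMAX_MAX]:
                jp = cp[CP_JMAX_MAX]
            for i in range(i_r_p):
                for k in range(nl):
                    sar_probe[k] = sar_p[k]
                sar_probe[i] = sar_p[i] * (1.0 + probe) + 1e-6
                up = replay_component_ncp(True, ma_p, dyn[0], sar_probe,
                                          i_r_p, lam_p, y_r_p, h_day, ia_day,
                                          ta_day, dv_day, c_a_mf, sp, pp, cp)
                newv = sar_p[i] * (1.0 + step) + 1e-6 if up > base_p \
                    else sar_p[i] * (1.0 - step)
                if newv < cp[CP_SAR_MIN]:
                    newv = cp[CP_SAR_MIN]
                if newv > cp[CP_SAR_MAX]:
                    newv = cp[CP_SAR_MAX]
                sar_p[i] = newv

            # seasonal: J_max25, cover and root profile
            base_s = replay_component_ncp(False, ma_s, js, sar_s, i_r_s,
                                          lam_s, y_r_s, h_day, ia_day,
                                          ta_day, dv_day, c_a_mf, sp, pp, cp)
            up = replay_component_ncp(False, ma_s, js * (1.0 + probe), sar_s,
                                      i_r_s, lam_s, y_r_s, h_day, ia_day,
                                      ta_day, dv_day, c_a_mf, sp, pp, cp)
            js = js * (1.0 + step) if up > base_s else js * (1.0 - step)
            if js < cp[CP_JMAX_MIN]:
                js = cp[CP_JMAX_MIN]
            if js > cp[CP_JMAX_MAX]:
                js = cp[CP_JMAX_MAX]
            up = replay_component_ncp(False, ma_s * (1.0 + probe) + 1e-6, js,
                                      sar_s, i_r_s, lam_s, y_r_s, h_day,
                                      ia_day, ta_day, dv_day, c_a_mf,
                                      sp, pp, cp)
            ma_new = ma_s * (1.0 + step) + 1e-6 if up > base_s \
                else ma_s * (1.0 - step)
            if ma_new < cp[CP_MAS_MIN]:
                ma_new = cp[CP_MAS_MIN]
            if ma_new > 1.0 - ma_p:
                ma_new = 1.0 - ma_p
            ma_s = ma_new
            for i in range(i_r_s):
                for k in range(nl):
                    sar_probe[k] = sar_s[k]
                sar_probe[i] = sar_s[i] * (1.0 + probe) + 1e-6
                up = replay_component_ncp(False, dyn[2], dyn[1], sar_probe,
                                          i_r_s, lam_s, y_r_s, h_day, ia_day,
                                          ta_day, dv_day, c_a_mf, sp, pp, cp)
                newv = sar_s[i] * (1.0 + step) + 1e-6 if up > base_s \
                    else sar_s[i] * (1.0 - step)
                if newv < cp[CP_SAR_MIN]:
                    newv = cp[CP_SAR_MIN]
                if newv > cp[CP_SAR_MAX]:
                    newv = cp[CP_SAR_MAX]
                sar_s[i] = newv

            dyn[0] = jp
            dyn[1] = js
            dyn[2] = ma_s
    return 0
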