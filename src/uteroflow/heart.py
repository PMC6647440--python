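"""Four-chamber varying-elastance heart and dynamic valve model (CGS).

Each chamber's free-wall elastance follows a double-activation curve whose
peak is normalised to E_max; chambers interact through a shared septal
elastance (left/right), a piston effect of ventricular flow on atrial filling,
and a common exponential pericardial pressure.  Valves are Bernoulli
resistance + inertance elements whose effective orifice follows a rate-limited
opening state zeta in [0, 1].
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from . import parameters as par
from .parameters import ChamberParams, PericardiumParams, ValveParams
from .solver1d import bdf_coeffs
from .units import MMHG

CHAMBER_ORDER = ("LV", "LA", "RV", "RA")


@dataclass(frozen=True)
class ChamberCGS:
    """Chamber parameters with elastances in dyn/cm^2 per cm^3 and absolute
    times for a given cardiac period T."""

    label: str
    E_min: float
    E_max: float
    tau1: float     # s
    tau2: float     # s
    m1: float
    m2: float
    V0: float       # cm^3
    V_init: float
    K_s: float      # s/cm^3
    kappa: float
    mu_AV: float    # g cm^-7 s^-1
    t_onset: float  # s
    T: float        # s
    k: float        # activation normalisation (dyn/cm^2/cm^3)


def _activation(ts, tau1, tau2, m1, m2):
    """g1/(1+g1) * 1/(1+g2) for time-since-onset ts >= 0."""
    ts = np.asarray(ts, dtype=float)
    g1 = (ts / tau1) ** m1
    g2 = (ts / tau2) ** m2
    return (g1 / (1.0 + g1)) * (1.0 / (1.0 + g2))


def chamber_cgs(p: ChamberParams, T: float) -> ChamberCGS:
    """Bind a chamber's fractional timing parameters to a cardiac period and
    precompute the activation normalisation k so that peak E_fw = E_max."""
    tau1, tau2, t_onset = p.tau1 * T, p.tau2 * T, p.t_onset * T
    # locate the activation peak: coarse grid then golden-section refinement
    ts = np.linspace(0.0, T, 2001)
    act = _activation(ts, tau1, tau2, p.m1, p.m2)
    i = int(np.argmax(act))
    lo, hi = ts[max(i - 1, 0)], ts[min(i + 1, len(ts) - 1)]
    res = minimize_scalar(lambda t: -_activation(t, tau1, tau2, p.m1, p.m2),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    peak = -res.fun
    E_min = p.E_min * MMHG
    E_max = p.E_max * MMHG
    return ChamberCGS(
        label=p.label, E_min=E_min, E_max=E_max, tau1=tau1, tau2=tau2,
        m1=p.m1, m2=p.m2, V0=p.V0, V_init=p.V_init, K_s=p.K_s, kappa=p.kappa,
        mu_AV=p.mu_AV, t_onset=t_onset, T=T, k=(E_max - E_min) / peak)


def free_wall_elastance(t, ch: ChamberCGS):
    """E_fw(t) in dyn/cm^2/cm^3; t interpreted modulo T relative to onset."""
    ts = np.mod(np.asarray(t, dtype=float) - ch.t_onset, ch.T)
    return ch.k * _activation(ts, ch.tau1, ch.tau2, ch.m1, ch.m2) + ch.E_min


def septal_elastance(E_fw_left, E_fw_right, kappa_left, kappa_right):
    """E_sep = kappa_L E_fw,L + kappa_R E_fw,R (per ventricle/atrium pair)."""
    return kappa_left * E_fw_left + kappa_right * E_fw_right


def native_elastance(E_fw, E_sep, mu_AV=0.0, Q_V=0.0):
    """Harmonic-style free-wall/septal combination minus the piston term."""
    denom = E_fw + E_sep
    if np.any(np.asarray(denom) == 0):
        raise ValueError("E_fw + E_sep = 0")
    return E_fw * E_sep / denom - mu_AV * Q_V


def pericardial_pressure(V_pc, pc: PericardiumParams):
    """P_pc = K_pc exp[(V_pc - V0_pc)/Phi] (V_pc includes pericardial fluid)."""
    return pc.K_pc_mmhg * MMHG * math.exp((V_pc - pc.V0_pc_ml) / pc.phi_ml)


def chamber_pressure(ch: ChamberCGS, V, Q, P_star, P_pc, E_nat, E_sep):
    """P = P_pc + E_nat (V - V0) - R_s Q + (E_nat/E_sep) P*, with the source
    resistance R_s = K_s E_nat (V - V0)."""
    R_s = ch.K_s * E_nat * (V - ch.V0)
    return P_pc + E_nat * (V - ch.V0) - R_s * Q + (E_nat / E_sep) * P_star


# --------------------------------------------------------------------- valves

def valve_orifice(zeta, p: ValveParams, A_eff_max=None):
    """Effective orifice area from the valve state, floored to stay finite."""
    amax = p.A_eff_max if A_eff_max is None else A_eff_max
    a = (amax - p.A_eff_min) * np.clip(zeta, 0.0, 1.0) + p.A_eff_min
    return np.maximum(a, par.A_EFF_FLOOR)


def valve_bernoulli(A_eff, l_eff, rho=par.RHO):
    """(B, L): Bernoulli coefficient rho/(2 A^2) and inertance rho l/A."""
    A_eff = np.asarray(A_eff, dtype=float)
    return rho / (2.0 * A_eff ** 2), rho * l_eff / A_eff


def valve_flow_residual(delta_p, Q, dQ_dt, zeta, p: ValveParams, A_eff_max=None):
    """Residual of dP = B Q|Q| + L dQ/dt at the current valve state."""
    B, L = valve_bernoulli(valve_orifice(zeta, p, A_eff_max), p.l_eff)
    return delta_p - B * Q * np.abs(Q) - L * dQ_dt


def valve_rate(zeta, delta_p, p: ValveParams, opening=None):
    """dzeta/dt: opening law K_vo (1-zeta) dP for dP > 0, closing law
    K_vc zeta dP otherwise."""
    if opening is None:
        opening = delta_p > 0
    return np.where(opening, p.K_vo * (1.0 - zeta) * delta_p,
                    p.K_vc * zeta * delta_p)


def valve_state_update(zeta_prev, zeta_prev2, delta_p, dt, p: ValveParams,
                       order: int = 2):
    """Advance zeta one step with backward differences at a given dP.

    Both laws are linear in zeta, so the implicit update solves exactly;
    the result is clamped to [0, 1].
    """
    a0, a1, a2 = bdf_coeffs(order)
    rhs = (a1 * zeta_prev - a2 * zeta_prev2) / dt
    if delta_p > 0:
        # a0/dt zeta + K_vo dP zeta = rhs + K_vo dP
        zeta = (rhs + p.K_vo * delta_p) / (a0 / dt + p.K_vo * delta_p)
    else:
        zeta = rhs / (a0 / dt - p.K_vc * delta_p)
    return float(np.clip(zeta, 0.0, 1.0))
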