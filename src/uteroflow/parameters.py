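"""Physical constants and reference parameter tables.

Blood properties, reference pressures per circulatory compartment, the
wave-speed coefficient table, cardiac chamber parameters and valve parameters.
Values are the model's literature defaults; everything is overridable through
the config layer.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .units import MMHG

# Blood
RHO = 1.06          # g/cm^3
MU = 0.035          # poise
XI = -22.0          # viscous friction coefficient (flat profile, thin boundary layer)

# Murray bifurcation exponent used to fill unknown diameters / split flows
MURRAY_EXPONENT = 2.76

# Height scaling: vessel lengths are tabulated for a 6 ft 1 in reference subject
BASE_HEIGHT_CM = 185.42

# Venous valves: one every 4 cm of systemic vein, none in the venae cavae
VENOUS_VALVE_SPACING_CM = 4.0

REGIONS = (
    "systemic_artery",
    "systemic_vein",
    "coronary_artery",
    "coronary_vein",
    "pulmonary_artery",
    "pulmonary_vein",
    "hepatic_portal",
)

#: Reference pressures P0 in mm Hg per region. Systemic arteries use the
#: participant diastolic pressure, substituted at network-initialisation time.
REFERENCE_PRESSURE_MMHG = {
    "systemic_artery": "DBP",
    "systemic_vein": 5.0,
    "hepatic_portal": 8.5,
    "pulmonary_artery": 11.0,
    "pulmonary_vein": 10.0,
    "coronary_artery": "DBP",
    "coronary_vein": 5.0,
}

#: (k1 [g/s^2/cm], k2 [1/cm], k3 [g/s^2/cm]) of the empirical wave-speed law
#: c0^2 = (2 / 3 rho) (k1 exp(k2 D0/2) + k3).
WAVE_SPEED_COEFFS = {
    "systemic_artery": (3.00e6, -9.0, 33.7e4),
    "systemic_vein": (0.60e6, -5.0, 2.8e4),
    "coronary_artery": (20.00e6, -22.5, 86.5e4),
    "coronary_vein": (4.44e6, -22.5, 19.2e4),
    "pulmonary_artery": (1.30e6, -7.0, 12.2e4),
    "pulmonary_vein": (0.29e6, -5.0, 2.1e4),
    "hepatic_portal": (0.60e6, -5.0, 2.8e4),  # treated as a systemic vein
}

#: Wall-viscosity law: systemic arteries follow Gamma = b1 / D + b0;
#: systemic veins and the pulmonary system use a constant 200 g/s.
WALL_VISC_B1 = 100.0   # g cm/s
WALL_VISC_B0 = 400.0   # g/s
WALL_VISC_CONST = 200.0  # g/s

#: Default collapse pressures (mm Hg) used to form the stiffening exponent
#: b = 2 rho c0^2 / (P0 - P_collapse). Not a measured quantity; chosen to give
#: physiological exponents and exposed in config.
P_COLLAPSE_MMHG = {
    "systemic_artery": -119.0,
    "coronary_artery": -119.0,
    "pulmonary_artery": -119.0,
    "systemic_vein": -10.0,
    "coronary_vein": -10.0,
    "pulmonary_vein": -10.0,
    "hepatic_portal": -10.0,
}

#: Zero-flow transmural pressure of the vascular beds (mm Hg)
P_ZF_MMHG = 5.0


@dataclass(frozen=True)
class ChamberParams:
    """Varying-elastance chamber parameters.

    Times tau1, tau2, t_onset are fractions of the cardiac period T.
    Elastances are mm Hg/ml, volumes ml, K_s s/ml, mu_AV g cm^-7 s^-1
    (CGS piston coefficient applied to atria only).
    """

    label: str
    E_min: float
    E_max: float
    tau1: float
    tau2: float
    m1: float
    m2: float
    V0: float
    V_init: float
    K_s: float
    kappa: float
    mu_AV: float
    t_onset: float


CHAMBERS = {
    "LV": ChamberParams("LV", 0.07, 2.8, 0.26875, 0.5025, 1.32, 21.9, 10.0, 136.0, 0.5e-3, 6.0, 0.0, 0.0),
    "LA": ChamberParams("LA", 0.09, 0.13, 0.0525, 0.1725, 1.99, 11.2, 3.0, 71.0, 0.25e-3, 2.0, 0.033, 0.8125),
    "RV": ChamberParams("RV", 0.035, 0.45, 0.26875, 0.5025, 1.32, 21.9, 40.0, 172.0, 1.0e-3, 6.0, 0.0, 0.0),
    "RA": ChamberParams("RA", 0.045, 0.09, 0.0525, 0.1725, 1.99, 11.2, 7.0, 67.0, 0.5e-3, 2.0, 0.05, 0.8125),
}


@dataclass(frozen=True)
class PericardiumParams:
    """Exponential pericardial constraint P_pc = K_pc exp[(V_pc - V0_pc)/Phi].

    The pericardial constants are not independently measured here; the defaults
    are mild (sub-mm Hg at the tabulated initial chamber volumes) and exposed
    in config.
    """

    K_pc_mmhg: float = 0.5
    V0_pc_ml: float = 500.0
    phi_ml: float = 45.0
    fluid_ml: float = 30.0  # constant pericardial fluid added to chamber volumes


@dataclass(frozen=True)
class ValveParams:
    """Bernoulli-resistance + inertance valve with rate-limited state zeta.

    K_vo/K_vc are the opening/closing rate coefficients (cm^2 s^2/g); the
    effective orifice interpolates between A_eff_min and A_eff_max with zeta.
    """

    label: str
    A_eff_max: float   # cm^2 (venous valves: area of the connecting vessel)
    A_eff_min: float   # cm^2
    l_eff: float       # cm
    K_vo: float
    K_vc: float


VALVES = {
    "AV": ValveParams("AV", 6.9, 0.0, 1.5, 0.02, 0.02),
    "MV": ValveParams("MV", 5.1, 0.0, 2.0, 0.02, 0.04),
    "PV": ValveParams("PV", 5.7, 0.0, 1.5, 0.02, 0.02),
    "TV": ValveParams("TV", 6.0, 0.0, 2.0, 0.03, 0.04),
    "venous": ValveParams("venous", float("nan"), 0.0, 1.0, 0.03, 0.03),
}

#: Orifice floor so the Bernoulli coefficient stays finite at zeta = 0
A_EFF_FLOOR = 1e-6  # cm^2


@dataclass(frozen=True)
class BedSplitConfig:
    """Internal split of a vascular bed's total resistance and compliance.

    The bed is an R-C-R-C-R ladder (inlet resistances per arterial terminal,
    arteriolar compliance node, middle resistance, venular compliance node with
    the volume source, outlet resistances per venous terminal).
    """

    r_inlet_frac: float = 0.4
    r_middle_frac: float = 0.4
    r_outlet_frac: float = 0.2
    c_arteriolar_frac: float = 0.1
    c_venular_frac: float = 0.9


def p0_mmhg(region: str, dbp_mmhg: float) -> float:
    """Reference pressure for a region, resolving the DBP placeholder."""
    v = REFERENCE_PRESSURE_MMHG[region]
    return dbp_mmhg if v == "DBP" else float(v)


def p0_cgs(region: str, dbp_mmhg: float) -> float:
    return p0_mmhg(region, dbp_mmhg) * MMHG
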