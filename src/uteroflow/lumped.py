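"""0D element library and vascular-bed models (CGS units).

A vascular bed is an R-C-R-C-R ladder between its terminal arteries and veins:
per-arterial-terminal inlet resistances feed a shared arteriolar compliance
node, a middle resistance leads to a shared venular compliance node (which
carries the blood-volume source S), and per-venous-terminal outlet resistances
return to the 1D veins.  All bed resistances except the coronary ones are
pressure dependent: R_vb = R0 (p_tm0 - p_zf)/(p_tm - p_zf) above the zero-flow
pressure, with flow shut off below it.  Coronary beds instead use
volume-dependent resistances driven by the intramyocardial compartment
volumes.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import parameters as par
from .network import VascularBedSpec, area_to_diameter, murray_flow_weights
from .solver1d import bdf_coeffs


# ------------------------------------------------------------------- elements

def resistor_residual(delta_p, R, Q):
    """Ohm-analogue residual dP/R - Q."""
    if np.any(np.asarray(R) == 0):
        raise ValueError("zero resistance")
    return delta_p / R - Q


def capacitor_residual(C, dP_dt, dPext_dt, Q, S=0.0):
    """Storage residual C d(P - P_ext)/dt - Q - S (Q is the net inflow)."""
    if np.any(np.asarray(C) == 0):
        raise ValueError("zero compliance")
    return C * (dP_dt - dPext_dt) - Q - S


def inductor_residual(delta_p, L, dQ_dt):
    """Inertance residual dP/L - dQ/dt."""
    return delta_p / L - dQ_dt


# ------------------------------------------------- pressure-dependent beds

def bed_resistance(p_tm, r0, p_tm0, p_zf):
    """R_vb(p_tm); infinite (zero flow) at or below the zero-flow pressure."""
    p_tm = np.asarray(p_tm, dtype=float)
    with np.errstate(divide="ignore"):
        r = np.where(p_tm > p_zf, r0 * (p_tm0 - p_zf) / np.maximum(p_tm - p_zf, 1e-300),
                     np.inf)
    return r if r.ndim else float(r)


def bed_conductance_factor(p_tm, p_tm0, p_zf):
    """1/R_vb relative to 1/R0: (p_tm - p_zf)/(p_tm0 - p_zf), clipped at zero.

    This is the form the implicit solver uses so that the zero-flow branch is a
    well-defined state rather than a division by infinity.
    """
    return np.clip((np.asarray(p_tm, dtype=float) - p_zf) / (p_tm0 - p_zf),
                   0.0, None)


# ------------------------------------------------------------- coronary beds

CORONARY_VOLUME_FLOOR = 0.05    # fraction of V0 below which volumes are floored
CORONARY_MID_WEIGHTS = (0.75, 0.25)


@dataclass
class CoronaryBedState:
    """Two intramyocardial compartments (subendocardial/subepicardial layers)
    with volume-dependent resistances."""

    V0: np.ndarray                 # reference volumes, cm^3
    C: np.ndarray                  # intramyocardial compliances, cm^5/dyn
    R0: np.ndarray                 # reference layer resistances, dyn s/cm^5
    R0_m: float                    # reference middle resistance
    V: np.ndarray = None
    p_tm_prev: np.ndarray = None

    def __post_init__(self):
        self.V0 = np.asarray(self.V0, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.R0 = np.asarray(self.R0, dtype=float)
        if self.V is None:
            self.V = self.V0.copy()
        if self.p_tm_prev is None:
            self.p_tm_prev = np.zeros_like(self.V0)


def coronary_update(state: CoronaryBedState, p_tm, dt):
    """Integrate compartment volumes from C dp_tm/dt and refresh resistances.

    Returns (V, R_layers, R_m).  Volumes are floored at 5% of their reference
    so the V^-2 law stays finite.
    """
    p_tm = np.asarray(p_tm, dtype=float)
    state.V = state.V + state.C * (p_tm - state.p_tm_prev)
    state.V = np.maximum(state.V, CORONARY_VOLUME_FLOOR * state.V0)
    state.p_tm_prev = p_tm.copy()
    ratio = state.V0 ** 2 / state.V ** 2
    R = state.R0 * ratio
    w = CORONARY_MID_WEIGHTS
    R_m = state.R0_m * (w[0] * ratio[0] + w[1] * ratio[1])
    return state.V, R, R_m


# ------------------------------------------------------------- bed assembly

@dataclass
class BedCircuit:
    """Concrete R-C-R-C-R realisation of a vascular bed.

    Resistances are the reference values at p_tm0; at run time each is divided
    by the conductance factor of the arteriolar transmural pressure.
    """

    bed_id: int
    name: str
    arterial_terminals: list          # segment ids
    venous_terminals: list
    r_inlet: np.ndarray               # per arterial terminal, dyn s/cm^5
    r_middle: float
    r_outlet: np.ndarray              # per venous terminal
    c_arteriolar: float               # cm^5/dyn
    c_venular: float
    p_tm0: float                      # dyn/cm^2
    p_zf: float
    kind: str = "pressure_dependent"

    def scale_resistance(self, factor: float):
        self.r_inlet = self.r_inlet * factor
        self.r_middle = self.r_middle * factor
        self.r_outlet = self.r_outlet * factor

    @property
    def r_total(self) -> float:
        return (1.0 / np.sum(1.0 / self.r_inlet) + self.r_middle
                + 1.0 / np.sum(1.0 / self.r_outlet))


def bed_assembly(bed: VascularBedSpec, terminal_areas: dict,
                 split: par.BedSplitConfig = par.BedSplitConfig()) -> BedCircuit:
    """Realise a bed spec as an internal 0D circuit.

    ``terminal_areas`` maps terminal segment id -> (area cm^2, multiplicity);
    inlet/outlet resistances divide the bed totals across terminals with
    Murray-law weights on the distal diameters (equal areas give equal split).
    """
    if not bed.arterial_terminal_ids:
        raise ValueError(f"bed {bed.id}: no arterial terminal")
    if not bed.venous_terminal_ids:
        raise ValueError(f"bed {bed.id}: no venous terminal (required in a closed loop)")
    if math.isnan(bed.r0_total) or math.isnan(bed.compliance_total):
        raise ValueError(f"bed {bed.id}: R0/compliance not estimated yet")

    def weights(ids):
        d = []
        for sid in ids:
            area, mult = terminal_areas[sid]
            # an effective terminal of m parallel copies carries m times the
            # single-vessel Murray share
            d.append(mult * area_to_diameter(area) ** par.MURRAY_EXPONENT)
        w = np.asarray(d)
        return w / w.sum()

    w_in = weights(bed.arterial_terminal_ids)
    w_out = weights(bed.venous_terminal_ids)
    r_in_total = split.r_inlet_frac * bed.r0_total
    r_out_total = split.r_outlet_frac * bed.r0_total
    return BedCircuit(
        bed_id=bed.id, name=bed.name,
        arterial_terminals=list(bed.arterial_terminal_ids),
        venous_terminals=list(bed.venous_terminal_ids),
        r_inlet=r_in_total / w_in,
        r_middle=split.r_middle_frac * bed.r0_total,
        r_outlet=r_out_total / w_out,
        c_arteriolar=split.c_arteriolar_frac * bed.compliance_total,
        c_venular=split.c_venular_frac * bed.compliance_total,
        p_tm0=bed.p_tm0, p_zf=bed.p_zf, kind=bed.kind,
    )
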