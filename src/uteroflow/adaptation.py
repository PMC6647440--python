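"""Initial parameter estimation and iterative adaptation to participant data.

From measured heart rate, brachial systolic/diastolic pressure and cardiac
output, the systemic vascular bed resistances are seeded from TPR = MAP/CO and
a table of regional cardiac-output fractions (Murray-law weighting inside
multi-bed regions); total arterial compliance is seeded from the decay-time
relation tau = TPR * C_T with tau = 1.79 s, the meshed 1D tree's compliance
subtracted, and the remainder distributed across beds in inverse proportion to
resistance.  The closed loop is then run to periodicity and three controls are
iterated until the model matches the measurements to +-0.5%:

* global systemic bed-resistance scale  -> mean pressure,
* global systemic arterial compliance scale (1D wave speeds and arteriolar
  compliances together, preserving the 1D distribution) -> pulse pressure,
* blood volume added/removed through the venular sources -> stroke volume.

The mean driving the resistance control is the form-factor mean
(2 DBP + SBP)/3 evaluated identically on the target and the model waveform,
which makes (mean, pulse pressure) a bijection of (SBP, DBP) and lets the
termination test on systolic and diastolic pressure individually succeed; the
sampled time-average of the brachial waveform remains the reported model MABP.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import parameters as par
from .network import NetworkModel, area_to_diameter
from .system import ConvergenceError, CycleMonitor, GlobalSystem, run_to_periodic
from .units import MMHG, mls_to_lmin, wood_to_cgs

#: decay-time constant tau = TPR * C_T of the systemic Windkessel, seconds
TAU_SYSTEMIC = 1.79

#: pulmonary seed values: arterio-venous pressure drop (mm Hg) at target CO and
#: the pulmonary RC decay time (s); no pulmonary measurements exist, so beds
#: are scaled to keep mean pulmonary pressures in the healthy range
PULMONARY_DROP_MMHG = 6.0
TAU_PULMONARY = 0.35

#: stage-dependent cardiac-output fractions of the utero-ovarian region
#: (uterine + placental beds combined, and the ovarian beds)
UTERINE_FRACTION = {"PP": 0.006, "T1": 0.035, "T2": 0.08, "T3": 0.12}
OVARIAN_FRACTION = {"PP": 0.004, "T1": 0.004, "T2": 0.004, "T3": 0.004}

UTERINE_BED_NAMES = ("fundus", "uterus_a", "uterus_b", "placenta", "cervix_vagina")
OVARIAN_BED_NAMES = ("ovary_left", "ovary_right")


@dataclass(frozen=True)
class ParticipantTargets:
    """Measured (or synthetic) haemodynamic targets of one participant."""

    HR: float                # bpm
    SBP: float               # mm Hg, brachial
    DBP: float               # mm Hg
    CO: float                # L/min
    height: float = par.BASE_HEIGHT_CM
    stage: str = "PP"
    label: str = ""

    def __post_init__(self):
        if not (self.SBP > self.DBP > 0):
            raise ValueError("need SBP > DBP > 0")
        if self.CO <= 0 or self.HR <= 0:
            raise ValueError("need positive CO and HR")

    @property
    def pulse_pressure(self):
        return self.SBP - self.DBP

    @property
    def map_ff(self):
        """Form-factor mean (2 DBP + SBP)/3, mm Hg."""
        return (2.0 * self.DBP + self.SBP) / 3.0

    @property
    def SV(self):
        """Stroke volume CO/HR, ml."""
        return self.CO * 1000.0 / self.HR


def initial_tpr(targets: ParticipantTargets) -> float:
    """Total peripheral resistance MAP/CO in mm Hg min/L (the form-factor MAP
    seeds the estimate)."""
    if targets.CO == 0:
        raise ValueError("zero cardiac output")
    return targets.map_ff / targets.CO


def region_alphas(network: NetworkModel, stage: str,
                  uterine_fraction: dict | None = None,
                  ovarian_fraction: dict | None = None) -> dict:
    """Cardiac-output fraction per systemic bed.

    Beds named for the utero-ovarian region take the stage-dependent regional
    fractions, split inside the region by Murray-law weights on the distal
    (terminal artery) diameters; every other systemic bed scales its
    ``alpha`` hint so the total is 1.
    """
    uf = (uterine_fraction or UTERINE_FRACTION)[stage]
    of = (ovarian_fraction or OVARIAN_FRACTION)[stage]

    def distal_weight(bed):
        w = 0.0
        for sid in bed.arterial_terminal_ids:
            seg = network.segments[sid]
            d = area_to_diameter(seg.area_ref(stage))
            w += seg.multiplicity * d ** par.MURRAY_EXPONENT
        return w

    systemic = {bid: bed for bid, bed in network.beds.items()
                if all(network.segments[t].region == "systemic_artery"
                       for t in bed.arterial_terminal_ids)}
    alphas = {}
    for names, frac in ((UTERINE_BED_NAMES, uf), (OVARIAN_BED_NAMES, of)):
        group = {bid: b for bid, b in systemic.items() if b.name in names}
        if not group:
            continue
        w = {bid: distal_weight(b) for bid, b in group.items()}
        tot = sum(w.values())
        for bid in group:
            alphas[bid] = frac * w[bid] / tot
    rest = {bid: b for bid, b in systemic.items() if bid not in alphas}
    hints = {bid: (b.alpha if not math.isnan(b.alpha) else 1.0)
             for bid, b in rest.items()}
    remaining = 1.0 - sum(alphas.values())
    tot = sum(hints.values())
    for bid, h in hints.items():
        alphas[bid] = remaining * h / tot
    return alphas


def distribute_resistance(tpr_cgs: float, alphas: dict) -> dict:
    """Per-bed reference resistance from the parallel-fraction rule
    R_bed = TPR / alpha (a bed carrying a fraction alpha of the flow at a
    common perfusion pressure)."""
    if any(a <= 0 for a in alphas.values()):
        raise ValueError("cardiac-output fractions must be positive")
    return {bid: tpr_cgs / a for bid, a in alphas.items()}


def distribute_resistance_literal(tpr_cgs: float, alphas: dict) -> dict:
    """The literal product form R_bed = alpha * TPR (exposed for comparison;
    not used by the default pipeline)."""
    return {bid: tpr_cgs * a for bid, a in alphas.items()}


def one_d_compliance(network: NetworkModel, stage: str) -> float:
    """Total systemic arterial 1D compliance sum(m A0 L / rho c0^2), cm^5/dyn."""
    from .network import init_wave_speed
    c = 0.0
    for seg in network.segments.values():
        if seg.region != "systemic_artery":
            continue
        A0 = seg.area_ref(stage)
        c0 = seg.c0_override or init_wave_speed(area_to_diameter(A0), seg.region)
        c += seg.multiplicity * A0 * seg.length / (par.RHO * c0 ** 2)
    return c


def initial_compliance(tpr_cgs: float, c1d_cgs: float, alphas: dict):
    """(C_T, per-bed 0D arterial compliance) in cm^5/dyn.

    C_T = tau/TPR; the 0D share C_T - C_1D is distributed proportionally to
    alpha (inverse to resistance).  If the meshed tree already exceeds C_T the
    0D share is floored at 5% of C_T.
    """
    c_t = TAU_SYSTEMIC / tpr_cgs
    c_0d = c_t - c1d_cgs
    if c_0d <= 0.05 * c_t:
        c_0d = 0.05 * c_t
    return c_t, {bid: c_0d * a for bid, a in alphas.items()}


def estimate_initial_parameters(network: NetworkModel, targets: ParticipantTargets):
    """Write initial R0/compliance/p_tm0 into the network's bed specs."""
    tpr_cgs = wood_to_cgs(initial_tpr(targets))
    stage = targets.stage
    alphas = region_alphas(network, stage)
    r_by_bed = distribute_resistance(tpr_cgs, alphas)
    c1d = one_d_compliance(network, stage)
    c_t, c_art_by_bed = initial_compliance(tpr_cgs, c1d, alphas)
    split = par.BedSplitConfig()
    map_cgs = targets.map_ff * MMHG
    for bid, bed in network.beds.items():
        if bid in r_by_bed:
            bed.r0_total = r_by_bed[bid]
            # the bed's arteriolar share is the allotted 0D arterial
            # compliance; the venular node gets the 0.9 share (venous storage)
            bed.compliance_total = c_art_by_bed[bid] / split.c_arteriolar_frac
            bed.p_tm0 = map_cgs
        else:  # pulmonary bed: healthy-range seed
            r = wood_to_cgs(PULMONARY_DROP_MMHG / targets.CO)
            bed.r0_total = r
            bed.compliance_total = TAU_PULMONARY / r
            bed.p_tm0 = 14.0 * MMHG
    return {"tpr_cgs": tpr_cgs, "alphas": alphas, "c_t": c_t, "c_1d": c1d}


# --------------------------------------------------------------- measurement

@dataclass
class CycleMeasurement:
    SBP: float          # mm Hg at the brachial probe
    DBP: float
    MABP: float         # Eq-style sampled time average, mm Hg
    CO: float           # L/min through the aortic valve
    SV: float           # ml

    @property
    def pulse_pressure(self):
        return self.SBP - self.DBP

    @property
    def map_ff(self):
        return (2.0 * self.DBP + self.SBP) / 3.0


def measure_cycle(system: GlobalSystem, rec, brachial_probe: int) -> CycleMeasurement:
    pb = rec.P[brachial_probe] / MMHG
    av = next(i for i, v in enumerate(system.valves) if v["name"] == "AV")
    sv = float(np.sum(rec.valve_q[av]) * system.dt)
    return CycleMeasurement(
        SBP=float(pb.max()), DBP=float(pb.min()), MABP=float(pb.mean()),
        CO=mls_to_lmin(sv / system.T), SV=sv)


# ----------------------------------------------------------------- iteration

@dataclass
class AdaptationState:
    resistance_scale: float = 1.0
    compliance_scale: float = 1.0
    added_volume: float = 0.0          # ml, cumulative
    relaxation: float = 0.8
    volume_gain: float = 4.0           # ml injected per ml of SV error (seed)
    tolerance_pct: float = 0.5
    history: list = field(default_factory=list)   # per-iteration dicts


def errors_pct(meas: CycleMeasurement, targets: ParticipantTargets) -> dict:
    return {
        "SBP": 100.0 * (meas.SBP - targets.SBP) / targets.SBP,
        "DBP": 100.0 * (meas.DBP - targets.DBP) / targets.DBP,
        "CO": 100.0 * (meas.CO - targets.CO) / targets.CO,
    }


def check_termination(errs: dict, cycle_metric_pct: float,
                      tol_pct: float = 0.5) -> bool:
    """Converged when all measurement errors and the periodicity metric are
    within the bound (inclusive)."""
    return (max(abs(e) for e in errs.values()) <= tol_pct
            and cycle_metric_pct <= tol_pct)


def adapt_iteration(system: GlobalSystem, targets: ParticipantTargets,
                    state: AdaptationState, meas: CycleMeasurement):
    """One multiplicative update of the three controls, applied in place.

    Resistance moves the form-factor mean, compliance the pulse pressure, and
    a venular volume injection over the next cycle moves the stroke volume.
    If the worst error has grown for three consecutive iterations the
    relaxation factor is halved.
    """
    errs = errors_pct(meas, targets)
    worst = max(abs(e) for e in errs.values())
    hist = state.history
    if len(hist) >= 3 and all(
            hist[-k]["worst"] > hist[-k - 1]["worst"] for k in (1, 2)) \
            and worst > hist[-1]["worst"]:
        state.relaxation = max(0.1, state.relaxation / 2.0)
    elif len(hist) >= 2 and worst < hist[-1]["worst"] < hist[-2]["worst"]:
        # errors shrinking steadily: let a previously halved relaxation recover
        state.relaxation = min(0.8, state.relaxation * 1.4)

    relax = state.relaxation
    r_ratio = (targets.map_ff / meas.map_ff) ** relax
    c_ratio = (meas.pulse_pressure / targets.pulse_pressure) ** relax

    # secant estimate of dSV/dV once two volume moves exist
    gain = state.volume_gain
    if len(hist) >= 1 and hist[-1].get("dv"):
        dsv = meas.SV - hist[-1]["SV"]
        dv = hist[-1]["dv"]
        if abs(dsv) > 1e-6 and dv != 0.0 and dv / dsv > 0:
            gain = float(np.clip(dv / dsv, 0.5, 12.0))
    dv = relax * gain * (targets.SV - meas.SV)

    apply_resistance_scale(system, r_ratio)
    apply_compliance_scale(system, c_ratio)
    if dv != 0.0:
        system.set_volume_injection(dv, system.t, system.T)
    state.resistance_scale *= r_ratio
    state.compliance_scale *= c_ratio
    state.added_volume += dv
    state.volume_gain = gain
    hist.append({"errs": errs, "worst": worst, "SV": meas.SV, "dv": dv,
                 "r_ratio": r_ratio, "c_ratio": c_ratio,
                 "r_scale": state.resistance_scale,
                 "c_scale": state.compliance_scale})
    return errs


def apply_resistance_scale(system: GlobalSystem, factor: float):
    """Scale every systemic bed resistance by a common factor (the relative
    distribution across beds is preserved)."""
    mask = system.systemic_bed[system.r_bed]
    system.r_gref[mask] /= factor
    for circ, is_sys in zip(system.bed_circuits, system.systemic_bed):
        if is_sys:
            circ.scale_resistance(factor)
    system._lu = None
    system._steps_since_jac = 10 ** 9


def apply_compliance_scale(system: GlobalSystem, factor: float):
    """Scale systemic arterial compliance by a common factor: all systemic
    artery wave speeds scale together (c0^2 by 1/factor) and the arteriolar
    compliances of systemic beds by the factor, so the 1D distribution of
    compliance is unchanged."""
    mask = np.array([system.net.segments[s].region == "systemic_artery"
                     for s in system.node_seg])
    system.p["c0sq"][mask] /= factor
    system.p["b"][mask] /= factor
    for bi, is_sys in enumerate(system.systemic_bed):
        if is_sys:
            ci = int(np.nonzero(system.cap_p == system.bed_pa_idx[bi])[0][0])
            system.cap_C[ci] *= factor
            system.bed_circuits[bi].c_arteriolar *= factor
    system.compliance_scale *= factor
    system._lu = None
    system._steps_since_jac = 10 ** 9


@dataclass
class AdaptationResult:
    converged: bool
    iterations: int
    errors_pct: dict
    cycle_metric_pct: float
    measurement: CycleMeasurement
    state: AdaptationState
    system: GlobalSystem
    record: object
    monitor: CycleMonitor


def run_adaptation(system: GlobalSystem, targets: ParticipantTargets,
                   brachial_segment_id: int,
                   max_iterations: int = 30,
                   state: AdaptationState | None = None,
                   min_cycles: int = 2) -> AdaptationResult:
    """Iterate the closed loop to the participant targets.

    The system keeps its state between iterations; each iteration re-runs to
    periodic convergence with the updated parameters and volume.
    """
    state = state or AdaptationState()
    probe = next(i for i, pr in enumerate(system.probes)
                 if pr.segment_id == brachial_segment_id)
    rec = mon = meas = None
    errs = {"SBP": math.inf, "DBP": math.inf, "CO": math.inf}
    for it in range(max_iterations):
        rec, mon = run_to_periodic(system, min_cycles=min_cycles)
        meas = measure_cycle(system, rec, probe)
        errs = errors_pct(meas, targets)
        metric = mon.metric_history[-1] if mon.metric_history else math.inf
        if check_termination(errs, metric, state.tolerance_pct):
            return AdaptationResult(True, it + 1, errs, metric, meas, state,
                                    system, rec, mon)
        adapt_iteration(system, targets, state, meas)
    metric = mon.metric_history[-1] if mon and mon.metric_history else math.inf
    return AdaptationResult(False, max_iterations, errs, metric, meas, state,
                            system, rec, mon)
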