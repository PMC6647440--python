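"""Derived haemodynamic indices from simulated waveforms.

Clinical quantities computed on one converged cardiac cycle: the sampled
time-average mean arterial pressure, total peripheral resistance in device
units, local and brachial-ankle pulse wave velocity (intersecting-tangent
foot detection), pulsatility index on velocity u = Q/A, and end-systolic
notch detection for uterine-artery waveforms.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .units import MMHG


@dataclass
class Waveform:
    """One uniformly sampled cardiac period at a probe site."""

    t: np.ndarray                   # s
    P: np.ndarray                   # mm Hg
    Q: np.ndarray                   # ml/s (group total)
    A: np.ndarray                   # cm^2
    segment_id: int = -1
    rel_pos: float = 0.5
    label: str = ""

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        if len(self.t) < 2:
            raise ValueError("waveform needs samples over a full period")

    @property
    def u(self):
        """Velocity Q/A per vessel copy? Q here is per-copy flow, so u=Q/A."""
        return self.Q / self.A

    @property
    def period(self):
        return float(self.t[-1] - self.t[0] + (self.t[1] - self.t[0]))


def waveform_from_record(system, rec, probe_index: int) -> Waveform:
    pr = system.probes[probe_index]
    return Waveform(t=rec.t, P=rec.P[probe_index] / MMHG,
                    Q=rec.Q[probe_index], A=rec.A[probe_index],
                    segment_id=pr.segment_id, rel_pos=pr.rel_pos,
                    label=pr.label)


def mabp(waveform: Waveform) -> float:
    """Sampled time-average of the pressure over one period, mm Hg."""
    if len(waveform.P) == 0:
        raise ValueError("empty series")
    return float(np.mean(waveform.P))


def tpr_variants(co_l_min: float, mabp_mmhg: float = None,
                 sbp: float = None, dbp: float = None):
    """(PTPR from the sampled mean, TPR from (2 DBP + SBP)/3), both in
    mm Hg min/L x 80 device units."""
    if co_l_min == 0:
        raise ValueError("zero cardiac output")
    out = {}
    if mabp_mmhg is not None:
        out["ptpr_mean"] = mabp_mmhg / co_l_min * 80.0
    if sbp is not None and dbp is not None:
        out["tpr_ff"] = ((2.0 / 3.0) * dbp + (1.0 / 3.0) * sbp) / co_l_min * 80.0
    return out


def local_pwv(system, segment_id: int) -> float:
    """Model PWV estimate at a vessel: the reference wave speed c0 (cm/s),
    i.e. the propagation speed at diastolic pressure with negligible flow."""
    nodes = np.nonzero(system.node_seg == segment_id)[0]
    if len(nodes) == 0:
        raise ValueError(f"segment {segment_id} not meshed")
    return float(np.sqrt(system.p["c0sq"][nodes[0]]))


def foot_time(waveform: Waveform) -> float:
    """Foot of the pressure wave by the intersecting-tangent method: the
    crossing of the steepest-upstroke tangent with the diastolic minimum."""
    P, t = waveform.P, waveform.t
    n = len(P)
    i0 = int(np.argmin(P))
    # rotate so the diastolic minimum leads; the upstroke follows it
    Pr = np.roll(P, -i0)
    dt = t[1] - t[0]
    dP = np.gradient(Pr, dt)
    i_max = int(np.argmax(dP[: max(2, n // 2)]))
    slope = dP[i_max]
    if slope <= 0:
        raise ValueError("no rising edge in waveform")
    t_rel = i_max * dt - (Pr[i_max] - Pr.min()) / slope
    return float((t[0] + i0 * dt + t_rel) % (n * dt))


def pwv_brachial_ankle(wf_brachial: Waveform, wf_ankle: Waveform,
                       L_brachial: float, L_ankle: float) -> float:
    """Path-length difference over foot-arrival delay, cm/s.

    L are distances from the aortic valve along the network; the magnitude
    convention |L_a - L_b| / |dt| is reported.
    """
    n = len(wf_brachial.P)
    period = n * (wf_brachial.t[1] - wf_brachial.t[0])
    dt = (foot_time(wf_ankle) - foot_time(wf_brachial)) % period
    if dt > period / 2:
        dt -= period
    if dt == 0:
        raise ValueError("identical arrival times; PWV undefined")
    return abs(L_ankle - L_brachial) / abs(dt)


def pulsatility_index(waveform: Waveform) -> float:
    """(u_max - u_min)/u_mean over one period, velocity-based."""
    u = waveform.u
    um = float(np.mean(u))
    if um == 0:
        raise ValueError("zero mean velocity")
    return float((u.max() - u.min()) / um)


def notch_detector(flow: np.ndarray, threshold_frac: float = 0.05,
                   window=(0.35, 0.85)):
    """Detect an end-systolic notch in a flow waveform.

    True when a local minimum below ``threshold_frac`` of the peak flow
    (including flow reversal) occurs after the systolic peak within the
    ``window`` fraction of the cycle and the flow rebounds afterwards (a dip,
    not a flat low-diastolic tail).  Returns (found, time_fraction).
    """
    q = np.asarray(flow, dtype=float)
    n = len(q)
    ipk = int(np.argmax(q))
    qpk = q[ipk]
    lo = max(ipk + 1, int(window[0] * n))
    hi = int(window[1] * n)
    if hi - lo < 3:
        return False, None
    seg = q[lo:hi]
    interior = np.nonzero((seg[1:-1] <= seg[:-2]) & (seg[1:-1] <= seg[2:]))[0] + 1
    for i in interior:
        rebound = np.max(seg[i:]) - seg[i]
        if seg[i] < threshold_frac * qpk and rebound > threshold_frac * qpk:
            return True, (lo + i) / n
    return False, None


@dataclass
class IndicesReport:
    MABP: float
    SBP: float
    DBP: float
    pulse_pressure: float
    tpr: dict
    local_pwv: float | None = None
    pulsatility_index: float | None = None
    notch: bool | None = None

    def as_dict(self):
        d = {"MABP_mmHg": self.MABP, "SBP_mmHg": self.SBP, "DBP_mmHg": self.DBP,
             "pulse_pressure_mmHg": self.pulse_pressure}
        d.update({f"TPR_{k}": v for k, v in self.tpr.items()})
        if self.local_pwv is not None:
            d["local_PWV_cm_s"] = self.local_pwv
        if self.pulsatility_index is not None:
            d["PI"] = self.pulsatility_index
        if self.notch is not None:
            d["notch"] = bool(self.notch)
        return d


def report(waveform: Waveform, co_l_min: float, system=None) -> IndicesReport:
    m = mabp(waveform)
    sbp, dbp = float(waveform.P.max()), float(waveform.P.min())
    rep = IndicesReport(
        MABP=m, SBP=sbp, DBP=dbp, pulse_pressure=sbp - dbp,
        tpr=tpr_variants(co_l_min, mabp_mmhg=m, sbp=sbp, dbp=dbp),
        pulsatility_index=pulsatility_index(waveform),
        notch=notch_detector(waveform.Q)[0])
    if system is not None and waveform.segment_id >= 0:
        rep.local_pwv = local_pwv(system, waveform.segment_id)
    return rep
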