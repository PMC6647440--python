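"""Global 1D-0D-heart-valve system: assembly, implicit time stepping and
periodic-convergence detection.

All 1D node areas/pressures/flows, 0D compartment pressures and element flows,
chamber volumes and pressures, and valve flows and opening states live in one
flat unknown vector.  Each step solves the full nonlinear residual with a
Newton iteration (BDF2 in time, backward Euler on the first step).  The
Jacobian is computed by finite differences compressed with a column colouring
derived from the numerically detected sparsity structure, factorised sparsely
and reused across steps until Newton convergence degrades or a valve changes
phase.

Junction and 1D-0D/heart couplings (mass conservation and static-pressure
continuity) enter as exact linear constraint rows that replace the boundary
continuity equations — the direct-elimination form of the Lagrange-multiplier
coupling.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from . import parameters as par
from .heart import CHAMBER_ORDER, chamber_cgs, pericardial_pressure
from .lumped import bed_assembly, bed_conductance_factor
from .network import NetworkModel, area_to_diameter, init_wave_speed, wall_viscosity
from .solver1d import bdf_coeffs, element_operators, trapz_weights
from .units import MMHG

_CH_PARTNER = np.array([2, 3, 0, 1])  # LV<->RV, LA<->RA


@dataclass
class SolverConfig:
    dt: float = 1e-3                 # s (snapped so a period is an integer step count)
    dx_max: float = 1.0              # cm
    min_nodes: int = 3
    newton_tol: float = 1e-8         # relative step tolerance
    newton_max_iter: int = 50
    jac_refresh_steps: int = 40      # ordinary refresh cadence
    max_cycles: int = 100
    periodicity_tol_pct: float = 0.5
    max_dt_halvings: int = 5


@dataclass
class BoundaryCondition:
    """Test-harness boundary condition for open fragments.

    kind: 'closed' (Q=0), 'flow' (Q=f(t)), 'pressure' (P=f(t)),
    'resistance' (P - P_out = R * m Q, a non-reflecting-ish termination).
    """

    kind: str = "closed"
    func: object = None           # f(t) for 'flow'/'pressure'
    R: float = 0.0                # dyn s/cm^5 for 'resistance'
    P_out: float = 0.0


@dataclass
class Probe:
    segment_id: int
    rel_pos: float = 0.5
    label: str = ""


class ConvergenceError(RuntimeError):
    pass


class GlobalSystem:
    """Assembled closed-loop (or open test) model ready for time stepping."""

    def __init__(self, network: NetworkModel, stage: str = "PP",
                 dbp_mmhg: float = 80.0, heart_rate_bpm: float = 70.0,
                 config: SolverConfig | None = None,
                 compliance_scale: float = 1.0,
                 boundary_conditions: dict | None = None,
                 probes: list | None = None,
                 pericardium: par.PericardiumParams | None = None,
                 include_heart: bool | None = None,
                 initial_pressure_scale: float = 1.0):
        self.net = network
        self.stage = stage
        self.dbp = dbp_mmhg
        self.cfg = config or SolverConfig()
        self.compliance_scale = compliance_scale
        self.bcs = dict(boundary_conditions or {})
        self.pericardium = pericardium or par.PericardiumParams()
        self.T = 60.0 / heart_rate_bpm
        self.steps_per_cycle = max(1, round(self.T / self.cfg.dt))
        self.dt = self.T / self.steps_per_cycle
        self.has_heart = (bool(network.heart) if include_heart is None
                          else include_heart)
        self.initial_pressure_scale = initial_pressure_scale
        self._compile(probes)
        self._init_state()
        self._lu = None
        self._steps_since_jac = 10 ** 9
        self._branch_sig = None
        self.newton_iters_last = 0

    # ------------------------------------------------------------------ build
    def _compile(self, probes):
        net, cfg = self.net, self.cfg
        seg_params = {}
        for seg in net.segments.values():
            A0 = seg.area_ref(self.stage)
            c0 = seg.c0_override or init_wave_speed(area_to_diameter(A0), seg.region)
            c0sq = c0 ** 2
            if seg.region == "systemic_artery":
                c0sq = c0sq / self.compliance_scale
            gamma = wall_viscosity(A0, seg.region)
            P0 = par.p0_cgs(seg.region, self.dbp)
            pc = par.P_COLLAPSE_MMHG[seg.region] * MMHG
            b = 2.0 * par.RHO * c0sq / (P0 - pc)
            seg_params[seg.id] = (A0, c0sq, b, gamma, P0)

        # --- split segments at venous valve sites, mesh the pieces
        valve_cuts = {}
        for site in net.valve_sites:
            valve_cuts.setdefault(site.segment_id, []).append(site.position)
        pieces = []           # (seg_id, x0, x1)
        piece_of_inlet = {}   # seg_id -> piece index of first piece
        piece_of_outlet = {}
        internal_valves = []  # (up_piece, dn_piece, seg_id)
        for sid in sorted(net.segments):
            seg = net.segments[sid]
            cuts = sorted(valve_cuts.get(sid, []))
            xs = [0.0] + cuts + [seg.length]
            first = len(pieces)
            for a, b_ in zip(xs[:-1], xs[1:]):
                pieces.append((sid, a, b_))
            piece_of_inlet[sid] = first
            piece_of_outlet[sid] = len(pieces) - 1
            for k in range(len(cuts)):
                internal_valves.append((first + k, first + k + 1, sid))

        node_x, slices = [], []
        n_off = 0
        for sid, a, b_ in pieces:
            L = b_ - a
            n = max(cfg.min_nodes, int(math.ceil(L / cfg.dx_max)) + 1)
            x = np.linspace(a, b_, n)
            node_x.append(x)
            slices.append(slice(n_off, n_off + n))
            n_off += n
        Nn = n_off
        self.Nn = Nn
        self.piece_slices = slices
        self.pieces = pieces

        # element (box) operators: trapezoid integral, difference, average
        ops = [element_operators(x) for x in node_x]
        self.Wg = sp.block_diag([o[0] for o in ops]).tocsr()
        self.Dg = sp.block_diag([o[1] for o in ops]).tocsr()
        self.Mg = sp.block_diag([o[2] for o in ops]).tocsr()
        # element equations live between the piece-end coupling rows:
        # row Nn+inlet_node holds the inlet coupling, rows Nn+start+1..Nn+stop-1
        # the element continuity equations; rows 2Nn+start..2Nn+stop-2 the
        # element momentum equations and 2Nn+outlet_node the outlet coupling.
        self.cont_rows = np.concatenate(
            [np.arange(Nn + sl.start + 1, Nn + sl.stop) for sl in slices])
        self.mom_rows = np.concatenate(
            [np.arange(2 * Nn + sl.start, 2 * Nn + sl.stop - 1) for sl in slices])
        w = np.concatenate([trapz_weights(x) for x in node_x])

        arr = {k: np.empty(Nn) for k in ("A0", "c0sq", "b", "Gamma", "P0", "mult")}
        self.node_seg = np.empty(Nn, dtype=int)
        for (sid, _, _), sl in zip(pieces, slices):
            A0, c0sq, b, gamma, P0 = seg_params[sid]
            arr["A0"][sl], arr["c0sq"][sl], arr["b"][sl] = A0, c0sq, b
            arr["Gamma"][sl], arr["P0"][sl] = gamma, P0
            arr["mult"][sl] = net.segments[sid].multiplicity
            self.node_seg[sl] = sid
        self.p = arr
        self.trapz_w = w
        self.iA = slice(0, Nn)
        self.iP = slice(Nn, 2 * Nn)
        self.iQ = slice(2 * Nn, 3 * Nn)

        # --- allocate extra unknowns; row index == unknown index for extras
        self._n = 3 * Nn
        def alloc(k=1):
            i = self._n
            self._n += k
            return np.arange(i, i + k)

        lin_rows, lin_trip, lin_rhs, lin_funcs = [], [], [], []

        def add_lin(row, terms, rhs=0.0, func=None):
            pos = len(lin_rows)
            lin_rows.append(row)
            for col, coeff in terms:
                lin_trip.append((pos, col, coeff))
            lin_rhs.append(rhs)
            if func is not None:
                lin_funcs.append((pos, func))

        def inlet_node(piece):
            return self.piece_slices[piece].start

        def outlet_node(piece):
            return self.piece_slices[piece].stop - 1

        def crow_in(node):
            return Nn + node          # coupling row at a piece inlet

        def crow_out(node):
            return 2 * Nn + node      # coupling row at a piece outlet

        iPn = lambda node: Nn + node
        iQn = lambda node: 2 * Nn + node

        # resistor / capacitor bookkeeping
        r_up, r_dn, r_q, r_gref, r_bed = [], [], [], [], []
        cap_p, cap_C, cap_bed_src = [], [], []
        cap_trip = []  # (cap_index, flow_col, sign)

        def add_resistor(up, dn, R, bed_index):
            q = alloc()[0]
            r_up.append(up)
            r_dn.append(dn)
            r_q.append(q)
            r_gref.append(1.0 / R)
            r_bed.append(bed_index)
            return q

        def add_capacitor(C, bed_src):
            pidx = alloc()[0]
            cap_p.append(pidx)
            cap_C.append(C)
            cap_bed_src.append(bed_src)
            return pidx

        # --- vascular beds
        self.bed_circuits = []
        terminal_areas = {sid: (seg_params[sid][0], net.segments[sid].multiplicity)
                          for sid in net.segments}
        self.bed_pa_idx, self.bed_pv_idx = [], []
        bed_index_of = {}
        systemic_bed = []
        for bi, bid in enumerate(sorted(net.beds)):
            bed = net.beds[bid]
            circ = bed_assembly(bed, terminal_areas)
            is_sys = all(net.segments[t].region == "systemic_artery"
                         for t in circ.arterial_terminals)
            if is_sys and self.compliance_scale != 1.0:
                circ.c_arteriolar *= self.compliance_scale
            systemic_bed.append(is_sys)
            bed_index_of[bid] = bi
            pa = add_capacitor(circ.c_arteriolar, bed_src=None)
            pv = add_capacitor(circ.c_venular, bed_src=bi)
            self.bed_pa_idx.append(pa)
            self.bed_pv_idx.append(pv)
            ca, cv = len(cap_p) - 2, len(cap_p) - 1
            for t, R in zip(circ.arterial_terminals, circ.r_inlet):
                node = outlet_node(piece_of_outlet[t])
                q = add_resistor(iPn(node), pa, R, bi)
                m = net.segments[t].multiplicity
                add_lin(crow_out(node), [(iQn(node), m), (q, -1.0)])
                cap_trip.append((ca, q, +1.0))
            qm = add_resistor(pa, pv, circ.r_middle, bi)
            cap_trip.append((ca, qm, -1.0))
            cap_trip.append((cv, qm, +1.0))
            for t, R in zip(circ.venous_terminals, circ.r_outlet):
                node = inlet_node(piece_of_inlet[t])
                q = add_resistor(pv, iPn(node), R, bi)
                m = net.segments[t].multiplicity
                add_lin(crow_in(node), [(iQn(node), m), (q, -1.0)])
                cap_trip.append((cv, q, -1.0))
            self.bed_circuits.append(circ)
        self.systemic_bed = np.asarray(systemic_bed, dtype=bool)

        # --- heart chambers and valves
        ch_inflow_trip = []   # (chamber, col, sign) for the volume equations
        self.valves = []      # dicts with parameter info
        v_up, v_dn, v_q, v_z = [], [], [], []
        v_Amax, v_Amin, v_leff, v_Kvo, v_Kvc = [], [], [], [], []

        def add_valve(pname, up_idx, dn_idx, A_eff_max=None):
            vp = par.VALVES[pname]
            q = alloc()[0]
            z = alloc()[0]
            v_up.append(up_idx)
            v_dn.append(dn_idx)
            v_q.append(q)
            v_z.append(z)
            v_Amax.append(vp.A_eff_max if A_eff_max is None else A_eff_max)
            v_Amin.append(vp.A_eff_min)
            v_leff.append(vp.l_eff)
            v_Kvo.append(vp.K_vo)
            v_Kvc.append(vp.K_vc)
            self.valves.append({"name": pname, "q": q, "z": z})
            return q, z

        if self.has_heart:
            self.ch_V_idx = alloc(4)
            self.ch_P_idx = alloc(4)
            self.chambers = [chamber_cgs(par.CHAMBERS[c], self.T)
                             for c in CHAMBER_ORDER]
            ichP = {c: self.ch_P_idx[i] for i, c in enumerate(CHAMBER_ORDER)}
            # heart valves: AV LV->aorta, MV LA->LV, PV RV->pulm art, TV RA->RV
            av_seg = net.heart["AV"]
            pv_seg = net.heart["PV"]
            av_node = inlet_node(piece_of_inlet[av_seg])
            pv_node = inlet_node(piece_of_inlet[pv_seg])
            qAV, _ = add_valve("AV", ichP["LV"], iPn(av_node))
            add_lin(crow_in(av_node), [(iQn(av_node), net.segments[av_seg].multiplicity),
                                       (qAV, -1.0)])
            qMV, _ = add_valve("MV", ichP["LA"], ichP["LV"])
            qPV, _ = add_valve("PV", ichP["RV"], iPn(pv_node))
            add_lin(crow_in(pv_node), [(iQn(pv_node), net.segments[pv_seg].multiplicity),
                                       (qPV, -1.0)])
            qTV, _ = add_valve("TV", ichP["RA"], ichP["RV"])
            # volume balances
            ch_inflow_trip += [(0, qMV, +1), (0, qAV, -1),   # LV
                               (1, qMV, -1),                 # LA (inflow below)
                               (2, qTV, +1), (2, qPV, -1),   # RV
                               (3, qTV, -1)]                 # RA
            self.ch_out_q = np.array([qAV, qMV, qPV, qTV])   # per CHAMBER_ORDER
            for key, ch in (("RA", 3), ("LA", 1)):
                for sid in net.heart.get(key, []):
                    node = outlet_node(piece_of_outlet[sid])
                    m = net.segments[sid].multiplicity
                    add_lin(crow_out(node), [(iPn(node), 1.0),
                                             (self.ch_P_idx[ch], -1.0)])
                    ch_inflow_trip.append((ch, iQn(node), m))
        else:
            self.ch_V_idx = np.array([], dtype=int)
            self.ch_P_idx = np.array([], dtype=int)
            self.chambers = []
            self.ch_out_q = np.array([], dtype=int)

        # --- venous valves at internal cuts
        for up_piece, dn_piece, sid in internal_valves:
            un, dn_ = outlet_node(up_piece), inlet_node(dn_piece)
            m = net.segments[sid].multiplicity
            a_con = seg_params[sid][0] * m
            qv, _ = add_valve("venous", iPn(un), iPn(dn_), A_eff_max=a_con)
            add_lin(crow_out(un), [(iQn(un), m), (qv, -1.0)])
            add_lin(crow_in(dn_), [(iQn(dn_), m), (qv, -1.0)])

        # --- junctions
        for j in net.junctions:
            ends = []   # (node, coupling row, sign into junction, mult)
            for sid in j.parent_ids:
                node = outlet_node(piece_of_outlet[sid])
                ends.append((node, crow_out(node), +1.0,
                             net.segments[sid].multiplicity))
            for sid in j.child_ids:
                node = inlet_node(piece_of_inlet[sid])
                ends.append((node, crow_in(node), -1.0,
                             net.segments[sid].multiplicity))
            n0 = ends[0][0]
            add_lin(ends[0][1], [(iQn(nd), s * m) for nd, _, s, m in ends])
            for nd, row, _, _ in ends[1:]:
                add_lin(row, [(iPn(nd), 1.0), (iPn(n0), -1.0)])

        # --- remaining uncoupled ends: boundary conditions (default closed)
        used_rows = {r for r in lin_rows}
        for sid, seg in net.segments.items():
            for which, node in (("inlet", inlet_node(piece_of_inlet[sid])),
                                ("outlet", outlet_node(piece_of_outlet[sid]))):
                row = crow_in(node) if which == "inlet" else crow_out(node)
                if row in used_rows:
                    continue
                bc = self.bcs.get((sid, which), BoundaryCondition())
                m = seg.multiplicity
                if bc.kind == "closed":
                    add_lin(row, [(iQn(node), 1.0)])
                elif bc.kind == "flow":
                    add_lin(row, [(iQn(node), 1.0)], func=bc.func)
                elif bc.kind == "pressure":
                    add_lin(row, [(iPn(node), 1.0)], func=bc.func)
                elif bc.kind == "resistance":
                    sgn = 1.0 if which == "outlet" else -1.0
                    add_lin(row, [(iPn(node), 1.0), (iQn(node), -sgn * bc.R * m)],
                            rhs=bc.P_out)
                else:
                    raise ValueError(f"unknown BC kind {bc.kind!r}")
                used_rows.add(row)

        n = self._n
        self.n = n

        self.lin_rows = np.asarray(lin_rows, dtype=int)
        rows = [t[0] for t in lin_trip]
        cols = [t[1] for t in lin_trip]
        vals = [t[2] for t in lin_trip]
        self.C_lin = sp.csr_matrix((vals, (rows, cols)), shape=(len(lin_rows), n))
        self.lin_rhs = np.asarray(lin_rhs)
        self.lin_funcs = lin_funcs

        self.r_up = np.asarray(r_up, dtype=int)
        self.r_dn = np.asarray(r_dn, dtype=int)
        self.r_q = np.asarray(r_q, dtype=int)
        self.r_gref = np.asarray(r_gref)
        self.r_bed = np.asarray(r_bed, dtype=int)

        self.cap_p = np.asarray(cap_p, dtype=int)
        self.cap_C = np.asarray(cap_C)
        self.cap_bed_src = cap_bed_src
        if cap_trip:
            rows = [t[0] for t in cap_trip]
            cols = [t[1] for t in cap_trip]
            vals = [t[2] for t in cap_trip]
            self.M_cap = sp.csr_matrix((vals, (rows, cols)), shape=(len(cap_p), n))
        else:
            self.M_cap = sp.csr_matrix((0, n))
        self.bed_pa_idx = np.asarray(self.bed_pa_idx, dtype=int)
        self.bed_pv_idx = np.asarray(self.bed_pv_idx, dtype=int)
        self.bed_ptm0 = np.array([c.p_tm0 for c in self.bed_circuits])
        self.bed_pzf = np.array([c.p_zf for c in self.bed_circuits])

        if ch_inflow_trip:
            rows = [t[0] for t in ch_inflow_trip]
            cols = [t[1] for t in ch_inflow_trip]
            vals = [float(t[2]) for t in ch_inflow_trip]
            self.M_ch = sp.csr_matrix((vals, (rows, cols)), shape=(4, n))
        else:
            self.M_ch = sp.csr_matrix((0, n))

        self.v_up = np.asarray(v_up, dtype=int)
        self.v_dn = np.asarray(v_dn, dtype=int)
        self.v_q = np.asarray(v_q, dtype=int)
        self.v_z = np.asarray(v_z, dtype=int)
        self.v_Amax = np.asarray(v_Amax)
        self.v_Amin = np.asarray(v_Amin)
        self.v_leff = np.asarray(v_leff)
        self.v_Kvo = np.asarray(v_Kvo)
        self.v_Kvc = np.asarray(v_Kvc)
        self.nv = len(v_q)
        self.v_opening = np.ones(self.nv, dtype=bool)

        if self.chambers:
            self.ch_Emin = np.array([c.E_min for c in self.chambers])
            self.ch_Emax = np.array([c.E_max for c in self.chambers])
            self.ch_k = np.array([c.k for c in self.chambers])
            self.ch_tau1 = np.array([c.tau1 for c in self.chambers])
            self.ch_tau2 = np.array([c.tau2 for c in self.chambers])
            self.ch_m1 = np.array([c.m1 for c in self.chambers])
            self.ch_m2 = np.array([c.m2 for c in self.chambers])
            self.ch_onset = np.array([c.t_onset for c in self.chambers])
            self.ch_V0 = np.array([c.V0 for c in self.chambers])
            self.ch_Ks = np.array([c.K_s for c in self.chambers])
            self.ch_kappa = np.array([c.kappa for c in self.chambers])
            self.ch_muAV = np.array([c.mu_AV for c in self.chambers])

        # volume-source program (ml/s per bed over a time window)
        self.S_rate = np.zeros(len(self.bed_circuits))
        self.S_window = (0.0, -1.0)

        # probes
        if probes is None:
            probes = [Probe(sid, 0.5, net.segments[sid].name)
                      for sid in sorted(net.segments)]
        self.probes = probes
        self.probe_nodes = np.array([self._probe_node(pr) for pr in probes])

        # scales for convergence tests and FD steps
        s = np.ones(n)
        s[self.iA] = self.p["A0"]
        s[self.iP] = 100.0 * MMHG
        s[self.iQ] = 50.0
        if len(self.r_q):
            s[self.r_q] = 50.0
        if len(self.cap_p):
            s[self.cap_p] = 100.0 * MMHG
        if len(self.ch_V_idx):
            s[self.ch_V_idx] = 100.0
            s[self.ch_P_idx] = 100.0 * MMHG
        if self.nv:
            s[self.v_q] = 50.0
            s[self.v_z] = 1.0
        self.scale = s

        self._jac_cache = None

    def _probe_node(self, pr: Probe) -> int:
        best, bestd = None, None
        for (sid, a, b_), sl in zip(self.pieces, self.piece_slices):
            if sid != pr.segment_id:
                continue
            L = self.net.segments[sid].length
            xt = pr.rel_pos * L
            xs = np.linspace(a, b_, sl.stop - sl.start)
            i = int(np.argmin(np.abs(xs - xt)))
            d = abs(xs[i] - xt)
            if bestd is None or d < bestd:
                best, bestd = sl.start + i, d
        if best is None:
            raise ValueError(f"probe segment {pr.segment_id} not in network")
        return best

    # ------------------------------------------------------------------ state
    def _init_state(self):
        u = np.zeros(self.n)
        u[self.iA] = self.p["A0"]
        u[self.iP] = self.p["P0"]
        if self.initial_pressure_scale != 1.0:
            # perturbed 1D initial pressures (sensitivity experiments), with
            # areas set consistently from the elastic tube law
            p = self.p
            u[self.iP] = p["P0"] * self.initial_pressure_scale
            dp = u[self.iP] - p["P0"]
            u[self.iA] = p["A0"] * (1.0 + dp * p["b"] /
                                    (2.0 * par.RHO * p["c0sq"])) ** (2.0 / p["b"])
        for bi, circ in enumerate(self.bed_circuits):
            # bed compartments start at the reference pressures of the vessels
            # they bridge, so the initial state is flow-free everywhere (no
            # startup shock into the stiff smallest vessels)
            art = self.net.segments[circ.arterial_terminals[0]]
            ven = self.net.segments[circ.venous_terminals[0]]
            u[self.bed_pa_idx[bi]] = par.p0_cgs(art.region, self.dbp)
            u[self.bed_pv_idx[bi]] = par.p0_cgs(ven.region, self.dbp)
        for i, ch in enumerate(self.chambers):
            u[self.ch_V_idx[i]] = ch.V_init
            u[self.ch_P_idx[i]] = ch.E_min * (ch.V_init - ch.V0)
        self.u = u
        self.u1 = u.copy()
        self.u2 = u.copy()
        self.t = 0.0
        self.nsteps = 0

    # --------------------------------------------------------------- residual
    def _efw(self, t):
        ts = np.mod(t - self.ch_onset, self.T)
        g1 = (ts / self.ch_tau1) ** self.ch_m1
        g2 = (ts / self.ch_tau2) ** self.ch_m2
        return self.ch_k * (g1 / (1.0 + g1)) / (1.0 + g2) + self.ch_Emin

    def residual(self, u, t, dt, order, opening=None):
        a0, a1, a2 = bdf_coeffs(order)
        ud = (a0 * u - a1 * self.u1 + a2 * self.u2) / dt
        p = self.p
        Nn = self.Nn
        A = np.maximum(u[self.iA], 1e-4 * p["A0"])
        P = u[self.iP]
        Q = u[self.iQ]
        res = np.empty(self.n)
        # tube law (per node)
        elast = (2.0 * par.RHO * p["c0sq"] / p["b"]) * ((A / p["A0"]) ** (p["b"] / 2.0) - 1.0)
        res[0:Nn] = P - p["P0"] - elast - p["Gamma"] / (p["A0"] * np.sqrt(A)) * ud[self.iA]
        # element continuity (mass-exact box form: int dA/dt + [Q])
        res[self.cont_rows] = self.Wg @ ud[self.iA] + self.Dg @ Q
        # element momentum; the viscous term -xi mu pi Q/A^2 (xi = -22)
        # opposes the flow so pressure falls along it
        res[self.mom_rows] = self.Wg @ (par.RHO / A * ud[self.iQ]
                                        - (par.XI * par.MU * math.pi) * Q / (A * A)) \
            + (par.RHO / (self.Mg @ A)) * (self.Dg @ (Q * Q / A)) + self.Dg @ P
        # coupling rows (linear)
        lin = self.C_lin @ u - self.lin_rhs
        for pos, f in self.lin_funcs:
            lin[pos] = lin[pos] - f(t) + self.lin_rhs[pos]
        res[self.lin_rows] = lin
        # 0D resistors with pressure-dependent bed factor
        if len(self.r_q):
            fac_bed = bed_conductance_factor(u[self.bed_pa_idx], self.bed_ptm0,
                                             self.bed_pzf)
            fac = fac_bed[self.r_bed]
            res[self.r_q] = u[self.r_q] - self.r_gref * fac * (u[self.r_up] - u[self.r_dn])
        # 0D capacitors (+ volume sources on venular nodes)
        if len(self.cap_p):
            src = np.zeros(len(self.cap_p))
            t0, t1 = self.S_window
            if t0 <= t < t1:
                for ci, bi in enumerate(self.cap_bed_src):
                    if bi is not None:
                        src[ci] = self.S_rate[bi]
            res[self.cap_p] = self.cap_C * ud[self.cap_p] - self.M_cap @ u - src
        # chambers
        if self.chambers:
            V = u[self.ch_V_idx]
            Pch = u[self.ch_P_idx]
            Qout = u[self.ch_out_q]
            Efw = self._efw(t)
            Esep = self.ch_kappa * Efw + self.ch_kappa[_CH_PARTNER] * Efw[_CH_PARTNER]
            Enat = Efw * Esep / (Efw + Esep) - self.ch_muAV * Qout
            Vpc = V.sum() + self.pericardium.fluid_ml
            Ppc = pericardial_pressure(Vpc, self.pericardium)
            Rs = self.ch_Ks * Enat * (V - self.ch_V0)
            res[self.ch_V_idx] = ud[self.ch_V_idx] - self.M_ch @ u
            res[self.ch_P_idx] = Pch - (Ppc + Enat * (V - self.ch_V0)
                                        - Rs * Qout
                                        + (Enat / Esep) * Pch[_CH_PARTNER])
        # valves
        if self.nv:
            if opening is None:
                opening = self.v_opening
            z = np.clip(u[self.v_z], 0.0, 1.0)
            Aeff = np.maximum((self.v_Amax - self.v_Amin) * z + self.v_Amin,
                              par.A_EFF_FLOOR)
            B = par.RHO / (2.0 * Aeff ** 2)
            L = par.RHO * self.v_leff / Aeff
            qv = u[self.v_q]
            dpv = u[self.v_up] - u[self.v_dn]
            # |Q| smoothed near zero so the Newton Jacobian stays accurate
            # through valve closure (the bias is B * 1e-6, far below any
            # physiological pressure)
            qabs = np.sqrt(qv * qv + 1e-6)
            res[self.v_q] = dpv - B * qv * qabs - L * ud[self.v_q]
            rate = np.where(opening, self.v_Kvo * (1.0 - z) * dpv,
                            self.v_Kvc * z * dpv)
            res[self.v_z] = ud[self.v_z] - rate
        return res

    # ----------------------------------------------------- jacobian machinery
    def _generic_state(self, rng):
        u = np.zeros(self.n)
        u[self.iA] = self.p["A0"] * rng.uniform(0.9, 1.1, self.Nn)
        u[self.iP] = self.p["P0"] * rng.uniform(0.95, 1.05, self.Nn) + rng.uniform(
            -500, 500, self.Nn)
        u[self.iQ] = rng.uniform(1.0, 10.0, self.Nn) * rng.choice([-1, 1], self.Nn)
        if len(self.r_q):
            u[self.r_q] = rng.uniform(1.0, 5.0, len(self.r_q))
        for bi in range(len(self.bed_circuits)):
            u[self.bed_pa_idx[bi]] = self.bed_ptm0[bi] * rng.uniform(0.8, 1.2)
            u[self.bed_pv_idx[bi]] = self.bed_pzf[bi] + rng.uniform(2, 6) * MMHG
        for i, ch in enumerate(self.chambers):
            u[self.ch_V_idx[i]] = ch.V_init * rng.uniform(0.8, 1.2)
            u[self.ch_P_idx[i]] = rng.uniform(0.5, 1.5) * 20 * MMHG
        if self.nv:
            u[self.v_q] = rng.uniform(1.0, 20.0, self.nv) * rng.choice([-1, 1], self.nv)
            u[self.v_z] = rng.uniform(0.3, 0.7, self.nv)
        return u

    def _detect_structure(self):
        rng = np.random.default_rng(12345)
        eps = 1e-6 * self.scale
        mask = sp.lil_matrix((self.n, self.n), dtype=bool)
        t0, dt = 0.37 * self.T, self.dt
        hist = (self.u1.copy(), self.u2.copy())
        for _ in range(2):
            u = self._generic_state(rng)
            self.u1 = self._generic_state(rng)
            self.u2 = self._generic_state(rng)
            r0 = self.residual(u, t0, dt, 2)
            for j in range(self.n):
                up = u.copy()
                up[j] += eps[j]
                dr = self.residual(up, t0, dt, 2) - r0
                rows = np.nonzero(dr)[0]
                mask[rows, j] = True
        self.u1, self.u2 = hist
        S = mask.tocsc()
        S = S + sp.identity(self.n, dtype=bool, format="csc")
        return S

    def _prepare_coloring(self):
        S = self._detect_structure()
        # greedy column colouring: columns sharing a row get distinct colours
        ST = S.tocsr()
        col_rows = [S.indices[S.indptr[j]:S.indptr[j + 1]] for j in range(self.n)]
        row_cols = [ST.indices[ST.indptr[i]:ST.indptr[i + 1]] for i in range(self.n)]
        color = -np.ones(self.n, dtype=int)
        order = np.argsort([-len(c) for c in col_rows])
        for j in order:
            used = set()
            for r in col_rows[j]:
                for k in row_cols[r]:
                    if color[k] >= 0:
                        used.add(color[k])
            c = 0
            while c in used:
                c += 1
            color[j] = c
        ncolor = color.max() + 1
        groups = [np.nonzero(color == c)[0] for c in range(ncolor)]
        # for each colour, the (row, col) pairs it resolves
        plan = []
        trip_rows, trip_cols = [], []
        for cols in groups:
            rows_list, colofrow = [], []
            for j in cols:
                rs = col_rows[j]
                rows_list.append(rs)
                colofrow.append(np.full(len(rs), j))
            rows_c = np.concatenate(rows_list)
            cols_c = np.concatenate(colofrow)
            plan.append((cols, rows_c, cols_c))
            trip_rows.append(rows_c)
            trip_cols.append(cols_c)
        self._color_plan = plan
        self._trip_rows = np.concatenate(trip_rows)
        self._trip_cols = np.concatenate(trip_cols)
        self._jac_cache = True

    def _refresh_jacobian(self, u, t, dt, order):
        if self._jac_cache is None:
            self._prepare_coloring()
        eps = 1e-7 * self.scale
        r0 = self.residual(u, t, dt, order)
        data = []
        for cols, rows_c, cols_c in self._color_plan:
            up = u.copy()
            up[cols] += eps[cols]
            dr = self.residual(up, t, dt, order) - r0
            data.append(dr[rows_c] / eps[cols_c])
        J = sp.csc_matrix((np.concatenate(data), (self._trip_rows, self._trip_cols)),
                          shape=(self.n, self.n))
        # equilibrate: column-scale by unknown magnitudes, then row-scale to
        # unit max (the raw matrix mixes Voigt wall terms ~1e12 with vessel
        # compliances ~1e-10, beyond float64 conditioning)
        Jc = (J @ sp.diags(self.scale)).tocsc()
        row_max = np.maximum(np.abs(Jc).max(axis=1).toarray().ravel(), 1e-300)
        self._row_scale = 1.0 / row_max
        self._lu = splu((sp.diags(self._row_scale) @ Jc).tocsc())
        self._steps_since_jac = 0
        return r0

    # ------------------------------------------------------------------- step
    def _newton(self, u, t, dt, order, refresh=False):
        cfg = self.cfg
        if refresh or self._lu is None:
            self._refresh_jacobian(u, t, dt, order)
        refreshes = 1 if refresh else 0
        prev_step = math.inf
        r = self.residual(u, t, dt, order)
        if not np.all(np.isfinite(r)):
            raise FloatingPointError("non-finite residual")
        rnorm = np.linalg.norm(self._row_scale * r)
        for it in range(cfg.newton_max_iter):
            du = self.scale * self._lu.solve(-(self._row_scale * r))
            if np.max(np.abs(du) / self.scale) < cfg.newton_tol:
                self.newton_iters_last = it + 1
                return u + du
            # keep areas positive
            A = u[self.iA]
            dA = du[self.iA]
            bad = dA < -0.5 * A
            alpha = 1.0
            if np.any(bad):
                alpha = min(1.0, 0.45 * np.min(A[bad] / -dA[bad]))
            # backtracking line search on the equilibrated residual norm
            for _ in range(10):
                u_try = u + alpha * du
                r_try = self.residual(u_try, t, dt, order)
                if np.all(np.isfinite(r_try)):
                    rn_try = np.linalg.norm(self._row_scale * r_try)
                    if rn_try <= (1.0 - 1e-4 * alpha) * rnorm or rn_try < 1e-12:
                        break
                alpha *= 0.5
            else:
                # no descent along this direction: the Jacobian is stale
                if refreshes < 10:
                    self._refresh_jacobian(u, t, dt, order)
                    refreshes += 1
                    r = self.residual(u, t, dt, order)
                    rnorm = np.linalg.norm(self._row_scale * r)
                    continue
                raise ConvergenceError(f"Newton line search failed at t={t:.4f}")
            u, r, rnorm = u_try, r_try, rn_try
            step = alpha * np.max(np.abs(du) / self.scale)
            if step < cfg.newton_tol:
                self.newton_iters_last = it + 1
                return u
            # a stale Jacobian shows up as slow linear contraction: refresh
            slow = step > 0.3 * prev_step or alpha < 1.0
            if it >= 2 and slow and refreshes < 10:
                self._refresh_jacobian(u, t, dt, order)
                refreshes += 1
                rnorm = np.linalg.norm(self._row_scale * r)
            prev_step = step
        raise ConvergenceError(f"Newton stalled at t={t:.4f}")

    def _set_branches(self):
        """Freeze each valve's opening/closing law for the coming step from
        the previously accepted transvalvular pressure."""
        if self.nv:
            dpv = self.u1[self.v_up] - self.u1[self.v_dn]
            self.v_opening = dpv > 0

    def step(self):
        """Advance one time step (with halving fallback on failure)."""
        dt = self.dt
        order = 2 if self.nsteps > 0 else 1
        self._set_branches()
        pred = np.clip(2.0 * self.u1 - self.u2, None, None)
        if self.nv:
            pred[self.v_z] = np.clip(pred[self.v_z], 0.0, 1.0)
        pred[self.iA] = np.maximum(pred[self.iA], 0.05 * self.p["A0"])
        t_new = self.t + dt
        need_refresh = self._steps_since_jac >= self.cfg.jac_refresh_steps
        try:
            u = self._newton(pred, t_new, dt, order, refresh=need_refresh)
        except (ConvergenceError, FloatingPointError, RuntimeError):
            try:
                u = self._newton(self.u1.copy(), t_new, dt, order, refresh=True)
            except (ConvergenceError, FloatingPointError, RuntimeError):
                u = self._substep(dt)
        if self.nv:
            u[self.v_z] = np.clip(u[self.v_z], 0.0, 1.0)
        self.u2 = self.u1
        self.u1 = u
        self.u = u
        self.t = t_new
        self.nsteps += 1
        self._steps_since_jac += 1
        return u

    def _substep(self, dt):
        """Backward-Euler sub-stepping fallback for a troublesome step:
        try 2, 4, ... sub-steps (up to ``max_dt_halvings`` halvings)."""
        saved = (self.u1.copy(), self.u2.copy())
        last_exc = None
        for halvings in range(1, self.cfg.max_dt_halvings + 1):
            k = 2 ** halvings
            h = dt / k
            self.u1, self.u2 = saved[0].copy(), saved[1].copy()
            u = self.u1.copy()
            try:
                tt = self.t
                for _ in range(k):
                    u = self._newton(u.copy(), tt + h, h, 1, refresh=True)
                    self.u2, self.u1 = self.u1, u
                    tt += h
                self.u1, self.u2 = saved
                self._lu = None
                return u
            except (ConvergenceError, FloatingPointError, RuntimeError) as exc:
                last_exc = exc
        self.u1, self.u2 = saved
        raise ConvergenceError(
            f"step at t={self.t:.4f} failed after {self.cfg.max_dt_halvings} "
            f"halvings: {last_exc}")

    # --------------------------------------------------------------- metrics
    def total_volume(self):
        """1D + 0D + chamber blood volume (0D relative to zero pressure)."""
        v1d = float(np.sum(self.trapz_w * self.p["mult"] * self.u[self.iA]))
        v0d = float(np.sum(self.cap_C * self.u[self.cap_p])) if len(self.cap_p) else 0.0
        vch = float(np.sum(self.u[self.ch_V_idx])) if len(self.ch_V_idx) else 0.0
        return v1d + v0d + vch

    def junction_mass_defect(self):
        """Max |sum of signed junction flows| over coupling rows (should be
        at solver tolerance)."""
        lin = self.C_lin @ self.u - self.lin_rhs
        for pos, f in self.lin_funcs:
            lin[pos] = lin[pos] - f(self.t) + self.lin_rhs[pos]
        return float(np.max(np.abs(lin))) if len(lin) else 0.0

    def bed_parameter_table(self):
        """Per-bed resistances/compliances at the current state (the values of
        the final cardiac cycle once a run has converged): reference and
        pressure-scaled totals in CGS, compliances in cm^5/dyn."""
        rows = []
        from .lumped import bed_conductance_factor
        for bi, circ in enumerate(self.bed_circuits):
            fac = float(bed_conductance_factor(self.u[self.bed_pa_idx[bi]],
                                               circ.p_tm0, circ.p_zf))
            rows.append({
                "bed_id": circ.bed_id, "name": circ.name,
                "r_total_ref": circ.r_total,
                "r_total_current": circ.r_total / max(fac, 1e-12),
                "c_arteriolar": circ.c_arteriolar,
                "c_venular": circ.c_venular,
                "p_arteriolar_mmhg": float(self.u[self.bed_pa_idx[bi]]) / MMHG,
                "p_venular_mmhg": float(self.u[self.bed_pv_idx[bi]]) / MMHG,
            })
        return rows

    def set_volume_injection(self, dv_ml, t_start, duration):
        """Distribute a volume increment equally across all vascular beds as
        venular sources over [t_start, t_start+duration)."""
        nb = len(self.bed_circuits)
        if nb == 0 or duration <= 0:
            return
        self.S_rate[:] = dv_ml / nb / duration
        self.S_window = (t_start, t_start + duration)


# ---------------------------------------------------------------- cycle runs

@dataclass
class CycleRecord:
    t: np.ndarray
    P: np.ndarray        # (nprobe, nstep) mm Hg-scale? stored CGS
    Q: np.ndarray        # per-copy flow cm^3/s
    A: np.ndarray
    chamber_V: np.ndarray
    chamber_P: np.ndarray
    valve_q: np.ndarray
    valve_z: np.ndarray
    volume: np.ndarray


class CycleMonitor:
    """Per-cycle waveform buffers and the cycle-to-cycle change metric
    (max over probe pressure/flow signals of the relative L2 difference,
    in percent)."""

    def __init__(self, system: GlobalSystem):
        self.sys = system
        self.prev: CycleRecord | None = None
        self.last: CycleRecord | None = None
        self.metric_history: list[float] = []

    def run_cycle(self) -> CycleRecord:
        s = self.sys
        ns = s.steps_per_cycle
        npb = len(s.probe_nodes)
        rec = CycleRecord(
            t=np.empty(ns), P=np.empty((npb, ns)), Q=np.empty((npb, ns)),
            A=np.empty((npb, ns)),
            chamber_V=np.empty((len(s.ch_V_idx), ns)),
            chamber_P=np.empty((len(s.ch_P_idx), ns)),
            valve_q=np.empty((s.nv, ns)), valve_z=np.empty((s.nv, ns)),
            volume=np.empty(ns))
        for k in range(ns):
            s.step()
            rec.t[k] = s.t
            rec.P[:, k] = s.u[s.Nn + s.probe_nodes]
            rec.Q[:, k] = s.u[2 * s.Nn + s.probe_nodes]
            rec.A[:, k] = s.u[s.probe_nodes]
            if len(s.ch_V_idx):
                rec.chamber_V[:, k] = s.u[s.ch_V_idx]
                rec.chamber_P[:, k] = s.u[s.ch_P_idx]
            if s.nv:
                rec.valve_q[:, k] = s.u[s.v_q]
                rec.valve_z[:, k] = s.u[s.v_z]
            rec.volume[k] = s.total_volume()
        self.prev, self.last = self.last, rec
        if self.prev is not None:
            self.metric_history.append(self.metric(self.prev, self.last))
        return rec

    @staticmethod
    def heart_summary(system: GlobalSystem, rec: CycleRecord) -> dict:
        """Per-cycle heart summary: stroke volume, ejection time and peak
        chamber pressures (mm Hg)."""
        out = {}
        if not system.chambers:
            return out
        names = [v["name"] for v in system.valves]
        if "AV" in names:
            q_av = rec.valve_q[names.index("AV")]
            out["stroke_volume_ml"] = float(np.sum(q_av) * system.dt)
            z_av = rec.valve_z[names.index("AV")]
            out["ejection_time_s"] = float(np.sum(z_av > 0.1) * system.dt)
        for i, label in enumerate(CHAMBER_ORDER):
            out[f"peak_P_{label}_mmhg"] = float(np.max(rec.chamber_P[i]) / MMHG)
        return out

    @staticmethod
    def metric(a: CycleRecord, b: CycleRecord) -> float:
        out = 0.0
        n = a.P.shape[1]
        for xa, xb, floor in ((a.P, b.P, 1.0 * MMHG), (a.Q, b.Q, 0.5)):
            num = np.linalg.norm(xb - xa, axis=1)
            den = np.maximum(np.linalg.norm(xa, axis=1), floor * math.sqrt(n))
            out = max(out, float(np.max(num / den)))
        return 100.0 * out


def run_to_periodic(system: GlobalSystem, min_cycles: int = 2,
                    max_cycles: int | None = None,
                    tol_pct: float | None = None) -> tuple[CycleRecord, CycleMonitor]:
    """Advance whole cardiac cycles until consecutive cycles differ by no more
    than the periodicity threshold (default 0.5%)."""
    mon = CycleMonitor(system)
    max_cycles = max_cycles or system.cfg.max_cycles
    tol = system.cfg.periodicity_tol_pct if tol_pct is None else tol_pct
    for cyc in range(max_cycles):
        rec = mon.run_cycle()
        if cyc + 1 >= min_cycles and mon.metric_history \
                and mon.metric_history[-1] <= tol:
            return rec, mon
    raise ConvergenceError(
        f"no periodic convergence in {max_cycles} cycles "
        f"(history {['%.3f' % m for m in mon.metric_history[-5:]]})")
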