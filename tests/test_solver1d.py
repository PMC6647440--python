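"""1D discretisation physics: tube law, characteristics, steady viscous drop,
pulse transit speed, junction coupling, temporal convergence, conservation."""
import math

import numpy as np
import pytest

import uteroflow.parameters as par
from uteroflow.network import NetworkModel, VesselSegment, init_wave_speed
from uteroflow.solver1d import (TubeLawParams, VesselMesh, area_compliance,
                                characteristic_speeds, continuity_residual,
                                elastic_pressure, junction_constraints,
                                local_wave_speed, momentum_residual, tube_law,
                                tube_law_residual)
from uteroflow.system import (BoundaryCondition, GlobalSystem, SolverConfig)
from uteroflow.units import MMHG


def params(A0=0.5, c0=500.0, P0=80 * MMHG, Gamma=0.0):
    return TubeLawParams(A0=np.asarray(A0), c0=np.asarray(c0), P0=P0,
                         Gamma=np.asarray(Gamma))


class TestTubeLaw:
    def test_reference_state(self):
        p = params()
        assert tube_law(p.A0, 0.0, p) == pytest.approx(p.P0 + p.P_ext)

    def test_elastic_slope_gives_wave_speed(self):
        # dP/dA at A0 must equal rho c0^2 / A0 (local wave speed = c0)
        p = params()
        h = 1e-6 * p.A0
        slope = (elastic_pressure(p.A0 + h, p) - elastic_pressure(p.A0 - h, p)) / (2 * h)
        assert slope == pytest.approx(par.RHO * float(p.c0) ** 2 / float(p.A0),
                                      rel=1e-6)
        assert local_wave_speed(p.A0, p) == pytest.approx(float(p.c0))

    def test_compliance_is_inverse_slope(self):
        p = params()
        A = 1.07 * p.A0
        h = 1e-7 * p.A0
        slope = (elastic_pressure(A + h, p) - elastic_pressure(A - h, p)) / (2 * h)
        assert area_compliance(A, p) == pytest.approx(1.0 / slope, rel=1e-5)

    def test_voigt_term_off(self):
        p = params(Gamma=0.0)
        assert tube_law(0.9 * p.A0, 123.0, p) == elastic_pressure(0.9 * p.A0, p)

    def test_voigt_term_adds_viscous_pressure(self):
        p = params(Gamma=400.0)
        dAdt = 0.01
        extra = tube_law(p.A0, dAdt, p) - tube_law(p.A0, 0.0, p)
        assert extra == pytest.approx(400.0 / (p.A0 * math.sqrt(p.A0)) * dAdt)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            tube_law(-1.0, 0.0, params())


class TestCharacteristics:
    def test_rest_state(self):
        p = params()
        lp, lm = characteristic_speeds(0.0, p.A0, p)
        assert lp == pytest.approx(500.0)
        assert lm == pytest.approx(-500.0)

    def test_physiological_flow_ordering(self):
        p = params()
        lp, lm = characteristic_speeds(25.0, p.A0, p)  # u = 50 cm/s << c
        assert lp > 0 > lm

    def test_diastolic_forward_speed_equals_reference_wave_speed(self):
        # with u ~ 0 at reference area, the forward speed is c0 (the model's
        # pulse-wave-velocity estimate)
        p = params()
        lp, _ = characteristic_speeds(1e-9, p.A0, p)
        assert lp == pytest.approx(float(p.c0), rel=1e-6)


class TestMeshResiduals:
    def test_rest_state_residuals_vanish(self):
        mesh = VesselMesh(1, np.linspace(0, 10, 6), params())
        assert np.allclose(continuity_residual(mesh, 1e-3), 0.0)
        assert np.allclose(momentum_residual(mesh, 1e-3), 0.0)
        assert np.allclose(tube_law_residual(mesh, 1e-3), 0.0)

    def test_uniform_flow_uniform_pressure(self):
        mesh = VesselMesh(1, np.linspace(0, 10, 6), params())
        mesh.Q[:] = mesh.Q1[:] = mesh.Q2[:] = 2.0
        assert np.allclose(continuity_residual(mesh, 1e-3), 0.0)

    def test_linear_flow_ramp_balanced_by_pressure_fall(self):
        # dQ/dx = k requires C_A dP/dt = -k; set the history so the BDF2
        # derivative matches and the element residual vanishes
        p = params()
        x = np.linspace(0, 10, 6)
        mesh = VesselMesh(1, x, p)
        k = 0.3
        mesh.Q[:] = mesh.Q1[:] = mesh.Q2[:] = k * x
        dt = 1e-3
        CA = area_compliance(mesh.A, p)
        dPdt = -k / CA
        # with P1 = P2, BDF2 gives dP/dt = 1.5 (P - P1)/dt
        mesh.P1 = mesh.P - dt * dPdt / 1.5
        mesh.P2 = mesh.P1.copy()
        r = continuity_residual(mesh, dt)
        assert np.max(np.abs(r)) < 1e-10 * k

    def test_junction_constraint_residuals(self):
        ends = [(1.0e5, 2.0, 1), (1.0e5, -1.0, 2)]
        mass, dp = junction_constraints(ends)
        assert mass == pytest.approx(0.0)
        assert dp == pytest.approx(0.0)
        with pytest.raises(ValueError):
            junction_constraints([(1.0, 1.0, 1)])


# ------------------------------------------------------------- solver physics

def single_vessel_system(L, A0, c0_override=None, dx=2.0, dt=1e-3, bcs=None,
                         region="systemic_artery", mult=1):
    net = NetworkModel()
    net.segments[1] = VesselSegment(1, "v", L, A0, A0, multiplicity=mult,
                                    region=region, c0_override=c0_override)
    return GlobalSystem(net, stage="PP", dbp_mmhg=80, heart_rate_bpm=60,
                        config=SolverConfig(dx_max=dx, dt=dt),
                        boundary_conditions=bcs or {}, include_heart=False)


class TestSteadyViscousDrop:
    def test_poiseuille_like_pressure_drop(self):
        # steady Q = 1 ml/s through A = 0.1 cm^2, L = 10 cm:
        # dP = |xi| mu pi L Q / A^2 ~ 2419 dyn/cm^2 (~1.81 mm Hg)
        Q0 = 1.0
        bcs = {(1, "inlet"): BoundaryCondition("flow",
                                               func=lambda t: Q0 * min(t / 0.05, 1.0)),
               (1, "outlet"): BoundaryCondition("pressure",
                                                func=lambda t: 80 * MMHG)}
        s = single_vessel_system(10.0, 0.1, c0_override=5000.0, dx=1.0, bcs=bcs)
        for _ in range(400):
            s.step()
        dp = s.u[s.iP][0] - s.u[s.iP][s.Nn - 1]
        expected = abs(par.XI) * par.MU * math.pi * 10.0 * Q0 / 0.1 ** 2
        assert dp == pytest.approx(expected, rel=5e-3)


def foot_arrival(trace, t, frac=0.1):
    base = trace[0]
    peak = np.max(trace) - base
    idx = np.argmax(trace - base > frac * peak)
    # linear interpolation of the threshold crossing
    if idx == 0:
        return t[0]
    y0, y1 = trace[idx - 1] - base, trace[idx] - base
    thr = frac * peak
    return t[idx - 1] + (t[idx] - t[idx - 1]) * (thr - y0) / (y1 - y0)


def run_pulse(system, steps, probe_nodes):
    traces = {n: [] for n in probe_nodes}
    ts = []
    for _ in range(steps):
        system.step()
        ts.append(system.t)
        for n in probe_nodes:
            traces[n].append(system.u[system.Nn + n])
    return np.asarray(ts), {n: np.asarray(v) for n, v in traces.items()}


class TestPulsePropagation:
    def make_pulse_system(self, L=200.0, A0=0.5, dx=2.0, dt=5e-4,
                          pulse_dur=0.03, elastic=False):
        c0 = init_wave_speed(2 * math.sqrt(A0 / math.pi), "systemic_artery")
        z0 = par.RHO * c0 / A0
        def qin(t):
            return (1.0 * math.sin(math.pi * t / pulse_dur) ** 2
                    if t < pulse_dur else 0.0)
        bcs = {(1, "inlet"): BoundaryCondition("flow", func=qin),
               (1, "outlet"): BoundaryCondition("resistance", R=z0,
                                                P_out=80 * MMHG)}
        s = single_vessel_system(L, A0, dx=dx, dt=dt, bcs=bcs)
        if elastic:
            # the reference wave speed is a property of the elastic branch;
            # the Voigt wall stiffens fast transients and speeds the foot up
            s.p["Gamma"][:] = 0.0
        return s, c0

    def test_small_pulse_travels_at_reference_wave_speed(self):
        # a well-resolved 60 ms pulse (~30 nodes per wavelength) so numerical
        # dispersion is below the 2% band being checked
        s, c0 = self.make_pulse_system(dx=1.0, dt=2.5e-4, pulse_dur=0.06,
                                       elastic=True)
        n1 = int(round(50 / 1.0))
        n2 = int(round(150 / 1.0))
        t, tr = run_pulse(s, 1800, [n1, n2])
        dt_foot = foot_arrival(tr[n2], t) - foot_arrival(tr[n1], t)
        speed = 100.0 / dt_foot
        assert speed == pytest.approx(c0, rel=0.02)

    def test_viscoelastic_damping_reduces_amplitude(self):
        s, _ = self.make_pulse_system()
        n1, n2 = 25, 75
        _, tr = run_pulse(s, 900, [n1, n2])
        a1 = tr[n1].max() - tr[n1][0]
        a2 = tr[n2].max() - tr[n2][0]
        assert a2 <= a1


class TestJunctions:
    def _two_segment_system(self, dt=5e-4):
        net = NetworkModel()
        net.segments[1] = VesselSegment(1, "a", 100.0, 0.5, 0.5)
        net.segments[2] = VesselSegment(2, "b", 100.0, 0.5, 0.5, parent_ids=(1,))
        c0 = init_wave_speed(2 * math.sqrt(0.5 / math.pi), "systemic_artery")
        z0 = par.RHO * c0 / 0.5
        def qin(t):
            return 1.0 * math.sin(math.pi * t / 0.03) ** 2 if t < 0.03 else 0.0
        bcs = {(1, "inlet"): BoundaryCondition("flow", func=qin),
               (2, "outlet"): BoundaryCondition("resistance", R=z0,
                                                P_out=80 * MMHG)}
        return GlobalSystem(net, stage="PP", dbp_mmhg=80, heart_rate_bpm=60,
                            config=SolverConfig(dx_max=2.0, dt=dt),
                            boundary_conditions=bcs, include_heart=False)

    def test_series_junction_transparent(self):
        # two identical vessels in series behave as one vessel of doubled
        # length: compare pulse arrival at the 3/4 point
        sj = self._two_segment_system()
        # probe 150 cm: 50 cm into segment 2
        node = next(sl.start for (sid, a, b), sl in zip(sj.pieces, sj.piece_slices)
                    if sid == 2) + 25
        t1, tr1 = run_pulse(sj, 900, [node])

        s1, c0 = TestPulsePropagation().make_pulse_system(L=200.0, dx=2.0, dt=5e-4)
        node1 = 75
        t2, tr2 = run_pulse(s1, 900, [node1])
        ta = foot_arrival(tr1[node], t1)
        tb = foot_arrival(tr2[node1], t2)
        assert ta == pytest.approx(tb, rel=0.01)

    def test_symmetric_bifurcation_splits_equally(self):
        net = NetworkModel()
        net.segments[1] = VesselSegment(1, "p", 50.0, 0.5, 0.5)
        for k in (2, 3):
            net.segments[k] = VesselSegment(k, f"c{k}", 50.0, 0.3, 0.3,
                                            parent_ids=(1,))
        def qin(t):
            return 1.0 * math.sin(math.pi * t / 0.03) ** 2 if t < 0.03 else 0.0
        bcs = {(1, "inlet"): BoundaryCondition("flow", func=qin)}
        for k in (2, 3):
            bcs[(k, "outlet")] = BoundaryCondition("resistance", R=2000.0,
                                                   P_out=80 * MMHG)
        s = GlobalSystem(net, stage="PP", dbp_mmhg=80, heart_rate_bpm=60,
                         config=SolverConfig(dx_max=2.0, dt=5e-4),
                         boundary_conditions=bcs, include_heart=False)
        in2 = next(sl.start for (sid, _, _), sl in zip(s.pieces, s.piece_slices)
                   if sid == 2)
        in3 = next(sl.start for (sid, _, _), sl in zip(s.pieces, s.piece_slices)
                   if sid == 3)
        worst = 0.0
        for _ in range(200):
            s.step()
            q2, q3 = s.u[2 * s.Nn + in2], s.u[2 * s.Nn + in3]
            worst = max(worst, abs(q2 - q3))
        assert worst < 1e-10

    def test_junction_mass_defect_at_machine_level(self):
        s = self._two_segment_system()
        worst = 0.0
        meanq = []
        for _ in range(300):
            s.step()
            worst = max(worst, s.junction_mass_defect())
            meanq.append(np.mean(np.abs(s.u[s.iQ])))
        assert worst < 1e-9 * max(np.mean(meanq), 1e-3)


class TestConservationAndConvergence:
    def closed_sloshing_system(self, dt):
        s = single_vessel_system(50.0, 0.5, dx=2.0, dt=dt)
        # smooth initial pressure bump, area consistent with the elastic law
        x = np.linspace(0, 1, s.Nn)
        dp = 1.0 * MMHG * np.exp(-((x - 0.5) / 0.15) ** 2)
        P = s.p["P0"] + dp
        A = s.p["A0"] * (1 + dp * s.p["b"] / (2 * par.RHO * s.p["c0sq"])) ** (2 / s.p["b"])
        for u in (s.u, s.u1, s.u2):
            u[s.iP] = P
            u[s.iA] = A
        return s

    def test_closed_vessel_conserves_volume(self):
        s = self.closed_sloshing_system(1e-3)
        v0 = s.total_volume()
        for _ in range(500):
            s.step()
        assert abs(s.total_volume() - v0) / v0 < 1e-8

    def test_bdf2_second_order_self_convergence(self):
        # probe pressure at fixed final time for dt, dt/2, dt/4
        vals = []
        for dt in (2e-3, 1e-3, 5e-4):
            s = self.closed_sloshing_system(dt)
            while s.t < 0.1 - 1e-12:
                s.step()
            vals.append(s.u[s.Nn + s.Nn // 3])
        e1 = abs(vals[0] - vals[1])
        e2 = abs(vals[1] - vals[2])
        order = math.log2(e1 / e2)
        assert 1.6 < order < 2.6
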