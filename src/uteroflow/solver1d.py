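"""1D vessel discretisation: visco-elastic tube law, continuity and momentum
residuals, characteristic speeds.

Each vessel segment is collocated at mesh nodes; spatial derivatives use
second-order central differences in the interior and one-sided second-order
stencils at the ends (for two-node meshes, first order).  Time derivatives are
BDF2 with a backward-Euler bootstrap; the same difference operators serve the
0D and heart equations so the whole system shares one time level structure.

A vessel group with multiplicity m is meshed once: A, P and Q are per-copy
quantities, so these residuals are multiplicity-free; the multiplicity enters
only in junction/bed mass balances and volume audits.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import parameters as par


def bdf_coeffs(order: int):
    """(a0, a1, a2) with du/dt ~= (a0 u - a1 u_prev + a2 u_prev2)/dt."""
    if order == 1:
        return 1.0, 1.0, 0.0
    return 1.5, 2.0, 0.5


@dataclass
class TubeLawParams:
    """Per-node constitutive parameters of one vessel (arrays or scalars)."""

    A0: np.ndarray          # cm^2
    c0: np.ndarray          # cm/s
    P0: float               # dyn/cm^2
    P_ext: float = 0.0      # dyn/cm^2
    P_collapse: float = -119.0 * 1333.22
    Gamma: np.ndarray = 0.0  # g/s
    rho: float = par.RHO
    mu: float = par.MU
    xi: float = par.XI

    @property
    def b(self):
        """Stiffening exponent b = 2 rho c0^2 / (P0 - P_collapse)."""
        b = 2.0 * self.rho * np.asarray(self.c0) ** 2 / (self.P0 - self.P_collapse)
        if np.any(b <= 0):
            raise ValueError("tube law requires P0 > P_collapse")
        return b


def elastic_pressure(A, p: TubeLawParams):
    """Elastic branch of the tube law (no Voigt term)."""
    A = np.asarray(A)
    if np.any(A <= 0):
        raise ValueError("non-positive area")
    b = p.b
    return p.P0 + p.P_ext + (2.0 * p.rho * np.asarray(p.c0) ** 2 / b) * (
        (A / p.A0) ** (b / 2.0) - 1.0)


def tube_law(A, dA_dt, p: TubeLawParams):
    """Visco-elastic tube law: elastic power law plus Voigt term
    Gamma/(A0 sqrt(A)) dA/dt."""
    A = np.asarray(A)
    return elastic_pressure(A, p) + np.asarray(p.Gamma) / (p.A0 * np.sqrt(A)) * dA_dt


def area_compliance(A, p: TubeLawParams):
    """dA/dP of the elastic branch, evaluated at A."""
    A = np.asarray(A)
    b = p.b
    return p.A0 / (p.rho * np.asarray(p.c0) ** 2) * (A / p.A0) ** (1.0 - b / 2.0)


def local_wave_speed(A, p: TubeLawParams):
    """c(A) = sqrt(A / (rho dA/dP)) = c0 (A/A0)^(b/4)."""
    A = np.asarray(A)
    return np.asarray(p.c0) * (A / p.A0) ** (p.b / 4.0)


def characteristic_speeds(Q, A, p: TubeLawParams):
    """Propagation speeds (lambda+, lambda-) = u +/- c with u = Q/A."""
    A = np.asarray(A)
    if np.any(A <= 0):
        raise ValueError("non-positive area")
    u = np.asarray(Q) / A
    c = local_wave_speed(A, p)
    return u + c, u - c


def derivative_matrix(x: np.ndarray) -> sp.csr_matrix:
    """Sparse d/dx operator on a (possibly non-uniform) 1D mesh: central
    second-order in the interior, one-sided second-order at the ends."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("mesh needs at least 2 nodes")
    rows, cols, vals = [], [], []
    if n == 2:
        h = x[1] - x[0]
        rows += [0, 0, 1, 1]
        cols += [0, 1, 0, 1]
        vals += [-1 / h, 1 / h, -1 / h, 1 / h]
    else:
        for i in range(1, n - 1):
            hm, hp = x[i] - x[i - 1], x[i + 1] - x[i]
            rows += [i, i, i]
            cols += [i - 1, i, i + 1]
            vals += [-hp / (hm * (hm + hp)),
                     (hp - hm) / (hm * hp),
                     hm / (hp * (hm + hp))]
        h0, h1 = x[1] - x[0], x[2] - x[1]
        rows += [0, 0, 0]
        cols += [0, 1, 2]
        vals += [-(2 * h0 + h1) / (h0 * (h0 + h1)),
                 (h0 + h1) / (h0 * h1),
                 -h0 / (h1 * (h0 + h1))]
        hm1, hm0 = x[-2] - x[-3], x[-1] - x[-2]
        rows += [n - 1, n - 1, n - 1]
        cols += [n - 3, n - 2, n - 1]
        vals += [hm0 / (hm1 * (hm0 + hm1)),
                 -(hm0 + hm1) / (hm1 * hm0),
                 (2 * hm0 + hm1) / (hm0 * (hm0 + hm1))]
    return sp.csr_matrix((vals, (rows, cols)), shape=(n, n))


def element_operators(x: np.ndarray):
    """Element (box-scheme) operators on a mesh: for each 2-node element,
    W integrates nodal values with trapezoid weights (h/2, h/2), D takes the
    nodal difference, and M averages the nodes.  Integrating continuity and
    momentum over elements instead of collocating at nodes keeps adjacent
    nodes coupled (no odd-even decoupling) and telescopes to exact discrete
    mass conservation."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("mesh needs at least 2 nodes")
    h = np.diff(x)
    ne = n - 1
    i = np.arange(ne)
    rows = np.repeat(i, 2)
    cols = np.ravel(np.column_stack([i, i + 1]))
    W = sp.csr_matrix((np.repeat(h / 2.0, 2), (rows, cols)), shape=(ne, n))
    D = sp.csr_matrix((np.ravel(np.column_stack([-np.ones(ne), np.ones(ne)])),
                       (rows, cols)), shape=(ne, n))
    M = sp.csr_matrix((np.full(2 * ne, 0.5), (rows, cols)), shape=(ne, n))
    return W, D, M


def trapz_weights(x: np.ndarray) -> np.ndarray:
    """Composite trapezoidal quadrature weights along the mesh."""
    x = np.asarray(x, dtype=float)
    w = np.zeros_like(x)
    w[:-1] += 0.5 * np.diff(x)
    w[1:] += 0.5 * np.diff(x)
    return w


@dataclass
class VesselMesh:
    """Meshed vessel with two history levels for BDF2 (mainly for unit tests;
    the closed-loop solver stores the same data in one flat vector)."""

    segment_id: int
    x: np.ndarray
    params: TubeLawParams
    A: np.ndarray = None
    P: np.ndarray = None
    Q: np.ndarray = None
    A1: np.ndarray = None
    A2: np.ndarray = None
    P1: np.ndarray = None
    P2: np.ndarray = None
    Q1: np.ndarray = None
    Q2: np.ndarray = None
    W: sp.csr_matrix = None
    D: sp.csr_matrix = None
    M: sp.csr_matrix = None

    def __post_init__(self):
        n = len(self.x)
        if n < 2:
            raise ValueError("mesh needs at least 2 nodes")
        self.W, self.D, self.M = element_operators(self.x)
        A0 = np.broadcast_to(np.asarray(self.params.A0, dtype=float), (n,)).copy()
        if self.A is None:
            self.A = A0.copy()
        if self.P is None:
            self.P = np.full(n, self.params.P0 + self.params.P_ext)
        if self.Q is None:
            self.Q = np.zeros(n)
        for h in ("A1", "A2", "P1", "P2", "Q1", "Q2"):
            if getattr(self, h) is None:
                setattr(self, h, getattr(self, h[0]).copy())


def continuity_residual(mesh: VesselMesh, dt: float, order: int = 2):
    """Element-integrated continuity: int(C_A dP/dt) + [Q] over each element
    (the compliance dA/dP from the elastic branch at the current state; along
    the elastic branch this equals int(dA/dt) + [Q])."""
    a0, a1, a2 = bdf_coeffs(order)
    dPdt = (a0 * mesh.P - a1 * mesh.P1 + a2 * mesh.P2) / dt
    CA = area_compliance(mesh.A, mesh.params)
    return mesh.W @ (CA * dPdt) + mesh.D @ mesh.Q


def momentum_residual(mesh: VesselMesh, dt: float, order: int = 2):
    """Element-integrated momentum: int(rho/A dQ/dt + |xi| mu pi Q/A^2)
    + (rho/A_mean) [Q^2/A] + [P] over each element.

    The viscous-friction coefficient xi is negative (-22 for the nearly flat
    profile); the friction force opposes the flow, so the steady balance gives
    a pressure DROP |xi| mu pi L Q / A^2 along the flow direction.
    """
    p = mesh.params
    a0, a1, a2 = bdf_coeffs(order)
    dQdt = (a0 * mesh.Q - a1 * mesh.Q1 + a2 * mesh.Q2) / dt
    Abar = mesh.M @ mesh.A
    return mesh.W @ (p.rho / mesh.A * dQdt
                     - p.xi * p.mu * math.pi * mesh.Q / mesh.A ** 2) \
        + (p.rho / Abar) * (mesh.D @ (mesh.Q ** 2 / mesh.A)) \
        + mesh.D @ mesh.P


def tube_law_residual(mesh: VesselMesh, dt: float, order: int = 2):
    """P - tube_law(A, dA/dt) at every node."""
    a0, a1, a2 = bdf_coeffs(order)
    dAdt = (a0 * mesh.A - a1 * mesh.A1 + a2 * mesh.A2) / dt
    return mesh.P - tube_law(mesh.A, dAdt, mesh.params)


def junction_constraints(ends):
    """Constraint residuals for vessel ends meeting at a junction.

    ``ends`` is a sequence of (P, Q_signed_in, multiplicity).  Returns the mass
    residual sum(m Q) followed by the pressure-continuity residuals P_i - P_0.
    In the assembled system these residuals replace the boundary continuity
    equations (an exact elimination of the Lagrange multipliers that would
    otherwise enforce them).
    """
    if len(ends) < 2:
        raise ValueError("junction needs at least two attachments")
    mass = sum(m * q for (_, q, m) in ends)
    p0 = ends[0][0]
    return [mass] + [p - p0 for (p, _, _) in ends[1:]]
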