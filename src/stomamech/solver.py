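"""Quasi-static nonlinear FE solution of the pressurized guard-cell pair.

Formulation: constant-strain triangle membranes with the incompressible
plane-stress reduction of the wall material (the thickness stretch is
eliminated by lambda3 = 1/(lambda1 lambda2), which is the correct membrane
limit of an incompressible solid).  Guard-cell turgor is applied as the
exact follower load derived from the enclosed-volume potential -P V(x) of
each closed cell surface; epidermal back-pressure is a follower facet load
on the dorsal walls (configurable).  The consistent tangent
(including follower-load stiffness) is assembled from central finite
differences of the analytic element residuals, element by element, which is
exact to O(h^2) and keeps the kernel free of fourth-order tensor algebra.

Newton-Raphson with backtracking line search, Levenberg regularization on
stalled iterations, and adaptive substepping on non-convergence.  Weak
grounding springs (k_reg, orders of magnitude below the wall stiffness)
remove rigid-body modes; the two ventral walls are kept from crossing the
pore midplane by a quadratic penalty.

Units: um, MPa, forces in uN (MPa * um^2), energies in pJ (MPa * um^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import SurfaceMesh, PATCH_ID
from .material import MaterialParams, fiber_energy, fiber_stress_scale

__all__ = [
    "LoadProtocol",
    "BCVariant",
    "EquilibriumState",
    "solve_quasistatic",
    "apply_fixed_poles",
    "inflate_sphere_benchmark",
    "MembraneSystem",
    "NonConvergenceError",
]

GEOMETRY_VARIANTS = ("circular", "VWT", "VWT+10", "VWT-10")


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, last_pressure=None, residual_history=None):
        super().__init__(msg)
        self.last_pressure = last_pressure
        self.residual_history = residual_history or []


@dataclass(frozen=True)
class LoadProtocol:
    """Staged pressurization: epidermal and guard-cell turgor co-ramp until
    the epidermal cap, then guard-cell turgor alone rises to its maximum."""

    p_epi_max: float = 0.5   # MPa
    p_gc_max: float = 6.0    # MPa
    n_steps: int = 60

    def __post_init__(self):
        if not (0.0 <= self.p_epi_max < self.p_gc_max):
            raise ValueError("need 0 <= p_epi_max < p_gc_max")
        if self.n_steps < 10:
            raise ValueError("need at least 10 load steps")

    @property
    def co_ramp_fraction(self) -> float:
        return self.p_epi_max / self.p_gc_max

    def steps(self):
        """(P_gc, P_epi) pairs, P_gc uniform from one increment to max."""
        pg = np.linspace(0.0, self.p_gc_max, self.n_steps + 1)[1:]
        pe = np.minimum(pg, self.p_epi_max)
        return list(zip(pg, pe))


@dataclass(frozen=True)
class BCVariant:
    kind: str = "baseline"          # or "fixed_poles"
    geometry: str = "circular"      # circular | VWT | VWT+10 | VWT-10

    def __post_init__(self):
        if self.kind not in ("baseline", "fixed_poles"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.geometry not in GEOMETRY_VARIANTS:
            raise ValueError(f"unknown geometry {self.geometry!r}")


@dataclass
class EquilibriumState:
    """Converged solution at one load step."""

    u: np.ndarray                 # (N, 3) nodal displacements, um
    green_strain: np.ndarray      # (M, 3, 3) Green-Lagrange tensors
    cauchy: np.ndarray            # (M, 3, 3) Cauchy stress tensors, MPa
    p_gc: float                   # MPa
    p_epi: float                  # MPa
    residual_norm: float          # nN
    strain_energy: float          # pJ
    cell_volumes: tuple           # (V0, V1) um^3
    converged: bool = True


# ---------------------------------------------------------------------------


class MembraneSystem:
    """Assembled membrane problem on a triangulated surface.

    ``closed_surfaces``: list of (element rows, orientation array) whose
    enclosed volumes receive the turgor pressure.  ``epi_rows``: facet rows
    loaded by external (epidermal) pressure.  ``fixed_dofs``: global dof
    indices pinned to zero displacement.  ``contact``: (node indices, side
    sign) pairs for the ventral midplane no-penetration penalty.
    """

    def __init__(self, nodes, elements, thickness, fiber, material: MaterialParams,
                 closed_surfaces, epi_rows=None, fixed_dofs=None,
                 contact=None, k_reg=None, k_contact=None, bend_scale=1.0):
        self.X = np.asarray(nodes, float)
        self.elements = np.asarray(elements, np.int64)
        self.t = np.asarray(thickness, float)
        self.mat = material
        self.closed_surfaces = closed_surfaces
        self.epi_rows = (np.asarray(epi_rows, np.int64)
                         if epi_rows is not None and len(epi_rows)
                         else np.empty(0, np.int64))
        self.n_dof = 3 * len(self.X)
        self.fixed = (np.asarray(fixed_dofs, np.int64)
                      if fixed_dofs is not None else np.empty(0, np.int64))
        free = np.ones(self.n_dof, bool)
        free[self.fixed] = False
        self.free = np.where(free)[0]
        self.contact = contact or []
        scale = self.mat.c1 * float(np.median(self.t))
        self.k_reg = 1e-6 * scale if k_reg is None else k_reg
        self.k_contact = 100.0 * scale if k_contact is None else k_contact
        self._precompute(np.asarray(fiber, float))
        self._fd_h = 1e-5 * max(1.0, float(np.abs(self.X).max()))
        self.bend_scale = bend_scale
        self._build_bending()

    # -- reference quantities ---------------------------------------------
    def _precompute(self, fiber):
        xe = self.X[self.elements]
        e1 = xe[:, 1] - xe[:, 0]
        e2 = xe[:, 2] - xe[:, 0]
        n = np.cross(e1, e2)
        a2 = np.linalg.norm(n, axis=1)
        if np.any(a2 <= 1e-14):
            raise ValueError("degenerate reference element")
        self.area = 0.5 * a2
        N = n / a2[:, None]
        E1 = e1 / np.linalg.norm(e1, axis=1)[:, None]
        E2 = np.cross(N, E1)
        self.frame = np.stack([E1, E2, N], axis=2)   # (M, 3, 3) columns
        Dm = np.empty((len(xe), 2, 2))
        Dm[:, 0, 0] = np.einsum("ij,ij->i", e1, E1)
        Dm[:, 1, 0] = np.einsum("ij,ij->i", e1, E2)
        Dm[:, 0, 1] = np.einsum("ij,ij->i", e2, E1)
        Dm[:, 1, 1] = np.einsum("ij,ij->i", e2, E2)
        det = Dm[:, 0, 0] * Dm[:, 1, 1] - Dm[:, 0, 1] * Dm[:, 1, 0]
        self.Dm_inv = np.empty_like(Dm)
        self.Dm_inv[:, 0, 0] = Dm[:, 1, 1] / det
        self.Dm_inv[:, 1, 1] = Dm[:, 0, 0] / det
        self.Dm_inv[:, 0, 1] = -Dm[:, 0, 1] / det
        self.Dm_inv[:, 1, 0] = -Dm[:, 1, 0] / det
        av = np.einsum("ij,ij->i", fiber, E1)
        bv = np.einsum("ij,ij->i", fiber, E2)
        nrm = np.hypot(av, bv)
        nrm = np.where(nrm > 0, nrm, 1.0)
        self.a0 = np.stack([av / nrm, bv / nrm], axis=1)
        self.has_fiber = (self.mat.c3 > 0.0 or self.mat.c5 > 0.0)

    # -- bending (discrete-shell hinges) ------------------------------------
    def _build_bending(self):
        """Hinge bending on interior edges shared by exactly two facets.

        Flexural rigidity from the linearized wall matrix modulus
        (E = 3 C1 C2, incompressible): D = E t^3 / (12 (1 - nu^2)) with
        nu = 1/2.  The undeformed dihedral angles are stress-free.  Edges at
        wall junctions (shared by more than two facets, e.g. the polar rims)
        carry no bending and act as hinges.
        """
        elems = self.elements
        edge_map = {}
        for f, tri in enumerate(elems):
            for k in range(3):
                i, j = int(tri[k]), int(tri[(k + 1) % 3])
                opp = int(tri[(k + 2) % 3])
                edge_map.setdefault((min(i, j), max(i, j)), []).append(
                    (i, j, opp, f))
        quads, faces = [], []
        for (_, _), lst in edge_map.items():
            if len(lst) != 2:
                continue
            (i0, j0, o0, f0), (_, _, o1, f1) = lst
            quads.append((i0, j0, o0, o1))
            faces.append((f0, f1))
        if not quads:
            self.bend_quads = np.empty((0, 4), np.int64)
            self.bend_k = np.empty(0)
            self.theta0 = np.empty(0)
            return
        self.bend_quads = np.asarray(quads, np.int64)
        faces = np.asarray(faces, np.int64)
        t_e = 0.5 * (self.t[faces[:, 0]] + self.t[faces[:, 1]])
        E_eff = 3.0 * self.mat.c1 * self.mat.c2
        D = self.bend_scale * E_eff * t_e ** 3 / 9.0     # 12 (1 - 1/4) = 9
        L = np.linalg.norm(self.X[self.bend_quads[:, 1]]
                           - self.X[self.bend_quads[:, 0]], axis=1)
        A2 = self.area[faces[:, 0]] + self.area[faces[:, 1]]
        self.bend_k = 1.5 * D * L ** 2 / A2      # E_e = bend_k (theta-theta0)^2
        self.theta0 = self._dihedral(self.X[self.bend_quads])

    @staticmethod
    def _dihedral(q):
        """Dihedral angle per hinge; q is (E, 4, 3): edge (0,1), wings 2, 3."""
        e = q[:, 1] - q[:, 0]
        n1 = np.cross(e, q[:, 2] - q[:, 0])
        n2 = np.cross(q[:, 3] - q[:, 0], e)
        ehat = e / np.linalg.norm(e, axis=1)[:, None]
        n1h = n1 / np.linalg.norm(n1, axis=1)[:, None]
        n2h = n2 / np.linalg.norm(n2, axis=1)[:, None]
        s = np.einsum("ij,ij->i", np.cross(n1h, n2h), ehat)
        c = np.einsum("ij,ij->i", n1h, n2h)
        return np.arctan2(s, c)

    def _bending_energy(self, x) -> float:
        if not len(self.bend_quads):
            return 0.0
        th = self._dihedral(x[self.bend_quads])
        return float(np.sum(self.bend_k * (th - self.theta0) ** 2))

    def _bending_grad_blocks(self, x):
        """(theta grad per hinge (E,4,3), theta-theta0) by central FD."""
        if not len(self.bend_quads):
            return None, None
        q = x[self.bend_quads]
        th = self._dihedral(q)
        g = np.empty_like(q)
        h = self._fd_h
        for a in range(4):
            for i in range(3):
                dq = np.zeros_like(q)
                dq[:, a, i] = h
                g[:, a, i] = (self._dihedral(q + dq)
                              - self._dihedral(q - dq)) / (2.0 * h)
        return g, th - self.theta0

    # -- membrane kinematics and energetics --------------------------------
    def _surface_C(self, xe):
        d = np.stack([xe[:, 1] - xe[:, 0], xe[:, 2] - xe[:, 0]], axis=2)
        F = d @ self.Dm_inv                       # (M, 3, 2)
        a = np.einsum("ij,ij->i", F[:, :, 0], F[:, :, 0])
        b = np.einsum("ij,ij->i", F[:, :, 1], F[:, :, 1])
        c = np.einsum("ij,ij->i", F[:, :, 0], F[:, :, 1])
        return F, a, b, c

    def _energy_density(self, a, b, c):
        """W per unit reference volume and its partials wrt (C11, C22, C12)."""
        p = self.mat
        D = a * b - c * c
        if np.any(D <= 0.0):
            bad = int(np.argmax(D <= 0.0))
            raise NonConvergenceError(f"inverted element {bad}")
        L = 1.0 / D
        I1 = a + b + L
        T = a * a + b * b + 2.0 * c * c + L * L
        I2 = 0.5 * (I1 * I1 - T)
        ew = np.exp(p.c2 * (I1 - 3.0))
        W = p.c1 * (ew - 1.0) - 0.5 * p.c1 * p.c2 * (I2 - 3.0)
        W1 = p.c1 * p.c2 * ew
        W2 = -0.5 * p.c1 * p.c2
        iD2 = 1.0 / (D * D)
        dLa, dLb, dLc = -b * iD2, -a * iD2, 2.0 * c * iD2
        dI1a, dI1b, dI1c = 1.0 + dLa, 1.0 + dLb, dLc
        dTa = 2.0 * a + 2.0 * L * dLa
        dTb = 2.0 * b + 2.0 * L * dLb
        dTc = 4.0 * c + 2.0 * L * dLc
        dI2a = I1 * dI1a - 0.5 * dTa
        dI2b = I1 * dI1b - 0.5 * dTb
        dI2c = I1 * dI1c - 0.5 * dTc
        Wa = W1 * dI1a + W2 * dI2a
        Wb = W1 * dI1b + W2 * dI2b
        Wc = W1 * dI1c + W2 * dI2c
        if self.has_fiber:
            av, bv = self.a0[:, 0], self.a0[:, 1]
            I4 = av * av * a + bv * bv * b + 2.0 * av * bv * c
            lam = np.sqrt(np.maximum(I4, 1e-12))
            W = W + fiber_energy(lam, p)
            W4 = fiber_stress_scale(lam, p) / (2.0 * I4)
            Wa = Wa + W4 * av * av
            Wb = Wb + W4 * bv * bv
            Wc = Wc + 2.0 * W4 * av * bv
        return W, Wa, Wb, Wc

    def _strain_grad(self, xe):
        """Per-element strain energy and nodal gradient (M, 3, 3)."""
        F, a, b, c = self._surface_C(xe)
        W, Wa, Wb, Wc = self._energy_density(a, b, c)
        vol = self.area * self.t
        # dW/dF = F @ [[2Wa, Wc], [Wc, 2Wb]]
        S = np.empty((len(a), 2, 2))
        S[:, 0, 0] = 2.0 * Wa
        S[:, 1, 1] = 2.0 * Wb
        S[:, 0, 1] = S[:, 1, 0] = Wc
        dWdF = F @ S
        G = vol[:, None, None] * (dWdF @ np.swapaxes(self.Dm_inv, 1, 2))
        g = np.empty_like(xe)
        g[:, 1] = G[:, :, 0]
        g[:, 2] = G[:, :, 1]
        g[:, 0] = -G[:, :, 0] - G[:, :, 1]
        return vol * W, g

    def strain_energy(self, x) -> float:
        """Stored elastic energy (membrane + bending), pJ."""
        _, a, b, c = self._surface_C(x[self.elements])
        W, _, _, _ = self._energy_density(a, b, c)
        return float(np.sum(self.area * self.t * W)) + self._bending_energy(x)

    # -- loads --------------------------------------------------------------
    def enclosed_volumes(self, x):
        out = []
        for rows, orient in self.closed_surfaces:
            tri = x[self.elements[rows]]
            v6 = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))
            out.append(float(np.sum(orient * v6) / 6.0))
        return out

    def _volume_grad_tris(self, rows, orient, x):
        """Per-triangle nodal gradient of the enclosed volume."""
        tri = x[self.elements[rows]]
        g = np.empty_like(tri)
        g[:, 0] = np.cross(tri[:, 1], tri[:, 2])
        g[:, 1] = np.cross(tri[:, 2], tri[:, 0])
        g[:, 2] = np.cross(tri[:, 0], tri[:, 1])
        return g * (orient[:, None, None] / 6.0)

    def _epi_grad_tris(self, x):
        """Per-facet residual contribution of external pressure (per unit P)."""
        tri = x[self.elements[self.epi_rows]]
        nA = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        g = np.repeat(nA[:, None, :] / 3.0, 3, axis=1)
        return g   # residual += P_epi * g  (force is inward: -P n A / 3)

    # -- residual and tangent ----------------------------------------------
    def _scatter(self, rows, g, out):
        np.add.at(out, self.elements[rows].ravel(),
                  g.reshape(-1, 3))

    def residual(self, x, p_gc, p_epi):
        R = np.zeros_like(x)
        _, g = self._strain_grad(x[self.elements])
        self._scatter(np.arange(len(self.elements)), g, R)
        if p_gc != 0.0:
            for rows, orient in self.closed_surfaces:
                gv = self._volume_grad_tris(rows, orient, x)
                self._scatter(rows, -p_gc * gv, R)
        if p_epi != 0.0 and len(self.epi_rows):
            self._scatter(self.epi_rows, p_epi * self._epi_grad_tris(x), R)
        if len(self.bend_quads):
            gth, dth = self._bending_grad_blocks(x)
            gb = (2.0 * self.bend_k * dth)[:, None, None] * gth
            np.add.at(R, self.bend_quads.ravel(), gb.reshape(-1, 3))
        R += self.k_reg * (x - self.X)
        for nodes_c, side in self.contact:
            gpen = side * x[nodes_c, 1]
            active = gpen < 0.0
            R[nodes_c[active], 1] += self.k_contact * gpen[active] * side
        return R

    def _fd_element_K(self, grad_fn, xe):
        M = xe.shape[0]
        K = np.empty((M, 9, 9))
        h = self._fd_h
        for a in range(3):
            for i in range(3):
                dx = np.zeros_like(xe)
                dx[:, a, i] = h
                gp = grad_fn(xe + dx)
                gm = grad_fn(xe - dx)
                K[:, :, 3 * a + i] = ((gp - gm) / (2.0 * h)).reshape(M, 9)
        return K

    def tangent(self, x, p_gc, p_epi):
        blocks = []   # (rows, K) pairs
        all_rows = np.arange(len(self.elements))
        blocks.append((all_rows, self._fd_element_K(
            lambda xe: self._strain_grad(xe)[1], x[self.elements])))
        if p_gc != 0.0:
            for rows, orient in self.closed_surfaces:
                xe = x[self.elements[rows]]

                def vg(xe_, rows=rows, orient=orient):
                    g = np.empty_like(xe_)
                    g[:, 0] = np.cross(xe_[:, 1], xe_[:, 2])
                    g[:, 1] = np.cross(xe_[:, 2], xe_[:, 0])
                    g[:, 2] = np.cross(xe_[:, 0], xe_[:, 1])
                    return g * (orient[:, None, None] * (-p_gc / 6.0))

                blocks.append((rows, self._fd_element_K(vg, xe)))
        if p_epi != 0.0 and len(self.epi_rows):
            xe = x[self.elements[self.epi_rows]]

            def eg(xe_):
                nA = 0.5 * np.cross(xe_[:, 1] - xe_[:, 0], xe_[:, 2] - xe_[:, 0])
                return np.repeat(nA[:, None, :] * (p_epi / 3.0), 3, axis=1)

            blocks.append((self.epi_rows, self._fd_element_K(eg, xe)))

        data, ri, ci = [], [], []
        for rows, K in blocks:
            dofs = (3 * self.elements[rows][:, :, None]
                    + np.arange(3)[None, None, :]).reshape(-1, 9)
            ri.append(np.repeat(dofs, 9, axis=1).ravel())
            ci.append(np.tile(dofs, (1, 9)).ravel())
            data.append(K.ravel())
        if len(self.bend_quads):
            # Gauss-Newton hinge stiffness: 2 k grad(theta) grad(theta)^T
            gth, _ = self._bending_grad_blocks(x)
            g12 = gth.reshape(-1, 12)
            Kb = 2.0 * self.bend_k[:, None, None] * np.einsum(
                "ei,ej->eij", g12, g12)
            dofs = (3 * self.bend_quads[:, :, None]
                    + np.arange(3)[None, None, :]).reshape(-1, 12)
            ri.append(np.repeat(dofs, 12, axis=1).ravel())
            ci.append(np.tile(dofs, (1, 12)).ravel())
            data.append(Kb.ravel())
        # grounding springs and contact penalty (diagonal)
        diag = np.full(self.n_dof, self.k_reg)
        for nodes_c, side in self.contact:
            active = side * x[nodes_c, 1] < 0.0
            diag[3 * nodes_c[active] + 1] += self.k_contact
        ri.append(np.arange(self.n_dof))
        ci.append(np.arange(self.n_dof))
        data.append(diag)
        K = sp.coo_matrix((np.concatenate(data),
                           (np.concatenate(ri), np.concatenate(ci))),
                          shape=(self.n_dof, self.n_dof)).tocsr()
        return K

    def external_force_ref(self, x, p_gc, p_epi):
        """Norm of the pressure force vector, for relative convergence."""
        R = np.zeros_like(x)
        if p_gc != 0.0:
            for rows, orient in self.closed_surfaces:
                self._scatter(rows, p_gc * self._volume_grad_tris(rows, orient, x), R)
        if p_epi != 0.0 and len(self.epi_rows):
            self._scatter(self.epi_rows, p_epi * self._epi_grad_tris(x), R)
        return float(np.linalg.norm(R))

    # -- Newton solve -------------------------------------------------------
    def solve_step(self, x0, p_gc, p_epi, tol_rel=1e-6, tol_abs=1e-9,
                   max_iter=80):
        """Levenberg-regularized Newton with backtracking line search.

        The tangent can be indefinite near wrinkling/bulging states (soft
        bending modes destabilized by follower pressure); the adaptive
        diagonal shift mu keeps the step well-posed and is driven back to
        zero as iterations succeed, so converged solutions satisfy the
        unmodified equilibrium equations to tol.
        """
        x = x0.copy()
        f = self.free
        hist = []
        ref = max(self.external_force_ref(x, p_gc, p_epi), 1e-6)
        mu = self._mu_carry if hasattr(self, "_mu_carry") else 0.0
        mu_min = 1e-5 * self.mat.c1
        step_cap = 0.05 * max(1.0, float(np.abs(self.X).max()))
        it = 0
        while it < max_iter:
            it += 1
            R = self.residual(x, p_gc, p_epi)
            rn = np.linalg.norm(R.ravel()[f])
            hist.append(rn)
            if rn <= tol_rel * ref + tol_abs:
                self._mu_carry = 0.1 * mu
                return x, hist
            K = self.tangent(x, p_gc, p_epi)
            accepted = False
            for _ in range(12):     # escalate mu until a step is accepted
                Kff = K[f][:, f]
                if mu > 0.0:
                    Kff = Kff + mu * sp.identity(len(f), format="csr")
                with np.errstate(all="ignore"):
                    try:
                        dx = spla.spsolve(Kff.tocsc(), -R.ravel()[f])
                    except RuntimeError:
                        dx = None
                if dx is None or not np.all(np.isfinite(dx)):
                    mu = max(5.0 * mu, mu_min)
                    continue
                big = np.abs(dx).max()
                if big > step_cap:
                    dx = dx * (step_cap / big)
                step = np.zeros(self.n_dof)
                step[f] = dx
                step = step.reshape(-1, 3)
                for alpha in (1.0, 0.5, 0.25, 0.1, 0.03):
                    try:
                        rn_t = np.linalg.norm(self.residual(
                            x + alpha * step, p_gc, p_epi).ravel()[f])
                    except NonConvergenceError:
                        continue
                    if np.isfinite(rn_t) and (rn_t < rn * (1.0 - 1e-4 * alpha)
                                              or rn_t < tol_rel * ref):
                        x = x + alpha * step
                        accepted = True
                        mu = 0.3 * mu if alpha >= 0.5 else mu
                        if mu < mu_min:
                            mu = 0.0
                        break
                if accepted:
                    break
                mu = max(5.0 * mu, mu_min)
            if not accepted:
                # Gauss-Newton least-squares fallback: minimizes |R|^2 even
                # where the tangent is indefinite (wrinkling states)
                KT = K[f][:, f].T.tocsr()
                g = KT @ R.ravel()[f]
                mu_gn = max(mu, mu_min)
                for _ in range(10):
                    H = (KT @ KT.T) + mu_gn * sp.identity(len(f), format="csr")
                    try:
                        dx = spla.spsolve(H.tocsc(), -g)
                    except RuntimeError:
                        mu_gn *= 10.0
                        continue
                    if not np.all(np.isfinite(dx)):
                        mu_gn *= 10.0
                        continue
                    big = np.abs(dx).max()
                    if big > step_cap:
                        dx = dx * (step_cap / big)
                    step = np.zeros(self.n_dof)
                    step[f] = dx
                    step = step.reshape(-1, 3)
                    for alpha in (1.0, 0.3, 0.1, 0.03):
                        try:
                            rn_t = np.linalg.norm(self.residual(
                                x + alpha * step, p_gc, p_epi).ravel()[f])
                        except NonConvergenceError:
                            continue
                        if np.isfinite(rn_t) and rn_t < rn:
                            x = x + alpha * step
                            accepted = True
                            break
                    if accepted:
                        break
                    mu_gn *= 10.0
            if not accepted:
                break
        raise NonConvergenceError(
            f"Newton stalled at P_gc={p_gc:.3f} MPa (residual {hist[-1]:.3e})",
            last_pressure=p_gc, residual_history=hist)

    def solve_path(self, steps: Sequence, x0=None, tol_rel=1e-6,
                   max_substeps=6):
        """March through (P_gc, P_epi) pairs with adaptive substepping.

        Yields (P_gc, P_epi, x, residual_history) per requested step.
        """
        x = self.X.copy() if x0 is None else x0.copy()
        prev = (0.0, 0.0)
        pg_final = max(p for p, _ in steps)
        # residuals are judged against the full applied load, so that
        # micro-substeps near zero pressure are not held to a vanishing bar
        self._tol_abs = max(tol_rel * self.external_force_ref(
            self.X, pg_final, 0.0), 1e-10)
        x_prev = None
        prev_dp = None
        for (pg, pe) in steps:
            x_start = x.copy()
            dp = pg - prev[0]
            if x_prev is not None and prev_dp and prev_dp > 0:
                x_try = x + (x - x_prev) * (dp / prev_dp)
            else:
                x_try = x
            try:
                x, hist = self.solve_step(x_try, pg, pe, tol_rel=tol_rel,
                                          tol_abs=self._tol_abs)
            except NonConvergenceError:
                try:
                    x, hist = self.solve_step(x_start, pg, pe,
                                              tol_rel=tol_rel,
                                              tol_abs=self._tol_abs)
                except NonConvergenceError as err:
                    x, hist = self._substep(x_start, prev, (pg, pe), tol_rel,
                                            max_substeps, err)
            x_prev, prev_dp = x_start, dp
            prev = (pg, pe)
            yield pg, pe, x, hist
        return

    def _substep(self, x, p_from, p_to, tol_rel, depth, err):
        if depth <= 0:
            raise err
        ta = getattr(self, "_tol_abs", 1e-9)
        mid = (0.5 * (p_from[0] + p_to[0]), 0.5 * (p_from[1] + p_to[1]))
        try:
            x, _ = self.solve_step(x, mid[0], mid[1], tol_rel=tol_rel,
                                   tol_abs=ta)
        except NonConvergenceError as e2:
            x, _ = self._substep(x, p_from, mid, tol_rel, depth - 1, e2)
        try:
            return self.solve_step(x, p_to[0], p_to[1], tol_rel=tol_rel,
                                   tol_abs=ta)
        except NonConvergenceError as e3:
            return self._substep(x, mid, p_to, tol_rel, depth - 1, e3)

    # -- element fields -----------------------------------------------------
    def element_tensors(self, x):
        """Green-Lagrange strain and Cauchy stress tensors per element.

        Both are built in the local reference frame from the membrane
        kinematics (with the incompressible thickness stretch) and pushed to
        global axes; the Cauchy stress satisfies the plane-stress condition
        through the incompressibility pressure.
        """
        xe = x[self.elements]
        F, a, b, c = self._surface_C(xe)
        D = a * b - c * c
        L = 1.0 / D
        M = len(a)
        # Green-Lagrange in local reference frame
        Eloc = np.zeros((M, 3, 3))
        Eloc[:, 0, 0] = 0.5 * (a - 1.0)
        Eloc[:, 1, 1] = 0.5 * (b - 1.0)
        Eloc[:, 0, 1] = Eloc[:, 1, 0] = 0.5 * c
        Eloc[:, 2, 2] = 0.5 * (L - 1.0)
        Rf = self.frame
        Egl = Rf @ Eloc @ np.swapaxes(Rf, 1, 2)
        # Second PK (local), isotropic part: 2 W1 I + 2 W2 (I1 I - C)
        p = self.mat
        I1 = a + b + L
        ew = np.exp(p.c2 * (I1 - 3.0))
        W1 = p.c1 * p.c2 * ew
        W2 = -0.5 * p.c1 * p.c2
        C3 = np.zeros((M, 3, 3))
        C3[:, 0, 0], C3[:, 1, 1], C3[:, 0, 1] = a, b, c
        C3[:, 1, 0], C3[:, 2, 2] = c, L
        S = (2.0 * W1)[:, None, None] * np.eye(3) \
            + 2.0 * W2 * (I1[:, None, None] * np.eye(3) - C3)
        if self.has_fiber:
            av, bv = self.a0[:, 0], self.a0[:, 1]
            I4 = av * av * a + bv * bv * b + 2.0 * av * bv * c
            lam = np.sqrt(np.maximum(I4, 1e-12))
            W4 = fiber_stress_scale(lam, p) / I4      # 2 dW/dI4
            A0 = np.zeros((M, 3, 3))
            A0[:, 0, 0] = av * av
            A0[:, 1, 1] = bv * bv
            A0[:, 0, 1] = A0[:, 1, 0] = av * bv
            S = S + W4[:, None, None] * A0
        # deformed 3x3 gradient in mixed (global x local-ref) basis
        n_def = np.cross(F[:, :, 0], F[:, :, 1])
        n_def = n_def / np.linalg.norm(n_def, axis=1)[:, None]
        F3 = np.empty((M, 3, 3))
        F3[:, :, 0] = F[:, :, 0]
        F3[:, :, 1] = F[:, :, 1]
        F3[:, :, 2] = np.sqrt(L)[:, None] * n_def
        sig = F3 @ S @ np.swapaxes(F3, 1, 2)          # J = 1
        pn = np.einsum("mij,mi,mj->m", sig, n_def, n_def)
        sig = sig - pn[:, None, None] * np.eye(3)
        return Egl, 0.5 * (sig + np.swapaxes(sig, 1, 2))


# ---------------------------------------------------------------------------
# public drivers


def apply_fixed_poles(mesh: SurfaceMesh) -> np.ndarray:
    """Constraint set pinning the long-axis (x) displacement of the polar
    wall nodes; returns the global dof indices, one per pole_tips node."""
    tips = mesh.node_sets.get("pole_tips")
    if tips is None or len(tips) == 0:
        raise ValueError("mesh has no pole_tips node set")
    return 3 * np.asarray(tips, np.int64)      # x dofs


def build_system(mesh: SurfaceMesh, material: MaterialParams,
                 variant: BCVariant | None = None,
                 epi_patches=("dorsal",)) -> MembraneSystem:
    """Wire a SurfaceMesh into a ready-to-solve membrane system.

    ``epi_patches`` selects the wall patches loaded by the epidermal
    back-pressure.  The default (dorsal walls, where neighboring epidermal
    cells press on the guard cells) is self-equilibrated; including
    "periclinal_outer" gives the complex a net out-of-plane resultant that
    would have to be reacted by a substrate model.
    """
    variant = variant or BCVariant()
    closed = [mesh.cell_surface(0), mesh.cell_surface(1)]
    epi = np.where(np.isin(mesh.patch,
                           [PATCH_ID[p] for p in epi_patches]))[0]
    fixed = []
    centers = mesh.node_sets.get("pole_centers")
    if centers is not None and len(centers):
        c = np.asarray(centers, np.int64)
        fixed.extend((3 * c + 1).tolist())   # y
        fixed.extend((3 * c + 2).tolist())   # z
    if variant.kind == "fixed_poles":
        fixed.extend(apply_fixed_poles(mesh).tolist())
    fixed = np.unique(np.asarray(fixed, np.int64)) if fixed else None
    contact = []
    for cell, side in ((0, 1.0), (1, -1.0)):
        key = f"ventral_nodes_{cell}"
        if key in mesh.node_sets:
            contact.append((np.asarray(mesh.node_sets[key], np.int64), side))
    return MembraneSystem(mesh.nodes, mesh.elements, mesh.thickness,
                          mesh.fiber, material, closed, epi_rows=epi,
                          fixed_dofs=fixed, contact=contact)


def solve_quasistatic(mesh: SurfaceMesh, material: MaterialParams,
                      protocol: LoadProtocol,
                      variant: BCVariant | None = None,
                      tol_rel: float = 1e-6) -> List[EquilibriumState]:
    """One converged EquilibriumState per load step of the protocol."""
    variant = variant or BCVariant()
    sys_ = build_system(mesh, material, variant)
    states: List[EquilibriumState] = []
    for pg, pe, x, hist in sys_.solve_path(protocol.steps(), tol_rel=tol_rel):
        E, sig = sys_.element_tensors(x)
        states.append(EquilibriumState(
            u=x - sys_.X, green_strain=E, cauchy=sig, p_gc=pg, p_epi=pe,
            residual_norm=1e3 * hist[-1],    # uN -> nN
            strain_energy=sys_.strain_energy(x),
            cell_volumes=tuple(sys_.enclosed_volumes(x)),
        ))
    return states


def _icosphere(radius: float, subdivisions: int = 3):
    import trimesh
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return np.asarray(m.vertices, float), np.asarray(m.faces, np.int64)


def inflate_sphere_benchmark(radius: float, thickness: float,
                             material: MaterialParams,
                             pressures: Sequence[float],
                             subdivisions: int = 3) -> np.ndarray:
    """FE inflation of a thin closed spherical shell (fibers disabled).

    Returns the mean radial stretch at each pressure; used to validate the
    membrane kernel against the closed-form thin-wall balloon relation.
    """
    if material.c3 != 0.0 or material.c5 != 0.0:
        raise ValueError("sphere benchmark requires fibers disabled")
    if thickness > 0.05 * radius:
        raise ValueError("shell is not thin")
    nodes, faces = _icosphere(radius, subdivisions)
    fiber = np.zeros((len(faces), 3))
    fiber[:, 0] = 1.0   # unused (c3=c5=0) but must be set
    # project fiber onto facets to satisfy the constructor
    tri = nodes[faces]
    n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    n /= np.linalg.norm(n, axis=1)[:, None]
    f = fiber - np.einsum("ij,ij->i", fiber, n)[:, None] * n
    f /= np.linalg.norm(f, axis=1)[:, None]
    closed = [(np.arange(len(faces)), np.ones(len(faces)))]
    sys_ = MembraneSystem(nodes, faces, np.full(len(faces), thickness), f,
                          material, closed)
    stretches = []
    steps = [(p, 0.0) for p in pressures]
    for pg, _, x, _ in sys_.solve_path(steps):
        r = np.linalg.norm(x, axis=1).mean()
        stretches.append(r / radius)
    return np.asarray(stretches)
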