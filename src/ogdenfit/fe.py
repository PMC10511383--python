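"""Quasistatic nonlinear finite-element model of the rheometer tests.

A cylindrical specimen is meshed with 27-node (triquadratic) hexahedra and
loaded in axial compression/tension or torsion under either ``glued`` ends
(all end-face nodes fully prescribed, as in the experiment) or ideal
``slipping`` ends (only the axial component prescribed, lateral expansion
free).  The discrete balance of linear momentum ``div(sigma) = 0`` with zero
body force and traction-free lateral surface is solved with a full
Newton-Raphson scheme in an updated-Lagrangian setting; the consistent
tangent combines the spectral Ogden elasticity tensor with the geometric
(initial-stress) stiffness.

Measured outputs mirror the experiment: nominal stress ``P = f_z / A`` over
stretch ``lambda = (H + dz)/H`` and apparent shear stress
``tau = 2 t / (pi r^3)`` over the outer-radius amount of shear
``gamma = r theta / H``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import OgdenParameters, _cauchy_batch, _spatial_tangent_batch

__all__ = [
    "SpecimenGeometry",
    "CylinderMesh",
    "BoundaryCondition",
    "FESolution",
    "SimulatedCurve",
    "SimulationError",
    "build_cylinder_mesh",
    "newton_solve",
    "simulate_axial_test",
    "simulate_torsion_test",
]

NEWTON_RTOL = 1e-9
NEWTON_ATOL = 1e-11  # N
NEWTON_MAX_ITER = 20
MAX_BISECTIONS = 4
DEFAULT_STEPS_PER_RAMP = 10


class SimulationError(RuntimeError):
    """Unrecoverable failure of the forward simulation."""


class _StepFailure(RuntimeError):
    """Newton divergence within one load step (triggers bisection)."""


@dataclass(frozen=True)
class SpecimenGeometry:
    """Cylindrical specimen: radius and height in metres.

    Defaults follow the 8 mm biopsy-punch diameter; heights vary per
    specimen (2.7-7.2 mm, mean 4.9 mm).
    """

    radius: float = 4.0e-3
    height: float = 4.9e-3

    def __post_init__(self) -> None:
        if self.radius <= 0.0 or self.height <= 0.0:
            raise ValueError(
                f"degenerate geometry r={self.radius}, H={self.height}"
            )

    @property
    def cross_section(self) -> float:
        """Undeformed cross-sectional area pi r^2 (m^2)."""
        return float(np.pi * self.radius**2)


@dataclass(frozen=True)
class CylinderMesh:
    """Structured 27-node hexahedral mesh of a cylinder.

    ``nodes`` are reference coordinates (m); ``elements`` index 27 nodes per
    element in tensor-product order (xi fastest).  The tagged node sets
    partition the boundary into the Dirichlet candidates (bottom/top faces)
    and the traction-free lateral surface; ``centerline`` / ``yplane`` carry
    the rigid-body constraints of the slipping case.
    """

    geometry: SpecimenGeometry
    refinement: int
    nodes: np.ndarray
    elements: np.ndarray
    bottom: np.ndarray
    top: np.ndarray
    lateral: np.ndarray
    centerline: np.ndarray
    yplane: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_dof(self) -> int:
        return 3 * self.nodes.shape[0]


# ---------------------------------------------------------------------------
# Q2 shape functions on [-1, 1]^3, tensor-product node ordering
# ---------------------------------------------------------------------------

def _lagrange_q2(x):
    vals = np.stack([0.5 * x * (x - 1.0), 1.0 - x**2, 0.5 * x * (x + 1.0)], axis=-1)
    ders = np.stack([x - 0.5, -2.0 * x, x + 0.5], axis=-1)
    return vals, ders


def _reference_element():
    """Shape values/gradients at the 3x3x3 Gauss points: (nq,27), (nq,27,3)."""
    gp = np.array([-np.sqrt(3.0 / 5.0), 0.0, np.sqrt(3.0 / 5.0)])
    gw = np.array([5.0 / 9.0, 8.0 / 9.0, 5.0 / 9.0])
    pts = np.array([(x, y, z) for z in gp for y in gp for x in gp])
    wts = np.array([wx * wy * wz for wz in gw for wy in gw for wx in gw])
    Lx, dLx = _lagrange_q2(pts[:, 0])
    Ly, dLy = _lagrange_q2(pts[:, 1])
    Lz, dLz = _lagrange_q2(pts[:, 2])
    nq = pts.shape[0]
    N = np.empty((nq, 27))
    dN = np.empty((nq, 27, 3))
    for dk in range(3):
        for dj in range(3):
            for di in range(3):
                m = di + 3 * dj + 9 * dk
                N[:, m] = Lx[:, di] * Ly[:, dj] * Lz[:, dk]
                dN[:, m, 0] = dLx[:, di] * Ly[:, dj] * Lz[:, dk]
                dN[:, m, 1] = Lx[:, di] * dLy[:, dj] * Lz[:, dk]
                dN[:, m, 2] = Lx[:, di] * Ly[:, dj] * dLz[:, dk]
    return N, dN, wts


_N_Q, _DN_Q, _W_Q = _reference_element()


def build_cylinder_mesh(
    geom: SpecimenGeometry, refinement: int = 1, nz: int | None = None
) -> CylinderMesh:
    """Structured hex mesh of the cylinder via the square-to-disk mapping.

    The parametric square (u, v) in [-1, 1]^2 is mapped onto the disk by
    ``x = r u sqrt(1 - v^2/2)``, ``y = r v sqrt(1 - u^2/2)`` (boundary maps
    exactly onto the circle) and extruded along z.  Node count grows ~8x per
    refinement level.
    """
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    n = 2 ** (refinement + 1)  # elements across the diameter
    if nz is None:
        nz = max(2, int(round(n * geom.height / (2.0 * geom.radius))))
    m = 2 * n + 1  # nodes per in-plane direction
    mz = 2 * nz + 1

    i = np.arange(m)
    u = i / n - 1.0
    U, V = np.meshgrid(u, u, indexing="ij")
    X = geom.radius * U * np.sqrt(1.0 - V**2 / 2.0)
    Y = geom.radius * V * np.sqrt(1.0 - U**2 / 2.0)
    z = geom.height * np.arange(mz) / (2.0 * nz)

    nodes = np.empty((m * m * mz, 3))
    for k in range(mz):
        sl = slice(k * m * m, (k + 1) * m * m)
        nodes[sl, 0] = X.ravel()
        nodes[sl, 1] = Y.ravel()
        nodes[sl, 2] = z[k]

    def nid(ii, jj, kk):
        # in-plane arrays are raveled C-style from (i, j) grids: j fastest
        return m * ii + jj + m * m * kk

    elems = []
    for K in range(nz):
        for J in range(n):
            for I in range(n):
                conn = [
                    nid(2 * I + di, 2 * J + dj, 2 * K + dk)
                    for dk in range(3)
                    for dj in range(3)
                    for di in range(3)
                ]
                elems.append(conn)
    elements = np.array(elems, dtype=np.int64)

    II, JJ, KK = np.meshgrid(i, i, np.arange(mz), indexing="ij")
    flat = nid(II, JJ, KK).ravel()
    ii, jj, kk = II.ravel(), JJ.ravel(), KK.ravel()
    bottom = flat[kk == 0]
    top = flat[kk == mz - 1]
    lateral = flat[(ii == 0) | (ii == m - 1) | (jj == 0) | (jj == m - 1)]
    centerline = flat[(ii == n) & (jj == n)]
    yplane = flat[jj == n]

    mesh = CylinderMesh(
        geometry=geom,
        refinement=refinement,
        nodes=nodes,
        elements=elements,
        bottom=np.sort(bottom),
        top=np.sort(top),
        lateral=np.sort(lateral),
        centerline=np.sort(centerline),
        yplane=np.sort(yplane),
    )
    det = _Operator(mesh).detJ0
    if det.min() <= 0.0:
        raise SimulationError("mesh has non-positive reference Jacobians")
    return mesh


def mesh_volume(mesh: CylinderMesh) -> float:
    """Integrated reference volume (converges to pi r^2 H with refinement)."""
    op = _Operator(mesh)
    return float(np.sum(op.detJ0 * _W_Q[None, :]))


# ---------------------------------------------------------------------------
# boundary conditions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryCondition:
    """Dirichlet data for one test: glued/slipping ends, axial or torsion drive.

    ``delta_z`` is the full axial end displacement (m); ``theta`` the full
    end rotation (rad).  ``values_at(mesh, load_factor)`` returns the fixed
    dof mask and prescribed values at a fraction of the full drive.
    """

    kind: str  # "glued" | "slipping"
    mode: str  # "axial" | "torsion"
    delta_z: float = 0.0
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("glued", "slipping"):
            raise ValueError(f"unknown BC kind {self.kind!r}")
        if self.mode not in ("axial", "torsion"):
            raise ValueError(f"unknown BC mode {self.mode!r}")
        if self.mode == "torsion" and self.kind != "glued":
            raise ValueError("torsion is driven through glued ends")

    def values_at(self, mesh: CylinderMesh, load_factor: float):
        fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
        vals = np.zeros((mesh.n_nodes, 3))
        if self.mode == "axial":
            dz = load_factor * self.delta_z
            if self.kind == "glued":
                fixed[mesh.bottom] = True
                fixed[mesh.top] = True
                vals[mesh.top, 2] = dz
            else:
                fixed[mesh.bottom, 2] = True
                fixed[mesh.top, 2] = True
                vals[mesh.top, 2] = dz
                # rigid-body constraints: centerline held laterally, in-plane
                # rotation about the axis suppressed on the y = 0 node line
                fixed[mesh.centerline, 0] = True
                fixed[mesh.centerline, 1] = True
                fixed[mesh.yplane, 1] = True
        else:
            th = load_factor * self.theta
            fixed[mesh.bottom] = True
            fixed[mesh.top] = True
            ct, st = np.cos(th), np.sin(th)
            Xt = mesh.nodes[mesh.top]
            vals[mesh.top, 0] = ct * Xt[:, 0] - st * Xt[:, 1] - Xt[:, 0]
            vals[mesh.top, 1] = st * Xt[:, 0] + ct * Xt[:, 1] - Xt[:, 1]
        return fixed.ravel(), vals.ravel()


@dataclass
class FESolution:
    """Converged displacement field with its measured reactions."""

    u: np.ndarray
    reaction_force: float  # axial force on the top face, N
    reaction_torque: float  # torque about the cylinder axis, N m
    load_factor: float
    residual_norm: float
    n_iter: int
    max_von_mises: float = 0.0


@dataclass(frozen=True)
class SimulatedCurve:
    """One loading mode's simulated response curve.

    ``mode`` is ``compression_tension`` (abscissa: stretch, ordinate: nominal
    stress Pa) or ``shear`` (abscissa: amount of shear, ordinate: apparent
    shear stress Pa).
    """

    mode: str
    abscissa: np.ndarray
    ordinate: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"mode": self.mode, "abscissa": self.abscissa, "ordinate_Pa": self.ordinate}
        )


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

class _Operator:
    """Per-mesh precomputations and assembly of residual and tangent."""

    def __init__(self, mesh: CylinderMesh):
        self.mesh = mesh
        Xe = mesh.nodes[mesh.elements]  # (nel, 27, 3)
        self.Xe = Xe
        # reference Jacobian dx_i/dxi_j at each qp
        J0 = np.einsum("qaj,eai->eqij", _DN_Q, Xe)
        self.detJ0 = np.linalg.det(J0)
        J0inv = np.linalg.inv(J0)
        # gradients w.r.t. reference coordinates
        self.dN_X = np.einsum("qaj,eqji->eqai", _DN_Q, J0inv)
        # scatter indices
        edof = (3 * mesh.elements[:, :, None] + np.arange(3)).reshape(-1, 81)
        self.edof = edof
        self.rows = np.repeat(edof, 81, axis=1).ravel()
        self.cols = np.tile(edof, (1, 81)).ravel()

    def assemble(self, u: np.ndarray, p: OgdenParameters, need_matrix: bool = True):
        """Internal force vector and (optionally) consistent tangent matrix."""
        mesh = self.mesh
        ue = u.reshape(-1, 3)[mesh.elements]  # (nel, 27, 3)
        F = np.eye(3) + np.einsum("eai,eqaj->eqij", ue, self.dN_X)
        detF = np.linalg.det(F)
        if detF.min() <= 0.0 or not np.all(np.isfinite(detF)):
            raise _StepFailure("element inversion (det F <= 0)")
        Finv = np.linalg.inv(F)
        dN_x = np.einsum("eqaJ,eqJj->eqaj", self.dN_X, Finv)

        nel, nq = F.shape[:2]
        w = self.detJ0 * _W_Q[None, :] * detF  # current-volume quadrature weight

        if not need_matrix:
            sig = _cauchy_batch(F.reshape(-1, 3, 3), p).reshape(nel, nq, 3, 3)
            fe = np.matmul(dN_x, np.swapaxes(sig, -1, -2)) * w[..., None, None]
            f_int = np.zeros(mesh.n_dof)
            np.add.at(f_int, self.edof.ravel(), fe.sum(axis=1).reshape(-1))
            return f_int, None, sig, detF

        c, sig = _spatial_tangent_batch(F.reshape(-1, 3, 3), p)
        sig = sig.reshape(nel, nq, 3, 3)
        gq = dN_x.reshape(nel * nq, 27, 3)
        wq = w.reshape(nel * nq)

        # internal force: f[a,i] = w sigma_ij dN_x[a,j]
        fe = np.matmul(gq, np.swapaxes(sig.reshape(-1, 3, 3), -1, -2))
        fe *= wq[:, None, None]
        f_int = np.zeros(mesh.n_dof)
        np.add.at(f_int, self.edof.ravel(), fe.reshape(nel, nq, 81).sum(axis=1).ravel())

        # constitutive part, contracted over the qp axis in one GEMM per
        # element: K[a(i), b(k)] = sum_{q,j} g[q,a,j] * T[q,j,(i,k,b)]
        t = np.matmul(c.reshape(-1, 27, 3), np.swapaxes(gq, -1, -2))  # (qp,(ijk),b)
        T = np.ascontiguousarray(
            t.reshape(-1, 3, 3, 3, 27).transpose(0, 2, 1, 3, 4)
        )  # (qp, j, i, k, b)
        T *= wq[:, None, None, None, None]
        T = T.reshape(nel, nq * 3, 243)
        G = np.ascontiguousarray(np.swapaxes(gq, -1, -2)).reshape(nel, nq * 3, 27)
        Kc = np.matmul(np.swapaxes(G, -1, -2), T)  # (e, a, (i k b))

        # geometric part: delta_ik * sum_q w g[a,j] sigma_jl g[b,l]
        M = np.matmul(sig.reshape(-1, 3, 3), np.swapaxes(gq, -1, -2))  # (qp, j, b)
        M *= wq[:, None, None]
        geo = np.matmul(
            np.swapaxes(G, -1, -2), M.reshape(nel, nq * 3, 27)
        )  # (e, a, b)

        Ke = np.ascontiguousarray(
            Kc.reshape(nel, 27, 3, 3, 27).transpose(0, 1, 2, 4, 3)
        ).reshape(nel, 81, 81)
        Kev = Ke.reshape(nel, 27, 3, 27, 3)
        for i in range(3):
            Kev[:, :, i, :, i] += geo
        K = sp.coo_matrix(
            (Ke.ravel(), (self.rows, self.cols)), shape=(mesh.n_dof, mesh.n_dof)
        ).tocsr()
        return f_int, K, sig, detF


def _von_mises_max(sig: np.ndarray) -> float:
    tr = np.trace(sig, axis1=-2, axis2=-1)
    dev = sig - tr[..., None, None] / 3.0 * np.eye(3)
    vm = np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
    return float(vm.max())


def _reactions(mesh: CylinderMesh, u: np.ndarray, f_int: np.ndarray):
    f = f_int.reshape(-1, 3)
    top = mesh.top
    fz = float(f[top, 2].sum())
    x = mesh.nodes[top] + u.reshape(-1, 3)[top]
    torque = float(np.sum(x[:, 0] * f[top, 1] - x[:, 1] * f[top, 0]))
    return fz, torque


def _newton_step(
    op: _Operator,
    u: np.ndarray,
    p: OgdenParameters,
    bc: BoundaryCondition,
    load_factor: float,
    rtol: float = NEWTON_RTOL,
    atol: float = NEWTON_ATOL,
    max_iter: int = NEWTON_MAX_ITER,
):
    mesh = op.mesh
    fixed, vals = bc.values_at(mesh, load_factor)
    free = ~fixed
    u = u.copy()
    u[fixed] = vals[fixed]

    r0 = None
    rnorm = np.inf
    for it in range(max_iter):
        f_int, K, sig, _ = op.assemble(u, p, need_matrix=True)
        r = f_int[free]
        rnorm = float(np.abs(r).max()) if r.size else 0.0
        fmax = float(np.abs(f_int).max()) if f_int.size else 0.0
        if r0 is None:
            r0 = max(rnorm, atol)
        # floor at the double-precision noise of the assembled forces so the
        # solver error stays far below the discretization error
        tol = max(atol, rtol * r0, 1e-12 * fmax)
        if rnorm < tol:
            fz, tq = _reactions(mesh, u, f_int)
            return (
                FESolution(
                    u=u,
                    reaction_force=fz,
                    reaction_torque=tq,
                    load_factor=load_factor,
                    residual_norm=rnorm,
                    n_iter=it,
                    max_von_mises=_von_mises_max(sig),
                ),
                it,
            )
        Kff = K[free][:, free]
        du = spla.spsolve(Kff.tocsc(), -r)
        if not np.all(np.isfinite(du)):
            raise _StepFailure("linear solve produced non-finite update")
        # backtracking line search: damp the update until the residual no
        # longer blows up (guards against element inversion on large steps)
        beta = 1.0
        for _ in range(6):
            try:
                f_try, _, _, _ = op.assemble(
                    _with_update(u, free, beta * du), p, need_matrix=False
                )
            except _StepFailure:
                beta *= 0.5
                continue
            rtry = float(np.abs(f_try[free]).max())
            if rtry < 10.0 * rnorm or beta <= 1.0 / 32.0:
                break
            beta *= 0.5
        else:
            raise _StepFailure("line search failed (persistent element inversion)")
        u[free] += beta * du
    raise _StepFailure(f"no convergence after {max_iter} iterations")


def _with_update(u, free, du):
    v = u.copy()
    v[free] += du
    return v


def newton_solve(
    mesh: CylinderMesh,
    p: OgdenParameters,
    bc: BoundaryCondition,
    state0: np.ndarray | None = None,
    load_factor: float = 1.0,
    **kw,
) -> FESolution:
    """Solve one load step with full Newton-Raphson from a previous state."""
    op = _Operator(mesh)
    u0 = np.zeros(mesh.n_dof) if state0 is None else np.asarray(state0, float).copy()
    sol, _ = _newton_step(op, u0, p, bc, load_factor, **kw)
    return sol


def _ramp(
    op: _Operator,
    p: OgdenParameters,
    bc: BoundaryCondition,
    targets: np.ndarray,
    n_steps: int,
):
    """March the load factor through ``targets`` with bisection on failure.

    ``targets`` are increasing load factors in (0, 1]; solutions are recorded
    at each.  Intermediate factors are inserted so no step exceeds
    ``1/n_steps`` of the ramp, and failing steps are halved up to
    MAX_BISECTIONS times.
    """
    out = []
    u = np.zeros(op.mesh.n_dof)
    u_prev, lf_prev = None, None
    current = 0.0
    max_inc = 1.0 / max(n_steps, 1)
    for tgt in targets:
        pending = [tgt]
        # uniform pre-subdivision of a large increment
        n_sub = int(np.ceil((tgt - current) / max_inc - 1e-12))
        if n_sub > 1:
            pending = list(np.linspace(current, tgt, n_sub + 1)[1:])
        depth = 0
        while pending:
            nxt = pending[0]
            # linear extrapolation of the converged path as predictor
            if u_prev is not None and current > lf_prev:
                scale = (nxt - current) / (current - lf_prev)
                guess = u + scale * (u - u_prev)
            else:
                guess = u
            try:
                sol, _ = _newton_step(op, guess, p, bc, nxt)
            except _StepFailure:
                try:  # retry from the last converged state before bisecting
                    sol, _ = _newton_step(op, u, p, bc, nxt)
                except _StepFailure:
                    depth += 1
                    if depth > MAX_BISECTIONS:
                        raise SimulationError(
                            f"load stepping failed near load factor {nxt:.4g} "
                            f"(last good {current:.4g})"
                        )
                    pending.insert(0, 0.5 * (current + nxt))
                    continue
            u_prev, lf_prev = u, current
            u = sol.u
            current = nxt
            pending.pop(0)
        out.append(sol)
    return out


def simulate_axial_test(
    geom: SpecimenGeometry,
    p: OgdenParameters,
    bc_kind: str,
    lambda_targets,
    n_steps: int = DEFAULT_STEPS_PER_RAMP,
    refinement: int = 1,
    mesh: CylinderMesh | None = None,
) -> SimulatedCurve:
    """Nominal stress P(lambda) of the cyclic compression/tension test.

    Compression (lambda < 1) and tension (lambda > 1) branches are ramped
    separately from the reference state; P = f_z / A.
    """
    lams = np.asarray(lambda_targets, dtype=float)
    if np.any(lams < 0.7) or np.any(lams > 1.3):
        raise ValueError("lambda targets must lie in [0.7, 1.3]")
    if mesh is None:
        mesh = build_cylinder_mesh(geom, refinement)
    op = _Operator(mesh)
    H, A = geom.height, geom.cross_section

    results: dict[float, float] = {lam: 0.0 for lam in lams[lams == 1.0]}
    for branch in (np.sort(lams[lams < 1.0])[::-1], np.sort(lams[lams > 1.0])):
        if branch.size == 0:
            continue
        full = branch[-1] - 1.0  # most extreme stretch increment
        bc = BoundaryCondition(kind=bc_kind, mode="axial", delta_z=full * H)
        factors = (branch - 1.0) / full
        sols = _ramp(op, p, bc, factors, n_steps)
        for lam, sol in zip(branch, sols):
            results[lam] = sol.reaction_force / A
    order = np.argsort(lams)
    ordinate = np.array([results[lam] for lam in lams])
    return SimulatedCurve(
        mode="compression_tension", abscissa=lams[order], ordinate=ordinate[order]
    )


def simulate_torsion_test(
    geom: SpecimenGeometry,
    p: OgdenParameters,
    gamma_targets,
    n_steps: int = DEFAULT_STEPS_PER_RAMP,
    refinement: int = 1,
    mesh: CylinderMesh | None = None,
) -> SimulatedCurve:
    """Apparent shear stress tau(gamma) = 2t/(pi r^3) of the torsion test.

    ``gamma`` is referenced to the outer radius, gamma = r theta / H; ends
    are glued (rotation prescribed on the top face, bottom fixed).  The
    response is odd in gamma, so targets are simulated at |gamma| and the
    sign restored.
    """
    gams = np.asarray(gamma_targets, dtype=float)
    if mesh is None:
        mesh = build_cylinder_mesh(geom, refinement)
    op = _Operator(mesh)
    r, H = geom.radius, geom.height

    mags = np.unique(np.abs(gams[gams != 0.0]))
    results = {0.0: 0.0}
    if mags.size:
        gmax = mags[-1]
        theta_max = gmax * H / r
        bc = BoundaryCondition(kind="glued", mode="torsion", theta=theta_max)
        sols = _ramp(op, p, bc, mags / gmax, n_steps)
        for g, sol in zip(mags, sols):
            results[g] = 2.0 * sol.reaction_torque / (np.pi * r**3)
    order = np.argsort(gams)
    ordinate = np.array([np.sign(g) * results[abs(g)] if g else 0.0 for g in gams])
    return SimulatedCurve(mode="shear", abscissa=gams[order], ordinate=ordinate[order])
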