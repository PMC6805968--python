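"""Local deformable registration: Laplacian-based and FEM-based (STEP 3).

Laplacian-based registration solves, per iteration, the linear least
squares problem

    min_{V'}  || L V' - L V0 ||^2  +  lambda * sum_c || v'_c - t_c ||^2

where ``L`` is the discrete Laplacian of the template at step entry,
``L V0`` are the delta (detail) coordinates of the entry shape, and the
positional constraints ``c`` are bidirectional nearest-surface
correspondences re-sampled every iteration. Preserving the delta
coordinates preserves local surface detail while the constraints pull the
surface onto the target.

FEM-based registration treats the template as a linear-elastic body at
rest in its step-entry shape: correspondence residuals attach springs
from the surface to the target, and each iteration solves the elastic
equilibrium for the total displacement field, so the spring forces
(proportional to the remaining residuals) balance the internal elastic
forces. The template deforms so as to represent the target surface as
closely as possible, with the elastic energy of the total deformation
smoothing and limiting the fit.

Both steps share the objective, damping and stopping rules of the global
steps: iterations that would increase the mean bidirectional distance are
damped and the windowed convergence policy decides when to stop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .global_reg import ConvergencePolicy, ConvergenceStatus, StepTrace, \
    check_convergence, DEFAULT_REG_SAMPLING, _barycentric_on_faces
from .mesh_core import SurfaceSampling, TriMesh, points_inside, require_valid

__all__ = [
    "LaplacianConfig",
    "FEMConfig",
    "build_laplacian",
    "solve_laplacian_positions",
    "laplacian_deform_step",
    "fem_stiffness",
    "fem_deform_step",
]


@dataclass(frozen=True)
class LaplacianConfig:
    """Laplacian registration parameters.

    weighting : "cotangent" (default; the discretization used throughout
        the Laplacian-editing literature) or "uniform" (delta_i = v_i -
        mean of neighbours).
    constraint_weight : lambda, the weight of the positional-constraint
        term relative to the Laplacian (detail) term.
    correspondence_fraction : fraction of template vertices constrained
        per iteration (deterministic stride subset).
    prune_factor : optional robust-ICP outlier pruning; when set, pairs
        with residual above prune_factor x median (never more than the
        worst decile) are dropped each iteration. Off by default: with
        clean closed surfaces the largest residuals are informative, not
        outliers, and pruning them stalls convergence.
    """

    weighting: str = "cotangent"
    constraint_weight: float = 50.0
    correspondence_fraction: float = 1.0
    prune_factor: float | None = None

    def __post_init__(self) -> None:
        if self.weighting not in ("uniform", "cotangent"):
            raise ValueError("weighting must be 'uniform' or 'cotangent'")
        if not self.constraint_weight > 0:
            raise ValueError("constraint_weight (lambda) must be > 0")
        if not 0 < self.correspondence_fraction <= 1:
            raise ValueError("correspondence_fraction must be in (0, 1]")


@dataclass(frozen=True)
class FEMConfig:
    """Linear-elastic FEM registration parameters.

    youngs_modulus : E in kPa. Stiffness is linear in E; with the
        residual-proportional force scheme below, only the ratio of
        force_scale to E matters.
    poisson_ratio : nu in [0, 0.5); higher values couple the displacement
        field more strongly (volumetric resistance).
    force_scale : dimensionless spring-stiffness gain: each
        corresponded vertex is attached to its target by a spring of
        stiffness force_scale x E x (vertex area / mean vertex area).
        Larger values pull the surface closer to the target against the
        elastic resistance.
    element_type : "tetrahedral" (default; linear tetrahedra on a
        Delaunay interior mesh — volumetric elasticity, the classical
        elastic-body registration model) or "surface-membrane"
        (constant-strain triangles on the surface; no bending stiffness,
        hence much more permissive to local surface deformation).
    prune_factor : optional robust-ICP outlier pruning, as in
        :class:`LaplacianConfig`. Off by default.
    """

    youngs_modulus: float = 1.0
    poisson_ratio: float = 0.3
    force_scale: float = 5.0
    element_type: str = "tetrahedral"
    prune_factor: float | None = None

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0 <= self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must be in [0, 0.5)")
        if self.element_type not in ("surface-membrane", "tetrahedral"):
            raise ValueError("element_type must be 'surface-membrane' or 'tetrahedral'")


# ----------------------------------------------------------------------
# Discrete Laplacian
# ----------------------------------------------------------------------

def build_laplacian(mesh: TriMesh, weighting: str = "cotangent") -> sp.csr_matrix:
    """Discrete Laplacian operator (n x n, rows sum to zero).

    uniform: L = I - D^-1 A, so (L V)_i = v_i - mean(neighbours of i).
    cotangent: L_ij = -(cot a_ij + cot b_ij)/2 for edge (i, j) with the
    two opposite angles a, b (one angle on boundary edges); diagonal =
    -sum of off-diagonals. Open (boundary) meshes are accepted here —
    closedness is enforced by the registration steps, not the operator.
    """
    n = mesh.n_vertices
    f = mesh.faces
    if weighting == "uniform":
        e = mesh.edges_unique()
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
        deg = np.asarray(adj.sum(axis=1)).ravel()
        if (deg == 0).any():
            raise ValueError(f"isolated vertex {int(np.argmin(deg))}")
        dinv = sp.diags(1.0 / deg)
        return (sp.identity(n, format="csr") - dinv @ adj).tocsr()
    if weighting != "cotangent":
        raise ValueError("weighting must be 'uniform' or 'cotangent'")
    # cotangent weights: accumulate per-face corner contributions
    tri = mesh.triangles
    rows, cols, vals = [], [], []
    for k in range(3):
        i, j, o = f[:, k], f[:, (k + 1) % 3], f[:, (k + 2) % 3]
        u = tri[:, k] - tri[:, (k + 2) % 3]
        v = tri[:, (k + 1) % 3] - tri[:, (k + 2) % 3]
        cross = np.linalg.norm(np.cross(u, v), axis=1)
        cot = np.einsum("ij,ij->i", u, v) / np.maximum(cross, 1e-300)
        w = 0.5 * cot
        rows += [i, j]
        cols += [j, i]
        vals += [-w, -w]
    rows, cols = np.concatenate(rows), np.concatenate(cols)
    vals = np.concatenate(vals)
    L = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    deg_mask = np.asarray((L != 0).sum(axis=1)).ravel()
    if (deg_mask == 0).any():
        raise ValueError(f"isolated vertex {int(np.argmin(deg_mask))}")
    L = L - sp.diags(np.asarray(L.sum(axis=1)).ravel())
    return L.tocsr()


def solve_laplacian_positions(L: sp.spmatrix, v0: np.ndarray,
                              constraint_rows: sp.spmatrix,
                              targets: np.ndarray,
                              lam: float) -> np.ndarray:
    """Solve min ||L V - L v0||^2 + lam ||C V - T||^2 for vertex positions V.

    ``constraint_rows`` C is (k, n): identity rows for vertex constraints
    or barycentric rows for on-surface constraints. Raises on a singular
    system (e.g. no constraints with lam = 0).
    """
    C = constraint_rows.tocsr()
    if lam < 0:
        raise ValueError("lam must be >= 0")
    if lam == 0 and C.shape[0] == 0:
        raise ValueError("singular Laplacian system: no positional constraints "
                         "and lam=0 (the Laplacian alone annihilates constants)")
    A = (L.T @ L + lam * (C.T @ C)).tocsc()
    b = L.T @ (L @ v0) + lam * (C.T @ targets)
    try:
        solve = spla.factorized(A)
    except RuntimeError as exc:
        raise ValueError(f"singular Laplacian system (lam={lam}, "
                         f"{C.shape[0]} constraints): {exc}") from exc
    out = np.column_stack([solve(b[:, k]) for k in range(3)])
    resid = abs(A @ out - b).max()
    scale = max(abs(b).max(), 1e-300)
    if not np.isfinite(out).all() or resid > 1e-6 * scale:
        raise ValueError("singular or ill-conditioned Laplacian system")
    return out


# ----------------------------------------------------------------------
# Correspondence machinery shared by both local steps
# ----------------------------------------------------------------------

def _prune_mask(residuals: np.ndarray, factor: float | None = None) -> np.ndarray:
    """Keep pairs with residual <= max(factor x median, 90th percentile).

    Robust-ICP outlier pruning with a percentile floor: when most of the
    surface already matches (median residual near zero) a bare
    median-multiple threshold would discard exactly the informative
    correspondences, so at most the worst decile is ever dropped.
    """
    if factor is None:
        return np.ones(len(residuals), dtype=bool)
    thr = max(factor * float(np.median(residuals)),
              float(np.percentile(residuals, 90.0)))
    if thr <= 0:
        return np.ones(len(residuals), dtype=bool)
    return residuals <= thr


class _LocalStepLoop:
    """Damped, policy-driven iteration shared by the two local methods."""

    def __init__(self, template: TriMesh, target: TriMesh,
                 policy: ConvergencePolicy, sampling: SurfaceSampling):
        require_valid(template, "template")
        require_valid(target, "target")
        self.template = template
        self.target = target
        self.policy = policy
        self.sampling = sampling
        self._target_prox = target.proximity()
        self._target_samples = sampling.sample(target)
        fi, bary = sampling.plan(template)
        self._plan = (fi, bary)

    def _sample_points(self, vertices: np.ndarray) -> np.ndarray:
        fi, bary = self._plan
        parts = [vertices] if self.sampling.include_vertices else []
        if len(fi):
            tri = vertices[self.template.faces[fi]]
            parts.append(np.einsum("ij,ijk->ik", bary, tri))
        return np.vstack(parts)

    def objective(self, vertices: np.ndarray) -> float:
        x = self._sample_points(vertices)
        _, df, _ = self._target_prox.query(x)
        mesh = self.template.with_vertices(vertices)
        _, db, _ = mesh.proximity().query(self._target_samples)
        return 0.5 * (float(df.mean()) + float(db.mean()))

    def correspondences(self, vertices: np.ndarray):
        """Bidirectional nearest-surface pairs at the current shape.

        Returns (fwd_targets (n,3), fwd_res (n,), back_closest, back_bary,
        back_faces, back_targets, back_res); forward entries cover every
        vertex.
        """
        yf, df, _ = self._target_prox.query(vertices)
        mesh = self.template.with_vertices(vertices)
        cb, db, fb = mesh.proximity().query(self._target_samples)
        bary = _barycentric_on_faces(cb, mesh, fb)
        return yf, df, cb, bary, fb, self._target_samples, db

    def run(self, update_fn):
        """Iterate ``update_fn(current_vertices) -> proposed_vertices``
        with damped acceptance until the policy stops the step."""
        v = self.template.vertices.copy()
        obj_prev = self.objective(v)
        if not np.isfinite(obj_prev):
            raise ValueError("non-finite objective at step entry")
        trace = StepTrace()
        while True:
            proposed = update_fn(v)
            if not np.isfinite(proposed).all():
                raise ValueError("non-finite displacement from local solve")
            accepted = None
            for damp in range(9):
                cand = v + 0.5 ** damp * (proposed - v)
                obj = self.objective(cand)
                if np.isfinite(obj) and obj <= obj_prev:
                    accepted = (cand, obj)
                    break
            if accepted is None:
                trace.objective_per_iteration.append(obj_prev)
                trace.terminated_by = "converged"
                break
            v, obj_prev = accepted
            trace.objective_per_iteration.append(obj_prev)
            status = check_convergence(trace.objective_per_iteration, self.policy)
            if status is ConvergenceStatus.CONVERGED:
                trace.terminated_by = "converged"
                break
            if status is ConvergenceStatus.TERMINATED:
                trace.terminated_by = "max_iterations"
                break
        return self.template.with_vertices(v), trace


# ----------------------------------------------------------------------
# Laplacian-based step
# ----------------------------------------------------------------------

def laplacian_deform_step(template: TriMesh, target: TriMesh,
                          config: LaplacianConfig = LaplacianConfig(),
                          policy: ConvergencePolicy = ConvergencePolicy(),
                          sampling: SurfaceSampling = DEFAULT_REG_SAMPLING):
    """STEP 3 (Algorithm A): Laplacian least-squares deformation.

    The delta coordinates ``L V0`` are taken from the step-entry shape
    (the globally registered template), so the geometric detail present
    after the global steps is what the deformation preserves. Returns
    ``(deformed_template, StepTrace)``.
    """
    loop = _LocalStepLoop(template, target, policy, sampling)
    L = build_laplacian(template, config.weighting)
    v0 = template.vertices
    n = template.n_vertices
    lam = config.constraint_weight
    stride = max(1, int(round(1.0 / config.correspondence_fraction)))
    constrained = np.arange(0, n, stride)

    def update(v):
        yf, df, cb, bary, fb, yt, db = loop.correspondences(v)
        keep = _prune_mask(np.concatenate([df[constrained], db]), config.prune_factor)
        kf = keep[:len(constrained)]
        kb = keep[len(constrained):]
        idx_f = constrained[kf]
        rows_f = sp.csr_matrix((np.ones(len(idx_f)), (np.arange(len(idx_f)), idx_f)),
                               shape=(len(idx_f), n))
        faces_b = template.faces[fb[kb]]
        nb = int(kb.sum())
        rows_b = sp.csr_matrix((bary[kb].ravel(),
                                (np.repeat(np.arange(nb), 3), faces_b.ravel())),
                               shape=(nb, n))
        C = sp.vstack([rows_f, rows_b])
        T = np.vstack([yf[idx_f], yt[kb]])
        if C.shape[0] == 0:
            raise ValueError("no positional constraints survive pruning")
        return solve_laplacian_positions(L, v0, C, T, lam)

    return loop.run(update)


# ----------------------------------------------------------------------
# FEM stiffness
# ----------------------------------------------------------------------

def _membrane_stiffness(mesh: TriMesh, E: float, nu: float,
                        thickness: float = 1.0) -> sp.csr_matrix:
    """Assembled constant-strain-triangle membrane stiffness (3n x 3n)."""
    D = (E / (1.0 - nu ** 2)) * np.array([[1.0, nu, 0.0],
                                          [nu, 1.0, 0.0],
                                          [0.0, 0.0, (1.0 - nu) / 2.0]])
    n = mesh.n_vertices
    tri = mesh.triangles
    rows, cols, vals = [], [], []
    for e, fidx in enumerate(mesh.faces):
        p0, p1, p2 = tri[e]
        e1 = p1 - p0
        l1 = np.linalg.norm(e1)
        nrm = np.cross(p1 - p0, p2 - p0)
        area2 = np.linalg.norm(nrm)
        if area2 <= 1e-12 or l1 <= 1e-12:
            raise ValueError(f"zero-area element (face {e})")
        e1 /= l1
        nhat = nrm / area2
        e2 = np.cross(nhat, e1)
        # local 2D coordinates
        x = np.array([0.0, l1, (p2 - p0) @ e1])
        y = np.array([0.0, 0.0, (p2 - p0) @ e2])
        A = 0.5 * area2
        b = np.array([y[1] - y[2], y[2] - y[0], y[0] - y[1]])
        c = np.array([x[2] - x[1], x[0] - x[2], x[1] - x[0]])
        B = np.zeros((3, 6))
        B[0, 0::2] = b
        B[1, 1::2] = c
        B[2, 0::2] = c
        B[2, 1::2] = b
        B /= 2.0 * A
        Ke_local = thickness * A * B.T @ D @ B          # (6, 6)
        T = np.zeros((6, 9))
        for i in range(3):
            T[2 * i, 3 * i:3 * i + 3] = e1
            T[2 * i + 1, 3 * i:3 * i + 3] = e2
        Ke = T.T @ Ke_local @ T                          # (9, 9)
        dof = np.concatenate([3 * fidx[i] + np.arange(3) for i in range(3)])
        rows.append(np.repeat(dof, 9))
        cols.append(np.tile(dof, 9))
        vals.append(Ke.ravel())
    K = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(3 * n, 3 * n))
    return ((K + K.T) * 0.5).tocsr()


def _tet_stiffness_matrix(nodes: np.ndarray, E: float, nu: float) -> np.ndarray:
    """Closed-form linear-tetrahedron element stiffness (12 x 12)."""
    v = np.hstack([np.ones((4, 1)), nodes])
    vol6 = np.linalg.det(v)
    if vol6 <= 0:
        raise ValueError("inverted or zero-volume tetrahedral element")
    grads = np.linalg.inv(v)[1:, :]        # (3, 4): grad N_a = grads[:, a]
    B = np.zeros((6, 12))
    for a in range(4):
        gx, gy, gz = grads[:, a]
        B[:, 3 * a:3 * a + 3] = [[gx, 0, 0], [0, gy, 0], [0, 0, gz],
                                 [gy, gx, 0], [0, gz, gy], [gz, 0, gx]]
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] += 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return (vol6 / 6.0) * B.T @ D @ B


def _interior_tets(mesh: TriMesh) -> np.ndarray:
    """Delaunay tetrahedra of the vertex cloud restricted to the interior."""
    from scipy.spatial import Delaunay
    tets = Delaunay(mesh.vertices).simplices
    cent = mesh.vertices[tets].mean(axis=1)
    inside = points_inside(mesh, cent)
    tets = tets[inside]
    # drop degenerate Delaunay slivers (no volume, no stiffness)
    v = mesh.vertices
    vol6 = np.abs(np.linalg.det(np.stack([v[tets[:, 1]] - v[tets[:, 0]],
                                          v[tets[:, 2]] - v[tets[:, 0]],
                                          v[tets[:, 3]] - v[tets[:, 0]]], axis=1)))
    tets = tets[vol6 > 1e-9 * max(vol6.max(), 1.0)]
    if len(tets) == 0:
        raise ValueError("no interior tetrahedra found")
    # enforce positive orientation
    d = np.linalg.det(np.stack([v[tets[:, 1]] - v[tets[:, 0]],
                                v[tets[:, 2]] - v[tets[:, 0]],
                                v[tets[:, 3]] - v[tets[:, 0]]], axis=1))
    flip = d < 0
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


def fem_stiffness(mesh: TriMesh, config: FEMConfig = FEMConfig()) -> sp.csr_matrix:
    """Assemble the linear-elastic stiffness operator (3n x 3n).

    Symmetric positive semi-definite; before boundary conditions its null
    space is spanned by the six rigid-body motions (for a closed,
    non-planar surface in the membrane case).
    """
    require_valid(mesh, "mesh")
    if config.element_type == "surface-membrane":
        return _membrane_stiffness(mesh, config.youngs_modulus, config.poisson_ratio)
    tets = _interior_tets(mesh)
    n = mesh.n_vertices
    rows, cols, vals = [], [], []
    for e, tet in enumerate(tets):
        try:
            Ke = _tet_stiffness_matrix(mesh.vertices[tet], config.youngs_modulus,
                                       config.poisson_ratio)
        except ValueError as exc:
            raise ValueError(f"element {e} (vertices {tet.tolist()}): {exc}") from exc
        dof = np.concatenate([3 * tet[i] + np.arange(3) for i in range(4)])
        rows.append(np.repeat(dof, 12))
        cols.append(np.tile(dof, 12))
        vals.append(Ke.ravel())
    K = sp.csr_matrix((np.concatenate(vals),
                       (np.concatenate(rows), np.concatenate(cols))),
                      shape=(3 * n, 3 * n))
    return ((K + K.T) * 0.5).tocsr()


def _rigid_basis(vertices: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the six rigid-body displacement fields (3n x 6)."""
    n = len(vertices)
    c = vertices.mean(axis=0)
    x = vertices - c
    R = np.zeros((3 * n, 6))
    for k in range(3):
        R[k::3, k] = 1.0
    R[1::3, 3] = -x[:, 2]
    R[2::3, 3] = x[:, 1]
    R[0::3, 4] = x[:, 2]
    R[2::3, 4] = -x[:, 0]
    R[0::3, 5] = -x[:, 1]
    R[1::3, 5] = x[:, 0]
    q, _ = np.linalg.qr(R)
    return q


# ----------------------------------------------------------------------
# FEM-based step
# ----------------------------------------------------------------------

def fem_deform_step(template: TriMesh, target: TriMesh,
                    config: FEMConfig = FEMConfig(),
                    policy: ConvergencePolicy = ConvergencePolicy(),
                    sampling: SurfaceSampling = DEFAULT_REG_SAMPLING):
    """STEP 3 (Algorithm B): linear-elastic FEM deformation.

    The template is an elastic body at rest in its step-entry shape.
    Correspondences attach elastic springs (stiffness force_scale x E x
    vertex area) from surface points to their nearest target points, and
    each iteration solves the equilibrium

        (K + B) U = B (correspondence targets - V0)

    for the *total* displacement field ``U`` from the entry shape ``V0``,
    where ``B`` is the diagonal spring-weight matrix. At equilibrium the
    spring forces are proportional to the remaining correspondence
    residuals and balance the internal elastic forces ``K U``; the
    elastic energy of the total deformation is what smooths and limits
    the fit. Correspondences are re-sampled every iteration at the
    current shape; updates are damped under the shared acceptance rule.
    Stiffness is assembled once on the entry shape (small-strain
    assumption). Returns ``(deformed_template, StepTrace)``.
    """
    loop = _LocalStepLoop(template, target, policy, sampling)
    K = fem_stiffness(template, config)
    n = template.n_vertices
    v0 = template.vertices
    areas = np.zeros(n)
    np.add.at(areas, template.faces.ravel(),
              np.repeat(template.face_areas / 3.0, 3))
    spring = config.force_scale * config.youngs_modulus * areas / areas.mean()

    def update(v):
        yf, df, cb, bary, fb, yt, db = loop.correspondences(v)
        keep = _prune_mask(np.concatenate([df, db]), config.prune_factor)
        kf, kb = keep[:n], keep[n:]
        # blend forward and backward correspondence targets per vertex
        num = np.zeros((n, 3))
        den = np.zeros(n)
        num[kf] += yf[kf] - v[kf]
        den[kf] += 1.0
        faces_b = template.faces[fb[kb]]
        res_b = yt[kb] - cb[kb]
        w = bary[kb]
        for k in range(3):
            np.add.at(num, faces_b[:, k], w[:, k:k + 1] * res_b)
            np.add.at(den, faces_b[:, k], w[:, k])
        has = den > 0
        # desired total displacement: current offset from rest + residual pull
        r_total = np.zeros((n, 3))
        r_total[has] = (v[has] - v0[has]) + num[has] / den[has, None]
        beta = np.where(has, spring * den, 0.0)
        if not has.any():
            raise ValueError("no correspondences survive pruning")
        B = sp.diags(np.repeat(beta, 3))
        try:
            solve = spla.factorized((K + B).tocsc())
        except RuntimeError as exc:
            raise ValueError(f"singular FEM system: {exc}") from exc
        U = solve((B @ r_total.ravel())).reshape(n, 3)
        return v0 + U

    return loop.run(update)
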