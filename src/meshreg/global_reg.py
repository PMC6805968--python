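"""Global registration: affine (STEP 1) and piece-wise affine (STEP 2).

Both steps are ICP-style alternations. One iteration is: (i) sample
bidirectional nearest-surface correspondences between the moving template
and the fixed target, (ii) solve the weighted linear least-squares problem
for the transform parameters mapping the *entry* template shape onto the
correspondence targets, (iii) re-evaluate the mean bidirectional distance.
Iterations that would increase the objective are damped (the parameter
update is repeatedly halved); if no damping level helps, the step stops at
the current stationary point. The per-step stopping rule is the windowed
criterion of :func:`check_convergence` — the mean absolute change of the
objective over the most recent ``window`` iterations falls below
``threshold`` — or a hard iteration cap.

The piece-wise affine deformation is a partition-of-unity blend of
per-region affine transforms: template vertices are clustered with
k-means, each cluster carries a Gaussian weight field (bandwidth 1.5 x
mean cluster RMS radius), and every vertex moves by the weight-blended
affine image of its entry position, which is continuous over the mesh by
construction. With one region the step reduces exactly to the affine step.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .mesh_core import (SurfaceSampling, TriMesh, mean_bidirectional_distance,
                        require_valid)

__all__ = [
    "AffineTransform",
    "PiecewiseAffineModel",
    "ConvergencePolicy",
    "StepTrace",
    "ConvergenceStatus",
    "check_convergence",
    "fit_affine_step",
    "fit_piecewise_affine_step",
]

# vertex-only sampling: the standard ICP correspondence set
DEFAULT_REG_SAMPLING = SurfaceSampling(density_per_mm2=0.0, include_vertices=True)


class DegenerateMeshError(ValueError):
    """Template vertices do not span 3D (rank-deficient covariance)."""


@dataclass(frozen=True)
class AffineTransform:
    """x -> linear @ x + translation, orientation-preserving."""

    linear: np.ndarray      # (3, 3), unitless
    translation: np.ndarray  # (3,), mm

    def __post_init__(self) -> None:
        object.__setattr__(self, "linear", np.asarray(self.linear, dtype=np.float64))
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=np.float64))
        det = np.linalg.det(self.linear)
        if not np.isfinite(det) or det <= 0:
            raise ValueError(f"affine linear part must have positive determinant (got {det})")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.linear.T + self.translation


@dataclass(frozen=True)
class ConvergencePolicy:
    """Windowed stopping rule for one registration step.

    Converged when the mean absolute change of the objective over the most
    recent ``window`` consecutive-iteration differences is below
    ``threshold`` (mm); terminated unconditionally at ``max_iterations``.
    """

    window: int = 10
    threshold: float = 0.001
    max_iterations: int = 3000

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not self.threshold > 0:
            raise ValueError("threshold must be > 0")
        if self.max_iterations < self.window:
            raise ValueError("max_iterations must be >= window")


class ConvergenceStatus(enum.Enum):
    CONTINUE = "continue"
    CONVERGED = "converged"
    TERMINATED = "terminated"


@dataclass
class StepTrace:
    """Objective (mean bidirectional distance, mm) after each iteration."""

    objective_per_iteration: list[float] = field(default_factory=list)
    terminated_by: str = "converged"   # "converged" | "max_iterations"

    @property
    def iterations_run(self) -> int:
        return len(self.objective_per_iteration)

    @property
    def final_objective(self) -> float:
        return self.objective_per_iteration[-1]


def check_convergence(trace, policy: ConvergencePolicy) -> ConvergenceStatus:
    """Classify an objective trace under the windowed stopping rule.

    ``trace`` is the sequence of objective values at the end of each
    iteration. Termination (iteration cap) takes precedence: a trace that
    has reached ``max_iterations`` entries is terminated regardless of the
    window statistic, since convergence would have stopped it earlier.
    """
    values = np.asarray(trace, dtype=np.float64)
    if values.size == 0:
        raise ValueError("trace is empty")
    if not np.isfinite(values).all():
        raise ValueError("trace contains non-finite objective values")
    if values.size >= policy.max_iterations:
        return ConvergenceStatus.TERMINATED
    if values.size >= policy.window + 1:
        deltas = np.abs(np.diff(values[-(policy.window + 1):]))
        if deltas.mean() < policy.threshold:
            return ConvergenceStatus.CONVERGED
    return ConvergenceStatus.CONTINUE


# ----------------------------------------------------------------------
# Blended-affine ICP engine
# ----------------------------------------------------------------------

def _weighted_affine_lstsq(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """min_P sum_i w_i ||P [x_i;1] - y_i||^2 -> P as a (3, 4) matrix."""
    sw = np.sqrt(w)[:, None]
    xh = np.column_stack([x, np.ones(len(x))]) * sw
    params, *_ = np.linalg.lstsq(xh, y * sw, rcond=None)
    return params.T  # (3, 4)


def _barycentric_on_faces(points: np.ndarray, mesh: TriMesh,
                          face_idx: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of surface points known to lie on given faces."""
    tri = mesh.triangles[face_idx]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d00 = np.einsum("ij,ij->i", ab, ab)
    d01 = np.einsum("ij,ij->i", ab, ac)
    d11 = np.einsum("ij,ij->i", ac, ac)
    d20 = np.einsum("ij,ij->i", ap, ab)
    d21 = np.einsum("ij,ij->i", ap, ac)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    bary = np.column_stack([1.0 - v - w, v, w])
    return np.clip(bary, 0.0, 1.0)


class _BlendedAffineEngine:
    """ICP alternation for a partition-of-unity blend of affine transforms.

    With one region (all weights 1) this is plain affine ICP. Parameters
    are the per-region (3, 4) affine matrices mapping *entry* template
    coordinates to deformed coordinates; each iteration refits them in
    total (not incrementally), so the returned model exactly describes the
    final deformation.
    """

    def __init__(self, template: TriMesh, target: TriMesh,
                 vertex_weights: np.ndarray, policy: ConvergencePolicy,
                 sampling: SurfaceSampling):
        require_valid(template, "template")
        require_valid(target, "target")
        sv = np.linalg.svd(template.vertices - template.centroid, compute_uv=False)
        if sv[2] <= 1e-9 * max(sv[0], 1.0):
            raise DegenerateMeshError("template vertices are rank-deficient")
        self.template = template
        self.target = target
        self.policy = policy
        self.sampling = sampling
        self.W = np.asarray(vertex_weights, dtype=np.float64)  # (n, R)
        self.R = self.W.shape[1]

        # fixed sample plan on the entry template, expressed in entry coords
        fi, bary = sampling.plan(template)
        self._plan = (fi, bary)
        parts_x = [template.vertices] if sampling.include_vertices else []
        parts_w = [self.W] if sampling.include_vertices else []
        if len(fi):
            tri = template.triangles[fi]
            parts_x.append(np.einsum("ij,ijk->ik", bary, tri))
            parts_w.append(np.einsum("ij,ijk->ik", bary, self.W[template.faces[fi]]))
        self.X0 = np.vstack(parts_x)
        self.WX = np.vstack(parts_w)
        self.Yt = sampling.sample(target)        # fixed target samples
        self._target_prox = target.proximity()

    # -- geometry -------------------------------------------------------
    def _positions(self, params: np.ndarray, x0: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Blend per-region affine images: sum_r w_r (A_r x + t_r)."""
        xh = np.column_stack([x0, np.ones(len(x0))])
        out = np.zeros((len(x0), 3))
        for r in range(self.R):
            out += w[:, r:r + 1] * (xh @ params[r].T)
        return out

    def _objective(self, params: np.ndarray) -> float:
        mesh = self.template.with_vertices(
            self._positions(params, self.template.vertices, self.W))
        x = self._positions(params, self.X0, self.WX)
        _, df, _ = self._target_prox.query(x)
        _, db, _ = mesh.proximity().query(self.Yt)
        return 0.5 * (float(df.mean()) + float(db.mean()))

    # -- main loop ------------------------------------------------------
    def run(self, init_params: np.ndarray | None = None):
        eye = np.tile(np.hstack([np.eye(3), np.zeros((3, 1))]), (self.R, 1, 1))
        params = eye.copy()
        entry_obj = self._objective(params)
        if not np.isfinite(entry_obj):
            raise ValueError("non-finite registration objective at entry")
        if init_params is not None:
            init_obj = self._objective(init_params)
            if init_obj <= entry_obj:
                params, entry_obj = init_params, init_obj

        trace = StepTrace()
        obj_prev = entry_obj
        while True:
            new_params = self._refit(params)
            accepted = None
            for damp in range(9):  # 1, 1/2, ..., 1/256
                cand = params + 0.5 ** damp * (new_params - params)
                obj = self._objective(cand)
                if np.isfinite(obj) and obj <= obj_prev:
                    accepted = (cand, obj)
                    break
            if accepted is None:
                # stationary: no damping level improves; stop where we are
                trace.objective_per_iteration.append(obj_prev)
                trace.terminated_by = "converged"
                break
            params, obj_prev = accepted
            trace.objective_per_iteration.append(obj_prev)
            status = check_convergence(trace.objective_per_iteration, self.policy)
            if status is ConvergenceStatus.CONVERGED:
                trace.terminated_by = "converged"
                break
            if status is ConvergenceStatus.TERMINATED:
                trace.terminated_by = "max_iterations"
                break
        vertices = self._positions(params, self.template.vertices, self.W)
        return vertices, params, trace

    def _refit(self, params: np.ndarray) -> np.ndarray:
        """Correspondences at the current pose -> refit per-region affines."""
        mesh = self.template.with_vertices(
            self._positions(params, self.template.vertices, self.W))
        x_cur = self._positions(params, self.X0, self.WX)
        yf, _, _ = self._target_prox.query(x_cur)          # forward pairs
        cb, _, fb = mesh.proximity().query(self.Yt)         # backward pairs
        bary = _barycentric_on_faces(cb, mesh, fb)
        xb0 = np.einsum("ij,ijk->ik", bary, self.template.triangles[fb])
        wb = np.einsum("ij,ijk->ik", bary, self.W[self.template.faces[fb]])

        xp = np.vstack([self.X0, xb0])
        yp = np.vstack([yf, self.Yt])
        wp = np.vstack([self.WX, wb])
        new = np.empty_like(params)
        for r in range(self.R):
            new[r] = _weighted_affine_lstsq(xp, yp, wp[:, r] + 1e-12)
        return new


def _similarity_init(template: TriMesh, target: TriMesh, n_regions: int) -> np.ndarray:
    """Centroid + RMS-radius alignment as a starting similarity transform."""
    ct, cg = template.centroid, target.centroid
    rt = np.sqrt(((template.vertices - ct) ** 2).sum(axis=1).mean())
    rg = np.sqrt(((target.vertices - cg) ** 2).sum(axis=1).mean())
    s = rg / rt if rt > 0 else 1.0
    p = np.hstack([s * np.eye(3), (cg - s * ct)[:, None]])
    return np.tile(p, (n_regions, 1, 1))


def fit_affine_step(template: TriMesh, target: TriMesh,
                    policy: ConvergencePolicy = ConvergencePolicy(),
                    sampling: SurfaceSampling = DEFAULT_REG_SAMPLING):
    """STEP 1: fit a single affine transform by bidirectional ICP.

    Starts from a centroid/RMS-scale alignment when that improves the
    objective. Returns ``(deformed_template, AffineTransform, StepTrace)``;
    the final objective never exceeds the entry objective.
    """
    engine = _BlendedAffineEngine(template, target, np.ones((template.n_vertices, 1)),
                                  policy, sampling)
    vertices, params, trace = engine.run(_similarity_init(template, target, 1))
    transform = AffineTransform(params[0, :, :3], params[0, :, 3])
    return template.with_vertices(vertices), transform, trace


@dataclass
class PiecewiseAffineModel:
    """Partition-of-unity blend of per-region affine transforms.

    ``vertex_weights[i, r]`` is region r's blending weight at template
    vertex i (non-negative, rows sum to 1); the induced map is continuous
    over the mesh. ``apply`` maps points given per-point weights; for the
    template vertices use :meth:`apply_to_vertices`.
    """

    transforms: list[AffineTransform]
    vertex_weights: np.ndarray   # (n, R)
    region_centers: np.ndarray   # (R, 3), in entry coordinates
    bandwidth: float             # Gaussian blending bandwidth, mm

    @property
    def n_regions(self) -> int:
        return len(self.transforms)

    def apply(self, points: np.ndarray, weights: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(points, dtype=np.float64))
        for r, tf in enumerate(self.transforms):
            out += weights[:, r:r + 1] * tf.apply(points)
        return out

    def apply_to_vertices(self, vertices: np.ndarray) -> np.ndarray:
        return self.apply(vertices, self.vertex_weights)


def _region_weights(vertices: np.ndarray, n_regions: int, seed: int):
    """K-means regions with Gaussian partition-of-unity blending weights."""
    if n_regions == 1:
        return np.ones((len(vertices), 1)), vertices.mean(axis=0)[None, :], np.inf
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=n_regions, n_init=4, random_state=seed).fit(vertices)
    centers = km.cluster_centers_
    radii = []
    for r in range(n_regions):
        pts = vertices[km.labels_ == r]
        radii.append(np.sqrt(((pts - centers[r]) ** 2).sum(axis=1).mean())
                     if len(pts) else 0.0)
    sigma = 1.5 * float(np.mean(radii))
    if sigma <= 0:
        raise ValueError("degenerate k-means regions (zero bandwidth)")
    d2 = ((vertices[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-0.5 * d2 / sigma ** 2)
    w /= w.sum(axis=1, keepdims=True)
    return w, centers, sigma


def fit_piecewise_affine_step(template: TriMesh, target: TriMesh,
                              n_regions: int = 8,
                              policy: ConvergencePolicy = ConvergencePolicy(),
                              sampling: SurfaceSampling = DEFAULT_REG_SAMPLING,
                              seed: int = 0):
    """STEP 2: fit a continuous piece-wise affine deformation by ICP.

    Regions come from seeded k-means on the entry template vertices with
    Gaussian blending; with ``n_regions=1`` this is exactly the affine
    step. Returns ``(deformed_template, PiecewiseAffineModel, StepTrace)``.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    W, centers, sigma = _region_weights(template.vertices, n_regions, seed)
    support = W.sum(axis=0)
    if (support < 4).any():
        bad = int(np.argmin(support))
        raise ValueError(
            f"region {bad} has effective support {support[bad]:.2f} < 4 vertices; "
            f"use fewer regions")
    engine = _BlendedAffineEngine(template, target, W, policy, sampling)
    vertices, params, trace = engine.run(_similarity_init(template, target, n_regions))
    transforms = [AffineTransform(p[:, :3], p[:, 3]) for p in params]
    model = PiecewiseAffineModel(transforms, W, centers,
                                 float(sigma) if np.isfinite(sigma) else 0.0)
    return template.with_vertices(vertices), model, trace
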