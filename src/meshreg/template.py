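"""Template-model construction and the PCA statistical shape model.

A template model is built by shape matching: an initial subject's organ
mesh is registered onto every subject in the construction set, which
yields per-subject meshes sharing the initial mesh's vertex count and
topology (point-to-point correspondence by construction). The average
template is then the coordinate-wise mean of the corresponded vertices.

With corresponded meshes in hand, a statistical shape model is principal
component analysis of the stacked vertex coordinates: a mean shape plus
orthonormal displacement modes scaled by their standard deviations, so
new shapes are expressed by a few weight parameters (w1, w2, ...).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh_core import TriMesh, require_valid
from .pipeline import AlgorithmSpec, algorithm_a, run_registration

__all__ = [
    "TemplateModel",
    "ShapeModel",
    "build_template",
    "average_template",
    "fit_shape_model",
    "sample_shape",
    "project_shape",
]


@dataclass
class TemplateModel:
    """Correspondence-consistent mean mesh over k subjects."""

    mesh: TriMesh                      # the average template
    registered: list[TriMesh]          # per-subject meshes, shared topology

    @property
    def source_count(self) -> int:
        return len(self.registered)


@dataclass
class ShapeModel:
    """Mean shape + principal displacement modes.

    ``modes`` is (m, n, 3) with mutually orthonormal flattened rows;
    ``mode_scales`` are the per-mode standard deviations (mm),
    non-increasing. A shape with weights w is
    ``mean + sum_j w_j * mode_scales_j * modes_j``.
    """

    mean: TriMesh
    modes: np.ndarray
    mode_scales: np.ndarray

    @property
    def n_modes(self) -> int:
        return len(self.mode_scales)


def average_template(registered: list[TriMesh]) -> TriMesh:
    """Coordinate-wise mean of topology-sharing meshes (faces copied)."""
    if not registered:
        raise ValueError("no meshes to average")
    first = registered[0]
    for i, m in enumerate(registered[1:], start=2):
        if m.n_vertices != first.n_vertices or not np.array_equal(m.faces, first.faces):
            raise ValueError(f"mesh {i} does not share the template topology")
    mean = np.mean([m.vertices for m in registered], axis=0)
    return first.with_vertices(mean, name=first.name)


def build_template(initial: TriMesh, subjects: list[TriMesh],
                   spec: AlgorithmSpec | None = None,
                   iterations: int = 1) -> TemplateModel:
    """Build the average template by shape matching from k subjects.

    The initial mesh (by convention the first subject's organ) is
    registered onto each subject — Algorithm A by default, the most
    accurate variant — giving corresponded meshes that share its
    topology exactly; the template is their coordinate-wise mean.
    ``iterations > 1`` repeats the process using the current average as
    the new initial mesh.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    require_valid(initial, "initial template")
    spec = spec if spec is not None else algorithm_a()
    current = initial
    for _ in range(max(1, iterations)):
        registered = []
        for i, subject in enumerate(subjects, start=1):
            try:
                res = run_registration(current, subject, spec)
            except Exception as exc:
                raise RuntimeError(
                    f"template construction failed on subject {i} "
                    f"('{subject.name}'): {exc}") from exc
            registered.append(res.deformed_template)
        current = average_template(registered)
    return TemplateModel(mesh=current, registered=registered)


def fit_shape_model(template: TemplateModel, n_modes: int | None = None) -> ShapeModel:
    """PCA of the corresponded vertex coordinates about their mean.

    Modes are unit-norm principal displacement fields ordered by
    decreasing standard deviation (population convention, divisor k, so
    two training shapes project to weights exactly +-1); zero-variance
    directions are dropped. Reconstruction with all
    retained modes reproduces every training shape to round-off.
    """
    k = template.source_count
    if k < 2:
        raise ValueError("shape model needs at least 2 subjects")
    n = template.registered[0].n_vertices
    limit = min(k - 1, 3 * n)
    if n_modes is None:
        n_modes = limit
    if n_modes > limit:
        raise ValueError(f"n_modes must be <= min(k-1, 3n) = {limit}")
    X = np.stack([m.vertices.ravel() for m in template.registered])  # (k, 3n)
    mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - mean, full_matrices=False)
    scales = s / np.sqrt(k)
    nz = scales > max(scales[0], 1.0) * 1e-12 if len(scales) else scales > 0
    Vt, scales = Vt[nz][:n_modes], scales[nz][:n_modes]
    # canonical mode sign: largest-magnitude component positive
    for row in Vt:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return ShapeModel(
        mean=template.registered[0].with_vertices(mean.reshape(n, 3)),
        modes=Vt.reshape(-1, n, 3),
        mode_scales=scales)


def sample_shape(model: ShapeModel, weights) -> TriMesh:
    """Shape at the given mode weights: mean + sum_j w_j s_j mode_j."""
    w = np.atleast_1d(np.asarray(weights, dtype=np.float64))
    if len(w) > model.n_modes:
        raise ValueError(f"got {len(w)} weights for {model.n_modes} modes")
    v = model.mean.vertices.copy()
    for j, wj in enumerate(w):
        v += wj * model.mode_scales[j] * model.modes[j]
    return model.mean.with_vertices(v)


def project_shape(model: ShapeModel, mesh: TriMesh) -> np.ndarray:
    """Mode weights of a topology-sharing mesh (inverse of sample_shape)."""
    if mesh.n_vertices != model.mean.n_vertices:
        raise ValueError("mesh does not share the model topology")
    d = (mesh.vertices - model.mean.vertices).ravel()
    flat = model.modes.reshape(model.n_modes, -1)
    return (flat @ d) / model.mode_scales
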