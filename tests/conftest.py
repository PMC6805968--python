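"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from meshreg.mesh_core import TriMesh


def make_tetrahedron(scale: float = 1.0) -> TriMesh:
    """Regular tetrahedron, the smallest closed mesh."""
    v = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                 dtype=float) * scale
    f = np.array([[0, 1, 2], [0, 3, 1], [0, 2, 3], [1, 3, 2]])
    return TriMesh(v, f, name="tetrahedron")


def make_icosphere(subdivisions: int = 2, radius: float = 1.0,
                   center=(0.0, 0.0, 0.0)) -> TriMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(np.asarray(ico.vertices) + np.asarray(center),
                   np.asarray(ico.faces), name="icosphere")


def random_blob(seed: int, subdivisions: int = 1, radius: float = 10.0) -> TriMesh:
    """Random smoothly-perturbed sphere (valid closed mesh)."""
    rng = np.random.default_rng(seed)
    m = make_icosphere(subdivisions, radius)
    dirs = m.vertices / np.linalg.norm(m.vertices, axis=1, keepdims=True)
    k = rng.normal(size=(6, 3)) / radius
    amp = rng.normal(size=6)
    f = (amp[None, :] * np.cos(m.vertices @ k.T)).sum(axis=1)
    f *= 0.15 * radius / max(np.abs(f).max(), 1e-12)
    v = m.vertices + dirs * f[:, None] + rng.normal(scale=0.3 * radius, size=3)
    return TriMesh(v, m.faces, name=f"blob{seed}")


def brute_force_closest(points: np.ndarray, mesh: TriMesh):
    """Independent all-pairs point-to-triangle oracle via trimesh.

    For every query point evaluates trimesh's closest-point-on-triangle
    primitive against *all* faces and takes the minimum — no spatial
    pruning, no shared code with the package's query engine.
    """
    from trimesh.triangles import closest_point as tri_closest
    tris = mesh.triangles
    out = np.empty(len(points))
    for i, p in enumerate(np.atleast_2d(points)):
        c = tri_closest(tris, np.repeat(p[None, :], len(tris), axis=0))
        out[i] = np.linalg.norm(c - p, axis=1).min()
    return out


def brute_force_directed_mean(source: TriMesh, target: TriMesh, sampling) -> float:
    return float(brute_force_closest(sampling.sample(source), target).mean())


def brute_force_directed_max(source: TriMesh, target: TriMesh, sampling) -> float:
    return float(brute_force_closest(sampling.sample(source), target).max())


@pytest.fixture(scope="session")
def tetra() -> TriMesh:
    return make_tetrahedron()


@pytest.fixture(scope="session")
def sphere() -> TriMesh:
    return make_icosphere(2, 18.0)
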