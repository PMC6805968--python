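"""Synthetic pelvic-organ meshes and cohorts.

Stands in for clinical contour data: deterministic generators for the
four organs of the male pelvis (prostate, seminal vesicles, rectum,
bladder) with per-organ volume distributions matching published
200-patient statistics, smooth large-scale shape variation, and
reproducible seeding throughout. Base geometries are deliberately simple
but organ-appropriate: ellipsoids for the compact organs (prostate,
bladder), a bent tube with hemispherical caps for the rectum, and a pair
of strongly curved tubes for the seminal vesicles — so the cohort spans
both low- and high-curvature registration targets.

Volumes are drawn from truncated normal distributions whose *truncated*
mean is calibrated to the published mean (a naive truncated normal with
the published location parameter would be biased upward by several cm^3
for the strongly skew-clipped bladder). All linear dimensions are mm;
volumes are cm^3 externally and mm^3 internally (1 cm^3 = 1000 mm^3).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import optimize, stats

from .mesh_core import TriMesh, validate_mesh

__all__ = [
    "OrganSpec",
    "CohortSpec",
    "Subject",
    "Cohort",
    "ORGAN_VOLUME_TABLE",
    "ORGANS",
    "generate_organ",
    "generate_cohort",
    "perturb_mesh",
]

ORGANS = ("prostate", "seminal_vesicles", "rectum", "bladder")

#: (mean, sd, lower clip, upper clip) of organ volume in cm^3, matching
#: the 200-patient registration cohort statistics the generator emulates.
ORGAN_VOLUME_TABLE: dict[str, tuple[float, float, float, float]] = {
    "prostate": (26.8, 10.6, 9.0, 90.5),
    "seminal_vesicles": (7.0, 3.5, 1.3, 19.8),
    "rectum": (59.9, 25.2, 23.6, 203.6),
    "bladder": (150.0, 79.9, 55.1, 442.6),
}

_BASE_SHAPE_FOR_ORGAN = {
    "prostate": "ellipsoid",
    "bladder": "ellipsoid",
    "rectum": "bent_tube",
    "seminal_vesicles": "paired_crescent",
}

# axis ratios for the ellipsoidal organs (transverse, AP, cranio-caudal)
_ELLIPSOID_RATIOS = {
    "prostate": (1.0, 0.95, 0.85),
    "bladder": (1.0, 1.0, 1.15),
}


class SelfIntersectionError(ValueError):
    """Perturbation amplitude too large for the local feature size."""


#: Per-organ deformation distributions: (smoothness mm, amplitude mean,
#: amplitude sd, amplitude clip lo, clip hi), all mm. Correlation lengths
#: scale with organ size (~1.5 x the sphere-equivalent radius of the mean
#: volume) and amplitudes follow clinical variability: bladder and rectum
#: change shape most day to day (filling), the seminal vesicles least.
ORGAN_DEFORMATION_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    "prostate": (22.0, 3.0, 1.0, 1.0, 5.0),
    "seminal_vesicles": (18.0, 2.5, 0.8, 0.5, 4.5),
    "rectum": (36.0, 5.0, 1.5, 1.0, 9.0),
    "bladder": (45.0, 6.0, 2.0, 2.0, 9.0),
}

#: Per-subject base-shape parameter variation: for the tube organs the
#: bend angle (mean deg, sd deg, clip lo, clip hi) and tube aspect
#: (length/radius sd as a fraction); for the ellipsoidal organs a
#: per-axis log-normal jitter sd of the axis ratios. Pose and curvature
#: changes of this kind (rectal/vesicle bending, bladder filling) are the
#: large-scale variation a global transform cannot fully fit.
ORGAN_SHAPE_VARIATION: dict[str, dict] = {
    "prostate": {"ratio_sd": 0.08},
    "bladder": {"ratio_sd": 0.15},
    "rectum": {"bend": (60.0, 28.0, 10.0, 120.0), "aspect_sd": 0.22,
               "s_bend_sd": 25.0, "s_bend_max": 45.0},
    "seminal_vesicles": {"bend": (100.0, 30.0, 40.0, 150.0), "aspect_sd": 0.25,
                         "splay_sd": 18.0, "splay_max": 28.0},
}

#: Small-scale "detail" component added on top of the large-scale field:
#: amplitude and correlation length as fractions of the main field's.
DETAIL_AMPLITUDE_FRACTION = 0.15
DETAIL_SMOOTHNESS_FRACTION = 0.35


@dataclass(frozen=True)
class OrganSpec:
    """Specification of one synthetic organ mesh.

    deformation is (smoothness mm, amplitude mm): the correlation length
    and maximum magnitude of the smooth random surface-normal
    displacement field applied to the base shape.
    """

    organ: str
    target_volume: float | None = None     # cm^3; None -> table mean
    base_shape: str | None = None          # None -> organ default
    deformation: tuple[float, float] = (20.0, 0.0)
    detail: tuple[float, float] | None = None   # (smoothness, amplitude) mm
    bend_angle: float | None = None        # deg, tube shapes (None -> default)
    aspect: float | None = None            # tube length/radius (None -> default)
    s_bend_angle: float = 0.0              # deg, secondary orthogonal bend
    splay: float = 0.0                     # deg, paired crescents only
    axis_ratios: tuple[float, float, float] | None = None  # ellipsoids
    seed: int = 0
    subdivisions: int = 2                  # tessellation level

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.target_volume is not None and not self.target_volume > 0:
            raise ValueError("target_volume must be > 0")
        if self.deformation[1] < 0:
            raise ValueError("deformation amplitude must be >= 0")

    @property
    def resolved_volume(self) -> float:
        return (ORGAN_VOLUME_TABLE[self.organ][0]
                if self.target_volume is None else self.target_volume)

    @property
    def resolved_shape(self) -> str:
        return (_BASE_SHAPE_FOR_ORGAN[self.organ]
                if self.base_shape is None else self.base_shape)


@dataclass(frozen=True)
class CohortSpec:
    """A synthetic cohort: a template-construction set and a disjoint
    evaluation set, mirroring the first-k-patients / remaining-patients
    design of template-based registration studies.

    Per-organ volume distributions default to :data:`ORGAN_VOLUME_TABLE`.
    Deformation amplitudes (mm) are drawn per organ from a truncated
    normal; smoothness is the correlation length of the random field.
    """

    n_subjects: int = 20                   # evaluation subjects
    n_template: int = 5                    # template-construction subjects
    volume_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(ORGAN_VOLUME_TABLE))
    deformation_table: dict[str, tuple[float, float, float, float, float]] = field(
        default_factory=lambda: dict(ORGAN_DEFORMATION_TABLE))
    shape_variation: dict[str, dict] = field(
        default_factory=lambda: {k: dict(v) for k, v in ORGAN_SHAPE_VARIATION.items()})
    detail_fraction: float = DETAIL_AMPLITUDE_FRACTION
    master_seed: int = 0
    subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_template < 1:
            raise ValueError("n_subjects and n_template must be >= 1")
        if self.detail_fraction < 0:
            raise ValueError("detail_fraction must be >= 0")


@dataclass
class Subject:
    subject_id: str
    organs: dict[str, TriMesh]


@dataclass
class Cohort:
    spec: CohortSpec
    template_subjects: list[Subject]
    evaluation_subjects: list[Subject]

    def volumes(self) -> "pd.DataFrame":  # noqa: F821 - optional import
        import pandas as pd
        rows = []
        for group, subjects in (("template", self.template_subjects),
                                ("evaluation", self.evaluation_subjects)):
            for s in subjects:
                for organ, mesh in s.organs.items():
                    rows.append({"subject_id": s.subject_id, "group": group,
                                 "organ": organ,
                                 "volume_cm3": mesh.volume / 1000.0})
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Base shapes (unit scale, closed, deterministic)
# ----------------------------------------------------------------------

def _ellipsoid(ratios, subdivisions: int) -> TriMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    return TriMesh(np.asarray(ico.vertices) * np.asarray(ratios), np.asarray(ico.faces))


def _bend(v: np.ndarray, extent: float, angle: float, axis: int) -> np.ndarray:
    """Bend along z by mapping z to a circular arc in the (axis, z) plane."""
    if angle == 0:
        return v
    rc = extent / abs(angle)                  # arc radius
    sgn = np.sign(angle)
    phi = v[:, 2] / rc
    out = v.copy()
    out[:, axis] = sgn * ((sgn * v[:, axis] + rc) * np.cos(phi) - rc)
    out[:, 2] = (sgn * v[:, axis] + rc) * np.sin(phi)
    return out


def _bent_capsule(length: float, radius: float, bend_angle: float,
                  count: int, s_bend_angle: float = 0.0) -> TriMesh:
    """Capsule bent along a circular arc, optionally S-curved by a
    secondary bend in the orthogonal plane."""
    cap = trimesh.creation.capsule(height=length, radius=radius,
                                   count=[count, count])
    v = np.asarray(cap.vertices).copy()
    v[:, 2] -= v[:, 2].mean()
    extent = length + 2 * radius
    if s_bend_angle:
        v = _bend(v, extent, np.deg2rad(s_bend_angle), axis=1)
    v = _bend(v, extent, bend_angle, axis=0)
    return TriMesh(v, np.asarray(cap.faces))


def _merge(meshes: list[TriMesh]) -> TriMesh:
    verts, faces, off = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        off += m.n_vertices
    return TriMesh(np.vstack(verts), np.vstack(faces))


_DEFAULT_TUBE = {"bent_tube": (60.0, 4.5), "paired_crescent": (100.0, 5.0)}


def _rot_z(deg: float) -> np.ndarray:
    c, s = np.cos(np.deg2rad(deg)), np.sin(np.deg2rad(deg))
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _base_mesh(shape: str, subdivisions: int, organ: str,
               bend_angle: float | None = None, aspect: float | None = None,
               axis_ratios=None, splay: float = 0.0,
               s_bend: float = 0.0) -> TriMesh:
    count = 6 + 4 * subdivisions              # capsule tessellation level
    if shape == "ellipsoid":
        ratios = (axis_ratios if axis_ratios is not None
                  else _ELLIPSOID_RATIOS.get(organ, (1.0, 1.0, 1.0)))
        return _ellipsoid(ratios, subdivisions)
    if shape not in _DEFAULT_TUBE:
        raise ValueError(f"unknown base shape {shape!r}")
    bend0, aspect0 = _DEFAULT_TUBE[shape]
    bend = np.deg2rad(bend0 if bend_angle is None else bend_angle)
    asp = aspect0 if aspect is None else aspect
    if shape == "bent_tube":
        return _bent_capsule(length=asp, radius=1.0, bend_angle=bend,
                             count=count, s_bend_angle=s_bend)
    left = _bent_capsule(length=asp, radius=1.0, bend_angle=bend, count=count)
    lv = left.vertices @ _rot_z(-splay).T
    lv[:, 1] -= 1.8
    rv = left.vertices @ _rot_z(splay).T
    rv[:, 1] += 1.8
    return _merge([left.with_vertices(lv), left.with_vertices(rv)])


# ----------------------------------------------------------------------
# Smooth random deformation
# ----------------------------------------------------------------------

_N_WAVES = 16


def _smooth_field(points: np.ndarray, smoothness: float, amplitude: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Band-limited random scalar field, max |field| = amplitude.

    A superposition of random plane waves with wavelength ~ smoothness;
    an isotropic, smooth field in the spirit of low-order spherical
    harmonics but independent of any particular center.
    """
    if amplitude == 0:
        return np.zeros(len(points))
    k = rng.normal(size=(_N_WAVES, 3))
    k /= np.linalg.norm(k, axis=1, keepdims=True)
    k *= 2.0 * np.pi / smoothness
    phase = rng.uniform(0, 2 * np.pi, _N_WAVES)
    amp = rng.normal(size=_N_WAVES)
    f = (amp[None, :] * np.cos(points @ k.T + phase[None, :])).sum(axis=1)
    peak = np.abs(f).max()
    return f * (amplitude / peak) if peak > 0 else f


def perturb_mesh(mesh: TriMesh, smoothness: float, amplitude: float,
                 seed: int) -> TriMesh:
    """Displace vertices along their normals by a smooth random field.

    Topology is unchanged and no vertex moves further than ``amplitude``
    mm. Raises :class:`SelfIntersectionError` when the amplitude is too
    large for the mesh's feature size (detected by face flips).
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return mesh.copy()
    rng = np.random.default_rng(seed)
    normals = mesh.vertex_normals()
    f = _smooth_field(mesh.vertices, smoothness, amplitude, rng)
    out = mesh.with_vertices(mesh.vertices + normals * f[:, None])
    _check_integrity(mesh, out)
    return out


def _check_integrity(before: TriMesh, after: TriMesh) -> None:
    t0, t1 = before.triangles, after.triangles
    n0 = np.cross(t0[:, 1] - t0[:, 0], t0[:, 2] - t0[:, 0])
    n1 = np.cross(t1[:, 1] - t1[:, 0], t1[:, 2] - t1[:, 0])
    if (np.einsum("ij,ij->i", n0, n1) <= 0).any():
        raise SelfIntersectionError(
            "deformation flips faces (self-intersection); reduce the amplitude "
            "or increase the smoothness")
    # sheet-overlap check: a point just outside the surface must be outside
    from .mesh_core import points_inside
    eps = 0.25 * float(np.linalg.norm(
        after.vertices[after.faces[:, 0]] - after.vertices[after.faces[:, 1]],
        axis=1).min())
    probes = after.vertices + after.vertex_normals() * max(eps, 1e-6)
    if points_inside(after, probes).any():
        raise SelfIntersectionError(
            "deformed surface self-intersects (folded sheets); reduce the "
            "amplitude or increase the smoothness")


# ----------------------------------------------------------------------
# Organ and cohort generation
# ----------------------------------------------------------------------

def _scale_to_volume(mesh: TriMesh, volume_mm3: float) -> TriMesh:
    vol = mesh.volume
    if vol <= 0:
        raise ValueError("mesh volume is non-positive")
    s = (volume_mm3 / vol) ** (1.0 / 3.0)
    c = mesh.centroid
    return mesh.with_vertices(c + (mesh.vertices - c) * s)


def generate_organ(spec: OrganSpec) -> TriMesh:
    """Generate one closed organ mesh (coordinates mm, volume exact).

    Deterministic per (spec, seed); enclosed volume matches
    ``spec.resolved_volume`` (cm^3) to floating-point precision because
    the mesh is rescaled after deformation.
    """
    target_mm3 = spec.resolved_volume * 1000.0
    base = _base_mesh(spec.resolved_shape, spec.subdivisions, spec.organ,
                      spec.bend_angle, spec.aspect, spec.axis_ratios,
                      spec.splay, spec.s_bend_angle)
    base = _scale_to_volume(base, target_mm3)
    smooth, amp = spec.deformation
    if amp > 0:
        base = perturb_mesh(base, smooth, amp, spec.seed)
    if spec.detail is not None and spec.detail[1] > 0:
        base = perturb_mesh(base, spec.detail[0], spec.detail[1],
                            spec.seed + 1_000_003)
    if amp > 0 or (spec.detail is not None and spec.detail[1] > 0):
        base = _scale_to_volume(base, target_mm3)
    out = base.with_vertices(base.vertices, name=spec.organ)
    defects = validate_mesh(out)
    if defects:
        raise ValueError(f"generated mesh invalid: {defects[:3]}")
    return out


def _calibrated_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter so the truncated normal's mean equals ``mean``."""
    def trunc_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        return stats.truncnorm.mean(a, b, loc=mu, scale=sd) - mean
    return float(optimize.brentq(trunc_mean, lo - 10 * sd, hi + 10 * sd))


_loc_cache: dict[tuple[float, float, float, float], float] = {}


def _sample_truncnorm(mean, sd, lo, hi, rng, size=None, calibrate=True):
    if sd == 0:
        return np.full(size, mean) if size else mean
    key = (mean, sd, lo, hi)
    if calibrate:
        if key not in _loc_cache:
            _loc_cache[key] = _calibrated_loc(mean, sd, lo, hi)
        mu = _loc_cache[key]
    else:
        mu = mean
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                               random_state=rng)


def generate_cohort(spec: CohortSpec = CohortSpec()) -> Cohort:
    """Generate a template-construction set and a disjoint evaluation set.

    Subject seeds, volumes and deformation amplitudes all derive
    reproducibly from ``master_seed``; two calls with the same spec
    return identical cohorts.
    """
    rng = np.random.default_rng(spec.master_seed)

    def make_subject(idx: int, group: str) -> Subject:
        organs = {}
        for organ in ORGANS:
            mean, sd, lo, hi = spec.volume_distributions[organ]
            vol = float(_sample_truncnorm(mean, sd, lo, hi, rng))
            smooth, a_mean, a_sd, a_lo, a_hi = spec.deformation_table[organ]
            amp = float(_sample_truncnorm(a_mean, a_sd, a_lo, a_hi, rng,
                                          calibrate=False))
            seed = int(rng.integers(2 ** 31))
            detail = (DETAIL_SMOOTHNESS_FRACTION * smooth,
                      spec.detail_fraction * amp)
            var = spec.shape_variation.get(organ, {})
            bend = aspect = ratios = None
            splay = s_bend = 0.0
            if "bend" in var:
                b_mean, b_sd, b_lo, b_hi = var["bend"]
                bend = float(_sample_truncnorm(b_mean, b_sd, b_lo, b_hi, rng,
                                               calibrate=False))
                a0 = _DEFAULT_TUBE[_BASE_SHAPE_FOR_ORGAN[organ]][1]
                aspect = float(a0 * np.exp(var.get("aspect_sd", 0.0)
                                           * rng.standard_normal()))
                splay = float(np.clip(var.get("splay_sd", 0.0) * rng.standard_normal(),
                                      -var.get("splay_max", 90.0),
                                      var.get("splay_max", 90.0)))
                s_bend = float(np.clip(var.get("s_bend_sd", 0.0) * rng.standard_normal(),
                                       -var.get("s_bend_max", 90.0),
                                       var.get("s_bend_max", 90.0)))
            if "ratio_sd" in var:
                base_r = np.asarray(_ELLIPSOID_RATIOS.get(organ, (1, 1, 1)))
                ratios = tuple(base_r * np.exp(var["ratio_sd"]
                                               * rng.standard_normal(3)))
            # deterministic retry with attenuated amplitude and shape
            # variation if the sampled draw folds the surface (rare)
            b_mean = var["bend"][0] if "bend" in var else 0.0
            for attempt in range(8):
                att = 0.8 ** attempt
                try:
                    organs[organ] = generate_organ(OrganSpec(
                        organ=organ, target_volume=vol,
                        deformation=(smooth, amp * att),
                        detail=(detail[0], detail[1] * att),
                        bend_angle=(None if bend is None
                                    else b_mean + (bend - b_mean) * att),
                        aspect=aspect, axis_ratios=ratios,
                        splay=splay * att, s_bend_angle=s_bend * att,
                        seed=seed + 7919 * attempt,
                        subdivisions=spec.subdivisions))
                    break
                except SelfIntersectionError:
                    if attempt == 7:
                        raise
        return Subject(subject_id=f"{group}{idx:03d}", organs=organs)

    template = [make_subject(i + 1, "tpl") for i in range(spec.n_template)]
    evaluation = [make_subject(i + 1, "eval") for i in range(spec.n_subjects)]
    return Cohort(spec=spec, template_subjects=template,
                  evaluation_subjects=evaluation)
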