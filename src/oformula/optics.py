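"""Exact sequential ray tracing through rotationally symmetric conic surfaces.

The tracer works on the optical axis ``z`` with distances in millimetres and
light travelling towards +z.  A surface is a conic of revolution

    z(r) = apex_z + c r^2 / (1 + sqrt(1 - (1+k) c^2 r^2)),

with curvature ``c = 1/radius`` (signed: positive when the centre of curvature
lies towards +z) and conic constant ``k`` (sphere k = 0, paraboloid k = -1;
a corneal eccentricity ``e`` corresponds to k = -e^2).  Refraction is the
vector form of Snell's law.  A 2x2 Gaussian (paraxial) reduction of the same
system serves as an independent small-angle oracle for the exact trace.

Everything here is deterministic: no randomness, fixed tolerances
(intersection polish 1e-12 mm, at most 50 Newton steps), and a fixed
hexapolar ray-fan pattern for spot metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Ray",
    "Surface",
    "OpticalSystem",
    "ParaxialSolution",
    "TraceError",
    "RayMissError",
    "TotalInternalReflectionError",
    "conic_sag",
    "intersect",
    "refract",
    "trace",
    "trace_to_image",
    "paraxial_power",
    "rms_spot_radius",
    "hexapolar_fan",
]

_NEWTON_TOL = 1e-12  # mm
_NEWTON_MAXITER = 50


class TraceError(RuntimeError):
    """Base class for ray-tracing failures; carries the offending surface index."""

    def __init__(self, message: str, surface_index: int | None = None):
        super().__init__(message)
        self.surface_index = surface_index


class RayMissError(TraceError):
    """Ray has no forward intersection within the surface's clear aperture."""


class TotalInternalReflectionError(TraceError):
    """Snell's law admits no transmitted ray (sin(theta_t) would exceed 1)."""


@dataclass(frozen=True)
class Ray:
    """A ray segment: origin in mm and a unit direction with positive z."""

    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        if o.shape != (3,) or d.shape != (3,):
            raise ValueError("origin and direction must be 3-vectors")
        norm = np.linalg.norm(d)
        if abs(norm - 1.0) > 1e-9:
            d = d / norm
        if d[2] <= 0:
            raise ValueError("ray direction must have a positive z component")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / np.linalg.norm(d))

    def point_at(self, z: float) -> np.ndarray:
        """Propagate the ray to axial position ``z`` (mm)."""
        t = (z - self.origin[2]) / self.direction[2]
        return self.origin + t * self.direction

    def reversed(self) -> "Ray":
        """The same line traversed backwards, mirrored through z -> -z.

        Used for path-reversibility checks: mirror the system, retrace.
        """
        o = self.origin.copy()
        d = -self.direction
        return Ray(np.array([o[0], o[1], -o[2]]), np.array([d[0], d[1], -d[2]]))


@dataclass(frozen=True)
class Surface:
    """One refracting conic surface.

    ``radius`` is signed (positive when the centre of curvature is towards
    +z); ``math.inf`` marks a planar surface.
    """

    apex_z: float
    radius: float
    n_before: float
    n_after: float
    conic_k: float = 0.0
    half_aperture: float = 6.0

    def __post_init__(self):
        if self.radius == 0:
            raise ValueError("radius must be nonzero; use math.inf for planar")
        if self.half_aperture <= 0:
            raise ValueError("half_aperture must be positive")
        if self.n_before < 1 or self.n_after < 1:
            raise ValueError("refractive indices must be >= 1")

    @property
    def is_planar(self) -> bool:
        return math.isinf(self.radius)

    @property
    def curvature(self) -> float:
        return 0.0 if self.is_planar else 1.0 / self.radius

    @property
    def power_diopters(self) -> float:
        """Paraxial surface power (n'-n)/R in diopters (R in mm)."""
        return 0.0 if self.is_planar else 1000.0 * (self.n_after - self.n_before) / self.radius


@dataclass
class OpticalSystem:
    """Ordered refracting surfaces along +z plus the image (evaluation) plane."""

    surfaces: list
    image_z: float

    def __post_init__(self):
        self.surfaces = list(self.surfaces)
        if not self.surfaces:
            raise ValueError("system needs at least one surface")
        zs = [s.apex_z for s in self.surfaces]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("surface apex positions must be strictly increasing")
        for a, b in zip(self.surfaces, self.surfaces[1:]):
            if abs(a.n_after - b.n_before) > 1e-12:
                raise ValueError(
                    f"media mismatch: n_after={a.n_after} vs next n_before={b.n_before}"
                )

    @property
    def n_object(self) -> float:
        return self.surfaces[0].n_before

    @property
    def n_image(self) -> float:
        return self.surfaces[-1].n_after

    def mirrored(self) -> "OpticalSystem":
        """The system traversed in the opposite direction, mapped through z -> -z."""
        rev = [
            Surface(
                apex_z=-s.apex_z,
                radius=-s.radius,
                n_before=s.n_after,
                n_after=s.n_before,
                conic_k=s.conic_k,
                half_aperture=s.half_aperture,
            )
            for s in reversed(self.surfaces)
        ]
        return OpticalSystem(rev, image_z=-self.surfaces[0].apex_z + 10.0)


def conic_sag(r, c: float, k: float = 0.0):
    """Axial sag z(r) of a conic with curvature ``c`` (1/mm) and conic constant ``k``.

    Raises ``ValueError`` outside the conic's valid zone (sqrt argument < 0).
    """
    r = np.asarray(r, dtype=float)
    arg = 1.0 - (1.0 + k) * c * c * r * r
    if np.any(arg < 0):
        raise ValueError("ray height beyond the conic's valid zone")
    out = c * r * r / (1.0 + np.sqrt(arg))
    return out if out.ndim else float(out)


def refract(direction, normal, n1: float, n2: float) -> np.ndarray:
    """Vector Snell refraction of a unit ``direction`` at a unit ``normal``."""
    d = np.asarray(direction, dtype=float)
    n = np.asarray(normal, dtype=float)
    cos_i = -float(np.dot(d, n))
    if cos_i < 0:  # flip the normal to face the incoming medium
        n = -n
        cos_i = -cos_i
    mu = n1 / n2
    sin2_t = mu * mu * (1.0 - cos_i * cos_i)
    if sin2_t > 1.0:
        raise TotalInternalReflectionError("total internal reflection")
    cos_t = math.sqrt(1.0 - sin2_t)
    t = mu * d + (mu * cos_i - cos_t) * n
    return t / np.linalg.norm(t)


def _refract_arrays(d: np.ndarray, n: np.ndarray, n1: float, n2: float,
                    surface_index: int | None = None) -> np.ndarray:
    cos_i = -np.einsum("ij,ij->i", d, n)
    flip = cos_i < 0
    n = np.where(flip[:, None], -n, n)
    cos_i = np.abs(cos_i)
    mu = n1 / n2
    sin2_t = mu * mu * (1.0 - cos_i * cos_i)
    if np.any(sin2_t > 1.0):
        raise TotalInternalReflectionError("total internal reflection", surface_index)
    cos_t = np.sqrt(1.0 - sin2_t)
    t = mu * d + ((mu * cos_i - cos_t))[:, None] * n
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _intersect_arrays(o: np.ndarray, d: np.ndarray, surface: Surface,
                      surface_index: int | None = None):
    """Vectorised ray/conic intersection -> (points, outward-facing normals).

    Spheres and planes solve in closed form; for k != 0 the closed-form root
    of the implicit conic is polished by Newton iteration (1e-12 mm, <=50
    steps).  Raises ``RayMissError`` when any ray has no forward intersection
    on the apex sheet inside the clear aperture.
    """
    c = surface.curvature
    k = surface.conic_k
    dz = o[:, 2] - surface.apex_z

    if surface.is_planar:
        t = -dz / d[:, 2]
        if np.any(t <= 1e-9):
            raise RayMissError("no forward intersection with the plane", surface_index)
    else:
        # implicit conic:  c (x^2 + y^2) + c (1+k) Z^2 - 2 Z = 0,  Z = z - apex_z
        kk = 1.0 + k
        A = c * (d[:, 0] ** 2 + d[:, 1] ** 2 + kk * d[:, 2] ** 2)
        B = 2.0 * c * (o[:, 0] * d[:, 0] + o[:, 1] * d[:, 1] + kk * dz * d[:, 2]) - 2.0 * d[:, 2]
        C = c * (o[:, 0] ** 2 + o[:, 1] ** 2 + kk * dz * dz) - 2.0 * dz
        disc = B * B - 4.0 * A * C
        if np.any(disc < 0):
            raise RayMissError("ray misses the conic surface", surface_index)
        sq = np.sqrt(disc)
        lin = np.abs(A) < 1e-14
        with np.errstate(divide="ignore", invalid="ignore"):
            q = -0.5 * (B + np.sign(B + (B == 0)) * sq)  # numerically stable quadratic
            r1 = np.where(lin, -C / B, q / A)
            r2 = np.where(lin, -C / B, np.where(np.abs(q) > 0, C / q, r1))
        t = np.full(len(o), np.nan)
        for cand in (np.minimum(r1, r2), np.maximum(r1, r2)):
            p = o + cand[:, None] * d
            r2h = p[:, 0] ** 2 + p[:, 1] ** 2
            arg = 1.0 - kk * c * c * r2h
            need = np.isnan(t) & (cand > 1e-9) & (arg >= 0)
            if np.any(need):
                s = np.sqrt(np.where(need, arg, 1.0))
                sag = c * r2h / (1.0 + s)
                on_branch = need & (np.abs((p[:, 2] - surface.apex_z) - sag) < 1e-6)
                t[on_branch] = cand[on_branch]
        if np.any(np.isnan(t)):
            raise RayMissError("no forward intersection with the surface", surface_index)
        if k != 0.0:
            for _ in range(_NEWTON_MAXITER):
                p = o + t[:, None] * d
                Z = p[:, 2] - surface.apex_z
                r2h = p[:, 0] ** 2 + p[:, 1] ** 2
                F = c * (r2h + kk * Z * Z) - 2.0 * Z
                dF = (
                    c * (2.0 * (p[:, 0] * d[:, 0] + p[:, 1] * d[:, 1]) + 2.0 * kk * Z * d[:, 2])
                    - 2.0 * d[:, 2]
                )
                step = F / dF
                t = t - step
                if np.all(np.abs(step) < _NEWTON_TOL):
                    break

    points = o + t[:, None] * d
    r = np.hypot(points[:, 0], points[:, 1])
    if np.any(r > surface.half_aperture + 1e-12):
        raise RayMissError("ray beyond the surface's clear aperture", surface_index)
    if surface.is_planar:
        normals = np.tile([0.0, 0.0, -1.0], (len(o), 1))
    else:
        Z = points[:, 2] - surface.apex_z
        normals = np.column_stack(
            [c * points[:, 0], c * points[:, 1], c * (1.0 + k) * Z - 1.0]
        )
        normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return points, normals


def intersect(ray: Ray, surface: Surface):
    """Intersection point and unit normal (facing the incoming medium) for one ray."""
    pts, nrm = _intersect_arrays(ray.origin[None, :], ray.direction[None, :], surface)
    normal = nrm[0]
    if np.dot(normal, ray.direction) > 0:
        normal = -normal
    return pts[0], normal


def trace_bundle(system: OpticalSystem, origins: np.ndarray, dirs: np.ndarray) -> np.ndarray:
    """Trace an (N, 3) bundle through every surface; return (N, 3) image-plane points."""
    o = np.array(origins, dtype=float, copy=True)
    d = np.array(dirs, dtype=float, copy=True)
    for i, s in enumerate(system.surfaces):
        o, normals = _intersect_arrays(o, d, s, surface_index=i)
        d = _refract_arrays(d, normals, s.n_before, s.n_after, surface_index=i)
    tt = (system.image_z - o[:, 2]) / d[:, 2]
    return o + tt[:, None] * d


def trace(system: OpticalSystem, ray: Ray) -> list:
    """Sequential exact trace.  Returns the ray segments: the entry ray, one
    segment leaving each surface, and a final zero-length segment whose origin
    is the image-plane point."""
    segments = [ray]
    current = ray
    for i, s in enumerate(system.surfaces):
        pts, nrm = _intersect_arrays(current.origin[None, :], current.direction[None, :], s,
                                     surface_index=i)
        point, normal = pts[0], nrm[0]
        if np.dot(normal, current.direction) > 0:
            normal = -normal
        try:
            new_dir = refract(current.direction, normal, s.n_before, s.n_after)
        except TotalInternalReflectionError as exc:
            raise TotalInternalReflectionError(str(exc), i) from None
        current = Ray(point, new_dir)
        segments.append(current)
    image_point = current.point_at(system.image_z)
    segments.append(Ray(image_point, current.direction))
    return segments


def trace_to_image(system: OpticalSystem, ray: Ray) -> np.ndarray:
    """Image-plane (x, y, z) of a single traced ray."""
    return trace(system, ray)[-1].origin


@dataclass(frozen=True)
class ParaxialSolution:
    """Gaussian constants of a system: equivalent power and cardinal points."""

    power_d: float                 # equivalent power, diopters
    back_focal_distance: float     # last vertex -> rear focal point, mm
    front_focal_distance: float    # first vertex -> front focal point, mm (negative = left)
    front_principal_z: float       # absolute z of front principal plane, mm
    back_principal_z: float        # absolute z of back principal plane, mm


def paraxial_power(system: OpticalSystem) -> ParaxialSolution:
    """Gaussian reduction of the system by a 2x2 refraction/translation cascade.

    State vector is (y, n*u); powers are in 1/mm internally and reported in
    diopters.  For a single surface this reduces to (n2-n1)/R.
    """
    M = np.eye(2)
    for i, s in enumerate(system.surfaces):
        if i > 0:
            prev = system.surfaces[i - 1]
            gap = (s.apex_z - prev.apex_z) / prev.n_after  # reduced thickness
            M = np.array([[1.0, gap], [0.0, 1.0]]) @ M
        phi = s.power_diopters / 1000.0  # 1/mm
        M = np.array([[1.0, 0.0], [-phi, 1.0]]) @ M
    if abs(M[1, 0]) < 1e-15:
        raise ValueError("afocal system has no equivalent power")
    n0 = system.n_object
    n_img = system.n_image
    K = -M[1, 0]
    bfd = -n_img * M[0, 0] / M[1, 0]
    ffd = n0 * M[1, 1] / M[1, 0]
    z_first = system.surfaces[0].apex_z
    z_last = system.surfaces[-1].apex_z
    return ParaxialSolution(
        power_d=K * 1000.0,
        back_focal_distance=bfd,
        front_focal_distance=ffd,
        front_principal_z=z_first + ffd + n0 / K,
        back_principal_z=z_last + bfd - n_img / K,
    )


def hexapolar_fan(pupil_diameter: float, n_rings: int = 6) -> np.ndarray:
    """Fixed hexapolar (x, y) sampling of a circular pupil: centre point plus
    ``n_rings`` rings with 6*i points on ring i.  127 points for 6 rings."""
    if pupil_diameter <= 0:
        raise ValueError("pupil_diameter must be positive")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    pts = [(0.0, 0.0)]
    rmax = pupil_diameter / 2.0
    for i in range(1, n_rings + 1):
        radius = rmax * i / n_rings
        for j in range(6 * i):
            ang = 2.0 * math.pi * j / (6 * i)
            pts.append((radius * math.cos(ang), radius * math.sin(ang)))
    return np.asarray(pts)


def rms_spot_radius(system: OpticalSystem, pupil_diameter: float, n_rings: int = 6) -> float:
    """RMS radial spot size (mm) at the image plane for a parallel axial fan."""
    if n_rings < 3:
        raise ValueError("n_rings must be >= 3 for a meaningful spot metric")
    xy = hexapolar_fan(pupil_diameter, n_rings)
    z0 = system.surfaces[0].apex_z - 5.0
    origins = np.column_stack([xy[:, 0], xy[:, 1], np.full(len(xy), z0)])
    dirs = np.tile([0.0, 0.0, 1.0], (len(xy), 1))
    pts = trace_bundle(system, origins, dirs)
    return float(np.sqrt(np.mean(pts[:, 0] ** 2 + pts[:, 1] ** 2)))
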