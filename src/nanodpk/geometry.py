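"""Analytic geometry for nanoparticle dose rescaling.

Conventions: continuous coordinates in nm; the nanosphere is centred at
the origin; the nanorod is a finite cylinder of radius ``r`` and
half-length ``h`` centred at the origin with its axis along z.

For a source point (SP) inside the particle and a tally point (TP)
outside, three path quantities are defined along the SP->TP segment:

GPL
    geometric path length, the Euclidean SP->TP distance;
DTI
    distance traversed inside the particle, found from the parametric
    point ``x(l) = x_S (1 - l) + x_T l`` and the particle surface
    equation (quadratic for the sphere/rod wall, linear for the rod caps);
MPL
    modified (water-equivalent) path length, ``GPL + (alpha - 1) DTI``.

The rod's exterior is split into a long-axis region (inside the double
cone of half-angle ``omega``, tan(omega) = r/h, beyond the caps) and a
short-axis region (outside the complementary cone of half-angle ``theta``,
tan(theta) = h/r, beyond the wall); dose profiles are scored in 1-nm-thick
frustum pairs (long axis) or frustum-bounded hollow cylinders (short
axis).  Boundary points (equality in the cone conditions) belong to
neither region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .materials import RescalingFactor

__all__ = [
    "Point3",
    "Sphere",
    "Rod",
    "PathDecomposition",
    "sample_in_sphere",
    "sample_in_rod",
    "gpl",
    "dti_sphere",
    "dti_rod",
    "classify_rod_region",
    "mpl",
    "scoring_volume_long",
    "scoring_volume_short",
]


@dataclass(frozen=True)
class Point3:
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError("coordinates must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Sphere:
    """Nanosphere of radius ``radius`` nm centred at the origin."""

    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


@dataclass(frozen=True)
class Rod:
    """Finite cylinder (nanorod): radius ``radius``, half-length
    ``half_length``, axis along z, centred at the origin."""

    radius: float
    half_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("radius and half_length must be positive")

    def contains(self, p: Point3) -> bool:
        return p.x**2 + p.y**2 <= self.radius**2 and abs(p.z) <= self.half_length


@dataclass(frozen=True)
class PathDecomposition:
    """(GPL, DTI, MPL) for one SP/TP pair."""

    gpl: float
    dti: float
    mpl: float

    def __post_init__(self) -> None:
        if not (0 <= self.dti <= self.gpl + 1e-9):
            raise ValueError("need 0 <= dti <= gpl")
        if self.mpl < self.gpl - 1e-9:
            raise ValueError("mpl < gpl implies alpha < 1")


# ---------------------------------------------------------------------------
# Sampling

def sample_in_sphere(s: Sphere, rng: np.random.Generator, size: int | None = None):
    """Uniform-by-volume point(s) in the sphere.

    Returns a :class:`Point3` for ``size=None``, else an (size, 3) array.
    """
    n = 1 if size is None else size
    r = s.radius * rng.random(n) ** (1.0 / 3.0)
    costh = 2.0 * rng.random(n) - 1.0
    sinth = np.sqrt(1.0 - costh**2)
    phi = 2.0 * math.pi * rng.random(n)
    pts = np.column_stack(
        [r * sinth * np.cos(phi), r * sinth * np.sin(phi), r * costh]
    )
    if size is None:
        return Point3(*pts[0])
    return pts


def sample_in_rod(rod: Rod, rng: np.random.Generator, size: int | None = None):
    """Uniform-by-volume point(s) in the cylinder."""
    n = 1 if size is None else size
    rho = rod.radius * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    z = rod.half_length * (2.0 * rng.random(n) - 1.0)
    pts = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    if size is None:
        return Point3(*pts[0])
    return pts


# ---------------------------------------------------------------------------
# Path quantities

def gpl(ps: Point3, pt: Point3) -> float:
    """Geometric path length: Euclidean SP->TP distance (nm)."""
    return math.dist((ps.x, ps.y, ps.z), (pt.x, pt.y, pt.z))


def dti_sphere_vec(ps: np.ndarray, pt: np.ndarray, radius: float) -> np.ndarray:
    """Vectorised sphere DTI for (n, 3) SP/TP arrays (SP inside, TP outside)."""
    d = pt - ps
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", ps, d)
    c = np.einsum("ij,ij->i", ps, ps) - radius**2
    disc = b**2 - 4.0 * a * c
    # SP inside (c <= 0), TP outside => exactly one root in [0, 1]
    lam = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    return lam * np.sqrt(a)


def dti_sphere(ps: Point3, pt: Point3, s: Sphere) -> float:
    """Distance traversed inside the sphere along the SP->TP segment.

    SP must lie inside (|SP| <= R0) and TP strictly outside; the exit
    point solves the parametric quadratic on the sphere surface.
    """
    a_s, a_t = ps.as_array(), pt.as_array()
    if np.dot(a_s, a_s) > s.radius**2 * (1 + 1e-12):
        raise ValueError("source point must be inside the sphere")
    if np.dot(a_t, a_t) <= s.radius**2:
        raise ValueError("tally point must be outside the sphere")
    return float(dti_sphere_vec(a_s[None, :], a_t[None, :], s.radius)[0])


def dti_rod_vec(ps: np.ndarray, pt: np.ndarray, radius: float, h: float) -> np.ndarray:
    """Vectorised first-exit rod DTI for (n, 3) SP/TP arrays.

    Minimum valid ``lambda`` among the cap-plane solutions (z(l) = +-h
    with the lateral constraint) and the wall quadratic (x^2 + y^2 = r^2
    with |z| <= h).
    """
    d = pt - ps
    n = ps.shape[0]
    lam_best = np.full(n, np.inf)

    # caps z = +h and z = -h
    dz = d[:, 2]
    for zcap in (h, -h):
        with np.errstate(divide="ignore", invalid="ignore"):
            lam = (zcap - ps[:, 2]) / dz
            x = ps[:, 0] + lam * d[:, 0]
            y = ps[:, 1] + lam * d[:, 1]
        ok = (
            np.isfinite(lam)
            & (lam >= 0.0)
            & (lam <= 1.0)
            & (x**2 + y**2 <= radius**2 * (1 + 1e-12))
        )
        lam_best = np.where(ok & (lam < lam_best), lam, lam_best)

    # lateral wall x^2 + y^2 = r^2
    a = d[:, 0] ** 2 + d[:, 1] ** 2
    b = 2.0 * (ps[:, 0] * d[:, 0] + ps[:, 1] * d[:, 1])
    c = ps[:, 0] ** 2 + ps[:, 1] ** 2 - radius**2
    disc = b**2 - 4.0 * a * c
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = (-b + np.sqrt(np.maximum(disc, 0.0))) / (2.0 * a)
    z = ps[:, 2] + lam * d[:, 2]
    ok = (
        np.isfinite(lam)
        & (disc >= 0)
        & (a > 0)
        & (lam >= 0.0)
        & (lam <= 1.0)
        & (np.abs(z) <= h * (1 + 1e-12))
    )
    lam_best = np.where(ok & (lam < lam_best), lam, lam_best)
    return lam_best * np.linalg.norm(d, axis=1)


def dti_rod(ps: Point3, pt: Point3, rod: Rod) -> float:
    """Distance traversed inside the rod along the SP->TP segment.

    Exact first exit over the full boundary (both caps and the lateral
    wall) — the per-region single-surface solution is a special case.
    """
    if not rod.contains(ps):
        raise ValueError("source point must be inside the rod")
    if rod.contains(pt):
        raise ValueError("tally point must be outside the rod")
    out = dti_rod_vec(
        ps.as_array()[None, :], pt.as_array()[None, :], rod.radius, rod.half_length
    )[0]
    if not np.isfinite(out):
        raise ValueError("no boundary crossing found (degenerate segment)")
    return float(out)


def classify_rod_region(p: Point3, rod: Rod) -> str:
    """Classify an exterior point as 'long_axis', 'short_axis' or 'neither'.

    Long axis: sqrt(x^2+y^2)/|z| < tan(omega) = r/h and |z| > h.
    Short axis: |z|/sqrt(x^2+y^2) < tan(theta) = h/r and sqrt(x^2+y^2) > r.
    Strict inequalities; cone-boundary points are 'neither'.
    """
    if rod.contains(p):
        raise ValueError("point must be outside the rod")
    rho = math.hypot(p.x, p.y)
    az = abs(p.z)
    r, h = rod.radius, rod.half_length
    if az > h and rho * h < az * r:       # rho/az < r/h
        return "long_axis"
    if rho > r and az * r < rho * h:      # az/rho < h/r
        return "short_axis"
    return "neither"


def mpl(gpl_value: float, dti_value: float, f: RescalingFactor) -> float:
    """Modified path length: GPL + (alpha - 1) * DTI."""
    if not (0 <= dti_value <= gpl_value):
        raise ValueError("need 0 <= dti <= gpl")
    return gpl_value + (f.alpha - 1.0) * dti_value


def scoring_volume_long(d: float, rod: Rod, t: float = 1.0) -> float:
    """Volume (nm^3) of the long-axis scoring solid at surface distance d.

    Two symmetric cone frustums (apex at the origin, half-angle omega)
    between the axial planes |z| in [h+d, h+d+t]:
    ``V = (2 pi tan^2(omega) / 3) ((h+d+t)^3 - (h+d)^3)``.
    """
    if d < 0 or t <= 0:
        raise ValueError("need d >= 0 and t > 0")
    tan_w = rod.radius / rod.half_length
    a = rod.half_length + d
    return (2.0 * math.pi * tan_w**2 / 3.0) * ((a + t) ** 3 - a**3)


def scoring_volume_short(d: float, rod: Rod, t: float = 1.0) -> float:
    """Volume (nm^3) of the short-axis scoring solid at surface distance d.

    Hollow cylinder between lateral radii s in [r+d, r+d+t] bounded by the
    short-axis cones |z| < s h / r:
    ``V = (4 pi h / (3 r)) ((r+d+t)^3 - (r+d)^3)``.
    """
    if d < 0 or t <= 0:
        raise ValueError("need d >= 0 and t > 0")
    a = rod.radius + d
    return (4.0 * math.pi * rod.half_length / (3.0 * rod.radius)) * (
        (a + t) ** 3 - a**3
    )
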