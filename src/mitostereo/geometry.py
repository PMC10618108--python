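"""Parametric 3D organelle solids and their exact section/projection measures.

Bodies are spheres, spherocylinders (cylinders with hemispherical caps, the
"dumbbell" model for mitosomes) and half-spheres (the spindle-pole-body model,
flat face resting on the nuclear envelope).  All lengths are nanometres,
areas nm^2, volumes nm^3; micrometre conversions happen only at I/O.

The cutting axis is the global z axis.  A section is a half-open slab
``[z_lo, z_hi)``.  Two profile models are supported:

* thin-plane: the exact cross-section of the body with the slab mid-plane,
  emulating a tomographic slice of negligible thickness;
* shadow (overprojected): the full projection of the body's intersection
  with the slab onto the section plane, emulating a conventional TEM section
  of finite thickness imaged in projection.

Cross-section and shadow areas of spheres and half-spheres are closed form.
For spherocylinders they are computed from the exact chord-width function
``w(alpha) = 2 sqrt(g(alpha))`` where ``g`` is a concave maximum of
piecewise quadratics (distance from a plane point to the cap-centre segment,
minimised over the slab); the area integral uses a sine substitution so the
square-root profile edges are integrated without endpoint singularities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

NM3_PER_UM3 = 1.0e9
UM3_PER_NM3 = 1.0e-9

KINDS = ("sphere", "spherocylinder", "half_sphere")
_AXIS_TOL = 1e-9
# panels for the width-function quadrature; 512 Simpson intervals resolve
# the profile boundary to <1e-6 relative area error for realistic shapes
_N_SIMPSON = 512
_SLAB_CHUNK = 128


@dataclass(frozen=True)
class Slab:
    """One section: the half-open slab [z_lo, z_hi) along the cutting axis."""

    z_lo: float
    z_hi: float

    def __post_init__(self) -> None:
        if not self.z_hi > self.z_lo:
            raise ValueError(f"slab must have positive thickness, got [{self.z_lo}, {self.z_hi})")

    @property
    def thickness(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def mid_z(self) -> float:
        return 0.5 * (self.z_lo + self.z_hi)


@dataclass(frozen=True, eq=False)
class BodyShape:
    """A parametric solid.

    Parameters
    ----------
    kind:
        ``sphere``, ``spherocylinder`` or ``half_sphere``.
    center:
        Body centre (sphere/spherocylinder: centroid of the bounding segment;
        half_sphere: centre of the flat face), nm.
    radius:
        Sphere/cap radius, nm.
    axis:
        Unit direction (spherocylinder: long axis; half_sphere: outward
        normal of the flat face, pointing into the cap).  Ignored for
        spheres.
    length:
        Spherocylinder total tip-to-tip length L including caps, nm;
        ``L >= 2 r`` (equality degenerates to a sphere).
    """

    kind: str
    center: np.ndarray
    radius: float
    axis: Optional[np.ndarray] = None
    length: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown body kind {self.kind!r}; expected one of {KINDS}")
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        if self.kind in ("spherocylinder", "half_sphere"):
            if self.axis is None:
                raise ValueError(f"{self.kind} requires an axis")
            ax = np.asarray(self.axis, dtype=float).reshape(3)
            if abs(np.linalg.norm(ax) - 1.0) > _AXIS_TOL:
                raise ValueError("axis must be a unit vector (|axis| - 1 within 1e-9)")
            object.__setattr__(self, "axis", ax)
        else:
            object.__setattr__(self, "axis", None)
        if self.kind == "spherocylinder":
            if self.length is None:
                raise ValueError("spherocylinder requires total length L")
            if self.length < 2.0 * self.radius - 1e-12:
                raise ValueError("spherocylinder requires L >= 2 r")
        else:
            object.__setattr__(self, "length", None)

    # -- derived geometry ---------------------------------------------------

    @property
    def cap_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Cap-sphere centres (A, B) of a spherocylinder."""
        if self.kind != "spherocylinder":
            raise ValueError("cap_centers defined only for spherocylinders")
        half = 0.5 * (self.length - 2.0 * self.radius)
        return self.center - half * self.axis, self.center + half * self.axis

    @property
    def z_extent(self) -> tuple[float, float]:
        lo, hi = self.bounding_box
        return float(lo[2]), float(hi[2])

    @property
    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        c, r = self.center, self.radius
        if self.kind == "sphere":
            return c - r, c + r
        if self.kind == "spherocylinder":
            a, b = self.cap_centers
            return np.minimum(a, b) - r, np.maximum(a, b) + r
        # half-sphere: per axis-aligned direction the cap reaches r when the
        # normal has a non-negative component there, else only the rim circle
        n = self.axis
        rim = r * np.sqrt(np.clip(1.0 - n * n, 0.0, 1.0))
        hi = np.where(n >= 0, r, rim)
        lo = np.where(n <= 0, -r, -rim)
        return c + lo, c + hi


# -- exact measures ---------------------------------------------------------


def volume(body: BodyShape) -> float:
    """Exact volume, nm^3."""
    r = body.radius
    if body.kind == "sphere":
        return 4.0 / 3.0 * np.pi * r**3
    if body.kind == "spherocylinder":
        return np.pi * r**2 * (body.length - 2.0 * r) + 4.0 / 3.0 * np.pi * r**3
    return 2.0 / 3.0 * np.pi * r**3


def surface(body: BodyShape) -> float:
    """Exact surface area, nm^2.

    For the half-sphere only the curved cap (2 pi r^2) counts: the flat face
    sits on the nuclear envelope and is not available for organelle docking.
    """
    r = body.radius
    if body.kind == "sphere":
        return 4.0 * np.pi * r**2
    if body.kind == "spherocylinder":
        return 2.0 * np.pi * r * (body.length - 2.0 * r) + 4.0 * np.pi * r**2
    return 2.0 * np.pi * r**2


def sphere_diameter_from_volume(v: float) -> float:
    """Diameter of the sphere with volume ``v`` (nm from nm^3)."""
    if not v > 0:
        raise ValueError("volume must be positive")
    return float((6.0 * v / np.pi) ** (1.0 / 3.0))


def report_sphere_diameter(v: float) -> int:
    """Equivalent-sphere diameter rounded to the nearest integer nm."""
    return int(round(sphere_diameter_from_volume(v)))


def spherocylinder_length_from_volume(v: float, d: float) -> float:
    """Total length L of a capped cylinder of cap diameter ``d`` and volume ``v``.

    Inverts V = pi r^2 (L - 2r) + (4/3) pi r^3 with r = d/2.  ``v`` below the
    cap-sphere volume admits no valid cylinder and is rejected.
    """
    if not d > 0:
        raise ValueError("cap diameter must be positive")
    r = 0.5 * d
    v_cap = 4.0 / 3.0 * np.pi * r**3
    if v < v_cap * (1.0 - 1e-12):
        raise ValueError(
            f"volume {v:.6g} nm^3 is below the cap-sphere volume {v_cap:.6g} nm^3; "
            "no spherocylinder of this diameter exists"
        )
    return float(2.0 * r + max(v - v_cap, 0.0) / (np.pi * r**2))


# -- membership queries -----------------------------------------------------


def _segment_sqdist(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Squared distance from 3D points (..., 3) to segment ab."""
    ab = b - a
    denom = float(ab @ ab)
    ap = points - a
    if denom < 1e-30:
        return np.einsum("...i,...i->...", ap, ap)
    t = np.clip(np.einsum("...i,i->...", ap, ab) / denom, 0.0, 1.0)
    diff = ap - t[..., None] * ab
    return np.einsum("...i,...i->...", diff, diff)


def contains(body: BodyShape, points: np.ndarray) -> np.ndarray:
    """Exact 3D membership of points (..., 3); strict <= in squared distance."""
    pts = np.asarray(points, dtype=float)
    r2 = body.radius**2
    if body.kind == "sphere":
        d = pts - body.center
        return np.einsum("...i,...i->...", d, d) <= r2
    if body.kind == "spherocylinder":
        a, b = body.cap_centers
        return _segment_sqdist(pts, a, b) <= r2
    d = pts - body.center
    inside = np.einsum("...i,...i->...", d, d) <= r2
    return inside & (np.einsum("...i,i->...", d, body.axis) >= 0.0)


def _points3(points_xy: np.ndarray, z: float | np.ndarray) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    zcol = np.broadcast_to(np.asarray(z, dtype=float), pts.shape[:-1])
    return np.concatenate([pts, zcol[..., None]], axis=-1)


def cross_section_membership(body: BodyShape, points_xy: np.ndarray, z_plane: float) -> np.ndarray:
    """True where the plane point (x, y, z_plane) lies inside the solid."""
    return contains(body, _points3(points_xy, z_plane))


def _interval_dist(z: np.ndarray, z_lo: float | np.ndarray, z_hi: float | np.ndarray) -> np.ndarray:
    """Distance from z to the interval [z_lo, z_hi] (0 inside)."""
    return np.maximum(np.maximum(z_lo - z, z - z_hi), 0.0)


def shadow_membership(body: BodyShape, points_xy: np.ndarray, slab: Slab) -> np.ndarray:
    """True where some z in the slab puts (x, y, z) inside the solid.

    This is the full-projection shadow: a point belongs to the shadow iff the
    vertical line through it meets the body inside the slab.
    """
    pts = np.atleast_2d(np.asarray(points_xy, dtype=float))
    r = body.radius
    if body.kind == "sphere":
        dz = _interval_dist(body.center[2], slab.z_lo, slab.z_hi)
        w2 = r * r - dz * dz
        d = pts - body.center[:2]
        return np.einsum("...i,...i->...", d, d) <= w2
    if body.kind == "spherocylinder":
        frame = _capsule_frame(body)
        alpha, beta = _capsule_plane_coords(frame, pts)
        g = _capsule_g(body, frame, alpha, slab.z_lo, slab.z_hi)
        return beta * beta <= g
    # half-sphere: intersect the vertical-line z-intervals allowed by the
    # ball, the half-space and the slab
    c, n = body.center, body.axis
    d = pts - c[:2]
    rho2 = np.einsum("...i,...i->...", d, d)
    w2 = r * r - rho2
    ok = w2 >= 0.0
    w = np.sqrt(np.clip(w2, 0.0, None))
    lo = np.maximum(c[2] - w, slab.z_lo)
    hi = np.minimum(c[2] + w, slab.z_hi)
    s = np.einsum("...i,i->...", d, n[:2])  # in-plane part of (p - c) . n
    nz = n[2]
    if abs(nz) < 1e-15:
        ok &= s >= 0.0
    elif nz > 0:
        lo = np.maximum(lo, c[2] - s / nz)
    else:
        hi = np.minimum(hi, c[2] - s / nz)
    return ok & (hi >= lo)


# -- spherocylinder width machinery ----------------------------------------


@dataclass(frozen=True)
class _CapsuleFrame:
    a_xy: np.ndarray  # in-plane position of cap centre A
    e1: np.ndarray
    e2: np.ndarray
    s: float  # in-plane length of the cap-centre segment
    za: float
    zb: float  # z(t) = za + zb t along the segment, t in [0, 1]


def _capsule_frame(body: BodyShape) -> _CapsuleFrame:
    a, b = body.cap_centers
    d_xy = (b - a)[:2]
    s = float(np.hypot(*d_xy))
    if s > 1e-12:
        e1 = d_xy / s
    else:
        s = 0.0
        e1 = np.array([1.0, 0.0])
    e2 = np.array([-e1[1], e1[0]])
    return _CapsuleFrame(a_xy=a[:2], e1=e1, e2=e2, s=s, za=float(a[2]), zb=float(b[2] - a[2]))


def _capsule_plane_coords(frame: _CapsuleFrame, pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rel = pts - frame.a_xy
    return rel @ frame.e1, rel @ frame.e2


def _capsule_g(
    body: BodyShape,
    frame: _CapsuleFrame,
    alpha: np.ndarray,
    z_lo: float | np.ndarray,
    z_hi: float | np.ndarray,
) -> np.ndarray:
    """max over t in [0,1] of r^2 - dist(z(t), [z_lo, z_hi])^2 - (alpha - s t)^2.

    The chord half-width of the capsule profile at in-plane abscissa
    ``alpha`` is sqrt(g) where g >= 0.  The objective is concave in t, so its
    maximum over [0, 1] is attained at a stationary point of one of the three
    quadratic pieces (z(t) below, inside or above the slab), at a piece
    breakpoint, or at an endpoint; all candidates are closed form.
    """
    s, za, zb = frame.s, frame.za, frame.zb
    r2 = body.radius**2
    alpha = np.asarray(alpha, dtype=float)
    z_lo = np.asarray(z_lo, dtype=float)
    z_hi = np.asarray(z_hi, dtype=float)

    cands = [np.zeros_like(alpha + z_lo), np.ones_like(alpha + z_lo)]
    if s > 0:
        cands.append(np.broadcast_to(alpha / s, cands[0].shape))
    den = s * s + zb * zb
    if den > 0:
        cands.append((zb * (z_lo - za) + s * alpha) / den)
        cands.append((zb * (z_hi - za) + s * alpha) / den)
    if abs(zb) > 1e-15:
        cands.append(np.broadcast_to((z_lo - za) / zb, cands[0].shape))
        cands.append(np.broadcast_to((z_hi - za) / zb, cands[0].shape))

    best = np.full(cands[0].shape, -np.inf)
    for t in cands:
        t = np.clip(t, 0.0, 1.0)
        zc = za + zb * t
        pen = _interval_dist(zc, z_lo, z_hi)
        f = r2 - pen * pen - (alpha - s * t) ** 2
        best = np.maximum(best, f)
    return best


def _capsule_profile_areas(body: BodyShape, z_lo: np.ndarray, z_hi: np.ndarray) -> np.ndarray:
    """Vectorised profile areas of a spherocylinder over many slabs.

    ``z_lo == z_hi`` gives thin-plane cross-section areas; otherwise the
    full-projection shadow area of the slab.
    """
    frame = _capsule_frame(body)
    r, s = body.radius, frame.s
    z_lo = np.asarray(z_lo, dtype=float).ravel()
    z_hi = np.asarray(z_hi, dtype=float).ravel()
    out = np.zeros(z_lo.shape)

    for start in range(0, z_lo.size, _SLAB_CHUNK):
        sl = slice(start, min(start + _SLAB_CHUNK, z_lo.size))
        zl, zh = z_lo[sl], z_hi[sl]

        def g_of(alpha: np.ndarray) -> np.ndarray:
            return _capsule_g(body, frame, alpha, zl, zh)

        # locate the maximiser of the concave width function by golden search
        lo = np.full(zl.shape, -r - 1.0)
        hi = np.full(zl.shape, s + r + 1.0)
        for _ in range(70):
            m1 = lo + 0.381966 * (hi - lo)
            m2 = hi - 0.381966 * (hi - lo)
            take = g_of(m1) < g_of(m2)
            lo = np.where(take, m1, lo)
            hi = np.where(take, hi, m2)
        a_star = 0.5 * (lo + hi)
        g_star = g_of(a_star)
        nonempty = g_star > 0.0

        # support endpoints: bisect the concave g between its peak and the
        # guaranteed-outside brackets
        def root(inside: np.ndarray, outside: np.ndarray) -> np.ndarray:
            lo_, hi_ = inside.copy(), outside.copy()
            for _ in range(60):
                mid = 0.5 * (lo_ + hi_)
                pos = g_of(mid) > 0.0
                lo_ = np.where(pos, mid, lo_)
                hi_ = np.where(pos, hi_, mid)
            return 0.5 * (lo_ + hi_)

        a_left = root(a_star, np.full(zl.shape, -r - 1.0))
        a_right = root(a_star, np.full(zl.shape, s + r + 1.0))

        # sine substitution removes the sqrt edge singularities
        mid = 0.5 * (a_left + a_right)
        half = 0.5 * (a_right - a_left)
        theta = np.linspace(-0.5 * np.pi, 0.5 * np.pi, _N_SIMPSON + 1)
        alpha = mid[:, None] + half[:, None] * np.sin(theta)
        g = _capsule_g(body, frame, alpha, zl[:, None], zh[:, None])
        integrand = 2.0 * np.sqrt(np.clip(g, 0.0, None)) * half[:, None] * np.cos(theta)
        w = np.ones(_N_SIMPSON + 1)
        w[1:-1:2] = 4.0
        w[2:-1:2] = 2.0
        area = integrand @ w * (theta[1] - theta[0]) / 3.0
        out[sl] = np.where(nonempty, area, 0.0)
    return out


def _half_sphere_section_area(body: BodyShape, z: float) -> float:
    """Closed-form thin cross-section of a half-ball: a circular segment."""
    c, n, r = body.center, body.axis, body.radius
    dz = z - c[2]
    w2 = r * r - dz * dz
    if w2 <= 0:
        return 0.0
    w = np.sqrt(w2)
    n_xy = float(np.hypot(n[0], n[1]))
    if n_xy < 1e-15:
        return float(np.pi * w2) if dz * n[2] >= 0 else 0.0
    # keep the part of the disc with xi >= h0 along the in-plane normal
    h0 = -dz * n[2] / n_xy
    if h0 <= -w:
        return float(np.pi * w2)
    if h0 >= w:
        return 0.0
    return float(w2 * np.arccos(h0 / w) - h0 * np.sqrt(w2 - h0 * h0))


def _half_sphere_shadow_area(body: BodyShape, slab: Slab, pitch: Optional[float] = None) -> float:
    """Shadow area of a half-ball by fine-grid counting (used rarely)."""
    r = body.radius
    if pitch is None:
        pitch = r / 96.0
    lo, hi = body.bounding_box
    xs = np.arange(lo[0] + 0.5 * pitch, hi[0], pitch)
    ys = np.arange(lo[1] + 0.5 * pitch, hi[1], pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    hits = int(np.count_nonzero(shadow_membership(body, pts, slab)))
    return hits * pitch * pitch


def profile_areas(
    body: BodyShape, z_lo: np.ndarray | float, z_hi: np.ndarray | float
) -> np.ndarray:
    """Profile areas for one body over many slabs (thin when z_lo == z_hi)."""
    z_lo = np.atleast_1d(np.asarray(z_lo, dtype=float))
    z_hi = np.atleast_1d(np.asarray(z_hi, dtype=float))
    if z_lo.shape != z_hi.shape:
        raise ValueError("z_lo and z_hi must have matching shapes")
    if np.any(z_hi < z_lo):
        raise ValueError("slabs must satisfy z_hi >= z_lo")
    r = body.radius
    if body.kind == "sphere":
        dz = _interval_dist(body.center[2], z_lo, z_hi)
        return np.pi * np.clip(r * r - dz * dz, 0.0, None)
    if body.kind == "spherocylinder":
        return _capsule_profile_areas(body, z_lo, z_hi)
    out = np.empty(z_lo.shape)
    for i, (zl, zh) in enumerate(zip(z_lo, z_hi)):
        if zh - zl < 1e-12:
            out[i] = _half_sphere_section_area(body, float(zl))
        else:
            out[i] = _half_sphere_shadow_area(body, Slab(float(zl), float(zh)))
    return out


def cross_section_area(body: BodyShape, z: float) -> float:
    """Exact thin-plane cross-section area at height z, nm^2."""
    return float(profile_areas(body, z, z)[0])


def shadow_area(body: BodyShape, slab: Slab) -> float:
    """Full-projection shadow area of the body over the slab, nm^2."""
    return float(profile_areas(body, slab.z_lo, slab.z_hi)[0])


# -- sampling helpers -------------------------------------------------------


def random_unit_vectors(rng: np.random.Generator, n: Optional[int] = None) -> np.ndarray:
    """Isotropic unit vectors: z uniform on [-1, 1], azimuth uniform on [0, 2pi)."""
    size = 1 if n is None else n
    z = rng.uniform(-1.0, 1.0, size)
    phi = rng.uniform(0.0, 2.0 * np.pi, size)
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    v = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=-1)
    return v[0] if n is None else v


def sample_points_inside(body: BodyShape, n: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform points inside the body, by rejection in its bounding box."""
    lo, hi = body.bounding_box
    out = np.empty((0, 3))
    while out.shape[0] < n:
        m = max(4 * (n - out.shape[0]), 256)
        cand = rng.uniform(lo, hi, size=(m, 3))
        out = np.vstack([out, cand[contains(body, cand)]])
    return out[:n]
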