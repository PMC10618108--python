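"""Virtual microtome: cut simulated cells into section stacks.

Produces the profile data the stereological estimators consume: exhaustive
serial stacks of conventional thickness (overprojected shadows), thin
tomographic slices (mid-plane cross-sections), superslices (blocks of thin
slices merged by mask union, emulating a conventional section rebuilt from a
tomogram), randomly placed ministacks for large cells, and intermittent
one-in-k subsampling for Cavalieri estimation of large compartments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import (
    BodyShape,
    Slab,
    cross_section_membership,
    profile_areas,
    shadow_membership,
)

MODES = ("thin_plane", "overprojected")


@dataclass
class SectionStack:
    """An ordered, contiguous run of sections through a set of bodies.

    ``presence[body_id]`` is a boolean vector over slabs: whether the body
    intersects the slab (overprojected) or its mid-plane (thin_plane) — the
    exact-geometry notion of "a profile is present", independent of any
    raster resolution.  ``areas[body_id]`` holds the matching exact profile
    areas when they were computed.  ``spacing_nm`` is the section-to-section
    spacing Cavalieri should use (equals slab thickness unless the stack was
    subsampled).
    """

    slabs: list[Slab]
    mode: str
    phase: float
    bodies: dict[str, BodyShape]
    presence: dict[str, np.ndarray]
    areas: Optional[dict[str, np.ndarray]] = None
    spacing_nm: Optional[float] = None
    every_k: int = 1

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown stack mode {self.mode!r}")
        for a, b in zip(self.slabs, self.slabs[1:]):
            if self.every_k == 1 and abs(a.z_hi - b.z_lo) > 1e-6:
                raise ValueError("slabs must be contiguous and non-overlapping")
        if self.spacing_nm is None:
            self.spacing_nm = self.slabs[0].thickness if self.slabs else 0.0

    @property
    def n_sections(self) -> int:
        return len(self.slabs)

    @property
    def thickness(self) -> float:
        return self.slabs[0].thickness if self.slabs else 0.0

    def membership(self, section_index: int, body_id: str, points_xy: np.ndarray) -> np.ndarray:
        """Exact profile membership query for point counting."""
        body = self.bodies[body_id]
        slab = self.slabs[section_index]
        if self.mode == "thin_plane":
            return cross_section_membership(body, points_xy, slab.mid_z)
        return shadow_membership(body, points_xy, slab)

    def area(self, section_index: int, body_id: str) -> float:
        if self.areas is None:
            raise ValueError("stack was cut without area computation")
        return float(self.areas[body_id][section_index])

    def section_area_totals(self) -> np.ndarray:
        """Per-section summed profile area over all bodies, nm^2."""
        if self.areas is None:
            raise ValueError("stack was cut without area computation")
        total = np.zeros(self.n_sections)
        for arr in self.areas.values():
            total += arr
        return total


def _presence(body: BodyShape, slabs: list[Slab], mode: str) -> np.ndarray:
    zmin, zmax = body.z_extent
    if mode == "thin_plane":
        mids = np.array([s.mid_z for s in slabs])
        return (mids > zmin) & (mids < zmax)
    lo = np.array([s.z_lo for s in slabs])
    hi = np.array([s.z_hi for s in slabs])
    return (zmin < hi) & (zmax > lo)


def _areas(body: BodyShape, slabs: list[Slab], mode: str, present: np.ndarray) -> np.ndarray:
    out = np.zeros(len(slabs))
    idx = np.flatnonzero(present)
    if idx.size:
        if mode == "thin_plane":
            z = np.array([slabs[i].mid_z for i in idx])
            out[idx] = profile_areas(body, z, z)
        else:
            lo = np.array([slabs[i].z_lo for i in idx])
            hi = np.array([slabs[i].z_hi for i in idx])
            out[idx] = profile_areas(body, lo, hi)
    return out


def _build_stack(
    bodies: dict[str, BodyShape],
    slabs: list[Slab],
    mode: str,
    phase: float,
    compute_areas: bool,
) -> SectionStack:
    presence = {bid: _presence(b, slabs, mode) for bid, b in bodies.items()}
    areas = None
    if compute_areas:
        areas = {bid: _areas(b, slabs, mode, presence[bid]) for bid, b in bodies.items()}
    return SectionStack(
        slabs=slabs, mode=mode, phase=phase, bodies=dict(bodies),
        presence=presence, areas=areas,
    )


def _z_span(bodies: dict[str, BodyShape]) -> tuple[float, float]:
    if not bodies:
        return 0.0, 0.0
    lo = min(b.z_extent[0] for b in bodies.values())
    hi = max(b.z_extent[1] for b in bodies.values())
    return lo, hi


def cut_serial(
    bodies: dict[str, BodyShape],
    t: float,
    rng: np.random.Generator | int | None = None,
    mode: str = "overprojected",
    compute_areas: bool = True,
) -> SectionStack:
    """Exhaustive serial sectioning at thickness ``t``.

    The first slab boundary is offset by a random phase uniform on [0, t);
    the stack spans the full z-extent of all bodies.  Default profiles are
    overprojected shadows, as in conventional TEM.
    """
    if not t > 0:
        raise ValueError("section thickness must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phase = float(rng.uniform(0.0, t))
    zmin, zmax = _z_span(bodies)
    if not bodies:
        return SectionStack([], mode, phase, {}, {}, areas={} if compute_areas else None)
    z0 = zmin - phase
    n = max(1, math.ceil((zmax - z0) / t - 1e-12))
    slabs = [Slab(z0 + i * t, z0 + (i + 1) * t) for i in range(n)]
    return _build_stack(bodies, slabs, mode, phase, compute_areas)


def cut_tomographic(
    bodies: dict[str, BodyShape],
    dz: float = 2.0,
    rng: np.random.Generator | int | None = None,
    compute_areas: bool = True,
) -> SectionStack:
    """Thin tomographic slicing: mid-plane cross-sections at spacing ``dz``."""
    if not dz > 0:
        raise ValueError("slice spacing must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    phase = float(rng.uniform(0.0, dz))
    zmin, zmax = _z_span(bodies)
    if not bodies:
        return SectionStack([], "thin_plane", phase, {}, {}, areas={} if compute_areas else None)
    z0 = zmin - phase
    n = max(1, math.ceil((zmax - z0) / dz - 1e-12))
    slabs = [Slab(z0 + i * dz, z0 + (i + 1) * dz) for i in range(n)]
    return _build_stack(bodies, slabs, "thin_plane", phase, compute_areas)


def union_mask(
    thin: SectionStack,
    member_indices: list[int],
    body_id: str,
    pitch: float = 2.0,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray, np.ndarray]:
    """Union of a body's thin cross-section masks over a block of slices.

    Returns (union, member masks, x centres, y centres) on a square grid of
    the stated pitch over the body's bounding box.
    """
    body = thin.bodies[body_id]
    lo, hi = body.bounding_box
    xs = np.arange(lo[0] + 0.5 * pitch, hi[0], pitch)
    ys = np.arange(lo[1] + 0.5 * pitch, hi[1], pitch)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel()], axis=-1)
    members = []
    for i in member_indices:
        m = cross_section_membership(body, pts, thin.slabs[i].mid_z).reshape(gx.shape)
        members.append(m)
    union = np.any(members, axis=0) if members else np.zeros(gx.shape, dtype=bool)
    return union, members, xs, ys


def assemble_superslices(thin: SectionStack, k: int, pitch: float = 2.0) -> SectionStack:
    """Merge consecutive groups of ``k`` thin slices into overprojected blocks.

    Each superslice profile is the union of its member cross-section masks,
    a discrete shadow; areas are mask areas at the stated grid pitch, so the
    effective thickness is k * dz.
    """
    if thin.mode != "thin_plane":
        raise ValueError("superslices are assembled from a thin_plane stack")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return thin
    groups = [list(range(i, min(i + k, thin.n_sections))) for i in range(0, thin.n_sections, k)]
    slabs = [Slab(thin.slabs[g[0]].z_lo, thin.slabs[g[-1]].z_hi) for g in groups]
    presence: dict[str, np.ndarray] = {}
    areas: dict[str, np.ndarray] = {}
    for bid in thin.bodies:
        pres = np.array([bool(thin.presence[bid][g].any()) for g in groups])
        ar = np.zeros(len(groups))
        for j, grp in enumerate(groups):
            if pres[j]:
                u, _, _, _ = union_mask(thin, [i for i in grp if thin.presence[bid][i]], bid, pitch)
                ar[j] = float(u.sum()) * pitch * pitch
        presence[bid] = pres
        areas[bid] = ar
    return SectionStack(
        slabs=slabs, mode="overprojected", phase=thin.phase,
        bodies=dict(thin.bodies), presence=presence, areas=areas,
    )


def sample_ministacks(
    bodies: dict[str, BodyShape],
    t: float,
    n_sections_per_stack: int,
    n_stacks: int,
    rng: np.random.Generator | int | None = None,
    z_range: Optional[tuple[float, float]] = None,
    compute_areas: bool = True,
) -> list[SectionStack]:
    """Randomly placed short runs of serial sections inside a z-range.

    Stack start positions are uniform over the range (typically the cell's
    z-extent); stacks never extend beyond it.  Used for Nv/Vv estimation in
    cells too large for exhaustive serial analysis.
    """
    if n_sections_per_stack < 2:
        raise ValueError("a ministack needs at least 2 sections")
    if n_stacks < 0:
        raise ValueError("n_stacks must be non-negative")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if n_stacks == 0:
        return []
    if z_range is None:
        z_range = _z_span(bodies)
    z_lo, z_hi = z_range
    length = n_sections_per_stack * t
    if z_hi - z_lo < length:
        raise ValueError("z-range shorter than one ministack")
    stacks = []
    for _ in range(n_stacks):
        start = float(rng.uniform(z_lo, z_hi - length))
        slabs = [Slab(start + i * t, start + (i + 1) * t) for i in range(n_sections_per_stack)]
        stacks.append(_build_stack(bodies, slabs, "overprojected", start - z_lo, compute_areas))
    return stacks


def subsample_intermittent(
    stack: SectionStack, every_k: int, rng: np.random.Generator | int | None = None
) -> SectionStack:
    """Keep one section in every ``every_k`` (random residue class).

    The retained sections are equally spaced at every_k * t, recorded in
    ``spacing_nm`` for Cavalieri.  Appearance counting must not be run on a
    subsampled stack (adjacency is destroyed).
    """
    if every_k < 1:
        raise ValueError("every_k must be >= 1")
    if every_k == 1:
        return stack
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    r = int(rng.integers(every_k))
    keep = list(range(r, stack.n_sections, every_k))
    return SectionStack(
        slabs=[stack.slabs[i] for i in keep],
        mode=stack.mode,
        phase=stack.phase,
        bodies=dict(stack.bodies),
        presence={bid: v[keep] for bid, v in stack.presence.items()},
        areas=None if stack.areas is None else {bid: v[keep] for bid, v in stack.areas.items()},
        spacing_nm=every_k * stack.thickness,
        every_k=every_k,
    )
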