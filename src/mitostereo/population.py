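"""Seeded generator of simulated microsporidian meront cells.

Each cell is a pair of concentric spheres (nucleus inside a cytoplasm
sphere), two half-sphere spindle-pole bodies (mSPBs) sitting on opposite
poles of the nuclear envelope, and a set of dumbbell (spherocylinder)
mitosomes.  Mitosomes are either tethered to one of the two mSPBs — their
near cap within a stated contact distance of the mSPB cap, their long axis
growing out into the cytoplasm — or free in the cytoplasm shell.

Two species profiles are provided.  The E. cuniculi profile draws the
per-cell mitosome count from a linear model in nucleus volume calibrated to
a cohort mean of 7.4, with 92% of mitosomes tethered and tethered counts
split as evenly as possible across the two mSPBs.  The T. hominis profile
draws a roughly constant count (14-18 per cell) with a developmental-stage
schedule of mSPB association rising to 0.73 at the prespore stage.

A dynamin-inhibition perturbation merges mitosomes pairwise: the count is
halved (odd counts carry one unmerged organelle) while each merged organelle
receives the summed volume of its pair, so aggregate volume is conserved.

Reproducibility: a single root seed; every cell derives an independent
substream keyed by its index, so cohorts are bit-identical for a fixed seed
regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .geometry import (
    BodyShape,
    random_unit_vectors,
    spherocylinder_length_from_volume,
    volume,
)

SPECIES = ("ecuniculi", "thominis")
STAGES = ("early", "multinucleate1", "multinucleate2", "multinucleate3", "prespore", "interphase")
PARTITION_MODES = ("ordered_even", "binomial_random")
PERTURBATIONS = ("none", "dynamin_inhibition")

_MAX_PLACEMENT_TRIES = 1000


@dataclass(frozen=True)
class CohortConfig:
    """Generator parameters for one simulated cohort.

    Lengths in nm.  ``count_slope_per_um3`` multiplies nucleus volume in um^3
    in the count model N = max(1, round(a + b * V_nuc + eps)).
    """

    n_cells: int = 18
    seed: int = 0
    species: str = "ecuniculi"
    stage: str = "interphase"
    minor_axis_range_nm: tuple[float, float] = (47.0, 119.0)
    major_axis_range_nm: tuple[float, float] = (78.0, 267.0)
    nucleus_radius_range_nm: tuple[float, float] = (380.0, 520.0)
    cell_radius_factor_range: tuple[float, float] = (1.95, 2.15)
    mspb_radius_range_nm: tuple[float, float] = (30.0, 60.0)
    count_intercept: float = 2.6
    count_slope_per_um3: float = 12.0
    count_sigma: float = 1.0
    count_range: Optional[tuple[int, int]] = None  # uniform-integer model instead
    tether_fraction: float = 0.92
    partition_mode: str = "ordered_even"
    perturbation: str = "none"
    contact_distance_nm: float = 10.0
    tether_max_tilt_deg: float = 20.0
    stage_association_schedule: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.partition_mode not in PARTITION_MODES:
            raise ValueError(f"unknown partition_mode {self.partition_mode!r}")
        if self.perturbation not in PERTURBATIONS:
            raise ValueError(f"unknown perturbation {self.perturbation!r}")
        if not 0.0 <= self.tether_fraction <= 1.0:
            raise ValueError("tether_fraction must lie in [0, 1]")
        for name in ("minor_axis_range_nm", "major_axis_range_nm", "nucleus_radius_range_nm"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a positive non-decreasing range")
        if self.minor_axis_range_nm[0] > self.major_axis_range_nm[1]:
            raise ValueError("minor axis range exceeds major axis range: no valid dumbbell")
        if self.stage_association_schedule is not None:
            for stage, frac in self.stage_association_schedule.items():
                if stage not in STAGES:
                    raise ValueError(f"schedule stage {stage!r} unknown")
                if not 0.0 <= frac <= 1.0:
                    raise ValueError("schedule fractions must lie in [0, 1]")


#: T. hominis default: constant-ish counts, stage-dependent mSPB association
THOMINIS_SCHEDULE = {
    "early": 0.10,
    "multinucleate1": 0.30,
    "multinucleate2": 0.45,
    "multinucleate3": 0.60,
    "prespore": 0.73,
    "interphase": 0.73,
}


def thominis_config(**overrides) -> CohortConfig:
    """Default T. hominis profile: ~16 mitosomes/cell, larger cells."""
    base = dict(
        species="thominis",
        count_range=(14, 18),
        cell_radius_factor_range=(2.3, 2.7),
        tether_fraction=0.73,
        stage_association_schedule=dict(THOMINIS_SCHEDULE),
        partition_mode="binomial_random",
    )
    base.update(overrides)
    return CohortConfig(**base)


@dataclass(frozen=True, eq=False)
class MerontCell:
    """One simulated parasite cell with immutable ground truth."""

    cell_id: str
    species: str
    stage: str
    nucleus: BodyShape
    cytoplasm_radius: float
    mspb: tuple[BodyShape, BodyShape]
    mitosomes: tuple[BodyShape, ...]
    tether: tuple[str, ...]  # per mitosome: SPB1 | SPB2 | free
    perturbation: str = "none"

    @property
    def n_true(self) -> int:
        return len(self.mitosomes)

    @property
    def v_true(self) -> float:
        return float(sum(volume(m) for m in self.mitosomes))

    @property
    def nucleus_radius(self) -> float:
        return self.nucleus.radius

    @property
    def v_nucleus(self) -> float:
        return volume(self.nucleus)

    @property
    def v_cell(self) -> float:
        return 4.0 / 3.0 * np.pi * self.cytoplasm_radius**3

    @property
    def v_cytoplasm(self) -> float:
        return self.v_cell - self.v_nucleus

    @property
    def spb_counts(self) -> tuple[int, int]:
        return (self.tether.count("SPB1"), self.tether.count("SPB2"))

    def mitosome_bodies(self) -> dict[str, BodyShape]:
        return {f"{self.cell_id}:mito{i}": m for i, m in enumerate(self.mitosomes)}


def assign_spb_counts(
    n_tethered: int, mode: str, rng: np.random.Generator
) -> tuple[int, int]:
    """Split ``n_tethered`` organelles across the two mSPBs.

    ``ordered_even`` yields counts differing by at most one (random side gets
    the odd one); ``binomial_random`` assigns each organelle independently
    with probability 1/2.
    """
    if mode == "ordered_even":
        n1 = n_tethered // 2
        if n_tethered % 2 and rng.random() < 0.5:
            n1 += 1
        return n1, n_tethered - n1
    if mode == "binomial_random":
        n1 = int(rng.binomial(n_tethered, 0.5))
        return n1, n_tethered - n1
    raise ValueError(f"unknown partition mode {mode!r}")


def _cell_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _sample_shape(config: CohortConfig, rng: np.random.Generator) -> tuple[float, float]:
    """Mitosome cap radius and total length; L >= 2r enforced by rejection."""
    d = rng.uniform(*config.minor_axis_range_nm)
    r = 0.5 * d
    lo, hi = config.major_axis_range_nm
    for _ in range(_MAX_PLACEMENT_TRIES):
        L = rng.uniform(lo, hi)
        if L >= d:
            return r, L
    raise RuntimeError("could not sample a dumbbell with L >= 2r; check axis ranges")


def _tilted_direction(
    n: np.ndarray, max_tilt_rad: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit vector uniformly distributed within a cone of half-angle around n."""
    cos_t = rng.uniform(np.cos(max_tilt_rad), 1.0)
    sin_t = np.sqrt(1.0 - cos_t * cos_t)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    # orthonormal frame around n
    a = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(n, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    v = cos_t * n + sin_t * (np.cos(phi) * e1 + np.sin(phi) * e2)
    return v / np.linalg.norm(v)


def _segment_fits(
    a: np.ndarray, b: np.ndarray, r: float, r_nuc: float, r_cell: float
) -> bool:
    """Capsule (a, b, r) inside the cytoplasm shell: outside the nucleus ball
    and inside the cell ball."""
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom < 1e-30 else float(np.clip(-(a @ ab) / denom, 0.0, 1.0))
    closest = a + t * ab
    if np.linalg.norm(closest) < r_nuc + r:
        return False
    return max(np.linalg.norm(a), np.linalg.norm(b)) + r <= r_cell


def _place_tethered(
    spb: BodyShape,
    r: float,
    L: float,
    config: CohortConfig,
    r_nuc: float,
    r_cell: float,
    rng: np.random.Generator,
) -> Optional[BodyShape]:
    """Place a mitosome end-on at an mSPB cap, axis pointing outward.

    The near cap centre is set so the cap-to-cap surface distance equals a
    gap drawn below the contact criterion; a bounded tilt keeps crowded SPBs
    from stacking organelles on a single ray.
    """
    n = spb.axis
    for attempt in range(_MAX_PLACEMENT_TRIES):
        # long organelles cannot grow radially inside a thin shell; let the
        # axis lean progressively towards the envelope if upright fails
        tilt = config.tether_max_tilt_deg
        if attempt >= _MAX_PLACEMENT_TRIES // 3:
            tilt = 60.0
        if attempt >= 2 * _MAX_PLACEMENT_TRIES // 3:
            tilt = 85.0
        u = _tilted_direction(n, tilt * np.pi / 180.0, rng)
        gap = rng.uniform(0.0, 0.9 * config.contact_distance_nm)
        a = spb.center + u * (spb.radius + r + gap)
        b = a + u * (L - 2.0 * r)
        if _segment_fits(a, b, r, r_nuc, r_cell):
            return BodyShape(
                "spherocylinder", 0.5 * (a + b), r, axis=u, length=L
            )
    return None


def _place_free(
    r: float, L: float, r_nuc: float, r_cell: float, rng: np.random.Generator
) -> Optional[BodyShape]:
    """Uniform placement in the cytoplasm shell by rejection."""
    for _ in range(_MAX_PLACEMENT_TRIES):
        center = rng.uniform(-r_cell, r_cell, 3)
        if np.linalg.norm(center) > r_cell:
            continue
        axis = random_unit_vectors(rng)
        half = 0.5 * (L - 2.0 * r)
        a, b = center - half * axis, center + half * axis
        if _segment_fits(a, b, r, r_nuc, r_cell):
            return BodyShape("spherocylinder", center, r, axis=axis, length=L)
    return None


def _draw_count(config: CohortConfig, v_nuc_nm3: float, rng: np.random.Generator) -> int:
    if config.count_range is not None:
        lo, hi = config.count_range
        return int(rng.integers(lo, hi + 1))
    v_um3 = v_nuc_nm3 * 1e-9
    mean = config.count_intercept + config.count_slope_per_um3 * v_um3
    return max(1, int(round(mean + rng.normal(0.0, config.count_sigma))))


def generate_cell(config: CohortConfig, index: int, stage: Optional[str] = None) -> MerontCell:
    """Generate one cell from the config's seed and the cell index."""
    rng = _cell_rng(config.seed, index)
    stage = stage or config.stage
    r_nuc = rng.uniform(*config.nucleus_radius_range_nm)
    r_cell = r_nuc * rng.uniform(*config.cell_radius_factor_range)
    nucleus = BodyShape("sphere", np.zeros(3), r_nuc)

    pole = random_unit_vectors(rng)
    spb_r = rng.uniform(*config.mspb_radius_range_nm, 2)
    spb1 = BodyShape("half_sphere", r_nuc * pole, spb_r[0], axis=pole)
    spb2 = BodyShape("half_sphere", -r_nuc * pole, spb_r[1], axis=-pole)

    tether_fraction = config.tether_fraction
    if config.stage_association_schedule is not None:
        if stage not in config.stage_association_schedule:
            raise ValueError(f"stage {stage!r} missing from stage_association_schedule")
        tether_fraction = config.stage_association_schedule[stage]

    n = _draw_count(config, volume(nucleus), rng)
    tethered_flags = rng.random(n) < tether_fraction
    n_tethered = int(tethered_flags.sum())
    n1, _ = assign_spb_counts(n_tethered, config.partition_mode, rng)

    mitosomes: list[BodyShape] = []
    tether: list[str] = []
    placed_on_1 = 0
    for i in range(n):
        r, L = _sample_shape(config, rng)
        if tethered_flags[i]:
            side = "SPB1" if placed_on_1 < n1 else "SPB2"
            placed_on_1 += side == "SPB1"
            body = _place_tethered(
                spb1 if side == "SPB1" else spb2, r, L, config, r_nuc, r_cell, rng
            )
        else:
            side = "free"
            body = _place_free(r, L, r_nuc, r_cell, rng)
        if body is None:
            raise RuntimeError(
                f"placement failed for cell {index} mitosome {i} after "
                f"{_MAX_PLACEMENT_TRIES} tries; widen the cytoplasm shell"
            )
        mitosomes.append(body)
        tether.append(side)

    cell = MerontCell(
        cell_id=f"cell{index:04d}",
        species=config.species,
        stage=stage,
        nucleus=nucleus,
        cytoplasm_radius=r_cell,
        mspb=(spb1, spb2),
        mitosomes=tuple(mitosomes),
        tether=tuple(tether),
    )
    if config.perturbation == "dynamin_inhibition":
        cell = _inhibit_cell(cell, rng)
    return cell


def generate_cohort(config: CohortConfig) -> list[MerontCell]:
    """Deterministic cohort of ``config.n_cells`` cells."""
    if config.n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    return [generate_cell(config, i) for i in range(config.n_cells)]


def _inhibit_cell(cell: MerontCell, rng: np.random.Generator) -> MerontCell:
    """Merge mitosomes pairwise: ceil(n/2) survivors, total volume conserved."""
    if cell.n_true == 0:
        raise ValueError("cannot perturb a cell with no mitosomes")
    r_nuc, r_cell = cell.nucleus_radius, cell.cytoplasm_radius
    merged: list[BodyShape] = []
    tether: list[str] = []
    order = list(range(cell.n_true))
    i = 0
    while i < len(order):
        first = cell.mitosomes[order[i]]
        side = cell.tether[order[i]]
        if i + 1 < len(order):
            second = cell.mitosomes[order[i + 1]]
            v = volume(first) + volume(second)
            d = 2.0 * max(first.radius, second.radius)
            L = spherocylinder_length_from_volume(v, d)
            body = _replace_body(cell, side, 0.5 * d, L, r_nuc, r_cell, rng)
            i += 2
        else:
            body, v = first, volume(first)
            i += 1
        merged.append(body)
        tether.append(side)
    return replace(
        cell,
        mitosomes=tuple(merged),
        tether=tuple(tether),
        perturbation="dynamin_inhibition",
    )


def _replace_body(
    cell: MerontCell,
    side: str,
    r: float,
    L: float,
    r_nuc: float,
    r_cell: float,
    rng: np.random.Generator,
) -> BodyShape:
    cfg = CohortConfig()  # placement tolerances only
    if side in ("SPB1", "SPB2"):
        spb = cell.mspb[0] if side == "SPB1" else cell.mspb[1]
        body = _place_tethered(spb, r, L, cfg, r_nuc, r_cell, rng)
    else:
        body = _place_free(r, L, r_nuc, r_cell, rng)
    if body is None:
        raise RuntimeError("could not re-place merged mitosome inside the cytoplasm shell")
    return body


def apply_dynamin_inhibition(cohort: list[MerontCell], seed: int = 0) -> list[MerontCell]:
    """Perturbed copy of a cohort: per-cell pairwise mitosome merging.

    Counts are halved (odd counts carry one unmerged organelle, so n becomes
    ceil(n/2)); each merged organelle keeps the larger cap diameter of its
    pair and takes the summed volume, so per-cell aggregate volume is
    conserved exactly.
    """
    out = []
    for i, cell in enumerate(cohort):
        if cell.perturbation != "none":
            raise ValueError("cohort already perturbed")
        rng = _cell_rng(seed + 1_000_003, i)
        out.append(_inhibit_cell(cell, rng))
    return out


def generate_thominis_stage_series(
    config: Optional[CohortConfig] = None, n_cells_per_stage: int = 10, seed: int = 0
) -> list[MerontCell]:
    """Cells across the developmental stages of the T. hominis schedule."""
    config = config or thominis_config(seed=seed, n_cells=n_cells_per_stage)
    if config.stage_association_schedule is None:
        raise ValueError("stage series requires a stage_association_schedule")
    stages = [s for s in STAGES if s in config.stage_association_schedule and s != "interphase"]
    cells = []
    for si, stage in enumerate(stages):
        for i in range(config.n_cells):
            cell = generate_cell(config, si * 1_000_000 + i, stage=stage)
            cells.append(replace(cell, cell_id=f"{stage}:{cell.cell_id}"))
    return cells
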