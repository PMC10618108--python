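"""Partitioning, contingency and correlation statistics for meront cohorts.

Covers the organelle-inheritance questions: how evenly mitosomes are split
across the two spindle-pole bodies (with a binomial null for what "even"
would look like under random assignment), the count-weighted pooled binomial
proportion with its confidence interval, chi-square contingency tests for
binned distance distributions, Pearson correlation tables between cell
compartment measurements, and the geometric occupancy capacity of an mSPB
cap for end-on docked mitosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .geometry import BodyShape

#: column names of the per-cell measurement table (volumes nm^3, areas nm^2)
CELL_MEASUREMENT_COLUMNS = (
    "V_cell", "V_nuc", "V_cyto", "V_mit_total", "N_mit", "V_mit_mean",
    "V_mspb1", "V_mspb2", "S_mspb1", "S_mspb2",
)


@dataclass(frozen=True)
class PartitionRecord:
    """Mitosome counts on the two mSPBs of one cell."""

    cell_id: str
    n_spb1: int
    n_spb2: int

    def __post_init__(self) -> None:
        if self.n_spb1 < 0 or self.n_spb2 < 0:
            raise ValueError("counts are non-negative")

    @property
    def even_or_near_even(self) -> bool:
        return classify_evenness(self)


def classify_evenness(record: PartitionRecord) -> bool:
    """Even or near-even: the two counts differ by at most one."""
    return abs(record.n_spb1 - record.n_spb2) <= 1


def partition_records(cells: Iterable) -> list[PartitionRecord]:
    """Per-cell tethered-count partition records from a cohort."""
    out = []
    for cell in cells:
        n1, n2 = cell.spb_counts
        out.append(PartitionRecord(cell.cell_id, n1, n2))
    return out


def even_fraction(records: Sequence[PartitionRecord]) -> float:
    if not records:
        raise ValueError("no records")
    return sum(r.even_or_near_even for r in records) / len(records)


@dataclass(frozen=True)
class PooledProportion:
    p_hat: float
    ci_low: float
    ci_high: float
    n_total: int
    method: str

    @property
    def highest_p(self) -> float:
        """max(P, 1 - P): the label-free summary of partition asymmetry."""
        return max(self.p_hat, 1.0 - self.p_hat)

    @property
    def highest_p_ci(self) -> tuple[float, float]:
        if self.p_hat >= 0.5:
            return (self.ci_low, self.ci_high)
        return (1.0 - self.ci_high, 1.0 - self.ci_low)


def pooled_binomial_proportion(
    records: Sequence[PartitionRecord], method: str = "normal", alpha: float = 0.05
) -> PooledProportion:
    """Count-weighted pooled proportion of mitosomes on SPB1 with a CI.

    P_hat = sum(n1) / sum(n1 + n2); the default CI is the normal
    approximation P +- z * sqrt(P (1 - P) / n), clipped to [0, 1]; Wilson is
    available.  The partition-asymmetry summary is ``highest_p`` =
    max(P, 1 - P).
    """
    n1 = sum(r.n_spb1 for r in records)
    n = sum(r.n_spb1 + r.n_spb2 for r in records)
    if n == 0:
        raise ValueError("pooled proportion needs at least one nonzero cell")
    from statsmodels.stats.proportion import proportion_confint

    if method not in ("normal", "wilson"):
        raise ValueError("method must be 'normal' or 'wilson'")
    lo, hi = proportion_confint(n1, n, alpha=alpha, method=method)
    return PooledProportion(
        p_hat=n1 / n, ci_low=float(max(lo, 0.0)), ci_high=float(min(hi, 1.0)),
        n_total=n, method=method,
    )


def even_split_null_probability(n: int) -> float:
    """P(|n1 - n2| <= 1) when n organelles are assigned Binomial(n, 1/2).

    Closed form from the central binomial term(s): C(n, n/2)/2^n for even n,
    2 C(n, (n-1)/2)/2^n for odd n; n = 0 or 1 gives 1.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if n <= 1:
        return 1.0
    if n % 2 == 0:
        return math.comb(n, n // 2) / 2**n
    return 2 * math.comb(n, (n - 1) // 2) / 2**n


def chi_square_contingency(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction: (chi2, df, p).

    Rejects tables with any zero expected count (the test statistic is
    undefined there: collapse sparse categories first).
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or np.any(arr < 0):
        raise ValueError("need a 2D table of non-negative counts")
    expected = sps.contingency.expected_freq(arr)
    if np.any(expected <= 0):
        raise ValueError(
            "some expected counts are zero; merge empty rows/columns before testing"
        )
    chi2, p, df, _ = sps.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


#: the compartment-scaling pairs reported for interphase meront cohorts
DEFAULT_CORRELATION_PAIRS = (
    ("V_mit_total", "V_cell"),
    ("N_mit", "V_cell"),
    ("V_mit_total", "V_nuc"),
    ("N_mit", "V_nuc"),
    ("V_mit_total", "V_cyto"),
    ("N_mit", "V_cyto"),
    ("V_mit_mean", "V_nuc"),
)


def correlation_table(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_CORRELATION_PAIRS,
) -> pd.DataFrame:
    """Pearson r with two-sided p (t transform) for each column pair.

    Rows: pair, r, p, n (complete cases).  Raw p-values: no multiplicity
    correction is applied.
    """
    rows = []
    for x, y in pairs:
        sub = table[[x, y]].dropna()
        n = len(sub)
        if n < 3:
            raise ValueError(f"pair ({x}, {y}) has fewer than 3 complete cases")
        r, p = sps.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "r": float(r), "p": float(p), "n": n})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OccupancyResult:
    """Geometric docking capacity of an mSPB cap."""

    radius_nm: float
    cap_area_nm2: float
    footprint_nm2: float
    capacity: int


def mspb_occupancy_capacity(v_mspb_nm3: float, mitosome_diameter_nm: float) -> OccupancyResult:
    """How many mitosomes fit end-on on a half-sphere mSPB of volume v.

    The cap radius follows from v = (2/3) pi r^3; the curved cap area
    2 pi r^2 is divided by the end-on footprint pi (d/2)^2 of a mitosome
    cylinder and floored.  All intermediates are reported so alternative
    area conventions can be compared.
    """
    if not v_mspb_nm3 > 0:
        raise ValueError("mSPB volume must be positive")
    if not mitosome_diameter_nm > 0:
        raise ValueError("mitosome diameter must be positive")
    r = (3.0 * v_mspb_nm3 / (2.0 * np.pi)) ** (1.0 / 3.0)
    cap = 2.0 * np.pi * r**2
    foot = np.pi * (0.5 * mitosome_diameter_nm) ** 2
    return OccupancyResult(
        radius_nm=float(r), cap_area_nm2=float(cap), footprint_nm2=float(foot),
        capacity=int(cap // foot),
    )


def distance_to_envelope(cell, mitosome: BodyShape) -> float:
    """Minimum surface-to-surface distance from a mitosome to the nucleus, nm."""
    if mitosome.kind != "spherocylinder":
        raise ValueError("expected a spherocylinder mitosome")
    a, b = mitosome.cap_centers
    c = cell.nucleus.center
    ab = b - a
    denom = float(ab @ ab)
    t = 0.0 if denom < 1e-30 else float(np.clip((c - a) @ ab / denom, 0.0, 1.0))
    closest = a + t * ab
    return float(np.linalg.norm(closest - c) - cell.nucleus_radius - mitosome.radius)


#: default distance categories (nm) for envelope-proximity contingency tests
DEFAULT_DISTANCE_BINS = (0.0, 50.0, 100.0, 200.0, np.inf)


def bin_distances(
    distances: Sequence[float], bin_edges: Sequence[float] = DEFAULT_DISTANCE_BINS
) -> np.ndarray:
    """Histogram of envelope distances over the stated categories."""
    d = np.asarray(distances, dtype=float)
    if d.size == 0:
        return np.zeros(len(bin_edges) - 1, dtype=int)
    counts, _ = np.histogram(np.clip(d, 0.0, None), bins=np.asarray(bin_edges, dtype=float))
    return counts.astype(int)


def cell_measurement_table(cells: Iterable) -> pd.DataFrame:
    """Per-cell compartment measurements from ground truth, nm^3 / nm^2."""
    from .geometry import surface as body_surface
    from .geometry import volume as body_volume

    rows = []
    for c in cells:
        v_mit = c.v_true
        n = c.n_true
        rows.append({
            "cell_id": c.cell_id,
            "V_cell": c.v_cell,
            "V_nuc": c.v_nucleus,
            "V_cyto": c.v_cytoplasm,
            "V_mit_total": v_mit,
            "N_mit": n,
            "V_mit_mean": v_mit / n if n else np.nan,
            "V_mspb1": body_volume(c.mspb[0]),
            "V_mspb2": body_volume(c.mspb[1]),
            "S_mspb1": body_surface(c.mspb[0]),
            "S_mspb2": body_surface(c.mspb[1]),
        })
    df = pd.DataFrame(rows)
    if len(df):
        bad = df[df.V_cell <= df.V_nuc]
        if len(bad):
            raise ValueError("cell volume must exceed nucleus volume")
    return df
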