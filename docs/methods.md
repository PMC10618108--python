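# Methods

## What the package models

`mitostereo` is a virtual laboratory for design-based stereology of
nanoscale organelles. It simulates microsporidian meront cells whose
geometry and statistics are known exactly, cuts them into virtual serial
sections the way an ultramicrotome and a transmission electron microscope
would, and runs the standard quantitative-EM estimators on the resulting
profiles. Because the ground truth is known, every estimator can be
validated by parameter recovery rather than by comparison with another
estimate.

The biological template is the meront (proliferative) stage of
*Encephalitozoon cuniculi* and *Trachipleistophora hominis*: a roughly
spherical cell with a spherical nucleus, two electron-dense spindle-pole
bodies (mSPBs) sitting on opposite poles of the nuclear envelope, and a
small population of dumbbell-shaped mitosomes (reduced mitochondria,
~50–270 nm) that are largely tethered end-on to the mSPBs.

## Geometry

Three parametric solids cover all structures:

* **sphere** — nucleus, whole cell, and the degenerate mitosome;
* **spherocylinder** (capsule: cylinder with hemispherical caps, total
  tip-to-tip length `L >= 2r`) — the dumbbell mitosome;
* **half-sphere** — the mSPB, flat face on the nuclear envelope. Its
  surface is the curved cap only (`2 pi r^2`): the flat face is not
  available for organelle docking.

All internal lengths are nm (volumes nm³); µm³ appears only at I/O. The
cutting axis is the global z axis and sections are half-open slabs
`[z_lo, z_hi)`, so boundary points belong to exactly one section.

Two profile models are implemented. A *thin-plane* profile is the exact
cross-section at the slab mid-plane (a tomographic slice of negligible
thickness). An *overprojected* profile is the full shadow of the body's
intersection with the slab (a conventional section of finite thickness
imaged in projection); this is the geometric origin of the Holmes effect.

Profile areas are exact up to quadrature, not rasterised. For a capsule the
chord half-width at in-plane abscissa `alpha` is `sqrt(g(alpha))`, where
`g` is the maximum over the cap-centre segment of a concave objective with
closed-form candidate maximisers (stationary points of three quadratic
pieces, their breakpoints, and the endpoints). The area integral uses a
sine substitution so the square-root edges of the profile are integrated
without endpoint singularities; 512 Simpson intervals give relative errors
below 1e-5 for realistic shapes. Sphere and half-sphere sections are closed
form; the rare half-sphere shadow falls back to fine-grid counting.

## Shape conversions

Two closed-form conversions mirror how organelle sizes are reported:
the equivalent-sphere diameter `d = (6V/pi)^(1/3)` (a 0.0001 µm³ organelle
reports as 58 nm after integer rounding), and the capped-cylinder length
`L = 2r + (V - 4/3 pi r^3) / (pi r^2)` at fixed cap diameter. The second
is also used to re-derive merged organelle shapes under the perturbation
model. Note that for a 50-nm cap diameter the closed form pairs 340 nm
with ~0.000635 µm³ and 0.00025 µm³ with 144 nm; the function exposes the
formula and rejects volumes below the cap-sphere volume.

## Synthetic cohorts

Defaults were fixed once, to the study conditions the estimators are meant
to face, and are not tuned per test:

* mitosome minor axes (cap diameter) uniform on 47–119 nm; major axes
  (total length) uniform on 78–267 nm with `L >= 2r` enforced by
  re-drawing the length;
* per-cell count for the *E. cuniculi* profile:
  `N = max(1, round(2.6 + 12.0 * V_nuc[µm³] + eps))`, `eps ~ N(0, 1)`.
  With nucleus radii uniform on 380–520 nm this gives a cohort mean of
  ~7.4 and a count–nucleus-volume correlation of ~0.75, i.e. smooth
  scaling of number with nuclear size without asserting a mechanism;
* tethered fraction 0.92; tethered counts split across the two mSPBs as
  evenly as possible (`ordered_even`) or binomially (`binomial_random`);
* the *T. hominis* profile draws counts uniformly on {14..18} and takes its
  tether fraction from a developmental-stage schedule rising to 0.73 at
  the prespore stage;
* mSPB cap radii uniform on 30–60 nm, placed at antipodal poles of the
  nucleus along an isotropic random direction;
* cell (cytoplasm sphere) radius = nucleus radius × uniform(1.95, 2.15)
  for *E. cuniculi* (2.3–2.7 for the larger *T. hominis*). The shell is
  deliberately generous so that the longest organelles can be placed
  without intersecting either boundary; as a consequence the simulated
  mitosome volume fraction (~0.2 %) is somewhat below the ~0.5 % seen in
  real meronts, which matters for none of the recovery tests.

A tethered mitosome is placed end-on: its near cap surface within a gap of
0–9 nm of the mSPB cap (contact criterion: ≤ 10 nm, below the membrane
resolution of the sections being emulated), axis within 20° of the local
outward normal. If a long organelle cannot fit radially inside the shell
the axis is allowed to lean progressively (60°, then 85°) towards the
envelope — the geometric analogue of long organelles lying along the
nucleus. Free mitosomes get isotropic axes and uniform positions in the
shell by rejection; placement retries are bounded (1000) and failure is an
error, never a silent omission. Where the within-cell distribution of free
mitosomes is not constrained by observation, uniform placement in the
shell is an explicit modelling assumption.

Reproducibility: one root seed; each cell derives an independent RNG
substream keyed by its index, so cohorts are byte-identical for a fixed
seed regardless of generation order or subsetting.

### Dynamin-inhibition perturbation

Mitosomes are merged pairwise in index order: `n -> ceil(n/2)` (an odd
count carries one unmerged organelle), each merged organelle takes the
summed volume of its pair at the larger cap diameter, with its length
re-derived from the capped-cylinder inversion. Aggregate volume per cell
is conserved exactly; the expected treated/control mean individual volume
ratio is slightly below 2 because of the odd-count carry.

## Virtual microtome

* `cut_serial` — exhaustive serial sections of thickness `t` (default
  43 nm), random phase uniform on `[0, t)`, spanning every body.
* `cut_tomographic` — thin mid-plane slices at spacing `dz` (default
  2 nm; the thin-slice Cavalieri reference uses 1 nm). The tomographic
  slice spacing of the real calibration is not constrained by the
  workflow being emulated; these defaults are implementation choices.
* `assemble_superslices` — blocks of `k` thin slices merged by mask union
  on a stated grid: the discrete route to an overprojected section,
  consistent with the exact shadow within grid resolution.
* `sample_ministacks` — short stacks with starts uniform over the cell
  z-extent, never extending beyond it.
* `subsample_intermittent` — one section in every `k` (random residue
  class), spacing metadata `k*t` for Cavalieri; appearance counting is
  invalid on subsampled stacks and is not offered there.

## Estimators

* **Point counting**: grid corners inside the profile (exact membership
  query, never the raster mask), `area = hits * s^2`; unbiased over random
  grid offsets.
* **Cavalieri**: `V = d * sum(areas)`; raw and corrected values are both
  reported whenever a correction factor is applied.
* **Overprojection factor**: ratio of conventional-section to thin-slice
  Cavalieri totals over the same objects (`derive_correction_factor`
  re-enacts the tomography calibration on a subset of cells); the
  model-based comparator is the full-shadow Holmes form
  `1 + t S / (4 V)` using the Cauchy mean projected area `S/4` of a convex
  body under isotropic orientation. For a sphere the phase-averaged factor
  is exactly `1 + 3t/(4r)` (2.29 at r = 25 nm, t = 43 nm), which the
  simulation reproduces; for the simulated mitosome shape mix the cohort
  factor comes out at ~1.55–1.65, the regime of the empirical 1/1.61
  correction used with real sections. Lost faint caps and finite slice
  thickness would push a real factor below the full-shadow ideal; an
  optional visibility threshold is deliberately *not* asserted with any
  particular value.
* **Appearance counting**: a particle is counted where its profile run
  ends (present in section *i*, absent in *i+1*). Runs reaching the final
  section are reported as truncated and not counted unless the caller
  asserts the stack spans everything (then a virtual empty terminal
  section closes them). On convex particles fully spanned by a stack the
  count is exact, not merely unbiased. For imported profile tables without
  identity, profiles in adjacent sections are linked iff their masks share
  a grid point, merging conservatively.
* **Densities**: `Nv = counted / reference volume`, `N_hat = Nv * V_ref`;
  `Vv` as a pooled area (or point-count) ratio. Two cohort-scale forms are
  provided: `cohort_pooled_densities` (ratio of sums — per-cell ratios
  from a few ministacks are heavy-tailed) and
  `fractionator_number_estimate`, which inverts the known inclusion
  probability `p = (k-1) t / (extent - k t)` of a particle top and needs
  no reference-volume estimate. Tops in the last `t` of the cell can never
  be counted (stacks must not leave the cell), a ~1–2 % negative edge
  bias at realistic sizes; it cancels in treated/control ratios.
* **Star volume**: `v* = (pi/3) * mean(l^3)` over point-sampled isotropic
  intercepts; intercepts are measured on the exact membership function by
  bisection (closed form for spheres). For a sphere `v*` equals the
  volume, the identity used as a recovery check.
* **CE**: the between-cell coefficient of error of the mean,
  `(SD/sqrt(n))/mean`, matching the `CE_n` notation attached to cohort
  means; the Gundersen–Jensen within-stack CE for systematic point-count
  series is a separately named output and never substituted.

## Partition and inference statistics

Evenness is `|n1 - n2| <= 1`. The binomial null for "even or near-even"
under random assignment of `n` organelles is closed form from the central
binomial terms (`70/128` at n = 7). The "weighted average analysis in a
binomial distribution" is implemented as the count-weighted pooled
proportion `P = sum(n1)/sum(n)` with a normal-approximation CI (Wilson
optional), reported as `highest P = max(P, 1-P)` so the arbitrary SPB
labelling drops out. Chi-square contingency tests are Pearson without
continuity correction; zero expected counts are rejected with guidance.
Correlations are Pearson r with two-sided p from the t transform, raw
(uncorrected) as is conventional for these cohort tables. The mSPB
occupancy model converts a half-sphere volume to its cap radius and
divides the curved cap area by the end-on footprint `pi (d/2)^2` of a
mitosome cylinder, reporting all intermediates because published area
conventions for this quantity are ambiguous.

## Sampling intensities used in the recovery studies

Chosen from precision (CE) considerations before comparison, and stated
here as the package's own study design:

* shadow-factor phase average: 5000 random phases (Monte-Carlo CE « 1 %);
* volume recovery: 50 cells, thin dz = 1 nm, conventional t = 43 nm,
  correction factor derived from a 10-cell calibration subset;
* appearance counting: 200 cells, exhaustive 43-nm stacks;
* star volume: 1e5 intercepts;
* partition null: 10 000 simulated cells at n = 7;
* perturbation detection: 100 cells/arm, 16 ministacks × 8 sections at
  43 nm with paired placements between arms and pooled (ratio-of-sums)
  densities — per-cell clustering of tethered organelles overdisperses
  ministack counts, so unpaired per-cell ratios at this size would be
  dominated by sampling noise;
* *T. hominis* number recovery: 60 ministacks × 8 sections at 40 nm per
  cell with the fractionator-style inversion.

## What passing these tests does and does not show

The generator provides convex, well-separated, ideal-contrast organelles
in ideal slabs. Passing recovery tests therefore validates the estimator
logic and its sampling theory — not robustness to segmentation error,
stain variability, section compression, tilt, or lost caps, none of which
are modelled. Tomographic reconstruction itself (tilt series, alignment)
is out of scope; thin slices are taken as geometrically perfect.

## Numerical choices

Membership uses strict `<=` on exact squared distances with no epsilon
inflation. Golden-section and bisection searches run to fixed iteration
counts chosen to exhaust double precision. Axis vectors must be unit to
1e-9. Degenerate inputs (empty stacks, zero counts, all-zero tables) are
either well-defined (empty histogram, Vv = 0 with a small-sample warning)
or rejected with a message naming the offending quantity.
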