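# mitostereo

Virtual serial-section stereology for nanoscale organelles.

Quantitative electron microscopy of very small organelles — here the
mitosomes (reduced, genome-less mitochondria, ~50–270 nm) of microsporidian
parasites — rests on a chain of design-based estimators: Cavalieri
point-counting volumetry on serial sections, a correction for
overprojection (the Holmes effect, severe when the object size is close to
the 43-nm section thickness), appearance-based particle counting on
adjacent sections, volume/number densities from randomly placed ministacks,
and star volume from point-sampled intercepts. Each of these is only as
trustworthy as its sampling theory, and with real micrographs there is no
ground truth to check it against.

`mitostereo` provides that ground truth synthetically. It generates meront
cells whose geometry is known exactly — a spherical nucleus carrying two
half-sphere spindle-pole bodies (mSPBs), dumbbell (spherocylinder)
mitosomes tethered end-on to them or free in the cytoplasm — cuts them
into virtual sections (thin tomographic slices, conventional overprojected
sections, superslices, ministacks, one-in-k intermittent series), and runs
the estimators so that every result can be compared with the simulated
truth. The partition statistics used to study organelle inheritance across
the two mSPBs (evenness classification, the binomial null for random
assignment, the pooled "highest P" proportion) are included, as are the
Pearson correlation tables between compartment measurements and the mSPB
occupancy-capacity model.

Core quantities, in the field's notation:

* Cavalieri: `V̂ = d · Σᵢ Aᵢ`, with areas from point counting,
  `Aᵢ = Pᵢ · s²`;
* overprojection factor: empirically `V̂_thick / V̂_thin` on the same
  objects, model-based `1 + t·S/(4V)` (Cauchy mean projected area of a
  convex body under isotropic orientation; for a sphere the phase average
  is exactly `1 + 3t/4r`);
* appearance counting: particles = profile runs ending between adjacent
  sections (the serial-section disector rule);
* densities: `Nv = ΣQ⁻ / V_ref`, `N̂ = Nv · V_ref`, `Vv = P_struct/P_ref`;
* star volume: `v* = (π/3)·E[ℓ³]` over point-sampled intercepts;
* CE: between-cell `(SD/√n)/mean`.

## Worked example

Simulate an 18-cell *E. cuniculi*-style cohort, section it at 43 nm,
estimate, and summarise:

```
mitostereo simulate --n-cells 18 --seed 42 --out-dir run
mitostereo section  --in-dir run --thickness 43 --seed 1
mitostereo estimate --in-dir run
mitostereo stats    --in-dir run
```

`estimates.csv` then contains, per cell, the raw and overprojection-
corrected Cavalieri volumes and the appearance count, plus cohort rows:

```
cell_id         quantity        value units       ce
 cohort       V_raw_mean 1.049759e+07  nm^3 0.078945
 cohort V_corrected_mean 6.714847e+06  nm^3 0.084008
```

The raw conventional-section mean (1.05e7 nm³ = 0.0105 µm³) overstates the
true mean total mitosome volume of this cohort (6.62e6 nm³) by the
overprojection factor ≈ 1.6; the corrected mean (6.71e6 nm³) lands within
1.5 % of the truth. `report.txt` summarises the cohort statistics:

```
Compartment correlations (Pearson r, two-sided p):
         N_mit vs V_nuc      r=+0.7049 (n=18) p=0.001087
   ...
Mitosome partition across the two mSPBs:
  even-or-near-even fraction: 1.000
  pooled binomial highest P = 0.504 [limits 0.41-0.60] (n = 115 mitosomes)
```

Mitosome number scales with nuclear volume, and under the even-split
partition mode every cell distributes its tethered mitosomes as evenly as
possible across the two spindle-pole bodies, with a pooled proportion
statistically indistinguishable from one half.

The same operations are available as a library
(`mitostereo.generate_cohort`, `cut_serial`, `stack_cavalieri`,
`count_by_appearance`, `cohort_pooled_densities`, ...); see
`docs/methods.md` for the model, the estimators and the study-design
choices.

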