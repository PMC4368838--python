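# ivusecho

Adventitia-referenced **differential echogenicity** analysis of
intravascular ultrasound (IVUS) pullbacks, built for monitoring the
degradation of bioresorbable (poly-L-lactide) vascular scaffolds.

IVUS grey levels are not comparable across pullbacks: transducer gain and
acoustic coupling shift the whole intensity scale. Differential
echogenicity solves this by referencing every pixel of the vessel wall to
the **adventitia**, the reliably bright layer just outside the external
elastic membrane (EEM). Given per-frame lumen, scaffold and vessel
contours, the pipeline:

1. extracts a thin adventitial ring 0.01–0.21 mm outside the vessel
   contour of each frame;
2. screens the ring in 2° sectors with an adaptive Otsu threshold,
   discarding sectors that are mostly dark (guidewire shadow, pericardium,
   side branches) so only genuine bright adventitia remains;
3. pools the surviving histograms over the pullback; the pooled **median**
   *m* splits the wall into hypo- (< *m*) and hyperechogenic (≥ *m*)
   pixels;
4. derives a **high-intensity threshold** *h* by three-stage iterated Otsu
   (each stage re-thresholds the levels strictly above the previous cut);
5. groups wall pixels with grey > *h* into connected components and tests
   each for an **acoustic shadow** (mean grey within 0.5 mm radially
   behind the component below 0.25 × *m*): shadowed components are
   **calcified** and their shadow **unknown**; shadowless ones are
   **upperechogenic**;
6. integrates the five classes into volumes (area × 0.5 mm frame spacing)
   per compartment — lumen–scaffold, scaffold–vessel, and total wall —
   with neointima volume = vessel − lumen, plus normalization of all
   volumes to the cohort mean scaffold length.

Because polymer struts are strongly echogenic while they are intact and
fade as the polymer resorbs, the hyper + upperechogenic volume in the
scaffold–vessel compartment is a non-invasive surrogate for the residual
molecular weight (Mw): the `stats` layer provides Pearson correlation,
OLS regression, Ward clustering (squared Euclidean, deterministic ties)
and ICC(2,1) reader-agreement statistics.

No acquired data ship with the package; a **synthetic phantom generator**
renders speckled layered cross-sections (Rayleigh multiplicative speckle)
with contours, bright strut blocks whose brightness is linear in Mw, dark
wedges over the adventitia, and calcified arcs with radial shadows — with
exact ground-truth labels for validation.

## Worked example

```python
import ivusecho as iv

pb = iv.generate_pullback(iv.PhantomConfig(seed=1, mw_kda=92.9))
res = iv.analyze_pullback(pb.frames, pb.contours)
print(res.thresholds.median_threshold, res.thresholds.high_threshold)
# 163 231
row = res.volume_table.as_row()
print(round(row["scaffold_vessel_hyper_upper_mm3"], 2))
# 0.91
```

The pooled adventitial median of this phantom is grey level 163 and the
iterated-Otsu high threshold 231; the intact struts contribute
0.91 mm³ of hyper + upperechogenic volume to the scaffold–vessel
compartment of the 3 mm pullback. Running the degradation cohort
(`examples/04_degradation_cohort_statistics.py`) yields

```
scaffold-vessel hyper        r=+0.960 (p=2.59e-15) R^2=0.921
scaffold-vessel upper        r=+0.948 (p=6.09e-14) R^2=0.899
scaffold-vessel hyper_upper  r=+0.975 (p=7.15e-18) R^2=0.951
```

i.e. high-echogenicity volume tracks the residual molecular weight across
the nine-timepoint degradation schedule. The `examples/` directory has one
short script per capability (pipeline, adaptive reference, shadow
discrimination, cohort statistics).

## Command line

```bash
ivusecho phantom data/ --seed 1 --n-frames 6          # synthetic dataset
ivusecho analyze data/ out/                           # full pipeline
ivusecho stats out/volumes_wide.csv mw.csv            # degradation stats
ivusecho reproducibility readings.csv                 # ICC
```

`analyze` consumes a directory with `frames.tif` (or `frames/*.png`),
`contours.csv` (`frame_index, contour_type, vertex_order, row, col`) and a
`meta.json` sidecar (pixel spacing, frame spacing, catheter center), and
writes per-frame label PNGs, reference diagnostics, volume tables and the
exact run configuration.

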