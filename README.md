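# pellimetrics

Quantitative characterization of bacterial cellulose, from single fibers to
macroscopic pellicles. Bacterial cellulose grows as a pellicle — a film of
entangled β-1,4-glucan fibers at the air–medium interface of a static
culture — and each fiber alternates ordered (crystalline) and disordered
(amorphous) domains. This package implements, as one tested pipeline, the
measurements used to characterize such material:

* **Single-fiber crystallinity** from TIRF timelapses of dye-stained fibers:
  super-resolution radial fluctuations (SRRF) reconstruction with temporal
  radiality auto-correlation (TRAC), intensity profiles along traced fibers,
  peak detection with FWHM/spacing/median-prominence filters, and

  ```
  crystallinity% = Σ dark lengths / (Σ dark + Σ bright lengths) × 100
  ```

  where bright (amorphous) lengths are peak FWHMs and dark (crystalline)
  lengths are the gaps between adjacent peaks at half maximum.

* **Pellicle crystallinity and crystallite metrics** from wide-angle X-ray
  scattering: slit-removal frame merging, azimuthal integration, amorphous
  background fitting, and on 2θ ∈ [10°, 45°]

  ```
  crystallinity% = (area_sample − area_background) / area_sample × 100
  ```

  plus per-reflection lattice spacings d = 2π/q (Bragg, first order) and
  crystallite sizes τ = Kλ/(β cos θ) (Scherrer, K = 0.94, Cu Kα λ = 1.54 Å).

* **Raman preprocessing** (Savitzky–Golay smoothing, piecewise polynomial
  background subtraction, normalization to the 1094 cm⁻¹ cellulose band) and
  a calibrated presence test for the acetylation carbonyl band near
  1740 cm⁻¹.

* **Tensile mechanics** of wet dogbone specimens: 2.5 mN onset shift,
  engineering stress–strain conversion, modulus from the 60–80% window of
  the strain at maximum stress, and strength at rupture.

* **Equivalent-cylinder density**: the segmented side-view cross-section
  area A gives h = A/(2r), V = πr²h and ρ = W/V from the dry mass W.

* **Statistics**: one/two-way ANOVA, Bonferroni-protected pairwise
  comparisons gated on the omnibus test, Pearson correlation.

A `synthetic_data` module generates every input the pipeline consumes —
blinking-fluorophore fiber stacks, diffractograms and detector frames,
tensile records, pellicle photographs — with stored ground truth, so each
stage is testable end-to-end without instrument data.

## Worked example

Recover the crystallinity of one synthetic fiber whose ground truth is
exactly 75% (600 nm crystalline / 200 nm amorphous domains):

```python
from pellimetrics import fiber_domains as fd, radiality, synthetic_data as sd

truth = sd.fixed_fiber_truth()            # 75.0% by construction
stack = sd.gen_fiber_stack(truth, seed=1) # 30-frame blinking timelapse
params = radiality.SRRFParams(radiality_magnification=4)
recon = radiality.trac_reconstruct(stack, params, linearize=True)

mag = params.radiality_magnification
trace = truth.path * mag + (mag - 1) / 2  # trace on the magnified grid
seg = fd.analyze_fiber(recon, trace, truth.pixel_size_nm / mag)
print(f"true {100 * truth.true_crystallinity:.1f}%  "
      f"estimated {seg.crystallinity_pct:.1f}%  "
      f"({len(seg.bright_lengths_nm)} bright / {len(seg.dark_lengths_nm)} dark domains)")
```

```
true 75.0%  estimated 69.8%  (8 bright / 7 dark domains)
```

The estimate is the fraction of the fiber span between the first and last
retained peak that is dark (crystalline); individual fibers scatter by a few
percentage points and the group mean over ~30 fibers recovers the truth
within about one point.

The same stages are available from the shell, e.g.:

```bash
pellimetrics simulate diffractogram --seed 1 --fraction 0.25 --out d.csv
pellimetrics waxs d.csv --out report.json
```

which prints `crystallinity 23.6%` and writes the fitted background areas,
per-reflection lattice spacings and Scherrer sizes to `report.json`.

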