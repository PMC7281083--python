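# filatrans

Quantification of the **material-transition distance** in single-nozzle
multi-material (SNMM) extrusion bioprinting.

When one nozzle dispenses several bioinks in sequence, the printed filament
does not switch instantly from one material to the next: residual ink in the
printhead blends into the incoming one over some length of filament. That
length — the transition distance — is the key quality metric of an SNMM
printhead, and it depends on extrusion pressure, nozzle inner diameter and
whether the printhead channels carry a hydrophobic (silicone) coating.

`filatrans` measures it from photographs of two-dye (red → blue) filaments:

1. **Segmentation** — the filament crop is converted to black and white and
   its boundaries delimited with Canny edge detection (high threshold 0.3,
   low = 0.4 × high).
2. **Profile extraction** — the RGB values of the pixels between the
   detected edges are averaged per image column and smoothed with a centered
   20-px moving average.
3. **The 90–10 statistic** — with the smoothed red signal r(x) normalized to
   its own extremes, the transition distance is

   D = x(r = 0.1) − x(r = 0.9)   (px, converted to mm; uncertainty floor 0.02 mm)

   i.e. the axial span between the positions where the signal crosses 90%
   and 10% of the maximum red value, refined to sub-pixel by linear
   interpolation. For a Gaussian-CDF blend of spread σ this equals
   (z₀.₉ − z₀.₁)·σ ≈ 2.5631 σ; for a linear ramp of length L it is 0.8 L.
4. **Diffusion correction** — dye keeps spreading inside the filament after
   deposition, inflating the apparent distance linearly with the time t
   between printing and imaging. A through-origin least-squares law
   D_diff = k·t (slope k = Σtᵢdᵢ / Σtᵢ², in mm/s) fitted on a repeatedly
   imaged filament is subtracted: D_corrected = D_measured − k·t.
5. **Aggregation** — per-condition summaries (n, mean, sd, min, max) over
   pressure / nozzle / coating, with descriptive trend slopes.

Because studies of this kind rarely deposit their photographs, the package
ships a first-class synthetic generator: straight two-ink filament rasters
whose 90–10 width is known in closed form (step, linear-ramp or
Gaussian-CDF blend, optional linear- or √t-growth over time, band-edge
softness, i.i.d. Gaussian pixel noise). Every pipeline stage is validated
against that analytic ground truth.

## Worked example

```python
import numpy as np
from filatrans import (SyntheticFilamentSpec, generate_filament_image,
                       analyze_image, measure_transition, fit_diffusion_model,
                       correct_transition)

# a filament imaged 120 s after printing: dye keeps spreading meanwhile
spec = SyntheticFilamentSpec(profile_kind="gaussian_cdf", profile_param=10.0,
                             elapsed_s=120.0, seed=42)
image, truth = generate_filament_image(spec)
profile = analyze_image(image)            # binarize -> Canny -> mask -> profile
result = measure_transition(profile)
print(f"measured transition distance: {result.distance_mm:.2f} "
      f"± {result.uncertainty_mm:.2f} mm ({result.distance_px:.1f} px)")
print(f"ground truth at capture time: {truth.true_width_90_10_mm:.2f} mm")

# through-origin fit of the apparent growth over time
t = np.array([10.0, 60.0, 120.0, 300.0])
model = fit_diffusion_model(t, 0.03060 * t)
print(f"fitted diffusion slope: {model.slope_mm_per_s:.5f} mm/s")

corrected = correct_transition(result, model)
print(f"diffusion-corrected distance: {corrected.corrected_mm:.2f} mm")
```

prints

```
measured transition distance: 5.26 ± 0.05 mm (105.1 px)
ground truth at capture time: 4.95 mm
fitted diffusion slope: 0.03060 mm/s
diffusion-corrected distance: 1.58 mm
```

The filament was generated with a fresh (t = 0) 90–10 width of 1.28 mm that
grew by 0.0306 mm/s × 120 s = 3.67 mm before "imaging"; the measurement
recovers the grown width (5.26 vs 4.95 mm — the excess is the documented
20-px smoothing bias), and subtracting the fitted growth law brings the
estimate back to the fresh width within the same bias allowance.

The same workflow is available from the shell:

```sh
filatrans simulate --spec spec.yaml --out images/ --n 5 --seed 1
filatrans measure images/*.png --mm-per-px 0.05 --elapsed-s 120 --out measurements.csv
filatrans fit-diffusion timeseries.csv --out model.json
filatrans summarize measurements.csv --conditions map.csv --plots figs/
```

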