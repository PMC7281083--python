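# Methods

## The measurement model

A two-ink filament is modelled as a one-dimensional color blend along the
print axis: at axial position x the filament color is

    c(x) = g(x) · c_A + (1 − g(x)) · c_B,

with g(x) the fraction of the upstream ink A, monotone non-increasing from
1 to 0 across the transition zone. The quantity of interest is the 90–10
width: the axial span over which the red channel, normalized to its own
extremes, falls from 0.9 to 0.1. For the three supported blend shapes the
width is closed-form:

| profile      | g(x)                          | 90–10 width |
|--------------|-------------------------------|-------------|
| step         | 1(x < c)                      | 0           |
| linear ramp  | clip(½ − (x − c)/L, 0, 1)     | 0.8 L       |
| Gaussian CDF | 1 − Φ((x − c)/σ)              | (z₀.₉ − z₀.₁)σ ≈ 2.5631 σ |

Because the red channel is affine in g, self-normalizing the red profile
makes the measured width independent of the particular ink colors, of the
background contribution mixed in at soft band edges, and of any affine
intensity change (exposure, white balance). This affine invariance is why
"maximum red value" is read as the profile's own maximum rather than the
8-bit channel maximum; the two readings coincide for saturated inks and
the former remains meaningful for unsaturated ones.

## Pipeline choices

**Binarization.** The "black and white" step is a global Otsu threshold on
luminance. The raw Otsu value is a histogram-bin center and can land on the
wrong side of a luminance value occupying that bin — a real problem for
near-noiseless synthetic images whose histogram is three spikes — so the
threshold is refined by isodata iteration to the midpoint between the two
class means, which is unambiguous. The *minority* class is taken as the
filament, making segmentation polarity-free (dark inks on light background
or the reverse).

**Edge detection.** Canny with high threshold 0.3 and low threshold
0.4 × high (the common dual-threshold convention when only one number is
quoted), Gaussian pre-smoothing σ = 1 px. By default Canny runs on the
binarized image; a `canny_on="gray"` switch runs it on the grayscale image
instead — on clean crops both delimit the same band.

**"Within the detected edges"** is interpreted per image column: the mask
is the rows strictly between the column's outermost edge pixels. This
matches the per-position averaging that an along-filament transition plot
implies. Columns with fewer than two edge pixels are excluded; fewer
covered columns than a configurable minimum (default: the smoothing
window) is an error rather than a silent short profile.

**Smoothing.** The 20-px moving average is centered. A centered window of
even length does not exist on an integer grid, so even windows use the
symmetric trapezoidal kernel of support `window + 1` with half-weight
endpoints. This keeps the filter free of the half-pixel positional bias of
the trailing/asymmetric convention, makes it exact (hence mean-preserving)
on linear profile segments, and still yields exactly 0.8 × window = 16 px
for the 90–10 span of a smoothed ideal step at the default window of 20.
At the profile ends the kernel is truncated symmetrically and
renormalized, so no padding value leaks into the profile. Smoothing a
Gaussian-CDF blend of spread σ inflates the measured width to roughly
2.5631·√(σ² + w²/12) px for window w; the tests and the acceptance
thresholds therefore carry an additive smoothing allowance of
0.8 · window · mm_per_px, which bounds that inflation for all widths used.

**Crossing rule.** Scanning in the print direction, the transition end is
the first sample at or below 0.1 and its start the last preceding sample at
or above 0.9 — an outermost-bracket rule that is stable when noise makes
the signal re-cross a threshold. Both crossings are refined to sub-pixel
by linear interpolation (distances are conventionally reported at 0.01-mm
resolution, finer than a pixel); a `pixel_exact` flag reproduces
integer-sample behavior. Crossings whose bracketing interval touches the
first or last profile sample set `clipped_at_boundary`; flat profiles and
profiles that never complete the transition raise errors naming the failed
bound. The reported uncertainty is max(0.02 mm, one pixel).

## Diffusion correction

The apparent width grows after deposition as dye spreads within the
filament. The growth law is fitted *empirically* as a straight line through
the origin, D_diff = k·t (slope k = Σtᵢdᵢ/Σtᵢ², mm/s): through-origin
because a filament imaged at t = 0 can have suffered no post-print
spreading, so the diffusion-attributable term must vanish there. R² is
computed about the through-origin model (uncentered) and the slope standard
error from the residual variance over Σt². The correction subtracts k·t
from a measurement taken at elapsed time t; the elapsed time must be
supplied (from image metadata or explicitly) — it is never assumed zero.
Negative corrected values are kept and flagged rather than clamped, which
keeps condition means unbiased. One global model is the default; nothing
prevents fitting per-condition models if the spreading rate is suspected to
vary with nozzle or pressure.

Physical 1-D diffusion would give √t growth of the blur width; the linear
law is treated as purely empirical over the time scales of interest, and
the generator supports both laws (default linear, coefficient 0.03060 mm/s,
the empirically fitted spreading rate for the dyed starch inks emulated
here).

## The synthetic generator

The generator renders what the analysis assumes: a straight, horizontal
filament band (default 40 px wide at 0.05 mm/px, i.e. a 2-mm filament at
20 px/mm) of two blended inks on a light background, with optional
Gaussian softening of the band boundary (default 1 px), i.i.d. per-channel
Gaussian pixel noise (default sd 0.01; 0.03 in the stress tests), and a
post-print growth law applied as an *additive widening of the 90–10 width*
regardless of profile shape, so the ground truth stays closed-form. A step
profile that must carry a positive width is rendered as the linear ramp of
that width. Identical specs (including seed) render bitwise-identical
images.

What it deliberately does not emulate: filament curvature (real serpentine
prints are cropped to straight segments before analysis, and a `--rotate`
flag handles small tilts), specular highlights, perspective or illumination
gradients, and non-Gaussian sensor noise. Passing tests therefore certify
the measurement chain — segmentation, masking, averaging, smoothing,
crossing detection, unit conversion, correction — against the stated image
model, not robustness to photographic artifacts.

## Numerical and degenerate-input conventions

- Pixel grid is 0-based, row-major, origin top-left; axial positions are
  column indices of the analyzed crop.
- Direction (red falling vs rising) is inferred from the smoothed red
  endpoints with a 0.02-intensity dead band; a flat filament yields an
  undetermined direction, which is flagged at profile level and refuses
  measurement rather than guessing.
- Condition summaries sort values before aggregating, so input order
  cannot change the result even in floating point; sd uses ddof = 1 and is
  0 for n = 1; batched summaries merge by exact pooled mean/variance.
- Trend diagnostics are descriptive least-squares slopes per factor cell
  (≥ 2 levels required, else "n/a"), not hypothesis tests.

## Problem sizes

Default test and acceptance images are 120 × 800 px (1600 px where the
grown transition needs more room), profile spreads σ ∈ {5, 10, 20, 40} px,
ramps of 50–200 px, 20 noise replicates per width at noise sd 0.03, 100
seeds for slope recovery at n = 50 points, elapsed times up to 300 s.
These sizes put every closed-form comparison well inside its tolerance
while keeping the full suite a few seconds of compute.

## Known limitations

- The 90–10 rule is the only metric; hi/lo are exposed as parameters but
  alternative statistics (hue-angle, per-channel fits) are out of scope.
- Curvilinear filaments need manual cropping to straight segments.
- The published per-condition minima of the printhead-characterization
  experiments cannot be reproduced because the underlying photographs are
  not publicly deposited; the aggregation layer is validated on synthetic
  sweeps instead.
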