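# Methods

## Operators and conventions

Images are 2-D float64 arrays throughout the pipeline; quantization
(round-half-even) happens only when an image is written to disk.
Structuring elements (SEs) are flat by default; per-offset heights are
supported by the type but unused by the enhancement method.

**Border policy.**  Dilation and erosion restrict the extremum to SE
offsets whose source pixel lies inside the image — equivalently, −∞
padding for dilation and +∞ for erosion.  This is the literal reading
of the domain constraint in the operator definitions and avoids
inventing reflected or replicated boundary values.  All the classical
algebra (duality, idempotence of opening/closing, anti-extensivity /
extensivity, monotonicity) holds exactly under this policy and is
enforced by property tests.

**SE rasterization.**  Line elements are 1 px wide with odd length so
the origin is the geometric centre; disks contain every offset with
s² + t² ≤ (d/2)².  Under this rule a diameter-3 disk includes the
diagonals (√2 ≤ 1.5) and is the full 3×3 square.  Odd sizes are
required; the sizes used in practice (9, 11, 21, 31, 41) all are.

**Rotation.**  RMP rotates the image clockwise by θ_i = 180·i/N about
the centre of the frame, filters, rotates back counter-clockwise.
Defaults: N = 8 (the method's orientation coverage; N is a free
parameter of the decomposition and 8 covers line orientations at
22.5° granularity for moderate cost), bilinear interpolation, and
edge-replicate fill for pixels without a source — constant fill would
create dark corner wedges that the closing would "repair",
contaminating the smoothing near borders.  Rotations by multiples of
90° on square frames are executed as exact pixel permutations, which
makes the N = 1 and N = 2 degeneracy identities exact.  Constants are
fixed points of all RMP operators to machine epsilon only (bilinear
weights at oblique angles sum to 1 up to rounding); the shifted
top-hat minimum is exactly 0 by construction.

## The two-step enhancement

Step 1: δ^TH(f) = f − SM(f), shifted so its minimum is 0, with
SM = ½(γ′ϕ′ + ϕ′γ′).  The SE must be larger than the base size of the
target structure and smaller than the background structures that
should be preserved — the method's central operating assumption.

Step 2: global histogram equalization over 256 levels (the feature
image is affinely pre-quantized to 256 bins; mapping T(v) =
round(255·CDF(v)), monotone, rank-preserving), then linear stretch to
[0, 255].  The pipeline is exactly invariant to adding a constant to
the input.

Comparison methods, at the settings used for the evaluation:

- **USM**: (f − w·G_σ(f)) / (1 − w), σ = 10 px, w = 0.7.  This
  normalization, among the several the verbal definition admits, is
  the one that leaves flat regions at their original level.
- **MSR**: Σ_k w_k·[log(f+1) − log(G_{σ_k}(f)+1)], σ = 5/50/150 px,
  w = ⅓; log(x+1) handles zeros; the output is linearly stretched to
  the display range (the post-retinex normalization is otherwise
  unspecified).
- **CLAHE**: 15×15 blocks; per-block histograms clipped at
  `clip` × uniform bin height (default 2.0) with the excess
  redistributed evenly; per-block CDF mappings bilinearly interpolated
  between block centres.  With one block and clip → ∞ this reduces
  exactly to global HE, a limit the tests pin.  It is implemented
  in-package because this clip parameterization and limit behaviour
  differ from library variants.
- **HE / LCS** applied directly to the original image.

## CIR

C(x,y) = |p − a| / (p + a) with p the 3×3 centre mean and a the mean
of the 40 surrounding pixels of the 7×7 window ("surrounding region"
is read as excluding the centre; a flag restores the full-49 reading
for sensitivity analysis).  CIR sums |C − C̄|² / ΣC² over the pixels
whose 7×7 window lies fully inside the ROI, so numerator and
denominator run over the identical pixel set.  Both images are
linearly stretched to [0, 255] before comparison: CIR then measures
change in contrast *structure*, and a pure affine re-scale of the
enhanced image scores exactly 0.  A ROI in which the original is
perfectly flat raises an error (the ratio is undefined).

## The synthetic experiment

The generator reproduces the geometry and statistical structure of
the simulated-mammogram evaluation without external data.

**Masses.**  Filled disks of diameters 11/21/31 px (2.2/4.2/6.2 mm at
200 μm/px), amplitude 30 intensity units, Gaussian edge smoothing
σ = 2 px, blended additively; square ROIs of 35/45/55 px centred on
each mass.  σ = 2 keeps every mass's base diameter (d + ~4σ ≤ 39 px)
below the 41-px element, as the SE-selection rule requires; a σ that
grows with diameter (d/8 is available as an option) pushes the 31-px
mass's base beyond the element and extraction becomes incomplete even
on a flat background — a useful illustration of the rule, but not a
valid default for an experiment premised on it.

**Background.**  Four components: a constant tissue level (128); a
coarse Gaussian-correlated texture (σ = 96 px, std 2) plus a gentle
diagonal gradient (span ±1) for parenchymal inhomogeneity; unsmoothed
pixel grain (std 1) for film/detector fine texture; and a dark
exposed-film margin (level 8, left 35 % of the width, sigmoid
transition of scale 16 px).  Masses are auto-placed along the
diagonal of the tissue region, clear of the transition and of each
other's ROIs.  Every component is seeded and the whole experiment is
bit-reproducible.

Each component is load-bearing for fidelity to the real evaluation
regime, and the defaults were calibrated so the generator satisfies
the method's stated operating conditions:

- The *fine grain* populates the feature-image histogram.  Without
  it, the extracted masses are the only non-background pixels, HE
  compresses them onto the background level, and unsharp masking —
  with nothing else to amplify — inflates mass-edge contrast and
  dominates the CIR comparison, inverting the known ordering.  With
  grain present, HE maps the background to mid-gray and the masses to
  the top of the range, while USM and CLAHE spend their gain on the
  grain.
- The *film margin* keeps the tissue at mid-to-high quantiles of the
  global histogram.  Global HE amplifies local noise contrast in
  direct proportion to how dark it renders a region; with a symmetric
  background the smallest-mass ROI lands at a low quantile for some
  seeds and global HE rivals the proposed method there.  The margin
  reproduces the real-image situation in which the dark film area
  occupies the low quantiles.
- The *coarse texture* must be weak and smooth at the SE scale: the
  top-hat's one-sided window minima pick up background slope, costing
  the extraction roughly slope × SE/2 intensity units of mass
  amplitude.  Background power at or below the SE scale is itself
  "feature" and leaks into the extraction.  At the defaults the
  top-hat retains < 0.1 % of background variance outside the ROIs and
  recovers ~90–96 % of each mass's added energy (measured as the
  energy of the change in the unshifted top-hat caused by adding the
  mass, relative to the added energy); the exact fraction varies by
  about ±3 points with the background realization.

**What the generator does not model** — and hence what passing tests
do not show: clustered-lumpy mammographic texture, anatomic
structures (ducts, vessels, pectoral muscle), spatially varying noise,
scanner MTF, and masses with irregular or spiculated margins.  The
synthetic background is deliberately in-regime; on real images whose
background has strong power near the SE scale the extraction degrades
as described above, and noise-reduction preprocessing would be needed
for low-dose images.

## Problem sizes and numerics

The CIR comparison runs at 512×512 (three masses, five seeds in the
acceptance tests) and the size-selectivity experiment at 256×256 —
sizes at which the background statistics are stable while the full
test suite and the acceptance script each complete in well under a
minute.  Morphology is computed by shifted-array extrema over SE
offsets (O(|B|·HW)), exact against the double-loop definition; no
decomposition or van Herk optimization is used, keeping the
brute-force contract as the implementation.  CIR uses uniform-filter
window means, matching the term-by-term oracle to 1e-12 relative.

## Known limitations

- RMP cost scales linearly in N and |B|; 8 directions with a 41-px
  line on 512² takes a few seconds on one core.
- The min-shift of δ^TH is a global statistic: a single extreme dark
  artifact shifts the whole feature image and, through HE binning,
  can compress the features of interest.
- CIR rewards contrast *change*, not diagnostic quality; noise
  amplification raises it too.  It is reported per-ROI around known
  targets for exactly that reason.
- 16-bit inputs are supported end to end, but the default HE bin
  count (256) coarsens them at the contrast-modification stage.
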