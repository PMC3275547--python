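# rotomorph

Selective contrast enhancement of low-contrast structures in grayscale
medical images — subtle masses in mammograms, nodules in chest
radiographs, vessels in retinal fundus images — by rotational
morphological processing (RMP), with the contrast improvement ratio
(CIR) as the evaluation metric and a fully synthetic phantom
experiment for quantitative testing.

## The method

Grayscale morphology probes an image *f* with a structuring element
*B* (a set of pixel offsets):

- dilation δ_B(f)(x,y) = max { f(x−s, y−t) + B(s,t) },
- erosion ε_B(f)(x,y) = min { f(x+s, y+t) − B(s,t) },
- opening γ_B = δ_B∘ε_B (removes bright structures smaller than *B*),
- closing ϕ_B = ε_B∘δ_B (fills dark structures smaller than *B*),

with out-of-bounds samples excluded from the extremum.  A directional
element such as a 1-px-wide line segment only matches structures of
its own orientation; RMP removes that restriction by rotating the
*image* clockwise through N angles θ_i = 180·i/N over the half turn,
filtering with the fixed element, rotating back, and recombining
pixelwise (max across directions for the opening γ′_B, min for the
closing ϕ′_B).

Two filters are built on these operators:

- smoothing  SM(f) = ½·γ′_B(ϕ′_B(f)) + ½·ϕ′_B(γ′_B(f)),
- feature extraction  δ^TH(f) = f − SM(f), shifted so min = 0.

SM removes every structure — bright or dark, in any orientation —
whose base size is smaller than the element, so δ^TH isolates exactly
those structures against a flattened background.  The two-step
enhancement then expands their contrast with global histogram
equalization (HE) followed by linear contrast stretching (LCS) to the
display range.  Choosing the element selects the target: a 41-px line
(8.2 mm at 200 μm/px) for circumscribed masses; disks for spiculated
margins and vessels.

Enhancement quality over an ROI *R* is measured by

    CIR = Σ_R |C − C̄|² / Σ_R C²,   C = |p − a| / (p + a),

where *C* and *C̄* are local contrast in the original and enhanced
image, *p* the mean of the 3×3 window centre and *a* the mean of the
surrounding 40 pixels of the 7×7 window.  Five standard methods are
provided for comparison at fixed settings: HE, LCS, unsharp masking
(Gaussian radius 10 px, weight 0.7), multiscale retinex (σ = 5, 50,
150 px, weights ⅓), and CLAHE (15×15 blocks).

## Worked example

Generate the seeded phantom experiment — three Gaussian-smoothed
circular masses of diameters 11/21/31 px blended at amplitude 30 into
a mammogram-like background — and compare all six methods:

```sh
$ rotomorph phantom --seed 7 --size 512 --out demo
wrote demo/phantom.pgm and demo/phantom.json
$ rotomorph compare demo/phantom.pgm --sidecar demo/phantom.json --out demo/cir.csv
               R1       R2       R3
method
proposed 265.8134 360.8472 326.1372
he        13.1613   3.8230   8.3282
lcs        0.0000   0.0000   0.0000
usm        3.4269   4.1130   4.5273
msr        0.1350   0.1288   0.1190
clahe     1.0562   1.1444   1.0582
```

Rows are methods, columns the 35/45/55-px ROIs centred on the three
masses.  The proposed method's CIR exceeds every comparison method by
more than an order of magnitude in every ROI: the top-hat deletes the
background (so HE spends the whole output range on the extracted
masses), while the comparison methods either change little in the ROI
(LCS, MSR), spend their range on the background (HE), or amplify fine
noise as much as the masses (USM, CLAHE).

To enhance a single image with the mammographic configuration:

```sh
rotomorph enhance input.pgm enhanced.pgm --se-shape line --se-size 41
```

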