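# Methods

## Scope and model

`semarct` models a single axial CT slice. The acquisition is a parallel-beam
scan with view angles uniformly spaced on [0°, 180°) and a detector row that
covers the image diagonal; the reconstruction is filtered back-projection
(FBP) via scikit-image's `radon`/`iradon`, wrapped so sinogram entries are
physical line integrals (attenuation μ in 1/cm, path length in cm; HU =
1000·(μ − μ_water)/μ_water with μ_water = 0.192 cm⁻¹, ≈70 keV water). Helical
cone-beam geometry, iterative reconstruction, and scatter are deliberately
out of scope: they change the numbers, not the structure of the artifact or
of the correction.

Metal artifacts are generated by the two dominant physical mechanisms:

- **Beam hardening.** The simulated source is polychromatic (default three
  energy bins at 50/70/100 keV with weights 0.3/0.5/0.2). Each material's
  attenuation is its reference value (from the HU table) scaled per bin;
  the scale factors are steeper for bone and steepest for metal, mimicking
  the photoelectric energy dependence of heavy elements. Jensen's
  inequality then biases the log-normalized measurement low on
  metal-crossing rays, which FBP turns into dark streaks between metal
  objects. The factors are declared plumbing with the right qualitative
  ordering, not measured cross sections.
- **Photon starvation.** Detected counts are Poisson with a configurable
  incident fluence (default 10⁵ photons/ray). Rays with zero counts are
  clamped to 0.5 counts before the log — the standard floor — which caps
  but does not remove the noise amplification behind metal.

## The three-pass MAR pipeline

Pass 1 reconstructs the corrupted sinogram and thresholds the image at
`metal_threshold_hu` (default 2500 HU; soft tissue, contrast and most bone
stay below it, metal far above). Pass 2 forward projects the binary metal
mask, marks sinogram bins whose metal path exceeds `trace_epsilon`, and
replaces each per-view run of trace bins by linear interpolation between the
nearest non-trace neighbors (edge runs copy the single available neighbor; a
view that is entirely trace is an error — metal spanning the whole field).
Pass 3 classifies the second-pass image into air (< −400 HU → −1000), water
(−400…400 HU → 0) and bone (> 400 HU, HU retained — flattening bone would
misproject it), forward projects this prior, and fills the trace with
`β·p_norm + (1−β)·p_lin`, where `p_lin` is the plain interpolation and
`p_norm` interpolates the ratio original/prior-projection and multiplies the
prior projection back. Outside the trace the original data are returned
bit-identical. After the third FBP, metal pixels take their first-pass
values (image-domain reinsertion; the alternative sinogram-domain reading of
"adding the metal back" is not reproducible without vendor internals).

Defaults: β = 1 (pure normalized in-painting), Shepp-Logan filter for all
three passes (comparability), prior projection floored at 10⁻³ before
division.

### Why `trace_epsilon` = 0.02 and not numerical zero

The trace threshold is expressed in cm of metal path along the ray. With
1 mm detector bins and point-like (1 px) stent struts, a numerically-zero
threshold marks every ray that grazes a strut corner. For a 6 mm renal
stent the lumen is only ~6 detector bins wide and the strut sinusoids
oscillate entirely inside that band, so a zero threshold puts essentially
every lumen ray in the trace; in-painting then erases the contrast column
and the "corrected" lumen collapses to water — the opposite of the method's
clinical behavior, where struts are sub-millimetre and shadow only a small
solid angle. 0.02 cm (20 % of one strut's full path) restricts the trace to
rays that materially cross metal. The parameter remains configurable and
the zero-threshold behavior remains testable.

## Synthetic phantom

The generator emulates what the clinical measurements were taken on: a body
ellipse of soft tissue (40 HU) in air, two paraspinal muscle ellipses
(60 HU), a vertebral body (700 HU), a 20 mm contrast-filled aorta and three
stented visceral vessels (300 HU lumen) with diameters drawn from the
clinical branch-stent ranges — 8–12 mm for celiac/SMA-type vessels, 5–8 mm
for renal-type — on a 256 px, 1.0 mm grid. Stents are rendered as N
point-like metal struts (8000 HU) on the vessel circumference, one strut
per ~5 mm of circumference (minimum 3): discrete high-density markers are
what throw streaks, and at 1 mm pixels a denser or thicker strut ring would
shadow the entire lumen, which real sub-millimetre struts do not.
Randomized phantoms jitter positions, diameters and strut phases
deterministically per seed.

What the generator does **not** model: 3-D stent geometry, vessel branching
and contrast dynamics, scatter, anatomical texture, and detector effects. A
green directional test therefore establishes that the pipeline removes the
streaks *this physics* produces and preserves lumen attenuation on *this
anatomy* — not vendor-equivalence or clinical effect sizes.

## ROI evaluation

ROIs are circles defined by center and physical area; membership is by
pixel center (no partial-area weighting); statistics are mean and
**population** SD (ddof = 0, the scanner ROI-tool convention — the choice
is declared because sample vs population SD differs by < 3 % at these ROI
sizes). Vessel ROIs default to 10 mm² (≥ 8 mm vessels) and 6 mm² (smaller,
renal-type); at 1 mm pixels a 6 mm² circle holds ≥ 5 pixel centers only
when grid-aligned, so evaluation ROIs snap to the nearest pixel. An ROI
must contain ≥ 5 pixels and must not intersect the segmented metal mask;
vessels where this cannot be satisfied are excluded from the cohort
evaluation, mirroring the exclusion of unattainable ROIs in clinical
practice. CNR = (vessel mean − muscle mean)/air SD with both reference ROIs
fixed per phantom, and ROIs are defined once and copied unchanged between
the paired reconstructions.

## Statistics

- **Wilcoxon signed-rank** (two-sided throughout): zero differences
  dropped, mid-ranks for tied |d|. For ≤ 12 nonzero differences the p-value
  is exact by enumeration of all 2ⁿ sign assignments (valid under ties);
  otherwise a normal approximation with the tie-corrected variance
  n(n+1)(2n+1)/24 − Σ(t³−t)/48 and no continuity correction (matching the
  common software default; the null rejection rate at α = 0.05, n = 20 is
  verified to sit in 0.05 ± 0.01).
- **Weighted kappa**: linear weights w_ij = 1 − |i−j|/(k−1) on the k×k
  table; 95 % CI from the large-sample (Fleiss–Cohen–Everitt) standard
  error — the asymptotic choice is declared, not inferred. Kappa is
  undefined (rejected) only when chance agreement p_e = 1, i.e. both
  readers constant at the same category.
- **Median (IQR)** with linear interpolation between order statistics
  (quantile conventions differ; this one is declared).

## Numerical and degenerate-input choices

Trace in-painting uses the explicit bracketing formula
`y0 + (x − x0)(y1 − y0)/(x1 − x0)` so results are bit-reproducible against
an independently coded per-element oracle. All stochastic operations take
explicit seeds; identical seed + spec reproduces every output bit-exactly.
Metal-free sinograms short-circuit the pipeline and return the standard
reconstruction unchanged. The 16-bit PNG export stores HU + 1024 clipped to
[0, 65535]; display windowing defaults to level 300 HU / width 1000 HU with
round-half-to-even.

## Known limitations

- 2-D parallel-beam only; quantitative HU accuracy of the polychromatic
  reconstruction is not calibrated (no water-beam-hardening correction), so
  absolute HU in the simulated images carry a bias of order 5–10 %.
- The prior's water class flattens contrast-filled lumens (they sit inside
  the water band); lumen attenuation inside the trace survives through the
  non-trace rays, so very densely strutted or very small stents will still
  lose contrast — visible as the renal-vessel rows having the smallest CNR
  gains.
- Reader ratings are a statistical fixture (truth + rounded Gaussian noise,
  clipped to 1–5) for exercising the agreement statistics; they model no
  perceptual process.
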