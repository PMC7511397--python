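# Methods

## Scope and model

`afmbend` measures local DNA bend angles in AFM topographs by tangent
overlay on sub-pixel backbone traces, decomposes angle samples into
conformational states with folded-Gaussian mixtures, checks 2D worm-like-
chain (WLC) statistics, and converts ensemble FRET intensities to bend
angles. A synthetic scene generator supplies ground truth for validation.
This note records the model assumptions, the defaults and why they hold,
the numerical choices, and the known limits of what the synthetic tests
demonstrate.

## Synthetic scenes

**Chain model.** DNA is sampled as a discrete 2D worm-like chain: segments
of fixed arc step (default 1 nm) whose successive turning angles are iid
N(0, step/L_P). This gives the 2D tangent correlation exp(−s/2L_P) and the
2D closed form ⟨R²⟩₂D = 4·L_P·L_c·{1 − (2L_P/L_c)(1 − e^(−L_c/2L_P))},
i.e. molecules equilibrated in the surface plane, as for DNA deposited on
mica in equilibrating buffer conditions. The defaults — contour 172 nm
(a 505 bp duplex at 0.34 nm/bp), persistence length 45 nm, pixel size
1.95 nm — are the study conditions of the glycosylase experiments this
package reproduces. A defined bend is imposed by rotating the chain tail
about the node nearest the chosen arc fraction by ±(angle + N(0, σ_bend));
the realized angle is recorded as ground truth.

**Rendering.** The DNA backbone is drawn with a Gaussian cross-section
(σ = 1 nm) rather than a hard-edged ribbon, avoiding raster aliasing at
~2 nm pixels; proteins are flat discs. Tip convolution is approximated by
an isotropic Gaussian blur (FWHM default 6 nm) and noise is additive
Gaussian (σ default 5% of the DNA apparent height, a good-quality tapping-
mode image). Amplitudes are pre-compensated for the blur attenuation of
narrow features, so `dna_height` and `protein_height` (default ratio 1:3)
are *apparent* heights as a cross-section through the image shows them —
that ratio is what makes protein peaks separable by height, which the
real workflow requires. The default true protein disc radius is 2.5 nm:
after tip convolution the apparent peak radius is ~6–7 nm, matching the
in-image radii reported for glycosylases (~3–7 nm), so the default 8 nm
query distance clears the protein. No scan-line artifacts, drift, or
tip-sample mechanics are modeled; self-crossing chains are rendered as-is
and left to the tracer to reject.

## Image processing and tracing

The pre-processing chain is median filter (disc radius 2 px) → Yen
threshold → shape filter → per-component ridge re-threshold → Gaussian
blur of the mask (2 px) → skeletonization. Two steps deserve comment:

* **Yen threshold** is computed by exhaustive maximization of Yen's
  maximum-correlation criterion over the 256-bin histogram of the min–max
  scaled 8-bit image, so its behavior is exactly reproducible and the
  level shifts bin-for-bin under additive offsets. On very clean synthetic
  backgrounds the optimal level sits just above the noise floor, producing
  filament masks about twice the ridge FWHM; each filament component is
  therefore re-thresholded at 50% of its own ridge height (median image
  value along its skeleton). Without this, the arms of strongly bent
  molecules fuse and the skeleton loops at the apex.
* **Protein mask.** The intermodes threshold (iterated window-3 histogram
  smoothing to exactly two modes, level at their midpoint) is computed on
  the foreground (above-Yen) histogram, and floored at 1.5× the measured
  DNA ridge height. The floor automates the manual threshold adjustment
  the interactive workflow uses: when protein pixels are too few to form
  their own histogram mode, the intermodes level collapses into the DNA
  class and only the height separation rescues it.

Skeletons are ordered end-to-end; skeletons with branch points (crossing
molecules) or no endpoints (loops) are rejected with reason codes, but
side spurs of ≤ 6 px — thinning artifacts that sharp bends produce — are
pruned first, because rejecting them would selectively discard strongly
bent molecules and bias the angle distributions. Traces are resampled at
2 nm, refined by moving each node to the center of a Gaussian fitted
(three-point log-parabola, exact for a sampled Gaussian) to the height
profile along the local normal over ±1.5 FWHM, iterated to 0.05 nm; the
profile peak nearest the current node is used, so a neighbouring arm of
the same molecule cannot capture the node near a sharp bend. Finally a
natural cubic spline is resampled at uniform 0.1 nm arc length.
`resample` picks the node count so endpoints are preserved *and* spacing
is exactly uniform (realized spacing = L/(n−1)).

Traced contours are shorter than truth — skeleton end erosion plus
unresolved undulations — by typically 4–10%, occasionally slightly more
for strongly curved molecules; the lesion-mode length window (150–180 nm
for the 172 nm substrate) is wide enough to retain them. Fragments broken
at extreme kinks can be rejoined with `connect_fragments` (closest
endpoints, straight gap segment, default tolerance 3× node spacing, pair
chosen by the user).

## Angle measurement

Θ = 180° − Φ with tangents at s₀ ± q oriented away from the site; secant
mode uses the chords P(s₀±q) − P(s₀) and, on a circular arc, equals
tangent mode at q/2 exactly. Tangent directions are estimated as
symmetric chords over ±2 nm of the 0.1 nm trace: on a circle a symmetric
chord has exactly the tangent direction of its midpoint, and a kink one
query distance away lies outside the window, but the chord averages out
sub-node spline wiggle which would otherwise deplete measured angles near
0°. The measurement is invariant under trace reversal and rigid motions.

Bound-protein sites are excluded (with recorded reasons, never silently)
when at a fragment end (closer than q, where no tangent pair exists),
closer than 50 nm to another bound protein (both members dropped — the
conservative reading of the spacing rule), farther from the backbone than
the protein+DNA radius sum, equidistant from two traces (ambiguous), or
outside the component area window (aggregates). Lesion mode measures the
arc-length midpoint of the *measured* contour, which tracks the true site
to within ~2 nm under symmetric end erosion.

Choice of q: at 8 nm the thermal WLC background contributes an angle
spread of σ ≈ 28–34° (the variance of the tangent-direction difference
over a 16 nm window of L_P = 45 nm DNA); larger q broadens the
distribution further, smaller q (≤ 4 nm ≈ 2 px) is noise-dominated.

## Angle statistics

Histograms (default 5° bins) are fit with sums of folded Gaussians by
bounded least squares with Pearson (counting-statistics) weights;
multi-start initialization uses sample quantiles plus deterministic
near-origin and histogram-peak starts and seeded jitter. R² is reported
unweighted, so the R²-threshold model selection (smallest k reaching
0.94/0.97) retains its conventional meaning; if no k ≤ 4 reaches the
threshold the best fit is returned flagged. Weights are folded-component
area fractions; widths are reported as ±2σ.

**Identifiability limit.** A folded Gaussian's density depends on μ only
at second order when μ < σ: the Fisher information on μ vanishes as
μ → 0 (only μ² is estimable, with err(μ) ~ σ(2/n)^(1/4)). With the q=8 nm
WLC background (σ ≈ 30°), centers below ~20° are therefore not resolvable
to ±5° at desk-scale sample sizes (n ≈ 200–1000): fits land anywhere
between 0° and ~25°, trading center against width. This is a property of
the measurement, not of the optimizer — nominally straight DNA genuinely
fits at a small positive center — and it is why recovery tests pin down
imposed bends of 45° and 70° to a few degrees while 0° and 20° cannot be
certified at that tolerance. States well above the background σ are
unaffected.

The WLC block evaluates the closed form and inverts it for L_P by Brent
bracketing on [1, 500] nm (the form is strictly increasing in L_P;
tolerance 0.01 nm).

## FRET

Eq. chain: E from background-corrected acceptor peak intensities with
Cy3/Cy5 extinction coefficients (ε_AA = 250,000, ε_AD = 3,079,
ε_DD = 71,769 M⁻¹cm⁻¹), r = R₀(1/E − 1)^(1/6) with R₀ = 5.6 nm (freely
rotating dyes, κ² = 2/3), and the bend-site triangle with arms
b = c = 7.17/2 nm. The 7.17 nm straight-substrate dye separation is an
effective point-dye distance that already absorbs linker and dye
dimensions; the accessible-volume dye simulation it summarizes is out of
scope, and the point-dye surrogate is only claimed adequate near the
straight-DNA geometry. Near-straight DNA makes Θ extremely sensitive to
E (the arccos argument approaches −1): cosines outside [−1, 1] by < 1%
are clamped with a warning, larger violations raise. The forward
simulator draws a state by population weight and a bend position uniform
on (0, 1) along the dye span (how the original averaging was discretized
is unstated; continuous uniform is assumed) and averages
E = 1/(1 + (r/R₀)⁶); it is seeded and reports the Monte-Carlo standard
error.

Note that direct evaluation of the equation chain at the rounded measured
efficiencies (E = 0.291, 0.233, 0.230) gives 50.1°, 35.4°, 34.4° — within
the reported uncertainties of the published 49°, 34°, 33°, which were
presumably computed from unrounded efficiencies.

## Configuration and reproducibility

All thresholds, radii, windows and seeds live in `PipelineConfig`
(validated, serialized as a JSON snapshot next to every output; re-running
from the snapshot reproduces outputs byte-for-byte). Pixel size always
comes from configuration, never from TIFF tags. Defaults follow the
interactive workflow they replace: query distance 8 nm, protein spacing
minimum 50 nm, area window 10⁻⁷–10⁻⁴ µm², length window 150–180 nm,
elongation 0.75–1 with perimeter ≥ 90 px, minimum per-image DNA coverage
0.70. For synthetic scenes with strongly kinked molecules the elongation
floor is lowered to 0 (an L-shaped filament has low moment-ellipse
anisotropy; the perimeter bound alone separates filaments from blobs).

## What the synthetic tests do and do not show

Passing recovery tests show the chain from rendered topograph to state
decomposition is unbiased to a few degrees for bends ≥ ~45° and that
molecule selection does not favor particular bend states (KS test on
ground-truth angles of kept vs. all rendered molecules). They do not
certify performance on real images with scan artifacts, surface debris,
aggregated protein, or tip asymmetry, none of which are simulated; nor do
they validate the point-dye FRET surrogate away from near-straight
geometries. Molecules bent beyond ~90–100° are systematically lost: their
arms fuse at this resolution and the skeleton loops at the apex (the
skeleton-interruption regime that motivates manual reconnection in
interactive workflows), censoring the extreme tail of broad distributions.

## Problem sizes

Default validation scales, chosen to keep the whole suite at desk scale:
10,000 chains for WLC ensemble checks, ~300 measured molecules per
condition for bend-angle recovery, 10⁵ draws for the FRET forward
simulation, 512×512 px scenes with 8 molecules each.
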