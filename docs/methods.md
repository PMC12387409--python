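# Methods

## The detection model

The detector treats a Placido-ring image as a collection of smooth
gray-level transitions (ring edges) embedded in structured interference
(eyelash shadows, specular spots) and noise. It works coarse-to-fine:

**Front-end.** Each scale σ contributes an accumulated response
`S_σ(x,y) = Σ_{b_x} Σ_{b_y} |(I ∗ h_σ)(x+b_x, y+b_y)|`, where `h_σ` is a
Mexican Hat (Ricker) wavelet multiplied by the radial modulation
`exp(−(√(x²+y²) − R)²/δ²)`. The translation lattice (the "position
step") makes the response insensitive to structures thinner than the
step — an eyelash a few pixels wide is averaged into the background,
while a ring edge, which extends coherently, survives. Scales are fused
with weights proportional to each scale's response standard deviation,
and the fused field is band-passed with a difference of Gaussians (DoG).

**Coarse edges from zero-crossings.** The DoG output `Ef` is a signed
band-pass field: its sign flips across a gray-level transition, so the
edge runs along its zero-crossing contour. Its *magnitude*, by contrast,
peaks on two lobes flanking each edge — thresholding |Ef| is precisely
what produces the double-edge artifact this detector is designed to
avoid. Coarse candidates are therefore the zero-crossing pixels
(marking, for each sign-flipping 4-neighbor pair, the pixel with the
smaller |Ef|, so the curve stays centered), kept when the local response
slope exceeds Otsu's threshold over all crossing slopes, thinned to
one-pixel curves, and filtered by connected-component size
(`min_component`, default 5 px).

**Sub-pixel refinement.** Zernike moments of order (0,0), (1,1), (2,0)
are computed at each candidate with N×N templates obtained by midpoint
integration of V₀₀ = 1, V₁₁ = ρe^{iθ}, V₂₀ = 2ρ²−1 over each cell's
intersection with the unit disc (64×64 subsamples per cell; the
integration error on the disc-area check Σm₀₀ = π is < 2·10⁻³). The
ideal step-edge model — intensity `h` on one side of a line at unit-disc
distance `l`, `h+k` on the other — is inverted in closed form from
(Z₀₀, Z₁₁, Z₂₀). Two conventions matter and are easy to get wrong:

* The closed-form inversion holds for *unnormalized* disc integrals.
  When moments carry the conventional (n+1)/π normalization (ours do, so
  a uniform patch of value c has Z₀₀ = c), `l = Z₂₀/Z₁₁′` acquires a
  spurious factor 3/2. `edge_parameters` rescales by π/(n+1) internally,
  which makes recovery on synthetic steps exact to the integration
  tolerance (≤ 0.017 in l, ≤ 0.21° in θ over the full test grid).
* The angular factor of the first-order template is chosen as `x + iy`
  in (column, row-down) image coordinates, so `θ = atan2(Im Z₁₁, Re Z₁₁)`
  is directly the edge-normal direction and the displacement
  `(xs, ys) = (col, row) + (N·l/2)(cos θ, sin θ)` needs no sign fixes.
  (With the conjugate kernel the recovered angle is −θ and the y
  displacement flips.)

**Adaptive gates.** `kt = (G² + σ_k² + ln(1+υ_k))/5` per pixel, with
`G = |Z₁₁|` and (μ_k, υ_k, σ_k) the 5×5 mean/unbiased variance/std of the
Z₂₀ field; `lt = 2/N + 0.2·l_k`, with `l_k` the largest absolute
eigenvalue of the Hessian of the normalized response (central second
differences, reflective borders). A candidate is accepted iff `k ≥ kt`
and `|l| ≤ lt` (closed inequalities); candidates whose raw |Z₂₀/Z₁₁′|
exceeds 1 violate the single-step model and are rejected outright. The
sign of the curvature term is configurable (`curvature_sign = ±1`); the
default adds it, which *loosens* the distance gate in curved regions —
the alternative (subtracting, so high curvature tightens the gate) is
also available since the two behaviors suit different ring densities.

## Parameters and calibration

| parameter | default | meaning |
|---|---|---|
| scales σ | 3, 4, 6 px | wavelet scales of the front-end |
| step | 6 px | side of the translation lattice |
| R, δ | 0.5·σ each | radial modulation center / width |
| DoG σ₁, σ₂ | 0.7, 1.4 px | band-pass of the fused response |
| N | 9 | Zernike template side |
| min_component | 5 px | smallest surviving coarse-edge component |

Scales and step are the operating point established for Placido imagery
(smaller scales re-introduce eyelash detail; larger steps narrow the
response band). R, δ and the DoG widths are free design parameters; they
are calibrated on an analytic criterion, not on any benchmark: the
front-end's response to an ideal straight step must (a) have a single
zero-crossing contour, (b) cross zero *on* the edge (no bias), and
(c) invert linearly under the 9×9 step model for candidates within ~1 px
of the edge. At the defaults the straight-edge localization bias is
+0.00 px with 0.054 px spread; other plausible defaults we examined
(e.g. R = δ = σ) bias the response by ~0.3 px or produce multiple
crossings per edge. The translation lattice is centered (for the even
default step the two length-6 windows are averaged, i.e. end shifts get
weight ½), because the one-sided lattice `{0,…,step−1}` translates every
feature by half the window diagonally.

Zernike moments are computed on the min-max-normalized DoG response
(`moment_source="response"`), not the raw image: the front-end's
smoothing is what lets the 9×9 operator see through pixel quantization,
and it is also the reading under which removing the front-end degrades
accuracy — consistent with the ablation behavior this architecture is
built around. `moment_source="image"` is available and useful when the
input is already smooth and noise-free.

## The synthetic benchmark

`make_binary_circle` renders the standard accuracy fixture: a white disc
of radius 150 px centered at (200, 200) in a 400×400 frame. By default
the disc is **area-sampled** (each boundary pixel carries its coverage
fraction; interior pixels are exactly 1, exterior 0) — the way raster
graphics draws filled circles. This matters: a hard center-sampled
rasterization (`supersample=1`) perturbs the boundary by a ±0.5 px
moiré (sawtooth runs of ~17 px near the axes, a diagonal lattice beat
near 45°), and *no* estimator with local support can undo it — on the
hard rasterization the same pipeline plateaus at ≈ 0.13 px mean radial
deviation, concentrated in the resonant angular sectors, versus
≈ 0.026 px on the area-sampled rendering. Sub-0.1-px localization claims
are only meaningful on a non-aliased boundary, so the area-sampled
rendering is the benchmark default and the hard rasterization is kept as
a documented stress case.

Evaluation follows the 20-point protocol: integer pixels within 0.2 px of
the true radius are the "actual" boundary points (the tolerance matches
the spread of reference boundary samples for this fixture), drawn
uniformly in angle; each is matched to the nearest detected sub-pixel
point; the per-point Euclidean distances are summarized by
mean/max/min/sample-std, and a paired two-sided t-test on the pooled x/y
coordinates probes for systematic bias. The noise experiment adds
clipped i.i.d. Gaussian noise of sd 0.2 (on the [0,1] scale — 0.2/255
would be visually negligible) and reports the increase in mean distance
error against the same points.

The Placido phantom emulates the clinical failure modes: Gaussian-profile
rings (11 rings, 15 px spacing, 4 px width by default), dark eyelash-like
polylines entering from the top, and bright specular blobs, all seeded.
Its ground truth records the ring half-maximum edge radii (what an edge
detector should localize on a bar-profile ring) and an occluder influence
zone (the occluder mask dilated by 3 px, since a detector reacting to a
lash localizes the lash's *edges*, which flank the mask).

What the phantom does not emulate: corneal curvature (ring spacing
gradients and ellipticity), defocus and tear-film blur, sensor noise
statistics, or true specular saturation. Passing the phantom tests
therefore shows interference *suppression relative to a plain wavelet
front-end* under controlled geometry, not clinical performance.

## Numerical choices

* Convolutions use FFTs on symmetrically padded arrays; all boundary
  handling in the package is reflective.
* The multi-position accumulation is an integral-image box sum — exact,
  and verified elementwise (1e−10) against the literal shift loop.
* Zernike templates are cached per (N, subsampling); cells wholly outside
  the unit disc have exactly zero weight.
* `l` is clamped to |l| ≤ 0.999 before the (1−l²)^{3/2} power; windows
  with |Z₁₁| ≤ 1e−12 are treated as flat and rejected.
* 5×5 variance uses the unbiased divisor 24 (mean divisor 25); the
  moving-average implementation is clipped at 0 to absorb roundoff.
* Min-max normalization of a constant field returns zeros rather than
  dividing by zero; a constant input image yields an empty result with a
  warning.
* All randomness (noise, phantoms, point sampling) flows through
  `numpy.random.default_rng` seeds; the detector itself is deterministic,
  and repeated runs produce byte-identical CSV output.

## Known limitations

* On hard-binarized inputs the accuracy is limited by the rasterization
  moiré described above, not by the estimator; the detector then tracks
  the rasterized boundary (the only locally available evidence) to
  ≈ 0.1 px.
* The step-edge model assumes one straight edge per 9×9 window; ring
  systems whose edges approach within ~4 px (dense Placido rings at the
  image periphery of strongly curved corneas) violate it, and such
  windows are only partially filtered by the model-violation and
  curvature gates.
* The reported p-value tests mean bias of the matched coordinates, not
  dispersion; with very small errors it is noise-dominated and should not
  be over-interpreted.
* The frequency-domain form of the enhanced wavelet (Bessel-modulated
  spectrum) is intentionally not implemented; all filtering is spatial.
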