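# placido-edge

Sub-pixel edge detection for corneal Placido-ring images.

Placido-disc corneal topography projects concentric illuminated rings onto
the cornea and reconstructs the corneal surface from the geometry of their
reflected images. The accuracy of the whole reconstruction hinges on how
precisely the ring edges can be localized, and clinical images are
contaminated by eyelash shadows and specular light spots that defeat
ordinary pixel-level edge operators. `placido-edge` implements a
coarse-to-fine detector built for this setting:

1. **Enhanced Mexican Hat wavelet front-end.** The image is convolved with
   Ricker wavelets `h_σ(x,y) = σ⁻²(2 − r²/σ²) e^(−r²/2σ²)` modulated by a
   radial Gaussian `e^(−(r−R)²/δ²)` that concentrates the response on an
   annulus. The absolute response is accumulated over a small lattice of
   integer translations (position step `b`), which averages away thin
   interference such as eyelashes while reinforcing extended ring edges.
   Responses at scales σ ∈ {3, 4, 6} with step 6 are fused with weights
   `M_σ = std(S_σ) / Σ std(S_σ')`, sharpened by a difference-of-Gaussians
   band-pass, and binarized at the zero-crossings of the band-pass field to
   give a one-pixel-wide coarse edge curve.
2. **Zernike-moment sub-pixel refinement.** At every coarse candidate a
   9×9 template computes the low-order Zernike moments Z₀₀, Z₁₁, Z₂₀ of
   the response, and the ideal step-edge model is inverted in closed form:
   `θ = atan2(Im Z₁₁, Re Z₁₁)`, `l = Z₂₀/Z₁₁′`,
   `k = 3Z₁₁′ / (2(1−l²)^{3/2})`, giving the edge's sub-disc offset `l`,
   step height `k`, background `h`, and normal direction `θ`. The edge
   point is then mapped to `(xs, ys) = (x, y) + (N·l/2)(cos θ, sin θ)`.
3. **Two adaptive thresholds.** A gray-level gate
   `kt = (G² + σ² + ln(1+υ))/5` built from the local gradient magnitude
   `G = |Z₁₁|` and the 5×5 mean/variance of the Z₂₀ field, and a distance
   gate `lt = 2/N + 0.2·l_k` with `l_k` the largest absolute Hessian
   eigenvalue of the response, accept a candidate only when `k ≥ kt` and
   `|l| ≤ lt`, suppressing spurious and double edges.

The package also ships the synthetic benchmark the detector is validated
on (a 400×400 disc of radius 150 centered at (200, 200), its Gaussian-noise
variant, and a Placido-ring phantom with eyelash/spot interference) and
the evaluation protocol (seeded boundary points, nearest-point matching,
error statistics and a paired t-test).

## Worked example

```bash
$ placido-edge synth circle --out circle.png
wrote circle.png and circle.json
$ placido-edge detect --input circle.png --output points.csv
848 accepted points (848 candidates) -> points.csv
$ placido-edge eval --n-points 20 --seed 1 --report report.json --points pts.csv
mean=0.0881 max=0.1563 min=0.0002 std=0.0448 p=0.6353 -> report.json
```

`points.csv` holds one row per accepted edge point:

```
xs,ys,k,l,theta,row,col
188.030656,50.403263,0.822421,0.089873,1.494921,50,188
189.023853,50.341002,0.825180,0.075963,1.500961,50,189
```

`xs, ys` are the sub-pixel coordinates (columns/rows, 0-based; add
`--one-based` for 1-based tables), `k` the recovered step height on the
normalized response, `l` the unit-disc edge offset and `theta` the edge
normal angle. The `eval` line says that over 20 randomly drawn boundary
pixels of the true circle, the matched sub-pixel points deviate by 0.088 px
on average (0.156 px at worst), i.e. the detector localizes the circular
edge an order of magnitude below the pixel grid.

The same API is available from Python:

```python
import placido_edge as pe

image = pe.make_binary_circle()                  # 400x400 benchmark disc
result = pe.detect_subpixel_edges(image)         # EdgePointSet
points = pe.sample_circle_points(pe.CircleSpec(), 20, seed=1)
report = pe.match_and_score(points, result)
print(report.mean, report.std)
```

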