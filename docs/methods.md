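# Methods

## The rugosity measurement

A terrain model is either a triangle mesh (native photogrammetry output) or a
regular heightfield with `NaN`-masked holes; heightfields are triangulated by
splitting every fully-unmasked grid cell along the same diagonal, so the
operation is deterministic and masked regions become holes rather than
interpolated surface. The diagonal choice perturbs facet areas by well under
1% at the 2.5 cm resolutions this pipeline targets.

The projection plane is a **total (orthogonal) least-squares** fit to the mesh
vertices — the smallest principal direction of the centered vertex cloud —
with the normal flipped into the +z hemisphere. Orthogonal residuals make the
fit rotation-invariant, which is what guarantees that a rigidly transformed
site, refit and remeasured, returns the same SR (tested to 1e-9 relative).
The first in-plane axis is the projection of world +x onto the plane, fixing
the quadrat-grid orientation deterministically.

Projected face areas use `a·|cos θ|`: the absolute value makes overhanging
faces add projected area rather than cancel it, keeping SR ≥ 1 everywhere
(the chain-and-tape analogue: a chain draped over an overhang still pays out
length). Faces are assigned to quadrats by their projected centroid, with no
clipping; the misassignment error is O(face size / quadrat size), negligible
at 2.5 cm faces in 2 m quadrats. A centroid exactly on an internal boundary
goes to the lower-index quadrat. Rim quadrats whose projected area falls
below `min_fill × quadrat_size²` (default 0.5 — the value is a judgment call;
the flag is carried in the output so callers can choose differently) are
flagged and dropped by default.

**Link-size resampling** acts on the heightfield, not by mesh decimation:
each output node takes the mean of the input nodes nearest to it (bins of
width `link_size` centred on the output lattice). Raw bin means are biased
near the site edges, where partial bins have an off-centre sample centroid;
the implementation therefore treats each bin mean as a sample at the bin's
true mean position and linearly interpolates back onto the regular lattice.
This first-order correction makes resampling exact for planar fields, so a
tilted plane keeps SR = 1 ± 1e-9 at every link size — the property the
best-fit plane exists to provide. Resampling at the native resolution is the
identity; requesting a finer-than-native link size is an error. Default link
sizes are 2.5 cm (native) and 5–25 cm in 5 cm steps.

## Repeated-survey error statistics

Per quadrat, the mean `μ`, deviations `δ`, and standard error `σ` use the
population denominator `N_survey` (an `unbiased` flag switches to `N−1`; the
default matches how the statistics are defined here and keeps `σ² =
mean(δ²)` exact). Deviations are centred by construction, so per-quadrat
deltas and per-group survey biases sum to zero at machine precision — both
are asserted as invariants.

Surveys are grouped `single_day` (back-to-back repeats under near-identical
ambient conditions) vs `multi_day` (repeats across days); statistics are
computed per group. Quadrats missing from any survey of a selection are
dropped complete-case and logged.

Site reports express mean σ and the **RMS** of the per-survey biases as
percentages of the observed SR range. "Observed range" is implemented as
max − min over all quadrat-survey SR values of the site, pooled across
groups; `range_scope` offers the within-group range and the range of quadrat
means as alternatives, since the pooling convention is genuinely ambiguous in
field practice.

## Coverage and annotation

Coverage rasters count, per 0.5 cm cell, the image footprints containing the
cell centre (point-in-polygon at centres, not area weighting — exact to one
cell at this resolution relative to 2 m quadrats). No occlusion is modelled:
a footprint observes everything inside it. Quadrat summaries are the mean
count and its population standard deviation, matching the σ convention above.

Dominant-class assignment takes the argmax benthic class when its area
proportion is strictly greater than 25%, else "Mixed"; a proportion exactly
at the threshold is Mixed (the strict inequality is a deliberate boundary
choice), and argmax ties break by a fixed class order with a warning. For the
regression, quadrats dominated by Sand or Abiotic/Mixed Hard Bottom are
pooled into the "Mixed" base category, leaving the four coral morphotypes as
levels — the error model is about coral growth forms, and non-coral bottoms
behave like the mixed base.

## Statistical layer

t-tests (one-sample and paired) and one-way ANOVA go through scipy; OLS
through statsmodels. All p-values are two-tailed; no multiple-testing
correction is applied anywhere. ANOVA reports the textbook decomposition
(p from `F(k−1, N−k)`); a `df_display` property additionally exposes the
`(k−1, N−1)` convention some field reports print, without affecting any
computation. The morphotype categorical uses treatment coding against
"Mixed", so coefficients read as per-class error offsets at fixed rugosity.
Degenerate inputs fail loudly: zero-variance t-tests, under-replicated ANOVA
cells, and rank-deficient designs (the offending terms are named) all raise
typed errors rather than returning NaN.

## The synthetic-data generator

`gen_surface` produces planes, tilted planes, sawtooth and sinusoidal waves,
hemisphere fields, and spectral (power-law) fractal terrains, attaching the
closed-form SR where one exists (plane → 1; sawtooth of facet slope `s` →
`sqrt(1+s²)`, exact under the grid triangulation when the half-wavelength is
a node multiple). Fractal surfaces are periodic FFT noise with amplitude
spectrum `|k|^(−β/2)`, rms-scaled; β ≈ 3 gives visually reef-like relief.

`simulate_study` draws, per site and group,

```
SR_j,i = sr_true_j + B_i + ε_j,i
B_i   ~ N(0, τ²)                        one offset per survey, shared by all quadrats
ε_j,i ~ N(0, σ(sr_j, class_j)²)         independent per measurement
σ(SR, class) = max(σ_floor, c₀ + c₁·SR + offset_class)
```

Noise is additive Gaussian on SR — the distributional choice consistent with
analysing these data by t-tests, ANOVA, and OLS. Defaults: c₀ = −0.1323,
c₁ = 0.1130, offsets −0.0202 / −0.0238 / +0.0204 / −0.0028 for massives /
plating / coarse- / fine-branching vs Mixed; τ = 0.01 SR units;
σ_floor = 0.002. The floor exists because the linear law is an empirical
trend, not a generative model: it goes negative below SR ≈ 1.2. For the same
reason the default true-SR distribution is Uniform(1.45, 2.15) — the upper
part of the realistic quadrat range, chosen so the law is positive for every
morphotype and recovery experiments are not distorted by flooring. The
default morphotype mix is 30% Mixed, 20% massives, 20% plating, 15% each
branching class; labels are drawn independently per quadrat for measurement
studies, while `gen_morphotype_map` grows contiguous nearest-seed patches
when spatial structure matters.

**Calibration.** The pipeline estimates σ with the population-form estimator
over N surveys, whose expectation is `c_N·σ` with
`c_N = sqrt(2/N)·Γ(N/2)/Γ((N−1)/2)` (≈ 0.798 at N = 4). Since the noise law
describes the *measured* standard error, the generator divides the drawn
noise sd by `c_N` (`calibrate=True`, default), so measured σ is centred on
the law. With calibration off, recovered slopes shrink by exactly this
factor.

**Recovery experiments** regress measured σ on the generator's *true* SR.
Regressing on the estimated mean instead attenuates the slope by ~5%
(errors-in-variables) — a property of field designs, where truth is
unavailable, not of the estimator; the acceptance suite isolates the latter.
Across 200 studies of 191 quadrats × 4 surveys the fitted slope is unbiased
to within ±0.01 and nominal-95% OLS intervals cover the true slope ~94% of
the time despite the heteroscedastic, chi-distributed response.

## What the synthetic data does and does not show

The generator reproduces the error *structure* of field photogrammetry —
per-survey systematic offsets, rugosity-dependent precision, morphotype
shifts — but not its causes: no lighting, turbidity, reconstruction-software,
or registration effects are modelled, noise is Gaussian and spatially
independent across quadrats, and coverage rasters ignore occlusion by relief.
Passing tests therefore demonstrate that the estimators and models are
correct and well-calibrated under the assumed error structure, not that real
surveys follow that structure. In particular the generator exposes separate
noise scales per survey group but takes no position on whether single-day or
multi-day surveys are noisier — field results differ by site.

## Problem sizes

Default simulated studies use 191 quadrats × 4 surveys per group, matching
the scale of the field design the package targets; recovery suites run 200
replicates. Synthetic terrains in tests use 2–12 m extents at 2.5 cm
resolution (up to ~115k faces), enough to exercise every code path with the
full multiscale ladder while keeping the suite fast.

## Known limitations

- Grid triangulation of heightfields is a stand-in for the (unspecified)
  meshing of real photogrammetric pipelines; absolute SR values at fine link
  sizes depend on it.
- Face-centroid quadrat assignment (no clipping) slightly blurs quadrat
  boundaries for large faces.
- The coverage layer is purely geometric; no visibility modelling.
- Registration between surveys is assumed given (applying a rigid transform
  is supported; estimating one is out of scope).
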