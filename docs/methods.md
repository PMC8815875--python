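# Methods

This note documents the models implemented in `dipoleloc`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic-data benchmarks do and do not establish.

## Optical model

**Geometry.** An emitter with a fixed transition dipole sits at the focal
plane, on the sample side (refractive index n₁ = 1.33) of a planar interface
to the immersion medium (n₂ = 1.0, a long-working-distance air objective as
used above a cryostat window). The objective obeys the sine condition with
numerical aperture NA = 0.7 < n₂; the normalized pupil radius ρ maps to the
air-side ray angle through n₂ sin θ₂ = NA·ρ, and Snell's law
n₁ sin θ₁ = n₂ sin θ₂ links it to the emission angle in the sample. Because
collection happens on the low-index side at NA < n₂, no supercritical-angle
or evanescent components enter the aperture.

**Back-focal-plane field.** The far field of the dipole
μ = (sin θ cos ϕ, sin θ sin ϕ, cos θ) is decomposed at each pupil azimuth
into s and p components, transmitted with the Fresnel amplitude coefficients
t_s(θ₁), t_p(θ₁), scaled by the angular-spectrum far-field Jacobian
cos θ₂ / cos θ₁ and by the aplanatic collection apodization 1/√cos θ₂, and
the p unit vector is rotated into the pupil plane by the collimating
objective. This is the standard angular-spectrum treatment of dipole
radiation at a planar interface; all constant prefactors are dropped because
the final intensity is normalized.

**Pupil-to-image propagation.** The image field is the Fourier integral of
the pupil field over the circular aperture, evaluated as a direct discrete
sum from a Cartesian midpoint pupil grid (default 128 samples per axis) to
the oversampled image grid. The sum is separable, so each evaluation is two
small complex matrix products per field component; arbitrary subpixel emitter
positions enter exactly as a linear pupil phase, with no interpolation
anywhere. The quadratic phase prefactor and the 1/(iλf) constant of the
imaging integral cancel in the normalized intensity and are omitted. An FFT
path would be faster at large image sizes but was not needed at 17×17 pixels.

**Aberrations.** Wavefront aberrations W(u, v) = Σⱼ wⱼ Zⱼ(u, v) use
orthonormal (unit-RMS) Zernike polynomials with Noll indexing, evaluated from
the closed-form radial sums. Coefficients are lengths in nanometers and enter
as the pupil phase exp(i·2πW/λ): with this convention the RMS wavefront
error of a single mode equals |wⱼ|, which is what makes the package's default
astigmatism w₆ = 0.11·680 nm ≈ 74.8 nm RMS internally consistent. The basis
is validated by quadrature orthonormality (error < 10⁻³ at 512² samples) up
to j = 15 and by closed-form spot checks.

**Defocus.** The fitted defocus d is the exact air-side phase
(2π/λ)·n₂·d·cos θ₂ applied across the pupil (`defocus_model="exact_air"`).
Two alternatives are available for comparison: `"exact_sample"`
((2π/λ)·n₁·d·cos θ₁) and `"zernike"` (a pure Z4 with
w₄ = −d·NA²/(4√3·n₂), the paraxial equivalent). The air-side convention is
the default because it reproduces the expected astigmatic behaviour of the
reference system best: with w₆ = 0.11λ it separates the two line foci by
1.38 μm (the zernike model gives 1.58 μm, the sample-side model 1.96 μm,
against the ≈1.4 μm that a weak-astigmatism system of this design exhibits).

**Pixel integration and normalization.** The intensity |E|² is computed on a
subpixel grid (oversampling 9 for simulation, 3 for fitting — finer grids
change no camera pixel by a measurable amount), summed into camera pixels
(108.33 nm in object space: 6.5 μm / 60×), and normalized so the computed
window sums to 1. Both the simulator and the fitter use this same
window-normalized PSF, so the photon budget N refers to photons delivered
into the ROI. One consequence is deliberately exposed in the API: Fisher
information computed from per-window-normalized models is *not* comparable
across nested ROI sizes (a smaller window would be credited the full budget);
`DipolePSFEngine(norm_roi_px=...)` normalizes over a larger reference window
and crops, restoring the physical monotonicity of information in ROI size.
The ROI-sweep benchmark uses the default window normalization (matching the
fitting protocol); the monotonicity property is asserted under shared
normalization.

## Noise and photometry

Pixel counts are independent Poisson draws with mean
ν_k = N_eff·PSF_k + b². The background parameter b is its conventional
"standard deviation" form: a Poisson background with mean b² has standard
deviation b, and the fitter's a-priori background estimate targets the mean
b². With polarization-modulated excitation enabled, the photon yield couples
to orientation as N_x = N_max sin²θ cos²ϕ, N_y = N_max sin²θ sin²ϕ,
N_eff = N_x + N_y = N_max sin²θ; an axial dipole is never excited, which is
why excitation-coupled benchmarks omit θ = 0. Defaults: N_max = 5·10⁵
photons, b ∈ {0, 100, 300} depending on scenario, 17×17 ROI. There is no
camera gain, offset, or read-noise map: the model is pure Poisson, which is
the regime the benchmarks describe.

The camera model and PSF normalization mean the simulator emulates an ideal
photon-counting detector observing a single, isolated, fully static emitter
with homogeneous background. Real data additionally contain sCMOS read
noise and gain maps, spatially varying background, drift, overlapping
emitters and blinking kinetics; none of these are modelled, so passing
benchmarks here demonstrate correctness of the estimator under its stated
model, not robustness to those effects.

## Estimation pipeline

1. **Background**: b̂² = mean of a signal-free frame (one per benchmark
   cell).
2. **Photon number**: N̂_eff = Σ_k (z_k − b̂²), clipped at a small positive
   floor with a warning if noise drives it negative.
3. **Starting values**: a non-linear least-squares fit of ν to the frame,
   started from (x, y) uniform in a 2×2-pixel box about the ROI center and d
   uniform in (−500, 500) nm. Without this stage the likelihood's
   near-defocus-symmetric local minima trap the optimizer.
4. **Maximum likelihood**: unconstrained BFGS (numerical gradients) on
   −Σ_k [z_k ln ν_k − ν_k]; the ln z_k! term is constant in the parameters
   and dropped (flagged in the result metadata). A `mode="normalized"`
   variant divides both data and model by the total count first; this scales
   the objective by a constant, so the argmin is identical — the equivalence
   is asserted in the tests rather than assumed. Up to 3 restarts with fresh
   random starts on non-convergence; non-converged fits are flagged, counted
   and excluded from ensemble statistics. Estimated d̂ outside ±1500 nm is
   flagged as non-physical. When θ (or θ and ϕ) are fitted, they are
   optimized unconstrained and folded back into θ ∈ [0, π/2], ϕ ∈ [0, 2π)
   using the dipole-axis symmetries.

**Model fidelity for fitting.** The fitting-grade PSF uses oversampling 3
(the standard accuracy/speed compromise for this model) and the full
128-sample pupil. A 64-sample pupil changes individual normalized pixels by
under 10⁻⁴, but the correlated residual shifts the fitted position by up to
≈0.2 nm — harmless for any single localization, yet statistically resolvable
as a spurious bias in ensembles of hundreds of frames, so the full pupil is
the default (`FitConfig.pupil_samples`).

**Orientation knowledge.** The fitter consumes an orientation estimate per
frame: exact, or perturbed by Gaussian errors with standard deviations
(2°, 2°) or (4°, 2°) for (θ, ϕ) — the two realistic error models for
polarization-based orientation measurements; perturbed θ is clipped to
[0, π/2]. These are standard deviations in degrees, not variances.

## Fisher information and CRB

For the Poisson pixel model, I(ξ) = Σ_k (∂ν_k/∂ξ)ᵀ(∂ν_k/∂ξ)/ν_k over
ξ = (x, y, d), with central difference quotients (1 nm lateral, 2 nm
defocus; halving the steps moves entries by < 0.5%). Pixels with
ν < 10⁻¹² photons are excluded — they carry no photons and their 1/ν weight
is undefined. N_eff and b² are treated as known in the bound, matching the
three-parameter estimation problem; since the pipeline actually estimates
them from data, the CRB very slightly understates the attainable variance,
which is visible only as attainment ratios scattering around 1.0 within
sampling error. Degenerate conditions (θ = 0 without astigmatism, where the
defocus sign carries no information, or zero photons under excitation
coupling) raise an explicit error naming the unidentifiable parameter.

## Benchmarks and their scale

Ensembles draw ground truth uniformly over the central 216×216 nm (x, y) and
either fix the orientation on the study grid (θ ∈ {π/2, π/3, π/6, 0},
ϕ ∈ {0, π/4}) or draw it uniformly over the upper hemisphere in solid angle
(θ = arccos U; a `uniform_angles` alternative exists because the hemisphere
measure is a modelling choice, not a law). Defocus runs over −500…500 nm in
100 nm steps. Seeds are hierarchical (master → condition → repetition), so
every frame is reproducible in isolation from its ground-truth row.

Default repetition counts are 200 per condition (100 for the two
precision-headline conditions in the acceptance script), a deliberate
reduction from the 1000–5000 of the full study protocols; standard errors of
σ scale as σ/√(2(n−1)), so all comparisons in the tests carry explicit
3-standard-error bands. The acceptance script's problem sizes are recorded in
its JSON output.

The headline behaviours the benchmarks reproduce:

* without astigmatism, tilted dipoles acquire lateral bias at |d| ≳ 300 nm
  because the defocus sign is nearly unidentifiable and random starting
  values scatter fits between the two mirror minima;
* with astigmatism and a known orientation the bias vanishes
  (statistically zero at 3 SE) and σ_x, σ_y attain the CRB across the
  defocus range (ratio ceilings 1.15, and 1.3 at θ = π/6 where defocus
  estimation is hardest);
* fitting the orientation along with position inflates σ by an order of
  magnitude, which is why the pipeline expects an external orientation
  estimate.

One quantitative caveat is worth stating: the magnitude of the
no-astigmatism bias depends strongly on the inclination. The mirror-minimum
displacement at |d| = 500 nm is ≈29 nm at θ = π/3 but ≈93 nm at θ = π/6, so
ensemble biases of ~50 nm arise at the stronger tilt, while θ = π/3 saturates
near ~15 nm (the displacement times the ≈50% basin-flip fraction). The
acceptance script therefore reports the defocus-sweep bias at both
inclinations.

## Known limitations

* Single emitter exactly at the interface/focal plane: no depth-dependent
  aberration stack, no supercritical-angle fluorescence (irrelevant at
  NA < n₂), no spatially varying aberrations or background.
* Pure Poisson camera; no gain/read-noise calibration layer.
* The CRB treats photon number and background as known (see above).
* Orientation estimation itself is out of scope: the package consumes
  orientation estimates and models their errors, it does not produce them.
* The direct pupil-sum propagator is exact but O(N²·M) per evaluation; it is
  sized for ROI-scale fitting, not for rendering large fields of view.
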