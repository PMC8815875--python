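# dipoleloc

Bias-free localization of **fixed dipole emitters** for single-molecule
localization microscopy (SMLM) at cryogenic temperatures.

At room temperature fluorophores rotate freely and their point-spread
function (PSF) is well approximated by a Gaussian. Under cryo-fixation the
transition dipole is frozen: the PSF becomes the vectorial image of a fixed
dipole, asymmetric and — under slight defocus — laterally displaced, so that
Gaussian fitting (or even exact-model fitting with an unknown defocus sign)
is biased by tens of nanometers. Cryo conditions also impose a long-distance
air objective (NA ≈ 0.7), where a defocused dipole PSF is nearly
indistinguishable from a laterally shifted one.

`dipoleloc` implements the remedy studied in that setting: **weak astigmatic
imaging plus knowledge of the dipole orientation**. A vertical-astigmatism
wavefront (Zernike Z6, coefficient w6 = 0.11 λ ≈ 75 nm RMS) separates the x-
and y-line foci by ≈ 1.4 μm, so the PSF ellipticity encodes the sign and
magnitude of the defocus *d*, and the position estimate becomes unbiased with
a precision that reaches the Cramér-Rao bound (CRB) — about 1 nm at
N = 5·10⁵ detected photons.

## What the package computes

* **Vectorial dipole PSF** — back-focal-plane field of a dipole with
  inclination θ and azimuth ϕ at a water/air interface (s/p decomposition,
  Fresnel transmission, aplanatic apodization), propagated to the image plane
  by a direct pupil-sum Fourier integral with Zernike aberrations
  W(u,v) = Σ wⱼ Zⱼ(u,v) and exact air-side defocus phase
  (2π/λ)·n₂·d·cos θ₂; pixel-integrated by oversampling (9× simulation,
  3× fitting) and normalized, I = |E_f|² / ∬|E_f|².
* **Forward simulator** — orientation-dependent photon yield
  N_x = N_max sin²θ cos²ϕ, N_y = N_max sin²θ sin²ϕ, N_eff = N_max sin²θ;
  per-pixel Poisson counts with mean ν_k = N_eff·PSF_k + b² (background
  standard deviation b); seeded ground-truth tables.
* **MLE fitter** — a-priori background estimate b̂² from a dark frame, photon
  estimate N̂_eff = Σ(z_k − b̂²), then quasi-Newton minimization of the
  Poisson negative log-likelihood −Σ[z_k ln ν_k − ν_k] over ξ = (x, y, d)
  (optionally + θ or θ, ϕ), started from a randomized non-linear
  least-squares fit.
* **Fisher information / CRB** — I(ξ) = Σ_k (∂ν_k/∂ξ)ᵀ(∂ν_k/∂ξ)/ν_k with
  central difference quotients; CRB_k = (I⁻¹)_kk.
* **Ensemble benchmarks** — bias μ = mean(ξ̂ − ξ₀) and precision
  σ = sd(ξ̂ − ξ₀) per condition, compared against √CRB, over
  orientation/defocus/noise grids mirroring the study's figure protocols.

## Worked example

```python
from math import pi
from dipoleloc import (
    AcquisitionParams, DipolePSFEngine, EnsembleCondition, OpticalConfig,
    ZernikeCoefficients, astigmatic_foci_separation, crb_for_condition,
    ensemble_stats, run_ensemble, wavefront_rms,
)

w6 = ZernikeCoefficients({6: 0.11 * 680.0})   # vertical astigmatism, nm RMS
print(round(wavefront_rms(w6), 1))            # 74.8   (~75 nm RMS)

cfg = OpticalConfig()                          # NA 0.7, 60x, 680 nm, 6.5 um px
print(round(cfg.object_pixel_size_nm, 1))     # 108.3  (nm per pixel, object space)
print(round(astigmatic_foci_separation(cfg, w6)))   # 1376  (nm between line foci)

# CRB at the focal plane, N = 5e5 photons, no background
acq = AcquisitionParams(n_max=5e5, background_sd=0.0)
r = crb_for_condition(pi/2, pi/4, 0.0, cfg, w6, acq)
print(round(r.sqrt_crb_x, 2))                 # 0.37   (nm)

# a small localization ensemble at b = 100
cond = EnsembleCondition(theta=pi/2, phi=pi/4, defocus_grid=(0.0,),
                         background_sd=100.0, n_repetitions=100, master_seed=1)
s = ensemble_stats(run_ensemble(cond), cond)[0]
print(round(s.sigma["x"], 2), round(s.sqrt_crb.sqrt_crb_x, 2))   # 0.78 0.8
```

The last line says: over 100 simulated frames the fitted x-position scatters
by σ_x ≈ 0.8 nm, matching the 0.80 nm Cramér-Rao bound for that condition —
the estimator is efficient, and well below the "2 nm at b = 100" operating
envelope.

A command-line interface mirrors the library:

```bash
dipoleloc simulate --n 100 --theta 60deg --phi 45deg --defocus 100 --seed 1 --out run/
dipoleloc fit --frames run/frames.tif --background 10000 --out run/
dipoleloc crb --theta-list 1.5708 --b 100 --out crb.csv
dipoleloc benchmark fig5 --n 200 --seed 1 --out bench/
dipoleloc psf --theta 90deg --phi 0 --defocus 200 --astig 75 --out psf.tif
```

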