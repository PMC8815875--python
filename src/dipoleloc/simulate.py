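"""Forward camera simulator: orientation-dependent photon yield, Poisson noise.

Frames are expected-photon images ``nu_k = N_eff * PSF_k + b**2`` corrupted by
independent per-pixel Poisson draws.  The background enters with mean ``b**2``
so that its Poisson standard deviation equals the conventional background
level ``b``.  With polarization-modulated excitation the photon yield couples
to the dipole orientation as N_x = N_max sin^2(theta) cos^2(phi) and
N_y = N_max sin^2(theta) sin^2(phi), so N_eff = N_max sin^2(theta) — an axial
dipole (theta = 0) is never excited.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Sequence

import numpy as np

from .psf import DipolePSFEngine, OpticalConfig, PixelImage
from .zernike import ZernikeCoefficients

__all__ = [
    "AcquisitionParams",
    "GroundTruthRecord",
    "excitation_yield",
    "sample_ground_truth",
    "render_frame",
    "default_defocus_grid",
]

# the study's orientation grid: all combinations of these inclinations/azimuths
THETA_GRID = (pi / 2, pi / 3, pi / 6, 0.0)
PHI_GRID = (0.0, pi / 4)


def default_defocus_grid() -> np.ndarray:
    """Defocus values -500..500 nm in 100 nm steps (11 points)."""
    return np.arange(-500.0, 500.0 + 50.0, 100.0)


@dataclass(frozen=True)
class AcquisitionParams:
    """Photon budget, background level and rendering geometry.

    ``background_sd`` is the Poisson background standard deviation b (the
    per-pixel background mean is b**2).  With ``excitation_coupling`` the
    delivered photon number is N_max sin^2(theta); without it, N_max photons
    reach the PSF regardless of orientation (N_eff = N_max).
    """

    n_max: float = 5e5
    background_sd: float = 0.0
    roi_px: int = 17
    oversampling: int = 9
    excitation_coupling: bool = False
    pupil_samples: int = 128

    def __post_init__(self) -> None:
        if self.n_max <= 0:
            raise ValueError("n_max must be positive")
        if self.background_sd < 0:
            raise ValueError("background_sd must be non-negative")
        if self.roi_px % 2 == 0 or self.roi_px < 1:
            raise ValueError("roi_px must be odd and positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")

    @property
    def background_mean(self) -> float:
        return self.background_sd**2


@dataclass(frozen=True)
class GroundTruthRecord:
    frame: int
    x: float
    y: float
    d: float
    theta: float
    phi: float
    n_x: float
    n_y: float
    n_eff: float
    seed: int

    def __post_init__(self) -> None:
        if abs(self.n_eff - (self.n_x + self.n_y)) > 1e-6 * max(self.n_eff, 1.0):
            raise ValueError("N_eff must equal N_x + N_y")


def excitation_yield(theta: float, phi: float, n_max: float) -> tuple[float, float, float]:
    """Detected photons (N_x, N_y, N_eff) under x/y-polarized excitation."""
    if n_max <= 0:
        raise ValueError("n_max must be positive")
    s2 = np.sin(theta) ** 2
    n_x = n_max * s2 * np.cos(phi) ** 2
    n_y = n_max * s2 * np.sin(phi) ** 2
    return float(n_x), float(n_y), float(n_max * s2)


def sample_ground_truth(
    n: int,
    acq: AcquisitionParams,
    defocus: float | Sequence[float] = 0.0,
    orientation: tuple[float, float] | str = (pi / 2, 0.0),
    rng_seed: int | np.random.SeedSequence | None = 0,
    xy_halfwidth_nm: float = 108.0,
    orientation_measure: str = "uniform_hemisphere",
) -> list[GroundTruthRecord]:
    """Draw ground-truth emitter states for an ensemble.

    Positions are i.i.d. uniform on the central square of half-width
    ``xy_halfwidth_nm`` (216 x 216 nm by default, about 2 x 2 pixels).
    ``defocus`` may be a scalar (shared) or a sequence cycled across frames.
    ``orientation`` is either a fixed ``(theta, phi)`` pair or ``"random"``;
    random orientations are uniform over the upper hemisphere in solid angle
    (``orientation_measure="uniform_angles"`` draws theta and phi uniformly
    over their ranges instead).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng_seed)
    d_values = np.atleast_1d(np.asarray(defocus, dtype=float))
    records = []
    for i in range(n):
        x, y = rng.uniform(-xy_halfwidth_nm, xy_halfwidth_nm, size=2)
        if orientation == "random":
            if orientation_measure == "uniform_hemisphere":
                theta = float(np.arccos(rng.uniform(0.0, 1.0)))
            elif orientation_measure == "uniform_angles":
                theta = float(rng.uniform(0.0, pi / 2))
            else:
                raise ValueError(f"unknown orientation measure {orientation_measure!r}")
            phi = float(rng.uniform(0.0, 2 * pi))
        else:
            theta, phi = float(orientation[0]), float(orientation[1])
        if acq.excitation_coupling:
            n_x, n_y, n_eff = excitation_yield(theta, phi, acq.n_max)
        else:
            n_x, n_y, n_eff = acq.n_max, 0.0, acq.n_max
        frame_seed = int(rng.integers(0, 2**31 - 1))
        records.append(
            GroundTruthRecord(
                frame=i, x=float(x), y=float(y), d=float(d_values[i % len(d_values)]),
                theta=theta, phi=phi, n_x=n_x, n_y=n_y, n_eff=n_eff, seed=frame_seed,
            )
        )
    return records


def expected_frame(
    gt: GroundTruthRecord,
    engine: DipolePSFEngine,
    acq: AcquisitionParams,
) -> np.ndarray:
    """Noise-free expected counts nu_k = N_eff * PSF_k + b^2."""
    psf = engine.intensity(gt.x, gt.y, gt.d, gt.theta, gt.phi)
    return gt.n_eff * psf + acq.background_mean


def render_frame(
    gt: GroundTruthRecord,
    cfg: OpticalConfig,
    coeffs: ZernikeCoefficients | dict | None,
    acq: AcquisitionParams,
    rng: np.random.Generator | int | None = None,
    engine: DipolePSFEngine | None = None,
) -> PixelImage:
    """Render one Poisson camera frame for a ground-truth state.

    Pass a prebuilt ``engine`` to amortize pupil setup across frames; it must
    match ``cfg``/``coeffs``/``acq`` geometry.  When ``rng`` is None the
    record's own per-frame seed is used, making frames reproducible from the
    ground-truth table alone.
    """
    if engine is None:
        engine = DipolePSFEngine(cfg, coeffs, roi_px=acq.roi_px,
                                 oversampling=acq.oversampling,
                                 pupil_samples=acq.pupil_samples)
    if rng is None:
        rng = np.random.default_rng(gt.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nu = expected_frame(gt, engine, acq)
    assert np.all(nu >= 0.0), "expected counts must be non-negative"
    counts = rng.poisson(nu).astype(np.int64)
    return PixelImage(pixels=counts, object_pixel_size_nm=cfg.object_pixel_size_nm)


def render_dark_frame(
    cfg: OpticalConfig,
    acq: AcquisitionParams,
    rng: np.random.Generator | int | None = 0,
) -> PixelImage:
    """A signal-free frame (background only), for a-priori b^2 estimation."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    counts = rng.poisson(acq.background_mean, size=(acq.roi_px, acq.roi_px)).astype(np.int64)
    return PixelImage(pixels=counts, object_pixel_size_nm=cfg.object_pixel_size_nm)
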