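"""Fisher information and Cramér-Rao bound for the Poisson pixel model.

The estimated parameters are xi = (x, y, d): lateral position and defocus.
For independent Poisson pixels with means nu_k(xi), the information matrix is

    I(xi) = sum_k (d nu_k / d xi)^T (d nu_k / d xi) / nu_k,

and sqrt of the diagonal of its inverse lower-bounds the standard deviation
of any unbiased estimator.  Derivatives are central difference quotients
(default steps: 1 nm laterally, 2 nm in defocus); pixels whose mean falls
below a small floor carry no photons and are excluded from the sum.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .psf import DipolePSFEngine, OpticalConfig
from .simulate import AcquisitionParams
from .zernike import ZernikeCoefficients

__all__ = [
    "DegenerateModelError",
    "PixelModelContext",
    "FisherMatrix",
    "CRBResult",
    "expected_pixels",
    "fisher_matrix",
    "crb",
    "crb_for_condition",
]

PARAM_NAMES = ("x", "y", "d")


class DegenerateModelError(RuntimeError):
    """Raised when the Fisher matrix is singular (a parameter is unidentifiable)."""


@dataclass(frozen=True)
class PixelModelContext:
    """Everything the Poisson pixel model needs besides xi itself."""

    theta: float
    phi: float
    n_eff: float
    background_sd: float
    cfg: OpticalConfig
    coeffs: ZernikeCoefficients
    roi_px: int = 17
    oversampling: int = 9
    pupil_samples: int = 128
    # optional shared normalization window: makes Fisher information
    # comparable across nested ROI sizes (the camera does not renormalize)
    norm_roi_px: int | None = None

    def engine(self) -> DipolePSFEngine:
        return DipolePSFEngine(self.cfg, self.coeffs, roi_px=self.roi_px,
                               oversampling=self.oversampling,
                               pupil_samples=self.pupil_samples,
                               norm_roi_px=self.norm_roi_px)


@dataclass(frozen=True)
class FisherMatrix:
    """3x3 information matrix over (x, y, d), in photons/nm^2."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("Fisher matrix must be 3x3")
        if not np.allclose(m, m.T, rtol=1e-10, atol=0.0):
            raise ValueError("Fisher matrix must be symmetric")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class CRBResult:
    """Lower-bound standard deviations sqrt(CRB) per parameter, in nm."""

    sqrt_crb_x: float
    sqrt_crb_y: float
    sqrt_crb_d: float

    def as_array(self) -> np.ndarray:
        return np.array([self.sqrt_crb_x, self.sqrt_crb_y, self.sqrt_crb_d])


def expected_pixels(
    xi: np.ndarray,
    ctx: PixelModelContext,
    engine: DipolePSFEngine | None = None,
) -> np.ndarray:
    """Per-pixel Poisson means nu_k = N_eff * PSF_k(xi) + b^2."""
    x, y, d = np.asarray(xi, dtype=float)
    if engine is None:
        engine = ctx.engine()
    return ctx.n_eff * engine.intensity(x, y, d, ctx.theta, ctx.phi) + ctx.background_sd**2


def fisher_matrix(
    xi: np.ndarray,
    ctx: PixelModelContext,
    steps_nm: tuple[float, float, float] = (1.0, 1.0, 2.0),
    zero_floor: float = 1e-12,
    engine: DipolePSFEngine | None = None,
) -> FisherMatrix:
    """Fisher information by central difference quotients of the pixel means."""
    if any(s <= 0 for s in steps_nm):
        raise ValueError("difference-quotient steps must be positive")
    xi = np.asarray(xi, dtype=float)
    if engine is None:
        engine = ctx.engine()
    nu = expected_pixels(xi, ctx, engine)
    grads = []
    for i, h in enumerate(steps_nm):
        e = np.zeros(3)
        e[i] = h
        nu_p = expected_pixels(xi + e, ctx, engine)
        nu_m = expected_pixels(xi - e, ctx, engine)
        grads.append((nu_p - nu_m) / (2.0 * h))
    g = np.stack([gr.ravel() for gr in grads])  # (3, K)
    keep = nu.ravel() > zero_floor
    w = 1.0 / nu.ravel()[keep]
    mat = (g[:, keep] * w) @ g[:, keep].T
    mat = 0.5 * (mat + mat.T)
    return FisherMatrix(matrix=mat)


def crb(info: FisherMatrix) -> CRBResult:
    """sqrt of the diagonal of the inverse information matrix.

    Raises :class:`DegenerateModelError` naming the unidentifiable parameter
    when the matrix is (numerically) singular.
    """
    m = info.matrix
    diag = np.diag(m)
    dead = [PARAM_NAMES[i] for i in range(3) if diag[i] <= 0 or not np.isfinite(diag[i])]
    if dead:
        raise DegenerateModelError(
            f"no information about parameter(s) {', '.join(dead)}: Fisher matrix singular"
        )
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > 1e12:
        # point at the weakest direction to aid diagnosis
        evals, evecs = np.linalg.eigh(m)
        weakest = PARAM_NAMES[int(np.argmax(np.abs(evecs[:, 0])))]
        raise DegenerateModelError(
            f"Fisher matrix is numerically singular (condition number {cond:.3g}); "
            f"parameter '{weakest}' is effectively unidentifiable"
        )
    inv = np.linalg.inv(m)
    var = np.diag(inv)
    if np.any(var <= 0):
        raise DegenerateModelError("inverse Fisher matrix has non-positive diagonal")
    return CRBResult(*np.sqrt(var))


def crb_for_condition(
    theta: float,
    phi: float,
    d: float,
    cfg: OpticalConfig,
    coeffs: ZernikeCoefficients | dict,
    acq: AcquisitionParams,
    xi_xy: tuple[float, float] = (0.0, 0.0),
    steps_nm: tuple[float, float, float] = (1.0, 1.0, 2.0),
    engine: DipolePSFEngine | None = None,
) -> CRBResult:
    """CRB at a benchmark condition, honoring excitation coupling if enabled."""
    if not isinstance(coeffs, ZernikeCoefficients):
        coeffs = ZernikeCoefficients(coeffs)
    n_eff = acq.n_max * np.sin(theta) ** 2 if acq.excitation_coupling else acq.n_max
    ctx = PixelModelContext(theta=theta, phi=phi, n_eff=n_eff,
                            background_sd=acq.background_sd, cfg=cfg, coeffs=coeffs,
                            roi_px=acq.roi_px, oversampling=acq.oversampling,
                            pupil_samples=acq.pupil_samples)
    if n_eff <= 0:
        raise DegenerateModelError(
            "zero expected photons (theta = 0 under excitation coupling): "
            "all of x, y, d are unidentifiable"
        )
    return crb(fisher_matrix(np.array([xi_xy[0], xi_xy[1], d]), ctx, steps_nm, engine=engine))
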