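"""Orthonormal Zernike polynomials (Noll indexing) and aberration wavefronts.

Coefficients carry nanometers of RMS wavefront error: because the basis is
orthonormal over the unit disk (mean-square of every ``Z_j`` equals 1), the
RMS of ``w_j * Z_j`` is exactly ``|w_j|``.  The wavefront enters the pupil
integral of the imaging model as the phase factor ``exp(i * 2*pi * W / lambda)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import factorial
from typing import Mapping

import numpy as np

__all__ = [
    "ZernikeCoefficients",
    "PupilGrid",
    "noll_to_nm",
    "zernike_polynomial",
    "build_wavefront",
    "make_pupil_grid",
]


def noll_to_nm(j: int) -> tuple[int, int]:
    """Convert a Noll single index ``j >= 1`` to (n, m).

    The returned ``m`` is signed: ``m >= 0`` selects the cosine term and
    ``m < 0`` the sine term, following Noll's even/odd-``j`` rule.
    """
    if not isinstance(j, (int, np.integer)) or isinstance(j, bool):
        raise TypeError(f"Noll index must be an integer, got {j!r}")
    if j < 1:
        raise ValueError(f"Noll index must be >= 1, got {j}")
    # walk down the rows of the Zernike pyramid
    n = 0
    k = j - 1
    while k > n:
        n += 1
        k -= n
    m = (-1) ** j * ((n % 2) + 2 * ((k + ((n + 1) % 2)) // 2))
    return n, m


def _radial(n: int, m_abs: int, rho: np.ndarray) -> np.ndarray:
    """Radial polynomial R_n^{|m|}(rho) via the closed-form factorial sum."""
    out = np.zeros_like(rho, dtype=float)
    for k in range((n - m_abs) // 2 + 1):
        c = (
            (-1) ** k
            * factorial(n - k)
            / (factorial(k) * factorial((n + m_abs) // 2 - k) * factorial((n - m_abs) // 2 - k))
        )
        out += c * rho ** (n - 2 * k)
    return out


def zernike_polynomial(j: int, u, v) -> np.ndarray:
    """Evaluate the unit-RMS Zernike polynomial Z_j at pupil coordinates (u, v).

    Points outside the unit disk evaluate to 0.  ``j`` uses Noll's single
    indexing (j=1 piston, j=4 defocus, j=5/6 oblique/vertical astigmatism).
    """
    n, m = noll_to_nm(j)
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    rad = _radial(n, abs(m), rho)
    if m == 0:
        z = np.sqrt(n + 1.0) * rad
    elif m > 0:
        z = np.sqrt(2.0 * (n + 1)) * rad * np.cos(m * phi)
    else:
        z = np.sqrt(2.0 * (n + 1)) * rad * np.sin(-m * phi)
    return np.where(rho <= 1.0, z, 0.0)


@dataclass(frozen=True)
class ZernikeCoefficients:
    """Sparse map from Noll index to coefficient in nm RMS wavefront error.

    Absent indices mean zero.  ``ZernikeCoefficients({6: 74.8})`` is a
    vertical astigmatism of 74.8 nm RMS.
    """

    entries: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for j, w in dict(self.entries).items():
            jj = int(j)
            if jj != j or jj < 1:
                raise ValueError(f"invalid Noll index {j!r}: must be an integer >= 1")
            w = float(w)
            if not np.isfinite(w):
                raise ValueError(f"coefficient for Z{jj} is not finite: {w}")
            clean[jj] = w
        object.__setattr__(self, "entries", clean)

    def get(self, j: int) -> float:
        return self.entries.get(j, 0.0)

    def __getitem__(self, j: int) -> float:
        return self.get(j)

    def items(self):
        return self.entries.items()


@dataclass(frozen=True)
class PupilGrid:
    """Cartesian sampling of the normalized pupil (unit disk).

    A midpoint grid symmetric about the origin; ``mask`` marks samples with
    u^2 + v^2 <= 1.  ``u`` and ``v`` are the 1-D axis coordinates; ``uu`` and
    ``vv`` the 2-D meshes.
    """

    samples: int
    u: np.ndarray
    v: np.ndarray
    uu: np.ndarray
    vv: np.ndarray
    mask: np.ndarray

    @property
    def step(self) -> float:
        return 2.0 / self.samples


def make_pupil_grid(samples: int = 128) -> PupilGrid:
    if samples < 32:
        raise ValueError(f"pupil sampling must be >= 32 per axis, got {samples}")
    ax = (np.arange(samples) + 0.5) / samples * 2.0 - 1.0
    uu, vv = np.meshgrid(ax, ax, indexing="ij")
    mask = uu**2 + vv**2 <= 1.0
    return PupilGrid(samples=samples, u=ax, v=ax, uu=uu, vv=vv, mask=mask)


def build_wavefront(coeffs: ZernikeCoefficients, grid: PupilGrid) -> np.ndarray:
    """Assemble W(u, v) = sum_j w_j Z_j(u, v) in nm on the pupil grid.

    Zero outside the aperture.
    """
    if not isinstance(coeffs, ZernikeCoefficients):
        coeffs = ZernikeCoefficients(coeffs)
    w = np.zeros_like(grid.uu)
    for j, wj in coeffs.items():
        if wj != 0.0:
            w += wj * zernike_polynomial(j, grid.uu, grid.vv)
    return np.where(grid.mask, w, 0.0)


def wavefront_rms(coeffs: ZernikeCoefficients, samples: int = 512) -> float:
    """RMS of the assembled wavefront over the unit disk, by quadrature."""
    grid = make_pupil_grid(samples)
    w = build_wavefront(coeffs, grid)
    return float(np.sqrt(np.mean(w[grid.mask] ** 2)))
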