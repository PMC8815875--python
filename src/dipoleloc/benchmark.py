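"""Seeded ensemble benchmarks: bias/precision per condition versus the CRB.

A condition fixes orientation, defocus grid, photon budget, background and
fit configuration; for each repetition a ground-truth state is drawn, a frame
rendered and fitted, and per-defocus bias mu (mean error) and precision sigma
(sample standard deviation of the error) are accumulated, together with the
matching Cramér-Rao bound.  Seeds are hierarchical — master seed, condition
key, repetition index — so any single repetition is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import pi
from typing import Sequence

import numpy as np
import pandas as pd

from .crb import CRBResult, DegenerateModelError, crb_for_condition
from .fit import FitConfig, FitContext, estimate_background, estimate_neff, mle_localize
from .psf import DipolePSFEngine, OpticalConfig
from .simulate import (
    AcquisitionParams,
    default_defocus_grid,
    render_dark_frame,
    render_frame,
    sample_ground_truth,
)
from .zernike import ZernikeCoefficients

__all__ = [
    "EnsembleCondition",
    "EnsembleStats",
    "run_ensemble",
    "ensemble_stats",
    "stats_frame",
    "precision_bias",
    "crb_comparison",
    "run_condition_grid",
    "roi_size_sweep",
    "scenario_conditions",
    "SCENARIOS",
]

# orientation-error cases: standard deviations in degrees for (theta, phi)
ORIENTATION_ERROR_CASES = {
    "exact": (0.0, 0.0),
    "normal_2deg": (2.0, 2.0),
    "normal_4_2deg": (4.0, 2.0),
}


@dataclass(frozen=True)
class EnsembleCondition:
    """One benchmark cell: orientation x defocus grid x noise x fit setup."""

    theta: float = pi / 2
    phi: float = pi / 4
    defocus_grid: tuple[float, ...] = tuple(default_defocus_grid())
    n_max: float = 5e5
    background_sd: float = 0.0
    astigmatism_rms_nm: float = 0.11 * 680.0
    excitation_coupling: bool = False
    orientation_error: str = "exact"
    fit: FitConfig = field(default_factory=FitConfig)
    n_repetitions: int = 200
    master_seed: int = 0
    roi_px: int = 17
    random_orientation: bool = False

    def __post_init__(self) -> None:
        if self.n_repetitions < 2:
            raise ValueError("need at least 2 repetitions for a standard deviation")
        if len(self.defocus_grid) == 0:
            raise ValueError("defocus grid must be non-empty")
        if self.orientation_error not in ORIENTATION_ERROR_CASES:
            raise ValueError(f"orientation_error must be one of {tuple(ORIENTATION_ERROR_CASES)}")

    @property
    def coeffs(self) -> ZernikeCoefficients:
        if self.astigmatism_rms_nm == 0.0:
            return ZernikeCoefficients()
        return ZernikeCoefficients({6: self.astigmatism_rms_nm})

    def acquisition(self) -> AcquisitionParams:
        return AcquisitionParams(
            n_max=self.n_max, background_sd=self.background_sd,
            roi_px=self.roi_px, excitation_coupling=self.excitation_coupling,
        )


@dataclass(frozen=True)
class EnsembleStats:
    """Per-parameter bias/precision (with standard errors) and matching CRB."""

    d_true: float
    n_converged: int
    n_total: int
    mu: dict
    sigma: dict
    se_mu: dict
    se_sigma: dict
    sqrt_crb: CRBResult | None


def precision_bias(errors: np.ndarray) -> tuple[float, float, float, float]:
    """(mu, sigma, se_mu, se_sigma) of a 1-D error sample.

    mu is the mean error (bias); sigma the sample standard deviation with the
    n-1 denominator; standard errors are sigma/sqrt(n) and
    sigma/sqrt(2*(n-1)).
    """
    errors = np.asarray(errors, dtype=float)
    n = errors.size
    if n < 2:
        raise ValueError("need at least 2 errors for precision statistics")
    mu = float(errors.mean())
    sigma = float(errors.std(ddof=1))
    return mu, sigma, sigma / np.sqrt(n), sigma / np.sqrt(2.0 * (n - 1))


def _perturbed_orientation(theta, phi, case, rng):
    sd_theta, sd_phi = ORIENTATION_ERROR_CASES[case]
    if sd_theta == 0.0 and sd_phi == 0.0:
        return theta, phi
    th = theta + rng.normal(0.0, np.deg2rad(sd_theta))
    ph = phi + rng.normal(0.0, np.deg2rad(sd_phi))
    return float(np.clip(th, 0.0, pi / 2)), float(ph)


def run_ensemble(
    cond: EnsembleCondition,
    condition_index: int = 0,
) -> pd.DataFrame:
    """Simulate and fit every repetition of a condition; one row per fit.

    Columns: defocus/ground truth, estimates, errors, convergence flag,
    repetition seed.  Non-converged fits are kept in the table (flagged) and
    excluded later by :func:`ensemble_stats`.
    """
    acq = cond.acquisition()
    coeffs = cond.coeffs
    cfg = OpticalConfig()
    sim_engine = DipolePSFEngine(cfg, coeffs, roi_px=cond.roi_px,
                                 oversampling=acq.oversampling)
    fit_engine = DipolePSFEngine(cfg, coeffs, roi_px=cond.roi_px,
                                 oversampling=cond.fit.oversampling,
                                 pupil_samples=cond.fit.pupil_samples)
    rows = []
    for di, d in enumerate(cond.defocus_grid):
        ss = np.random.SeedSequence([cond.master_seed, condition_index, di])
        cond_rng = np.random.default_rng(ss)
        orientation = "random" if cond.random_orientation else (cond.theta, cond.phi)
        gts = sample_ground_truth(cond.n_repetitions, acq, defocus=d,
                                  orientation=orientation, rng_seed=cond_rng)
        for gt in gts:
            rep_rng = np.random.default_rng(gt.seed)
            frame = render_frame(gt, cfg, coeffs, acq, rng=rep_rng, engine=sim_engine)
            # a-priori background estimate from a signal-free frame drawn per
            # repetition (independent estimates, as from separate movie regions)
            b2_hat = (
                estimate_background(render_dark_frame(cfg, acq, rng=rep_rng))
                if cond.background_sd > 0 else 0.0
            )
            th_fit, ph_fit = _perturbed_orientation(gt.theta, gt.phi,
                                                    cond.orientation_error, rep_rng)
            n_eff_hat = estimate_neff(frame, b2_hat)
            ctx = FitContext(cfg=cfg, coeffs=coeffs, n_eff=n_eff_hat,
                             background_mean=b2_hat, theta=th_fit, phi=ph_fit,
                             engine=fit_engine)
            res = mle_localize(frame, cond.fit, ctx, rng=rep_rng)
            rows.append({
                "d_true": d, "x_true": gt.x, "y_true": gt.y,
                "theta_true": gt.theta, "phi_true": gt.phi,
                "n_eff_true": gt.n_eff,
                "theta_fit_input": th_fit, "phi_fit_input": ph_fit,
                "x_hat": res.x, "y_hat": res.y, "d_hat": res.d,
                "theta_hat": res.theta, "phi_hat": res.phi,
                "err_x": res.x - gt.x, "err_y": res.y - gt.y, "err_d": res.d - d,
                "nll": res.nll, "converged": res.converged,
                "n_restarts": res.n_restarts, "seed": gt.seed,
            })
    return pd.DataFrame(rows)


def ensemble_stats(
    table: pd.DataFrame,
    cond: EnsembleCondition,
    with_crb: bool = True,
) -> list[EnsembleStats]:
    """Reduce a fit table to per-defocus bias/precision statistics + CRB."""
    cfg = OpticalConfig()
    acq = cond.acquisition()
    crb_engine = (
        DipolePSFEngine(cfg, cond.coeffs, roi_px=cond.roi_px, oversampling=acq.oversampling)
        if with_crb else None
    )
    out = []
    for d, sub in table.groupby("d_true", sort=True):
        ok = sub[sub["converged"]]
        if len(ok) < 2:
            raise RuntimeError(f"fewer than 2 converged fits at defocus {d}")
        mu, sigma, se_mu, se_sigma = {}, {}, {}, {}
        for p in ("x", "y", "d"):
            m, s, sem, ses = precision_bias(ok[f"err_{p}"].to_numpy())
            mu[p], sigma[p], se_mu[p], se_sigma[p] = m, s, sem, ses
        bound = None
        if with_crb and not cond.random_orientation:
            try:
                bound = crb_for_condition(cond.theta, cond.phi, float(d), cfg,
                                          cond.coeffs, acq, engine=crb_engine)
            except DegenerateModelError:
                bound = None
        out.append(EnsembleStats(
            d_true=float(d), n_converged=int(len(ok)), n_total=int(len(sub)),
            mu=mu, sigma=sigma, se_mu=se_mu, se_sigma=se_sigma, sqrt_crb=bound,
        ))
    return out


def stats_frame(stats: list[EnsembleStats]) -> pd.DataFrame:
    """Flatten EnsembleStats into the stats.csv schema."""
    rows = []
    for s in stats:
        row = {"d_true": s.d_true, "n_converged": s.n_converged, "n_total": s.n_total}
        for p in ("x", "y", "d"):
            row[f"mu_{p}"] = s.mu[p]
            row[f"sigma_{p}"] = s.sigma[p]
            row[f"se_mu_{p}"] = s.se_mu[p]
            row[f"se_sigma_{p}"] = s.se_sigma[p]
        if s.sqrt_crb is not None:
            row["sqrt_crb_x"] = s.sqrt_crb.sqrt_crb_x
            row["sqrt_crb_y"] = s.sqrt_crb.sqrt_crb_y
            row["sqrt_crb_d"] = s.sqrt_crb.sqrt_crb_d
            for p in ("x", "y", "d"):
                row[f"ratio_{p}"] = row[f"sigma_{p}"] / row[f"sqrt_crb_{p}"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_condition_grid(cond: EnsembleCondition, condition_index: int = 0,
                       with_crb: bool = True) -> pd.DataFrame:
    """run_ensemble + ensemble_stats in one call."""
    return stats_frame(ensemble_stats(run_ensemble(cond, condition_index), cond, with_crb))


@dataclass(frozen=True)
class EfficiencyReport:
    parameter: str
    ratio: float
    ceiling: float
    passed: bool
    suspicious: bool  # ratio below the CRB by more than sampling allows


def crb_comparison(stats: EnsembleStats, bound: CRBResult | None = None,
                   ceiling: float = 1.15) -> list[EfficiencyReport]:
    """Efficiency ratios sigma/sqrt(CRB) per parameter with pass/fail flags.

    Ratios below ``1 - 3/sqrt(2 n)`` are flagged suspicious: the CRB is a
    lower bound for unbiased estimators, so a markedly smaller sample sigma
    indicates a mismatch between the ensemble and the bound's condition.
    """
    if bound is None:
        bound = stats.sqrt_crb
    if bound is None:
        raise ValueError("no CRB available for this condition")
    floor = 1.0 - 3.0 / np.sqrt(2.0 * stats.n_converged)
    out = []
    for p, b in zip(("x", "y", "d"), bound.as_array()):
        ratio = stats.sigma[p] / b
        out.append(EfficiencyReport(parameter=p, ratio=float(ratio), ceiling=ceiling,
                                    passed=bool(ratio <= ceiling),
                                    suspicious=bool(ratio < floor)))
    return out


def roi_size_sweep(
    roi_sizes: Sequence[int],
    base: EnsembleCondition,
) -> pd.DataFrame:
    """Repeat a condition across ROI sizes; one stats row per (roi, defocus)."""
    frames = []
    for i, roi in enumerate(roi_sizes):
        if roi % 2 == 0:
            raise ValueError("ROI sizes must be odd")
        cond = replace(base, roi_px=int(roi))
        df = run_condition_grid(cond, condition_index=1000 + i)
        df.insert(0, "roi_px", int(roi))
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def scenario_conditions(name: str, n: int | None = None, seed: int = 0,
                        fit: FitConfig | None = None) -> list[EnsembleCondition]:
    """Benchmark scenarios mirroring the study's figure protocols.

    fig2: no astigmatism, known orientation, b=300, four inclinations.
    fig3a/fig3b: random orientations, astigmatism, b=100, orientation (or
    inclination only) fitted.  fig4/fig5: astigmatism, known orientation,
    b=0 / b=100.  fig6: ROI sweep base condition (theta=pi/6).  fig7:
    astigmatism + 2 deg orientation noise, b=100.  fig8: excitation-coupled
    photon yield + 2 deg orientation noise, b=100.
    """
    thetas = (pi / 2, pi / 3, pi / 6, 0.0)
    w6 = 0.11 * 680.0

    def cell(**kw):
        base = dict(phi=pi / 4, master_seed=seed)
        if n is not None:
            base["n_repetitions"] = n
        if fit is not None:
            base["fit"] = fit
        base.update(kw)
        return EnsembleCondition(**base)

    if name == "fig2":
        return [cell(theta=t, background_sd=300.0, astigmatism_rms_nm=0.0) for t in thetas]
    if name == "fig3a":
        return [cell(random_orientation=True, background_sd=100.0,
                     fit=fit or FitConfig(fitted_parameters="xyd_theta_phi"))]
    if name == "fig3b":
        return [cell(random_orientation=True, background_sd=100.0,
                     fit=fit or FitConfig(fitted_parameters="xyd_theta"))]
    if name == "fig4":
        return [cell(theta=t, background_sd=0.0) for t in thetas]
    if name == "fig5":
        return [cell(theta=t, background_sd=100.0) for t in thetas]
    if name == "fig6":
        return [cell(theta=pi / 6, background_sd=b, defocus_grid=(-400.0, 0.0, 400.0))
                for b in (0.0, 300.0)]
    if name == "fig7":
        return [cell(theta=t, background_sd=100.0, orientation_error="normal_2deg")
                for t in thetas]
    if name == "fig8":
        return [cell(theta=t, background_sd=100.0, orientation_error="normal_2deg",
                     excitation_coupling=True) for t in thetas if t > 0.0]
    raise ValueError(f"unknown scenario {name!r}")


SCENARIOS = ("fig2", "fig3a", "fig3b", "fig4", "fig5", "fig6", "fig7", "fig8")
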