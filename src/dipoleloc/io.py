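"""Run configuration, TIFF/CSV file exchange, and provenance headers.

Frames travel as multi-page TIFF (16-bit unsigned counts, with an automatic
32-bit float fallback for out-of-range or non-integer data) with a CSV
ground-truth sidecar and an echo of the configuration used.  Every CSV starts
with ``#``-prefixed provenance lines recording the seed and coordinate
convention, so each row is traceable to (config, seed) alone.
"""

from __future__ import annotations

import configparser
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .fit import FitConfig
from .psf import OpticalConfig, PixelImage
from .simulate import AcquisitionParams, GroundTruthRecord
from .zernike import ZernikeCoefficients

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_frames",
    "read_frames",
    "write_table",
    "read_table",
]

GROUND_TRUTH_COLUMNS = [
    "frame", "x_nm", "y_nm", "d_nm", "theta_rad", "phi_rad", "Nx", "Ny", "Neff", "seed",
]

COORDINATE_NOTE = (
    "coordinates: object-space nm, origin at the center of the middle ROI pixel, "
    "x right / y up; angles in radians"
)


@dataclass(frozen=True)
class RunConfig:
    """Validated bundle of optical, aberration, acquisition and fit settings."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    aberrations: ZernikeCoefficients = field(
        default_factory=lambda: ZernikeCoefficients({6: 0.11 * 680.0})
    )
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    output_dir: str = "."


_OPTICAL_KEYS = {
    "numerical_aperture": float, "n_sample": float, "n_immersion": float,
    "magnification": float, "tube_focal_length_mm": float,
    "wavelength_nm": float, "camera_pixel_size_um": float, "defocus_model": str,
}
_ACQ_KEYS = {
    "n_max": float, "background_sd": float, "roi_px": int, "oversampling": int,
    "excitation_coupling": bool, "pupil_samples": int,
}
_FIT_KEYS = {
    "fitted_parameters": str, "oversampling": int, "pupil_samples": int,
    "start_d_range_nm": float, "start_xy_box_px": float, "max_retries": int,
    "max_iterations": int, "gradient_tol": float, "mode": str,
    "d_sanity_window_nm": float,
}
_RUN_KEYS = {"seed": int, "output_dir": str}


def _parse_section(parser, section, spec):
    out = {}
    if not parser.has_section(section):
        return out
    for key, raw in parser.items(section):
        if key not in spec:
            raise ValueError(f"unknown key '{key}' in section [{section}]")
        typ = spec[key]
        try:
            if typ is bool:
                out[key] = parser.getboolean(section, key)
            else:
                out[key] = typ(raw)
        except ValueError as exc:
            raise ValueError(f"invalid value for [{section}] {key}: {raw!r}") from exc
    return out


def _parse_aberrations(parser, wavelength_nm: float) -> ZernikeCoefficients:
    entries: dict[int, float] = {}
    if parser.has_section("aberrations"):
        for key, raw in parser.items("aberrations"):
            if key == "astigmatism_rms_nm":
                entries[6] = float(raw)
            elif key.startswith("z"):
                try:
                    j = int(key[1:])
                except ValueError as exc:
                    raise ValueError(f"invalid aberration key '{key}'") from exc
                entries[j] = float(raw)
            else:
                raise ValueError(
                    f"unknown key '{key}' in section [aberrations] "
                    "(use 'z<noll index> = value_nm' or 'astigmatism_rms_nm')"
                )
    else:
        entries[6] = 0.11 * wavelength_nm
    return ZernikeCoefficients(entries)


def load_config(path: str | Path | None = None, text: str | None = None) -> RunConfig:
    """Load and validate a flat sectioned config file; defaults fill gaps.

    Sections: [optical], [aberrations], [acquisition], [fit], [run].  Unknown
    sections or keys are rejected with a per-field diagnostic.  An empty or
    absent file yields the study defaults (NA 0.7, lambda 680 nm, 60x,
    6.5 um pixels -> 108.3 nm object pixels, N_max 5e5, w6 = 0.11 lambda).
    """
    parser = configparser.ConfigParser()
    if text is not None:
        parser.read_string(text)
    elif path is not None:
        p = Path(path)
        if not p.exists():
            raise FileNotFoundError(f"config file not found: {p}")
        parser.read_string(p.read_text())
    known = {"optical", "aberrations", "acquisition", "fit", "run"}
    unknown = set(parser.sections()) - known
    if unknown:
        raise ValueError(f"unknown config section(s): {sorted(unknown)}")
    optical = OpticalConfig(**_parse_section(parser, "optical", _OPTICAL_KEYS))
    acq = AcquisitionParams(**_parse_section(parser, "acquisition", _ACQ_KEYS))
    fit_cfg = FitConfig(**_parse_section(parser, "fit", _FIT_KEYS))
    run = _parse_section(parser, "run", _RUN_KEYS)
    coeffs = _parse_aberrations(parser, optical.wavelength_nm)
    return RunConfig(optical=optical, aberrations=coeffs, acquisition=acq,
                     fit=fit_cfg, seed=run.get("seed", 0),
                     output_dir=run.get("output_dir", "."))


def config_text(cfg: RunConfig) -> str:
    """Serialize a RunConfig back to the sectioned text format."""
    parser = configparser.ConfigParser()
    parser["optical"] = {k: str(getattr(cfg.optical, k)) for k in _OPTICAL_KEYS}
    parser["aberrations"] = {f"z{j}": str(w) for j, w in sorted(cfg.aberrations.items())}
    parser["acquisition"] = {k: str(getattr(cfg.acquisition, k)) for k in _ACQ_KEYS}
    parser["fit"] = {k: str(getattr(cfg.fit, k)) for k in _FIT_KEYS}
    parser["run"] = {"seed": str(cfg.seed), "output_dir": cfg.output_dir}
    buf = _stdio.StringIO()
    parser.write(buf)
    return buf.getvalue()


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(config_text(cfg))


def write_frames(
    frames: list[PixelImage] | list[np.ndarray],
    ground_truth: list[GroundTruthRecord],
    outdir: str | Path,
    stem: str = "frames",
    run_config: RunConfig | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write a frame stack + ground-truth sidecar (+ config echo).

    Integer counts go to 16-bit unsigned TIFF; values above 65535 or float
    frames fall back to 32-bit float.  Returns the paths written.
    """
    if len(frames) != len(ground_truth):
        raise ValueError("frames and ground_truth must have matching lengths")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    arrays = [f.pixels if isinstance(f, PixelImage) else np.asarray(f) for f in frames]
    stack = np.stack(arrays)
    if np.issubdtype(stack.dtype, np.integer) and stack.max(initial=0) <= np.iinfo(np.uint16).max:
        stack = stack.astype(np.uint16)
    else:
        stack = stack.astype(np.float32)
    tiff_path = outdir / f"{stem}.tif"
    tifffile.imwrite(tiff_path, stack, photometric="minisblack")

    gt = pd.DataFrame(
        [
            {
                "frame": g.frame, "x_nm": g.x, "y_nm": g.y, "d_nm": g.d,
                "theta_rad": g.theta, "phi_rad": g.phi,
                "Nx": g.n_x, "Ny": g.n_y, "Neff": g.n_eff, "seed": g.seed,
            }
            for g in ground_truth
        ],
        columns=GROUND_TRUTH_COLUMNS,
    )
    csv_path = outdir / f"{stem}_ground_truth.csv"
    write_table(gt, csv_path, seed=seed)
    paths = {"tiff": tiff_path, "ground_truth": csv_path}
    if run_config is not None:
        echo = outdir / f"{stem}_config_used.ini"
        save_config(run_config, echo)
        paths["config"] = echo
    return paths


def read_frames(tiff_path: str | Path, object_pixel_size_nm: float | None = None
                ) -> list[PixelImage]:
    """Read a frame stack written by :func:`write_frames` (or any ROI TIFF)."""
    data = tifffile.imread(tiff_path)
    if data.ndim == 2:
        data = data[None]
    px = object_pixel_size_nm if object_pixel_size_nm is not None else OpticalConfig().object_pixel_size_nm
    return [PixelImage(pixels=frame, object_pixel_size_nm=px) for frame in data]


def write_table(df: pd.DataFrame, path: str | Path, seed: int | None = None,
                extra_notes: tuple[str, ...] = ()) -> None:
    """CSV with '#' provenance header lines (seed, coordinate convention)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# dipoleloc table schema v1\n# {COORDINATE_NOTE}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        for note in extra_notes:
            fh.write(f"# {note}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def ground_truth_from_table(df: pd.DataFrame) -> list[GroundTruthRecord]:
    return [
        GroundTruthRecord(
            frame=int(r.frame), x=float(r.x_nm), y=float(r.y_nm), d=float(r.d_nm),
            theta=float(r.theta_rad), phi=float(r.phi_rad),
            n_x=float(r.Nx), n_y=float(r.Ny), n_eff=float(r.Neff), seed=int(r.seed),
        )
        for r in df.itertuples()
    ]
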