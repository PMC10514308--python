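"""smFISH image and intensity quantification.

Turns fluorescence measurements into per-cell transcript counts: image
stacks are blurred, background-subtracted (rolling ball) and z-binned;
isolated single transcripts are fitted with 2D Gaussians whose mean
integrated intensity calibrates the intensity-to-count conversion; per-cell
integrated intensities divided by that calibration give transcripts per
cell, and bright nuclear foci divided by it give RNAs per nascent site.
Crystal cells are gated on a bimodal marker channel, and the gated
population's nascent tally feeds the k_on/k_off constraint of the burst fit.

Cell segmentation is out of scope (outlines are typically drawn manually in
this protocol); functions accept label masks or pre-integrated tables.
Image coordinates are 0-based (row, column) pixel indices.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_otsu
from skimage.restoration import rolling_ball

from .exceptions import ArgumentError, CalibrationError, GatingError
from .inference import NascentTally

__all__ = [
    "PreprocessSettings",
    "SpotFit",
    "CalibrationResult",
    "preprocess_stack",
    "fit_gaussian_2d",
    "calibrate_single_transcript",
    "transcripts_per_cell",
    "nascent_rna_count",
    "gate_crystal_cells",
    "nascent_tally",
    "integrate_cell_intensities",
    "detect_and_fit_spots",
    "read_stack",
    "write_stack",
]


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PreprocessSettings:
    """Image preprocessing parameters (pixel units).

    Defaults follow the standard smFISH recipe: 1 px Gaussian blur, 50 px
    rolling-ball background subtraction, z-binning by 7 planes.
    """

    blur_radius: float = 1.0
    ball_radius: float = 50.0
    z_bin: int = 7

    def __post_init__(self):
        if self.blur_radius < 0 or self.ball_radius <= 0 or self.z_bin < 1:
            raise ArgumentError("preprocessing radii must be positive")


def preprocess_stack(stack, settings: PreprocessSettings | None = None) -> np.ndarray:
    """Blur -> rolling-ball background subtraction -> z-binning, in that order.

    ``stack`` is (z, y, x) or a single (y, x) plane; output is non-negative
    with the z dimension reduced by the bin factor (remainder planes beyond
    the last full bin are dropped).
    """
    settings = settings or PreprocessSettings()
    stack = np.asarray(stack, dtype=float)
    squeeze = stack.ndim == 2
    if squeeze:
        stack = stack[None]
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ArgumentError("stack must be a 2D plane or a (z, y, x) array")
    if settings.z_bin > stack.shape[0]:
        raise ArgumentError(
            f"z_bin={settings.z_bin} exceeds stack depth {stack.shape[0]}"
        )
    planes = []
    for plane in stack:
        if settings.blur_radius > 0:
            plane = _gaussian_filter(
                plane, sigma=settings.blur_radius, preserve_range=True
            )
        background = rolling_ball(plane, radius=settings.ball_radius)
        planes.append(np.clip(plane - background, 0.0, None))
    out = np.stack(planes)
    n_bins = out.shape[0] // settings.z_bin
    out = out[: n_bins * settings.z_bin]
    out = out.reshape(n_bins, settings.z_bin, *out.shape[1:]).sum(axis=1)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# 2D Gaussian spot fitting
# ---------------------------------------------------------------------------


@dataclass
class SpotFit:
    """Elliptical 2D Gaussian fit of a single diffraction-limited spot.

    ``integrated_intensity`` is the analytic volume 2*pi*A*sigma_x*sigma_y
    above the local background.  ``ok=False`` fits must be skipped downstream.
    """

    center: tuple[float, float]  # (row, col)
    widths: tuple[float, float]  # (sigma_row, sigma_col)
    amplitude: float
    background: float
    residual_norm: float
    ok: bool
    reason: str = ""

    @property
    def integrated_intensity(self) -> float:
        return 2.0 * math.pi * self.amplitude * self.widths[0] * self.widths[1]


def _gauss2d(rr, cc, r0, c0, sr, sc, amp, bg):
    return amp * np.exp(
        -((rr - r0) ** 2 / (2 * sr**2) + (cc - c0) ** 2 / (2 * sc**2))
    ) + bg


def fit_gaussian_2d(patch, initial_guess: dict | None = None) -> SpotFit:
    """Nonlinear least-squares fit of (elliptical Gaussian + constant) to a
    patch.  Returns ok=False (with a reason) instead of raising when the fit
    cannot be trusted: non-convergence, widths pinned at bounds, or a
    non-positive amplitude."""
    patch = np.asarray(patch, dtype=float)
    if patch.ndim != 2 or min(patch.shape) <= 5:
        raise ArgumentError("patch must be 2D and larger than 5x5 pixels")
    if not np.all(np.isfinite(patch)):
        raise ArgumentError("patch contains non-finite values")

    rr, cc = np.indices(patch.shape)
    bg0 = float(np.percentile(patch, 10))
    amp0 = float(patch.max() - bg0)
    if initial_guess:
        r0 = initial_guess.get("row", patch.shape[0] / 2)
        c0 = initial_guess.get("col", patch.shape[1] / 2)
        s0 = initial_guess.get("sigma", 1.5)
        amp0 = initial_guess.get("amplitude", amp0)
        bg0 = initial_guess.get("background", bg0)
    else:
        r0, c0 = np.unravel_index(np.argmax(patch), patch.shape)
        s0 = 1.5
    if amp0 <= 0:
        return SpotFit((r0, c0), (s0, s0), 0.0, bg0, float(np.linalg.norm(patch - bg0)),
                       ok=False, reason="no signal above background")

    max_sigma = max(patch.shape)
    lb = [-1.0, -1.0, 0.2, 0.2, 0.0, -np.inf]
    ub = [patch.shape[0] + 1.0, patch.shape[1] + 1.0, max_sigma, max_sigma,
          np.inf, np.inf]
    x0 = np.clip([r0, c0, s0, s0, amp0, bg0], lb, ub)

    def resid(x):
        return (_gauss2d(rr, cc, *x) - patch).ravel()

    res = least_squares(resid, x0, bounds=(lb, ub), method="trf", xtol=1e-12)
    r0, c0, sr, sc, amp, bg = res.x
    ok = bool(res.status > 0)
    reason = "" if ok else "optimizer did not converge"
    if ok and (sr <= lb[2] * 1.01 or sc <= lb[2] * 1.01
               or sr >= max_sigma * 0.99 or sc >= max_sigma * 0.99):
        ok, reason = False, "width at bound"
    if ok and amp <= 0:
        ok, reason = False, "non-positive amplitude"
    return SpotFit(
        center=(float(r0), float(c0)),
        widths=(float(sr), float(sc)),
        amplitude=float(amp),
        background=float(bg),
        residual_norm=float(np.linalg.norm(res.fun)),
        ok=ok,
        reason=reason,
    )


def detect_and_fit_spots(
    image,
    *,
    patch_radius: int = 5,
    min_distance: int = 4,
    threshold: float | None = None,
) -> list[SpotFit]:
    """Locate local maxima and fit each with a 2D Gaussian.

    A convenience wrapper for calibration fields of isolated single
    transcripts; overlapping emitters should be quantified via their summed
    intensity instead.
    """
    from skimage.feature import peak_local_max

    image = np.asarray(image, dtype=float)
    if threshold is None:
        threshold = image.mean() + 3.0 * image.std()
    peaks = peak_local_max(image, min_distance=min_distance,
                           threshold_abs=threshold, exclude_border=patch_radius)
    fits = []
    for r, c in peaks:
        patch = image[r - patch_radius : r + patch_radius + 1,
                      c - patch_radius : c + patch_radius + 1]
        f = fit_gaussian_2d(patch)
        f.center = (f.center[0] + r - patch_radius, f.center[1] + c - patch_radius)
        fits.append(f)
    return fits


# ---------------------------------------------------------------------------
# calibration and counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationResult:
    """Mean integrated intensity of a single transcript (and its CV)."""

    mean_intensity: float
    cv: float
    n_spots: int

    def __post_init__(self):
        if self.mean_intensity <= 0 or self.n_spots < 1:
            raise CalibrationError("calibration requires >= 1 spot with positive mean")


def calibrate_single_transcript(spot_fits) -> CalibrationResult:
    """Average the integrated intensities of successfully fitted single spots."""
    vals = np.array([s.integrated_intensity for s in spot_fits if s.ok])
    if vals.size == 0:
        raise CalibrationError("no successfully fitted spots to calibrate from")
    mean = float(vals.mean())
    if mean <= 0:
        raise CalibrationError("calibration mean is non-positive")
    cv = float(vals.std(ddof=1) / mean) if vals.size > 1 else 0.0
    return CalibrationResult(mean, cv, int(vals.size))


def transcripts_per_cell(
    total_intensity: float, calibration: CalibrationResult, rounding: str | None = None
) -> float:
    """Total cell intensity divided by the single-transcript mean intensity.

    Returned as a non-negative real by default (the model PMF is evaluated on
    binned reals); ``rounding="nearest"`` gives integer counts.
    """
    if total_intensity < 0:
        raise ArgumentError("total intensity must be non-negative")
    if calibration.mean_intensity <= 0:
        raise CalibrationError("calibration mean must be positive")
    count = total_intensity / calibration.mean_intensity
    return float(round(count)) if rounding == "nearest" else float(count)


def nascent_rna_count(
    nascent_fit: SpotFit, calibration: CalibrationResult
) -> float | None:
    """RNAs at the nascent site: its integrated intensity over the
    single-transcript mean.  Returns None for a failed fit (caller skips)."""
    if not nascent_fit.ok:
        return None
    if calibration.mean_intensity <= 0:
        raise CalibrationError("calibration mean must be positive")
    return float(nascent_fit.integrated_intensity / calibration.mean_intensity)


# ---------------------------------------------------------------------------
# gating and tallying
# ---------------------------------------------------------------------------


def gate_crystal_cells(
    records: pd.DataFrame,
    policy: str = "otsu",
    manual_threshold: float | None = None,
    marker_column: str = "marker_intensity",
) -> pd.DataFrame:
    """Label each cell crystal/other from its marker-channel intensity.

    Default policy thresholds log-intensity with Otsu's method, which
    separates the high-marker (crystal) mode of a bimodal distribution from
    background cells; ``policy="manual"`` applies ``manual_threshold`` on the
    raw intensity instead.  Adds a ``gate_label`` column to a copy.
    """
    if marker_column not in records.columns:
        raise ArgumentError(f"records lack a {marker_column!r} column")
    marker = records[marker_column].to_numpy(dtype=float)
    if np.any(marker < 0):
        raise ArgumentError("marker intensities must be non-negative")
    out = records.copy()
    if policy == "manual":
        if manual_threshold is None:
            raise ArgumentError("manual policy requires manual_threshold")
        thr = float(manual_threshold)
        out["gate_label"] = np.where(marker > thr, "crystal", "other")
        return out
    if policy != "otsu":
        raise ArgumentError(f"unknown gating policy {policy!r}")
    if np.allclose(marker, marker[0]):
        warnings.warn(
            "all marker intensities identical; degenerate gate labels every "
            "cell 'other'",
            stacklevel=2,
        )
        out["gate_label"] = "other"
        return out
    log_marker = np.log10(marker + 1e-12)
    thr = threshold_otsu(log_marker)
    out["gate_label"] = np.where(log_marker > thr, "crystal", "other")
    return out


def nascent_tally(
    records: pd.DataFrame,
    detection_threshold: float,
    nascent_column: str = "nascent_intensity",
) -> NascentTally:
    """Count gated crystal cells with a nascent-site intensity above the
    detection threshold versus those without; feeds the k_on/k_off ratio."""
    if "gate_label" not in records.columns:
        raise GatingError("records are not gated; run gate_crystal_cells first")
    crystal = records[records["gate_label"] == "crystal"]
    if len(crystal) == 0:
        raise GatingError("no crystal cells in the gated population")
    nas = crystal[nascent_column].to_numpy(dtype=float) > detection_threshold
    return NascentTally(int(nas.sum()), int(len(crystal) - nas.sum()))


def read_stack(path) -> np.ndarray:
    """Read a (multi-plane) TIFF stack as a float array."""
    import tifffile

    return tifffile.imread(path).astype(float)


def write_stack(path, stack) -> None:
    """Write a 2D image or (z, y, x) stack as TIFF (float32)."""
    import tifffile

    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def integrate_cell_intensities(
    image, label_mask, threshold: float = 0.0
) -> pd.DataFrame:
    """Sum per-cell intensity above ``threshold`` within each labelled region.

    ``image`` and ``label_mask`` may be 2D or (z, y, x) with a shared mask
    applied to every plane.  Returns columns (cell_id, total_intensity).
    """
    image = np.asarray(image, dtype=float)
    label_mask = np.asarray(label_mask)
    if image.ndim == 3 and label_mask.ndim == 2:
        label_mask = np.broadcast_to(label_mask, image.shape)
    if image.shape != label_mask.shape:
        raise ArgumentError("image and label mask shapes do not match")
    vals = np.where(image > threshold, image, 0.0)
    ids = np.unique(label_mask)
    ids = ids[ids != 0]
    totals = [float(vals[label_mask == i].sum()) for i in ids]
    return pd.DataFrame({"cell_id": ids, "total_intensity": totals})
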