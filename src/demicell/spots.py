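"""Detection and quantification of diffraction-limited fluorescent foci.

Candidates are local maxima above a robust noise threshold; each candidate is
refined by least-squares fitting of a symmetric 2D Gaussian plus constant
background over a square window.  The per-spot intensity statistic is
``I = pi * w^2 * h`` with ``w`` the FWHM and ``h`` the fitted peak height.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize
from shapely.geometry import Point, Polygon
from shapely.strtree import STRtree

from .synthdata import FWHM_TO_SIGMA

__all__ = [
    "DetectionConfig",
    "SpotFit",
    "spot_intensity",
    "detect_candidates",
    "fit_spot",
    "quantify_image",
    "assign_spots_to_cells",
]


@dataclass(frozen=True)
class DetectionConfig:
    threshold_sd: float = 5.0  # candidate threshold, multiples of image noise sd
    window_halfsize: int = 7  # fit window is (2k+1) x (2k+1)
    max_iterations: int = 200
    tolerance: float = 1e-10
    min_separation_px: float = 3.0

    def validate(self) -> None:
        if self.window_halfsize < 2:
            raise ValueError("window_halfsize must be >= 2 px")
        if self.threshold_sd <= 0 or self.min_separation_px <= 0:
            raise ValueError("thresholds must be positive")


@dataclass
class SpotFit:
    """Result of a single Gaussian spot fit (positions in px, 0-based)."""

    x: float
    y: float
    w: float  # FWHM
    h: float  # peak height above background
    b: float  # local background
    fit_residual: float  # RMS of residuals over the window
    converged: bool = True
    clipped: bool = False  # window truncated at an image edge

    @property
    def I(self) -> float:  # noqa: E743 - the field is called I throughout
        return spot_intensity(self.w, self.h)

    @property
    def ok(self) -> bool:
        return self.converged and self.h > 0 and self.w > 0


def spot_intensity(w: float, h: float) -> float:
    """Integrated spot intensity statistic ``I = pi * w**2 * h``."""
    return math.pi * w**2 * h


def estimate_noise_sd(image: np.ndarray) -> float:
    """Robust noise scale: 1.4826 * median absolute deviation."""
    med = np.median(image)
    return 1.4826 * np.median(np.abs(image - med))


def detect_candidates(image: np.ndarray, config: DetectionConfig | None = None) -> list[tuple[int, int]]:
    """Integer-pixel candidate maxima, brightest first.

    A pixel qualifies if it is a strict local maximum of its 3x3
    neighbourhood and exceeds ``median + threshold_sd * noise_sd``.
    Candidates closer than ``min_separation_px`` are merged, keeping the
    brighter one.  Returns ``(x, y)`` = (column, row) tuples.
    """
    config = config or DetectionConfig()
    config.validate()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3 or not np.all(np.isfinite(image)):
        return []
    noise = estimate_noise_sd(image)
    floor = np.median(image) + config.threshold_sd * noise
    if noise == 0 and image.max() <= floor:
        return []
    footprint = np.ones((3, 3), dtype=bool)
    local_max = image == ndimage.maximum_filter(image, footprint=footprint, mode="nearest")
    # strict maximum: exclude plateaus wider than one pixel (constant regions)
    local_max &= image > ndimage.minimum_filter(image, footprint=footprint, mode="nearest")
    local_max &= image > floor
    rows, cols = np.nonzero(local_max)
    if len(rows) == 0:
        return []
    order = np.argsort(image[rows, cols])[::-1]
    rows, cols = rows[order], cols[order]
    kept: list[tuple[int, int]] = []
    min_sep2 = config.min_separation_px**2
    for r, c in zip(rows, cols):
        if all((c - kc) ** 2 + (r - kr) ** 2 >= min_sep2 for kc, kr in kept):
            kept.append((int(c), int(r)))
    return kept


def _gaussian_window(params, cc, rr):
    x0, y0, fwhm, h, b = params
    sigma = max(fwhm, 1e-6) * FWHM_TO_SIGMA
    return h * np.exp(-((cc - x0) ** 2 + (rr - y0) ** 2) / (2 * sigma**2)) + b


def fit_spot(
    image: np.ndarray,
    candidate: tuple[int, int],
    config: DetectionConfig | None = None,
) -> SpotFit:
    """Least-squares fit of a symmetric Gaussian + constant background.

    ``candidate`` is an ``(x, y)`` integer pixel.  Windows that extend past
    the image edge are clipped and flagged.  Quality control: fits whose
    centre leaves the window, whose FWHM exceeds the window size, or with
    non-positive height are flagged ``converged=False`` and should be
    discarded downstream.
    """
    config = config or DetectionConfig()
    config.validate()
    image = np.asarray(image, dtype=float)
    cx, cy = int(candidate[0]), int(candidate[1])
    k = config.window_halfsize
    r0, r1 = max(0, cy - k), min(image.shape[0], cy + k + 1)
    c0, c1 = max(0, cx - k), min(image.shape[1], cx + k + 1)
    clipped = (r1 - r0) != 2 * k + 1 or (c1 - c0) != 2 * k + 1
    window = image[r0:r1, c0:c1]
    rr, cc = np.mgrid[r0:r1, c0:c1]

    b0 = float(np.median(window))
    h0 = float(window.max() - b0)
    if h0 <= 0:
        return SpotFit(float(cx), float(cy), 0.0, 0.0, b0, 0.0, converged=False, clipped=clipped)
    p0 = [float(cx), float(cy), 2.5, h0, b0]
    lo = [c0 - 0.5, r0 - 0.5, 0.3, 0.0, -np.inf]
    hi = [c1 - 0.5, r1 - 0.5, 4.0 * k, np.inf, np.inf]

    def resid(p):
        return (_gaussian_window(p, cc, rr) - window).ravel()

    try:
        sol = optimize.least_squares(
            resid,
            p0,
            bounds=(lo, hi),
            xtol=config.tolerance,
            ftol=config.tolerance,
            gtol=config.tolerance,
            max_nfev=config.max_iterations * len(p0),
        )
    except Exception:
        return SpotFit(float(cx), float(cy), 0.0, 0.0, b0, 0.0, converged=False, clipped=clipped)

    x0, y0, fwhm, h, b = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    ok = (
        sol.status > 0
        and h > 0
        and fwhm <= 2 * k + 1
        and c0 - 0.5 <= x0 <= c1 - 0.5
        and r0 - 0.5 <= y0 <= r1 - 0.5
    )
    return SpotFit(float(x0), float(y0), float(fwhm), float(h), float(b), rms,
                   converged=bool(ok), clipped=clipped)


def quantify_image(image: np.ndarray, config: DetectionConfig | None = None) -> pd.DataFrame:
    """Detect candidates and fit each; return accepted spots as a table.

    Columns: x, y, w, h, b, I, residual, clipped.
    """
    config = config or DetectionConfig()
    rows = []
    for cand in detect_candidates(image, config):
        fit = fit_spot(image, cand, config)
        if fit.ok:
            rows.append(
                dict(x=fit.x, y=fit.y, w=fit.w, h=fit.h, b=fit.b,
                     I=fit.I, residual=fit.fit_residual, clipped=fit.clipped)
            )
    df = pd.DataFrame(rows, columns=["x", "y", "w", "h", "b", "I", "residual", "clipped"])
    # two candidates may have converged onto the same emitter; keep the brighter
    if len(df) > 1:
        df = df.sort_values("I", ascending=False).reset_index(drop=True)
        keep = np.ones(len(df), dtype=bool)
        xs, ys = df["x"].to_numpy(), df["y"].to_numpy()
        for i in range(1, len(df)):
            d2 = (xs[:i][keep[:i]] - xs[i]) ** 2 + (ys[:i][keep[:i]] - ys[i]) ** 2
            if d2.size and d2.min() < config.min_separation_px**2:
                keep[i] = False
        df = df[keep].reset_index(drop=True)
    return df


def assign_spots_to_cells(
    spots: pd.DataFrame,
    contours: dict[int, np.ndarray] | list[np.ndarray],
    x_col: str = "x",
    y_col: str = "y",
) -> tuple[pd.DataFrame, int]:
    """Assign each spot to the contour that contains it.

    ``contours`` maps cell_id -> (N, 2) polygon vertices (or a list, in which
    case cell ids are list positions).  Spots inside no contour are dropped;
    the number dropped is returned.  If contours overlap, the spot goes to
    the polygon whose centroid is nearest, with a warning.
    """
    if isinstance(contours, dict):
        ids = list(contours.keys())
        polys = [Polygon(np.asarray(contours[i])) for i in ids]
    else:
        ids = list(range(len(contours)))
        polys = [Polygon(np.asarray(c)) for c in contours]
    for i, p in zip(ids, polys):
        if not p.is_valid or p.area <= 0:
            raise ValueError(f"contour {i} is not a valid simple polygon")
    tree = STRtree(polys)
    assigned = np.full(len(spots), -1, dtype=int)
    overlap_hits = 0
    pts = [Point(x, y) for x, y in zip(spots[x_col].to_numpy(), spots[y_col].to_numpy())]
    for j, pt in enumerate(pts):
        hits = [k for k in tree.query(pt) if polys[k].covers(pt)]
        if not hits:
            continue
        if len(hits) > 1:
            overlap_hits += 1
            hits.sort(key=lambda k: polys[k].centroid.distance(pt))
        assigned[j] = ids[hits[0]]
    if overlap_hits:
        warnings.warn(f"{overlap_hits} spot(s) fell in overlapping contours; "
                      "assigned to the nearest centroid", stacklevel=2)
    out = spots.copy()
    out["cell_id"] = assigned
    n_discarded = int((assigned == -1).sum())
    return out[out["cell_id"] >= 0].reset_index(drop=True), n_discarded
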