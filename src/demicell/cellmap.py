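"""Projection of spot coordinates into a normalized demi-coccoid model cell.

Each cell contributes a local frame (centroid + principal long axis).  Spot
coordinates are expressed in that frame, the axial offset is folded about
mid-cell, and both coordinates are scaled per cell onto a model half-cell of
800 nm (full width) x 900 nm (half length).  Pooled normalized spots yield
2D location maps, axial intensity profiles, and zone classifications
(membrane / nucleoid / pole / cytoplasm).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon

from ._geometry import distance_to_demi_outline, in_ellipse
from .errors import ParameterError

__all__ = [
    "ModelCell",
    "CellFrame",
    "LocationMap",
    "cell_frame",
    "normalize_spot",
    "normalize_spots",
    "build_location_map",
    "axial_profile",
    "zone_classify",
]

ZONES = ("membrane", "nucleoid", "pole", "cytoplasm")


@dataclass(frozen=True)
class ModelCell:
    """The demi-coccoid projection space (all lengths in nm)."""

    half_length_nm: float = 900.0
    width_nm: float = 800.0
    membrane_band_nm: float = 50.0
    nucleoid_scale: float = 0.55  # central ellipse, fraction of each dimension
    pole_v_fraction: float = 0.6  # v >= fraction * half_length counts as polar

    def __post_init__(self) -> None:
        if self.half_length_nm <= 0 or self.width_nm <= 0:
            raise ParameterError("model dimensions must be positive")
        if self.membrane_band_nm >= self.width_nm / 2:
            raise ParameterError("membrane band must be thinner than half the cell width")


@dataclass(frozen=True)
class CellFrame:
    """Centroid + principal axes of one cell contour."""

    centroid: tuple[float, float]
    axis: tuple[float, float]  # unit vector along the long axis
    length: float  # extent along the long axis
    width: float  # extent across it

    @property
    def angle_deg(self) -> float:
        return float(np.degrees(np.arctan2(self.axis[1], self.axis[0])) % 180.0)


def _polygon_moments(vertices: np.ndarray):
    """Area, centroid and second central area moments of a simple polygon."""
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise ParameterError("degenerate contour: zero area")
    cx = ((x + xn) * cross).sum() / (6 * area)
    cy = ((y + yn) * cross).sum() / (6 * area)
    sxx = ((x**2 + x * xn + xn**2) * cross).sum() / (12 * area) - cx**2
    syy = ((y**2 + y * yn + yn**2) * cross).sum() / (12 * area) - cy**2
    sxy = ((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cross).sum() / (24 * area) - cx * cy
    return abs(area), (cx, cy), np.array([[sxx, sxy], [sxy, syy]])


def cell_frame(contour: np.ndarray | Polygon) -> CellFrame:
    """Principal-axis frame of a cell contour.

    The long axis is the eigenvector of the larger second-area-moment
    eigenvalue; length and width are the extents of the contour vertices
    projected on / across that axis.
    """
    if isinstance(contour, Polygon):
        contour = np.asarray(contour.exterior.coords)[:-1]
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3:
        raise ParameterError("contour must be an (N>=3, 2) polygon")
    _, (cx, cy), cov = _polygon_moments(contour)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    rel = contour - [cx, cy]
    along = rel @ axis
    across = rel @ np.array([-axis[1], axis[0]])
    return CellFrame(
        centroid=(float(cx), float(cy)),
        axis=(float(axis[0]), float(axis[1])),
        length=float(along.max() - along.min()),
        width=float(across.max() - across.min()),
    )


def _clamp_to_model(u: float, v: float, model: ModelCell) -> tuple[float, float]:
    """Pull a point just outside the demi-coccoid outline back onto it."""
    r = model.width_nm / 2.0
    v = min(max(v, 0.0), model.half_length_nm)
    u = min(max(u, -r), r)
    cap_c = model.half_length_nm - r
    if v > cap_c:
        d = np.hypot(u, v - cap_c)
        if d > r:
            u, v = u * r / d, cap_c + (v - cap_c) * r / d
    return float(u), float(v)


def normalize_spot(x: float, y: float, frame: CellFrame, model: ModelCell | None = None) -> tuple[float, float]:
    """Map an image-coordinate spot into model half-cell coordinates (u, v).

    The axial offset is folded about mid-cell and scaled by
    ``half_length / (cell length / 2)``; the signed lateral offset is scaled
    by ``width / cell width``.  Because scaling is per-cell affine, input
    units cancel; output is in nm of the model cell.
    """
    model = model or ModelCell()
    ax = np.array(frame.axis)
    perp = np.array([-ax[1], ax[0]])
    rel = np.array([x - frame.centroid[0], y - frame.centroid[1]])
    axial = float(rel @ ax)
    lateral = float(rel @ perp)
    v = abs(axial) * model.half_length_nm / (frame.length / 2.0)
    u = lateral * model.width_nm / frame.width
    return _clamp_to_model(u, v, model)


def normalize_spots(
    spots: pd.DataFrame,
    contours: dict[int, np.ndarray],
    model: ModelCell | None = None,
    x_col: str = "x",
    y_col: str = "y",
) -> pd.DataFrame:
    """Vector version of :func:`normalize_spot` over a spots table.

    ``spots`` must carry a ``cell_id`` column mapping into ``contours``.
    Returns the input table with added ``u``/``v`` columns (nm).
    """
    model = model or ModelCell()
    frames = {cid: cell_frame(c) for cid, c in contours.items()}
    uv = np.empty((len(spots), 2))
    for j, (cid, x, y) in enumerate(
        zip(spots["cell_id"].to_numpy(), spots[x_col].to_numpy(), spots[y_col].to_numpy())
    ):
        if cid not in frames:
            raise KeyError(f"spot {j} references unknown cell_id {cid}")
        uv[j] = normalize_spot(float(x), float(y), frames[cid], model)
    out = spots.copy()
    out["u"] = uv[:, 0]
    out["v"] = uv[:, 1]
    return out


@dataclass
class LocationMap:
    """2D spot-density map over the model half-cell.

    ``counts`` holds raw per-bin counts (or intensity sums if weighted);
    ``density`` is the optionally smoothed map.  Grid axes: rows index v
    (axial, 0 at mid-cell), columns index u (lateral).
    """

    counts: np.ndarray
    density: np.ndarray
    u_edges: np.ndarray
    v_edges: np.ndarray
    n_spots: int
    n_cells: int
    bin_nm: float
    smoothing_nm: float


def build_location_map(
    spots: pd.DataFrame,
    bin_nm: float = 25.0,
    smoothing_nm: float = 50.0,
    model: ModelCell | None = None,
    weight_by_intensity: bool = False,
) -> LocationMap:
    """Histogram normalized spots on the model half-cell grid.

    Raw counts are retained before smoothing so that the sum over bins always
    equals the number of projected spots.
    """
    model = model or ModelCell()
    if len(spots) < 1:
        raise ParameterError("need at least one spot")
    if bin_nm <= 0 or bin_nm > min(model.width_nm, model.half_length_nm):
        raise ParameterError("bin_nm must be positive and smaller than the model cell")
    r = model.width_nm / 2.0
    u_edges = np.arange(-r, r + bin_nm / 2, bin_nm)
    v_edges = np.arange(0.0, model.half_length_nm + bin_nm / 2, bin_nm)
    if u_edges[-1] < r:
        u_edges = np.append(u_edges, r)
    if v_edges[-1] < model.half_length_nm:
        v_edges = np.append(v_edges, model.half_length_nm)
    w = spots["I"].to_numpy() if weight_by_intensity else None
    counts, _, _ = np.histogram2d(
        spots["v"].to_numpy(), spots["u"].to_numpy(), bins=[v_edges, u_edges], weights=w
    )
    if smoothing_nm > 0:
        density = ndimage.gaussian_filter(counts, sigma=smoothing_nm / bin_nm, mode="constant")
    else:
        density = counts.copy()
    n_cells = int(spots["cell_id"].nunique()) if "cell_id" in spots else 0
    return LocationMap(counts, density, u_edges, v_edges, len(spots), n_cells, bin_nm, smoothing_nm)


def axial_profile(location_map: LocationMap, strip_halfwidth_nm: float = 100.0) -> pd.DataFrame:
    """Density summed over a central axial strip, peak-normalized.

    Returns columns ``v_nm`` (bin centres) and ``profile`` (max = 1).
    """
    u_centers = 0.5 * (location_map.u_edges[:-1] + location_map.u_edges[1:])
    strip = np.abs(u_centers) <= strip_halfwidth_nm
    if not strip.any():
        warnings.warn("axial strip contains no bins; returning a zero profile", stacklevel=2)
        prof = np.zeros(location_map.density.shape[0])
    else:
        prof = location_map.density[:, strip].sum(axis=1)
    peak = prof.max()
    if peak > 0:
        prof = prof / peak
    else:
        warnings.warn("axial strip is empty of signal", stacklevel=2)
    v_centers = 0.5 * (location_map.v_edges[:-1] + location_map.v_edges[1:])
    return pd.DataFrame({"v_nm": v_centers, "profile": prof})


def zone_classify(u: float, v: float, model: ModelCell | None = None) -> str:
    """Classify a normalized spot into a model-cell zone.

    Precedence: membrane > nucleoid > pole > cytoplasm.  The membrane zone is
    a band of ``membrane_band_nm`` inside the outline; the nucleoid is a
    central ellipse scaled by ``nucleoid_scale``.
    """
    model = model or ModelCell()
    dist = float(distance_to_demi_outline(u, v, model.half_length_nm, model.width_nm))
    if dist <= model.membrane_band_nm:
        return "membrane"
    if bool(
        in_ellipse(
            u,
            v,
            model.nucleoid_scale * model.width_nm / 2.0,
            model.nucleoid_scale * model.half_length_nm,
        )
    ):
        return "nucleoid"
    if v >= model.pole_v_fraction * model.half_length_nm:
        return "pole"
    return "cytoplasm"


def zone_fractions(spots: pd.DataFrame, model: ModelCell | None = None) -> pd.Series:
    """Fraction of spots per zone (index ordered as membrane/nucleoid/pole/cytoplasm)."""
    model = model or ModelCell()
    zones = [zone_classify(u, v, model) for u, v in zip(spots["u"], spots["v"])]
    frac = pd.Series(zones).value_counts(normalize=True)
    return frac.reindex(ZONES, fill_value=0.0)
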