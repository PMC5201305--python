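"""Seeded synthetic microscopy scenes and transcription-chase datasets.

Scenes contain coccoid (capsule-shaped) cells with diffraction-limited spots
rendered as isotropic 2D Gaussians plus optional Poisson shot noise and
Gaussian read noise.  Four localization patterns are supported:

``membrane``
    spots on an inset ring just inside the cell outline;
``cytoplasmic_nucleoid_excluded``
    spots in the cytoplasm outside a central nucleoid ellipse;
``polar_cluster``
    one bright, compact spot near a pole carrying a configurable fraction of
    the cell's total intensity, the remainder as dim cytoplasmic spots;
``uniform``
    spots anywhere inside the cell.

Chase datasets emulate per-cell fluorescence after transcription shut-off:
``N(t) = N0 * exp(-lambda * t)`` with multiplicative cell-to-cell noise,
optional additive background, and optional subpopulation structure
(e.g. cluster-positive vs cluster-negative cells with distinct half-lives).

Every generator is a pure function of its spec, whose ``seed`` fully
determines the output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._geometry import capsule_polygon, in_capsule, in_ellipse
from .errors import ParameterError, SceneSizingError

__all__ = [
    "SceneSpec",
    "GroundTruth",
    "Subpopulation",
    "ChaseSpec",
    "generate_scene",
    "generate_chase",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

PATTERNS = ("membrane", "cytoplasmic_nucleoid_excluded", "polar_cluster", "uniform")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.  All lengths in nm unless noted."""

    n_cells: int = 25
    cell_width_nm: float = 800.0
    cell_length_nm: float = 1800.0
    pixel_size_nm: float = 65.0
    psf_sigma_nm: float = 100.0
    pattern: str = "uniform"
    spots_per_cell: float = 4.0  # Poisson mean (polar_cluster: dim spots only)
    spot_height: float = 200.0
    spot_height_cv: float = 0.0
    cluster_fraction_of_signal: float = 0.6
    cluster_v_fraction: float = 0.8  # axial placement of the cluster spot
    membrane_band_nm: float = 50.0
    nucleoid_scale: float = 0.55
    background: float = 10.0
    poisson_noise: bool = True
    read_noise_sd: float = 2.0
    margin_px: int = 6
    seed: int = 0

    def validate(self) -> None:
        for name in ("cell_width_nm", "cell_length_nm", "pixel_size_nm", "psf_sigma_nm"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.cell_length_nm < self.cell_width_nm:
            raise ParameterError("cell_length_nm must be >= cell_width_nm")
        if self.pattern not in PATTERNS:
            raise ParameterError(f"unknown pattern {self.pattern!r}; expected one of {PATTERNS}")
        if not 0.0 <= self.cluster_fraction_of_signal <= 1.0:
            raise ParameterError("cluster_fraction_of_signal must lie in [0, 1]")
        if self.n_cells < 0 or self.spots_per_cell < 0:
            raise ParameterError("counts must be non-negative")


@dataclass
class GroundTruth:
    """Pre-noise truth for a generated scene.

    ``cells`` columns: cell_id, cx_px, cy_px, angle_deg, length_px, width_px,
    contour_wkt, has_cluster, total_intensity.
    ``spots`` columns: cell_id, x_px, y_px, fwhm_px, height, intensity,
    is_cluster.  Intensities use the pi * FWHM^2 * height convention.
    """

    cells: pd.DataFrame
    spots: pd.DataFrame
    contours: list[np.ndarray] = field(default_factory=list)  # (N,2) px, per cell


def _contour_wkt(vertices: np.ndarray) -> str:
    pts = ", ".join(f"{x:.4f} {y:.4f}" for x, y in vertices)
    first = f"{vertices[0, 0]:.4f} {vertices[0, 1]:.4f}"
    return f"POLYGON (({pts}, {first}))"


def _sample_in_capsule(rng, n, length, width):
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(16, 2 * (n - got))
        x = rng.uniform(-length / 2, length / 2, m)
        y = rng.uniform(-width / 2, width / 2, m)
        keep = in_capsule(x, y, length, width)
        take = min(n - got, int(keep.sum()))
        out[got : got + take] = np.column_stack([x[keep], y[keep]])[:take]
        got += take
    return out


def _sample_pattern(rng, n, spec: SceneSpec, length, width):
    """Local-coordinate spot positions for the dim/regular spots of one cell."""
    if n == 0:
        return np.empty((0, 2))
    if spec.pattern == "uniform":
        return _sample_in_capsule(rng, n, length, width)
    if spec.pattern == "membrane":
        # uniform along the perimeter of an inset capsule outline
        r = width / 2.0 - spec.membrane_band_nm / 2.0
        half_body = length / 2.0 - width / 2.0
        straight = 2 * half_body
        arc = np.pi * r
        per = 2 * straight + 2 * arc
        s = rng.uniform(0, per, n)
        pts = np.empty((n, 2))
        for i, si in enumerate(s):
            if si < straight:  # top wall
                pts[i] = (si - half_body, r)
            elif si < straight + arc:  # right cap
                a = (si - straight) / arc * np.pi - np.pi / 2
                pts[i] = (half_body + r * np.cos(a), r * np.sin(a))
            elif si < 2 * straight + arc:  # bottom wall
                pts[i] = (si - (straight + arc) - half_body, -r)
            else:  # left cap
                a = (si - 2 * straight - arc) / arc * np.pi + np.pi / 2
                pts[i] = (-half_body + r * np.cos(a), r * np.sin(a))
        return pts
    if spec.pattern == "cytoplasmic_nucleoid_excluded":
        semi_x = spec.nucleoid_scale * length / 2.0
        semi_y = spec.nucleoid_scale * width / 2.0
        out = np.empty((n, 2))
        got = 0
        while got < n:
            cand = _sample_in_capsule(rng, 2 * (n - got) + 8, length, width)
            keep = ~in_ellipse(cand[:, 0], cand[:, 1], semi_x, semi_y)
            take = min(n - got, int(keep.sum()))
            out[got : got + take] = cand[keep][:take]
            got += take
        return out
    if spec.pattern == "polar_cluster":
        # dim companion spots are cytoplasmic
        return _sample_in_capsule(rng, n, length, width)
    raise ParameterError(f"unknown pattern {spec.pattern!r}")


def _render_gaussian(image: np.ndarray, x: float, y: float, fwhm: float, h: float) -> None:
    """Add an isotropic Gaussian (pixel centres at integer coordinates)."""
    sigma = fwhm * FWHM_TO_SIGMA
    half = int(math.ceil(5 * sigma)) + 1
    r0 = max(0, int(y) - half)
    r1 = min(image.shape[0], int(y) + half + 1)
    c0 = max(0, int(x) - half)
    c1 = min(image.shape[1], int(x) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None]
    cc = np.arange(c0, c1)[None, :]
    image[r0:r1, c0:c1] += h * np.exp(-((cc - x) ** 2 + (rr - y) ** 2) / (2 * sigma**2))


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene and return ``(image, truth)``.

    The image is float64 (pre-quantization); use :func:`demicell.io.write_image`
    for 16-bit TIFF export.  Cells are laid out on a square grid with random
    in-plane orientation; the canvas is sized so cells never overlap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size_nm
    length_px = spec.cell_length_nm / px
    width_px = spec.cell_width_nm / px
    fwhm_px = spec.psf_sigma_nm / px / FWHM_TO_SIGMA

    n_side = max(1, int(math.ceil(math.sqrt(max(spec.n_cells, 1)))))
    pitch = length_px + 2 * spec.margin_px
    size = int(math.ceil(n_side * pitch))
    if size > 8192:
        raise SceneSizingError(
            f"canvas of {size} px exceeds the 8192 px limit; reduce n_cells or pixel pitch"
        )
    image = np.zeros((size, size))

    cell_rows, spot_rows, contours = [], [], []
    for i in range(spec.n_cells):
        gx = (i % n_side + 0.5) * pitch
        gy = (i // n_side + 0.5) * pitch
        angle = rng.uniform(0, 180.0)
        theta = math.radians(angle)
        rot = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])

        n_dim = int(rng.poisson(spec.spots_per_cell))
        # inset the sampling capsule by the polygon chord sagitta so every
        # true spot also lies inside the discretized contour
        sag = (spec.cell_width_nm / 2.0) * (1.0 - math.cos(0.5 * math.pi / 24))
        local = _sample_pattern(
            rng, n_dim, spec, spec.cell_length_nm - 2 * sag, spec.cell_width_nm - 2 * sag
        )
        heights = np.full(n_dim, float(spec.spot_height))
        if spec.spot_height_cv > 0 and n_dim:
            heights *= np.clip(rng.normal(1.0, spec.spot_height_cv, n_dim), 0.05, None)
        is_cluster = np.zeros(n_dim, dtype=bool)

        has_cluster = spec.pattern == "polar_cluster"
        if has_cluster:
            f = spec.cluster_fraction_of_signal
            dim_sum = float(heights.sum())
            if f >= 1.0 or dim_sum == 0.0:
                h_cl = spec.spot_height * max(1.0, spec.spots_per_cell)
                heights = np.empty(0)
                local = np.empty((0, 2))
                is_cluster = np.zeros(0, dtype=bool)
                n_dim = 0
            else:
                h_cl = f / (1.0 - f) * dim_sum
            side = rng.choice([-1.0, 1.0])
            v_ax = side * rng.uniform(spec.cluster_v_fraction, 0.95) * spec.cell_length_nm / 2.0
            local = np.vstack([local, [v_ax, 0.0]])
            heights = np.append(heights, h_cl)
            is_cluster = np.append(is_cluster, True)

        # nm local -> px global
        pos = (rot @ (local.T / px)).T + [gx, gy] if len(local) else np.empty((0, 2))
        contour = (rot @ capsule_polygon(length_px, width_px).T).T + [gx, gy]
        contours.append(contour)

        total = float(np.pi * fwhm_px**2 * heights.sum()) if len(heights) else 0.0
        cell_rows.append(
            dict(
                cell_id=i,
                cx_px=gx,
                cy_px=gy,
                angle_deg=angle,
                length_px=length_px,
                width_px=width_px,
                contour_wkt=_contour_wkt(contour),
                has_cluster=has_cluster,
                total_intensity=total,
            )
        )
        for (sx, sy), h, cl in zip(pos, heights, is_cluster):
            spot_rows.append(
                dict(
                    cell_id=i,
                    x_px=sx,
                    y_px=sy,
                    fwhm_px=fwhm_px,
                    height=float(h),
                    intensity=float(np.pi * fwhm_px**2 * h),
                    is_cluster=bool(cl),
                )
            )
            _render_gaussian(image, sx, sy, fwhm_px, h)

    if spec.poisson_noise:
        image = rng.poisson(np.clip(image + spec.background, 0, None)).astype(float)
    else:
        image = image + spec.background
    if spec.read_noise_sd > 0:
        image = image + rng.normal(0.0, spec.read_noise_sd, image.shape)

    spots = pd.DataFrame(
        spot_rows,
        columns=["cell_id", "x_px", "y_px", "fwhm_px", "height", "intensity", "is_cluster"],
    )
    cells = pd.DataFrame(cell_rows)
    return image, GroundTruth(cells=cells, spots=spots, contours=contours)


# ---------------------------------------------------------------------------
# chase datasets


@dataclass(frozen=True)
class Subpopulation:
    label: str
    weight: float
    half_life_min: float
    n0_mean: float = 1000.0
    n0_cv: float = 0.0
    cluster: bool = False


@dataclass(frozen=True)
class ChaseSpec:
    """Design of a synthetic transcription shut-off (chase) experiment."""

    time_points_min: tuple[float, ...] = (0, 1, 2, 4, 8, 16, 32, 64)
    n_cells_per_timepoint: int = 500
    subpopulations: tuple[Subpopulation, ...] = (Subpopulation("all", 1.0, 10.0),)
    cell_noise_cv: float = 0.3
    background_level: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        t = np.asarray(self.time_points_min, dtype=float)
        if len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ParameterError("time points must strictly increase from 0")
        w = sum(s.weight for s in self.subpopulations)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ParameterError(f"subpopulation weights must sum to 1 (got {w})")
        for s in self.subpopulations:
            if s.half_life_min <= 0:
                raise ParameterError(f"half_life_min must be positive ({s.label})")
            if s.n0_mean <= 0 or s.weight < 0:
                raise ParameterError(f"invalid subpopulation {s.label}")
        if self.n_cells_per_timepoint <= 0:
            raise ParameterError("n_cells_per_timepoint must be positive")


def generate_chase(spec: ChaseSpec) -> pd.DataFrame:
    """Simulate per-cell fluorescence for each chase time point.

    Cells are independent across time points (the assay fixes a fresh field
    of cells per time point).  Returns columns: cell_id, time_min,
    fluorescence, subpopulation, cluster_flag.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = [s.label for s in spec.subpopulations]
    weights = np.array([s.weight for s in spec.subpopulations])
    by_label = {s.label: s for s in spec.subpopulations}

    frames = []
    cell_id = 0
    for t in spec.time_points_min:
        n = spec.n_cells_per_timepoint
        idx = rng.choice(len(labels), size=n, p=weights)
        lam = np.array([math.log(2) / by_label[labels[k]].half_life_min for k in idx])
        n0 = np.array([by_label[labels[k]].n0_mean for k in idx])
        cvs = np.array([by_label[labels[k]].n0_cv for k in idx])
        if np.any(cvs > 0):
            n0 = n0 * np.clip(1.0 + rng.standard_normal(n) * cvs, 0.01, None)
        vals = n0 * np.exp(-lam * t)
        if spec.cell_noise_cv > 0:
            vals = vals * np.clip(rng.normal(1.0, spec.cell_noise_cv, n), 0.01, None)
        vals = vals + spec.background_level
        frames.append(
            pd.DataFrame(
                dict(
                    cell_id=np.arange(cell_id, cell_id + n),
                    time_min=float(t),
                    fluorescence=vals,
                    subpopulation=[labels[k] for k in idx],
                    cluster_flag=[by_label[labels[k]].cluster for k in idx],
                )
            )
        )
        cell_id += n
    return pd.concat(frames, ignore_index=True)


def scene_spec_with(base: SceneSpec, **kw) -> SceneSpec:
    """Convenience wrapper around :func:`dataclasses.replace`."""
    return replace(base, **kw)
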