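"""Polar-cluster classification and population statistics.

A cell carries a polar mRNA cluster if one of its spots simultaneously
(i) holds at least a configurable fraction of the cell's total intensity,
(ii) is compact (FWHM below a cutoff), and (iii) sits in the polar region of
the model half-cell.  On top of the per-cell call, this module provides
cluster-fraction-vs-expression-level curves, gamma fits to expression
distributions, FWHM-vs-reciprocal-intensity heat maps, focus-to-cluster
distance statistics, and the axial spread ratio of a fluorescence profile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cellmap import ModelCell
from .errors import DegenerateDataError, ParameterError

__all__ = [
    "ClusterConfig",
    "ExpressionFit",
    "DistanceStats",
    "classify_cell",
    "classify_cells",
    "cluster_fraction_by_level",
    "fit_expression_gamma",
    "fwhm_intensity_heatmap",
    "foci_distances",
    "spread_ratio",
]


@dataclass(frozen=True)
class ClusterConfig:
    min_intensity_fraction: float = 0.5  # one spot holds >= this share of the cell total
    max_fwhm_px: float = 5.0  # compactness cutoff
    polar_v_fraction: float = 0.6  # v >= fraction * half_length
    level_threshold_au: float = 10.0  # expression cutoff for windowed analyses

    def validate(self) -> None:
        if not 0 < self.min_intensity_fraction <= 1:
            raise ParameterError("min_intensity_fraction must lie in (0, 1]")
        if not 0 < self.polar_v_fraction <= 1:
            raise ParameterError("polar_v_fraction must lie in (0, 1]")
        if self.max_fwhm_px <= 0 or self.level_threshold_au <= 0:
            raise ParameterError("cutoffs must be positive")


def classify_cell(
    spots: pd.DataFrame,
    total_intensity: float,
    config: ClusterConfig | None = None,
    model: ModelCell | None = None,
) -> tuple[bool, pd.Series | None]:
    """Return ``(has_cluster, qualifying spot or None)`` for one cell.

    ``spots`` needs columns ``I``, ``v`` and ``w``.  Of several qualifying
    spots the one of largest intensity is returned.  Zero total intensity
    yields a negative call.
    """
    config = config or ClusterConfig()
    config.validate()
    model = model or ModelCell()
    if total_intensity <= 0 or len(spots) == 0:
        return False, None
    v_min = config.polar_v_fraction * model.half_length_nm
    mask = (
        (spots["I"] >= config.min_intensity_fraction * total_intensity)
        & (spots["w"] <= config.max_fwhm_px)
        & (spots["v"] >= v_min)
    )
    if not mask.any():
        return False, None
    hit = spots.loc[mask, "I"].idxmax()
    return True, spots.loc[hit]


def classify_cells(
    spots: pd.DataFrame,
    cell_totals: pd.Series,
    config: ClusterConfig | None = None,
    model: ModelCell | None = None,
) -> pd.DataFrame:
    """Per-cell classification table (cell_id, level, has_cluster)."""
    config = config or ClusterConfig()
    rows = []
    grouped = dict(tuple(spots.groupby("cell_id"))) if len(spots) else {}
    for cid, total in cell_totals.items():
        sub = grouped.get(cid, spots.iloc[0:0])
        flag, _ = classify_cell(sub, float(total), config, model)
        rows.append(dict(cell_id=cid, level=float(total), has_cluster=flag))
    return pd.DataFrame(rows)


def cluster_fraction_by_level(
    cells: pd.DataFrame,
    n_bins: int = 8,
    config: ClusterConfig | None = None,
    bin_edges: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binomial cluster fraction per expression-level bin.

    ``cells`` needs columns ``level`` and ``has_cluster``.  Bins default to
    equal-count (quantile) bins; pass explicit ``bin_edges`` to override.
    SE is sqrt(p(1-p)/n); single-cell bins get SE 0 with a warning.
    """
    if len(cells) == 0:
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "n", "fraction", "se"])
    levels = cells["level"].to_numpy(dtype=float)
    if bin_edges is None:
        qs = np.linspace(0, 1, n_bins + 1)
        bin_edges = np.unique(np.quantile(levels, qs))
        if len(bin_edges) < 2:
            bin_edges = np.array([levels.min(), levels.max() + 1e-9])
    idx = np.clip(np.digitize(levels, bin_edges[1:-1]), 0, len(bin_edges) - 2)
    rows = []
    for b in range(len(bin_edges) - 1):
        sel = idx == b
        n = int(sel.sum())
        if n == 0:
            continue  # empty bins are reported as missing
        p = float(cells.loc[sel, "has_cluster"].mean())
        se = float(np.sqrt(p * (1 - p) / n))
        if n == 1:
            warnings.warn(f"bin [{bin_edges[b]:.3g}, {bin_edges[b+1]:.3g}) holds a single cell; "
                          "its SE is not meaningful", stacklevel=2)
        rows.append(dict(bin_lo=bin_edges[b], bin_hi=bin_edges[b + 1], n=n, fraction=p, se=se))
    return pd.DataFrame(rows)


@dataclass
class ExpressionFit:
    shape: float
    scale: float
    loglik: float
    n_cells: int
    n_zero_excluded: int = 0


def fit_expression_gamma(levels: np.ndarray, min_n: int = 10) -> ExpressionFit:
    """Maximum-likelihood gamma fit to per-cell expression levels.

    Exact zeros (below the detection floor) are excluded and counted; the fit
    requires at least ``min_n`` positive values and refuses all-equal data.
    """
    levels = np.asarray(levels, dtype=float)
    if np.any(levels < 0):
        raise ParameterError("expression levels must be non-negative")
    positive = levels[levels > 0]
    n_zero = int(len(levels) - len(positive))
    if len(positive) < min_n:
        raise ParameterError(f"need at least {min_n} positive levels (got {len(positive)})")
    if np.ptp(positive) == 0:
        raise DegenerateDataError("all expression levels identical; gamma fit undefined")
    shape, _, scale = stats.gamma.fit(positive, floc=0)
    loglik = float(np.sum(stats.gamma.logpdf(positive, shape, scale=scale)))
    return ExpressionFit(float(shape), float(scale), loglik, len(positive), n_zero)


def fwhm_intensity_heatmap(
    spots: pd.DataFrame,
    fwhm_range: tuple[float, float] = (0.0, 10.0),
    inv_intensity_range: tuple[float, float] | None = None,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D histogram of (FWHM, 1/I) pairs; returns (H, fwhm_edges, inv_edges)."""
    w = spots["w"].to_numpy(dtype=float)
    intens = spots["I"].to_numpy(dtype=float)
    bad = intens <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} spot(s) with non-positive intensity",
                      stacklevel=2)
    w, intens = w[~bad], intens[~bad]
    inv = 1.0 / intens
    if inv_intensity_range is None:
        inv_intensity_range = (0.0, float(inv.max()) if len(inv) else 1.0)
    H, fe, ie = np.histogram2d(w, inv, bins=bins, range=[fwhm_range, inv_intensity_range])
    return H, fe, ie


@dataclass
class DistanceStats:
    distances: np.ndarray = field(repr=False)
    mean: float = float("nan")
    sd: float = float("nan")
    n_cells_skipped: int = 0

    @property
    def n(self) -> int:
        return len(self.distances)


def foci_distances(protein_foci: pd.DataFrame, cluster_spots: pd.DataFrame) -> DistanceStats:
    """Nearest protein-focus-to-cluster distance per cell, with a normal fit.

    Both tables need ``cell_id``, ``u``, ``v`` (nm).  Cells lacking either
    focus type are skipped and counted.
    """
    by_cell_p = dict(tuple(protein_foci.groupby("cell_id")))
    by_cell_c = dict(tuple(cluster_spots.groupby("cell_id")))
    dists = []
    skipped = 0
    for cid in sorted(set(by_cell_p) | set(by_cell_c)):
        if cid not in by_cell_p or cid not in by_cell_c:
            skipped += 1
            continue
        p = by_cell_p[cid][["u", "v"]].to_numpy(dtype=float)
        c = by_cell_c[cid][["u", "v"]].to_numpy(dtype=float)
        d = np.sqrt(((p[:, None, :] - c[None, :, :]) ** 2).sum(axis=2))
        dists.append(float(d.min()))
    arr = np.asarray(dists)
    if len(arr) == 0:
        return DistanceStats(arr, n_cells_skipped=skipped)
    mu, sd = stats.norm.fit(arr)
    return DistanceStats(arr, float(mu), float(sd), skipped)


def spread_ratio(
    profile: np.ndarray,
    cell_length: float | None = None,
    threshold_fraction: float = 0.25,
) -> float:
    """Fraction of the cell length covered by signal around the profile peak.

    The spread is the contiguous run of samples around the maximum whose
    value is at least ``threshold_fraction * max``; the ratio is spread
    length over total profile length (the profile is assumed to sample the
    full cell length uniformly, so ``cell_length`` cancels and is accepted
    only for interface symmetry).
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) == 0 or profile.max() <= 0:
        raise DegenerateDataError("flat or empty profile; spread undefined")
    if not 0 < threshold_fraction <= 1:
        raise ParameterError("threshold_fraction must lie in (0, 1]")
    peak = int(np.argmax(profile))
    cut = threshold_fraction * profile.max()
    lo = peak
    while lo > 0 and profile[lo - 1] >= cut:
        lo -= 1
    hi = peak
    while hi < len(profile) - 1 and profile[hi + 1] >= cut:
        hi += 1
    return float((hi - lo + 1) / len(profile))
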