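"""Capsule / ellipse primitives shared by the scene generator and the projection code.

A cell is modelled as a capsule: a rectangle of length ``length - width``
capped by two semicircles of radius ``width / 2``.  Local coordinates put the
origin at the capsule centre with the long axis along +x.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "capsule_polygon",
    "in_capsule",
    "in_ellipse",
    "capsule_area",
    "distance_to_demi_outline",
]


def capsule_polygon(length: float, width: float, n_arc: int = 25) -> np.ndarray:
    """Vertices (N, 2) of a capsule outline in local coordinates.

    Vertices run counter-clockwise; the polygon is closed implicitly
    (last vertex != first).
    """
    if length <= 0 or width <= 0:
        raise ValueError("capsule length and width must be positive")
    if length < width:
        raise ValueError("capsule length must be >= width")
    r = width / 2.0
    half_body = length / 2.0 - r
    # right cap: angles -90 -> +90, left cap: +90 -> 270
    ang_right = np.linspace(-np.pi / 2, np.pi / 2, n_arc)
    ang_left = np.linspace(np.pi / 2, 3 * np.pi / 2, n_arc)
    right = np.column_stack([half_body + r * np.cos(ang_right), r * np.sin(ang_right)])
    left = np.column_stack([-half_body + r * np.cos(ang_left), r * np.sin(ang_left)])
    return np.vstack([right, left])


def in_capsule(x, y, length: float, width: float) -> np.ndarray:
    """Boolean mask: do local points lie inside the capsule?"""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = width / 2.0
    half_body = length / 2.0 - r
    ax = np.abs(x)
    in_body = (ax <= half_body) & (np.abs(y) <= r)
    dx = ax - half_body
    in_cap = (dx > 0) & (dx**2 + y**2 <= r**2)
    return in_body | in_cap


def in_ellipse(x, y, semi_x: float, semi_y: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return (x / semi_x) ** 2 + (y / semi_y) ** 2 <= 1.0


def capsule_area(length: float, width: float) -> float:
    r = width / 2.0
    return (length - width) * width + np.pi * r**2


def distance_to_demi_outline(u, v, half_length: float, width: float) -> np.ndarray:
    """Distance from points in a demi-capsule to its curved outline.

    The demi-capsule spans ``v`` in [0, half_length], ``|u| <= width/2``; its
    outline is the two lateral walls plus the pole arc.  The ``v = 0`` cut is
    the mid-cell plane, not membrane, so it does not count as outline.
    Negative values mean the point is outside.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    r = width / 2.0
    cap_c = half_length - r  # v-coordinate of the pole-cap centre
    lateral = r - np.abs(u)
    radial = r - np.sqrt(u**2 + np.clip(v - cap_c, 0.0, None) ** 2)
    return np.where(v <= cap_c, lateral, radial)
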