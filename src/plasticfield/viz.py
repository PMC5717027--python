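"""Figures: landscape evolution maps and the polygon view of phrase vectors.

An m-dimensional positive vector is drawn as a planar polygon: vertex j
sits on the half-axis at angle 2*pi*j/m at a radius equal to component j
(for m = 4 the half-axes are a right-angle cross).  A set of phrase minima
is then shown as polygons stacked at altitudes equal to their landscape
depths, deepest drawn on top.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .errors import InvalidInputError

__all__ = [
    "PolygonRepr",
    "polygon_coords",
    "plot_landscape_map",
    "plot_polygon_stack",
    "plot_minima_polygons",
]


@dataclass
class PolygonRepr:
    """Planar polygon for an m-dimensional positive vector; ``vertices``
    has shape (m, 2), vertex j on the half-axis at angle 2*pi*j/m."""

    vertices: np.ndarray
    altitude: float = 0.0


def polygon_coords(v, altitude: float = 0.0) -> PolygonRepr:
    """Polygon representation of a positive vector.

    Vertex j = (v_j cos(2 pi j / m), v_j sin(2 pi j / m)).  Raises for any
    non-positive component (the radius must be a positive length).
    """
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if v.ndim != 1 or v.size < 1:
        raise InvalidInputError("expected a 1-D vector")
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise InvalidInputError("all components must be positive and finite")
    m = v.size
    ang = 2.0 * np.pi * np.arange(m) / m
    verts = np.stack([v * np.cos(ang), v * np.sin(ang)], axis=-1)
    return PolygonRepr(vertices=verts, altitude=float(altitude))


def plot_landscape_map(snapshots, axis, stimuli=None, ax=None, cmap="viridis"):
    """Time-color map of a 1-D landscape's evolution, with the stimulus
    stream overplotted as dots (the classic learning picture).

    ``snapshots`` is a list of (time, values) pairs for a common 1-D grid
    ``axis``.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    times = np.asarray([t for t, _ in snapshots])
    V = np.stack([v for _, v in snapshots], axis=0)
    pc = ax.pcolormesh(axis, times, V, shading="nearest", cmap=cmap)
    ax.figure.colorbar(pc, ax=ax, label="V(x, t)")
    if stimuli is not None:
        ax.plot(stimuli.values[:, 0], stimuli.times, ".", ms=2, color="white", alpha=0.6)
    ax.set_xlabel("x (stimulus units)")
    ax.set_ylabel("t")
    return ax.figure


def plot_polygon_stack(vectors, times, ax=None, color="tab:blue"):
    """A melody as a sequence of phrase polygons placed along the time axis."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    vectors = np.atleast_2d(vectors)
    scale = np.max(vectors)
    for t, v in zip(times, vectors):
        poly = polygon_coords(v).vertices / scale
        closed = np.vstack([poly, poly[:1]])
        ax.plot(t + closed[:, 0], closed[:, 1], "-", lw=0.8, color=color, alpha=0.7)
    ax.set_xlabel("t (s)")
    ax.set_yticks([])
    return ax.figure


def plot_minima_polygons(minima, ax=None, cmap="viridis"):
    """Phrase minima as polygons placed at altitude = depth, deepest drawn
    on top (i.e. last)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    order = np.argsort(-minima.depths)  # shallow first, deepest drawn last
    scale = float(np.max(minima.locations))
    span = float(np.ptp(minima.depths)) or 1.0
    cm = plt.get_cmap(cmap)
    for rank, i in enumerate(order):
        poly = polygon_coords(minima.locations[i], altitude=minima.depths[i]).vertices / scale
        closed = np.vstack([poly, poly[:1]])
        ax.plot(
            closed[:, 0],
            minima.depths[i] + 0.4 * span * closed[:, 1],
            "-",
            lw=1.5,
            color=cm(rank / max(len(order) - 1, 1)),
        )
    ax.set_xlabel("polygon x (components / max component)")
    ax.set_ylabel("depth V")
    return ax.figure
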