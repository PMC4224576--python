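"""Leaflet surfaces and bilayer thickness from phosphate z-coordinates.

The z of each leaflet's phosphate markers is a sparse sampling of a smooth
surface; cubic (Clough-Tocher) scattered-data interpolation on the pixel
grid turns it into a dense height field.  Periodicity is respected by tiling
markers near the box edges with their periodic images before fitting and
evaluating only inside the box.  Thickness is the upper minus the lower
surface, measured phosphate-to-phosphate; cholesterol hydroxyl beads are
excluded from surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import (CloughTocher2DInterpolator, LinearNDInterpolator,
                               NearestNDInterpolator)
from scipy.spatial import QhullError

from .density import PixelGrid
from .phases import MATCH_BOTH_LD, MATCH_BOTH_LO, MATCH_MISMATCH, MatchMap

logger = logging.getLogger(__name__)

MATCH_CATEGORY_NAMES = {
    MATCH_BOTH_LO: "both_lo",
    MATCH_BOTH_LD: "both_ld",
    MATCH_MISMATCH: "mismatch",
}


@dataclass
class SurfaceField:
    """Interpolated leaflet height z (Å) at every pixel centre."""

    grid: PixelGrid
    values: np.ndarray
    leaflet: Optional[str] = None
    interpolation: str = "cubic"


@dataclass
class ThicknessField:
    """Upper minus lower leaflet surface (Å) per pixel."""

    grid: PixelGrid
    values: np.ndarray
    n_unphysical: int = 0  # pixels with thickness <= 0

    @property
    def mean(self) -> float:
        return float(self.values.mean())


def _tile_periodic(points: np.ndarray, z: np.ndarray, box: tuple[float, float],
                   margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Add periodic images of points within ``margin`` of any box edge."""
    lx, ly = box
    tiles_p = [points]
    tiles_z = [z]
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            if sx == 0 and sy == 0:
                continue
            shifted = points + np.array([sx * lx, sy * ly])
            keep = ((shifted[:, 0] > -margin) & (shifted[:, 0] < lx + margin) &
                    (shifted[:, 1] > -margin) & (shifted[:, 1] < ly + margin))
            if np.any(keep):
                tiles_p.append(shifted[keep])
                tiles_z.append(z[keep])
    return np.vstack(tiles_p), np.concatenate(tiles_z)


def _merge_close_markers(pts: np.ndarray, z: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Average z over markers sharing a 1 Å pixel cell.

    Nearly coincident (x, y) points with different z (distinct lipids whose
    heads overlap laterally) make the triangulation ill-conditioned and the
    cubic interpolant spike; averaging them is the physical reading of a
    surface sampled at pixel resolution.
    """
    cells = np.floor(pts).astype(np.int64)
    _, inv, counts = np.unique(cells, axis=0, return_inverse=True,
                               return_counts=True)
    if np.all(counts == 1):
        return pts, z
    n = counts.size
    sx = np.bincount(inv, weights=pts[:, 0], minlength=n)
    sy = np.bincount(inv, weights=pts[:, 1], minlength=n)
    sz = np.bincount(inv, weights=z, minlength=n)
    return np.column_stack([sx / counts, sy / counts]), sz / counts


def leaflet_surface(markers: np.ndarray, grid: PixelGrid,
                    box: Optional[tuple[float, float]] = None,
                    leaflet: Optional[str] = None, periodic: bool = True,
                    margin: float = 25.0) -> SurfaceField:
    """Cubic interpolation of scattered (x, y, z) markers onto the pixel grid.

    Needs at least 16 markers.  With ``periodic=True`` (default) markers near
    the edges are tiled with their periodic images so the surface is seamless
    across the box boundary; use ``periodic=False`` for intrinsically
    non-periodic test surfaces.  Markers sharing a pixel cell are merged
    (z averaged) before fitting.  Degenerate point sets fall back to linear
    interpolation with a warning; any remaining pixels outside the convex
    hull are filled by nearest-neighbour extrapolation.
    """
    markers = np.asarray(markers, dtype=float)
    if markers.ndim != 2 or markers.shape[1] != 3:
        raise ValueError("markers must be an (n, 3) array")
    if len(markers) < 16:
        raise ValueError(f"need >= 16 markers for cubic interpolation, "
                         f"got {len(markers)}")
    if box is None:
        box = (float(grid.nx), float(grid.ny))
    pts, z = _merge_close_markers(markers[:, :2], markers[:, 2])
    if periodic:
        pts, z = _tile_periodic(pts, z, box, margin)
    xc = np.arange(grid.nx) + 0.5
    yc = np.arange(grid.ny) + 0.5
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    interpolation = "cubic"
    try:
        interp = CloughTocher2DInterpolator(pts, z)
        values = interp(xx, yy)
    except QhullError:
        values = np.full(grid.shape, np.nan)
    if np.any(~np.isfinite(values)):
        n_bad = int(np.sum(~np.isfinite(values)))
        if n_bad == values.size:
            logger.warning("cubic interpolation degenerate; falling back to linear")
            try:
                values = LinearNDInterpolator(pts, z)(xx, yy)
                interpolation = "linear"
            except QhullError:
                values = np.full(grid.shape, np.nan)
        bad = ~np.isfinite(values)
        if np.any(bad):
            nearest = NearestNDInterpolator(pts, z)
            values[bad] = nearest(xx[bad], yy[bad])
    return SurfaceField(grid=grid, values=values, leaflet=leaflet,
                        interpolation=interpolation)


def thickness_field(upper: SurfaceField, lower: SurfaceField) -> ThicknessField:
    """Per-pixel upper minus lower surface; non-positive pixels are counted.

    Negative or zero thickness is unphysical for a bilayer and flags either
    swapped arguments or a badly undulating frame.
    """
    if upper.grid.shape != lower.grid.shape:
        raise ValueError(f"grid mismatch: {upper.grid.shape} vs {lower.grid.shape}")
    values = upper.values - lower.values
    n_bad = int(np.sum(values <= 0))
    if n_bad:
        logger.warning("%d pixels have non-positive thickness", n_bad)
    return ThicknessField(grid=upper.grid, values=values, n_unphysical=n_bad)


def phase_thickness_stats(thickness: ThicknessField, match: MatchMap,
                          bin_width: float = 0.5) -> dict[str, dict]:
    """Thickness mean and histogram per inter-leaflet match category.

    Returns a dict keyed by "both_lo", "both_ld", "mismatch" (absent when a
    category is empty) plus "global".  Unphysical (<= 0) pixels are excluded
    throughout, so the identity
    ``global mean == sum(category fraction x category mean)`` holds exactly
    over the retained pixels.  Histogram bins are ``bin_width`` Å wide on a
    shared range.
    """
    if thickness.grid.shape != match.grid.shape:
        raise ValueError("thickness and match map are on different grids")
    valid = thickness.values > 0
    vals = thickness.values[valid]
    if vals.size == 0:
        raise ValueError("no physical (positive-thickness) pixels")
    lo_edge = np.floor(vals.min() / bin_width) * bin_width
    hi_edge = np.ceil(vals.max() / bin_width) * bin_width
    edges = np.arange(lo_edge, hi_edge + bin_width / 2, bin_width)
    if len(edges) < 2:
        edges = np.array([lo_edge, lo_edge + bin_width])
    out: dict[str, dict] = {}
    n_valid = vals.size
    for code, name in MATCH_CATEGORY_NAMES.items():
        sel = valid & (match.values == code)
        v = thickness.values[sel]
        if v.size == 0:
            continue
        counts, _ = np.histogram(v, bins=edges)
        out[name] = {"mean": float(v.mean()), "fraction": v.size / n_valid,
                     "n_pixels": int(v.size), "hist": counts,
                     "bin_edges": edges}
    counts, _ = np.histogram(vals, bins=edges)
    out["global"] = {"mean": float(vals.mean()), "fraction": 1.0,
                     "n_pixels": int(n_valid), "hist": counts,
                     "bin_edges": edges}
    return out
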