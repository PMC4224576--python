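"""Lo/Ld phase masks, interface detection and domain statistics.

The phase mask follows the density-difference rule: subtract the saturated
lipid (DPPC) density from the unsaturated one (DUPC) and mark every pixel
strictly above the mean of that difference as Ld (disordered, DUPC-rich);
the remainder is Lo.  Cholesterol never enters the mask definition.

The interface between the phases is found with the Canny edge detector
(Gaussian smoothing sigma = 2 Å by default) run on a wrap-padded copy of
the mask so that edges are continuous across the periodic seam and no
spurious border edges appear.  Interface length is the edge-pixel count
times 1 Å — exact for axis-aligned interfaces, biased low for diagonals; an
optional chain estimator weighting diagonal steps by sqrt(2) is provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage

from .density import DensityField, PixelGrid

MATCH_BOTH_LO = 0
MATCH_BOTH_LD = 1
MATCH_MISMATCH = 2


@dataclass
class PhaseMask:
    """Binary phase grid: True/1 = Ld (unsaturated-rich), False/0 = Lo."""

    grid: PixelGrid
    values: np.ndarray  # bool (nx, ny)
    leaflet: Optional[str] = None
    time: float = 0.0
    threshold_used: float = 0.0

    @property
    def ld_fraction(self) -> float:
        return float(np.mean(self.values))

    @property
    def lo_fraction(self) -> float:
        return 1.0 - self.ld_fraction


@dataclass
class EdgeMap:
    """Binary interface-pixel grid from Canny edge detection."""

    grid: PixelGrid
    values: np.ndarray  # bool (nx, ny)
    smoothing_sigma: float = 2.0

    @property
    def n_edge_pixels(self) -> int:
        return int(self.values.sum())


@dataclass
class MatchMap:
    """Per-pixel inter-leaflet phase agreement (both-Lo / both-Ld / mismatch)."""

    grid: PixelGrid
    values: np.ndarray  # int8 codes MATCH_*
    fractions: dict[str, float] = field(default_factory=dict)

    @property
    def mismatch_fraction(self) -> float:
        return self.fractions["mismatch"]


def _check_same_grid(a, b) -> None:
    if a.grid.shape != b.grid.shape:
        raise ValueError(f"grid mismatch: {a.grid.shape} vs {b.grid.shape}")


def phase_mask(dupc: DensityField, dppc: DensityField) -> PhaseMask:
    """Threshold the DUPC - DPPC density difference at its mean.

    Pixels strictly above the mean difference are Ld; ties and the rest are
    Lo.  Both fields must live on the same grid and leaflet.
    """
    _check_same_grid(dupc, dppc)
    if dupc.leaflet is not None and dppc.leaflet is not None \
            and dupc.leaflet != dppc.leaflet:
        raise ValueError("density fields come from different leaflets")
    diff = dupc.values - dppc.values
    threshold = float(diff.mean())
    return PhaseMask(grid=dupc.grid, values=diff > threshold,
                     leaflet=dupc.leaflet, time=dupc.time,
                     threshold_used=threshold)


def _interp_magnitude(mag: np.ndarray, ddx: np.ndarray, ddy: np.ndarray,
                      I: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Bilinear sample of ``mag`` at (i + ddx, j + ddy), periodic."""
    nx, ny = mag.shape
    i0 = np.floor(ddx).astype(int)
    j0 = np.floor(ddy).astype(int)
    fx, fy = ddx - i0, ddy - j0

    def at(di, dj):
        return mag[(I + di) % nx, (J + dj) % ny]

    return ((1 - fx) * (1 - fy) * at(i0, j0) + fx * (1 - fy) * at(i0 + 1, j0)
            + (1 - fx) * fy * at(i0, j0 + 1) + fx * fy * at(i0 + 1, j0 + 1))


def detect_interface(mask: PhaseMask, smoothing_sigma: float = 2.0) -> EdgeMap:
    """Canny edge detection on the phase mask, fully periodic.

    The classic stages are applied with wrap-around boundary handling
    throughout: Gaussian-derivative gradients at ``smoothing_sigma``,
    non-maximum suppression along the interpolated gradient direction with a
    deterministic tie-break (so a symmetric step yields exactly one edge
    chain, not two), a single-response cleanup that keeps only the strongest
    of gradient-adjacent edge pixels, and hysteresis at 0.1 / 0.2 of the
    maximum gradient magnitude with periodic connected components.  A
    uniform mask yields an empty edge map.
    """
    m = mask.values.astype(float)
    if m.min() == m.max():
        return EdgeMap(grid=mask.grid,
                       values=np.zeros_like(mask.values, dtype=bool),
                       smoothing_sigma=smoothing_sigma)
    gx = ndimage.gaussian_filter(m, smoothing_sigma, order=(1, 0), mode="wrap")
    gy = ndimage.gaussian_filter(m, smoothing_sigma, order=(0, 1), mode="wrap")
    mag = np.hypot(gx, gy)
    gmax = mag.max()
    nx, ny = mag.shape
    with np.errstate(invalid="ignore"):
        ux = np.where(mag > 0, gx / mag, 0.0)
        uy = np.where(mag > 0, gy / mag, 0.0)
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    fwd = _interp_magnitude(mag, ux, uy, I, J)
    bwd = _interp_magnitude(mag, -ux, -uy, I, J)
    # >= forward, > backward: a symmetric two-pixel tie keeps one pixel only
    ridge = (mag >= fwd) & (mag > bwd) & (mag > 0)
    # single-response cleanup: among ridge pixels adjacent along the rounded
    # gradient direction, keep the strongest (same asymmetric tie-break)
    di = np.rint(ux).astype(int)
    dj = np.rint(uy).astype(int)
    nf_r = ridge[(I + di) % nx, (J + dj) % ny]
    nf_m = mag[(I + di) % nx, (J + dj) % ny]
    nb_r = ridge[(I - di) % nx, (J - dj) % ny]
    nb_m = mag[(I - di) % nx, (J - dj) % ny]
    ridge &= ~((nf_r & (nf_m > mag)) | (nb_r & (nb_m >= mag)))
    strong = ridge & (mag >= 0.2 * gmax)
    weak = ridge & (mag >= 0.1 * gmax)
    labels, n = label_periodic(weak, connectivity=2)
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return EdgeMap(grid=mask.grid, values=keep[labels],
                   smoothing_sigma=smoothing_sigma)


def interface_length(edges: EdgeMap, method: str = "pixel") -> float:
    """Total interface length in Å.

    ``method="pixel"`` (default) sums the edge pixels at 1 Å each.
    ``method="chain"`` instead sums steps between 8-adjacent edge pixels,
    counting diagonal steps as sqrt(2)/2 per pixel pair (each adjacency is
    shared by two pixels), which reduces the diagonal bias.
    """
    e = edges.values
    if method == "pixel":
        return float(e.sum())
    if method != "chain":
        raise ValueError(f"unknown method {method!r}")
    length = 0.0
    # each unordered 8-adjacency is visited exactly once by these four shifts
    for shift, w in (((1, 0), 1.0), ((0, 1), 1.0),
                     ((1, 1), math.sqrt(2)), ((1, -1), math.sqrt(2))):
        length += w * np.sum(e & np.roll(e, shift, axis=(0, 1)))
    # closed periodic loops have as many steps as pixels; open chains one fewer
    return float(length)


def _union(parent: np.ndarray, a: int, b: int) -> None:
    ra, rb = _find(parent, a), _find(parent, b)
    if ra != rb:
        parent[max(ra, rb)] = min(ra, rb)


def _find(parent: np.ndarray, a: int) -> int:
    while parent[a] != a:
        parent[a] = parent[parent[a]]
        a = parent[a]
    return a


def label_periodic(mask: np.ndarray, connectivity: int = 2) -> tuple[np.ndarray, int]:
    """Connected-component labelling with both periodic seams merged.

    8-connectivity by default (``connectivity=2``).  Returns (labels, count)
    with labels 1..count and 0 for background, like ``scipy.ndimage.label``.
    """
    mask = np.asarray(mask, dtype=bool)
    structure = np.ones((3, 3)) if connectivity == 2 else None
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return labels, 0
    parent = np.arange(n + 1)
    nx, ny = mask.shape
    offsets = [0] if connectivity == 1 else [-1, 0, 1]
    # x seam: row nx-1 adjacent to row 0 (with diagonal offsets along y)
    for d in offsets:
        a = labels[nx - 1, :]
        b = labels[0, (np.arange(ny) + d) % ny]
        for la, lb in zip(a, b):
            if la and lb:
                _union(parent, la, lb)
    # y seam: column ny-1 adjacent to column 0 (with diagonal offsets along x)
    for d in offsets:
        a = labels[:, ny - 1]
        b = labels[(np.arange(nx) + d) % nx, 0]
        for la, lb in zip(a, b):
            if la and lb:
                _union(parent, la, lb)
    roots = np.array([_find(parent, i) for i in range(n + 1)])
    # compress to consecutive labels
    uniq = np.unique(roots[1:])
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[uniq] = np.arange(1, len(uniq) + 1)
    return remap[roots[labels]], len(uniq)


def _periodic_centroid(ix: np.ndarray, n: int) -> float:
    """Centroid of pixel indices on a ring of circumference n (circular mean)."""
    theta = 2.0 * np.pi * (ix + 0.5) / n
    c = np.cos(theta).mean()
    s = np.sin(theta).mean()
    if c == 0 and s == 0:
        return n / 2.0
    return float((math.atan2(s, c) % (2.0 * np.pi)) * n / (2.0 * np.pi))


def label_domains(mask: PhaseMask) -> pd.DataFrame:
    """Label Lo and Ld domains (8-connected, merged across periodic seams).

    Returns a DataFrame with columns label, phase, area (Å^2),
    equivalent_radius (Å, sqrt(area/pi)) and periodic-aware centroid_x/y.
    """
    records = []
    next_label = 1
    for phase, arr in (("Ld", mask.values), ("Lo", ~mask.values)):
        labels, n = label_periodic(arr, connectivity=2)
        for k in range(1, n + 1):
            ix, iy = np.nonzero(labels == k)
            area = float(len(ix))
            records.append({
                "label": next_label,
                "phase": phase,
                "area": area,
                "equivalent_radius": math.sqrt(area / math.pi),
                "centroid_x": _periodic_centroid(ix, mask.grid.nx),
                "centroid_y": _periodic_centroid(iy, mask.grid.ny),
            })
            next_label += 1
    return pd.DataFrame(records, columns=["label", "phase", "area",
                                          "equivalent_radius",
                                          "centroid_x", "centroid_y"])


def mean_domain_radius(domains: pd.DataFrame, min_area: float = 100.0,
                       phases: tuple[str, ...] = ("Lo", "Ld")) -> float:
    """Unweighted mean equivalent radius of domains with area >= min_area.

    ``phases`` restricts which phases contribute (e.g. only the dispersed
    phase when the other percolates as a background sea).  Raises if no
    domain survives the filter.
    """
    sel = domains[(domains["area"] >= min_area) & domains["phase"].isin(phases)]
    if sel.empty:
        raise ValueError(
            f"no domain of phases {phases} with area >= {min_area} Å^2; "
            "mean radius is undefined")
    return float(sel["equivalent_radius"].mean())


def leaflet_match(mask_upper: PhaseMask, mask_lower: PhaseMask) -> MatchMap:
    """Classify each pixel as both-Lo, both-Ld or mismatch across leaflets."""
    _check_same_grid(mask_upper, mask_lower)
    up, lo = mask_upper.values, mask_lower.values
    values = np.full(up.shape, MATCH_MISMATCH, dtype=np.int8)
    values[~up & ~lo] = MATCH_BOTH_LO
    values[up & lo] = MATCH_BOTH_LD
    total = values.size
    fractions = {
        "both_lo": float(np.sum(values == MATCH_BOTH_LO)) / total,
        "both_ld": float(np.sum(values == MATCH_BOTH_LD)) / total,
        "mismatch": float(np.sum(values == MATCH_MISMATCH)) / total,
    }
    return MatchMap(grid=mask_upper.grid, values=values, fractions=fractions)


def species_partition(density: DensityField, mask: PhaseMask) -> float:
    """Fraction of a species' density lying in the Ld phase (complement: Lo)."""
    _check_same_grid(density, mask)
    total = density.values.sum()
    if total <= 0:
        raise ValueError("total density is zero; partition fraction undefined")
    return float(density.values[mask.values].sum() / total)
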