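"""Ground-truthed synthetic coarse-grained bilayer frames.

These generators emulate the statistical structure of a phase-separating
DPPC:DUPC:cholesterol (5:3:2) bilayer at the marker-bead level — one PO4 or
ROH bead per lipid placed by blue-noise (minimum-distance) sampling in each
leaflet — so every analysis stage can be tested against known truth without
molecular dynamics.  Lateral organisations available:

* randomly mixed (no phases): one blue-noise point set per leaflet, species
  assigned by random permutation matching the composition exactly;
* a periodic Ld stripe with optionally sinusoidal edges;
* circular Ld domains in an Lo sea;
* a coarsening time series whose characteristic length grows as t^alpha.

Phase-separated frames place each species as its own blue-noise pattern
inside its phase region (DUPC in the Ld region, DPPC and cholesterol
independently in the Lo region).  This deliberately suppresses the
compositional shot noise a molecular-dynamics frame would carry, so the
planted geometry (interface length, area fraction, domain radii) is exact
ground truth; a thin mixing band (3 Å by default) at the interfaces keeps
the compositional step from being unphysically sharp at 1 Å pixels.

Phase-separated frames also plant a phase-dependent leaflet separation
(defaults: Lo 45 Å, Ld 36 Å; mixed bilayer 41 Å) so thickness recovery can
be tested.  Protein centres of mass can be planted with known phase labels.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.integrate import quad

from .density import PixelGrid
from .phases import PhaseMask
from .trajectory_io import Frame

#: default composition per 1500 lipids (one leaflet of the reference patch)
DEFAULT_COMPOSITION_PER_1500 = {"DPPC": 751, "DUPC": 450, "CHOL": 299}
#: area per lipid implied by 3000 lipids per leaflet in a ~400 Å square box
AREA_PER_LIPID = 400.0 * 400.0 / 3000.0  # ~53.3 Å^2
#: minimum marker-marker distance for blue-noise placement
MIN_MARKER_DISTANCE = 5.0
#: coarse-grained beads per molecule (MARTINI v2.1 mapping)
BEADS_PER_MOLECULE = {"DPPC": 12, "DUPC": 12, "CHOL": 8,
                      "W": 1, "NA": 1, "CL": 1}

MARKER_BEAD = {"DPPC": "PO4", "DUPC": "PO4", "CHOL": "ROH"}

DEFAULT_LO_SEPARATION = 45.0
DEFAULT_LD_SEPARATION = 36.0
DEFAULT_MIXED_SEPARATION = 41.0


def largest_remainder(weights: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` into integers proportional to ``weights``."""
    weights = np.asarray(weights, dtype=float)
    quotas = weights / weights.sum() * total
    counts = np.floor(quotas).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(quotas - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


@dataclass(frozen=True)
class CompositionSpec:
    """Lipid counts per leaflet at the 5:3:2 DPPC:DUPC:CHOL reference ratio."""

    n_dppc: int = 751
    n_dupc: int = 450
    n_chol: int = 299

    def __post_init__(self):
        if min(self.n_dppc, self.n_dupc, self.n_chol) < 0:
            raise ValueError("lipid counts must be non-negative")

    @classmethod
    def from_total(cls, n_per_leaflet: int) -> "CompositionSpec":
        """Scale the reference composition to a leaflet size, preserving the
        ratio by largest-remainder rounding."""
        ref = DEFAULT_COMPOSITION_PER_1500
        d, u, c = largest_remainder([ref["DPPC"], ref["DUPC"], ref["CHOL"]],
                                    n_per_leaflet)
        return cls(n_dppc=d, n_dupc=u, n_chol=c)

    @classmethod
    def for_box(cls, box: Sequence[float],
                area_per_lipid: float = AREA_PER_LIPID) -> "CompositionSpec":
        n = int(round(box[0] * box[1] / area_per_lipid))
        return cls.from_total(n)

    @property
    def n_lipids(self) -> int:
        return self.n_dppc + self.n_dupc + self.n_chol

    @property
    def n_phospholipids(self) -> int:
        return self.n_dppc + self.n_dupc

    @property
    def dppc_fraction_of_phospholipids(self) -> float:
        return self.n_dppc / self.n_phospholipids

    def species_array(self) -> np.ndarray:
        return np.array(["DPPC"] * self.n_dppc + ["DUPC"] * self.n_dupc +
                        ["CHOL"] * self.n_chol, dtype=object)


def count_system_beads(n_dppc: int, n_dupc: int, n_chol: int,
                       n_water: int = 0, n_na: int = 0, n_cl: int = 0,
                       beads_per_molecule: Optional[dict] = None) -> int:
    """Exact coarse-grained bead total for a solvated bilayer system."""
    bp = dict(BEADS_PER_MOLECULE)
    if beads_per_molecule:
        bp.update(beads_per_molecule)
    return (n_dppc * bp["DPPC"] + n_dupc * bp["DUPC"] + n_chol * bp["CHOL"]
            + n_water * bp["W"] + n_na * bp["NA"] + n_cl * bp["CL"])


@dataclass
class GroundTruth:
    """Construction-time truth accompanying a generated frame."""

    leaflet_by_resid: dict = field(default_factory=dict)
    phase_by_resid: Optional[dict] = None        # resid -> "Lo" | "Ld"
    interface_length: Optional[float] = None     # Å, both edges / all rims
    ld_area_fraction: Optional[float] = None
    domain_radii: Optional[tuple] = None         # Å
    lo_separation: Optional[float] = None        # Å, phosphate-to-phosphate
    ld_separation: Optional[float] = None
    characteristic_length: Optional[float] = None  # Å
    time_us: Optional[float] = None
    protein_labels: dict = field(default_factory=dict)   # id -> planted label
    protein_leaflets: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# blue-noise point placement
# ---------------------------------------------------------------------------

def poisson_disk_sample(n: int, box: Sequence[float], r_min: float,
                        rng: np.random.Generator,
                        accept: Optional[Callable[[float, float], bool]] = None,
                        region_fraction: float = 1.0,
                        max_trials_per_point: int = 2000) -> np.ndarray:
    """Place n points in a periodic box with pairwise min-image distance >= r_min.

    Dart throwing with a periodic cell grid.  ``accept(x, y)`` optionally
    restricts placement to a region covering ``region_fraction`` of the box
    (used only for the feasibility check).  Raises when the requested density
    is infeasible (disk coverage beyond the random-sequential-adsorption
    regime) or sampling stalls.
    """
    lx, ly = float(box[0]), float(box[1])
    area = lx * ly * region_fraction
    coverage = n * math.pi * r_min ** 2 / 4.0 / area
    if coverage > 0.5:
        raise ValueError(
            f"{n} points at min distance {r_min} Å in {area:.0f} Å^2 "
            f"(disk coverage {coverage:.2f}) is infeasibly dense")
    gx = max(1, int(lx // max(r_min / math.sqrt(2), 1e-6)))
    gy = max(1, int(ly // max(r_min / math.sqrt(2), 1e-6)))
    cx, cy = lx / gx, ly / gy
    cells: dict[tuple[int, int], list[int]] = {}
    pts = np.empty((n, 2))
    r2 = r_min * r_min
    placed = 0
    trials = 0
    budget = max_trials_per_point * n
    reach_x = int(math.ceil(r_min / cx))
    reach_y = int(math.ceil(r_min / cy))
    while placed < n:
        if trials >= budget:
            raise RuntimeError(
                f"blue-noise sampling stalled at {placed}/{n} points")
        trials += 1
        x = rng.uniform(0, lx)
        y = rng.uniform(0, ly)
        if accept is not None and not accept(x, y):
            continue
        ci, cj = int(x / cx), int(y / cy)
        ok = True
        for di in range(-reach_x, reach_x + 1):
            for dj in range(-reach_y, reach_y + 1):
                for idx in cells.get(((ci + di) % gx, (cj + dj) % gy), ()):
                    ddx = abs(pts[idx, 0] - x)
                    ddy = abs(pts[idx, 1] - y)
                    ddx = min(ddx, lx - ddx)
                    ddy = min(ddy, ly - ddy)
                    if ddx * ddx + ddy * ddy < r2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            pts[placed] = (x, y)
            cells.setdefault((ci, cj), []).append(placed)
            placed += 1
    return pts


def _species_min_distance(n: int, region_area: float) -> float:
    """Blue-noise radius for one species in its region: 75% of the species'
    mean spacing, the strongest short-range order dart throwing reaches
    reliably."""
    if n == 0:
        return MIN_MARKER_DISTANCE
    return 0.75 * math.sqrt(region_area / n)


# ---------------------------------------------------------------------------
# frame assembly
# ---------------------------------------------------------------------------

def _assemble_frame(leaflet_data: dict, box: Sequence[float], box_z: float,
                    time_ns: float) -> tuple[Frame, dict]:
    """Build a marker-bead Frame from per-leaflet (species, xy, z) arrays.

    Resids are assigned sequentially, upper leaflet first; returns the frame
    plus a resid -> leaflet mapping.
    """
    names, resnames, resids, positions = [], [], [], []
    leaflet_by_resid = {}
    rid = 1
    for leaflet in ("upper", "lower"):
        species, xy, z = leaflet_data[leaflet]
        for k in range(len(species)):
            sp = species[k]
            names.append(MARKER_BEAD[sp])
            resnames.append(sp)
            resids.append(rid)
            positions.append((xy[k, 0], xy[k, 1], z[k]))
            leaflet_by_resid[rid] = leaflet
            rid += 1
    frame = Frame(names=np.array(names, dtype=object),
                  resnames=np.array(resnames, dtype=object),
                  resids=np.array(resids),
                  positions=np.array(positions),
                  box=np.array([box[0], box[1], box_z], dtype=float),
                  time=time_ns)
    return frame, leaflet_by_resid


def _leaflet_z(separation: np.ndarray, leaflet: str, sigma_z: float,
               rng: np.random.Generator, midplane: float) -> np.ndarray:
    sign = 1.0 if leaflet == "upper" else -1.0
    return midplane + sign * separation / 2.0 + rng.normal(0, sigma_z,
                                                           len(separation))


def _phase_truth(phases_per_leaflet: dict) -> dict[int, str]:
    phase_by_resid = {}
    rid = 1
    for leaflet in ("upper", "lower"):
        for is_ld in phases_per_leaflet[leaflet]:
            phase_by_resid[rid] = "Ld" if is_ld else "Lo"
            rid += 1
    return phase_by_resid


def _region_composition(box: Sequence[float], ld_area: float,
                        area_per_lipid: float = AREA_PER_LIPID
                        ) -> tuple[int, int, int]:
    """Counts (DPPC, DUPC, CHOL) giving uniform total lipid density with all
    DUPC in the Ld region and DPPC:CHOL at the reference ratio in Lo."""
    total_area = box[0] * box[1]
    n_total = int(round(total_area / area_per_lipid))
    n_dupc = int(round(ld_area / area_per_lipid))
    n_lo = n_total - n_dupc
    ref = DEFAULT_COMPOSITION_PER_1500
    n_dppc, n_chol = largest_remainder([ref["DPPC"], ref["CHOL"]], n_lo)
    return n_dppc, n_dupc, n_chol


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def random_mixed_frame(composition: Optional[CompositionSpec] = None,
                       box: Sequence[float] = (400.0, 400.0), seed: int = 0,
                       d0: float = DEFAULT_MIXED_SEPARATION,
                       sigma_z: float = 1.0,
                       box_z: float = 100.0) -> tuple[Frame, GroundTruth]:
    """A randomly mixed bilayer: blue-noise lateral positions, random species.

    Species are assigned by a random permutation matching the composition
    exactly; all lipids sit at +/- d0/2 with Gaussian z jitter.
    """
    if composition is None:
        composition = CompositionSpec.for_box(box)
    rng = np.random.default_rng(seed)
    midplane = box_z / 2.0
    data = {}
    for leaflet in ("upper", "lower"):
        xy = poisson_disk_sample(composition.n_lipids, box,
                                 MIN_MARKER_DISTANCE, rng)
        species = rng.permutation(composition.species_array())
        sep = np.full(len(species), d0)
        data[leaflet] = (species, xy, _leaflet_z(sep, leaflet, sigma_z, rng,
                                                 midplane))
    frame, leaflet_by_resid = _assemble_frame(data, box, box_z, 0.0)
    truth = GroundTruth(leaflet_by_resid=leaflet_by_resid,
                        lo_separation=d0, ld_separation=d0,
                        geometry={"kind": "mixed", "box": tuple(box)})
    return frame, truth


def _stripe_edge_x(y, x0: float, amplitude: float, wavelength: float):
    return x0 + amplitude * np.sin(2.0 * math.pi * np.asarray(y) / wavelength)


def stripe_arc_length(amplitude: float, wavelength: float, ly: float) -> float:
    """Arc length of one sinusoidal stripe edge across the box, by quadrature."""
    if amplitude == 0:
        return ly
    k = 2.0 * math.pi / wavelength
    val, _ = quad(lambda y: math.sqrt(1.0 + (amplitude * k * math.cos(k * y)) ** 2),
                  0.0, ly, limit=200)
    return val


def striped_frame(composition: Optional[CompositionSpec] = None,
                  box: Sequence[float] = (400.0, 400.0),
                  stripe_width: float = 120.0,
                  roughness_amplitude: float = 0.0,
                  roughness_wavelength: Optional[float] = None,
                  seed: int = 0, x0: Optional[float] = None,
                  lo_separation: float = DEFAULT_LO_SEPARATION,
                  ld_separation: float = DEFAULT_LD_SEPARATION,
                  mixing_band: float = 3.0, sigma_z: float = 1.0,
                  box_z: float = 100.0) -> tuple[Frame, GroundTruth]:
    """One periodic Ld (DUPC) stripe in an Lo (DPPC + cholesterol) background.

    The stripe runs along y with edges optionally perturbed by a sinusoid
    (both edges in phase, so the width is constant and the Ld area fraction
    is exactly stripe_width / Lx).  Each species is blue-noise placed inside
    its own region; lipids within the mixing band are then displaced to a
    uniformly random offset across the edge.  When ``composition`` is None,
    counts are derived from the box at uniform density with all DUPC in the
    stripe.  The true interface length is twice the edge arc length.
    """
    lx, ly = float(box[0]), float(box[1])
    if not 0 < stripe_width < lx:
        raise ValueError("stripe width must lie strictly inside the box")
    if roughness_amplitude > stripe_width / 2:
        raise ValueError("roughness amplitude exceeds half the stripe width")
    if roughness_wavelength is None:
        roughness_wavelength = ly
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = rng.uniform(0, lx)
    a_ld = stripe_width / lx * lx * ly
    if composition is None:
        n_dppc, n_dupc, n_chol = _region_composition(box, a_ld)
    else:
        n_dppc, n_dupc, n_chol = (composition.n_dppc, composition.n_dupc,
                                  composition.n_chol)
    midplane = box_z / 2.0

    def offset(x, y):
        return np.mod(x - _stripe_edge_x(y, x0, roughness_amplitude,
                                         roughness_wavelength), lx)

    ld_frac = stripe_width / lx
    data = {}
    phases_per_leaflet = {}
    for leaflet in ("upper", "lower"):
        groups = [
            ("DUPC", n_dupc, lambda x, y: offset(x, y) < stripe_width,
             ld_frac, a_ld, True),
            ("DPPC", n_dppc, lambda x, y: offset(x, y) >= stripe_width,
             1 - ld_frac, lx * ly - a_ld, False),
            ("CHOL", n_chol, lambda x, y: offset(x, y) >= stripe_width,
             1 - ld_frac, lx * ly - a_ld, False),
        ]
        species_l, xy_l, ld_l = [], [], []
        for sp, n, acc, frac, area, is_ld in groups:
            if n == 0:
                continue
            pts = poisson_disk_sample(n, box, _species_min_distance(n, area),
                                      rng, accept=acc, region_fraction=frac)
            # mixing band: lipids near an edge take a random offset across it
            u = offset(pts[:, 0], pts[:, 1])
            near0 = np.minimum(u, lx - u) < mixing_band / 2.0
            near1 = np.abs(u - stripe_width) < mixing_band / 2.0
            for near, edge_u in ((near0, 0.0), (near1, stripe_width)):
                k = int(near.sum())
                if k:
                    new_u = edge_u + rng.uniform(-mixing_band / 2,
                                                 mixing_band / 2, k)
                    edge = _stripe_edge_x(pts[near, 1], x0,
                                          roughness_amplitude,
                                          roughness_wavelength)
                    pts[near, 0] = np.mod(edge + new_u, lx)
            species_l.append(np.full(n, sp, dtype=object))
            xy_l.append(pts)
            ld_l.append(np.full(n, is_ld))
        species = np.concatenate(species_l)
        xy = np.vstack(xy_l)
        is_ld = np.concatenate(ld_l)
        sep = np.where(is_ld, ld_separation, lo_separation)
        data[leaflet] = (species, xy, _leaflet_z(sep, leaflet, sigma_z, rng,
                                                 midplane))
        phases_per_leaflet[leaflet] = is_ld
    frame, leaflet_by_resid = _assemble_frame(data, box, box_z, 0.0)
    edge_len = stripe_arc_length(roughness_amplitude, roughness_wavelength, ly)
    truth = GroundTruth(
        leaflet_by_resid=leaflet_by_resid,
        phase_by_resid=_phase_truth(phases_per_leaflet),
        interface_length=2.0 * edge_len,
        ld_area_fraction=stripe_width / lx,
        lo_separation=lo_separation, ld_separation=ld_separation,
        characteristic_length=stripe_width,
        geometry={"kind": "stripe", "box": (lx, ly), "x0": x0,
                  "stripe_width": stripe_width,
                  "amplitude": roughness_amplitude,
                  "wavelength": roughness_wavelength})
    return frame, truth


def _sample_circle_centers(radii: Sequence[float], box: Sequence[float],
                           gap: float, rng: np.random.Generator,
                           max_trials: int = 20000) -> np.ndarray:
    lx, ly = float(box[0]), float(box[1])
    for r in radii:
        if 2 * r + gap > min(lx, ly):
            raise ValueError(f"circle of radius {r} Å cannot keep a {gap} Å "
                             "gap from its own periodic image")
    centers: list[tuple[float, float]] = []
    for i, r in enumerate(radii):
        for _ in range(max_trials):
            x, y = rng.uniform(0, lx), rng.uniform(0, ly)
            ok = True
            for (px, py), pr in zip(centers, radii):
                dx = min(abs(px - x), lx - abs(px - x))
                dy = min(abs(py - y), ly - abs(py - y))
                if math.hypot(dx, dy) < r + pr + gap:
                    ok = False
                    break
            if ok:
                centers.append((x, y))
                break
        else:
            raise ValueError(f"could not place circle {i} (r = {r} Å) without "
                             "overlap; box too crowded")
    return np.asarray(centers)


def _validate_given_centers(centers: np.ndarray, radii: Sequence[float],
                            box: Sequence[float], gap: float) -> None:
    lx, ly = box
    if len(centers) != len(radii):
        raise ValueError("need one centre per radius")
    for r in radii:
        if 2 * r + gap > min(lx, ly):
            raise ValueError(f"circle of radius {r} Å overlaps its own image")
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            dx = min(abs(centers[i, 0] - centers[j, 0]),
                     lx - abs(centers[i, 0] - centers[j, 0]))
            dy = min(abs(centers[i, 1] - centers[j, 1]),
                     ly - abs(centers[i, 1] - centers[j, 1]))
            if math.hypot(dx, dy) < radii[i] + radii[j] + gap:
                raise ValueError(
                    f"circles {i} and {j} overlap (min gap {gap} Å)")


def circular_domain_frame(composition: Optional[CompositionSpec] = None,
                          box: Sequence[float] = (400.0, 400.0),
                          radii: Sequence[float] = (50.0,),
                          centers: Optional[np.ndarray] = None, seed: int = 0,
                          gap: float = 3.0,
                          lo_separation: float = DEFAULT_LO_SEPARATION,
                          ld_separation: float = DEFAULT_LD_SEPARATION,
                          mixing_band: float = 3.0, sigma_z: float = 1.0,
                          box_z: float = 100.0) -> tuple[Frame, GroundTruth]:
    """Circular Ld (DUPC) domains in an Lo sea, non-overlapping with 3 Å gaps.

    True interface length is 2 pi sum(r); true domain radii are recorded.
    When ``composition`` is None, counts keep the total lipid density uniform
    with all DUPC inside the circles.
    """
    lx, ly = float(box[0]), float(box[1])
    radii = tuple(float(r) for r in radii)
    rng = np.random.default_rng(seed)
    if gap < 3.0:
        raise ValueError("circles must keep at least 3 Å gaps")
    if centers is None:
        centers = _sample_circle_centers(radii, box, gap=gap, rng=rng)
    else:
        centers = np.asarray(centers, dtype=float)
        _validate_given_centers(centers, radii, (lx, ly), gap=gap)
    area_ld = sum(math.pi * r ** 2 for r in radii)
    if composition is None:
        n_dppc, n_dupc, n_chol = _region_composition(box, area_ld)
    else:
        n_dppc, n_dupc, n_chol = (composition.n_dppc, composition.n_dupc,
                                  composition.n_chol)
    midplane = box_z / 2.0
    carr = np.asarray(centers, dtype=float)
    rarr = np.asarray(radii, dtype=float)

    def signed_dist(x, y):
        """Distance inside the nearest circle (positive inside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        best = np.full(x.shape, -np.inf)
        for (cx, cy), r in zip(carr, rarr):
            dx = np.abs(x - cx)
            dy = np.abs(y - cy)
            dx = np.minimum(dx, lx - dx)
            dy = np.minimum(dy, ly - dy)
            best = np.maximum(best, r - np.hypot(dx, dy))
        return best

    ld_frac = area_ld / (lx * ly)
    data = {}
    phases_per_leaflet = {}
    for leaflet in ("upper", "lower"):
        groups = [
            ("DUPC", n_dupc, lambda x, y: signed_dist(x, y)[0] > 0,
             ld_frac, area_ld, True),
            ("DPPC", n_dppc, lambda x, y: signed_dist(x, y)[0] <= 0,
             1 - ld_frac, lx * ly - area_ld, False),
            ("CHOL", n_chol, lambda x, y: signed_dist(x, y)[0] <= 0,
             1 - ld_frac, lx * ly - area_ld, False),
        ]
        species_l, xy_l, ld_l = [], [], []
        for sp, n, acc, frac, area, is_ld in groups:
            if n == 0:
                continue
            pts = poisson_disk_sample(n, box, _species_min_distance(n, area),
                                      rng, accept=acc, region_fraction=frac)
            # mixing band: move near-rim lipids to a random radial offset
            s = signed_dist(pts[:, 0], pts[:, 1])
            near = np.abs(s) < mixing_band / 2.0
            if np.any(near):
                shift = rng.uniform(-mixing_band / 2, mixing_band / 2,
                                    int(near.sum())) - s[near]
                # push along the radial direction of the nearest circle
                for i, idx in enumerate(np.nonzero(near)[0]):
                    px, py = pts[idx]
                    dists = []
                    for (cx, cy), r in zip(carr, rarr):
                        dx = px - cx
                        dy = py - cy
                        dx -= lx * round(dx / lx)
                        dy -= ly * round(dy / ly)
                        dists.append((abs(r - math.hypot(dx, dy)), dx, dy))
                    _, dx, dy = min(dists)
                    norm = math.hypot(dx, dy) or 1.0
                    pts[idx, 0] = (px - shift[i] * dx / norm) % lx
                    pts[idx, 1] = (py - shift[i] * dy / norm) % ly
            species_l.append(np.full(n, sp, dtype=object))
            xy_l.append(pts)
            ld_l.append(np.full(n, is_ld))
        species = np.concatenate(species_l)
        xy = np.vstack(xy_l)
        is_ld = np.concatenate(ld_l)
        sep = np.where(is_ld, ld_separation, lo_separation)
        data[leaflet] = (species, xy, _leaflet_z(sep, leaflet, sigma_z, rng,
                                                 midplane))
        phases_per_leaflet[leaflet] = is_ld
    frame, leaflet_by_resid = _assemble_frame(data, box, box_z, 0.0)
    truth = GroundTruth(
        leaflet_by_resid=leaflet_by_resid,
        phase_by_resid=_phase_truth(phases_per_leaflet),
        interface_length=2.0 * math.pi * float(np.sum(rarr)),
        ld_area_fraction=ld_frac,
        domain_radii=radii,
        lo_separation=lo_separation, ld_separation=ld_separation,
        characteristic_length=float(np.mean(rarr)),
        geometry={"kind": "circles", "box": (lx, ly),
                  "centers": carr, "radii": radii})
    return frame, truth


def coarsening_series(box: Sequence[float] = (200.0, 200.0), alpha: float = 0.5,
                      n_frames: int = 10, t_start: float = 0.3,
                      t_end: float = 5.0, seed: int = 0,
                      r_start: float = 16.0, ld_fraction: float = 0.3,
                      gap: float = 12.0,
                      **frame_kwargs) -> tuple[list[Frame], list[GroundTruth]]:
    """Frames whose true characteristic length grows as r_start (t/t_start)^alpha.

    Times are log-spaced in [t_start, t_end] µs.  Each frame contains
    circular Ld domains of radius L(t); the domain count keeps the Ld area
    fraction near ``ld_fraction`` (capped so circles stay feasible), so the
    total interface length shrinks as the domains coarsen.  The default
    inter-circle gap (12 Å) keeps neighbouring domains resolvable after
    smoothing with the ~4 Å lipid kernel.  Frames are independently noisy.
    """
    if alpha <= 0:
        raise ValueError("coarsening exponent must be positive")
    lx, ly = float(box[0]), float(box[1])
    times = np.geomspace(t_start, t_end, n_frames)
    frames, truths = [], []
    rng = np.random.default_rng(seed)
    for t in times:
        r = r_start * (t / t_start) ** alpha
        m = max(1, int(round(ld_fraction * lx * ly / (math.pi * r ** 2))))
        while m > 1 and m * math.pi * (r + gap) ** 2 > 0.45 * lx * ly:
            m -= 1  # keep the circle rejection sampler feasible
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        frame, truth = circular_domain_frame(box=box, radii=[r] * m,
                                             seed=sub_seed, gap=gap,
                                             **frame_kwargs)
        frame = replace(frame, time=t * 1000.0)  # µs -> ns
        truth.time_us = float(t)
        truth.characteristic_length = r
        frames.append(frame)
        truths.append(truth)
    return frames, truths


def truth_series(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    """Tabulate per-frame ground truth (times in µs) for kinetics tests."""
    return pd.DataFrame({
        "time": [t.time_us for t in truths],
        "characteristic_length": [t.characteristic_length for t in truths],
        "interface_length": [t.interface_length for t in truths],
        "ld_area_fraction": [t.ld_area_fraction for t in truths],
    })


def truth_mask(truth: GroundTruth, grid: Optional[PixelGrid] = None) -> PhaseMask:
    """Rasterize the planted phase geometry into an exact PhaseMask.

    Pixels are classified by their centre against the true stripe or circle
    geometry (no densities involved); useful as a clean reference for the
    edge-detection and domain-measurement stages.
    """
    geom = truth.geometry
    kind = geom.get("kind")
    if kind not in ("stripe", "circles"):
        raise ValueError(f"no planted phase geometry (kind = {kind!r})")
    lx, ly = geom["box"]
    if grid is None:
        grid = PixelGrid(nx=int(round(lx)), ny=int(round(ly)))
    xc = np.arange(grid.nx) + 0.5
    yc = np.arange(grid.ny) + 0.5
    xx, yy = np.meshgrid(xc, yc, indexing="ij")
    if kind == "stripe":
        edge = _stripe_edge_x(yy, geom["x0"], geom["amplitude"],
                              geom["wavelength"])
        values = np.mod(xx - edge, lx) < geom["stripe_width"]
    else:
        values = np.zeros(grid.shape, dtype=bool)
        for (cx, cy), r in zip(geom["centers"], geom["radii"]):
            dx = np.abs(xx - cx)
            dy = np.abs(yy - cy)
            dx = np.minimum(dx, lx - dx)
            dy = np.minimum(dy, ly - dy)
            values |= dx ** 2 + dy ** 2 < r ** 2
    return PhaseMask(grid=grid, values=values)


# ---------------------------------------------------------------------------
# protein placement
# ---------------------------------------------------------------------------

def _hexagonal_points(n: int, box: Sequence[float]) -> np.ndarray:
    """First n sites of a triangular lattice spanning the box."""
    lx, ly = box
    rows = int(math.ceil(math.sqrt(n)))
    cols = int(math.ceil(n / rows))
    pts = []
    for j in range(rows):
        for i in range(cols):
            x = (i + 0.25 + 0.5 * (j % 2)) * lx / cols
            y = (j + 0.5) * ly / rows
            pts.append((x % lx, y % ly))
    return np.asarray(pts[:n])


def _stripe_placement(label: str, k: int, n: int, geom: dict,
                      rng: np.random.Generator) -> tuple[float, float]:
    lx, ly = geom["box"]
    w = geom["stripe_width"]
    y = (k + 0.5) * ly / n
    edge = float(_stripe_edge_x(y, geom["x0"], geom["amplitude"],
                                geom["wavelength"]))
    if label == "Ld":
        x = edge + w / 2.0
    elif label == "Lo":
        x = edge + w + (lx - w) / 2.0
    else:  # interfacial: alternate between the two edges
        x = edge if k % 2 == 0 else edge + w
    return x % lx, y % ly


def _circle_placement(label: str, k: int, n: int, geom: dict,
                      rng: np.random.Generator) -> tuple[float, float]:
    lx, ly = geom["box"]
    centers, radii = geom["centers"], geom["radii"]
    c = centers[k % len(centers)]
    r = radii[k % len(radii)]
    theta = 2.0 * math.pi * k / max(n, 1)
    if label == "Ld":
        return c[0] % lx, c[1] % ly
    if label == "interface":
        return ((c[0] + r * math.cos(theta)) % lx,
                (c[1] + r * math.sin(theta)) % ly)
    # Lo: the most circle-distant point on a coarse grid, slightly jittered
    gx, gy = np.meshgrid(np.linspace(0, lx, 40, endpoint=False),
                         np.linspace(0, ly, 40, endpoint=False), indexing="ij")
    mindist = np.full(gx.shape, np.inf)
    for (cx, cy), rr in zip(centers, radii):
        dx = np.abs(gx - cx)
        dy = np.abs(gy - cy)
        dx = np.minimum(dx, lx - dx)
        dy = np.minimum(dy, ly - dy)
        mindist = np.minimum(mindist, np.hypot(dx, dy) - rr)
    i, j = np.unravel_index(np.argmax(mindist), mindist.shape)
    jitter = rng.uniform(-2, 2, size=2)
    return (gx[i, j] + jitter[0]) % lx, (gy[i, j] + jitter[1]) % ly


def place_proteins(frame: Frame, truth: GroundTruth,
                   n_per_leaflet: int = 10,
                   placement: Union[str, dict] = "hexagonal",
                   seed: int = 0, z_offset: float = 5.0
                   ) -> tuple[Frame, GroundTruth]:
    """Plant protein centres of mass with known phase labels in both leaflets.

    ``placement`` is either a single mode ("Lo", "Ld", "interface",
    "hexagonal") or a dict of counts, e.g. ``{"Lo": 3, "Ld": 1,
    "interface": 6}``, applied to each leaflet.  Hexagonal placement ignores
    the phase truth (no labels are planted).  Phase-aware placement requires
    a frame with stripe or circle geometry.
    """
    if isinstance(placement, str):
        plan = [(placement, n_per_leaflet)]
    else:
        plan = list(placement.items())
        n_per_leaflet = sum(c for _, c in plan)
    kind = truth.geometry.get("kind")
    for label, _ in plan:
        if label not in ("Lo", "Ld", "interface", "hexagonal"):
            raise ValueError(f"unknown placement {label!r}")
        if label != "hexagonal" and kind not in ("stripe", "circles"):
            raise ValueError(
                f"placement {label!r} needs stripe or circle phase geometry, "
                f"got {kind!r}")
    rng = np.random.default_rng(seed)
    sep = max(truth.lo_separation or DEFAULT_MIXED_SEPARATION,
              truth.ld_separation or DEFAULT_MIXED_SEPARATION)
    midplane = frame.box[2] / 2.0
    place_fn = _stripe_placement if kind == "stripe" else _circle_placement

    new_names, new_resnames, new_resids, new_pos = [], [], [], []
    next_rid = int(frame.resids.max()) + 1 if frame.n_beads else 1
    truth = replace(truth, protein_labels=dict(truth.protein_labels),
                    protein_leaflets=dict(truth.protein_leaflets))
    for leaflet in ("upper", "lower"):
        zsign = 1.0 if leaflet == "upper" else -1.0
        hex_pts = _hexagonal_points(
            n_per_leaflet, truth.geometry.get("box", frame.box[:2]))
        k_global = 0
        for label, count in plan:
            for _ in range(count):
                if label == "hexagonal":
                    x, y = hex_pts[k_global]
                    planted = None
                else:
                    x, y = place_fn(label, k_global, n_per_leaflet,
                                    truth.geometry, rng)
                    planted = "interfacial" if label == "interface" else label
                z = midplane + zsign * (sep / 2.0 + z_offset)
                new_names.append("BB")
                new_resnames.append("PROT")
                new_resids.append(next_rid)
                new_pos.append((x, y, z))
                if planted is not None:
                    truth.protein_labels[next_rid] = planted
                truth.protein_leaflets[next_rid] = leaflet
                next_rid += 1
                k_global += 1
    out = Frame(
        names=np.concatenate([frame.names, np.array(new_names, dtype=object)]),
        resnames=np.concatenate([frame.resnames,
                                 np.array(new_resnames, dtype=object)]),
        resids=np.concatenate([frame.resids, np.array(new_resids)]),
        positions=np.vstack([frame.positions, np.array(new_pos)]),
        box=frame.box.copy(), time=frame.time)
    return out, truth
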