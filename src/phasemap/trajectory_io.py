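"""Reading, writing and leaflet bookkeeping for coarse-grained bilayer frames.

All coordinates are handled internally in Å.  GRO files store nm and are
converted on read/write.  A :class:`Frame` holds one snapshot of bead
coordinates together with the periodic box; lateral analysis downstream only
ever consumes per-molecule *marker* points:

* phospholipids (DPPC, DUPC) — their PO4 phosphate bead,
* cholesterol (CHOL)         — its ROH hydroxyl bead,
* proteins                   — the centre of mass over all their beads.

Leaflets are identified against a flat midplane placed at the mean z of all
phosphate markers.  This assumes the bilayer does not undulate appreciably;
frames where many markers sit close to the midplane are rejected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

NM_TO_ANGSTROM = 10.0

#: residue names recognised as phospholipids (marker bead PO4)
PHOSPHOLIPID_RESNAMES = ("DPPC", "DUPC")
#: residue names recognised as cholesterol (marker bead ROH)
CHOLESTEROL_RESNAMES = ("CHOL",)
LIPID_RESNAMES = PHOSPHOLIPID_RESNAMES + CHOLESTEROL_RESNAMES
#: default residue names treated as protein molecules
PROTEIN_RESNAMES = ("PROT", "NRAS")

PHOSPHATE_BEAD = "PO4"
HYDROXYL_BEAD = "ROH"

SPECIES = ("DPPC", "DUPC", "CHOL", "PROTEIN")


class GroParseError(ValueError):
    """Raised when a GRO file record cannot be parsed."""


@dataclass
class Frame:
    """One snapshot of bead coordinates in a periodic box.

    Attributes
    ----------
    names, resnames : arrays of str, one per bead
    resids : int array, constant across the beads of one molecule
    positions : (n, 3) float array, Å
    box : (3,) float array, Å (orthorhombic)
    time : float, ns
    """

    names: np.ndarray
    resnames: np.ndarray
    resids: np.ndarray
    positions: np.ndarray
    box: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.names = np.asarray(self.names, dtype=object)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.resids = np.asarray(self.resids, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.box = np.asarray(self.box, dtype=np.float64)
        n = len(self.names)
        if not (len(self.resnames) == len(self.resids) == self.positions.shape[0] == n):
            raise ValueError("inconsistent per-bead array lengths")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_beads(self) -> int:
        return len(self.names)


@dataclass(frozen=True)
class MarkerSet:
    """Lateral marker points for one molecular species in one frame."""

    species: str
    resids: np.ndarray
    positions: np.ndarray  # (n, 3) Å


@dataclass
class LeafletAssignment:
    """Mapping of lipid molecules to leaflets against a flat midplane."""

    mapping: dict[int, str]  # resid -> "upper" | "lower"
    midplane_z: float

    def resids(self, leaflet: str) -> np.ndarray:
        return np.array(sorted(r for r, lf in self.mapping.items() if lf == leaflet),
                        dtype=np.int64)


# ---------------------------------------------------------------------------
# GRO format I/O
# ---------------------------------------------------------------------------

def _parse_gro_atom(line: str, lineno: int) -> tuple[int, str, str, float, float, float]:
    # fixed columns: resid(5) resname(5) atom(5) serial(5) x(8.3) y(8.3) z(8.3)
    if len(line.rstrip("\n")) < 44:
        raise GroParseError(f"line {lineno}: atom record too short: {line!r}")
    try:
        resid = int(line[0:5])
        resname = line[5:10].strip()
        name = line[10:15].strip()
        x = float(line[20:28])
        y = float(line[28:36])
        z = float(line[36:44])
    except ValueError as exc:
        raise GroParseError(f"line {lineno}: malformed atom record: {line!r}") from exc
    return resid, resname, name, x, y, z


def _parse_title_time(title: str) -> float:
    """Extract the time stamp (ps in GRO convention) from a title line, as ns."""
    if "t=" in title:
        try:
            return float(title.split("t=")[1].split()[0]) / 1000.0
        except (ValueError, IndexError):
            pass
    return 0.0


def read_frames(path: str | Path, stride: int = 1) -> list[Frame]:
    """Read a single- or multi-frame GRO file.

    Every ``stride``-th snapshot is retained (the first is always kept).
    Coordinates are converted from nm to Å.
    """
    if stride < 1:
        raise ValueError(f"stride must be a positive integer, got {stride}")
    path = Path(path)
    frames: list[Frame] = []
    index = 0
    with path.open() as fh:
        lineno = 0
        while True:
            title = fh.readline()
            lineno += 1
            if not title:
                break
            if not title.strip() and not fh.readline():
                break
            try:
                n_atoms = int(fh.readline())
            except ValueError as exc:
                raise GroParseError(
                    f"line {lineno + 1}: expected atom count") from exc
            lineno += 1
            names, resnames, resids = [], [], []
            xyz = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if not line:
                    raise GroParseError(f"line {lineno}: truncated frame")
                resid, resname, name, x, y, z = _parse_gro_atom(line, lineno)
                resids.append(resid)
                resnames.append(resname)
                names.append(name)
                xyz[i] = (x, y, z)
            box_line = fh.readline()
            lineno += 1
            if not box_line or len(box_line.split()) < 3:
                raise GroParseError(f"line {lineno}: missing or short box line")
            box = np.array([float(v) for v in box_line.split()[:3]])
            if index % stride == 0:
                frames.append(Frame(
                    names=np.array(names, dtype=object),
                    resnames=np.array(resnames, dtype=object),
                    resids=np.array(resids),
                    positions=xyz * NM_TO_ANGSTROM,
                    box=box * NM_TO_ANGSTROM,
                    time=_parse_title_time(title),
                ))
            index += 1
    return frames


def write_frames(path: str | Path, frames: Frame | Sequence[Frame],
                 title: str = "phasemap frame") -> None:
    """Write one or more frames as a (multi-frame) GRO file, Å -> nm."""
    if isinstance(frames, Frame):
        frames = [frames]
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            fh.write(f"{title}, t= {frame.time * 1000.0:.3f}\n")
            fh.write(f"{frame.n_beads}\n")
            for i in range(frame.n_beads):
                x, y, z = frame.positions[i] / NM_TO_ANGSTROM
                # GRO resid/serial fields wrap at 100000
                fh.write(f"{int(frame.resids[i]) % 100000:5d}"
                         f"{frame.resnames[i]:<5.5s}{frame.names[i]:>5.5s}"
                         f"{(i + 1) % 100000:5d}{x:8.3f}{y:8.3f}{z:8.3f}\n")
            bx, by, bz = frame.box / NM_TO_ANGSTROM
            fh.write(f"{bx:10.5f}{by:10.5f}{bz:10.5f}\n")


# ---------------------------------------------------------------------------
# Coordinate wrapping and marker selection
# ---------------------------------------------------------------------------

def wrap_frame(frame: Frame) -> Frame:
    """Return a copy with all coordinates wrapped into [0, L) per axis."""
    if not np.all(np.isfinite(frame.positions)):
        raise ValueError("frame contains non-finite coordinates")
    wrapped = np.mod(frame.positions, frame.box[np.newaxis, :])
    # guard against -1e-16 % L == L due to rounding
    for ax in range(3):
        wrapped[wrapped[:, ax] >= frame.box[ax], ax] = 0.0
    return replace(frame, positions=wrapped)


def select_markers(frame: Frame, species: str,
                   protein_resnames: Iterable[str] = PROTEIN_RESNAMES) -> MarkerSet:
    """Extract one lateral marker point per molecule of ``species``.

    DPPC/DUPC use their PO4 bead, CHOL its ROH bead, and PROTEIN the equal-
    weight centre of mass over all beads of each protein molecule.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    if species == "PROTEIN":
        sel = np.isin(frame.resnames.astype(str), list(protein_resnames))
        if not np.any(sel):
            return MarkerSet(species, np.empty(0, dtype=np.int64), np.empty((0, 3)))
        resids = frame.resids[sel]
        uniq = np.unique(resids)
        coms = np.empty((len(uniq), 3))
        pos = frame.positions[sel]
        for k, rid in enumerate(uniq):
            coms[k] = pos[resids == rid].mean(axis=0)
        return MarkerSet(species, uniq, coms)
    marker = PHOSPHATE_BEAD if species in PHOSPHOLIPID_RESNAMES else HYDROXYL_BEAD
    sel = (frame.resnames.astype(str) == species) & (frame.names.astype(str) == marker)
    resids = frame.resids[sel]
    if len(resids) != len(np.unique(resids)):
        raise ValueError(f"duplicate {marker} markers within one {species} molecule")
    return MarkerSet(species, resids.copy(), frame.positions[sel].copy())


def assign_leaflets(frame: Frame, undulation_fraction: float = 0.05,
                    undulation_margin: float = 5.0) -> LeafletAssignment:
    """Assign every lipid molecule to the upper or lower leaflet.

    The midplane is the mean z of all phospholipid phosphate markers; each
    lipid goes to the side its own marker (PO4 or ROH) lies on.  Frames where
    more than ``undulation_fraction`` of markers fall within
    ``undulation_margin`` Å of the midplane are rejected: a flat midplane is
    then no longer a safe leaflet separator.
    """
    phosphates = [select_markers(frame, sp) for sp in PHOSPHOLIPID_RESNAMES]
    po4_z = np.concatenate([m.positions[:, 2] for m in phosphates])
    if len(po4_z) < 2:
        raise ValueError("need at least two phosphate markers to place a midplane")
    midplane = float(po4_z.mean())

    mapping: dict[int, str] = {}
    all_z = []
    for sp in LIPID_RESNAMES:
        markers = select_markers(frame, sp)
        for rid, z in zip(markers.resids, markers.positions[:, 2]):
            if z == midplane:
                logger.warning("lipid %d marker exactly on midplane; assigned upper", rid)
            mapping[int(rid)] = "upper" if z >= midplane else "lower"
        all_z.append(markers.positions[:, 2])
    z = np.concatenate(all_z)
    near = np.mean(np.abs(z - midplane) < undulation_margin)
    if near > undulation_fraction:
        raise ValueError(
            f"{near:.1%} of lipid markers lie within {undulation_margin} Å of the "
            f"midplane z = {midplane:.1f} Å; the bilayer undulates too much for a "
            "flat-midplane leaflet assignment")
    return LeafletAssignment(mapping=mapping, midplane_z=midplane)


def leaflet_markers(frame: Frame, assignment: LeafletAssignment, species: str,
                    leaflet: str) -> MarkerSet:
    """Markers of one species restricted to one leaflet."""
    markers = select_markers(frame, species)
    keep = np.array([assignment.mapping.get(int(r)) == leaflet for r in markers.resids])
    if len(keep) == 0:
        return markers
    return MarkerSet(species, markers.resids[keep], markers.positions[keep])
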