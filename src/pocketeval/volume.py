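"""Grid-based pocket and chain volumes on a shared 1 Å lattice.

All volumes are sets of points on one *global* lattice (points at integer
multiples of the spacing, anchored at the origin), so intersections and
unions between any two volumes are exact set operations and relative
overlaps need no alignment step.

A pocket volume is computed in the spirit of grid-based cavity tools:

1. take the smallest axis-aligned rectangular prism containing all pocket
   atoms, centred on the pocket centroid (degenerate axes padded +1 Å);
2. enumerate lattice points inside the prism;
3. delete points clashing with protein heavy atoms (within the atom's van
   der Waals radius plus a padding, default 1.09 Å);
4. delete points outside the convex hull of the pocket atoms (points on the
   hull are kept);
5. keep only the contiguous region: the 26-connected lattice component(s)
   reachable from seed points within 5 Å of the pocket centroid.
"""
from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial import Delaunay, QhullError

from .errors import InvariantError
from .model import Atom

log = logging.getLogger(__name__)

DEFAULT_SPACING = 1.0
DEFAULT_CLASH_PADDING = 1.09
DEFAULT_SEED_RADIUS = 5.0
DEGENERATE_PADDING = 1.0


def vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) from gemmi's element table."""
    r = gemmi.Element(element).vdw_r
    return float(r) if r > 0 else 1.7


@dataclass(frozen=True)
class GridVolume:
    """A set of unit-volume lattice points (integer lattice indices)."""

    points: frozenset  # of (i, j, k) integer triples
    spacing: float = DEFAULT_SPACING

    @property
    def volume(self) -> float:
        return len(self.points) * self.spacing**3

    def __len__(self) -> int:
        return len(self.points)

    def union(self, other: "GridVolume") -> "GridVolume":
        self._check_lattice(other)
        return GridVolume(points=self.points | other.points, spacing=self.spacing)

    def intersection(self, other: "GridVolume") -> "GridVolume":
        self._check_lattice(other)
        return GridVolume(points=self.points & other.points, spacing=self.spacing)

    def _check_lattice(self, other: "GridVolume") -> None:
        if self.spacing != other.spacing:
            raise InvariantError("grid volumes live on different lattices")

    def coords(self) -> np.ndarray:
        """Cartesian coordinates of the lattice points."""
        if not self.points:
            return np.empty((0, 3))
        return np.array(sorted(self.points), dtype=float) * self.spacing


@dataclass
class InclusionPrism:
    """Axis-aligned prism centred on the pocket centroid."""

    centre: np.ndarray
    half_extents: np.ndarray

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return np.all(np.abs(pts - self.centre) <= self.half_extents + 1e-9, axis=1)


def _atom_coords(atoms: Sequence[Atom] | np.ndarray) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return atoms.reshape(-1, 3).astype(float)
    return np.array([a.coords for a in atoms if a.is_heavy]).reshape(-1, 3)


def build_inclusion_region(pocket_atoms: Sequence[Atom] | np.ndarray) -> InclusionPrism:
    """Smallest axis-aligned prism containing the pocket atoms.

    Centred on the coordinate mean; each half-extent is half the atom
    spread on that axis.  Axes with (near-)zero spread are padded by
    +1 Å so flat or single-atom pockets still enclose lattice points.
    """
    coords = _atom_coords(pocket_atoms)
    if len(coords) == 0:
        raise InvariantError("inclusion region of an empty atom set")
    centre = coords.mean(axis=0)
    spread = coords.max(axis=0) - coords.min(axis=0)
    half = spread / 2.0
    half[half < 1e-9] += DEGENERATE_PADDING
    return InclusionPrism(centre=centre, half_extents=half)


def _lattice_points_in_box(
    lo: np.ndarray, hi: np.ndarray, spacing: float
) -> np.ndarray:
    idx_lo = np.ceil(lo / spacing - 1e-9).astype(int)
    idx_hi = np.floor(hi / spacing + 1e-9).astype(int)
    if np.any(idx_hi < idx_lo):
        return np.empty((0, 3), dtype=int)
    axes = [np.arange(idx_lo[d], idx_hi[d] + 1) for d in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    return grid


def _remove_clashes(
    lattice_idx: np.ndarray,
    protein_atoms: Sequence[Atom],
    spacing: float,
    padding: float,
) -> np.ndarray:
    if len(lattice_idx) == 0 or not protein_atoms:
        return lattice_idx
    pts = lattice_idx.astype(float) * spacing
    keep = np.ones(len(pts), dtype=bool)
    for a in protein_atoms:
        if not a.is_heavy:
            continue
        limit = vdw_radius(a.element) + padding
        d = np.linalg.norm(pts - a.coords, axis=1)
        keep &= d >= limit
    return lattice_idx[keep]


def _inside_hull(pts: np.ndarray, hull_points: np.ndarray) -> np.ndarray:
    """Inclusive point-in-convex-hull test; degenerate hulls keep all points."""
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    try:
        tri = Delaunay(hull_points)
    except (QhullError, ValueError):
        # < 4 non-coplanar pocket atoms: hull filter not applicable
        return np.ones(len(pts), dtype=bool)
    return tri.find_simplex(pts, tol=1e-9) >= 0


def _connected_to_seeds(
    lattice_idx: np.ndarray, seeds: np.ndarray
) -> np.ndarray:
    """26-connectivity BFS from the seed points over the kept lattice points."""
    if len(lattice_idx) == 0 or len(seeds) == 0:
        return np.empty((0, 3), dtype=int)
    available = {tuple(p) for p in lattice_idx}
    frontier = deque(tuple(p) for p in seeds if tuple(p) in available)
    reached = set(frontier)
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    while frontier:
        x, y, z = frontier.popleft()
        for dx, dy, dz in offsets:
            nb = (x + dx, y + dy, z + dz)
            if nb in available and nb not in reached:
                reached.add(nb)
                frontier.append(nb)
    return np.array(sorted(reached), dtype=int).reshape(len(reached), 3)


def pocket_volume(
    protein_atoms: Sequence[Atom],
    pocket_atoms: Sequence[Atom] | np.ndarray,
    centroid: Optional[np.ndarray] = None,
    spacing: float = DEFAULT_SPACING,
    clash_padding: float = DEFAULT_CLASH_PADDING,
    seed_radius: float = DEFAULT_SEED_RADIUS,
) -> GridVolume:
    """Grid volume of a pocket defined by its atoms, on the global lattice.

    ``protein_atoms`` are the chain heavy atoms used for clash removal (may
    be empty); ``centroid`` defaults to the pocket atoms' coordinate mean.
    An empty result (fully occluded or unreachable pocket) returns an empty
    GridVolume with a warning.
    """
    pocket_coords = _atom_coords(pocket_atoms)
    if len(pocket_coords) == 0:
        raise InvariantError("pocket volume of an empty atom set")
    if centroid is None:
        centroid = pocket_coords.mean(axis=0)
    centroid = np.asarray(centroid, dtype=float)
    prism = build_inclusion_region(pocket_coords)
    prism = InclusionPrism(centre=centroid, half_extents=prism.half_extents)
    lattice = _lattice_points_in_box(
        prism.centre - prism.half_extents, prism.centre + prism.half_extents, spacing
    )
    lattice = _remove_clashes(lattice, list(protein_atoms), spacing, clash_padding)
    if len(lattice):
        inside = _inside_hull(lattice.astype(float) * spacing, pocket_coords)
        lattice = lattice[inside]
    if len(lattice):
        pts = lattice.astype(float) * spacing
        seed_mask = np.linalg.norm(pts - centroid, axis=1) <= seed_radius
        lattice = _connected_to_seeds(lattice, lattice[seed_mask])
    if len(lattice) == 0:
        log.warning("pocket volume is empty (occluded or no seed points)")
        return GridVolume(points=frozenset(), spacing=spacing)
    return GridVolume(
        points=frozenset(map(tuple, lattice.tolist())), spacing=spacing
    )


def chain_grid_volume(
    atoms: Sequence[Atom],
    spacing: float = DEFAULT_SPACING,
) -> GridVolume:
    """Occupied-volume grid for a chain: lattice points within the van der
    Waals radius of any heavy atom."""
    coords = _atom_coords(atoms)
    if len(coords) == 0:
        raise InvariantError("chain volume of an empty atom set")
    radii = np.array([vdw_radius(a.element) for a in atoms if a.is_heavy])
    rmax = float(radii.max())
    lattice = _lattice_points_in_box(
        coords.min(axis=0) - rmax, coords.max(axis=0) + rmax, spacing
    )
    pts = lattice.astype(float) * spacing
    occupied = np.zeros(len(pts), dtype=bool)
    for c, r in zip(coords, radii):
        occupied |= np.linalg.norm(pts - c, axis=1) <= r
    kept = lattice[occupied]
    return GridVolume(points=frozenset(map(tuple, kept.tolist())), spacing=spacing)


def relative_volume_overlap(pred: GridVolume, obs: GridVolume) -> Optional[float]:
    """RVO = |pred ∩ obs| / |obs| on the shared lattice.

    Undefined (None) when the observed volume is empty; callers exclude
    such pairs from means.
    """
    if pred.spacing != obs.spacing:
        raise InvariantError("volumes live on different lattices")
    if len(obs) == 0:
        return None
    return len(pred.points & obs.points) / len(obs.points)


def write_grid_pdb(grid: GridVolume, path) -> None:
    """Dump lattice points as dummy HETATM records for visual inspection."""
    lines = []
    for i, (x, y, z) in enumerate(grid.coords(), start=1):
        lines.append(
            f"HETATM{i:5d}  O   GRD A{min(i, 9999):4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           O"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
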