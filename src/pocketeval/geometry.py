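"""Chain alignment on principal axes and size/shape descriptors.

A chain is centred on its (unweighted, heavy-atom) centre of mass and
rotated so that the largest principal component of the coordinates lies on
the Y axis (height), the second on X (width) and their cross product on Z
(depth).  Building the rotation from rows (pc2, pc1, pc1 × pc2) gives a
determinant of −1; multiplying by the negative identity restores a proper
rotation (det +1), so chain chirality is preserved.

Size descriptors: radius of gyration Rg = sqrt(mean ||r_i − CM||²); the
CM-centred enclosing sphere with R = max ||r_i − CM|| and volume 4/3 π R³;
and the volume ratio VR = chain grid volume / sphere volume.  Chains with
VR ≤ 0.08 are classified elongated, otherwise globular; chains of ≤ 100
residues get an additional "tiny" label.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvariantError
from .model import Atom, Chain

VR_THRESHOLD = 0.08
TINY_THRESHOLD = 100

SHAPE_CLASSES = ("globular", "elongated", "globular-tiny", "elongated-tiny")


@dataclass
class AlignmentFrame:
    """Principal-axis frame of a chain: P rows are (pc2, pc1, pc_perp)."""

    pc1: np.ndarray
    pc2: np.ndarray
    pc_perp: np.ndarray
    P: np.ndarray
    R: np.ndarray
    cm: np.ndarray


@dataclass
class ChainDescriptors:
    cm: np.ndarray
    rg: float
    sphere_radius: float
    sphere_volume: float
    chain_volume: float
    volume_ratio: float
    width: float
    height: float
    depth: float
    shape_class: Optional[str]


def _coords(atoms: Sequence[Atom] | np.ndarray) -> np.ndarray:
    if isinstance(atoms, np.ndarray):
        return atoms.reshape(-1, 3).astype(float)
    return np.array([a.coords for a in atoms if a.is_heavy]).reshape(-1, 3)


def centre_of_mass(atoms: Sequence[Atom] | np.ndarray) -> np.ndarray:
    """Unweighted mean of heavy-atom coordinates."""
    coords = _coords(atoms)
    if len(coords) == 0:
        raise InvariantError("centre of mass of an empty atom set")
    return coords.mean(axis=0)


def _fix_sign(v: np.ndarray) -> np.ndarray:
    # PCA eigenvector signs are arbitrary; pin the largest-magnitude entry positive
    idx = int(np.argmax(np.abs(v)))
    return -v if v[idx] < 0 else v


def principal_alignment(
    atoms: Sequence[Atom] | np.ndarray,
) -> tuple[AlignmentFrame, np.ndarray]:
    """Align coordinates on principal axes (Y = major, X = second, Z = depth).

    Returns the frame and the transformed coordinates.  The rotation is a
    proper rotation (det +1), distances are preserved, and the output
    covariance is diagonal with var(Y) >= var(X) >= var(Z).
    """
    coords = _coords(atoms)
    if len(coords) < 3:
        raise DegenerateGeometryError("principal alignment needs >= 3 atoms")
    cm = coords.mean(axis=0)
    centred = coords - cm
    cov = np.cov(centred.T)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    if eigvals[1] <= 1e-12 * max(eigvals[0], 1.0):
        raise DegenerateGeometryError("coordinates are collinear (rank < 2)")
    pc1 = _fix_sign(eigvecs[:, order[0]])
    pc2 = _fix_sign(eigvecs[:, order[1]])
    pc_perp = np.cross(pc1, pc2)
    P = np.vstack([pc2, pc1, pc_perp])
    R = P @ (-np.eye(3))
    frame = AlignmentFrame(pc1=pc1, pc2=pc2, pc_perp=pc_perp, P=P, R=R, cm=cm)
    transformed = centred @ R.T
    return frame, transformed


def radius_of_gyration(atoms: Sequence[Atom] | np.ndarray) -> float:
    """Rg = sqrt(mean squared heavy-atom distance to the centre of mass)."""
    coords = _coords(atoms)
    if len(coords) == 0:
        raise InvariantError("radius of gyration of an empty atom set")
    centred = coords - coords.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum(centred**2, axis=1))))


def enclosing_sphere(
    atoms: Sequence[Atom] | np.ndarray, cm: Optional[np.ndarray] = None
) -> tuple[float, float]:
    """CM-centred enclosing sphere: R = max distance to CM, volume 4/3 π R³.

    This is deliberately the sphere centred on the centre of mass, not the
    minimal enclosing sphere.
    """
    coords = _coords(atoms)
    if len(coords) == 0:
        raise InvariantError("enclosing sphere of an empty atom set")
    if cm is None:
        cm = coords.mean(axis=0)
    radius = float(np.max(np.linalg.norm(coords - np.asarray(cm, dtype=float), axis=1)))
    volume = (4.0 / 3.0) * np.pi * radius**3
    return radius, float(volume)


def classify_shape(
    chain_length: int,
    vr: float,
    vr_threshold: float = VR_THRESHOLD,
    tiny_threshold: int = TINY_THRESHOLD,
) -> str:
    """Four-way shape/size label: {globular, elongated} × {tiny, not}.

    Both thresholds are inclusive: VR exactly at the threshold is elongated
    and a chain of exactly ``tiny_threshold`` residues is tiny.
    """
    if not (0.0 < vr <= 1.0):
        raise InvariantError(f"volume ratio {vr} outside (0, 1]")
    if chain_length < 1:
        raise InvariantError("chain length must be >= 1")
    elongated = vr <= vr_threshold
    tiny = chain_length <= tiny_threshold
    label = "elongated" if elongated else "globular"
    return f"{label}-tiny" if tiny else label


def characterise_chain(
    chain: Chain,
    grid_spacing: float = 1.0,
) -> ChainDescriptors:
    """Full per-chain descriptor set, tolerant of degenerate chains.

    The chain volume is computed with the shared grid engine (lattice points
    within the van der Waals radius of any heavy atom).  Chains with fewer
    than 3 non-collinear atoms are reported unclassified (shape_class None)
    instead of failing the pipeline.
    """
    from .volume import chain_grid_volume

    atoms = chain.heavy_atoms()
    coords = _coords(atoms)
    cm = coords.mean(axis=0)
    rg = radius_of_gyration(coords)
    sphere_r, sphere_v = enclosing_sphere(coords, cm)
    grid = chain_grid_volume(atoms, spacing=grid_spacing)
    chain_v = grid.volume
    width = height = depth = float("nan")
    shape: Optional[str] = None
    try:
        _, transformed = principal_alignment(coords)
        var = transformed.var(axis=0)
        width, height, depth = (float(np.sqrt(v)) for v in var)
        if sphere_v > 0 and chain_v > 0:
            vr = min(chain_v / sphere_v, 1.0)
            shape = classify_shape(len(chain), vr)
        else:
            vr = float("nan")
    except DegenerateGeometryError:
        vr = float("nan")
    return ChainDescriptors(
        cm=cm,
        rg=rg,
        sphere_radius=sphere_r,
        sphere_volume=sphere_v,
        chain_volume=chain_v,
        volume_ratio=vr if np.isfinite(vr) else float("nan"),
        width=width,
        height=height,
        depth=depth,
        shape_class=shape,
    )
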