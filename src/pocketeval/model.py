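"""Domain types shared across the package.

Identity convention: everywhere downstream of I/O, residues are identified
by their UniProt sequence number.  Author (PDB) numbering is retained on
:class:`Residue` purely for reporting.  All coordinates are in Angstrom,
right-handed, exactly as stored in the source file.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np

from .errors import InvariantError

#: A ligand interaction fingerprint: the set of UniProt residue numbers the
#: ligand's heavy atoms contact.  Plain frozenset so set algebra stays cheap.
Fingerprint = frozenset


def validate_fingerprint(fp: frozenset) -> frozenset:
    """Check fingerprint invariants: non-empty, all members integers >= 1."""
    if not fp:
        raise InvariantError("fingerprint must be non-empty")
    for r in fp:
        if not isinstance(r, (int, np.integer)) or r < 1:
            raise InvariantError(f"fingerprint member {r!r} is not an integer >= 1")
    return frozenset(int(r) for r in fp)


_HYDROGENS = {"H", "D", "T"}


@dataclass
class Atom:
    """One atom: element, position and a link back to its residue."""

    element: str
    coords: np.ndarray
    residue_id: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise InvariantError("atom coordinates must be a 3-vector")
        if not np.all(np.isfinite(self.coords)):
            raise InvariantError("atom coordinates must be finite")
        if not self.element:
            raise InvariantError("atom element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in _HYDROGENS


@dataclass
class Residue:
    """A polymer residue with author identity and optional UniProt number."""

    auth_seq_id: int
    name: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""
    uniprot_num: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.atoms:
            raise InvariantError(
                f"residue {self.name} {self.auth_id} has no atoms"
            )
        if self.uniprot_num is not None and self.uniprot_num < 1:
            raise InvariantError("UniProt residue numbers start at 1")

    @property
    def auth_id(self) -> str:
        return f"{self.auth_seq_id}{self.icode}".strip()

    def heavy_atoms(self) -> Iterator[Atom]:
        return (a for a in self.atoms if a.is_heavy)

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(len(coords), 3)


@dataclass
class Chain:
    """An ordered protein chain from one structure."""

    structure_id: str
    chain_id: str
    residues: list[Residue] = field(default_factory=list)
    uniprot_acc: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise InvariantError(f"chain {self.chain_id} has no residues")
        seen: set[str] = set()
        for res in self.residues:
            if res.auth_id in seen:
                raise InvariantError(
                    f"duplicate residue identifier {res.auth_id} in chain {self.chain_id}"
                )
            seen.add(res.auth_id)
        up_seen: set[int] = set()
        for res in self.residues:
            if res.uniprot_num is not None:
                if res.uniprot_num in up_seen:
                    raise InvariantError(
                        f"duplicate UniProt number {res.uniprot_num} in chain {self.chain_id}"
                    )
                up_seen.add(res.uniprot_num)

    def __len__(self) -> int:
        return len(self.residues)

    def by_uniprot(self) -> dict[int, Residue]:
        """Map UniProt residue number -> residue (mapped residues only)."""
        return {r.uniprot_num: r for r in self.residues if r.uniprot_num is not None}

    def heavy_coords(self) -> np.ndarray:
        blocks = [r.heavy_coords() for r in self.residues]
        blocks = [b for b in blocks if len(b)]
        if not blocks:
            return np.empty((0, 3))
        return np.vstack(blocks)

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms()]


@dataclass
class LigandInstance:
    """One observed ligand molecule: heavy atoms plus its contact fingerprint."""

    structure_id: str
    ccd_code: str
    instance_id: str
    atoms: list[Atom] = field(default_factory=list)
    fingerprint: Optional[frozenset] = None

    def heavy_coords(self) -> np.ndarray:
        coords = [a.coords for a in self.atoms if a.is_heavy]
        return np.array(coords, dtype=float).reshape(len(coords), 3)

    @property
    def ligand_id(self) -> str:
        """Dataset-overlap identifier string: ``<entry>_<CCD code>``."""
        return f"{self.structure_id}_{self.ccd_code}"


@dataclass
class PocketPrediction:
    """One predicted pocket as reported (or derived) for a single method.

    At least one of ``centroid``, ``residues`` or ``points`` must be present;
    missing score/rank are stored as ``None`` (some methods report neither).
    """

    method: str
    chain_id: str
    pocket_id: str = ""
    rank: Optional[int] = None
    score: Optional[float] = None
    centroid: Optional[np.ndarray] = None
    residues: Optional[frozenset] = None
    points: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.centroid is not None:
            self.centroid = np.asarray(self.centroid, dtype=float)
            if self.centroid.shape != (3,):
                raise InvariantError("pocket centroid must be a 3-vector")
        if self.points is not None:
            self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.residues is not None:
            self.residues = frozenset(int(r) for r in self.residues)
        if self.centroid is None and self.residues is None and self.points is None:
            raise InvariantError(
                "pocket prediction needs a centroid, residue set or point cloud"
            )
        if self.rank is not None and self.rank < 1:
            raise InvariantError("pocket rank must be >= 1")
        if self.score is not None and not math.isfinite(self.score):
            raise InvariantError("pocket score must be finite")


@dataclass
class ResidueScoreTrack:
    """Per-residue ligandability scores for one chain."""

    chain_id: str
    scores: dict[int, float] = field(default_factory=dict)
    probability_like: bool = True

    def __post_init__(self) -> None:
        for res, s in self.scores.items():
            if not math.isfinite(s):
                raise InvariantError(f"score for residue {res} is not finite")
            if self.probability_like and not (0.0 <= s <= 1.0):
                raise InvariantError(
                    f"probability-type score for residue {res} outside [0, 1]: {s}"
                )

    def __getitem__(self, residue: int) -> float:
        return self.scores[residue]

    def get(self, residue: int, default: float = 0.0) -> float:
        return self.scores.get(residue, default)

    def __len__(self) -> int:
        return len(self.scores)


def as_mapping(track: "ResidueScoreTrack | Mapping[int, float]") -> Mapping[int, float]:
    if isinstance(track, ResidueScoreTrack):
        return track.scores
    return track
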