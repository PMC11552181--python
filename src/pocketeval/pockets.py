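"""Predicted-pocket characterisation and redundancy removal.

Two predicted pockets on one chain are *redundant* when their centroids lie
within 5 Å of each other or their residue sets share a Jaccard index of at
least 0.75.  Redundant duplicates of a real site inflate pocket-level
precision and depress window-limited recall, so the evaluation offers a
greedy removal: sweep pockets in descending score order, keep a pocket only
if it is not redundant with an already-kept one, then re-rank the survivors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InvariantError
from .geometry import radius_of_gyration
from .model import Chain, PocketPrediction

log = logging.getLogger(__name__)

DEFAULT_DIST_THRESHOLD = 5.0
DEFAULT_JI_THRESHOLD = 0.75
DEFAULT_POINT_CUTOFF = 6.0


@dataclass
class PocketStats:
    """Per-pocket geometry summary within one chain."""

    pocket_id: str
    centroid: np.ndarray
    rg: float
    n_residues: int
    mcd: Optional[float] = None  # min centroid distance to any other pocket
    mro: Optional[float] = None  # max Jaccard overlap with any other pocket
    singleton: bool = False


@dataclass
class RedundancyReport:
    kept: list[PocketPrediction]
    dropped: list[tuple[PocketPrediction, PocketPrediction]] = field(default_factory=list)

    @property
    def redundancy_fraction(self) -> float:
        total = len(self.kept) + len(self.dropped)
        return len(self.dropped) / total if total else 0.0


def residues_near_points(
    chain: Chain,
    points: np.ndarray,
    cutoff: float = DEFAULT_POINT_CUTOFF,
) -> tuple[frozenset, bool]:
    """Residues with any heavy atom within ``cutoff`` Å of any query point.

    Returns (residue set in UniProt numbering, empty-result flag).  An empty
    result is legitimate — some predicted centroids sit too far from the
    chain — and is flagged rather than raised.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(pts) == 0:
        raise InvariantError("residues_near_points needs at least one point")
    found: set[int] = set()
    for res in chain.residues:
        if res.uniprot_num is None:
            continue
        coords = res.heavy_coords()
        if len(coords) and np.min(cdist(coords, pts)) <= cutoff:
            found.add(res.uniprot_num)
    empty = not found
    if empty:
        log.warning("no residues within %.1f Å of the query points", cutoff)
    return frozenset(found), empty


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """Jaccard index |A ∩ B| / |A ∪ B|; two empty sets give 0 by convention
    (so empty pockets are never redundant by overlap alone)."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def pocket_centroid(pocket: PocketPrediction, chain: Optional[Chain] = None) -> np.ndarray:
    """Centroid of a prediction, derived if the method did not report one.

    Point-cloud pockets use the mean of their points; residues-only pockets
    the mean of the pocket-residue heavy atoms on the chain.
    """
    if pocket.centroid is not None:
        return pocket.centroid
    if pocket.points is not None and len(pocket.points):
        return pocket.points.mean(axis=0)
    if pocket.residues and chain is not None:
        by_up = chain.by_uniprot()
        coords = [
            by_up[r].heavy_coords() for r in sorted(pocket.residues) if r in by_up
        ]
        coords = [c for c in coords if len(c)]
        if coords:
            return np.vstack(coords).mean(axis=0)
    raise InvariantError(f"cannot derive a centroid for pocket {pocket.pocket_id!r}")


def pocket_residues(
    pocket: PocketPrediction,
    chain: Optional[Chain] = None,
    cutoff: float = DEFAULT_POINT_CUTOFF,
) -> frozenset:
    """Residue set of a prediction, derived from its points/centroid if absent."""
    if pocket.residues is not None:
        return pocket.residues
    if chain is None:
        raise InvariantError(
            f"pocket {pocket.pocket_id!r} has no residues and no chain was given"
        )
    source = pocket.points if pocket.points is not None else pocket.centroid.reshape(1, 3)
    residues, _ = residues_near_points(chain, source, cutoff=cutoff)
    return residues


def pocket_pairwise_stats(
    pockets: Sequence[PocketPrediction],
    chain: Optional[Chain] = None,
    cutoff: float = DEFAULT_POINT_CUTOFF,
) -> list[PocketStats]:
    """Rg, minimum centroid distance (MCD) and maximum residue overlap (MRO)
    per pocket.  On a single-pocket chain MCD and MRO are absent, never zero.
    """
    centroids = [pocket_centroid(p, chain) for p in pockets]
    residue_sets = []
    for p in pockets:
        try:
            residue_sets.append(pocket_residues(p, chain, cutoff=cutoff))
        except InvariantError:
            residue_sets.append(frozenset())
    stats: list[PocketStats] = []
    for i, p in enumerate(pockets):
        rg = 0.0
        if chain is not None and residue_sets[i]:
            by_up = chain.by_uniprot()
            coords = [
                by_up[r].heavy_coords() for r in sorted(residue_sets[i]) if r in by_up
            ]
            coords = [c for c in coords if len(c)]
            if coords:
                rg = radius_of_gyration(np.vstack(coords))
        mcd = mro = None
        if len(pockets) > 1:
            mcd = min(
                float(np.linalg.norm(centroids[i] - centroids[j]))
                for j in range(len(pockets))
                if j != i
            )
            mro = max(
                jaccard(residue_sets[i], residue_sets[j])
                for j in range(len(pockets))
                if j != i
            )
        stats.append(
            PocketStats(
                pocket_id=p.pocket_id or f"{p.method}_{i}",
                centroid=centroids[i],
                rg=rg,
                n_residues=len(residue_sets[i]),
                mcd=mcd,
                mro=mro,
                singleton=len(residue_sets[i]) == 1,
            )
        )
    return stats


def _is_redundant_pair(
    ci: np.ndarray,
    cj: np.ndarray,
    ri: frozenset,
    rj: frozenset,
    dist_threshold: float,
    ji_threshold: float,
) -> bool:
    if float(np.linalg.norm(ci - cj)) <= dist_threshold:
        return True
    return jaccard(ri, rj) >= ji_threshold


def remove_redundancy(
    pockets: Sequence[PocketPrediction],
    chain: Optional[Chain] = None,
    dist_threshold: float = DEFAULT_DIST_THRESHOLD,
    ji_threshold: float = DEFAULT_JI_THRESHOLD,
) -> RedundancyReport:
    """Greedy redundancy removal, always keeping the higher-scoring pocket.

    Pockets are swept in descending score order (ties broken by original
    rank, then pocket id); a pocket is kept iff it is not redundant with any
    already-kept pocket.  Survivors are re-ranked 1..k in sweep order.
    Unscored inputs fall back to rank order as the score proxy (warned).
    """
    if not pockets:
        return RedundancyReport(kept=[])
    if any(p.score is None for p in pockets):
        log.warning("unscored pocket(s): using rank order as score proxy")

    def sweep_key(item):
        idx, p = item
        score = p.score if p.score is not None else -(p.rank if p.rank else idx + 1)
        return (-score, p.rank if p.rank is not None else idx + 1, p.pocket_id, idx)

    ordered = sorted(enumerate(pockets), key=sweep_key)
    centroids = {i: pocket_centroid(p, chain) for i, p in enumerate(pockets)}
    residue_sets = {}
    for i, p in enumerate(pockets):
        try:
            residue_sets[i] = pocket_residues(p, chain)
        except InvariantError:
            residue_sets[i] = frozenset()

    kept_idx: list[int] = []
    report = RedundancyReport(kept=[])
    for idx, p in ordered:
        duplicate_of = None
        for k in kept_idx:
            if _is_redundant_pair(
                centroids[idx],
                centroids[k],
                residue_sets[idx],
                residue_sets[k],
                dist_threshold,
                ji_threshold,
            ):
                duplicate_of = k
                break
        if duplicate_of is None:
            kept_idx.append(idx)
        else:
            report.dropped.append((p, pockets[duplicate_of]))

    for new_rank, idx in enumerate(kept_idx, start=1):
        p = pockets[idx]
        report.kept.append(
            PocketPrediction(
                method=p.method,
                chain_id=p.chain_id,
                pocket_id=p.pocket_id,
                rank=new_rank,
                score=p.score,
                centroid=p.centroid,
                residues=p.residues,
                points=p.points,
            )
        )
    return report
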