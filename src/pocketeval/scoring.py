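"""Residue ligandability scores and pocket (re-)scoring schemes.

Residue-level: an ensemble ligandability score LS is the arithmetic mean of
the per-model binding probabilities of a residue; atom-scored methods
collapse to residue scores by taking the maximum over the residue's atoms.

Pocket-level schemes:

* ``aa_count``   — number of pocket residues (larger pockets rank higher);
* ``ss_residue`` — sum of squared residue ligandability scores over the
  pocket's residues;
* ``ss_grid``    — the same sum of squares over grid/cloud-point scores;
* ``native``     — the method's own scores and ranks, passed through.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .errors import InvariantError
from .model import PocketPrediction, ResidueScoreTrack, as_mapping

log = logging.getLogger(__name__)

SCHEMES = ("aa_count", "ss_residue", "ss_grid", "native")

DEFAULT_ENSEMBLE_SIZE = 40


@dataclass
class PocketScore:
    pocket_id: str
    scheme: str
    value: float
    rank: Optional[int] = None


def ensemble_ligandability(
    ensemble: Mapping[int, Sequence[float]] | np.ndarray,
    residues: Optional[Sequence[int]] = None,
    ensemble_size: int = DEFAULT_ENSEMBLE_SIZE,
    chain_id: str = "",
) -> ResidueScoreTrack:
    """Mean of per-model binding probabilities, per residue.

    ``ensemble`` is either a residue -> probabilities mapping or an
    (n_residues, ensemble_size) matrix accompanied by ``residues`` giving
    the row order.  Every residue must carry exactly ``ensemble_size``
    probabilities in [0, 1].
    """
    if isinstance(ensemble, np.ndarray):
        if residues is None:
            raise InvariantError("matrix input needs the residue row order")
        if ensemble.shape != (len(residues), ensemble_size):
            raise InvariantError(
                f"expected a {len(residues)}x{ensemble_size} matrix, "
                f"got {ensemble.shape}"
            )
        items = zip(residues, ensemble)
    else:
        items = ensemble.items()
    scores: dict[int, float] = {}
    for res, probs in items:
        probs = np.asarray(probs, dtype=float)
        if probs.shape != (ensemble_size,):
            raise InvariantError(
                f"residue {res}: expected {ensemble_size} probabilities, "
                f"got {probs.shape}"
            )
        if np.any(probs < 0) or np.any(probs > 1):
            raise InvariantError(f"residue {res}: probabilities outside [0, 1]")
        scores[int(res)] = float(probs.mean())
    return ResidueScoreTrack(chain_id=chain_id, scores=scores, probability_like=True)


def residue_score_from_atoms(
    atom_scores: Mapping[str, Mapping[str, float]] | Mapping[int, Sequence[float]],
) -> dict:
    """Residue score = max over its atoms' scores.

    Accepts residue -> {atom name: score} or residue -> [scores].
    """
    out = {}
    for res, scores in atom_scores.items():
        values = list(scores.values()) if isinstance(scores, Mapping) else list(scores)
        if not values:
            raise InvariantError(f"residue {res}: no scored atoms")
        out[res] = float(max(values))
    return out


def sum_squares_score(
    pocket: PocketPrediction,
    scores: ResidueScoreTrack | Mapping[int, float] | Sequence[float],
    mode: str = "residue",
) -> PocketScore:
    """Sum of squared ligandability scores over the pocket's members.

    ``mode="residue"`` sums over the pocket's residue set using the score
    track (residues missing a score contribute 0, logged); ``mode="grid"``
    sums over an explicit sequence of grid/cloud-point scores.
    """
    if mode == "grid":
        values = np.asarray(list(scores), dtype=float)
        ss = float(np.sum(values**2))
        return PocketScore(pocket_id=pocket.pocket_id, scheme="ss_grid", value=ss)
    if pocket.residues is None:
        raise InvariantError(
            f"pocket {pocket.pocket_id!r} has no residue set for residue-mode scoring"
        )
    mapping = as_mapping(scores)
    missing = [r for r in pocket.residues if r not in mapping]
    if missing:
        log.warning(
            "pocket %s: %d residue(s) without a ligandability score contribute 0",
            pocket.pocket_id,
            len(missing),
        )
    ss = float(sum(mapping.get(r, 0.0) ** 2 for r in pocket.residues))
    return PocketScore(pocket_id=pocket.pocket_id, scheme="ss_residue", value=ss)


def _scheme_value(
    pocket: PocketPrediction,
    scheme: str,
    scores: Optional[ResidueScoreTrack | Mapping[int, float]],
    grid_scores: Optional[Mapping[str, Sequence[float]]],
) -> float:
    if scheme == "aa_count":
        if pocket.residues is None:
            raise InvariantError(
                f"pocket {pocket.pocket_id!r} has no residues for aa_count"
            )
        return float(len(pocket.residues))
    if scheme == "ss_residue":
        if scores is None:
            raise InvariantError("ss_residue scheme needs a residue score track")
        return sum_squares_score(pocket, scores, mode="residue").value
    if scheme == "ss_grid":
        if grid_scores is None or pocket.pocket_id not in grid_scores:
            raise InvariantError(
                f"ss_grid scheme: no grid scores for pocket {pocket.pocket_id!r}"
            )
        return sum_squares_score(
            pocket, grid_scores[pocket.pocket_id], mode="grid"
        ).value
    if scheme == "native":
        if pocket.score is None:
            raise InvariantError(
                f"native scheme: pocket {pocket.pocket_id!r} has no score"
            )
        return float(pocket.score)
    raise InvariantError(f"unknown scoring scheme {scheme!r}")


def rerank(
    pockets: Sequence[PocketPrediction],
    scheme: str = "native",
    scores: Optional[ResidueScoreTrack | Mapping[int, float]] = None,
    grid_scores: Optional[Mapping[str, Sequence[float]]] = None,
) -> list[PocketPrediction]:
    """Re-score and re-rank pockets under a scheme; ranks become 1..n.

    Sorting is by descending score with stable ties broken by original rank
    then pocket id, so re-ranking is idempotent.  ``native`` keeps the
    method-reported scores but still normalises ranks to 1..n.
    """
    values = [_scheme_value(p, scheme, scores, grid_scores) for p in pockets]

    def key(item):
        idx, (p, v) = item
        return (-v, p.rank if p.rank is not None else idx + 1, p.pocket_id, idx)

    ordered = sorted(enumerate(zip(pockets, values)), key=key)
    out: list[PocketPrediction] = []
    for new_rank, (idx, (p, v)) in enumerate(ordered, start=1):
        out.append(
            PocketPrediction(
                method=p.method,
                chain_id=p.chain_id,
                pocket_id=p.pocket_id,
                rank=new_rank,
                score=v,
                centroid=p.centroid,
                residues=p.residues,
                points=p.points,
            )
        )
    return out
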