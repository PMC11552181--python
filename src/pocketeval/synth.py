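"""Deterministic synthetic fixtures: toy chains with planted ligand sites
and prediction sets with controlled correctness, redundancy and score
quality.

The chain backbone is laid on an ideal helix (rise 1.5 Å and radius 2.3 Å
per residue step, 100° twist) with one CA and one outward CB pseudo-atom
per residue — enough geometry for contacts, centroids, alignment and grid
volumes while staying closed-form and bit-reproducible.  Disjoint residue
windows are designated as binding sites and a pseudo-ligand atom is placed
just outside each site residue's CB, so the derived contact fingerprints
recover exactly the planted windows.

Prediction sets are built with guaranteed margins: "correct" predictions
are placed within half the DCC correctness threshold of a site centroid,
"false" ones on the helix-axis extension at more than twice the threshold
from every site, and "redundant" ones within 2 Å of a correct prediction
with strictly lower scores.  Score models: ``calibrated`` (correct scores
drawn above false ones, overlap controlled by ``score_separation``),
``anti_correlated`` (reversed) and ``constant`` (uninformative).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import InvariantError
from .model import Atom, Chain, LigandInstance, PocketPrediction, Residue
from .sites import (
    DEFAULT_CONTACT_CUTOFF,
    BindingSite,
    compute_contacts,
    site_centroid,
)

HELIX_RISE = 1.5
HELIX_RADIUS = 2.3
HELIX_TWIST_DEG = 100.0
CB_OFFSET = 1.5
LIGAND_OFFSET = 1.2

SCORE_MODELS = ("calibrated", "anti_correlated", "constant")


@dataclass
class FixtureSpec:
    """Parameters of one synthetic protein/prediction fixture."""

    seed: int = 0
    chain_length: int = 100
    n_sites: int = 3
    residues_per_site: int = 8
    ligand_jitter: float = 0.25
    n_correct: int = 3
    n_redundant: int = 0
    n_false: int = 2
    centroid_noise: float = 2.0
    score_model: str = "calibrated"
    score_separation: float = 0.4
    dcc_threshold: float = 12.0

    def __post_init__(self) -> None:
        if self.score_model not in SCORE_MODELS:
            raise InvariantError(f"unknown score model {self.score_model!r}")
        for name in ("n_correct", "n_redundant", "n_false"):
            if getattr(self, name) < 0:
                raise InvariantError(f"{name} must be >= 0")
        if self.ligand_jitter < 0:
            raise InvariantError("ligand jitter must be >= 0")
        if self.chain_length < self.n_sites * self.residues_per_site:
            raise InvariantError(
                "chain too short for the requested sites "
                f"({self.chain_length} < {self.n_sites} x {self.residues_per_site})"
            )


def _helix_position(i: int) -> tuple[np.ndarray, np.ndarray]:
    """CA position and outward radial unit vector of residue index i (0-based)."""
    theta = np.deg2rad(HELIX_TWIST_DEG) * i
    radial = np.array([np.cos(theta), np.sin(theta), 0.0])
    ca = HELIX_RADIUS * radial + np.array([0.0, 0.0, HELIX_RISE * i])
    return ca, radial


def _site_windows(spec: FixtureSpec) -> list[range]:
    k, w = spec.n_sites, spec.residues_per_site
    slack = spec.chain_length - k * w
    gap = slack // (k + 1)
    windows = []
    start = gap
    for _ in range(k):
        windows.append(range(start, start + w))
        start += w + max(gap, 2)  # >= 2-residue separation keeps fingerprints disjoint
    if windows and windows[-1][-1] >= spec.chain_length:
        raise InvariantError("site windows do not fit on the chain")
    return windows


def make_chain_with_sites(
    spec: FixtureSpec,
) -> tuple[Chain, list[BindingSite], list[LigandInstance]]:
    """Build a helix chain, its planted binding sites and pseudo-ligands.

    Residue i (1-based UniProt number i) carries a CA and a CB atom.  Each
    site window gets one pseudo-ligand with a heavy atom just outside every
    window residue's CB (plus Gaussian jitter), so its contact fingerprint
    (4.5 Å heavy-atom cutoff) equals the window exactly at zero jitter and
    stays within it for small jitter.  Same spec -> bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    residues = []
    for i in range(spec.chain_length):
        ca, radial = _helix_position(i)
        cb = ca + CB_OFFSET * radial
        residues.append(
            Residue(
                auth_seq_id=i + 1,
                name="ALA",
                atoms=[
                    Atom(element="C", coords=ca, name="CA", residue_id=f"A/{i + 1}"),
                    Atom(element="C", coords=cb, name="CB", residue_id=f"A/{i + 1}"),
                ],
                uniprot_num=i + 1,
            )
        )
    chain = Chain(structure_id="SYNTH", chain_id="A", residues=residues)

    windows = _site_windows(spec)
    sites: list[BindingSite] = []
    ligands: list[LigandInstance] = []
    for s_idx, window in enumerate(windows):
        atoms = []
        for i in window:
            ca, radial = _helix_position(i)
            pos = ca + (CB_OFFSET + LIGAND_OFFSET) * radial
            pos = pos + rng.normal(0.0, spec.ligand_jitter, size=3)
            atoms.append(Atom(element="C", coords=pos, name="L"))
        lig = LigandInstance(
            structure_id="SYNTH",
            ccd_code="LIG",
            instance_id=f"SYNTH_LIG_{s_idx + 1}",
            atoms=atoms,
        )
        lig.fingerprint = compute_contacts(chain, atoms, DEFAULT_CONTACT_CUTOFF)
        ligands.append(lig)
        residues_set = frozenset(i + 1 for i in window)
        site = BindingSite(
            site_id=f"site_{s_idx + 1}",
            residues=residues_set,
            members=(lig.instance_id,),
            multiplicity=1,
        )
        site.centroid = site_centroid(site, chain)
        sites.append(site)
    return chain, sites, ligands


def _draw_scores(rng: np.random.Generator, n: int, high: bool, spec: FixtureSpec):
    centre = 0.5 + (spec.score_separation / 2.0 if high else -spec.score_separation / 2.0)
    return np.clip(rng.normal(centre, 0.1, size=n), 0.0, 1.0)


def make_prediction_set(
    sites: list[BindingSite],
    chain: Optional[Chain],
    spec: FixtureSpec,
    method: str = "synthetic",
) -> list[PocketPrediction]:
    """Build a ranked prediction set with known correctness structure.

    ``n_correct`` predictions hit distinct sites (cycling when more correct
    predictions than sites are requested) within half the DCC threshold;
    ``n_redundant`` are jittered copies of the first correct prediction
    with strictly lower scores; ``n_false`` sit on the helix-axis extension
    at more than twice the threshold from every site.
    """
    if not sites:
        raise InvariantError("make_prediction_set needs at least one site")
    rng = np.random.default_rng(spec.seed + 1)
    tau = spec.dcc_threshold
    centroids = []
    for s in sites:
        if s.centroid is None:
            if chain is None:
                raise InvariantError(f"site {s.site_id} has no centroid")
            s.centroid = site_centroid(s, chain)
        centroids.append(s.centroid)
    z_top = max(c[2] for c in centroids)

    records: list[tuple[str, np.ndarray, Optional[frozenset], bool, bool]] = []
    # (kind, centroid, residues, is_correct, _)
    for i in range(spec.n_correct):
        site = sites[i % len(sites)]
        noise = rng.normal(0.0, spec.centroid_noise, size=3)
        norm = float(np.linalg.norm(noise))
        limit = 0.5 * tau
        if norm > limit:
            noise = noise * (limit / norm)
        records.append(("correct", site.centroid + noise, site.residues, True, False))
    if spec.n_redundant and not spec.n_correct:
        raise InvariantError("redundant predictions need a correct parent")
    for _ in range(spec.n_redundant):
        parent = records[0]
        offset = rng.normal(0.0, 0.7, size=3)
        norm = float(np.linalg.norm(offset))
        if norm > 2.0:
            offset = offset * (2.0 / norm)
        records.append(("redundant", parent[1] + offset, parent[2], True, True))
    for j in range(spec.n_false):
        pos = np.array([0.0, 0.0, z_top + 2.0 * tau + 3.0 * (j + 1)])
        records.append(("false", pos, None, False, False))

    n = len(records)
    correct_mask = np.array([r[3] for r in records])
    if spec.score_model == "constant":
        scores = np.full(n, 0.5)
    else:
        high = correct_mask if spec.score_model == "calibrated" else ~correct_mask
        scores = np.empty(n)
        scores[high] = _draw_scores(rng, int(high.sum()), True, spec)
        scores[~high] = _draw_scores(rng, int((~high).sum()), False, spec)
    # redundant copies score strictly below their parent
    parent_score = scores[0] if spec.n_correct else None
    for i, rec in enumerate(records):
        if rec[0] == "redundant":
            scores[i] = min(scores[i], parent_score - 0.01 * (i + 1))

    order = sorted(range(n), key=lambda i: (-scores[i], i))
    preds: list[PocketPrediction] = []
    for rank, i in enumerate(order, start=1):
        kind, centroid, residues, _, _ = records[i]
        preds.append(
            PocketPrediction(
                method=method,
                chain_id=chain.chain_id if chain is not None else "A",
                pocket_id=f"{method}_{kind}_{i}",
                rank=rank,
                score=float(scores[i]),
                centroid=centroid,
                residues=residues,
            )
        )
    return preds


def make_scored_benchmark(
    n_predictions: int,
    correct_fraction: float,
    score_model: str = "constant",
    seed: int = 0,
    method: str = "synthetic",
) -> tuple[list[PocketPrediction], set[str]]:
    """A flat dataset-level prediction set for ranking-curve studies.

    Each prediction is independently correct with probability
    ``correct_fraction``.  Under the ``constant`` model scores carry no
    information, so the precision of any top-k slice estimates the
    generating correct fraction; ``calibrated``/``anti_correlated`` scores
    sort correct predictions first/last.
    """
    if not 0.0 <= correct_fraction <= 1.0:
        raise InvariantError("correct_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    correct = rng.random(n_predictions) < correct_fraction
    if score_model == "constant":
        scores = np.full(n_predictions, 0.5)
    elif score_model in ("calibrated", "anti_correlated"):
        high = correct if score_model == "calibrated" else ~correct
        scores = np.where(
            high,
            np.clip(rng.normal(0.75, 0.1, n_predictions), 0, 1),
            np.clip(rng.normal(0.35, 0.1, n_predictions), 0, 1),
        )
    else:
        raise InvariantError(f"unknown score model {score_model!r}")
    preds = []
    correct_ids: set[str] = set()
    for i in range(n_predictions):
        pid = f"{method}_{i}"
        preds.append(
            PocketPrediction(
                method=method,
                chain_id=f"chain_{i % 97}",
                pocket_id=pid,
                rank=None,
                score=float(scores[i]),
                centroid=np.array([float(i), 0.0, 0.0]),
            )
        )
        if correct[i]:
            correct_ids.add(pid)
    return preds, correct_ids


def redundancy_scenario() -> tuple[list[BindingSite], list[PocketPrediction]]:
    """The worked five-site / ten-prediction redundancy configuration.

    Five well-separated observed sites (centroids 40 Å apart on the x
    axis).  Ten ranked predictions: ranks 1–7 are mutually redundant
    correct hits of site 1 (pairwise centroid distances <= 3 Å, identical
    residue sets), rank 8 hits site 2, rank 9 hits site 3 and rank 10 lies
    far beyond every site.  Deterministic coordinates throughout.

    With the default thresholds, top-(N+2) evaluation before redundancy
    removal gives recall 1/5 with precision 7/7; after greedy removal four
    predictions remain and the same window gives recall 3/5 with
    precision 3/4.
    """
    sites = []
    for k in range(5):
        sites.append(
            BindingSite(
                site_id=f"site_{k + 1}",
                residues=frozenset(range(100 * k + 1, 100 * k + 9)),
                members=(f"lig_{k + 1}",),
                multiplicity=1,
                centroid=np.array([40.0 * k, 0.0, 0.0]),
            )
        )
    preds: list[PocketPrediction] = []
    for j in range(7):  # mutually redundant hits of site 1
        preds.append(
            PocketPrediction(
                method="demo",
                chain_id="A",
                pocket_id=f"demo_{j + 1}",
                rank=j + 1,
                score=0.95 - 0.05 * j,
                centroid=np.array([0.5 * j, 0.0, 0.0]),
                residues=sites[0].residues,
            )
        )
    preds.append(
        PocketPrediction(
            method="demo",
            chain_id="A",
            pocket_id="demo_8",
            rank=8,
            score=0.55,
            centroid=np.array([40.0, 0.5, 0.0]),
            residues=sites[1].residues,
        )
    )
    preds.append(
        PocketPrediction(
            method="demo",
            chain_id="A",
            pocket_id="demo_9",
            rank=9,
            score=0.5,
            centroid=np.array([80.0, 0.5, 0.0]),
            residues=sites[2].residues,
        )
    )
    preds.append(
        PocketPrediction(
            method="demo",
            chain_id="A",
            pocket_id="demo_10",
            rank=10,
            score=0.45,
            centroid=np.array([400.0, 0.0, 0.0]),
        )
    )
    return sites, preds
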