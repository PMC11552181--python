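"""Residue- and pocket-level benchmark metrics for binding-site predictors.

Residue level treats prediction as binary classification over the residues
of a chain: confusion counts, F1 and the Matthews correlation coefficient
for hard labels; ROC and precision–recall curves (with per-chain means on a
shared threshold grid) for ligandability score tracks, where a residue is
called positive when its score strictly exceeds the threshold.

Pocket level is multi-instance: for each observed site the best prediction
(minimum centroid–centroid distance, DCC) is chosen within a rank window of
the top N + X predictions (N = observed sites on the protein), and the site
counts as recalled when DCC <= 12 Å (or, alternatively, when the relative
residue intersection I_rel >= 0.5).  Dataset-wide ranking quality is
summarised by the cumulative TP-vs-FP curve truncated at 100 false
positives and by the precision of the 1000 highest-scoring predictions.
Shape agreement of correct matches is measured by the relative residue
overlap (RRO) and relative volume overlap (RVO).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .errors import InvariantError, UndefinedResultError
from .model import Chain, PocketPrediction, ResidueScoreTrack, as_mapping
from .pockets import pocket_residues
from .sites import BindingSite, relative_intersection, site_centroid
from .volume import GridVolume, relative_volume_overlap

DEFAULT_DCC_THRESHOLD = 12.0
DEFAULT_IREL_THRESHOLD = 0.5
DEFAULT_FP_STOP = 100
DEFAULT_PRECISION_K = 1000

#: Shared threshold grid for probability-type score tracks.
DEFAULT_THRESHOLD_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class CurvePoint:
    threshold: float
    tpr: float
    fpr: float
    precision: float
    recall: float


@dataclass
class ScoreCurves:
    points: list[CurvePoint]
    auc: float
    ap: float


@dataclass
class PocketMatch:
    site_id: str
    prediction_id: Optional[str]
    dcc: Optional[float]
    dca: Optional[float] = None
    correct: bool = False
    i_rel: Optional[float] = None
    rro: Optional[float] = None
    rvo: Optional[float] = None


@dataclass
class MatchResult:
    matches: list[PocketMatch]
    recall: float
    precision: Optional[float]
    window: str = ""
    n_windowed: int = 0


def residue_metrics(
    predicted: Sequence[int] | np.ndarray,
    truth: Sequence[int] | np.ndarray,
) -> tuple[ConfusionCounts, float, float]:
    """Confusion counts, F1 and MCC for aligned binary label vectors.

    Degenerate denominators (no predicted positives, single-class truth)
    follow the zero convention: F1 = 0 and MCC = 0.
    """
    pred = np.asarray(predicted, dtype=int)
    true = np.asarray(truth, dtype=int)
    if pred.shape != true.shape:
        raise InvariantError(
            f"label vectors differ in length: {pred.shape} vs {true.shape}"
        )
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (true == 1))),
        fp=int(np.sum((pred == 1) & (true == 0))),
        tn=int(np.sum((pred == 0) & (true == 0))),
        fn=int(np.sum((pred == 0) & (true == 1))),
    )
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = ((tp * tn) - (fp * fn)) / denom if denom else 0.0
    return counts, f1, mcc


def score_curves(
    scores: ResidueScoreTrack | Mapping[int, float],
    truth: Mapping[int, int],
    grid: Optional[np.ndarray] = None,
) -> ScoreCurves:
    """ROC and PR curves from a ligandability score track.

    A residue is positive when its score LS > t for each threshold t on the
    grid.  AUC is the trapezoid area over FPR; AP sums precision-weighted
    recall increments over decreasing thresholds.  Chains whose truth is
    single-class are excluded upstream (UndefinedResultError here).
    """
    mapping = as_mapping(scores)
    residues = sorted(set(mapping) & set(truth))
    if not residues:
        raise UndefinedResultError("no residues shared between scores and truth")
    s = np.array([mapping[r] for r in residues], dtype=float)
    y = np.array([truth[r] for r in residues], dtype=int)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedResultError("single-class truth: ROC/PR undefined")
    if grid is None:
        if np.all((s >= 0) & (s <= 1)):
            grid = DEFAULT_THRESHOLD_GRID
        else:
            # unbounded score tracks: per-chain quantiles define the grid
            grid = np.quantile(s, np.linspace(0.0, 1.0, 101))
    points: list[CurvePoint] = []
    for t in grid:
        pos = s > t
        tp = int(np.sum(pos & (y == 1)))
        fp = int(np.sum(pos & (y == 0)))
        fn = n_pos - tp
        precision = tp / (tp + fp) if tp + fp else 1.0
        recall = tp / n_pos
        points.append(
            CurvePoint(
                threshold=float(t),
                tpr=tp / n_pos,
                fpr=fp / n_neg,
                precision=precision,
                recall=recall,
            )
        )
    # AUC: trapezoid over FPR along the curve traversal (descending
    # threshold), where both FPR and TPR are monotone non-decreasing
    by_desc = sorted(points, key=lambda p: -p.threshold)
    fprs = np.array([p.fpr for p in by_desc])
    tprs = np.array([p.tpr for p in by_desc])
    auc = float(np.trapezoid(tprs, fprs))
    # AP: precision-weighted recall increments, thresholds high -> low
    ap = 0.0
    prev_recall = 0.0
    for p in by_desc:
        ap += (p.recall - prev_recall) * p.precision
        prev_recall = p.recall
    return ScoreCurves(points=points, auc=auc, ap=float(ap))


def mean_curves(per_chain: Sequence[ScoreCurves]) -> ScoreCurves:
    """Pointwise mean ROC/PR across chains on the shared threshold grid;
    mean AUC/AP are the means of the per-chain values."""
    if not per_chain:
        raise InvariantError("mean_curves needs at least one chain curve")
    n_points = len(per_chain[0].points)
    for c in per_chain:
        if len(c.points) != n_points:
            raise InvariantError("chain curves are not on a shared threshold grid")
    points = []
    for i in range(n_points):
        pts = [c.points[i] for c in per_chain]
        points.append(
            CurvePoint(
                threshold=pts[0].threshold,
                tpr=float(np.mean([p.tpr for p in pts])),
                fpr=float(np.mean([p.fpr for p in pts])),
                precision=float(np.mean([p.precision for p in pts])),
                recall=float(np.mean([p.recall for p in pts])),
            )
        )
    return ScoreCurves(
        points=points,
        auc=float(np.mean([c.auc for c in per_chain])),
        ap=float(np.mean([c.ap for c in per_chain])),
    )


def dcc_dca(
    prediction: PocketPrediction,
    site: BindingSite,
    chain: Optional[Chain] = None,
    ligand_atoms: Optional[np.ndarray] = None,
) -> tuple[float, Optional[float]]:
    """DCC (prediction centroid to observed-site centroid) and optional DCA
    (prediction centroid to the closest member-ligand heavy atom)."""
    if prediction.centroid is None:
        raise InvariantError(f"prediction {prediction.pocket_id!r} has no centroid")
    if site.centroid is not None:
        obs = site.centroid
    elif chain is not None:
        obs = site_centroid(site, chain)
    else:
        raise InvariantError(f"site {site.site_id} has no centroid and no chain given")
    dcc = float(np.linalg.norm(prediction.centroid - obs))
    dca = None
    if ligand_atoms is not None and len(ligand_atoms):
        atoms = np.asarray(ligand_atoms, dtype=float).reshape(-1, 3)
        dca = float(np.min(np.linalg.norm(atoms - prediction.centroid, axis=1)))
    return dcc, dca


def _windowed(
    pockets: Sequence[PocketPrediction], n_sites: int, window: str
) -> list[PocketPrediction]:
    if window == "ALL":
        return list(pockets)
    if window == "top-N":
        extra = 0
    elif window.startswith("top-N+"):
        extra = int(window.split("+", 1)[1])
    else:
        raise InvariantError(f"unknown rank window {window!r}")
    limit = n_sites + extra

    def rank_of(item):
        idx, p = item
        return p.rank if p.rank is not None else idx + 1

    ordered = sorted(enumerate(pockets), key=rank_of)
    return [p for _, p in ordered if rank_of((0, p)) <= limit][:limit]


def match_and_recall(
    sites: Sequence[BindingSite],
    pockets: Sequence[PocketPrediction],
    chain: Optional[Chain] = None,
    window: str = "top-N+2",
    criterion: str = "dcc",
    dcc_threshold: float = DEFAULT_DCC_THRESHOLD,
    irel_threshold: float = DEFAULT_IREL_THRESHOLD,
    ligand_atoms: Optional[Mapping[str, np.ndarray]] = None,
) -> MatchResult:
    """Pocket-level recall and precision for one protein.

    Pockets are restricted to the rank window (N = number of observed
    sites).  For each observed site the best windowed prediction is chosen:
    minimum DCC under the ``dcc`` criterion, maximum I_rel under ``irel``.
    Recall = correctly predicted sites / observed sites.  A windowed
    prediction counts as correct for precision when it lies within the DCC
    threshold of any observed site centroid (I_rel criterion analogously),
    so each redundant duplicate counts separately.  With an empty window
    recall is 0 and precision undefined.
    """
    if not sites:
        raise InvariantError("match_and_recall needs at least one observed site")
    windowed = _windowed(pockets, len(sites), window)
    site_centroids = {}
    for s in sites:
        site_centroids[s.site_id] = (
            s.centroid if s.centroid is not None else site_centroid(s, chain)
        )
    matches: list[PocketMatch] = []
    n_correct_sites = 0
    for s in sites:
        best = None
        if criterion == "dcc":
            for p in windowed:
                if p.centroid is None:
                    continue
                d = float(np.linalg.norm(p.centroid - site_centroids[s.site_id]))
                if best is None or d < best[0]:
                    best = (d, p)
            if best is None:
                matches.append(
                    PocketMatch(site_id=s.site_id, prediction_id=None, dcc=None)
                )
                continue
            d, p = best
            correct = d <= dcc_threshold
            dca = None
            if ligand_atoms and s.site_id in ligand_atoms:
                _, dca = dcc_dca(p, s, chain, ligand_atoms[s.site_id])
            matches.append(
                PocketMatch(
                    site_id=s.site_id,
                    prediction_id=p.pocket_id,
                    dcc=d,
                    dca=dca,
                    correct=correct,
                )
            )
        elif criterion == "irel":
            for p in windowed:
                try:
                    pres = pocket_residues(p, chain)
                except InvariantError:
                    continue
                if not pres:
                    continue
                i_rel, _ = relative_intersection(pres, s.residues)
                if best is None or i_rel > best[0]:
                    best = (i_rel, p)
            if best is None:
                matches.append(
                    PocketMatch(site_id=s.site_id, prediction_id=None, dcc=None)
                )
                continue
            i_rel, p = best
            matches.append(
                PocketMatch(
                    site_id=s.site_id,
                    prediction_id=p.pocket_id,
                    dcc=None,
                    i_rel=i_rel,
                    correct=i_rel >= irel_threshold,
                )
            )
        else:
            raise InvariantError(f"unknown criterion {criterion!r}")
        if matches[-1].correct:
            n_correct_sites += 1

    recall = n_correct_sites / len(sites)
    precision: Optional[float] = None
    if windowed:
        chosen_correct = {
            m.prediction_id for m in matches if m.correct and m.prediction_id
        }
        n_correct_preds = 0
        for p in windowed:
            if p.pocket_id in chosen_correct:
                n_correct_preds += 1
                continue
            if criterion == "dcc" and p.centroid is not None:
                if any(
                    float(np.linalg.norm(p.centroid - c)) <= dcc_threshold
                    for c in site_centroids.values()
                ):
                    n_correct_preds += 1
            elif criterion == "irel":
                try:
                    pres = pocket_residues(p, chain)
                except InvariantError:
                    continue
                if pres and any(
                    relative_intersection(pres, s.residues)[0] >= irel_threshold
                    for s in sites
                ):
                    n_correct_preds += 1
        precision = n_correct_preds / len(windowed)
    return MatchResult(
        matches=matches,
        recall=recall,
        precision=precision,
        window=window,
        n_windowed=len(windowed),
    )


@dataclass
class RankingCurves:
    cum_tp: list[int]
    cum_fp: list[int]
    tp_at_fp_stop: int
    fp_budget_exhausted: bool
    precision_k: float
    k_used: int


def dataset_ranking_curves(
    predictions: Sequence[PocketPrediction],
    is_correct: Callable[[PocketPrediction], bool],
    fp_stop: int = DEFAULT_FP_STOP,
    k: int = DEFAULT_PRECISION_K,
) -> RankingCurves:
    """Dataset-wide score-ranking quality.

    Predictions (across all chains) are sorted by descending score; the
    cumulative TP-vs-FP curve is truncated once ``fp_stop`` false positives
    accumulate, and Precision_k is the fraction of correct predictions
    among the top ``k``.  With fewer than ``k`` predictions the precision is
    over the available count and flagged via ``k_used``.
    """
    if any(p.score is None for p in predictions):
        raise InvariantError("dataset ranking needs a score on every prediction")
    ordered = sorted(
        enumerate(predictions), key=lambda ip: (-ip[1].score, ip[0])
    )
    cum_tp: list[int] = []
    cum_fp: list[int] = []
    tp = fp = 0
    tp_at_stop = 0
    exhausted = False
    for _, p in ordered:
        if is_correct(p):
            tp += 1
        else:
            fp += 1
        cum_tp.append(tp)
        cum_fp.append(fp)
        if fp >= fp_stop:
            tp_at_stop = tp
            exhausted = True
            break
    if not exhausted:
        tp_at_stop = tp
    k_used = min(k, len(ordered))
    top_k_correct = sum(1 for _, p in ordered[:k_used] if is_correct(p))
    precision_k = top_k_correct / k_used if k_used else 0.0
    return RankingCurves(
        cum_tp=cum_tp,
        cum_fp=cum_fp,
        tp_at_fp_stop=tp_at_stop,
        fp_budget_exhausted=exhausted,
        precision_k=precision_k,
        k_used=k_used,
    )


def shape_overlap(
    pred_residues: frozenset | set,
    obs_residues: frozenset | set,
    pred_volume: Optional[GridVolume] = None,
    obs_volume: Optional[GridVolume] = None,
) -> tuple[float, Optional[float]]:
    """RRO = |R_p ∩ R_o| / |R_o| and, when volumes are supplied, RVO.

    Means over a benchmark are taken over correct matches only; pairs whose
    observed volume is empty return RVO None and are excluded from means.
    """
    obs = set(obs_residues)
    if not obs:
        raise UndefinedResultError("observed residue set is empty")
    rro = len(set(pred_residues) & obs) / len(obs)
    rvo = None
    if pred_volume is not None and obs_volume is not None:
        rvo = relative_volume_overlap(pred_volume, obs_volume)
    return rro, rvo


@dataclass
class DatasetStats:
    shannon_entropy: float
    top_k_fraction: float
    n_species: int
    n_instances: int


def dataset_stats(ligand_counts: Mapping[str, int], top_k: int = 5) -> DatasetStats:
    """Ligand-composition diversity: Shannon entropy H' = −Σ p_i ln p_i
    (natural log) and the share of instances in the top-k species."""
    if not ligand_counts:
        raise InvariantError("empty ligand multiset")
    counts = np.array(list(ligand_counts.values()), dtype=float)
    if np.any(counts < 1):
        raise InvariantError("ligand counts must be >= 1")
    p = counts / counts.sum()
    entropy = float(-np.sum(p * np.log(p)))
    top = sorted(counts, reverse=True)[:top_k]
    return DatasetStats(
        shannon_entropy=entropy,
        top_k_fraction=float(sum(top) / counts.sum()),
        n_species=len(counts),
        n_instances=int(counts.sum()),
    )


def ligand_id_overlap(
    reference_ids: set[str] | Sequence[str], other_ids: set[str] | Sequence[str]
) -> float:
    """Shared ligand-ID fraction (``entry_CCD`` strings), relative to the
    reference set."""
    ref = set(reference_ids)
    if not ref:
        raise InvariantError("empty reference ligand-ID set")
    return len(ref & set(other_ids)) / len(ref)


def two_proportion_ztest(
    success_a: int, n_a: int, success_b: int, n_b: int
) -> tuple[float, float]:
    """Two-sided two-proportion z-test; returns (z, p).

    Used to compare recall/precision between method variants.
    """
    from scipy.stats import norm

    if n_a <= 0 or n_b <= 0:
        raise InvariantError("sample sizes must be positive")
    p_pool = (success_a + success_b) / (n_a + n_b)
    se = math.sqrt(p_pool * (1 - p_pool) * (1 / n_a + 1 / n_b))
    if se == 0:
        return 0.0, 1.0
    z = (success_a / n_a - success_b / n_b) / se
    return z, 2 * float(norm.sf(abs(z)))
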