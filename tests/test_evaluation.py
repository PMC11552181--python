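import itertools

import numpy as np
import pytest

import pocketeval as pe
from pocketeval.errors import InvariantError, UndefinedResultError
from pocketeval.model import PocketPrediction


def _pred(pid, centroid, score=None, rank=None, residues=None):
    return PocketPrediction(
        method="m", chain_id="A", pocket_id=pid, rank=rank, score=score,
        centroid=np.asarray(centroid, dtype=float),
        residues=None if residues is None else frozenset(residues),
    )


class TestResidueMetrics:
    def test_perfect_prediction(self):
        counts, f1, mcc = pe.residue_metrics([1, 0], [1, 0])
        assert (counts.tp, counts.tn, counts.fp, counts.fn) == (1, 1, 0, 0)
        assert f1 == 1.0 and mcc == 1.0

    def test_all_negative_prediction_zero_convention(self):
        _, f1, mcc = pe.residue_metrics([0, 0, 0], [1, 1, 0])
        assert f1 == 0.0 and mcc == 0.0

    def test_hand_computed_case(self):
        # TP=2 FP=2 FN=2 TN=4
        pred = [1, 1, 1, 1, 0, 0, 0, 0, 0, 0]
        true = [1, 1, 0, 0, 1, 1, 0, 0, 0, 0]
        counts, f1, mcc = pe.residue_metrics(pred, true)
        assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 2, 2, 4)
        assert f1 == pytest.approx(0.5)
        assert mcc == pytest.approx((2 * 4 - 2 * 2) / np.sqrt(4 * 4 * 6 * 6))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvariantError):
            pe.residue_metrics([1, 0], [1])


class TestScoreCurves:
    def test_perfect_separation_auc_one(self):
        scores = {1: 0.9, 2: 0.8, 3: 0.7, 4: 0.3, 5: 0.2, 6: 0.1}
        truth = {1: 1, 2: 1, 3: 1, 4: 0, 5: 0, 6: 0}
        curves = pe.score_curves(scores, truth)
        assert curves.auc == pytest.approx(1.0)
        assert curves.ap == pytest.approx(1.0)

    def test_constant_scores_auc_half(self):
        scores = {i: 0.5 for i in range(6)}
        truth = {0: 1, 1: 1, 2: 1, 3: 0, 4: 0, 5: 0}
        assert pe.score_curves(scores, truth).auc == pytest.approx(0.5)

    def test_single_class_truth_excluded(self):
        with pytest.raises(UndefinedResultError):
            pe.score_curves({1: 0.5, 2: 0.6}, {1: 1, 2: 1})

    @pytest.mark.parametrize("seed", range(8))
    def test_auc_equals_mann_whitney_fraction(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        # scores on the 0.01 grid so the default threshold grid resolves them
        scores = {i: round(float(rng.integers(1, 100)) / 100, 2) for i in range(n)}
        truth = {i: int(rng.random() < 0.5) for i in range(n)}
        if len(set(truth.values())) < 2:
            truth[0], truth[1] = 0, 1
        curves = pe.score_curves(scores, truth)
        pos = [scores[i] for i in scores if truth[i] == 1]
        neg = [scores[i] for i in scores if truth[i] == 0]
        mw = np.mean(
            [1.0 if p > q else (0.5 if p == q else 0.0) for p in pos for q in neg]
        )
        assert curves.auc == pytest.approx(mw, abs=1e-12)

    def test_curve_points_bounded(self):
        scores = {i: float(s) for i, s in enumerate([0.1, 0.4, 0.6, 0.9])}
        truth = {0: 0, 1: 1, 2: 0, 3: 1}
        for p in pe.score_curves(scores, truth).points:
            for v in (p.tpr, p.fpr, p.precision, p.recall):
                assert 0.0 <= v <= 1.0


class TestMeanCurves:
    def _curve(self, scores, truth):
        return pe.score_curves(scores, truth)

    def test_single_chain_identity(self):
        c = self._curve({1: 0.9, 2: 0.1}, {1: 1, 2: 0})
        mean = pe.mean_curves([c])
        assert mean.auc == c.auc and mean.ap == c.ap
        assert [p.tpr for p in mean.points] == [p.tpr for p in c.points]

    def test_two_identical_curves_unchanged(self):
        c = self._curve({1: 0.9, 2: 0.4, 3: 0.1}, {1: 1, 2: 1, 3: 0})
        mean = pe.mean_curves([c, c])
        assert mean.auc == pytest.approx(c.auc)

    def test_mean_auc_is_arithmetic_mean(self):
        perfect = self._curve({1: 0.9, 2: 0.1}, {1: 1, 2: 0})
        flat = self._curve({1: 0.5, 2: 0.5}, {1: 1, 2: 0})
        mean = pe.mean_curves([perfect, flat])
        assert mean.auc == pytest.approx((1.0 + 0.5) / 2)


class TestDccDca:
    def test_coincident_centroids(self):
        site = pe.BindingSite(site_id="s", residues={1}, members=("l",),
                              centroid=np.zeros(3))
        dcc, dca = pe.dcc_dca(_pred("p", [0, 0, 0]), site)
        assert dcc == 0.0 and dca is None

    def test_three_four_five_triangle(self):
        site = pe.BindingSite(site_id="s", residues={1}, members=("l",),
                              centroid=np.zeros(3))
        dcc, _ = pe.dcc_dca(_pred("p", [3, 4, 0]), site)
        assert dcc == pytest.approx(5.0)

    def test_dca_to_closest_ligand_atom(self):
        site = pe.BindingSite(site_id="s", residues={1}, members=("l",),
                              centroid=np.zeros(3))
        atoms = np.array([[2.0, 0, 0], [10.0, 0, 0]])
        _, dca = pe.dcc_dca(_pred("p", [0, 0, 0]), site, ligand_atoms=atoms)
        assert dca == pytest.approx(2.0)


class TestMatchAndRecall:
    def test_worked_example_before_redundancy_removal(self):
        sites, preds = pe.redundancy_scenario()
        res = pe.match_and_recall(sites, preds, window="top-N+2")
        assert res.recall == pytest.approx(1 / 5)
        assert res.precision == pytest.approx(7 / 7)
        assert res.n_windowed == 7

    def test_worked_example_after_redundancy_removal(self):
        sites, preds = pe.redundancy_scenario()
        report = pe.remove_redundancy(preds)
        assert len(report.kept) == 4
        res = pe.match_and_recall(sites, report.kept, window="top-N+2")
        assert res.recall == pytest.approx(3 / 5)
        assert res.precision == pytest.approx(3 / 4)

    def test_redundancy_removal_never_hurts_recall_here(self):
        sites, preds = pe.redundancy_scenario()
        before = pe.match_and_recall(sites, preds, window="top-N+2").recall
        after = pe.match_and_recall(
            sites, pe.remove_redundancy(preds).kept, window="top-N+2"
        ).recall
        assert after >= before

    def test_perfect_predictions_full_window(self):
        sites, _ = pe.redundancy_scenario()
        preds = [
            _pred(f"hit{i}", s.centroid, rank=i + 1, score=1.0 - 0.01 * i)
            for i, s in enumerate(sites)
        ]
        res = pe.match_and_recall(sites, preds, window="ALL")
        assert res.recall == 1.0 and res.precision == 1.0

    def test_window_monotonicity(self, helix_fixture, helix_predictions):
        _, chain, sites, _ = helix_fixture
        recalls = [
            pe.match_and_recall(sites, helix_predictions, chain=chain, window=w).recall
            for w in ("top-N", "top-N+2", "ALL")
        ]
        assert recalls[0] <= recalls[1] <= recalls[2]

    def test_irel_criterion(self, helix_fixture, helix_predictions):
        _, chain, sites, _ = helix_fixture
        res = pe.match_and_recall(
            sites, helix_predictions, chain=chain, window="ALL", criterion="irel"
        )
        # synthetic correct predictions carry the exact site residue sets
        assert res.recall == 1.0


class TestDatasetRankingCurves:
    def test_all_correct_budget_not_exhausted(self):
        preds = [_pred(f"p{i}", [0, 0, 0], score=1.0 - i * 1e-3) for i in range(50)]
        rc = pe.dataset_ranking_curves(preds, lambda p: True, fp_stop=100, k=10)
        assert not rc.fp_budget_exhausted
        assert rc.tp_at_fp_stop == 50
        assert rc.precision_k == 1.0 and rc.k_used == 10

    def test_anticorrelated_scores_zero_tp_at_stop(self):
        preds, correct = pe.make_scored_benchmark(
            400, 0.5, score_model="anti_correlated", seed=3
        )
        rc = pe.dataset_ranking_curves(preds, lambda p: p.pocket_id in correct)
        assert rc.tp_at_fp_stop == 0

    def test_brute_force_recount_on_synthetic_set(self):
        preds, correct = pe.make_scored_benchmark(
            2000, 0.7, score_model="calibrated", seed=11
        )
        rc = pe.dataset_ranking_curves(preds, lambda p: p.pocket_id in correct)
        ordered = sorted(enumerate(preds), key=lambda ip: (-ip[1].score, ip[0]))
        top_k = [p for _, p in ordered[:1000]]
        brute_precision = sum(p.pocket_id in correct for p in top_k) / 1000
        assert rc.precision_k == pytest.approx(brute_precision)
        # brute-force ROC100 recount
        tp = fp = 0
        brute_tp_at_stop = None
        for _, p in ordered:
            if p.pocket_id in correct:
                tp += 1
            else:
                fp += 1
            if fp >= 100:
                brute_tp_at_stop = tp
                break
        assert rc.tp_at_fp_stop == brute_tp_at_stop

    def test_unscored_predictions_rejected(self):
        with pytest.raises(InvariantError):
            pe.dataset_ranking_curves([_pred("p", [0, 0, 0])], lambda p: True)


class TestShapeOverlap:
    def test_superset_prediction(self):
        rro, _ = pe.shape_overlap({1, 2, 3, 4, 5}, {2, 3})
        assert rro == 1.0

    def test_half_coverage(self):
        rro, _ = pe.shape_overlap({1, 2}, {1, 2, 3, 4})
        assert rro == 0.5

    def test_disjoint(self):
        rro, _ = pe.shape_overlap({9}, {1, 2})
        assert rro == 0.0

    def test_empty_observed_rejected(self):
        with pytest.raises(UndefinedResultError):
            pe.shape_overlap({1}, set())

    def test_with_volumes(self):
        pred_v = pe.GridVolume(points=frozenset({(0, 0, 0), (1, 0, 0)}))
        obs_v = pe.GridVolume(points=frozenset({(1, 0, 0), (2, 0, 0)}))
        rro, rvo = pe.shape_overlap({1}, {1}, pred_v, obs_v)
        assert rro == 1.0 and rvo == 0.5


class TestDatasetStats:
    def test_single_species_zero_entropy(self):
        assert pe.dataset_stats({"ATP": 10}).shannon_entropy == 0.0

    def test_uniform_entropy_is_log_r(self):
        stats = pe.dataset_stats({f"L{i}": 7 for i in range(5)})
        assert stats.shannon_entropy == pytest.approx(np.log(5))

    def test_hand_computed_mixture(self):
        counts = {"A": 50, "B": 30, "C": 20}
        p = np.array([0.5, 0.3, 0.2])
        expected = -float(np.sum(p * np.log(p)))
        stats = pe.dataset_stats(counts)
        assert stats.shannon_entropy == pytest.approx(expected)
        assert stats.top_k_fraction == 1.0

    def test_ligand_id_overlap(self):
        ref = {"1ABC_ATP", "1ABC_MG", "2XYZ_GTP"}
        other = {"1ABC_ATP", "9QQQ_HEM"}
        assert pe.ligand_id_overlap(ref, other) == pytest.approx(1 / 3)


class TestTwoProportionZTest:
    def test_identical_proportions_not_significant(self):
        z, p = pe.two_proportion_ztest(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_large_difference_significant(self):
        z, p = pe.two_proportion_ztest(90, 100, 50, 100)
        assert p < 0.05 and z > 0
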