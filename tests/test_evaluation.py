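import numpy as np
import pytest

import fcmdap
from fcmdap import (
    AssociationMatrix,
    Params,
    Scorer,
    confusion_rates,
    final_scores,
    loocv,
    mann_whitney_auc,
    permute_associations,
    pooled_roc,
)


class TestConfusionRates:
    @pytest.mark.parametrize(
        "tp, fp, tn, fn, expected",
        [
            (3, 0, 0, 1, (0.75, 0.0)),
            (0, 0, 5, 0, (0.0, 0.0)),
            (0, 2, 3, 0, (0.0, 0.4)),
        ],
    )
    def test_rates(self, tp, fp, tn, fn, expected):
        assert confusion_rates(tp, fp, tn, fn) == pytest.approx(expected)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            confusion_rates(-1, 0, 0, 0)


class TestPooledROC:
    def test_perfect_ranking_auc_one(self):
        roc = pooled_roc([(1, 20)] * 10)
        assert roc.auc == pytest.approx(1.0, abs=1e-9)

    def test_worst_ranking_auc_near_zero(self):
        roc = pooled_roc([(500, 500)] * 4)
        assert roc.auc < 0.01

    def test_uniform_ranks_null_auc_half(self):
        """Monte-Carlo null: ranks uniform over list positions."""
        rng = np.random.default_rng(123)
        n = 80
        records = [(int(rng.integers(1, n + 1)), n) for _ in range(10_000)]
        roc = pooled_roc(records)
        assert roc.auc == pytest.approx(0.5, abs=0.01)

    def test_curve_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(7)
        records = [
            (int(rng.integers(1, 30 + 1)), 30 + int(rng.integers(0, 5)))
            for _ in range(200)
        ]
        roc = pooled_roc(records)
        assert roc.tpr[0] == 0.0 and roc.fpr[0] == 0.0
        assert roc.tpr[-1] == 1.0 and roc.fpr[-1] == 1.0
        assert (np.diff(roc.tpr) >= 0).all() and (np.diff(roc.fpr) >= 0).all()
        assert roc.auc == pytest.approx(np.trapezoid(roc.tpr, roc.fpr))

    def test_rank_out_of_bounds_raises(self):
        with pytest.raises(ValueError):
            pooled_roc([(5, 4)])

    def test_matches_mann_whitney_concordance(self):
        """Pooled AUC equals the tie-corrected pairwise-concordance
        statistic within 1/(2 * candidate count) when list lengths are
        uniform."""
        rng = np.random.default_rng(2)
        n = 40
        ranks = rng.integers(1, n + 1, size=300)
        roc = pooled_roc([(int(r), n) for r in ranks])
        # per-fold concordance of 1 positive vs n-1 negatives
        mw = np.mean([(n - r) / (n - 1) for r in ranks])
        assert abs(roc.auc - mw) <= 1 / (2 * n)


class TestMannWhitneyAUC:
    def test_separated_scores_give_one(self):
        assert mann_whitney_auc([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_all_tied_scores_give_half(self):
        assert mann_whitney_auc([0, 0, 0, 0], [1, 0, 1, 0]) == 0.5

    def test_degenerate_labels_give_half(self):
        assert mann_whitney_auc([1, 2], [1, 1]) == 0.5


class TestLOOCV:
    def test_incremental_equals_naive_recomputation(self, planted):
        """Oracle equivalence: per-fold column scoring must equal a full
        matrix recomputation with the pair removed, fold by fold."""
        rng = np.random.default_rng(0)
        AS = planted.associations
        small = AssociationMatrix(
            AS.values[:20, :10], AS.mirna_ids[:20], AS.disease_ids[:10]
        )
        res = fcmdap.FCMDAP.from_bundle(planted).fit()
        sim = res.mirna_similarity[:20, :20]
        SD = res.disease_similarity[:10, :10]
        params = Params(k1=5, k2=4)
        report = loocv(small, sim, SD, None, params)
        # naive oracle
        naive = []
        for i, j in zip(*np.nonzero(small.values)):
            mod = small.values.copy()
            mod[i, j] = 0
            AS_mod = AssociationMatrix(mod, small.mirna_ids, small.disease_ids)
            fc = final_scores(AS_mod, sim, SD, None, params).values[:, j]
            cands = sorted(set(np.where(small.values[:, j] == 0)[0]) | {i})
            better = sum(
                1
                for m in cands
                if m != i and (fc[m] > fc[i] or (fc[m] == fc[i] and m < i))
            )
            naive.append((int(i), int(j), better + 1, len(cands)))
        got = {(f.mirna, f.disease): (f.rank, f.n_candidates) for f in report.folds}
        assert len(got) == len(naive)
        for i, j, rank, ncand in naive:
            key = (small.mirna_ids[i], small.disease_ids[j])
            assert got[key] == (rank, ncand)

    def test_single_association_uninformative_similarity(self):
        """With all-equal similarities the held-out miRNA lands mid-list
        by the tie rule."""
        AS = AssociationMatrix(np.array([[0, 1], [1, 0], [0, 0]]),
                               ["m1", "m2", "m3"], ["d1", "d2"])
        sim = np.ones((3, 3))
        SD = np.ones((2, 2))
        report = loocv(AS, sim, SD, None, Params(k1=2, k2=1))
        rec = {(f.mirna, f.disease): f for f in report.folds}
        # fold (m2, d1): candidates m1, m2, m3 all score equally -> rank 2
        assert rec[("m2", "d1")].rank == 2

    def test_fold_count_equals_association_count(self, planted_results):
        report = planted_results.loocv()
        n_assoc = int(planted_results.model.associations.values.sum())
        assert len(report.folds) == n_assoc
        assert set(report.per_disease_auc) <= set(
            planted_results.model.associations.disease_ids
        )

    def test_planted_signal_recovered(self, planted_results):
        assert planted_results.loocv().auc > 0.80

    def test_permuted_labels_drive_auc_to_chance(self, planted, planted_results):
        """Negative control across several permutation seeds."""
        res = planted_results
        aucs = []
        for s in range(10):
            rng = np.random.default_rng(1000 + s)
            ASp = permute_associations(planted.associations, rng)
            rep = loocv(
                ASp, res.mirna_similarity, res.disease_similarity,
                res.cluster_matrix, res.model.params,
            )
            aucs.append(rep.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_empty_association_matrix_raises(self):
        AS = AssociationMatrix(np.zeros((2, 2), int), ["a", "b"], ["x", "y"])
        with pytest.raises(ValueError):
            loocv(AS, np.eye(2), np.eye(2), None, Params())

    def test_stronger_target_overlap_never_hurts(self):
        """Monotonicity: increasing within-block target sharing does not
        decrease the mean LOOCV AUC over seeds."""
        means = []
        for overlap in (0.2, 0.7):
            aucs = []
            for seed in range(5):
                cfg = fcmdap.SyntheticConfig(
                    target_overlap_within_block=overlap
                )
                b = fcmdap.generate(seed, cfg)
                aucs.append(fcmdap.FCMDAP.from_bundle(b).fit().loocv().auc)
            means.append(np.mean(aucs))
        assert means[1] >= means[0]


def _best_planted_mirna(bundle):
    """Highest-degree miRNA whose associations are all within its own
    block pair (i.e. planted, not noise flips)."""
    AS = bundle.associations
    grp = np.array(
        [bundle.truth["disease_groups"][d] for d in AS.disease_ids]
    )
    best, best_deg = None, 0
    for i, m in enumerate(AS.mirna_ids):
        deg = int(AS.values[i].sum())
        within = int(AS.values[i][grp == bundle.truth["mirna_blocks"][m]].sum())
        if deg == within and deg > best_deg:
            best, best_deg = m, deg
    return best


def _best_planted_disease(bundle):
    AS = bundle.associations
    blk = np.array(
        [bundle.truth["mirna_blocks"][m] for m in AS.mirna_ids]
    )
    best, best_deg = None, 0
    for j, d in enumerate(AS.disease_ids):
        deg = int(AS.values[:, j].sum())
        within = int(
            AS.values[:, j][blk == bundle.truth["disease_groups"][d]].sum()
        )
        if deg == within and deg > best_deg:
            best, best_deg = d, deg
    return best


class TestIsolatedEntities:
    def test_planted_disease_recovery(self, planted, planted_results):
        """Cold-start AUC for the best-attested purely planted disease."""
        _, auc = planted_results.isolated_disease(_best_planted_disease(planted))
        assert auc > 0.75

    def test_planted_mirna_recovery(self, planted, planted_results):
        _, auc = planted_results.isolated_mirna(_best_planted_mirna(planted))
        assert auc > 0.75

    def test_uninformative_similarity_gives_half(self):
        AS = AssociationMatrix(
            np.array([[1, 0], [0, 1], [0, 0]]), ["m1", "m2", "m3"], ["d1", "d2"]
        )
        ranked, auc = fcmdap.isolated_disease_eval(
            "d1", AS, np.zeros((3, 3)), np.zeros((2, 2)), None, Params()
        )
        assert auc == 0.5
        assert set(ranked) == {"m1", "m2", "m3"}

    def test_zero_similarity_mirna_gives_half(self):
        AS = AssociationMatrix(
            np.array([[1, 0], [0, 1]]), ["m1", "m2"], ["d1", "d2"]
        )
        _, auc = fcmdap.isolated_mirna_eval(
            "m1", AS, np.zeros((2, 2)), np.zeros((2, 2)), None, Params()
        )
        assert auc == 0.5

    def test_unknown_entity_raises(self, planted_results):
        with pytest.raises(KeyError):
            planted_results.isolated_disease("not-a-disease")
        with pytest.raises(KeyError):
            planted_results.isolated_mirna("not-a-mirna")


class TestParameterGrid:
    def test_singleton_grid_equals_loocv(self, planted_results):
        frame = planted_results.parameter_grid([0.5], [0.8])
        assert len(frame) == 1
        assert frame["auc"].iloc[0] == pytest.approx(
            planted_results.loocv().auc, abs=1e-12
        )

    def test_argmax_flagged(self, planted_results):
        frame = planted_results.parameter_grid([0.3, 0.7], [0.5, 0.9])
        assert len(frame) == 4
        assert frame["best"].sum() == 1
        best = frame[frame["best"]].iloc[0]
        assert best["auc"] == frame["auc"].max()

    def test_empty_grid_raises(self, planted_results):
        with pytest.raises(ValueError):
            planted_results.parameter_grid([], [0.5])
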