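import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fvtlda.core_data import AssociationTable, EntityRegistry, build_incidence
from fvtlda.evaluation import (
    CvPlan,
    auc,
    contrast_score,
    kfold_run,
    loocv_run,
    rank_candidates,
    summarize,
)


def ld_from(values):
    values = np.asarray(values, dtype=float)
    rows = EntityRegistry("lncRNA", [f"l{i}" for i in range(values.shape[0])])
    cols = EntityRegistry("disease", [f"d{j}" for j in range(values.shape[1])])
    table = AssociationTable(
        [(rows.names[i], cols.names[j]) for i, j in zip(*np.nonzero(values))]
    )
    return build_incidence(table, rows, cols)


class TestAuc:
    def test_hand_counted_concordance(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == 0.75

    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([0.5, 0.5], [0.5, 0.5, 0.5]) == 0.5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            auc([], [0.5])

    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8),
    )
    def test_complement_symmetry(self, pos, neg):
        assert auc(pos, neg) + auc(neg, pos) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.random(20)
        neg = rng.random(30)
        f = lambda s: np.exp(3 * np.asarray(s)) + 1
        assert auc(pos, neg) == pytest.approx(auc(f(pos), f(neg)))

    def test_matches_sklearn_oracle(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.random(25)
        neg = rng.random(40)
        labels = np.r_[np.ones(25), np.zeros(40)]
        scores = np.r_[pos, neg]
        assert auc(pos, neg) == pytest.approx(roc_auc_score(labels, scores))


class TestContrastScore:
    def test_published_gastric_mlr_value(self):
        assert round(contrast_score([1, 2, 4, 5, 6, 7, 9, 10, 29, 11]), 4) == 0.7168

    def test_consecutive_top_ranks_score_one(self):
        assert contrast_score(list(range(1, 8))) == pytest.approx(1.0)

    def test_single_rank_hand_value(self):
        assert contrast_score([2]) == pytest.approx(math.exp(0.5 - 1.0))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            contrast_score([])

    def test_nonpositive_rank_errors(self):
        with pytest.raises(ValueError):
            contrast_score([1, 0])

    @given(
        st.lists(st.integers(1, 50), min_size=1, max_size=10),
        st.integers(0, 9),
        st.integers(1, 20),
    )
    def test_strictly_decreasing_when_a_rank_worsens(self, ranks, pos, bump):
        pos = pos % len(ranks)
        worse = list(ranks)
        worse[pos] += bump + 1
        assert contrast_score(worse) < contrast_score(ranks)


class TestRankCandidates:
    def test_all_known_gives_empty_list(self):
        ld = ld_from([[1], [1]])
        report = rank_candidates(np.array([[0.5], [0.9]]), 0, ld)
        assert report.candidates == []

    def test_descending_order_with_one_based_ranks(self):
        ld = ld_from([[0], [0], [0]])
        report = rank_candidates(np.array([[0.9], [0.2], [0.5]]), 0, ld)
        assert report.candidates == ["l0", "l2", "l1"]
        assert report.ranks == [1, 2, 3]

    def test_ties_break_by_registry_order(self):
        ld = ld_from([[0], [0], [0]])
        report = rank_candidates(np.array([[0.5], [0.5], [0.9]]), 0, ld)
        assert report.candidates == ["l2", "l0", "l1"]

    def test_known_pairs_excluded(self):
        ld = ld_from([[1], [0], [0]])
        report = rank_candidates(np.array([[0.99], [0.2], [0.5]]), 0, ld)
        assert "l0" not in report.candidates


class TestCrossValidation:
    def test_loocv_needs_two_known(self, pipeline_data):
        ld = ld_from([[1, 0], [0, 0]])
        with pytest.raises(ValueError):
            loocv_run(np.zeros((2, 2, 3)), ld, pipeline_data.ds_ld)

    def test_kfold_matching_known_count_equals_loocv_for_mlr(self, pipeline_data, fixture_dataset):
        from fvtlda.validation import SYNTHETIC_PARAMS

        data = pipeline_data
        n_known = int(data.ld.values.sum())
        loo = loocv_run(data.pair_feats, data.ld, data.ds_ld, "mlr", SYNTHETIC_PARAMS, seed=0)
        kf = kfold_run(
            data.pair_feats, data.ld, data.ds_ld, "mlr",
            CvPlan(k=n_known, repeats=1, seed=0), SYNTHETIC_PARAMS,
        )
        assert kf[0].auc == pytest.approx(loo.auc, abs=1e-12)

    def test_same_seed_reproduces_fold_assignment(self, pipeline_data):
        from fvtlda.validation import SYNTHETIC_PARAMS

        data = pipeline_data
        a = kfold_run(data.pair_feats, data.ld, data.ds_ld, "mlr",
                      CvPlan(k=5, repeats=1, seed=3), SYNTHETIC_PARAMS)
        b = kfold_run(data.pair_feats, data.ld, data.ds_ld, "mlr",
                      CvPlan(k=5, repeats=1, seed=3), SYNTHETIC_PARAMS)
        assert a[0].auc == b[0].auc

    def test_repeats_produce_positive_std(self, pipeline_data):
        from fvtlda.validation import SYNTHETIC_PARAMS

        data = pipeline_data
        results = kfold_run(data.pair_feats, data.ld, data.ds_ld, "mlr",
                            CvPlan(k=5, repeats=3, seed=0), SYNTHETIC_PARAMS)
        mean, std = summarize(results)
        assert len(results) == 3
        assert std > 0
        assert 0.0 <= mean <= 1.0

    def test_k_larger_than_known_errors(self, pipeline_data):
        data = pipeline_data
        with pytest.raises(ValueError, match="exceeds"):
            kfold_run(data.pair_feats, data.ld, data.ds_ld, "mlr",
                      CvPlan(k=10_000, repeats=1, seed=0))

    def test_roc_points_monotone(self, pipeline_data):
        from fvtlda.validation import SYNTHETIC_PARAMS

        data = pipeline_data
        res = loocv_run(data.pair_feats, data.ld, data.ds_ld, "mlr", SYNTHETIC_PARAMS, seed=0)
        pts = np.array(res.points)
        assert (np.diff(pts[:, 0]) >= 0).all()
        assert (np.diff(pts[:, 1]) >= 0).all()
        assert res.points[0] == (0.0, 0.0) and res.points[-1] == (1.0, 1.0)
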