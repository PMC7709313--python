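import numpy as np
import pytest
from hypothesis import given, strategies as st

from fvtlda.config import RwrConfig
from fvtlda.core_data import AssociationTable, EntityRegistry, build_incidence
from fvtlda.rwr import (
    column_normalize_seeds,
    pair_feature,
    pair_feature_matrix,
    row_normalize,
    rwr,
    rwr_closed_form,
    FeatureMatrix,
)
from fvtlda.similarity import SimilarityMatrix


def sim_from(values):
    values = np.asarray(values, dtype=float)
    return SimilarityMatrix([f"m{i}" for i in range(values.shape[0])], values)


def inc_from(values):
    values = np.asarray(values, dtype=float)
    rows = EntityRegistry("miRNA", [f"m{i}" for i in range(values.shape[0])])
    cols = EntityRegistry("lncRNA", [f"l{j}" for j in range(values.shape[1])])
    table = AssociationTable(
        [(rows.names[i], cols.names[j]) for i, j in zip(*np.nonzero(values))]
    )
    return build_incidence(table, rows, cols)


class TestNormalizations:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([[1, 1], [1, 1]], [[0.5, 0.5], [0.5, 0.5]]),
            ([[1, 0], [0, 1]], [[1, 0], [0, 1]]),
            ([[2, 1, 1], [1, 1, 2], [4, 0, 0]], [[0.5, 0.25, 0.25], [0.25, 0.25, 0.5], [1, 0, 0]]),
        ],
    )
    def test_row_normalize(self, values, expected):
        assert np.allclose(row_normalize(sim_from(values)), expected)

    def test_row_normalize_keeps_zero_rows(self):
        out = row_normalize(sim_from([[0, 0], [1, 1]]))
        assert out[0].tolist() == [0, 0]

    @pytest.mark.parametrize(
        "col, expected",
        [([1, 1, 0, 0], [0.5, 0.5, 0, 0]), ([1, 0, 0], [1, 0, 0]), ([0, 0], [0, 0])],
    )
    def test_column_normalize_seeds(self, col, expected):
        inc = inc_from(np.array(col, dtype=float)[:, None])
        assert np.allclose(column_normalize_seeds(inc)[:, 0], expected)


class TestRwr:
    def test_restart_near_one_returns_seeds(self):
        seeds = np.array([[1.0, 0.2], [0.0, 0.8]])
        w = np.array([[0.5, 0.5], [0.5, 0.5]])
        out = rwr(seeds, w, RwrConfig(restart=0.999999))
        assert np.allclose(out.values, seeds, atol=1e-5)

    def test_hand_solved_stationary_point(self):
        # uniform two-node transition, seed [1, 0], r = 0.5 -> [0.75, 0.25]
        out = rwr(
            np.array([[1.0], [0.0]]),
            np.array([[0.5, 0.5], [0.5, 0.5]]),
            RwrConfig(restart=0.5),
        )
        assert np.allclose(out.values[:, 0], [0.75, 0.25], atol=1e-9)

    def test_columns_stay_stochastic(self, rng):
        w = rng.random((6, 6))
        w /= w.sum(axis=1, keepdims=True)
        seeds = column_normalize_seeds(inc_from((rng.random((6, 4)) < 0.5).astype(float)))
        nonzero = seeds.sum(axis=0) > 0
        out = rwr(seeds, w, RwrConfig(restart=0.3))
        assert out.converged
        assert np.allclose(out.values[:, nonzero].sum(axis=0), 1.0, atol=1e-8)

    def test_iterative_agrees_with_closed_form(self, rng):
        # oracle equivalence on random instances
        for _ in range(10):
            w = rng.random((10, 10))
            w /= w.sum(axis=1, keepdims=True)
            seeds = rng.random((10, 3))
            seeds /= seeds.sum(axis=0, keepdims=True)
            got = rwr(seeds, w, RwrConfig(restart=0.2)).values
            want = rwr_closed_form(seeds, w, 0.2)
            assert np.abs(got - want).max() < 1e-8

    @given(st.floats(min_value=0.5, max_value=0.99))
    def test_output_approaches_seeds_monotonically_in_restart(self, r):
        seeds = np.array([[1.0], [0.0], [0.0]])
        w = np.full((3, 3), 1 / 3)
        lo = rwr(seeds, w, RwrConfig(restart=r)).values
        hi = rwr(seeds, w, RwrConfig(restart=min(r + 0.009, 0.999))).values
        assert np.abs(hi - seeds).max() <= np.abs(lo - seeds).max() + 1e-12

    def test_unconverged_run_flagged(self):
        seeds = np.array([[1.0], [0.0]])
        w = np.array([[0.9, 0.1], [0.2, 0.8]])
        out = rwr(seeds, w, RwrConfig(restart=0.001, tol=1e-14, max_iter=3))
        assert not out.converged

    def test_zero_seed_column_stays_zero(self):
        seeds = np.array([[1.0, 0.0], [0.0, 0.0]])
        w = np.array([[0.5, 0.5], [0.5, 0.5]])
        out = rwr(seeds, w, RwrConfig(restart=0.5))
        assert np.allclose(out.values[:, 1], 0.0)


class TestPairFeature:
    def fm(self, values):
        values = np.asarray(values, dtype=float)
        return FeatureMatrix(
            [f"m{i}" for i in range(values.shape[0])],
            [f"e{j}" for j in range(values.shape[1])],
            values,
        )

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ([0.5, 0.5], [1.0, 0.0], [0.5, 0.0]),
            ([0.0, 0.0], [0.3, 0.7], [0.0, 0.0]),
            ([0.75, 0.25], [0.2, 0.8], [0.15, 0.2]),
        ],
    )
    def test_elementwise_product(self, a, b, expected):
        pl = self.fm(np.array(a)[:, None])
        pd_ = self.fm(np.array(b)[:, None])
        assert np.allclose(pair_feature(pl, pd_, 0, 0), expected)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            pair_feature(self.fm([[1.0], [0.0]]), self.fm([[1.0], [0.0], [0.0]]), 0, 0)

    def test_full_tensor_matches_single_pairs(self, rng):
        pl = self.fm(rng.random((4, 3)))
        pd_ = self.fm(rng.random((4, 2)))
        tensor = pair_feature_matrix(pl, pd_)
        assert tensor.shape == (3, 2, 4)
        assert np.allclose(tensor[2, 1], pair_feature(pl, pd_, 2, 1))
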