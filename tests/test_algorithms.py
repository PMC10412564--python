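"""The four stability statistics: worked examples, oracle equivalence,
shift invariances, and geNorm's stepwise trace."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import _oracles as oracle
from refstab.algorithms import (
    DegenerateMatrixError,
    bestkeeper_stability,
    delta_ct_stability,
    genorm_stability,
    normfinder_stability,
    pairwise_sd_matrix,
    rank_within_algorithm,
)

from conftest import make_matrix


class TestDeltaCt:
    def test_toy_values_and_ranks(self, toy_matrix):
        t = delta_ct_stability(toy_matrix)
        assert t.values.tolist() == pytest.approx([1.0, 1.0, 2.0])
        assert t.ranks.tolist() == [1.5, 1.5, 3.0]

    def test_constant_difference_contributes_zero(self):
        # B = A + 3 in every sample: SD(A−B) = 0 for both partners
        m = make_matrix([[20, 21, 22], [23, 24, 25], [20, 22, 21]], genes=["A", "B", "C"])
        v = pairwise_sd_matrix(m.values.to_numpy())
        assert v[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_shift_invariance(self, toy_matrix):
        shifted = make_matrix(toy_matrix.values.to_numpy() + np.array([5.0, 0.0, 0.0]),
                              genes=list(toy_matrix.values.index))
        t0 = delta_ct_stability(toy_matrix)
        t1 = delta_ct_stability(shifted)
        assert np.allclose(t0.values, t1.values)

    def test_needs_two_samples(self):
        with pytest.raises(DegenerateMatrixError):
            delta_ct_stability(make_matrix([[1.0], [2.0], [3.0]]))


class TestGeNorm:
    def test_toy_stepwise(self, toy_matrix):
        t, trace = genorm_stability(toy_matrix)
        # initial M: X=1, Y=1, Z=2 -> Z removed; final pair M = SD(X−Y) = 0
        assert trace.m_by_round[0] == pytest.approx({"X": 1.0, "Y": 1.0, "Z": 2.0})
        assert trace.exclusion_order == ["Z"]
        assert t.values["Z"] == pytest.approx(2.0)
        assert t.values["X"] == pytest.approx(0.0, abs=1e-12)
        assert t.ranks.tolist() == [1.5, 1.5, 3.0]

    def test_final_round_has_two_genes(self, random_matrices):
        for m in random_matrices[:5]:
            _, trace = genorm_stability(m)
            assert len(trace.exclusion_order) == len(m.genes) - 2
            assert len(trace.m_by_round[-1]) == 2

    def test_initial_m_equals_delta_ct(self, random_matrices):
        for m in random_matrices:
            _, trace = genorm_stability(m)
            dct = delta_ct_stability(m)
            first = pd.Series(trace.m_by_round[0])
            assert np.allclose(first.loc[dct.values.index], dct.values, atol=1e-12)

    def test_identical_genes_tie_broken_lexicographically(self):
        m = make_matrix([[1, 2, 3]] * 3, genes=["B", "A", "C"])
        _, trace = genorm_stability(m)
        assert trace.exclusion_order == ["A"]  # all M = 0; lexicographic rule


class TestBestKeeper:
    def test_constant_gene_ranks_first(self):
        m = make_matrix([[10, 10, 10], [1, 2, 3], [5, 3, 4]])
        t = bestkeeper_stability(m)
        assert t.values.iloc[0] == 0.0
        assert t.ranks.iloc[0] == 1.0

    def test_toy_sd_index_and_r(self, toy_matrix):
        t = bestkeeper_stability(toy_matrix)
        assert t.values.tolist() == pytest.approx([1.0, 1.0, 1.0])
        assert t.ranks.tolist() == [2.0, 2.0, 2.0]  # three-way tie
        sd, index, r = oracle.bestkeeper(toy_matrix.values.to_numpy())
        assert t.extras["index"].to_numpy() == pytest.approx(index)
        assert t.extras["index"].to_numpy() == pytest.approx([1.4422, 2.0, 2.0801], abs=5e-5)
        assert t.extras["r"]["X"] == pytest.approx(r[0])
        assert t.extras["r"]["X"] == pytest.approx(0.918, abs=5e-4)

    def test_duplicate_panel_self_correlates(self):
        m = make_matrix([[1, 2, 3], [1, 2, 3]], genes=["A1", "A2"])
        t = bestkeeper_stability(m)
        assert t.extras["index"].tolist() == pytest.approx([1, 2, 3])
        assert t.extras["r"].tolist() == pytest.approx([1.0, 1.0])

    def test_zero_variance_r_is_missing_but_sd_ranks(self):
        m = make_matrix([[10, 10, 10], [10, 10, 10]])
        t = bestkeeper_stability(m)
        assert t.extras["r"].isna().all()
        assert t.ranks.tolist() == [1.5, 1.5]

    def test_not_invariant_to_per_sample_shift(self, random_matrices):
        m = random_matrices[0]
        shift = np.arange(len(m.samples), dtype=float)
        shifted = make_matrix(m.values.to_numpy() + shift, genes=m.genes)
        assert not np.allclose(bestkeeper_stability(m).values,
                               bestkeeper_stability(shifted).values)


class TestNormFinder:
    def test_toy_two_gene_panel(self):
        m = make_matrix([[1, 2, 3], [3, 2, 1]], genes=["X", "Z"])
        t = normfinder_stability(m, use_groups=False)
        assert t.values.tolist() == pytest.approx([1.0, 1.0])

    def test_identical_genes_all_zero(self):
        m = make_matrix([[1, 2, 3]] * 3)
        t = normfinder_stability(m, use_groups=False)
        assert t.values.tolist() == pytest.approx([0.0, 0.0, 0.0], abs=1e-12)

    def test_per_gene_constant_invariance(self, random_matrices):
        m = random_matrices[1]
        x = m.values.to_numpy().copy()
        x[0] += 7.5
        shifted = make_matrix(x, genes=m.genes, conditions=list(m.condition_of))
        for groups in (False, True):
            a = normfinder_stability(m, use_groups=groups).values
            b = normfinder_stability(shifted, use_groups=groups).values
            assert np.allclose(a, b, atol=1e-12)

    def test_grouped_needs_two_per_group(self):
        m = make_matrix([[1, 2], [2, 3], [3, 4]], conditions=["control", "treated"])
        with pytest.raises(DegenerateMatrixError):
            normfinder_stability(m, use_groups=True)

    def test_auto_falls_back_to_ungrouped_on_paired_design(self):
        m = make_matrix([[1, 2], [2, 3], [3, 4]], conditions=["control", "treated"])
        t = normfinder_stability(m)  # auto
        assert t.extras["grouped"] is False

    def test_auto_uses_groups_when_possible(self, random_matrices):
        t = normfinder_stability(random_matrices[0])
        assert t.extras["grouped"] is True


class TestRankWithinAlgorithm:
    @pytest.mark.parametrize("values,expected", [
        ({"A": 0.5, "B": 0.7, "C": 0.7}, [1.0, 2.5, 2.5]),
        ({"A": 1.0, "B": 2.0, "C": 3.0}, [1.0, 2.0, 3.0]),
    ])
    def test_average_ties(self, values, expected):
        assert rank_within_algorithm(pd.Series(values)).tolist() == expected

    def test_nonfinite_value_names_gene(self):
        with pytest.raises(ValueError, match="B"):
            rank_within_algorithm(pd.Series({"A": 1.0, "B": np.nan}))

    @given(arrays(float, 8, elements=st.floats(0, 10, allow_nan=False)))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_sum_conserved(self, vals):
        ranks = rank_within_algorithm(pd.Series(vals, index=[f"g{i}" for i in range(8)]))
        assert ranks.sum() == pytest.approx(8 * 9 / 2)


class TestOracleEquivalence:
    """Naive triple-loop recomputation agrees with the implementation."""

    def test_delta_ct(self, random_matrices):
        for m in random_matrices:
            expected = oracle.delta_ct(m.values.to_numpy())
            assert np.allclose(delta_ct_stability(m).values, expected, atol=1e-12)

    def test_genorm(self, random_matrices):
        for m in random_matrices:
            t, trace = genorm_stability(m)
            values, order = oracle.genorm_stepwise(m.values.to_numpy(), list(m.values.index))
            assert trace.exclusion_order == order
            for g, v in values.items():
                assert t.values[g] == pytest.approx(v, abs=1e-12)

    def test_bestkeeper(self, random_matrices):
        for m in random_matrices:
            t = bestkeeper_stability(m)
            sd, index, r = oracle.bestkeeper(m.values.to_numpy())
            assert np.allclose(t.values, sd, atol=1e-12)
            assert np.allclose(t.extras["index"], index, atol=1e-12)
            assert np.allclose(t.extras["r"], r, atol=1e-12)

    def test_normfinder_both_modes(self, random_matrices):
        for m in random_matrices:
            cond = list(m.condition_of)
            assert np.allclose(
                normfinder_stability(m, use_groups=False).values,
                oracle.normfinder_ungrouped(m.values.to_numpy()), atol=1e-12)
            assert np.allclose(
                normfinder_stability(m, use_groups=True).values,
                oracle.normfinder_grouped(m.values.to_numpy(), cond), atol=1e-12)


@st.composite
def cq_matrices(draw):
    g = draw(st.integers(3, 6))
    s = draw(st.integers(4, 8))
    x = draw(arrays(float, (g, s), elements=st.floats(10, 35, allow_nan=False)))
    return make_matrix(x, conditions=["control"] * (s // 2) + ["treated"] * (s - s // 2))


class TestShiftInvariances:
    """delta-Ct, geNorm and NormFinder are invariant to per-sample loading
    shifts and per-gene baseline shifts; BestKeeper's SD only to the latter."""

    @given(cq_matrices(), st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_per_sample_shift(self, m, delta):
        rng = np.random.default_rng(0)
        shift = rng.uniform(-2, 2, size=len(m.samples)) + delta
        shifted = make_matrix(m.values.to_numpy() + shift, genes=m.genes,
                              conditions=list(m.condition_of))
        assert np.allclose(delta_ct_stability(m).values,
                           delta_ct_stability(shifted).values, atol=1e-9)
        assert np.allclose(genorm_stability(m)[0].values,
                           genorm_stability(shifted)[0].values, atol=1e-9)
        for groups in (False, True):
            assert np.allclose(normfinder_stability(m, use_groups=groups).values,
                               normfinder_stability(shifted, use_groups=groups).values,
                               atol=1e-9)

    @given(cq_matrices(), st.floats(-5, 5, allow_nan=False))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_per_gene_shift(self, m, delta):
        rng = np.random.default_rng(1)
        shift = (rng.uniform(-2, 2, size=len(m.genes)) + delta)[:, None]
        shifted = make_matrix(m.values.to_numpy() + shift, genes=m.genes,
                              conditions=list(m.condition_of))
        assert np.allclose(delta_ct_stability(m).values,
                           delta_ct_stability(shifted).values, atol=1e-9)
        assert np.allclose(genorm_stability(m)[0].values,
                           genorm_stability(shifted)[0].values, atol=1e-9)
        assert np.allclose(bestkeeper_stability(m).values,
                           bestkeeper_stability(shifted).values, atol=1e-9)
        for groups in (False, True):
            assert np.allclose(normfinder_stability(m, use_groups=groups).values,
                               normfinder_stability(shifted, use_groups=groups).values,
                               atol=1e-9)
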