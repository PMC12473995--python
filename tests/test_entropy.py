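"""Standardization, information entropy and entropy weights.

The brute-force oracle below recomputes the whole weighting chain with
plain Python loops and ``math`` calls, independently of the vectorized
implementation it checks.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wqfce.entropy import (
    DegenerateWeightsError,
    compute_entropy,
    compute_weights,
    entropy_weights,
    standardize_minmax,
    uniform_weights,
)
from wqfce.indicators import INDICATORS, DataMatrix


def brute_force_weights(rows, polarity):
    """Independent loop-based evaluation of the full weighting chain."""
    n, m = len(rows), len(rows[0])
    cols = [[rows[i][j] for i in range(n)] for j in range(m)]
    std = []
    for j, col in enumerate(cols):
        lo, hi = min(col), max(col)
        if hi == lo:
            std.append([1.0] * n)
        elif polarity[j] == "benefit":
            std.append([(x - lo) / (hi - lo) for x in col])
        else:
            std.append([(hi - x) / (hi - lo) for x in col])
    k = 1.0 / math.log(n)
    entropies = []
    for col in std:
        total = sum(col)
        e = 0.0
        for x in col:
            p = x / total
            if p > 0:
                e -= p * math.log(p)
        entropies.append(k * e)
    info = [1.0 - e for e in entropies]
    s = sum(info)
    return [v / s for v in info], entropies


def _matrix(rows):
    rows = np.asarray(rows, dtype=float)
    return DataMatrix(values=rows, site_ids=[f"S{i}" for i in range(len(rows))])


class TestStandardize:
    def test_benefit_column_maps_endpoints(self):
        dm = _matrix([[2, 2, 2, 2, 2], [4, 4, 4, 4, 4], [6, 6, 6, 6, 6]])
        std = standardize_minmax(dm)
        assert np.allclose(std.values[:, 0], [0, 0.5, 1])  # DO is benefit

    def test_cost_column_reverses(self):
        dm = _matrix([[2, 2, 2, 2, 2], [4, 4, 4, 4, 4], [6, 6, 6, 6, 6]])
        std = standardize_minmax(dm)
        assert np.allclose(std.values[:, 1], [1, 0.5, 0])  # TN is cost

    def test_constant_column_maps_to_ones(self):
        dm = _matrix([[5, 1, 1, 1, 1], [5, 2, 2, 2, 2], [5, 3, 3, 3, 3]])
        std = standardize_minmax(dm)
        assert np.all(std.values[:, 0] == 1.0)

    def test_all_outputs_in_unit_interval(self):
        rng = np.random.default_rng(0)
        std = standardize_minmax(_matrix(rng.uniform(0, 50, size=(12, 5))))
        assert std.values.min() >= 0 and std.values.max() <= 1

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            standardize_minmax(_matrix([[1, 1, 1, 1, 1]]))


class TestEntropy:
    def test_uniform_column_has_entropy_one(self):
        x = np.full((7, 1), 0.3)
        assert compute_entropy(x) == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_column_has_entropy_zero(self):
        x = np.array([[1.0], [0.0]])
        assert compute_entropy(x) == pytest.approx(0.0, abs=1e-12)

    def test_known_three_sample_column(self):
        # frozen from -(1/ln 3) * sum(p ln p) with p = (0.5, 0.25, 0.25)
        x = np.array([[0.5], [0.25], [0.25]])
        assert compute_entropy(x)[0] == pytest.approx(0.9463946, abs=1e-6)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError, match="n < 2"):
            compute_entropy(np.array([[1.0]]))


class TestWeights:
    def test_equal_entropy_gives_equal_weights(self):
        w = compute_weights(np.array([0.5, 0.5]))
        assert np.allclose(w.weights, [0.5, 0.5])

    def test_uninformative_column_gets_zero_weight(self):
        w = compute_weights(np.array([1.0, 0.0]))
        assert np.allclose(w.weights, [0.0, 1.0])

    def test_hand_arithmetic_example(self):
        w = compute_weights(np.array([0.9, 0.8, 0.7]))
        assert np.allclose(w.weights, [1 / 6, 2 / 6, 3 / 6])

    def test_all_uninformative_raises_with_fallback_advice(self):
        with pytest.raises(DegenerateWeightsError, match="uniform"):
            compute_weights(np.array([1.0, 1.0]))
        assert np.allclose(uniform_weights().weights, 0.2)


matrices = st.lists(
    st.lists(st.floats(min_value=0.0, max_value=100.0, allow_nan=False), min_size=5, max_size=5),
    min_size=3,
    max_size=8,
)


@settings(deadline=None, derandomize=True, max_examples=60)
@given(matrices)
def test_weights_always_normalized(rows):
    """sum(w) == 1 for every matrix where at least one column is informative."""
    dm = _matrix(rows)
    try:
        w = entropy_weights(dm)
    except DegenerateWeightsError:
        return
    assert w.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(w.weights >= 0)
    assert np.all((w.entropy >= -1e-12) & (w.entropy <= 1 + 1e-12))


@settings(deadline=None, derandomize=True, max_examples=30)
@given(matrices, st.randoms(use_true_random=False))
def test_permutation_equivariance(rows, rnd):
    """Shuffling sample rows leaves W unchanged; permuting columns permutes W."""
    dm = _matrix(rows)
    try:
        w = entropy_weights(dm)
    except DegenerateWeightsError:
        return
    rows_perm = list(rows)
    rnd.shuffle(rows_perm)
    w_rows = entropy_weights(_matrix(rows_perm))
    assert np.allclose(w.weights, w_rows.weights, atol=1e-10)

    # reversing the columns must reverse the weights; use an all-cost polarity
    # map so the reversal does not change any column's direction
    vals = np.asarray(rows, dtype=float)
    pol = {ind: "cost" for ind in INDICATORS}
    std_f = standardize_minmax(vals, polarity=pol)
    std_r = standardize_minmax(vals[:, ::-1], polarity=pol)
    wf = compute_weights(compute_entropy(std_f)).weights
    wr = compute_weights(compute_entropy(std_r)).weights
    assert np.allclose(wf, wr[::-1], atol=1e-10)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(matrices)
def test_matches_brute_force_oracle(rows):
    """Vectorized chain agrees with the loop/math oracle to 1e-10."""
    dm = _matrix(rows)
    polarity = ["benefit" if INDICATORS[j] == "DO" else "cost" for j in range(5)]
    try:
        w = entropy_weights(dm)
    except DegenerateWeightsError:
        return
    expected_w, expected_e = brute_force_weights([list(r) for r in rows], polarity)
    assert np.allclose(w.weights, expected_w, atol=1e-10)
    assert np.allclose(w.entropy, expected_e, atol=1e-10)


def test_dispersed_column_outweighs_uniform_column():
    """A column with concentrated proportions never gets less weight than a
    flat one (more dispersion = more information)."""
    flat = [1.0, 1.0, 1.0, 1.0]
    spread = [0.0, 0.2, 1.0, 5.0]
    vals = np.column_stack([spread, flat, flat, flat, spread])
    pol = {ind: "cost" for ind in INDICATORS}
    std = standardize_minmax(vals, polarity=pol)
    w = compute_weights(compute_entropy(std))
    assert w.weights[0] > w.weights[1]
    assert w.weights[4] > w.weights[3]
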