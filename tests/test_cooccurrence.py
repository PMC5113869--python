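"""Metric unit tests plus brute-force oracle cross-checks.

The oracles enumerate species/fragment pairs explicitly with python
loops, independent of the vectorized implementations.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fragcomm import IncidenceMatrix, MetricUndefinedError, beta_p, c_score, nodf


# ---------------------------------------------------------------------------
# Independent oracles (explicit pair loops)
# ---------------------------------------------------------------------------

def cscore_oracle(a: np.ndarray) -> float:
    a = a[a.sum(axis=1) > 0]
    total, pairs = 0.0, 0
    for i, j in itertools.combinations(range(a.shape[0]), 2):
        shared = int(np.sum(a[i] * a[j]))
        total += (a[i].sum() - shared) * (a[j].sum() - shared)
        pairs += 1
    return total / pairs


def nodf_oracle(a: np.ndarray) -> float:
    a = a[a.sum(axis=1) > 0]

    def axis_pairs(m: np.ndarray):
        vals = []
        for i, j in itertools.combinations(range(m.shape[0]), 2):
            ri, rj = m[i].sum(), m[j].sum()
            if ri == rj:
                vals.append(0.0)
            else:
                rich, poor = (m[i], m[j]) if ri > rj else (m[j], m[i])
                pt = poor.sum()
                vals.append(100.0 * np.sum(rich * poor) / pt if pt else 0.0)
        return vals

    vals = axis_pairs(a) + axis_pairs(a.T)
    return float(np.mean(vals))


def _inc(a) -> IncidenceMatrix:
    a = np.asarray(a)
    return IncidenceMatrix(
        [f"s{i}" for i in range(a.shape[0])],
        [f"f{j}" for j in range(a.shape[1])],
        a,
    )


# ---------------------------------------------------------------------------
# C-score
# ---------------------------------------------------------------------------

class TestCScore:
    def test_single_checkerboard(self):
        assert c_score(_inc([[1, 0], [0, 1]])).value == 1.0

    def test_full_cooccurrence_is_zero(self):
        assert c_score(_inc(np.ones((3, 4)))).value == 0.0

    def test_three_cycle_each_pair_one_unit(self, triplet_inc):
        assert c_score(triplet_inc).value == 1.0

    def test_pairwise_fraction_normalization(self, triplet_inc):
        # each pair: (2-1)(2-1)/(2*2) = 0.25
        assert c_score(triplet_inc, normalization="pairwise-fraction").value == 0.25

    def test_too_few_species(self):
        with pytest.raises(MetricUndefinedError):
            c_score(_inc([[1, 1]]))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        a = (rng.random((6, 7)) < 0.5).astype(int)
        a[a.sum(axis=1) == 0, 0] = 1
        base = c_score(_inc(a)).value
        perm = a[rng.permutation(6)][:, rng.permutation(7)]
        assert c_score(_inc(perm)).value == pytest.approx(base)

    def test_shared_fragment_never_increases_numerator(self):
        # appending a fragment where every species occurs leaves every
        # pair's checkerboard-unit count unchanged and adds none
        rng = np.random.default_rng(7)
        a = (rng.random((5, 6)) < 0.5).astype(int)
        a[a.sum(axis=1) == 0, 0] = 1
        extended = np.hstack([a, np.ones((5, 1), dtype=int)])
        assert cscore_oracle(extended) <= cscore_oracle(a)


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

class TestNODF:
    def test_stepped_triangle_is_perfectly_nested(self):
        assert nodf(_inc([[1, 1, 1], [1, 1, 0], [1, 0, 0]])).value == 100.0

    def test_equal_fills_contribute_zero(self):
        assert nodf(_inc([[1, 0], [0, 1]])).value == 0.0

    def test_mixed_matrix_matches_hand_enumeration(self):
        # rows (3,2,2): two 100% pairs, one equal-fill zero; columns
        # (2,3,2): same -> (200+200)/6
        a = [[1, 1, 1], [1, 1, 0], [0, 1, 1]]
        assert nodf(_inc(a)).value == pytest.approx(400 / 6)
        assert nodf_oracle(np.array(a)) == pytest.approx(400 / 6)

    def test_empty_matrix_rejected(self):
        with pytest.raises(MetricUndefinedError):
            nodf(_inc(np.zeros((2, 2), dtype=int)))

    @pytest.mark.parametrize(
        ("matrix", "expected"),
        [
            ([[1, 1, 1], [1, 1, 0], [0, 1, 1]], 66.6666666667),
            ([[1, 1, 1, 1], [1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]], 100.0),
            ([[1, 0, 1, 1, 0], [0, 1, 1, 0, 1], [1, 1, 0, 1, 1], [1, 0, 0, 1, 0]],
             39.5833333333),
            ([[1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0], [0, 1, 0, 1], [1, 1, 1, 1]],
             25.0),
        ],
    )
    def test_agrees_with_vegan_reference(self, matrix, expected):
        """Values frozen from R vegan's NODF on the same matrices."""
        assert nodf(_inc(matrix)).value == pytest.approx(expected, abs=1e-9)

    def test_bounds(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a = (rng.random((5, 5)) < 0.5).astype(int)
            if (a.sum(axis=1) > 0).sum() < 2:
                continue
            assert 0.0 <= nodf(_inc(a)).value <= 100.0


# ---------------------------------------------------------------------------
# beta_P
# ---------------------------------------------------------------------------

class TestBetaP:
    def test_three_cycle(self, triplet_inc):
        # alpha = 2, gamma = 3
        assert beta_p(triplet_inc).value == pytest.approx(1 / 3)

    def test_identical_fragments_no_turnover(self):
        assert beta_p(_inc(np.ones((4, 5)))).value == 0.0

    def test_one_species_per_fragment_closed_form(self):
        s = 5
        assert beta_p(_inc(np.eye(s, dtype=int))).value == pytest.approx(1 - 1 / s)

    def test_fragment_duplication_and_rich_additions(self):
        a = np.array([[1, 0, 1], [0, 1, 1], [1, 1, 0]])
        b1 = beta_p(_inc(a)).value
        # duplicating every fragment leaves alpha and gamma unchanged
        assert beta_p(_inc(np.hstack([a, a]))).value == pytest.approx(b1)
        # adding a fragment holding the full species pool raises alpha,
        # so turnover strictly decreases
        full = np.hstack([a, np.ones((3, 1), dtype=int)])
        assert beta_p(_inc(full)).value < b1

    def test_all_zero_rejected(self):
        with pytest.raises(MetricUndefinedError):
            beta_p(_inc(np.zeros((2, 2), dtype=int)))


# ---------------------------------------------------------------------------
# Oracle equivalence on random matrices (acceptance-grade property)
# ---------------------------------------------------------------------------

@settings(max_examples=120, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_metrics_match_bruteforce_oracles(seed):
    """Vectorized C-score and NODF equal explicit pair enumeration."""
    from conftest import random_incidence

    inc = random_incidence(np.random.default_rng(seed))
    a = inc.presence.astype(int)
    assert c_score(inc).value == pytest.approx(cscore_oracle(a), abs=1e-12)
    assert nodf(inc).value == pytest.approx(nodf_oracle(a), abs=1e-10)
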