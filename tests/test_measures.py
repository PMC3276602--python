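"""Unit and property tests for the five informativeness measures."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aimsel import (
    AdmixtureSpec,
    FrequencyTable,
    UnsupportedMeasureError,
    delta,
    fic,
    fst_pair,
    informativeness_assignment,
    score_table,
    sic,
)

freq = st.floats(min_value=0.0, max_value=1.0)
interior_freq = st.floats(min_value=0.01, max_value=0.99)
m_interior = st.floats(min_value=0.05, max_value=0.95)


def sic_oracle(p1, p2, m1):
    """Independent evaluation of the three entropy terms."""
    def plogp(p):
        return p * math.log(p) if p > 0 else 0.0
    pa = m1 * p1 + (1 - m1) * p2
    return (
        m1 * (plogp(p1) + plogp(1 - p1))
        + (1 - m1) * (plogp(p2) + plogp(1 - p2))
        - (plogp(pa) + plogp(1 - pa))
    )


@pytest.mark.parametrize(
    "p1,p2,expected",
    [(0.7, 0.2, 0.5), (0.35, 0.35, 0.0), (1.0, 0.0, 1.0)],
)
def test_delta_worked_examples(p1, p2, expected):
    assert delta(p1, p2) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "p1,p2,expected",
    [
        (1.0, 0.0, 1.0),
        (0.7, 0.2, float(Fraction(1, 4) / Fraction(99, 100))),
        (0.9, 0.1, 0.64),
    ],
)
def test_fst_worked_examples(p1, p2, expected):
    assert fst_pair(p1, p2) == pytest.approx(expected, abs=1e-12)


def test_fst_monomorphic_same_allele_is_zero():
    assert fst_pair(0.0, 0.0) == 0.0
    assert fst_pair(1.0, 1.0) == 0.0


@pytest.mark.parametrize(
    "p1,p2,m1,expected",
    [
        (1.0, 0.0, 0.8, 6.25),
        (0.7, 0.2, 0.8, float(Fraction(25, 24))),
        (0.4, 0.4, 0.3, 0.0),
    ],
)
def test_fic_worked_examples(p1, p2, m1, expected):
    assert fic(p1, p2, AdmixtureSpec(m1)) == pytest.approx(expected, abs=1e-9)


@pytest.mark.parametrize("m1", [0.0, 1.0, -0.1])
def test_fic_requires_interior_m1(m1):
    if 0.0 <= m1 <= 1.0:
        with pytest.raises(ValueError, match="strictly"):
            fic(0.5, 0.2, AdmixtureSpec(m1))
    else:
        with pytest.raises(ValueError):
            AdmixtureSpec(m1)


@pytest.mark.parametrize(
    "p1,p2,m1,expected",
    [
        (1.0, 0.0, 0.5, math.log(2.0)),
        (0.7, 0.2, 0.8, sic_oracle(0.7, 0.2, 0.8)),
        (0.55, 0.55, 0.8, 0.0),
    ],
)
def test_sic_worked_examples(p1, p2, m1, expected):
    assert sic(p1, p2, AdmixtureSpec(m1)) == pytest.approx(expected, abs=1e-9)
    assert sic(0.7, 0.2, AdmixtureSpec(0.8)) == pytest.approx(0.084240, abs=1e-6)


@pytest.mark.parametrize(
    "rows,expected",
    [
        ([[1.0, 0.0], [0.0, 1.0]], math.log(2.0)),
        ([[0.7, 0.3], [0.2, 0.8]], 0.13250545091704785),
        ([[0.4, 0.6], [0.4, 0.6]], 0.0),
    ],
)
def test_informativeness_worked_examples(rows, expected):
    assert informativeness_assignment(rows) == pytest.approx(expected, abs=1e-9)


def test_informativeness_shape_and_sum_validation():
    with pytest.raises(ValueError):
        informativeness_assignment([[0.5, 0.5]])  # K=1
    with pytest.raises(ValueError, match="sum"):
        informativeness_assignment([[0.5, 0.4], [0.5, 0.5]])


def test_log_base_rescales_but_preserves_ranks():
    val_e = sic(0.7, 0.2, AdmixtureSpec(0.8), log_base="e")
    val_2 = sic(0.7, 0.2, AdmixtureSpec(0.8), log_base="2")
    assert val_2 == pytest.approx(val_e / math.log(2.0), rel=1e-12)
    i_e = informativeness_assignment([[0.7, 0.3], [0.2, 0.8]], log_base="e")
    i_2 = informativeness_assignment([[0.7, 0.3], [0.2, 0.8]], log_base="2")
    assert i_2 == pytest.approx(i_e / math.log(2.0), rel=1e-12)


def test_out_of_range_frequency_raises():
    for fn in (delta, fst_pair):
        with pytest.raises(ValueError):
            fn(1.2, 0.5)
    with pytest.raises(ValueError):
        sic(-0.1, 0.5)


# ----------------------------------------------------------------------
# property tests
# ----------------------------------------------------------------------

@settings(max_examples=200, deadline=None)
@given(p=freq, m1=m_interior)
def test_zero_at_equality(p, m1):
    spec = AdmixtureSpec(m1)
    assert delta(p, p) == pytest.approx(0.0, abs=1e-12)
    assert fst_pair(p, p) == pytest.approx(0.0, abs=1e-12)
    assert fic(p, p, spec) == pytest.approx(0.0, abs=1e-12)
    assert sic(p, p, spec) == pytest.approx(0.0, abs=1e-12)
    assert informativeness_assignment([[p, 1 - p], [p, 1 - p]]) == pytest.approx(
        0.0, abs=1e-12
    )


@settings(max_examples=200, deadline=None)
@given(p1=freq, p2=freq, m1=m_interior)
def test_allele_relabeling_invariance(p1, p2, m1):
    """Swapping which allele is 'reference' changes no measure."""
    spec = AdmixtureSpec(m1)
    assert delta(1 - p1, 1 - p2) == pytest.approx(delta(p1, p2), abs=1e-12)
    assert fst_pair(1 - p1, 1 - p2) == pytest.approx(fst_pair(p1, p2), abs=1e-12)
    assert fic(1 - p1, 1 - p2, spec) == pytest.approx(fic(p1, p2, spec), rel=1e-9, abs=1e-12)
    assert sic(1 - p1, 1 - p2, spec) == pytest.approx(sic(p1, p2, spec), abs=1e-12)
    a = informativeness_assignment([[p1, 1 - p1], [p2, 1 - p2]])
    b = informativeness_assignment([[1 - p1, p1], [1 - p2, p2]])
    assert a == pytest.approx(b, abs=1e-12)


@settings(max_examples=200, deadline=None)
@given(p1=freq, p2=freq, m1=m_interior)
def test_population_swap_symmetries(p1, p2, m1):
    spec = AdmixtureSpec(m1)
    swapped = AdmixtureSpec(1 - m1)
    assert delta(p2, p1) == delta(p1, p2)
    assert fst_pair(p2, p1) == pytest.approx(fst_pair(p1, p2), abs=1e-12)
    # FIC/SIC invariant only under the simultaneous swap m1 <-> 1 - m1
    assert fic(p2, p1, swapped) == pytest.approx(fic(p1, p2, spec), rel=1e-9, abs=1e-12)
    assert sic(p2, p1, swapped) == pytest.approx(sic(p1, p2, spec), abs=1e-12)
    a = informativeness_assignment([[p1, 1 - p1], [p2, 1 - p2]])
    b = informativeness_assignment([[p2, 1 - p2], [p1, 1 - p1]])
    assert a == pytest.approx(b, abs=1e-12)


def test_fic_is_asymmetric_without_m_swap():
    """FIC favors fixation in the majority-contribution population."""
    spec = AdmixtureSpec(0.8)
    assert fic(0.9, 0.3, spec) != pytest.approx(fic(0.3, 0.9, spec), rel=1e-6)


def test_bounds_on_random_pairs(rng):
    p1 = rng.uniform(0, 1, 10_000)
    p2 = rng.uniform(0, 1, 10_000)
    spec = AdmixtureSpec(0.8)
    assert np.all((delta(p1, p2) >= 0) & (delta(p1, p2) <= 1))
    f = fst_pair(p1, p2)
    assert np.all((f >= 0) & (f <= 1))
    assert np.all(sic(p1, p2, spec) >= 0)
    assert np.all(fic(p1, p2, spec) >= 0)
    i_n = np.array(
        [
            informativeness_assignment([[a, 1 - a], [b, 1 - b]])
            for a, b in zip(p1[:200], p2[:200])
        ]
    )
    assert np.all((i_n >= 0) & (i_n <= math.log(2) + 1e-12))


# ----------------------------------------------------------------------
# table-level scoring
# ----------------------------------------------------------------------

def test_score_table_delta_rank_order(toy_table):
    scores = score_table(toy_table)
    by_id = scores.df.set_index("marker_id")
    assert by_id.loc[["A", "B", "C"], "rank_delta"].tolist() == [1, 2, 3]
    assert by_id.loc["A", "delta"] == 1.0


def test_score_table_empty():
    table = FrequencyTable.from_arrays([], [], [], {"p1": [], "p2": []})
    scores = score_table(table)
    assert len(scores) == 0


def test_score_table_all_equal_scores_zero_ranks_by_tiebreak():
    table = FrequencyTable.from_arrays(
        ["a", "b", "c"], ["2", "1", "1"], [500, 900, 100],
        {"p1": [0.4, 0.4, 0.4], "p2": [0.4, 0.4, 0.4]},
    )
    scores = score_table(table)
    for m in scores.measures:
        assert np.all(scores.values(m) == 0.0)
        # tie-break: (chrom, pos, id) -> c@1:100, b@1:900, a@2:500
        by_id = scores.df.set_index("marker_id")
        assert by_id.loc[["c", "b", "a"], f"rank_{m}"].tolist() == [1, 2, 3]


def test_score_table_monomorphic_flagged_zero():
    table = FrequencyTable.from_arrays(
        ["a", "b"], ["1", "1"], [100, 200],
        {"p1": [0.0, 0.7], "p2": [0.0, 0.2]},
    )
    scores = score_table(table)
    assert scores.df["monomorphic"].tolist() == [True, False]
    assert scores.df.set_index("marker_id").loc["a", ["delta", "fst", "fic", "sic", "i_n"]].eq(0).all()


def test_score_table_k3_rejects_pairwise_measures():
    table = FrequencyTable.from_arrays(
        ["a"], ["1"], [100], {"p1": [0.1], "p2": [0.5], "p3": [0.9]}
    )
    with pytest.raises(UnsupportedMeasureError, match="fst"):
        score_table(table)
    scores = score_table(table, measures=["i_n"])
    assert scores.values("i_n")[0] > 0


def test_ranks_are_permutation(small_sim):
    _, _, scores, _, _ = small_sim
    M = len(scores)
    for m in scores.measures:
        assert sorted(scores.ranks(m)) == list(range(1, M + 1))
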