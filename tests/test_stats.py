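"""Summary statistics and pairwise comparison layer.

Printed multi-taxon reference values come from a published comparison
table of 30 prokaryotic replicons; centers and geometric means printed at
2 decimals are used as inputs, so reconstructions are checked to the
rounding tolerance of 2-decimal inputs.
"""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gfmap import (
    GeometricSummary,
    NucleotideSequence,
    compare_all_pairs,
    compare_chain,
    compare_pair,
    differentiate_rate,
    euclidean_distance,
    fingerprint_incremental,
    geometric_mean_signed,
    summarize_track,
    weighted_differentiate_rate,
)

finite = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


def make_summary(id, center, gm=None):
    return GeometricSummary(
        id=id,
        n_bases=1000,
        center=center,
        sd=(0.0, 0.0, 0.0),
        gm=geometric_mean_signed(center) if gm is None else gm,
    )


# --- geometric mean -------------------------------------------------------


@pytest.mark.parametrize(
    "center,expected,tol",
    [
        ((4145.50, 7328.50, 395302.72), 22900.28, 0.05),
        ((476.50, -1916.50, 387938.65), -7075.85, 0.05),
        ((-299.00, -2237.00, -38421.01), -2951.00, 0.05),
        ((1.0, 1.0, 1.0), 1.0, 0),
        ((0.0, 5.0, -3.0), 0.0, 0),
        ((-2.0, 4.0, 1.0), -2.0, 1e-12),
    ],
)
def test_geometric_mean_signed(center, expected, tol):
    assert geometric_mean_signed(center) == pytest.approx(expected, abs=tol)


@given(center=st.tuples(finite, finite, finite), k=st.floats(0.01, 100))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_gm_positive_homogeneity(center, k):
    scaled = tuple(k * c for c in center)
    assert geometric_mean_signed(scaled) == pytest.approx(
        k * geometric_mean_signed(center), rel=1e-9, abs=1e-9
    )


@given(center=st.tuples(finite, finite, finite))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_gm_sign_and_magnitude(center):
    gm = geometric_mean_signed(center)
    prod = center[0] * center[1] * center[2]
    if prod == 0:
        assert gm == 0.0
    else:
        assert np.sign(gm) == np.sign(prod)
        assert abs(gm) ** 3 == pytest.approx(abs(prod), rel=1e-9)


# --- summaries ------------------------------------------------------------


def test_summarize_constant_track():
    track = fingerprint_incremental(NucleotideSequence("s", "AAAA"))
    summary = summarize_track(track)
    assert summary.center == (2.5, 2.5, 2.5)
    assert summary.sd == (0.0, 0.0, 0.0)
    assert summary.gm == 2.5
    assert summary.n_bases == 4


def test_forty_mer_summary(forty_mer):
    summary = summarize_track(fingerprint_incremental(forty_mer))
    # closed form with c_A=12, c_C=16, c_G=8, c_T=4: factor 41/80 = 0.5125
    assert summary.center == (0.0, 8.2, -4.1)
    assert summary.gm == 0.0


def test_center_depends_only_on_composition(random_seq):
    """Shuffling the sequence leaves the geometric center unchanged, exactly."""
    shuffled = "".join(random.Random(0).sample(random_seq.residues, random_seq.n_bases))
    a = summarize_track(fingerprint_incremental(random_seq))
    b = summarize_track(fingerprint_incremental(NucleotideSequence("shuf", shuffled)))
    assert a.center == b.center


# --- pairwise measures ----------------------------------------------------


@pytest.mark.parametrize(
    "ca,cb,expected",
    [
        ((-723.50, 3286.50, -25173.50), (-686.50, 1944.50, -36639.51), 11544.34),
        ((-874.00, 1275.00, -360470.18), (-851.50, 1213.50, -360811.68), 347.72),
        ((644.00, -2081.00, 388729.15), (476.50, -1916.50, 387938.65), 824.63),
    ],
)
def test_euclidean_distance_printed_pairs(ca, cb, expected):
    assert euclidean_distance(ca, cb) == pytest.approx(expected, abs=0.05)


def test_euclidean_distance_identity():
    c = (1.5, -2.5, 3.5)
    assert euclidean_distance(c, c) == 0.0


@given(st.tuples(finite, finite, finite), st.tuples(finite, finite, finite),
       st.tuples(finite, finite, finite))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_euclidean_distance_is_a_metric(a, b, c):
    assert euclidean_distance(a, b) >= 0
    assert euclidean_distance(a, b) == euclidean_distance(b, a)
    assert euclidean_distance(a, c) <= (
        euclidean_distance(a, b) + euclidean_distance(b, c) + 1e-7
    )


@pytest.mark.parametrize(
    "gma,gmb,expected,tol",
    [
        (-8046.40, -7075.85, 6.42, 0.01),
        (22900.28, -19979.20, 1467.93, 0.05),
        (5620.22, -2951.00, 321.11, 0.05),
        (10615.71, 10284.83, 1.58, 0.01),
        (3.7, 3.7, 0.0, 0),
    ],
)
def test_differentiate_rate_printed_values(gma, gmb, expected, tol):
    assert differentiate_rate(gma, gmb) == pytest.approx(expected, abs=tol)


def test_differentiate_rate_undefined_on_cancellation():
    assert differentiate_rate(5.0, -5.0) is None
    assert differentiate_rate(0.0, 0.0) is None


@given(gma=finite, gmb=finite, k=st.floats(0.01, 100))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_differentiate_rate_symmetric_and_scale_invariant(gma, gmb, k):
    dr = differentiate_rate(gma, gmb)
    assert dr == differentiate_rate(gmb, gma)
    if dr is not None and gma + gmb != 0:
        scaled = differentiate_rate(k * gma, k * gmb)
        if scaled is not None:
            assert scaled == pytest.approx(dr, rel=1e-6, abs=1e-9)


@pytest.mark.parametrize(
    "gma,gmb,ca,cb,expected",
    [
        (7378.43, 7197.28,
         (-874.00, 1275.00, -360470.18), (-851.50, 1213.50, -360811.68), 432.16),
        (-8046.40, -7075.85,
         (644.00, -2081.00, 388729.15), (476.50, -1916.50, 387938.65), 5292.47),
    ],
)
def test_weighted_differentiate_rate_printed_values(gma, gmb, ca, cb, expected):
    dr = differentiate_rate(gma, gmb)
    ed = euclidean_distance(ca, cb)
    assert weighted_differentiate_rate(dr, ed) == pytest.approx(expected, abs=0.5)


def test_weighted_differentiate_rate_degenerate():
    assert weighted_differentiate_rate(None, 10.0) is None
    assert weighted_differentiate_rate(0.0, 10.0) == 0.0


# --- pair / chain / matrix ------------------------------------------------


def test_compare_pair_self_is_zero():
    s = make_summary("a", (1.0, 2.0, 3.0))
    cmp_row = compare_pair(s, s)
    assert (cmp_row.ed, cmp_row.dr, cmp_row.wdr) == (0.0, 0.0, 0.0)


def test_compare_pair_opposite_sign_gm_is_flagged():
    a = make_summary("a", (1.0, 1.0, 8.0))   # gm 2
    b = make_summary("b", (-1.0, 1.0, 8.0))  # gm -2
    cmp_row = compare_pair(a, b)
    assert cmp_row.dr is None and cmp_row.wdr is None
    assert cmp_row.ed > 0


def test_compare_chain_shape():
    ss = [make_summary(str(i), (float(i + 1), 1.0, 1.0)) for i in range(3)]
    rows = compare_chain(ss)
    assert len(rows) == 3
    assert rows[-1].is_empty and rows[-1].ed is None
    assert all(not r.is_empty for r in rows[:2])
    with pytest.raises(ValueError):
        compare_chain(ss[:1])


# Printed (center, Gm) rows for the 8 E. coli chromosomes, in report order.
ECOLI_ROWS = [
    ("SMS-3-5", (-723.50, 3286.50, -25173.50), 3911.76),
    ("K-12/MG1655", (-686.50, 1944.50, -36639.51), 3657.07),
    ("K-12/DH10B", (-626.50, 1452.50, -36613.51), 3217.80),
    ("K-12/W3110", (254.00, -1905.00, -37151.01), 2619.59),
    ("UTI89", (-3518.50, 1648.50, -30606.51), 5620.22),
    ("BL21(DE3)", (-299.00, -2237.00, -38421.01), -2951.00),
    ("O55:H7/CB9615", (4072.00, 3474.00, -28174.01), -7359.17),
    ("CFT073", (1205.00, 3302.00, -24979.00), -4632.12),
]


def test_compare_chain_reconstructs_printed_rates():
    ss = [make_summary(i, c, gm) for i, c, gm in ECOLI_ROWS]
    rows = compare_chain(ss)
    printed = [3.36, 6.39, 10.25, 36.42, 321.11, 42.76, 22.74]
    got = [r.dr for r in rows[:-1]]
    assert got == pytest.approx(printed, abs=0.05)


def test_compare_chain_identical_summaries():
    s = make_summary("x", (2.0, 3.0, 4.0))
    rows = compare_chain([s, s, s])
    assert all(r.dr == 0.0 for r in rows[:-1])


def test_compare_all_pairs_matrix():
    ss = [make_summary(str(i), (float(i + 1), 2.0, 3.0)) for i in range(3)]
    matrix = compare_all_pairs(ss)
    assert len(matrix) == 3 and all(len(row) == 3 for row in matrix)
    for i in range(3):
        assert matrix[i][i].ed == 0.0 and matrix[i][i].dr == 0.0
        for j in range(3):
            assert matrix[i][j].ed == matrix[j][i].ed
            assert matrix[i][j].dr == matrix[j][i].dr
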