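import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from floodmeadow import community as comm
from floodmeadow.io import CoverMatrix, ValidationError


@pytest.mark.parametrize(
    "score,percent",
    [(0, 0.0), (1, 3.125), (2, 9.375), (3, 18.75), (4, 37.5), (5, 75.0)],
)
def test_hsd_midpoints(score, percent):
    assert comm.hsd_to_percent(score) == percent


def test_hsd_rejects_out_of_range():
    with pytest.raises(ValidationError):
        comm.hsd_to_percent(6)


def test_percent_to_hsd_class_bounds():
    assert comm.percent_to_hsd(60.0) == 5  # >= 50 %
    assert comm.percent_to_hsd(5.0) == 1  # <= 6.25 %
    assert comm.percent_to_hsd(0.1) == 0  # below detection


def test_species_richness(small_cover):
    assert comm.species_richness(small_cover) == 3
    assert comm.species_richness(small_cover, plots=[3]) == 2


def test_species_richness_all_zero_is_zero():
    scores = pd.DataFrame({"a": [0, 0], "b": [0, 0]}, index=[1, 2])
    cm = CoverMatrix(survey_year=2016, scores=scores)
    assert comm.species_richness(cm) == 0


@pytest.mark.parametrize(
    "abund,expected",
    [
        ([7.0], 1.0),
        ([1, 1, 1, 1], 4.0),
        ([2, 1, 1], 1 / (0.25 + 0.0625 + 0.0625)),
    ],
)
def test_inverse_simpson(abund, expected):
    assert comm.inverse_simpson(np.array(abund)) == pytest.approx(expected)


def test_inverse_simpson_requires_positive_total():
    with pytest.raises(ValidationError):
        comm.inverse_simpson(np.zeros(3))


def test_relative_abundance_symmetry():
    scores = pd.DataFrame({"a": [3, 2], "b": [3, 2]}, index=[1, 2])
    cm = CoverMatrix(survey_year=1982, scores=scores)
    assert comm.relative_abundance(cm, "a") == pytest.approx(50.0)
    only = pd.DataFrame({"a": [3, 2], "b": [0, 0]}, index=[1, 2])
    cm2 = CoverMatrix(survey_year=1982, scores=only)
    assert comm.relative_abundance(cm2, "a") == pytest.approx(100.0)


def test_rank_abundance_order_and_permutation_invariance():
    scores = pd.DataFrame({"b": [5, 5], "a": [1, 0], "c": [1, 0]}, index=[1, 2])
    cm = CoverMatrix(survey_year=1982, scores=scores)
    table = comm.rank_abundance(cm)
    assert list(table["species"]) == ["b", "a", "c"]  # ties alphabetical
    assert list(table["mean_cover"]) == [5.0, 0.5, 0.5]
    reversed_cm = CoverMatrix(survey_year=1982, scores=scores.loc[[2, 1]])
    pd.testing.assert_frame_equal(table, comm.rank_abundance(reversed_cm))


@pytest.mark.parametrize(
    "x,y,expected",
    [
        ([1, 2, 3], [1, 2, 3], 0.0),
        ([1, 0], [0, 2], 1.0),
        ([1, 2], [2, 2], 1 / 7),
    ],
)
def test_bray_curtis_examples(x, y, expected):
    assert comm.bray_curtis(x, y) == pytest.approx(expected)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0, max_value=100), min_size=2, max_size=10),
    st.data(),
)
def test_bray_curtis_properties(x, data):
    y = data.draw(
        st.lists(
            st.floats(min_value=0, max_value=100), min_size=len(x), max_size=len(x)
        )
    )
    if sum(x) + sum(y) == 0:
        return
    d = comm.bray_curtis(x, y)
    assert 0 <= d <= 1
    assert d == pytest.approx(comm.bray_curtis(y, x))
    if all(a == 0 or b == 0 for a, b in zip(x, y)):
        assert d == 1.0  # disjoint supports: numerator equals denominator


def test_bray_curtis_undefined_for_empty_pair():
    with pytest.raises(ValidationError):
        comm.bray_curtis([0, 0], [0, 0])


# ---------------------------------------------------------------------------
# Ward clustering


from tests_support_ward import oracle_partition, scipy_partition, ward_d2_oracle


def test_ward_recovers_two_separated_pairs():
    d = np.array(
        [
            [0, 0.02, 0.9, 0.91],
            [0.02, 0, 0.92, 0.9],
            [0.9, 0.92, 0, 0.03],
            [0.91, 0.9, 0.03, 0],
        ]
    )
    dm = comm.DissimilarityMatrix(labels=[10, 11, 20, 21], values=d)
    result = comm.ward_cluster(dm)
    assignment = comm.cut_clusters(result, 2)
    assert assignment.labels[10] == assignment.labels[11]
    assert assignment.labels[20] == assignment.labels[21]
    assert assignment.labels[10] != assignment.labels[20]


def test_ward_matches_brute_force_oracle(rng):
    for n in (4, 5, 6, 7, 8):
        for _ in range(10):
            pts = rng.random((n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            d = d / (d.max() + 1e-9)
            dm = comm.DissimilarityMatrix(labels=list(range(n)), values=d)
            result = comm.ward_cluster(dm)
            heights, merges = ward_d2_oracle(d)
            np.testing.assert_allclose(result.merge_heights, heights, rtol=1e-9)
            for k in range(1, n + 1):
                assert scipy_partition(result, k) == oracle_partition(merges, n, k)


def test_cut_clusters_extremes(small_cover):
    d = comm.dissimilarity_matrix(small_cover)
    result = comm.ward_cluster(d)
    singletons = comm.cut_clusters(result, 3)
    assert len(set(singletons.labels.values())) == 3
    one = comm.cut_clusters(result, 1)
    assert set(one.labels.values()) == {"Cluster1"}
    with pytest.raises(ValidationError):
        comm.cut_clusters(result, 4)


def test_cluster_labels_follow_descending_elevation():
    d = np.array([[0, 0.05, 0.9], [0.05, 0, 0.92], [0.9, 0.92, 0]])
    dm = comm.DissimilarityMatrix(labels=[1, 2, 3], values=d)
    assignment = comm.cut_clusters(
        comm.ward_cluster(dm), 2, elevations={1: 1.3, 2: 1.35, 3: 2.0}
    )
    # the high-elevation singleton gets the lowest cluster id (driest first)
    assert assignment.labels[3] == "Cluster1"
    assert assignment.labels[1] == assignment.labels[2] == "Cluster2"


# ---------------------------------------------------------------------------
# colonisation/extinction test


@pytest.mark.parametrize(
    "gains,losses,expected",
    [(4, 4, 1.0), (8, 0, 2 / 256), (7, 1, 18 / 256)],
)
def test_frequency_change_examples(gains, losses, expected):
    assert comm.frequency_change_test(gains, losses) == pytest.approx(expected)


def test_frequency_change_matches_enumeration_and_scipy():
    for n in range(1, 13):
        for gains in range(n + 1):
            losses = n - gains
            p = comm.frequency_change_test(gains, losses)
            # enumerate all 2^n equally likely gain/loss outcomes: the lower
            # tail is the share of outcomes at least as extreme on that side
            k = min(gains, losses)
            tail_count = sum(
                1
                for outcome in itertools.product([0, 1], repeat=n)
                if sum(outcome) <= k
            )
            assert p == pytest.approx(min(1.0, 2 * tail_count / 2**n))
            assert p == pytest.approx(
                sps.binomtest(gains, n, 0.5, alternative="two-sided").pvalue
            )


def test_frequency_change_undefined_for_no_change():
    with pytest.raises(ValidationError):
        comm.frequency_change_test(0, 0)
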