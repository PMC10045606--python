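import numpy as np
import pandas as pd
import pytest

from floodmeadow import demography as dem
from floodmeadow import simulate
from floodmeadow.io import STAGES, ValidationError


def _histories(rows):
    return pd.DataFrame(rows, columns=["individual_id", "year", "stage"])


def test_gap_year_classified_as_dormant():
    h = _histories([(1, 1981, "small"), (1, 1983, "medium")])
    fates = dem.classify_fates(h, (1981, 1983))
    assert fates.counts[(1981, 1982)].loc["dormant", "small"] == 1
    assert fates.counts[(1982, 1983)].loc["medium", "dormant"] == 1
    assert fates.dormant_years[1] == [1982]


def test_never_relocated_is_dead():
    h = _histories([(1, 1981, "reproductive")])
    fates = dem.classify_fates(h, (1981, 1983))
    assert fates.counts[(1981, 1982)].loc["dead", "reproductive"] == 1
    assert fates.dead_from[1] == 1982


def test_new_plant_emerges_from_dormancy():
    h = _histories([(1, 1982, "small"), (1, 1983, "small")])
    fates = dem.classify_fates(h, (1981, 1983))
    assert fates.counts[(1981, 1982)].loc["small", "dormant"] == 1


def test_zero_observation_individual_rejected():
    h = pd.DataFrame(
        {"individual_id": [1], "year": [1982], "stage": [np.nan]}
    )
    with pytest.raises(ValidationError, match="zero observations"):
        dem.classify_fates(h, (1981, 1983))


def test_classification_conserves_individual_years():
    # every individual-year in the window is exactly one of:
    # observed stage, inferred dormant, dead, or pre-appearance
    cfg = simulate.DemographyGenConfig(n_individuals=300, n_years=5, seed=9)
    observed, _, _ = simulate.gen_individual_fates(cfg)
    window = (1981, 1985)
    fates = dem.classify_fates(observed, window)
    for ind, sub in observed.groupby("individual_id"):
        seen = set(sub["year"])
        dormant = set(fates.dormant_years.get(ind, []))
        dead_from = fates.dead_from.get(ind)
        for year in range(window[0], window[1] + 1):
            in_obs = year in seen
            in_dorm = year in dormant
            is_dead = dead_from is not None and year >= dead_from
            pre = year < min(seen | dormant)
            assert sum([in_obs, in_dorm, is_dead, pre]) == 1, (ind, year)


def test_projection_matrix_from_hand_counts():
    h = _histories(
        [(i, 1981, "small") for i in range(1, 5)]
        + [(1, 1982, "medium"), (2, 1982, "medium"), (3, 1982, "small")]
        + [(i, 1983, "medium") for i in (1, 2, 3)]
        # one individual per remaining origin stage so every column is defined
        + [(10, y, "medium") for y in (1981, 1982, 1983)]
        + [(11, y, "large_vegetative") for y in (1981, 1982, 1983)]
        + [(12, y, "reproductive") for y in (1981, 1982, 1983)]
        + [(13, 1982, "small"), (13, 1983, "small")]  # dormant in 1981
    )
    fates = dem.classify_fates(h, (1981, 1983))
    pm = dem.build_projection_matrix(fates, (1981, 1982))
    col = pm.matrix["small"]
    assert col["small"] == pytest.approx(0.25)
    assert col["medium"] == pytest.approx(0.5)
    assert col.sum() == pytest.approx(0.75)  # 1 of 4 died


def test_projection_matrix_all_survive():
    stages = ["small"] * 10 + [
        "medium",
        "large_vegetative",
        "reproductive",
    ]
    h = _histories(
        [(i, 1981, s) for i, s in enumerate(stages)]
        + [(i, 1982, s) for i, s in enumerate(stages)]
        + [(99, 1982, "small")]  # dormant in 1981, so that column is defined
    )
    fates = dem.classify_fates(h, (1981, 1982))
    pm = dem.build_projection_matrix(fates, (1981, 1982))
    assert pm.matrix.loc["small", "small"] == pytest.approx(1.0)
    np.testing.assert_allclose(pm.matrix["small"], [1, 0, 0, 0, 0])


def test_empty_origin_stage_names_stage():
    h = _histories([(1, 1981, "small"), (1, 1982, "small")])
    fates = dem.classify_fates(h, (1981, 1982))
    with pytest.raises(ValidationError, match="medium"):
        dem.build_projection_matrix(fates, (1981, 1982))


def test_growth_rate_identity_and_hand_example():
    assert dem.growth_rate(np.eye(5)) == pytest.approx(1.0)
    a = np.array([[0.5, 0.2], [0.3, 0.4]])
    assert dem.growth_rate(a) == pytest.approx(0.7)  # (0.9 + sqrt(0.25))/2
    with pytest.raises(ValidationError):
        dem.growth_rate(np.array([[np.nan, 0], [0, 1]]))


def test_constructed_matrices_have_lambda_at_most_one(rng):
    # without a fecundity row a column-substochastic matrix cannot grow
    for _ in range(50):
        a = rng.random((5, 5))
        a = a / a.sum(axis=0) * rng.uniform(0.3, 1.0, size=5)
        assert dem.growth_rate(a) <= 1.0 + 1e-10


def test_stable_structure_diagonal_and_duality():
    a = np.diag([0.9, 0.5, 0.3])
    w, v = dem.stable_structure(a)
    np.testing.assert_allclose(w, [1, 0, 0], atol=1e-12)
    b = np.array([[0.5, 0.3], [0.2, 0.6]])
    w_b, v_b = dem.stable_structure(b)
    w_t, v_t = dem.stable_structure(b.T)
    np.testing.assert_allclose(w_b / w_b.max(), v_t / v_t.max(), atol=1e-10)


def test_stable_structure_matches_projection_iteration(rng):
    a = simulate.default_truth_matrix().to_numpy()
    w, v = dem.stable_structure(a)
    lam = dem.growth_rate(a)
    x = rng.random(5) + 0.1
    for _ in range(2000):
        x = a @ x
        x = x / x.sum()
    np.testing.assert_allclose(x, w, atol=1e-8)
    assert w.sum() == pytest.approx(1.0)
    assert v @ w == pytest.approx(1.0)
    assert lam <= 1.0


def test_sensitivity_matches_finite_difference(rng):
    a = simulate.default_truth_matrix().to_numpy()
    s = dem.sensitivity_matrix(a)
    h = 1e-6
    for i in range(5):
        for j in range(5):
            ap = a.copy()
            ap[i, j] += h
            fd = (dem.growth_rate(ap, cross_check=False) - dem.growth_rate(a, cross_check=False)) / h
            assert fd == pytest.approx(s[i, j], rel=1e-4, abs=1e-8)


def test_elasticities_sum_to_one_and_scalar_case():
    a = simulate.default_truth_matrix().to_numpy()
    assert dem.elasticity_matrix(a).sum() == pytest.approx(1.0, abs=1e-10)
    s1 = dem.sensitivity_matrix(np.array([[0.8]]))
    e1 = dem.elasticity_matrix(np.array([[0.8]]))
    assert s1[0, 0] == pytest.approx(1.0)
    assert e1[0, 0] == pytest.approx(1.0)


def test_dormant_column_reuse_is_flagged():
    h = _histories(
        [
            (1, 1981, "small"),
            (1, 1983, "small"),  # dormant 1982, exits 1983
            (2, 1981, "medium"),
            (2, 1982, "medium"),
            (2, 1983, "medium"),
            (3, 1981, "large_vegetative"),
            (3, 1982, "large_vegetative"),
            (3, 1983, "large_vegetative"),
            (4, 1981, "reproductive"),
            (4, 1982, "reproductive"),
            (4, 1983, "reproductive"),
            (5, 1981, "small"),
            (5, 1982, "small"),
            (5, 1983, "small"),
        ]
    )
    fates = dem.classify_fates(h, (1981, 1983))
    # dormant exits are only observable in 1982→1983 (plant 1 re-emerging);
    # the 1981→1982 matrix must borrow that column and say so
    direct = dem.build_projection_matrix(fates, (1982, 1983))
    assert direct.flags == []
    assert direct.matrix.loc["small", "dormant"] == pytest.approx(1.0)
    borrowed = dem.build_projection_matrix(
        fates, (1981, 1982), reuse_dormant_from=(1982, 1983)
    )
    assert any("reused" in f for f in borrowed.flags)
    assert borrowed.matrix.loc["small", "dormant"] == pytest.approx(1.0)
    with pytest.raises(ValidationError, match="dormant"):
        dem.build_projection_matrix(fates, (1981, 1982))


def test_dormancy_flow_summary_hand_counts():
    h = _histories(
        [
            (1, 1981, "small"), (1, 1983, "small"),
            (2, 1981, "small"), (2, 1983, "medium"),
            (3, 1981, "large_vegetative"), (3, 1983, "large_vegetative"),
        ]
    )
    fates = dem.classify_fates(h, (1981, 1983))
    summary = dem.dormancy_flow_summary(fates)
    into = summary[
        (summary.year_pair == "1981-1982") & (summary.direction == "into_dormancy")
    ].set_index("stage")
    assert into.loc["small", "count"] == 2
    assert into.loc["small", "percent"] == pytest.approx(100 * 2 / 3)
    assert into.loc["large_vegetative", "percent"] == pytest.approx(100 / 3)
    # totals equal the dormant-row sums of the fate table
    assert into["count"].sum() == fates.counts[(1981, 1982)].loc["dormant"].sum()


def test_generator_truth_tally_matches_probabilities():
    cfg = simulate.DemographyGenConfig(n_individuals=4000, n_years=3, seed=21)
    _, truth_states, truth = simulate.gen_individual_fates(cfg)
    tallies = simulate.tally_true_transitions(truth_states)
    frame = tallies[(1981, 1982)]
    p = truth.to_numpy()
    n_origin = frame.sum(axis=0).to_numpy()
    phat = frame.loc[list(STAGES)].to_numpy() / np.maximum(n_origin, 1)
    # 99% familywise binomial bounds over the 25 entries
    z = 3.54
    bound = z * np.sqrt(p * (1 - p) / np.maximum(n_origin[None, :], 1))
    assert (np.abs(phat - p) <= bound + 1e-12).all()
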