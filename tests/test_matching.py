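import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphoxfer import (
    balanced_config,
    build_cost_matrix,
    compute_smd,
    estimate_propensity,
    generate_cohort,
    match_subgroups,
    solve_assignment,
)
from morphoxfer.matching import resolve_caliper


def brute_force_total(cost):
    """Exhaustive minimum assignment cost (oracle for small instances)."""
    n, m = cost.shape
    if n <= m:
        return min(
            sum(cost[i, p[i]] for i in range(n))
            for p in itertools.permutations(range(m), n)
        )
    return brute_force_total(cost.T)


class TestSmd:
    def test_identical_vectors_zero(self):
        v = np.array([1.0, 2.0, 3.0])
        assert compute_smd(v, v) == 0.0

    def test_unit_shift_unit_sd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 200_000)
        assert compute_smd(a, a + 1.0) == pytest.approx(1.0, abs=0.02)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 50), rng.normal(0.4, 1.2, 60)
        assert compute_smd(a, b) == pytest.approx(compute_smd(10 * a, 10 * b))

    def test_binary_uses_proportion_variance(self):
        a = np.array([1, 1, 0, 0], float)  # p = 0.5
        b = np.array([1, 1, 1, 0], float)  # p = 0.75
        pooled = np.sqrt((0.25 + 0.1875) / 2)
        assert compute_smd(a, b) == pytest.approx(0.25 / pooled)

    def test_zero_pooled_sd_unequal_means(self):
        assert compute_smd([1.0, 1.0], [2.0, 2.0], binary=False) == float("inf")


class TestCostMatrix:
    def test_absolute_difference(self):
        cost, _ = build_cost_matrix([0.2], [0.5], caliper=float("inf"))
        assert cost.shape == (1, 1)
        assert cost[0, 0] == pytest.approx(0.3)

    def test_all_gaps_beyond_caliper_hit_sentinel(self):
        cost, sentinel = build_cost_matrix([0.1, 0.15], [0.9, 0.95], caliper=0.1)
        assert (cost == sentinel).all()

    @given(
        st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
        st.lists(st.floats(0.01, 0.99), min_size=1, max_size=8),
    )
    @settings(max_examples=50, deadline=None)
    def test_sentinel_exceeds_any_feasible_total(self, a, b):
        cost, sentinel = build_cost_matrix(a, b, caliper=float("inf"))
        assert sentinel > min(len(a), len(b)) * cost.max()

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            build_cost_matrix([], [0.5])


class TestAssignment:
    def test_two_by_two_example(self):
        cost = np.array([[0.1, 0.4], [0.3, 0.2]])
        pairs = solve_assignment(cost)
        assert pairs == [(0, 0), (1, 1)]
        assert sum(cost[i, j] for i, j in pairs) == pytest.approx(0.3)

    def test_identical_lists_zero_total(self):
        scores = [0.2, 0.4, 0.6]
        cost, sentinel = build_cost_matrix(scores, scores, caliper=float("inf"))
        pairs = solve_assignment(cost, sentinel)
        assert len(pairs) == 3
        assert sum(cost[i, j] for i, j in pairs) == pytest.approx(0.0)

    @pytest.mark.parametrize("trial", range(20))
    def test_matches_brute_force_on_random_7x7(self, trial):
        rng = np.random.default_rng(trial)
        n, m = rng.integers(2, 8, size=2)
        cost = rng.uniform(0, 1, (n, m))
        pairs = solve_assignment(cost)
        total = sum(cost[i, j] for i, j in pairs)
        assert total == pytest.approx(brute_force_total(cost), abs=1e-10)

    def test_sentinel_pairs_discarded(self):
        cost, sentinel = build_cost_matrix([0.1, 0.9], [0.12, 0.5], caliper=0.05)
        pairs = solve_assignment(cost, sentinel)
        assert pairs == [(0, 0)]


def _two_group_frame(n_a=80, n_b=80, age_shift=0.0, seed=0, site_imbalance=False):
    cfg = balanced_config({"HC": n_b, "sPD": n_a}, seed=seed)
    participants, _ = generate_cohort(cfg)
    if age_shift:
        participants.loc[participants["pd_diagnosis"] == 1, "age"] += age_shift
    if site_imbalance:
        rng = np.random.default_rng(seed + 1)
        cases = participants["pd_diagnosis"] == 1
        # cases drawn 2:1 towards site_1
        participants.loc[cases, "site"] = np.where(
            rng.random(cases.sum()) < 2 / 3, "site_1", "site_2"
        )
        participants.loc[~cases, "site"] = np.where(
            rng.random((~cases).sum()) < 1 / 3, "site_1", "site_2"
        )
    return participants


class TestPropensity:
    def test_uninformative_covariates_give_prevalence_scores(self):
        participants = _two_group_frame(600, 600, seed=4)
        model = estimate_propensity(participants, "pd_diagnosis", ["age", "sex", "site"])
        assert model.scores.between(0, 1).all()
        assert model.scores.mean() == pytest.approx(0.5, abs=0.03)
        from sklearn.metrics import roc_auc_score

        y = participants.sort_values("participant_id")["pd_diagnosis"]
        auc = roc_auc_score(y, model.scores.to_numpy())
        assert auc == pytest.approx(0.5, abs=0.06)

    def test_lrrk2_vs_spd_covariate_terms(self):
        cfg = balanced_config({"sPD": 60, "LRRK2_PD": 40}, seed=5)
        participants, _ = generate_cohort(cfg)
        model = estimate_propensity(
            participants, "lrrk2_carrier", ["sex", "age", "disease_duration", "site"]
        )
        assert model.covariates == ("sex", "age", "disease_duration", "site")
        named = [c for c in model.design_columns if not c.startswith("site_")]
        assert named == ["const", "sex", "age", "disease_duration"]

    def test_perfect_separation_flagged_with_ridge_fallback(self):
        participants = _two_group_frame(40, 40, seed=6)
        participants["age"] = np.where(
            participants["pd_diagnosis"] == 1, 70.0, 50.0
        ) + np.random.default_rng(0).normal(0, 0.5, len(participants))
        with pytest.warns(UserWarning, match="ridge"):
            model = estimate_propensity(participants, "pd_diagnosis", ["age"])
        assert model.method == "ridge"
        from sklearn.metrics import roc_auc_score

        y = participants.sort_values("participant_id")["pd_diagnosis"]
        assert roc_auc_score(y, model.scores.to_numpy()) == 1.0

    def test_constant_outcome_rejected(self):
        participants = _two_group_frame(30, 30)
        participants["pd_diagnosis"] = 1
        with pytest.raises(ValueError, match="binary and non-constant"):
            estimate_propensity(participants, "pd_diagnosis", ["age"])

    def test_morphometry_covariates_refused(self):
        participants = _two_group_frame(30, 30)
        participants["lh_precuneus_thickness"] = 2.5
        with pytest.raises(ValueError, match="primary scientific interest"):
            estimate_propensity(
                participants, "pd_diagnosis", ["age", "lh_precuneus_thickness"]
            )


class TestMatchSubgroups:
    def test_identical_groups_fully_matched_with_zero_smd(self):
        cfg = balanced_config({"HC": 50, "sPD": 50}, seed=12)
        participants, _ = generate_cohort(cfg)
        cases = participants[participants["pd_diagnosis"] == 1].copy()
        clones = cases.copy()
        clones["participant_id"] = clones["participant_id"] + "_c"
        clones["pd_diagnosis"] = 0
        clones["group"] = "HC"
        clones["disease_duration"] = np.nan
        both = pd.concat([cases, clones], ignore_index=True)
        matched, report = match_subgroups(both, "pd_diagnosis", ["age", "sex", "site"])
        assert matched.n_pairs == len(cases)
        for entry in report.smd.values():
            assert entry["after"] == pytest.approx(0.0, abs=1e-12)

    def test_matching_improves_age_balance(self):
        improved = 0
        for seed in range(10):
            participants = _two_group_frame(150, 150, age_shift=4.0, seed=seed)
            matched, report = match_subgroups(
                participants, "pd_diagnosis", ["age", "sex", "site"]
            )
            assert matched.n_pairs > 0
            if report.smd["age"]["after"] < report.smd["age"]["before"]:
                improved += 1
        assert improved >= 9

    def test_matched_count_monotone_in_caliper(self):
        participants = _two_group_frame(60, 60, age_shift=5.0, seed=3)
        counts = []
        for caliper in (2.0, 0.5, 0.1, 0.02, 1e-6):
            matched, _ = match_subgroups(
                participants, "pd_diagnosis", ["age", "sex", "site"], caliper
            )
            counts.append(matched.n_pairs)
        assert counts == sorted(counts, reverse=True)
        assert counts[-1] <= 2  # caliper -> 0 kills essentially all pairs

    def test_caliper_respected_on_raw_scale(self):
        participants = _two_group_frame(80, 80, age_shift=4.0, seed=8)
        caliper = 0.03
        matched, _ = match_subgroups(
            participants, "pd_diagnosis", ["age", "sex", "site"], caliper
        )
        assert matched.caliper_scale == "raw"
        assert all(d <= caliper + 1e-12 for _, _, d in matched.pairs)

    def test_row_order_invariance(self):
        participants = _two_group_frame(50, 50, age_shift=3.0, seed=9)
        matched1, _ = match_subgroups(participants, "pd_diagnosis", ["age", "sex"])
        shuffled = participants.sample(frac=1.0, random_state=7).reset_index(drop=True)
        matched2, _ = match_subgroups(shuffled, "pd_diagnosis", ["age", "sex"])
        assert matched1.pairs == matched2.pairs

    def test_unmatched_participants_reported(self):
        participants = _two_group_frame(70, 40, seed=10)
        matched, _ = match_subgroups(participants, "pd_diagnosis", ["age", "sex"])
        assert matched.n_pairs <= 40
        assert len(matched.unmatched_a) == 70 - matched.n_pairs
        assert len(matched.unmatched_b) == 40 - matched.n_pairs

    def test_zero_matches_is_explicit_not_silent(self):
        participants = _two_group_frame(30, 30, age_shift=40.0, seed=11)
        matched, report = match_subgroups(
            participants, "pd_diagnosis", ["age"], caliper_spec=1e-9
        )
        assert matched.n_pairs == 0
        assert report.empty


def test_caliper_spec_parsing():
    scores = np.linspace(0.2, 0.8, 50)
    val, scale = resolve_caliper("0.2sd-logit", scores, scores)
    assert scale == "logit" and val > 0
    val2, scale2 = resolve_caliper(0.05, scores, scores)
    assert (val2, scale2) == (0.05, "raw")
    val3, scale3 = resolve_caliper(None, scores, scores)
    assert val3 == float("inf") and scale3 == "raw"
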