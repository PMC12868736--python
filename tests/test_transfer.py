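import copy

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from morphoxfer import (
    balanced_config,
    compute_prediction_difference,
    fit_model_set,
    generate_cohort,
    predict_morphometry,
    preservation_map,
    random_effects,
)
from morphoxfer import test_group_difference as group_difference_test
from morphoxfer import io as mio


@pytest.fixture(scope="module")
def fitted(registry):
    cfg = balanced_config({"HC": 60, "sPD": 60}, seed=20)
    participants, morphometry = generate_cohort(cfg)
    ms = fit_model_set(participants, morphometry, registry)
    return cfg, participants, morphometry, ms


def test_training_sample_mean_residual_zero(fitted):
    """OLS with intercept: in-sample mean prediction difference is 0."""
    _, participants, morphometry, ms = fitted
    predicted = predict_morphometry(ms, participants)
    measured = ms.standardize(morphometry.loc[predicted.index])
    resid = (measured - predicted).mean(axis=0)
    np.testing.assert_allclose(resid.to_numpy(), 0.0, atol=1e-10)


def test_prediction_is_linear_in_coefficients(fitted):
    _, participants, _, ms = fitted
    region = ms.regions[0]
    base = predict_morphometry(ms, participants)[region]
    ms2 = copy.deepcopy(ms)
    ms2.models[region].params["age"] *= 2.0
    doubled = predict_morphometry(ms2, participants)[region]
    spec = ms.spec
    age_part = ms.models[region].params["age"] * (
        participants.sort_values("participant_id")["age"].to_numpy() - spec.age_center
    )
    np.testing.assert_allclose(
        doubled.to_numpy() - base.to_numpy(), age_part, atol=1e-10
    )


def test_transfer_does_not_mutate_the_model_set(fitted, registry):
    _, _, _, ms = fitted
    cfg = balanced_config({"LRRK2_PD": 15, "sPD": 15}, seed=21)
    participants, _ = generate_cohort(cfg)
    before = {r: dict(m.params) for r, m in ms.models.items()}
    predict_morphometry(ms, participants)
    assert {r: dict(m.params) for r, m in ms.models.items()} == before


def test_identical_tables_give_zero_differences(fitted):
    _, participants, _, ms = fitted
    predicted = predict_morphometry(ms, participants)
    groups = pd.Series("x", index=predicted.index)
    pdiff = compute_prediction_difference(predicted, predicted, groups)
    assert np.allclose(pdiff.differences.to_numpy(), 0.0)
    assert np.allclose(pdiff.region_means.to_numpy(), 0.0)


def test_misaligned_ids_rejected(fitted):
    _, participants, _, ms = fitted
    predicted = predict_morphometry(ms, participants)
    groups = pd.Series("x", index=predicted.index)
    with pytest.raises(ValueError, match="different participants"):
        compute_prediction_difference(predicted.iloc[:-1], predicted, groups)


def _transfer_sim(seed, attenuation, n_per_side=30, n_ref=60, saa=False):
    """Fit a reference model, then score attenuated/SAA arms against it."""
    effects = random_effects(seed + 10_000)
    ref_cfg = balanced_config(
        {"HC": n_ref, "sPD": n_ref}, seed=seed, diagnosis_effect=effects
    )
    ref_p, ref_m = generate_cohort(ref_cfg)
    ms = fit_model_set(ref_p, ref_m)
    if saa:
        arm_cfg = balanced_config(
            {"sPD": 2 * n_per_side},
            seed=seed + 1,
            diagnosis_effect=effects,
            saa_positive_rate={"sPD": 0.5},
        )
    else:
        arm_cfg = balanced_config(
            {"sPD": n_per_side, "LRRK2_PD": n_per_side},
            seed=seed + 1,
            lrrk2_attenuation=attenuation,
            diagnosis_effect=effects,
        )
    parts, morph = generate_cohort(arm_cfg)
    predicted = predict_morphometry(ms, parts)
    measured = ms.standardize(morph.loc[predicted.index])
    meta = parts.set_index("participant_id")
    if saa:
        labels = meta.loc[predicted.index, "saa_status"].rename("subgroup")
    else:
        labels = meta.loc[predicted.index, "group"].rename("subgroup")
    return compute_prediction_difference(measured, predicted, labels)


def test_attenuated_arm_shows_positive_preservation():
    """Halved atrophy in the LRRK2-like arm appears as structure preservation."""
    positives = 0
    for seed in range(8):
        pdiff = _transfer_sim(seed, attenuation=0.5)
        if pdiff.region_means.loc["LRRK2_PD"].mean() > 0:
            positives += 1
    assert positives >= 7


def test_null_arm_differences_center_on_zero():
    means = [
        _transfer_sim(seed, attenuation=1.0).region_means.loc["LRRK2_PD"].mean()
        for seed in range(10)
    ]
    assert abs(np.mean(means)) < 0.05


def test_saa_positive_arm_shows_extra_atrophy():
    pdiff = _transfer_sim(3, attenuation=1.0, n_per_side=200, saa=True)
    assert pdiff.region_means.loc["positive"].mean() < 0
    assert (
        pdiff.region_means.loc["positive"].mean()
        < pdiff.region_means.loc["negative"].mean()
    )


class TestGroupDifference:
    def _pdiff(self, shift=0.0, seed=0, n_regions=82):
        rng = np.random.default_rng(seed)
        regions = [f"r{i}" for i in range(n_regions)]
        a = rng.normal(0, 1, (10, n_regions))
        b = rng.normal(shift, 1, (12, n_regions))
        diff = pd.DataFrame(
            np.vstack([a, b]),
            index=[f"p{i}" for i in range(22)],
            columns=regions,
        )
        groups = pd.Series(["A"] * 10 + ["B"] * 12, index=diff.index)
        return compute_prediction_difference(diff, diff * 0.0, groups)

    def test_identical_region_means_give_t_zero_p_one(self):
        pdiff = self._pdiff(seed=1)
        pdiff.region_means.loc["B"] = pdiff.region_means.loc["A"]
        res = group_difference_test(pdiff, "A", "B")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_large_shift_is_overwhelmingly_significant(self):
        res = group_difference_test(self._pdiff(shift=5.0, seed=2), "A", "B")
        assert res.p_value < 1e-6

    def test_two_sample_matches_welch_oracle(self):
        pdiff = self._pdiff(shift=0.4, seed=3)
        res = group_difference_test(pdiff, "A", "B")
        a = pdiff.region_means.loc["A"].to_numpy()
        b = pdiff.region_means.loc["B"].to_numpy()
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        p = 2 * stats.t.sf(abs(t), df)
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_paired_family_available(self):
        pdiff = self._pdiff(shift=0.3, seed=4)
        res = group_difference_test(pdiff, "A", "B", family="paired")
        a = pdiff.region_means.loc["A"].to_numpy()
        b = pdiff.region_means.loc["B"].to_numpy()
        t, p = stats.ttest_rel(a, b)
        assert res.statistic == pytest.approx(float(t), abs=1e-12)
        assert res.p_value == pytest.approx(float(p), abs=1e-12)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="not present"):
            group_difference_test(self._pdiff(), "A", "Z")


def test_preservation_map_round_trips_through_io(fitted, tmp_path, registry):
    pdiff = _transfer_sim(5, attenuation=0.5)
    bmap = preservation_map(pdiff, "LRRK2_PD")
    assert len(bmap.values) == 82
    path = tmp_path / "map.tsv"
    mio.write_brain_map(bmap.values, path)
    back = mio.read_brain_map(path)
    np.testing.assert_allclose(back.to_numpy(), bmap.values.to_numpy(), atol=1e-12)


def test_preservation_concentrates_where_atrophy_is_strong():
    """With attenuation 0.5, preservation tracks the injected effect size."""
    effects = random_effects(777)
    agg = np.zeros(82)
    for seed in range(6):
        ref_cfg = balanced_config({"HC": 120, "sPD": 120}, seed=seed, diagnosis_effect=effects)
        ref_p, ref_m = generate_cohort(ref_cfg)
        ms = fit_model_set(ref_p, ref_m)
        arm_cfg = balanced_config(
            {"LRRK2_PD": 100, "sPD": 100},
            seed=seed + 100,
            lrrk2_attenuation=0.5,
            diagnosis_effect=effects,
        )
        parts, morph = generate_cohort(arm_cfg)
        predicted = predict_morphometry(ms, parts)
        measured = ms.standardize(morph.loc[predicted.index])
        labels = parts.set_index("participant_id").loc[predicted.index, "group"]
        pdiff = compute_prediction_difference(measured, predicted, labels)
        agg += pdiff.region_means.loc["LRRK2_PD"].to_numpy()
    magnitude = -np.array([effects[r] for r in pdiff.region_means.columns])
    rho = stats.spearmanr(agg, magnitude).statistic
    assert rho > 0.5
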