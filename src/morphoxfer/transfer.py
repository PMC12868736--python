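"""Transfer the fitted atrophy model set to data-poor subgroups.

The reference models' coefficients are frozen; for each target participant
we compute the model's predicted regional morphometry (using the
participant's observed diagnosis status) and the prediction difference

    difference = measured - predicted

so positive values mean the structure is better preserved than the
reference PD atrophy model expects. Differences are averaged within each
subgroup per region, and subgroups are compared with a t-test whose unit of
analysis is the 82 per-region subgroup means (two-sample by default, with a
paired-across-regions option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .models import AtrophyModelSet, build_design


@dataclass
class BrainMap:
    """An 82-entry (or declared cortical-only) region -> value map."""

    values: pd.Series
    kind: str  # "beta" | "prediction_difference" | "correlation" | ...
    sign_semantics: str = ""


@dataclass
class PredictionDifference:
    differences: pd.DataFrame  # participant x region, measured - predicted
    groups: pd.Series  # participant_id -> subgroup label
    region_means: pd.DataFrame  # group x region mean difference


@dataclass
class GroupDifferenceTest:
    statistic: float
    p_value: float
    family: str  # "two_sample" | "paired"
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    unit: str = "region_means"


def predict_morphometry(
    model_set: AtrophyModelSet,
    participants: pd.DataFrame,
    unseen_site: str = "error",
) -> pd.DataFrame:
    """Frozen-coefficient linear predictions, participant x region.

    Predictions are in model units (z if the set was fitted z-scored) and
    use each participant's observed diagnosis status; no coefficient is
    re-estimated.
    """
    participants = participants.sort_values("participant_id").reset_index(drop=True)
    designs = {
        t: build_design(participants, model_set.spec, t, unseen_site=unseen_site)
        for t in ("cortical", "subcortical")
    }
    preds = {}
    for region, model in model_set.models.items():
        X = designs[model.tissue]
        beta = np.array([model.params[c] for c in X.columns])
        preds[region] = X.to_numpy() @ beta
    return pd.DataFrame(
        preds, index=pd.Index(participants["participant_id"], name="participant_id")
    )[model_set.regions]


def compute_prediction_difference(
    measured: pd.DataFrame, predicted: pd.DataFrame, groups: pd.Series
) -> PredictionDifference:
    """Per-participant (measured - predicted) and per-region subgroup means.

    ``measured`` must already be in model units (see
    :meth:`AtrophyModelSet.standardize`); rows are aligned by participant_id
    and must coincide with ``predicted`` and ``groups``.
    """
    if set(measured.index) != set(predicted.index):
        raise ValueError("measured and predicted tables have different participants")
    if set(groups.index) != set(predicted.index):
        raise ValueError("group labels do not align with the prediction table")
    if list(measured.columns) != list(predicted.columns):
        measured = measured[predicted.columns]
    measured = measured.loc[predicted.index]
    diff = measured - predicted
    region_means = diff.groupby(groups.loc[diff.index]).mean()
    return PredictionDifference(
        differences=diff, groups=groups.loc[diff.index], region_means=region_means
    )


def test_group_difference(
    pdiff: PredictionDifference,
    group_a: str,
    group_b: str,
    family: str = "two_sample",
) -> GroupDifferenceTest:
    """Compare two subgroups' per-region mean prediction differences.

    ``two_sample`` is Welch's t-test treating the 82 regional means of each
    subgroup as the samples; ``paired`` pairs regions across subgroups.
    Two-sided p either way.
    """
    for g in (group_a, group_b):
        if g not in pdiff.region_means.index:
            raise ValueError(f"group {g!r} not present")
    a = pdiff.region_means.loc[group_a].to_numpy(float)
    b = pdiff.region_means.loc[group_b].to_numpy(float)
    n_a = int((pdiff.groups == group_a).sum())
    n_b = int((pdiff.groups == group_b).sum())
    if n_a < 2 or n_b < 2:
        raise ValueError("each subgroup needs at least 2 participants")
    if family == "two_sample":
        t, p = stats.ttest_ind(a, b, equal_var=False)
    elif family == "paired":
        t, p = stats.ttest_rel(a, b)
    else:
        raise ValueError(f"unknown test family {family!r}")
    return GroupDifferenceTest(
        statistic=float(t),
        p_value=float(p),
        family=family,
        group_a=group_a,
        group_b=group_b,
        n_a=n_a,
        n_b=n_b,
    )


def preservation_map(pdiff: PredictionDifference, group: str) -> BrainMap:
    """Per-region mean prediction difference for one subgroup.

    Positive entries: less thinning / volume loss than the reference PD
    model predicts; negative entries: increased atrophy.
    """
    if group not in pdiff.region_means.index:
        raise ValueError(f"group {group!r} not present")
    return BrainMap(
        values=pdiff.region_means.loc[group].rename("prediction_difference"),
        kind="prediction_difference",
        sign_semantics="positive = structure preserved relative to the PD model",
    )
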