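"""End-to-end orchestration of the four subgroup comparisons.

The reference contrast (sPD vs HC, matched on age, sex, site) yields the
82-model atrophy set; three transfer contrasts (LRRK2 PD vs sPD, LRRK2 NMC
vs HC, SAA+ vs SAA-) reuse its frozen coefficients; clinical/genetic
associations are computed on the LRRK2-comparison participants. A single
top-level seed fans out to per-stage seeds through spawned
``numpy.random.SeedSequence`` children (stage order: cohort, spin), so each
stage is reproducible in isolation and no stage reuses another's stream.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .associations import associate_scores
from .config import CohortConfig, default_config
from .matching import BalanceReport, MatchedPairs, match_subgroups
from .models import AtrophyModelSet, fit_model_set
from .regions import RegionRegistry, default_registry, generate_parcel_geometry
from .spatial import SpinResult, spin_test
from .synthetic import generate_cohort
from .transfer import (
    PredictionDifference,
    compute_prediction_difference,
    predict_morphometry,
    preservation_map,
    test_group_difference,
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ComparisonSpec:
    name: str
    group_a: str  # outcome = 1 side
    group_b: str  # outcome = 0 side
    covariates: tuple[str, ...]
    mode: str  # "fit_reference" | "transfer"
    groups: tuple[str, ...] | None = None  # subset by group label; None = SAA strata
    test_family: str = "two_sample"

    def __post_init__(self):
        if self.mode not in ("fit_reference", "transfer"):
            raise ValueError(f"unknown mode {self.mode!r}")


REFERENCE = ComparisonSpec(
    name="spd_vs_hc",
    group_a="sPD",
    group_b="HC",
    covariates=("age", "sex", "site"),
    mode="fit_reference",
    groups=("sPD", "HC"),
)

TRANSFER_COMPARISONS = (
    ComparisonSpec(
        name="lrrk2_pd_vs_spd",
        group_a="LRRK2_PD",
        group_b="sPD",
        covariates=("sex", "age", "disease_duration", "site"),
        mode="transfer",
        groups=("LRRK2_PD", "sPD"),
    ),
    ComparisonSpec(
        name="nmc_vs_hc",
        group_a="LRRK2_NMC",
        group_b="HC",
        covariates=("sex", "age", "site"),
        mode="transfer",
        groups=("LRRK2_NMC", "HC"),
    ),
    ComparisonSpec(
        name="saa_pos_vs_neg",
        group_a="SAA_positive",
        group_b="SAA_negative",
        covariates=("sex", "age", "disease_duration", "site"),
        mode="transfer",
        groups=None,
    ),
)


def _comparison_frame(
    participants: pd.DataFrame, comp: ComparisonSpec
) -> tuple[pd.DataFrame, pd.Series]:
    """Subset the cohort for a comparison and build its binary outcome."""
    if comp.groups is not None:
        sub = participants[participants["group"].isin(comp.groups)].copy()
        y = (sub["group"] == comp.group_a).astype(int)
    else:
        if "saa_status" not in participants.columns:
            raise KeyError("saa_status")
        sub = participants[participants["saa_status"].isin(["positive", "negative"])].copy()
        y = (sub["saa_status"] == "positive").astype(int)
    if "disease_duration" in comp.covariates:
        # duration is undefined for non-PD participants; the matching model
        # treats "no diagnosis" as zero years of disease
        sub["disease_duration"] = sub["disease_duration"].fillna(0.0)
    y.name = comp.name
    return sub.reset_index(drop=True), y.reset_index(drop=True)


@dataclass
class TransferResult:
    comparison: ComparisonSpec
    matched: MatchedPairs
    balance: BalanceReport
    pdiff: PredictionDifference
    test: object
    maps: dict[str, pd.Series]


def run_reference(
    participants: pd.DataFrame,
    morphometry: pd.DataFrame,
    registry: RegionRegistry | None = None,
    caliper_spec="0.2sd-logit",
    zscore: bool = True,
) -> tuple[AtrophyModelSet, MatchedPairs, BalanceReport]:
    """Match sPD vs HC and fit the 82-region reference atrophy model set."""
    registry = registry or default_registry()
    sub, y = _comparison_frame(participants, REFERENCE)
    try:
        matched, balance = match_subgroups(sub, y, REFERENCE.covariates, caliper_spec)
    except ValueError as err:
        raise PipelineError(f"stage reference: {err}") from err
    if matched.n_pairs == 0:
        raise PipelineError("stage reference: zero matched pairs between sPD and HC")
    sel = sub[sub["participant_id"].isin(matched.matched_ids)]
    model_set = fit_model_set(
        sel,
        morphometry,
        registry,
        zscore=zscore,
        provenance={
            "comparison": REFERENCE.name,
            "matched_ids": sorted(matched.matched_ids),
            "caliper": matched.caliper,
            "caliper_scale": matched.caliper_scale,
            "n_pairs": matched.n_pairs,
        },
    )
    return model_set, matched, balance


def run_transfer(
    participants: pd.DataFrame,
    morphometry: pd.DataFrame,
    model_set: AtrophyModelSet,
    comp: ComparisonSpec,
    caliper_spec="0.2sd-logit",
    unseen_site: str = "error",
) -> TransferResult:
    """Match a data-poor contrast and score it against the frozen model set."""
    sub, y = _comparison_frame(participants, comp)
    matched, balance = match_subgroups(sub, y, comp.covariates, caliper_spec)
    if matched.n_pairs == 0:
        raise PipelineError(f"stage {comp.name}: zero matched pairs")
    sel = sub[sub["participant_id"].isin(matched.matched_ids)]
    labels = pd.Series(
        np.where(y[sub["participant_id"].isin(matched.matched_ids)] == 1,
                 comp.group_a, comp.group_b),
        index=sel["participant_id"],
        name="subgroup",
    )
    predicted = predict_morphometry(model_set, sel, unseen_site=unseen_site)
    measured = model_set.standardize(morphometry.loc[predicted.index])
    pdiff = compute_prediction_difference(measured, predicted, labels)
    test = test_group_difference(pdiff, comp.group_a, comp.group_b, comp.test_family)
    maps = {
        f"preservation_{comp.group_a}": preservation_map(pdiff, comp.group_a).values,
        f"preservation_{comp.group_b}": preservation_map(pdiff, comp.group_b).values,
    }
    return TransferResult(comp, matched, balance, pdiff, test, maps)


def _config_hash(config: CohortConfig) -> str:
    payload = json.dumps(mio._jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int, names=("cohort", "spin")) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)
    }


def run_all(
    config: CohortConfig | None = None,
    participants: pd.DataFrame | None = None,
    morphometry: pd.DataFrame | None = None,
    registry: RegionRegistry | None = None,
    seed: int = 0,
    outdir: str | Path | None = None,
    caliper_spec="0.2sd-logit",
    n_perm: int = 1000,
    zscore: bool = True,
) -> dict:
    """Execute reference fit, the three transfers, and the associations.

    With no explicit tables, a synthetic cohort is generated from
    ``config`` (default study-scale configuration) using the fanned-out
    cohort seed. Returns the manifest; when ``outdir`` is given all data
    products are written beneath it.
    """
    registry = registry or default_registry()
    seeds = _stage_seeds(seed)
    if participants is None or morphometry is None:
        config = config or default_config()
        config = replace(config, seed=seeds["cohort"])
        participants, morphometry = generate_cohort(config, registry)
        cfg_hash = _config_hash(config)
    else:
        cfg_hash = None

    manifest: dict = {
        "seed": seed,
        "stage_seeds": seeds,
        "config_hash": cfg_hash,
        "caliper_spec": str(caliper_spec),
        "n_perm": n_perm,
        "zscore": zscore,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "comparisons": {},
    }
    artifacts: dict[str, dict] = {}

    try:
        model_set, matched_ref, balance_ref = run_reference(
            participants, morphometry, registry, caliper_spec, zscore
        )
    except PipelineError:
        raise
    except Exception as err:
        raise PipelineError(f"stage reference: {err}") from err
    beta_map = model_set.diagnosis_map()
    manifest["comparisons"][REFERENCE.name] = {
        "mode": "fit_reference",
        "n_pairs": matched_ref.n_pairs,
        "caliper": matched_ref.caliper,
        "caliper_scale": matched_ref.caliper_scale,
        "smd": balance_ref.smd,
        "share_negative_beta": float((beta_map < 0).mean()),
        "strongest_beta": float(beta_map.min()),
    }
    artifacts[REFERENCE.name] = {
        "diagnosis_beta_map": beta_map,
        "r2_map": model_set.r2_map(),
        "matched_pairs": pd.DataFrame(
            matched_ref.pairs, columns=["id_a", "id_b", "delta_ps"]
        ),
        "balance": balance_ref,
    }

    transfer_results: dict[str, TransferResult] = {}
    for comp in TRANSFER_COMPARISONS:
        try:
            res = run_transfer(
                participants, morphometry, model_set, comp, caliper_spec
            )
        except KeyError as err:
            if "saa" in comp.name:
                warnings.warn(
                    f"skipping comparison {comp.name}: column {err} unavailable",
                    stacklevel=2,
                )
                manifest["comparisons"][comp.name] = {"skipped": str(err)}
                continue
            raise PipelineError(f"stage {comp.name}: {err}") from err
        except PipelineError:
            raise
        except Exception as err:
            raise PipelineError(f"stage {comp.name}: {err}") from err
        transfer_results[comp.name] = res
        mean_pres = float(res.pdiff.region_means.loc[comp.group_a].mean())
        manifest["comparisons"][comp.name] = {
            "mode": "transfer",
            "n_pairs": res.matched.n_pairs,
            "caliper": res.matched.caliper,
            "caliper_scale": res.matched.caliper_scale,
            "smd": res.balance.smd,
            "test": {
                "family": res.test.family,
                "statistic": res.test.statistic,
                "p_value": res.test.p_value,
            },
            "mean_preservation_a": mean_pres,
        }
        artifacts[comp.name] = {
            "matched_pairs": pd.DataFrame(
                res.matched.pairs, columns=["id_a", "id_b", "delta_ps"]
            ),
            "test": res.test,
            "balance": res.balance,
            **res.maps,
        }

    # spatial comparison: LRRK2 preservation pattern vs reference atrophy betas
    if "lrrk2_pd_vs_spd" in transfer_results:
        geometry = generate_parcel_geometry(registry)
        pres = transfer_results["lrrk2_pd_vs_spd"].maps["preservation_LRRK2_PD"]
        cortical = [r.name for r in registry.cortical]
        spin = spin_test(
            pres.loc[cortical],
            beta_map.loc[cortical],
            geometry,
            n_perm=n_perm,
            seed=seeds["spin"],
        )
        manifest["spin_preservation_vs_atrophy"] = {
            "r": spin.r_observed,
            "p_spin": spin.p_value,
            "n_perm": spin.n_perm,
            "n_regions": spin.n_regions,
        }
        artifacts.setdefault("lrrk2_pd_vs_spd", {})["spin"] = spin

        # associations on the matched PD participants of that comparison
        res = transfer_results["lrrk2_pd_vs_spd"]
        sub, _ = _comparison_frame(participants, res.comparison)
        sel = sub[sub["participant_id"].isin(res.matched.matched_ids)]
        predicted = predict_morphometry(model_set, sel)
        try:
            assoc = associate_scores(predicted, sel)
        except Exception as err:
            raise PipelineError(f"stage associations: {err}") from err
        manifest["associations"] = {
            g.variable: {"r": g.r, "p": g.p, "q": g.q, "n": g.n}
            for g in assoc["global"]
        }
        artifacts["associations"] = {
            "global": assoc["global"],
            "regional": pd.DataFrame(
                [
                    {"variable": a.variable, "region": a.scope, "r": a.r, "p": a.p, "q": a.q}
                    for a in assoc["regional"]
                ]
            ),
        }

    if outdir is not None:
        outdir = Path(outdir)
        files = {}
        for name, arts in artifacts.items():
            files[name] = mio.write_results(outdir / name, arts)
        mio.write_participants(participants, outdir / "participants.tsv")
        mio.write_morphometry(morphometry, outdir / "morphometry.tsv")
        manifest["files"] = files
        mio.write_json(manifest, outdir / "manifest.json")
    return manifest
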