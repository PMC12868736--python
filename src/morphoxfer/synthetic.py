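"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: four
clinical groups with realistic demographics, additive site offsets, signed
per-region diagnosis effects (attenuated for LRRK2 PD), an extra atrophy
effect for SAA-positive participants, TIV coupling for subcortical volumes,
and clinical scores correlated with each participant's structural deviation.

Regional values are generated as

    value = baseline_mean + scale * (age_slope * (age - age_ref)
                                     + site_offset
                                     + pd * effect * attenuation
                                     + saa_positive * saa_scale * effect
                                     + tiv_coupling * tiv_z   [subcortical]
                                     + noise)

with ``scale = baseline_sd`` when effects are specified in SD units and
``scale = 1`` in native-units mode. Fixing the seed fixes every output.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import GROUPS, LRRK2_GROUPS, PD_GROUPS, CohortConfig
from .regions import RegionRegistry, default_registry

PARTICIPANT_COLUMNS = (
    "participant_id",
    "group",
    "pd_diagnosis",
    "lrrk2_carrier",
    "saa_status",
    "age",
    "sex",
    "site",
    "disease_duration",
    "tiv",
    "moca",
    "updrs3",
    "prs",
    *[f"pc{i}" for i in range(1, 11)],
)


def generate_cohort(
    config: CohortConfig, registry: RegionRegistry | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (participants, morphometry) tables.

    Returns a participants DataFrame (one row per participant, schema
    ``PARTICIPANT_COLUMNS``) and a wide morphometry DataFrame indexed by
    participant_id with one column per registry region, in registry order.
    """
    registry = registry or default_registry()
    config.validate(registry)
    rng = np.random.default_rng(config.seed)
    region_names = registry.names
    n_regions = len(region_names)
    subcortical_mask = np.array(
        [registry.tissue_of(n) == "subcortical" for n in region_names]
    )

    base_mean = np.array([config.baseline[n][0] for n in region_names])
    base_sd = np.array([config.baseline[n][1] for n in region_names])
    effect = np.array([config.diagnosis_effect[n] for n in region_names])
    scale = base_sd if config.effect_units == "sd" else np.ones(n_regions)

    # one region-constant offset per site, shared across the cohort
    site_offsets = rng.normal(0.0, config.site_effect_sd, config.n_sites)

    rows: list[dict] = []
    deviations: list[np.ndarray] = []
    counter = 0
    for group in GROUPS:
        n = config.group_sizes.get(group, 0)
        if n == 0:
            continue
        pd_dx = 1 if group in PD_GROUPS else 0
        carrier = 1 if group in LRRK2_GROUPS else 0
        mu_age, sd_age = config.age_params[group]
        age = np.maximum(rng.normal(mu_age, sd_age, n), 25.0)
        sex_male = rng.random(n) < config.male_fraction[group]
        site = rng.integers(0, config.n_sites, n)
        if pd_dx:
            mu_d, sd_d = config.duration_params[group]
            duration = np.maximum(rng.normal(mu_d, sd_d, n), 0.0)
        else:
            duration = np.full(n, np.nan)
        tiv = rng.normal(*config.tiv_params, n)
        saa_pos = rng.random(n) < config.saa_positive_rate.get(group, 0.0)
        saa_missing = rng.random(n) < config.saa_missing_rate

        atten = config.lrrk2_attenuation if group == "LRRK2_PD" else 1.0
        tiv_z = (tiv - config.tiv_params[0]) / max(config.tiv_params[1], 1e-12)

        # deterministic deviation per participant x region (effect units)
        dev = (
            config.age_slope * (age - config.age_ref)[:, None]
            + site_offsets[site][:, None]
            + pd_dx * atten * effect[None, :]
            + saa_pos[:, None] * config.saa_effect_scale * effect[None, :]
        )
        dev = dev + subcortical_mask[None, :] * (
            config.tiv_volume_coupling * tiv_z[:, None]
        )
        noise = rng.normal(0.0, config.noise_sd, (n, n_regions))
        deviations.append(base_mean[None, :] + scale[None, :] * (dev + noise))

        # clinical scores couple to the mean injected deviation (SD units):
        # the disease/SAA/age components, which carry the structural signal
        burden_units = dev - site_offsets[site][:, None]
        burden_units = burden_units - subcortical_mask[None, :] * (
            config.tiv_volume_coupling * tiv_z[:, None]
        )
        if config.effect_units == "native":
            burden = (burden_units / np.where(base_sd > 0, base_sd, 1.0)).mean(axis=1)
        else:
            burden = burden_units.mean(axis=1)
        cc = config.clinical_coupling
        moca = np.clip(
            cc.moca_base + cc.moca_slope * burden + rng.normal(0, cc.moca_noise_sd, n),
            0.0,
            30.0,
        )
        updrs_base = cc.updrs_base_pd if pd_dx else cc.updrs_base_nonpd
        updrs3 = np.maximum(
            updrs_base + cc.updrs_slope * burden + rng.normal(0, cc.updrs_noise_sd, n),
            0.0,
        )
        pp = config.prs_params
        prs = rng.normal(pp.mean, pp.sd, n) + pp.lrrk2_shift * carrier + pp.pd_shift * pd_dx
        pcs = rng.multivariate_normal(np.zeros(10), np.asarray(pp.pc_cov, float), n)

        for i in range(n):
            status = "missing" if saa_missing[i] else ("positive" if saa_pos[i] else "negative")
            row = {
                "participant_id": f"sub-{counter + i:04d}",
                "group": group,
                "pd_diagnosis": pd_dx,
                "lrrk2_carrier": carrier,
                "saa_status": status,
                "age": float(age[i]),
                "sex": "male" if sex_male[i] else "female",
                "site": f"site_{site[i] + 1}",
                "disease_duration": float(duration[i]) if pd_dx else np.nan,
                "tiv": float(tiv[i]),
                "moca": float(moca[i]),
                "updrs3": float(updrs3[i]),
                "prs": float(prs[i]),
            }
            row.update({f"pc{j + 1}": float(pcs[i, j]) for j in range(10)})
            rows.append(row)
        counter += n

    participants = pd.DataFrame(rows, columns=list(PARTICIPANT_COLUMNS))
    morphometry = pd.DataFrame(
        np.vstack(deviations) if deviations else np.empty((0, n_regions)),
        index=pd.Index(participants["participant_id"], name="participant_id"),
        columns=region_names,
    )
    return participants, morphometry
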