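"""Cohort configuration: the generative conditions the synthetic module emulates.

The default configuration mirrors the structure of the PPMI-style study
population: four groups (sporadic PD, LRRK2 PD, healthy controls, LRRK2
non-manifesting carriers) with the published group sizes and demographics,
multi-site acquisition with additive site offsets, per-region diagnosis
effects with an attenuation factor for LRRK2 PD, an extra atrophy effect
for alpha-synuclein SAA-positive participants, and clinical scores coupled
to each participant's structural deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .regions import RegionRegistry, default_registry

GROUPS = ("HC", "sPD", "LRRK2_PD", "LRRK2_NMC")
PD_GROUPS = ("sPD", "LRRK2_PD")
LRRK2_GROUPS = ("LRRK2_PD", "LRRK2_NMC")

# internal seed for the *profile* draws (per-region baselines and effect
# pattern) so that the default config is a fixed object, independent of the
# sampling seed a user passes
_PROFILE_SEED = 714_253

_SUBCORTICAL_VOLUMES = {  # typical adult volumes, mm^3
    "Thalamus": 7500.0,
    "Caudate": 3600.0,
    "Putamen": 4800.0,
    "Pallidum": 1800.0,
    "Hippocampus": 4000.0,
    "Amygdala": 1600.0,
    "Accumbens": 550.0,
}


class ConfigError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


@dataclass
class ClinicalCoupling:
    """Links a participant's mean structural deviation (SD units) to scores.

    Positive deviation = preserved structure, so the MoCA slope is positive
    (preserved structure, better cognition) and the UPDRS III slope negative
    (preserved structure, milder motor signs).
    """

    moca_base: float = 26.5
    moca_slope: float = 5.0  # MoCA points per SD of mean deviation
    moca_noise_sd: float = 2.0
    updrs_base_pd: float = 21.0
    updrs_base_nonpd: float = 2.0
    updrs_slope: float = -10.0  # UPDRS III points per SD of mean deviation
    updrs_noise_sd: float = 8.0


@dataclass
class PrsGeneticsParams:
    """Polygenic risk score and 10 genetic principal components."""

    mean: float = 0.0
    sd: float = 1.0
    lrrk2_shift: float = 0.5  # PRS is elevated in LRRK2 carriers
    pd_shift: float = 0.3
    pc_cov: np.ndarray = field(default_factory=lambda: np.eye(10))


@dataclass
class CohortConfig:
    group_sizes: dict[str, int]
    age_params: dict[str, tuple[float, float]]  # group -> (mean yr, sd yr)
    male_fraction: dict[str, float]
    duration_params: dict[str, tuple[float, float]]  # PD group -> (mean, sd) yr
    n_sites: int
    site_effect_sd: float  # SD units (or native if effect_units="native")
    baseline: dict[str, tuple[float, float]]  # region -> (mean, sd), native units
    diagnosis_effect: dict[str, float]  # region -> signed effect
    effect_units: str = "sd"  # "sd" | "native"
    lrrk2_attenuation: float = 0.5
    saa_effect_scale: float = 1.0
    saa_positive_rate: dict[str, float] = field(
        default_factory=lambda: {"HC": 0.05, "sPD": 0.92, "LRRK2_PD": 0.67, "LRRK2_NMC": 0.10}
    )
    saa_missing_rate: float = 0.25
    noise_sd: float = 1.0  # per-region residual SD (effect units)
    age_slope: float = -0.02  # effect units per year
    age_ref: float = 60.0
    tiv_params: tuple[float, float] = (1.45e6, 1.5e5)  # mm^3
    tiv_volume_coupling: float = 0.3  # SD units per SD of TIV, subcortical only
    clinical_coupling: ClinicalCoupling = field(default_factory=ClinicalCoupling)
    prs_params: PrsGeneticsParams = field(default_factory=PrsGeneticsParams)
    seed: int = 0

    def validate(self, registry: RegionRegistry | None = None) -> None:
        registry = registry or default_registry()
        names = set(registry.names)
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ConfigError(f"group_sizes: unknown group {g!r}")
            if n < 0:
                raise ConfigError(f"group_sizes[{g!r}] must be >= 0, got {n}")
        for g in self.group_sizes:
            if g not in self.age_params:
                raise ConfigError(f"age_params: missing group {g!r}")
            if g not in self.male_fraction:
                raise ConfigError(f"male_fraction: missing group {g!r}")
        for g, (mu, sd) in self.age_params.items():
            if sd < 0:
                raise ConfigError(f"age_params[{g!r}]: sd must be >= 0")
        for g, f in self.male_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"male_fraction[{g!r}] must be in [0, 1]")
        for g in self.group_sizes:
            if g in PD_GROUPS and self.group_sizes[g] > 0 and g not in self.duration_params:
                raise ConfigError(f"duration_params: missing PD group {g!r}")
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.site_effect_sd < 0:
            raise ConfigError("site_effect_sd must be >= 0")
        if set(self.baseline) != names:
            raise ConfigError("baseline: region set must equal the registry")
        if set(self.diagnosis_effect) != names:
            raise ConfigError("diagnosis_effect: region set must equal the registry")
        for r, (mu, sd) in self.baseline.items():
            if mu <= 0 or sd < 0:
                raise ConfigError(f"baseline[{r!r}]: need mean > 0 and sd >= 0")
        if self.effect_units not in ("sd", "native"):
            raise ConfigError("effect_units must be 'sd' or 'native'")
        if not 0.0 <= self.lrrk2_attenuation <= 1.0:
            raise ConfigError("lrrk2_attenuation must be in [0, 1]")
        if self.saa_effect_scale < 0:
            raise ConfigError("saa_effect_scale must be >= 0")
        for g, p in self.saa_positive_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"saa_positive_rate[{g!r}] must be in [0, 1]")
        if not 0.0 <= self.saa_missing_rate <= 1.0:
            raise ConfigError("saa_missing_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.tiv_params[1] < 0:
            raise ConfigError("tiv_params: sd must be >= 0")
        cov = np.asarray(self.prs_params.pc_cov, float)
        if cov.shape != (10, 10):
            raise ConfigError("prs_params.pc_cov must be 10x10")


def default_profiles(
    registry: RegionRegistry | None = None,
) -> tuple[dict[str, tuple[float, float]], dict[str, float]]:
    """Fixed per-region baselines and diagnosis-effect pattern.

    Cortical baselines are plausible mean parcel thicknesses (2.0-3.2 mm,
    between-subject SD 0.10-0.20 mm); subcortical baselines use typical
    structure volumes with a 10% between-subject SD. Diagnosis effects are
    drawn once from Uniform(-0.4, 0) SD, matching the magnitude range of
    the strongest reported PD atrophy coefficients.
    """
    registry = registry or default_registry()
    rng = np.random.default_rng(_PROFILE_SEED)
    baseline: dict[str, tuple[float, float]] = {}
    for r in registry:
        if r.tissue == "cortical":
            mu = float(rng.uniform(2.0, 3.2))
            sd = float(rng.uniform(0.10, 0.20))
        else:
            struct = r.name.split("-", 1)[1].removesuffix("_volume")
            mu = float(_SUBCORTICAL_VOLUMES[struct] * rng.uniform(0.95, 1.05))
            sd = 0.10 * mu
        baseline[r.name] = (mu, sd)
    effect = {r.name: float(rng.uniform(-0.4, 0.0)) for r in registry}
    return baseline, effect


def random_effects(
    seed: int,
    registry: RegionRegistry | None = None,
    low: float = -0.4,
    high: float = 0.0,
) -> dict[str, float]:
    """Draw a fresh per-region diagnosis-effect pattern from Uniform(low, high)."""
    registry = registry or default_registry()
    rng = np.random.default_rng(seed)
    return {n: float(rng.uniform(low, high)) for n in registry.names}


def balanced_config(
    group_sizes: dict[str, int],
    seed: int = 0,
    *,
    n_sites: int = 3,
    lrrk2_attenuation: float = 0.5,
    saa_positive_rate: dict[str, float] | None = None,
    saa_missing_rate: float = 0.0,
    saa_effect_scale: float = 1.0,
    diagnosis_effect: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    site_effect_sd: float = 0.1,
    age_slope: float = -0.02,
    registry: RegionRegistry | None = None,
) -> CohortConfig:
    """Config whose groups share one demographic distribution.

    Emulates a sample *after* propensity matching has balanced the
    covariates, so simulations can be run at a fixed post-matching size
    without re-running the matching stage in every repetition. SAA status
    defaults to all-negative (no SAA confound) unless rates are given.
    """
    baseline, effect = default_profiles(registry)
    if diagnosis_effect is not None:
        effect = diagnosis_effect
    groups = list(group_sizes)
    cfg = CohortConfig(
        group_sizes=dict(group_sizes),
        age_params={g: (62.0, 8.0) for g in groups},
        male_fraction={g: 0.55 for g in groups},
        duration_params={g: (2.5, 1.5) for g in groups if g in PD_GROUPS},
        n_sites=n_sites,
        site_effect_sd=site_effect_sd,
        baseline=baseline,
        diagnosis_effect=effect,
        lrrk2_attenuation=lrrk2_attenuation,
        saa_effect_scale=saa_effect_scale,
        saa_positive_rate=saa_positive_rate or {g: 0.0 for g in GROUPS},
        saa_missing_rate=saa_missing_rate,
        noise_sd=noise_sd,
        age_slope=age_slope,
        seed=seed,
    )
    cfg.validate(registry)
    return cfg


def default_config(seed: int = 0, registry: RegionRegistry | None = None) -> CohortConfig:
    """Study-scale default: published group sizes and demographics."""
    baseline, effect = default_profiles(registry)
    cfg = CohortConfig(
        group_sizes={"sPD": 293, "LRRK2_PD": 77, "HC": 139, "LRRK2_NMC": 94},
        age_params={
            "sPD": (63.3, 9.5),
            "LRRK2_PD": (65.0, 8.7),
            "HC": (61.1, 11.7),
            "LRRK2_NMC": (62.0, 6.9),
        },
        male_fraction={
            "sPD": 181 / 293,
            "LRRK2_PD": 44 / 77,
            "HC": 92 / 139,
            "LRRK2_NMC": 40 / 94,
        },
        duration_params={"sPD": (2.2, 1.9), "LRRK2_PD": (3.2, 2.2)},
        n_sites=5,
        site_effect_sd=0.1,
        baseline=baseline,
        diagnosis_effect=effect,
        seed=seed,
    )
    cfg.validate(registry)
    return cfg
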