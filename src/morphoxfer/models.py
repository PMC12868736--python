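"""Per-region linear atrophy models fitted on the matched reference sample.

Each of the 82 regions gets its own OLS model

    Y = b0 + b1*diagnosis + b2*age + b3*sex + b4*site(+...) (+ b5*TIV)

with the TIV term included only for subcortical volumes. The diagnosis
coefficient b1 is the quantity of interest; the full set of 82 models is
the transferable "PD atrophy model". Outcomes are z-scored by default using
the reference-sample mean/SD per region (stored in the model set so that
transfer never peeks at target-group statistics); a native-units mode is
available.

Sex is encoded male=0, female=1 inside these designs (the convention of the
modelling stage; the propensity stage uses the opposite one — b1 is
unaffected by either choice). Age is centered at the reference-sample mean
for numerical stability; this shifts only the intercept.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .regions import RegionRegistry, default_registry

#: sex encoding used inside the regional linear models: male=0, female=1
MODEL_SEX_CODES = {"male": 0.0, "female": 1.0}


@dataclass
class CovariateSpec:
    """Shared covariate specification for all 82 regional models."""

    site_levels: tuple[str, ...]  # first level is the reference (absorbed)
    age_center: float = 0.0
    tiv_center: float = 0.0
    tiv_scale: float = 1.0
    sex_encoding: str = "male=0,female=1"


@dataclass
class RegionModel:
    region: str
    tissue: str
    params: dict[str, float]
    bse: dict[str, float]
    resid_sd: float
    r2: float
    n: int
    df_resid: int

    def ci_diagnosis(self, alpha: float = 0.05) -> tuple[float, float]:
        t = stats.t.ppf(1 - alpha / 2, self.df_resid)
        b, se = self.params["diagnosis"], self.bse["diagnosis"]
        return (b - t * se, b + t * se)


@dataclass
class AtrophyModelSet:
    models: dict[str, RegionModel]
    spec: CovariateSpec
    zscore: bool
    standardization: dict[str, tuple[float, float]]  # region -> (mean, sd)
    provenance: dict = field(default_factory=dict)

    @property
    def regions(self) -> list[str]:
        return list(self.models)

    def diagnosis_map(self) -> pd.Series:
        return pd.Series(
            {r: m.params["diagnosis"] for r, m in self.models.items()}, name="beta_diagnosis"
        )

    def r2_map(self) -> pd.Series:
        return pd.Series({r: m.r2 for r, m in self.models.items()}, name="r2")

    def standardize(self, morphometry: pd.DataFrame) -> pd.DataFrame:
        """Map native-unit morphometry into model units (z if enabled)."""
        out = morphometry[self.regions].astype(float)
        if not self.zscore:
            return out
        mu = pd.Series({r: self.standardization[r][0] for r in self.regions})
        sd = pd.Series({r: self.standardization[r][1] for r in self.regions})
        return (out - mu) / sd

    def to_json(self, path: str | Path) -> None:
        payload = {
            "region_order": list(self.models),
            "spec": {
                "site_levels": list(self.spec.site_levels),
                "age_center": self.spec.age_center,
                "tiv_center": self.spec.tiv_center,
                "tiv_scale": self.spec.tiv_scale,
                "sex_encoding": self.spec.sex_encoding,
            },
            "zscore": self.zscore,
            "standardization": {r: list(v) for r, v in self.standardization.items()},
            "provenance": self.provenance,
            "models": {
                r: {
                    "tissue": m.tissue,
                    "params": m.params,
                    "bse": m.bse,
                    "resid_sd": m.resid_sd,
                    "r2": m.r2,
                    "n": m.n,
                    "df_resid": m.df_resid,
                }
                for r, m in self.models.items()
            },
        }
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "AtrophyModelSet":
        with open(path) as fh:
            payload = json.load(fh)
        spec = CovariateSpec(
            site_levels=tuple(payload["spec"]["site_levels"]),
            age_center=payload["spec"]["age_center"],
            tiv_center=payload["spec"]["tiv_center"],
            tiv_scale=payload["spec"]["tiv_scale"],
            sex_encoding=payload["spec"]["sex_encoding"],
        )
        order = payload.get("region_order", list(payload["models"]))
        models = {
            r: RegionModel(
                region=r,
                tissue=m["tissue"],
                params=m["params"],
                bse=m["bse"],
                resid_sd=m["resid_sd"],
                r2=m["r2"],
                n=m["n"],
                df_resid=m["df_resid"],
            )
            for r, m in ((r, payload["models"][r]) for r in order)
        }
        return cls(
            models=models,
            spec=spec,
            zscore=payload["zscore"],
            standardization={r: tuple(v) for r, v in payload["standardization"].items()},
            provenance=payload.get("provenance", {}),
        )


def build_design(
    participants: pd.DataFrame,
    spec: CovariateSpec,
    tissue: str,
    unseen_site: str = "error",
) -> pd.DataFrame:
    """Design matrix: intercept, diagnosis, age, sex, site indicators (+ TIV).

    Site uses indicator coding against the first level in ``spec.site_levels``.
    ``unseen_site``: "error" rejects participants at a site the spec does not
    know; "reference" maps them to the reference level (all indicators zero)
    with a warning.
    """
    if tissue not in ("cortical", "subcortical"):
        raise ValueError(f"unknown tissue {tissue!r}")
    known = set(spec.site_levels)
    sites = participants["site"].astype(str)
    unknown = sorted(set(sites) - known)
    if unknown:
        if unseen_site == "error":
            raise ValueError(
                f"site level(s) {unknown} absent from the model's covariate spec"
            )
        if unseen_site != "reference":
            raise ValueError(f"unknown unseen_site policy {unseen_site!r}")
        import warnings

        warnings.warn(
            f"mapping unseen site level(s) {unknown} to the reference level",
            stacklevel=2,
        )
    cols: dict[str, np.ndarray] = {
        "intercept": np.ones(len(participants)),
        "diagnosis": participants["pd_diagnosis"].to_numpy(float),
        "age": participants["age"].to_numpy(float) - spec.age_center,
        "sex": participants["sex"].map(MODEL_SEX_CODES).to_numpy(float),
    }
    for lvl in spec.site_levels[1:]:
        cols[f"site_{lvl}"] = (sites == lvl).to_numpy(float)
    if tissue == "subcortical":
        cols["tiv"] = (
            participants["tiv"].to_numpy(float) - spec.tiv_center
        ) / spec.tiv_scale
    X = pd.DataFrame(cols, index=participants.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValueError(f"design column {bad!r} has missing values")
    return X


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    _, r = np.linalg.qr(X.to_numpy())
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [c for c, d in zip(X.columns, diag) if d < tol]


def fit_region_model(y, X: pd.DataFrame, region: str = "", tissue: str = "cortical") -> RegionModel:
    """Ordinary least squares for one region."""
    y = np.asarray(y, float)
    if len(y) <= X.shape[1]:
        raise ValueError(f"need n > p ({len(y)} rows, {X.shape[1]} columns)")
    if not (np.isfinite(y).all() and np.isfinite(X.to_numpy()).all()):
        raise ValueError("non-finite values in outcome or design")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    res = sm.OLS(y, X).fit()
    return RegionModel(
        region=region,
        tissue=tissue,
        params={c: float(v) for c, v in res.params.items()},
        bse={c: float(v) for c, v in res.bse.items()},
        resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        r2=float(res.rsquared) if np.var(y) > 0 else 0.0,
        n=int(res.nobs),
        df_resid=int(res.df_resid),
    )


def fit_model_set(
    participants: pd.DataFrame,
    morphometry: pd.DataFrame,
    registry: RegionRegistry | None = None,
    zscore: bool = True,
    provenance: dict | None = None,
) -> AtrophyModelSet:
    """Fit all 82 regional models on the matched reference sample.

    ``participants`` must be the matched HC + sPD sample; morphometry rows
    are aligned by participant_id. Standardization parameters (when
    z-scoring) come from this sample and travel with the model set.
    """
    registry = registry or default_registry()
    participants = participants.sort_values("participant_id").reset_index(drop=True)
    Y = morphometry.loc[participants["participant_id"], registry.names].astype(float)
    spec = CovariateSpec(
        site_levels=tuple(sorted(participants["site"].astype(str).unique())),
        age_center=float(participants["age"].mean()),
        tiv_center=float(participants["tiv"].mean()),
        tiv_scale=float(participants["tiv"].std(ddof=1)) or 1.0,
    )
    standardization = {
        r: (float(Y[r].mean()), float(Y[r].std(ddof=1)) or 1.0) for r in registry.names
    }
    designs = {
        t: build_design(participants, spec, t) for t in ("cortical", "subcortical")
    }
    models: dict[str, RegionModel] = {}
    for region in registry.names:
        tissue = registry.tissue_of(region)
        y = Y[region].to_numpy()
        if zscore:
            mu, sd = standardization[region]
            y = (y - mu) / sd
        try:
            models[region] = fit_region_model(y, designs[tissue], region, tissue)
        except ValueError as err:
            raise ValueError(f"region {region!r}: {err}") from err
    return AtrophyModelSet(
        models=models,
        spec=spec,
        zscore=zscore,
        standardization=standardization,
        provenance=provenance or {},
    )
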