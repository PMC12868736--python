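"""Propensity-score matching with optimal assignment and a caliper.

The propensity score is the logistic-regression probability of carrying the
outcome (e.g. PD diagnosis) given background covariates only — morphometry
columns are never admitted into the score. Pairs are formed by solving the
minimum-cost one-to-one assignment (Hungarian algorithm) on the matrix of
absolute score differences, with pairs beyond the caliper priced at a
sentinel cost and discarded from the returned matching, so only
sufficiently close pairs survive. Covariate balance is summarized as
standardized mean differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment
from scipy.special import logit

#: sex encoding used inside the propensity model: female=0, male=1
PS_SEX_CODES = {"female": 0.0, "male": 1.0}

_MORPHOMETRY_MARKERS = ("_thickness", "_volume")


@dataclass
class PropensityModel:
    outcome: str
    covariates: tuple[str, ...]
    design_columns: tuple[str, ...]
    coef: pd.Series  # includes intercept
    scores: pd.Series  # participant_id -> PS in (0, 1)
    method: str = "mle"  # "mle" | "ridge"


@dataclass
class MatchedPairs:
    pairs: list[tuple[str, str, float]]  # (id_A, id_B, |dPS|)
    caliper: float
    caliper_scale: str  # "logit" | "raw"
    unmatched_a: list[str]
    unmatched_b: list[str]

    @property
    def matched_ids(self) -> list[str]:
        return [i for p in self.pairs for i in p[:2]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


@dataclass
class BalanceReport:
    smd: dict[str, dict[str, float]]  # covariate -> {"before": ..., "after": ...}
    n_before: tuple[int, int] = (0, 0)
    n_matched: int = 0
    empty: bool = field(default=False)  # zero matched pairs


def compute_smd(values_a, values_b, binary: bool | None = None) -> float:
    """Standardized mean difference |mA - mB| / pooled SD.

    Pooled SD is sqrt((var_A + var_B) / 2); binary covariates use the
    proportion variance p(1-p). Returns +inf when means differ but the
    pooled SD is zero.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compute_smd requires nonempty vectors")
    if binary is None:
        binary = set(np.unique(np.concatenate([a, b]))) <= {0.0, 1.0}
    diff = abs(a.mean() - b.mean())
    if binary:
        va, vb = a.mean() * (1 - a.mean()), b.mean() * (1 - b.mean())
    else:
        va, vb = a.var(ddof=1) if a.size > 1 else 0.0, b.var(ddof=1) if b.size > 1 else 0.0
    pooled = np.sqrt((va + vb) / 2.0)
    if pooled == 0.0:
        return 0.0 if diff == 0.0 else float("inf")
    return float(diff / pooled)


def _ps_design(participants: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design for the PS model (no intercept column; added by caller)."""
    cols = {}
    for cov in covariates:
        if any(m in cov for m in _MORPHOMETRY_MARKERS):
            raise ValueError(
                f"covariate {cov!r} looks like a morphometry column; the propensity "
                "model must not see variables of primary scientific interest"
            )
        if cov == "sex":
            cols["sex"] = participants["sex"].map(PS_SEX_CODES).astype(float)
        elif cov == "site":
            levels = sorted(participants["site"].unique())
            for lvl in levels[1:]:
                cols[f"site_{lvl}"] = (participants["site"] == lvl).astype(float)
        else:
            cols[cov] = participants[cov].astype(float)
    X = pd.DataFrame(cols, index=participants.index)
    if X.isna().any().any():
        bad = X.columns[X.isna().any()][0]
        raise ValueError(f"covariate {bad!r} has missing values")
    return X


def estimate_propensity(
    participants: pd.DataFrame, outcome: str | pd.Series, covariates
) -> PropensityModel:
    """Maximum-likelihood logistic propensity model.

    ``outcome`` is a binary participant column name or an aligned binary
    Series. Falls back to a ridge-penalized fit (penalty 1e-4) with a
    warning when the MLE separates or fails to converge.
    """
    participants = participants.sort_values("participant_id").reset_index(drop=True)
    if isinstance(outcome, str):
        y = participants[outcome].astype(float)
        outcome_name = outcome
    else:
        y = outcome.reindex(participants.index).astype(float)
        outcome_name = str(outcome.name or "outcome")
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError(f"outcome {outcome_name!r} must be binary and non-constant")
    X = _ps_design(participants, covariates)
    Xc = sm.add_constant(X, prepend=True, has_constant="add")

    method = "mle"
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            res = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        params = res.params
        if not res.mle_retvals.get("converged", True) or np.abs(params.iloc[1:]).max() > 30:
            raise RuntimeError("suspect separation")
    except Exception:
        from sklearn.linear_model import LogisticRegression

        warnings.warn(
            "propensity MLE failed or separated; using ridge-penalized fit (penalty 1e-4)",
            stacklevel=2,
        )
        method = "ridge"
        clf = LogisticRegression(C=1e4, max_iter=2000)
        clf.fit(X.to_numpy(), y.to_numpy())
        params = pd.Series(
            np.concatenate([[clf.intercept_[0]], clf.coef_[0]]), index=Xc.columns
        )
    eta = Xc.to_numpy() @ params.to_numpy()
    ps = 1.0 / (1.0 + np.exp(-eta))
    ps = np.clip(ps, 1e-12, 1 - 1e-12)
    scores = pd.Series(ps, index=participants["participant_id"], name="propensity")
    return PropensityModel(
        outcome=outcome_name,
        covariates=tuple(covariates),
        design_columns=tuple(Xc.columns),
        coef=params,
        scores=scores,
        method=method,
    )


def resolve_caliper(caliper_spec, scores_a, scores_b) -> tuple[float, str]:
    """Turn a caliper spec into (value, scale).

    ``"0.2sd-logit"`` (default convention) means 0.2 x SD of the logit of
    the pooled scores, applied on the logit scale; ``"0.2sd-raw"`` is the
    analogue on the raw PS scale; a bare float is an absolute raw-scale
    caliper; ``None`` or ``inf`` disables the caliper.
    """
    pooled = np.concatenate([np.asarray(scores_a, float), np.asarray(scores_b, float)])
    if caliper_spec is None:
        return float("inf"), "raw"
    if isinstance(caliper_spec, (int, float)):
        return float(caliper_spec), "raw"
    s = str(caliper_spec)
    if s.endswith("sd-logit"):
        mult = float(s[: -len("sd-logit")])
        val = mult * float(np.std(logit(pooled), ddof=1))
        # degenerate scores (no covariate signal) leave nothing to constrain
        return (val if val > 0 else float("inf")), "logit"
    if s.endswith("sd-raw"):
        mult = float(s[: -len("sd-raw")])
        val = mult * float(np.std(pooled, ddof=1))
        return (val if val > 0 else float("inf")), "raw"
    return float(s), "raw"


def build_cost_matrix(
    scores_a, scores_b, caliper: float = float("inf"), caliper_scale: str = "raw"
) -> tuple[np.ndarray, float]:
    """Cost matrix of |PS_i - PS_j| with sentinel cost beyond the caliper.

    The caliper is checked on ``caliper_scale`` ("raw" PS differences or
    differences of logit-PS); costs themselves are raw PS differences.
    Returns (cost, sentinel) where sentinel exceeds any feasible total.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be nonempty")
    if not caliper > 0:
        raise ValueError("caliper must be > 0 (use inf to disable)")
    gaps = np.abs(a[:, None] - b[None, :])
    if caliper_scale == "logit":
        check = np.abs(logit(a)[:, None] - logit(b)[None, :])
    elif caliper_scale == "raw":
        check = gaps
    else:
        raise ValueError(f"unknown caliper scale {caliper_scale!r}")
    sentinel = (a.size + b.size) * (float(gaps.max()) + 1.0)
    cost = np.where(check <= caliper, gaps, sentinel)
    return cost, sentinel


def solve_assignment(cost: np.ndarray, sentinel: float | None = None) -> list[tuple[int, int]]:
    """Optimal one-to-one assignment minimizing total cost.

    Costs are rounded at 1e-12 before solving so that floating-point ties
    break deterministically by lowest (i, j). Pairs assigned at sentinel
    cost (beyond the caliper) are discarded.
    """
    cost = np.asarray(cost, float)
    if cost.ndim != 2:
        raise ValueError("cost matrix must be 2-D")
    rows, cols = linear_sum_assignment(np.round(cost, 12))
    pairs = []
    for i, j in zip(rows, cols):
        if sentinel is not None and cost[i, j] >= sentinel:
            continue
        pairs.append((int(i), int(j)))
    return sorted(pairs)


# covariates whose balance is reported when present
_BALANCE_CANDIDATES = ("age", "disease_duration", "tiv")


def _balance_columns(participants: pd.DataFrame, covariates) -> pd.DataFrame:
    cols = {}
    for cov in covariates:
        if cov == "sex":
            cols["sex"] = participants["sex"].map(PS_SEX_CODES).astype(float)
        elif cov == "site":
            for lvl in sorted(participants["site"].unique()):
                cols[f"site={lvl}"] = (participants["site"] == lvl).astype(float)
        else:
            cols[cov] = participants[cov].astype(float)
    return pd.DataFrame(cols, index=participants.index)


def match_subgroups(
    participants: pd.DataFrame,
    outcome: str | pd.Series,
    covariates,
    caliper_spec="0.2sd-logit",
) -> tuple[MatchedPairs, BalanceReport]:
    """Full matching stage: propensity fit, caliper assignment, balance.

    Side A is the outcome=1 group, side B the outcome=0 group. An empty
    matching is returned with ``BalanceReport.empty=True`` rather than
    failing silently.
    """
    participants = participants.sort_values("participant_id").reset_index(drop=True)
    model = estimate_propensity(participants, outcome, covariates)
    if isinstance(outcome, str):
        y = participants[outcome].astype(int)
    else:
        y = outcome.reindex(participants.index).astype(int)
    ids = participants["participant_id"].to_numpy()
    mask_a = (y == 1).to_numpy()
    ids_a, ids_b = ids[mask_a], ids[~mask_a]
    ps = model.scores
    sa, sb = ps.loc[ids_a].to_numpy(), ps.loc[ids_b].to_numpy()
    caliper, scale = resolve_caliper(caliper_spec, sa, sb)
    cost, sentinel = build_cost_matrix(sa, sb, caliper, scale)
    idx_pairs = solve_assignment(cost, sentinel)
    pairs = [(str(ids_a[i]), str(ids_b[j]), float(cost[i, j])) for i, j in idx_pairs]
    matched_a = {p[0] for p in pairs}
    matched_b = {p[1] for p in pairs}
    matched = MatchedPairs(
        pairs=pairs,
        caliper=float(caliper),
        caliper_scale=scale,
        unmatched_a=[i for i in ids_a if i not in matched_a],
        unmatched_b=[i for i in ids_b if i not in matched_b],
    )

    bal_cols = _balance_columns(participants, covariates)
    sel = participants["participant_id"].isin(matched_a | matched_b).to_numpy()
    smd: dict[str, dict[str, float]] = {}
    for col in bal_cols.columns:
        v = bal_cols[col].to_numpy()
        entry = {"before": compute_smd(v[mask_a], v[~mask_a])}
        if matched.n_pairs > 0:
            entry["after"] = compute_smd(v[sel & mask_a], v[sel & ~mask_a])
        else:
            entry["after"] = float("nan")
        smd[col] = entry
    report = BalanceReport(
        smd=smd,
        n_before=(int(mask_a.sum()), int((~mask_a).sum())),
        n_matched=matched.n_pairs,
        empty=matched.n_pairs == 0,
    )
    return matched, report
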