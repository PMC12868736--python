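"""Clinical and genetic associations of predicted morphometry.

Relates model-predicted regional morphometry (the default structural
quantity; measured values or prediction differences are config options) to
motor severity (MDS-UPDRS III), global cognition (MoCA), and the PD
polygenic risk score. PRS associations are partial correlations controlling
the first 10 genetic principal components. Region-wise analyses are
FDR-adjusted within the full 82-regions x 3-variables family
(Benjamini-Hochberg); global analyses within their 3-test family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENETIC_PCS = tuple(f"pc{i}" for i in range(1, 11))


@dataclass
class AssociationResult:
    variable: str  # "updrs3" | "moca" | "prs"
    scope: str  # "global" or a region name
    r: float
    p: float
    q: float | None
    n: int
    covariates: tuple[str, ...] = field(default_factory=tuple)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Correlation of x and y after removing linear covariate effects.

    Both variables are residualized on the covariate matrix (plus an
    intercept); r is the Pearson correlation of the residuals and p comes
    from the t distribution with n - 2 - k degrees of freedom. With no
    covariates this reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    if covariates is None:
        Z = np.ones((n, 1))
        k = 0
    else:
        C = np.asarray(covariates, float)
        if C.ndim == 1:
            C = C[:, None]
        Z = np.column_stack([np.ones(n), C])
        k = C.shape[1]
        if np.linalg.matrix_rank(Z) < Z.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")
    if n <= k + 2:
        raise ValueError(f"need n > n_covariates + 2 (n={n}, k={k})")
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    sx, sy = np.sqrt((rx**2).sum()), np.sqrt((ry**2).sum())
    # a variable (numerically) fully explained by the covariates carries no
    # partial signal
    tol_x = 1e-10 * max(np.linalg.norm(x - x.mean()), 1e-300)
    tol_y = 1e-10 * max(np.linalg.norm(y - y.mean()), 1e-300)
    if sx <= tol_x or sy <= tol_y:
        return 0.0, 1.0
    r = float(np.clip((rx @ ry) / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _aligned(predictions: pd.DataFrame, participants: pd.DataFrame, cols):
    meta = participants.set_index("participant_id")
    ids = [i for i in predictions.index if i in meta.index]
    sub = meta.loc[ids, list(cols)]
    keep = sub.notna().all(axis=1)
    return predictions.loc[sub.index[keep]], sub[keep]


def correlate_global(
    predictions: pd.DataFrame,
    participants: pd.DataFrame,
    score: str,
    pc_covariates: tuple[str, ...] = (),
) -> AssociationResult:
    """Pearson correlation between a score and mean predicted morphometry.

    The structural quantity is each participant's prediction averaged
    across all regions. ``pc_covariates`` switches to a partial correlation
    (used for the PRS, controlling the 10 genetic PCs).
    """
    cols = [score, *pc_covariates]
    preds, meta = _aligned(predictions, participants, cols)
    if len(preds) < 3:
        raise ValueError("need at least 3 participants with complete data")
    mean_pred = preds.mean(axis=1).to_numpy()
    cov = meta[list(pc_covariates)].to_numpy() if pc_covariates else None
    r, p = partial_correlation(mean_pred, meta[score].to_numpy(), cov)
    return AssociationResult(
        variable=score,
        scope="global",
        r=r,
        p=p,
        q=None,
        n=len(preds),
        covariates=tuple(pc_covariates),
    )


def correlate_regional(
    predictions: pd.DataFrame,
    participants: pd.DataFrame,
    score: str,
    pc_covariates: tuple[str, ...] = (),
) -> list[AssociationResult]:
    """One correlation per region between the score and predicted values.

    q-values are not attached here; the FDR family spans all regional tests
    of all scores (see :func:`associate_scores`).
    """
    cols = [score, *pc_covariates]
    preds, meta = _aligned(predictions, participants, cols)
    if len(preds) < 3:
        raise ValueError("need at least 3 participants with complete data")
    yv = meta[score].to_numpy()
    cov = meta[list(pc_covariates)].to_numpy() if pc_covariates else None
    out = []
    for region in predictions.columns:
        r, p = partial_correlation(preds[region].to_numpy(), yv, cov)
        out.append(
            AssociationResult(
                variable=score,
                scope=region,
                r=r,
                p=p,
                q=None,
                n=len(preds),
                covariates=tuple(pc_covariates),
            )
        )
    return out


def associate_scores(
    predictions: pd.DataFrame,
    participants: pd.DataFrame,
    scores=("updrs3", "moca", "prs"),
    prs_pcs: tuple[str, ...] = GENETIC_PCS,
) -> dict:
    """Global + regional associations for all scores, with FDR families.

    Global q-values are BH-adjusted over the len(scores) global tests;
    regional q-values over the full n_regions x len(scores) family.
    """
    pcs_for = lambda s: tuple(prs_pcs) if s == "prs" else ()
    global_results = [
        correlate_global(predictions, participants, s, pcs_for(s)) for s in scores
    ]
    qg = fdr_adjust([g.p for g in global_results])
    for g, q in zip(global_results, qg):
        g.q = float(q)
    regional: list[AssociationResult] = []
    for s in scores:
        regional.extend(correlate_regional(predictions, participants, s, pcs_for(s)))
    qr = fdr_adjust([r.p for r in regional])
    for res, q in zip(regional, qr):
        res.q = float(q)
    return {"global": global_results, "regional": regional}
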