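"""Metabolome-wide association models and cohort-table statistics.

Each retained feature is tested for association with case status by plain
(unconditional) maximum-likelihood logistic regression adjusted for the
matching factors — conditional logistic is deliberately not used; the pair
identifier is ignored in fitting.  Continuous features enter per standard
deviation, binary features as presence indicators, and the top continuous
hit can additionally be coded in quartiles against Q1.  Two covariate sets
are predefined:

* model 1 — gestational age, age at sampling, season of birth (three
  dummies, winter reference), birth year;
* model 2 — model 1 plus family history of psychiatric disorders, the
  polygenic score, and six genetic principal components.

Multiplicity is controlled with Benjamini-Hochberg across all tested
features jointly.  Wald intervals and p-values are reported; features whose
fit fails contribute p = 1 to the BH adjustment (conservative) rather than
shrinking the number of tests.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
import statsmodels.api as sm

from .io_model import AssocResult
from .feature_processing import ProcessedFeatures

__all__ = [
    "ModelSpec",
    "TestResult",
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "design_matrix",
    "fit_feature_assoc",
    "run_mwas",
    "bh_adjust",
    "stratified_interaction",
    "auc_single",
    "contingency_chisq",
    "two_sample_t",
]

logger = logging.getLogger(__name__)

MODEL1_COVARIATES = ("gestational_age", "age_at_sampling", "season", "birth_year")
MODEL2_COVARIATES = MODEL1_COVARIATES + ("family_history", "prs", "pc1", "pc2", "pc3", "pc4", "pc5", "pc6")

_Z975 = stats.norm.ppf(0.975)


@dataclass
class ModelSpec:
    """Which outcome and covariates an association scan uses."""

    outcome: str = "case_status"  # {"case_status", "prs", "family_history"}
    covariates: tuple[str, ...] = MODEL1_COVARIATES
    model_id: str = "model1"
    stratum_filter: Callable[[pd.DataFrame], pd.Series] | None = None

    @classmethod
    def model1(cls) -> "ModelSpec":
        return cls()

    @classmethod
    def model2(cls) -> "ModelSpec":
        return cls(covariates=MODEL2_COVARIATES, model_id="model2")


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float


def design_matrix(samples: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """Covariate design: season expands to 3 dummies with winter as reference.

    Continuous covariates are mean-centered — this leaves every feature
    coefficient unchanged but keeps the design well conditioned (birth year
    enters as a raw calendar year otherwise).
    """
    cols = {}
    for cov in covariates:
        if cov == "season":
            for s in ("spring", "summer", "autumn"):
                cols[f"season_{s}"] = (samples["season"] == s).astype(float)
        else:
            v = samples[cov].astype(float)
            cols[cov] = v - v.mean() if v.nunique() > 2 else v
    return pd.DataFrame(cols, index=samples.index)


def _wald_logistic(
    y: np.ndarray, X: np.ndarray, check_cols: Sequence[int] = (1,)
) -> tuple[np.ndarray, np.ndarray, str]:
    """ML logistic fit; on separation/non-convergence, ridge-penalized fallback.

    Returns (coef, se, flag).  Separation is judged on the coefficient(s) of
    interest (``check_cols``), not the intercept.  The fallback adds a small
    L2 penalty to the likelihood and reports Wald quantities from the
    penalized Hessian.
    """
    flag = ""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            coef, se = np.asarray(res.params), np.asarray(res.bse)
            ok = res.mle_retvals.get("converged", True)
        except Exception:
            ok = False
            coef = se = None
    cc = list(check_cols)
    if not ok or np.any(~np.isfinite(se[cc])) or np.nanmax(np.abs(coef[cc])) > 15 or np.nanmax(se[cc]) > 50:
        coef, se = _ridge_logistic(y, X, alpha=0.5)
        flag = "penalized"
        logger.info("separation or non-convergence; penalized fallback used")
    return coef, se, flag


def _ridge_logistic(y: np.ndarray, X: np.ndarray, alpha: float = 0.5, maxiter: int = 200):
    """Newton iterations for L2-penalized logistic log-likelihood.

    The intercept is not penalized.  Covariance from the penalized Hessian.
    """
    n, k = X.shape
    pen = np.full(k, alpha)
    pen[0] = 0.0  # leading column assumed to be the constant
    beta = np.zeros(k)
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1 - mu)
        grad = X.T @ (y - mu) - pen * beta
        H = X.T @ (X * W[:, None]) + np.diag(pen)
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    H = X.T @ (X * (mu * (1 - mu))[:, None]) + np.diag(pen)
    cov = np.linalg.inv(H)
    return beta, np.sqrt(np.diag(cov))


def fit_feature_assoc(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    mode: str = "continuous_per_sd",
    feature_id: str = "feature",
    model_id: str = "custom",
) -> list[AssocResult]:
    """Logistic association of a binary outcome with one coded feature.

    ``mode='quartile'`` fits a single model with dummies for Q2-Q4 against
    Q1 and returns one result per non-reference quartile (plus the Q1
    reference row with OR fixed at 1).  Other modes return a single result.
    Rows with a missing feature value are dropped.
    """
    y = np.asarray(y, dtype=float)
    xv = np.asarray(x, dtype=float)
    keep = ~np.isnan(xv)
    if covariates is not None:
        cov = covariates.to_numpy(dtype=float)
        keep &= ~np.isnan(cov).any(axis=1)
    y_, x_ = y[keep], xv[keep]
    n_used = int(keep.sum())
    if len(np.unique(y_)) < 2:
        raise ValueError("outcome must have both classes present")
    if min((y_ == 0).sum(), (y_ == 1).sum()) < 10:
        logger.info("feature %s: fewer than 10 per outcome class", feature_id)

    cov_block = covariates.to_numpy(dtype=float)[keep] if covariates is not None else np.empty((n_used, 0))

    if mode == "quartile":
        dummies = np.column_stack([(x_ == q).astype(float) for q in (2, 3, 4)])
        X = np.column_stack([np.ones(n_used), dummies, cov_block])
        coef, se, flag = _wald_logistic(y_, X, check_cols=(1, 2, 3))
        results = [
            AssocResult(feature_id, "quartile", 1.0, 1.0, 1.0, 1.0,
                        model_id=model_id, n_used=n_used, quartile_level=1, flag="reference")
        ]
        for i, q in enumerate((2, 3, 4), start=1):
            results.append(
                AssocResult(
                    feature_id, "quartile",
                    math.exp(coef[i]),
                    math.exp(coef[i] - _Z975 * se[i]),
                    math.exp(coef[i] + _Z975 * se[i]),
                    _wald_p(coef[i], se[i]),
                    model_id=model_id, n_used=n_used, quartile_level=q, flag=flag,
                )
            )
        return results

    X = np.column_stack([np.ones(n_used), x_, cov_block])
    coef, se, flag = _wald_logistic(y_, X)
    b, s = coef[1], se[1]
    return [
        AssocResult(
            feature_id, mode,
            math.exp(b), math.exp(b - _Z975 * s), math.exp(b + _Z975 * s),
            _wald_p(b, s),
            model_id=model_id, n_used=n_used, flag=flag,
        )
    ]


def _wald_p(b: float, se: float) -> float:
    if not np.isfinite(se) or se <= 0:
        return 1.0
    return float(max(2.0 * stats.norm.sf(abs(b / se)), np.finfo(float).tiny))


def _fit_linear(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = max(len(y) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, np.sqrt(np.diag(cov))


def run_mwas(
    features: ProcessedFeatures,
    samples: pd.DataFrame,
    spec: ModelSpec = ModelSpec(),
) -> list[AssocResult]:
    """One association result per retained feature, with joint BH q-values.

    ``samples`` is a covariate frame indexed by sample id (see
    ``io_model.records_to_frame``); it is aligned to the feature blocks.
    For a linear outcome (``prs``) estimates are betas, not ORs.
    """
    idx = features.continuous.index if len(features.continuous.columns) else features.binary.index
    samples = samples.loc[idx]
    if spec.stratum_filter is not None:
        keep = spec.stratum_filter(samples)
        samples = samples.loc[keep]
    cov = design_matrix(samples, spec.covariates)

    if spec.outcome == "case_status":
        y = samples["y"].to_numpy(dtype=float)
        logistic = True
    elif spec.outcome == "family_history":
        y = samples["family_history"].to_numpy(dtype=float)
        logistic = True
    elif spec.outcome == "prs":
        y = samples["prs"].to_numpy(dtype=float)
        logistic = False
    else:
        raise ValueError(f"unknown outcome {spec.outcome!r}")

    results: list[AssocResult] = []
    blocks = [
        (features.continuous, "continuous_per_sd"),
        (features.binary, "binary_presence"),
    ]
    for block, mode in blocks:
        if not len(block.columns):
            continue
        for fid in block.columns:
            x = block[fid].loc[samples.index].to_numpy(dtype=float)
            try:
                if logistic:
                    res = fit_feature_assoc(
                        y, x, cov, mode=mode, feature_id=fid, model_id=spec.model_id
                    )[0]
                else:
                    keep = ~np.isnan(x)
                    X = np.column_stack([np.ones(keep.sum()), x[keep], cov.to_numpy(dtype=float)[keep]])
                    beta, se = _fit_linear(y[keep], X)
                    b, s = beta[1], se[1]
                    dfree = keep.sum() - X.shape[1]
                    p = float(max(2.0 * stats.t.sf(abs(b / s), dfree), np.finfo(float).tiny))
                    tq = stats.t.ppf(0.975, dfree)
                    res = AssocResult(fid, "linear", b, b - tq * s, b + tq * s, p,
                                      model_id=spec.model_id, n_used=int(keep.sum()))
            except Exception as exc:  # failed fit: conservative placeholder
                logger.info("fit failed for %s: %s", fid, exc)
                res = AssocResult(fid, mode, math.nan, math.nan, math.nan, 1.0,
                                  model_id=spec.model_id, n_used=0, flag="fit_failed")
            results.append(res)

    qvals = bh_adjust([r.p for r in results])
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stratified_interaction(
    features: ProcessedFeatures,
    samples: pd.DataFrame,
    age_threshold: float = 6.0,
    covariates: Sequence[str] = MODEL1_COVARIATES,
) -> pd.DataFrame:
    """Age-of-diagnosis stratified ORs plus an interaction test per feature.

    Each stratum's cases (diagnosed before / at-or-after ``age_threshold``)
    are compared against the full shared control group with the primary
    covariate set.  Effect heterogeneity between strata is tested case-only:
    a logistic model of early-versus-late diagnosis among cases on the
    feature (plus covariates), whose feature Wald test equals the
    feature-by-stratum product-term test in the polytomous augmentation.
    Controls being shared across strata is flagged in the output.
    """
    is_case = samples["y"] == 1
    early = is_case & (samples["age_at_diagnosis"] < age_threshold)
    late = is_case & (samples["age_at_diagnosis"] >= age_threshold)
    if early.sum() == 0 or late.sum() == 0:
        raise ValueError("empty age-of-diagnosis stratum")

    rows = []
    blocks = [(features.continuous, "continuous_per_sd"), (features.binary, "binary_presence")]
    for block, mode in blocks:
        for fid in block.columns:
            x = block[fid]
            row = {"feature_id": fid, "mode": mode, "shared_controls": True}
            for name, mask in (("early", early), ("late", late)):
                sub = samples.loc[mask | ~is_case]
                cov = design_matrix(sub, covariates)
                res = fit_feature_assoc(
                    sub["y"].to_numpy(float), x.loc[sub.index].to_numpy(float), cov,
                    mode=mode, feature_id=fid,
                )[0]
                row[f"or_{name}"] = res.estimate
                row[f"p_{name}"] = res.p
            cases = samples.loc[is_case]
            cov = design_matrix(cases, covariates)
            res = fit_feature_assoc(
                early.loc[cases.index].astype(float).to_numpy(),
                x.loc[cases.index].to_numpy(float),
                cov, mode=mode, feature_id=fid,
            )[0]
            row["p_interaction"] = res.p
            rows.append(row)
    return pd.DataFrame(rows).set_index("feature_id")


def auc_single(marker, y) -> float:
    """Rank-based (Mann-Whitney) AUC of one marker for a binary outcome."""
    m = np.asarray(marker, dtype=float)
    yv = np.asarray(y, dtype=int)
    n1, n0 = int((yv == 1).sum()), int((yv == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(m, method="average")
    u = ranks[yv == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def contingency_chisq(table) -> TestResult:
    """Pearson chi-square on an r x c count table, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = stats.chi2_contingency(t, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected count of zero")
    return TestResult(statistic=float(chi2), df=int(dof), p=float(p))


def two_sample_t(a, b, equal_var: bool = True) -> TestResult:
    """Two-sided t-test; pooled variance by default (Welch optional)."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.size < 2 or bv.size < 2:
        raise ValueError("each group needs >= 2 values")
    if av.var(ddof=1) == 0 and bv.var(ddof=1) == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(av, bv, equal_var=equal_var)
    dfree = int(av.size + bv.size - 2) if equal_var else int(np.floor(res.df))
    return TestResult(statistic=float(res.statistic), df=dfree, p=float(res.pvalue))
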