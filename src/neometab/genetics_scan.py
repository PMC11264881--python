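"""Per-SNP additive association scan and LASSO phenome-wide determinant scan.

The GWAS fits, for every SNP, an ordinary least-squares linear model of the
metabolite on the additive dosage (0/1/2 copies of the minor allele) plus
covariates, with two-sided Wald p-values.  Covariates are projected out once
(Frisch-Waugh-Lovell), so the scan is a single vectorized pass over the
dosage matrix while remaining exactly equal to the per-SNP multiple
regression.  Genomic-control lambda — median association chi-square divided
by the null median 0.4549 — is the calibration diagnostic.

The phenome-wide scan is an L1-penalized least-squares (LASSO) fit over a
mixed predictor table, with the penalty chosen by k-fold cross-validated
prediction error and the one-standard-error rule, reporting nonzero
coefficients ranked by magnitude and the out-of-fold R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np
import pandas as pd
from scipy import stats

from .io_model import ConfigError

__all__ = [
    "GwasRow",
    "LassoConfig",
    "LassoResult",
    "gwas_scan",
    "lambda_gc",
    "lasso_phewas",
]

CHI2_NULL_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class GwasRow:
    snp: str
    beta: float
    se: float
    p: float
    maf: float
    n: int
    flag: str = ""


@dataclass
class LassoConfig:
    folds: int = 10
    seed: int = 0
    standardize: bool = True
    n_lambda: int = 100

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ConfigError("folds must be >= 2")


@dataclass
class LassoResult:
    coefficients: pd.Series  # nonzero coefficients, original scale of X
    alpha: float
    cv_r2: float
    ranking: list[str] = field(default_factory=list)  # by |coefficient|, descending


def gwas_scan(
    genotypes: pd.DataFrame,
    y,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive per-SNP linear scan; returns a PLINK-like association table.

    Columns: SNP, BETA, SE, P, MAF, N, FLAG.  Monomorphic SNPs get NA
    estimates and are flagged.  Missing dosages are not supported (the
    generator guarantees completeness).
    """
    yv = np.asarray(y, dtype=float)
    G = genotypes.to_numpy(dtype=float)
    n, m = G.shape
    if np.isnan(G).any() or np.isnan(yv).any():
        raise ValueError("missing values are not supported")
    if np.all(yv == yv[0]):
        raise ValueError("constant outcome")
    k = 0 if covariates is None else covariates.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")

    # project out the covariates (with intercept) from y and every dosage
    if covariates is not None and k:
        Z = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    else:
        Z = np.ones((n, 1))
    Q, _ = np.linalg.qr(Z)
    yr = yv - Q @ (Q.T @ yv)
    Gr = G - Q @ (Q.T @ G)

    sxx = np.einsum("ij,ij->j", Gr, Gr)
    sxy = Gr.T @ yr
    dfree = n - Z.shape[1] - 1
    mono = sxx <= 1e-12
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(mono, np.nan, sxy / np.where(mono, 1.0, sxx))
        rss = float(yr @ yr) - beta**2 * sxx
        sigma2 = rss / dfree
        se = np.sqrt(sigma2 / np.where(mono, np.nan, sxx))
        tstat = beta / se
        pvals = 2.0 * stats.t.sf(np.abs(tstat), dfree)

    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame(
        {
            "SNP": genotypes.columns,
            "BETA": beta,
            "SE": se,
            "P": pvals,
            "MAF": maf,
            "N": n,
            "FLAG": np.where(mono, "monomorphic", ""),
        }
    )


def lambda_gc(pvals) -> float:
    """Genomic-control inflation factor from two-sided association p-values."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.ppf(1.0 - p, 1)
    return float(np.median(chi2) / CHI2_NULL_MEDIAN)


def _lasso_path_cv(X: np.ndarray, y: np.ndarray, config: LassoConfig):
    from sklearn.linear_model import lasso_path
    from sklearn.model_selection import KFold

    # shared alpha grid from the full data: log-spaced down from the
    # smallest penalty that zeroes every coefficient
    n = X.shape[0]
    alpha_max = float(np.max(np.abs((X - X.mean(axis=0)).T @ (y - y.mean())))) / n
    alphas = np.logspace(math.log10(alpha_max), math.log10(alpha_max * 1e-3), config.n_lambda)
    kf = KFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    fold_mse = np.zeros((config.folds, alphas.size))
    for f, (tr, te) in enumerate(kf.split(X)):
        _, coefs, _ = lasso_path(X[tr], y[tr], alphas=alphas)
        # lasso_path fits on centered data: intercept = mean(y_tr) - mean(X_tr) @ coef
        icept = y[tr].mean() - X[tr].mean(axis=0) @ coefs
        pred = X[te] @ coefs + icept
        fold_mse[f] = ((pred - y[te][:, None]) ** 2).mean(axis=0)
    cvm = fold_mse.mean(axis=0)
    cvse = fold_mse.std(axis=0, ddof=1) / math.sqrt(config.folds)
    i_min = int(np.argmin(cvm))
    # 1-SE rule: most-penalized model within one SE of the minimum
    threshold = cvm[i_min] + cvse[i_min]
    candidates = np.nonzero(cvm <= threshold)[0]
    i_sel = int(candidates[np.argmax(alphas[candidates])])
    return float(alphas[i_sel]), float(cvm[i_sel])


def lasso_phewas(
    target,
    predictors: pd.DataFrame,
    config: LassoConfig = LassoConfig(),
) -> LassoResult:
    """LASSO determinant scan for a metabolite over a mixed predictor table.

    Predictors are standardized (when ``config.standardize``); the penalty
    is chosen by cross-validated prediction error with the one-standard-
    error rule; the result reports nonzero coefficients sorted by magnitude
    and the out-of-fold R^2 at the chosen penalty.
    """
    from sklearn.linear_model import Lasso

    y = np.asarray(target, dtype=float)
    Xdf = pd.DataFrame(predictors)
    if Xdf.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if len(y) < config.folds:
        raise ValueError("n smaller than the number of folds")
    X = Xdf.to_numpy(dtype=float)
    if config.standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd

    alpha, cv_mse = _lasso_path_cv(X, y, config)
    model = Lasso(alpha=alpha, max_iter=50000)
    model.fit(X, y)
    coefs = pd.Series(model.coef_, index=Xdf.columns)
    nonzero = coefs[coefs != 0.0]
    ranking = list(nonzero.reindex(nonzero.abs().sort_values(ascending=False).index).index)
    var_y = float(np.var(y))
    cv_r2 = 1.0 - cv_mse / var_y if var_y > 0 else float("nan")
    return LassoResult(coefficients=nonzero, alpha=alpha, cv_r2=cv_r2, ranking=ranking)
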