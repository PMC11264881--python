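"""Metabolite-class enrichment, partial-correlation networks, diet analysis.

Class enrichment uses the classical two-sided Fisher exact test (all tables
with point probability at most that observed) on the 2x2 layout of in-class
versus out-of-class against significant versus not, restricted to annotated
features.

Feature-feature partial correlations "adjusted for all other features" are
computed from the standardized inverse covariance, rho_ij =
-Omega_ij / sqrt(Omega_ii * Omega_jj) — algebraically identical to the
per-pair regress-out-everything-else route but vastly cheaper.  When the
sample size does not exceed the feature count, an explicitly flagged
ridge-regularized mode is available.  Binary presence indicators enter as
0/1 numeric columns.

Diet correlations use partial Spearman (rank, residualize on covariates,
Pearson on residuals) and intakes are energy-adjusted by dividing with
non-alcoholic energy intake.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EnrichmentResult",
    "PartialCorrResult",
    "PartialCorrMatrix",
    "class_enrichment",
    "partial_corr_matrix",
    "partial_spearman",
    "energy_adjust",
]


@dataclass
class EnrichmentResult:
    class_label: str
    a: int  # significant and in class
    b: int  # significant, not in class
    c: int  # not significant, in class
    d: int  # not significant, not in class
    odds_ratio: float
    p: float


@dataclass
class PartialCorrResult:
    i: str
    j: str
    rho: float
    p: float
    adjustment: str


@dataclass
class PartialCorrMatrix:
    """Symmetric partial-correlation and p-value matrices."""

    rho: pd.DataFrame
    p: pd.DataFrame
    n: int
    mode: str  # {"exact", "ridge"}
    adjustment: str = "all other features"

    def pairs(self) -> Iterator[PartialCorrResult]:
        cols = list(self.rho.columns)
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                yield PartialCorrResult(
                    cols[a], cols[b],
                    float(self.rho.iloc[a, b]), float(self.p.iloc[a, b]),
                    self.adjustment,
                )


def class_enrichment(sig_flags: pd.Series, class_labels: pd.Series) -> list[EnrichmentResult]:
    """Fisher exact enrichment of each metabolite class among significant hits.

    ``class_labels`` may contain NaN for unannotated features, which are
    excluded from every table.  A class covering all annotated features
    yields a degenerate table and raises.
    """
    sig = pd.Series(sig_flags).astype(bool)
    labels = pd.Series(class_labels).reindex(sig.index)
    annotated = labels.notna()
    if annotated.sum() == 0 or labels[annotated].nunique() == 0:
        raise ValueError("no annotated features")
    sig = sig[annotated]
    labels = labels[annotated]
    results = []
    for cls in sorted(labels.unique()):
        in_cls = labels == cls
        if in_cls.all():
            raise ValueError(f"class {cls!r} covers all annotated features (degenerate table)")
        a = int((sig & in_cls).sum())
        b = int((sig & ~in_cls).sum())
        c = int((~sig & in_cls).sum())
        d = int((~sig & ~in_cls).sum())
        orr, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        results.append(EnrichmentResult(str(cls), a, b, c, d, float(orr), float(p)))
    return results


def partial_corr_matrix(
    X: pd.DataFrame,
    mode: str = "exact",
    ridge_lambda: float = 0.1,
) -> PartialCorrMatrix:
    """Pairwise partial correlations of all columns given all other columns.

    Exact mode requires ``n > p`` and a nonsingular correlation matrix;
    otherwise it raises with a pointer to ridge mode, which inverts
    ``R + lambda * I`` instead and is flagged in the result.  P-values use
    the t transform with ``df = n - p`` (NaN when that is not positive).
    """
    Xdf = pd.DataFrame(X)
    n, p = Xdf.shape
    vals = Xdf.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValueError("partial correlations need a complete matrix")
    sds = vals.std(axis=0, ddof=1)
    if np.any(sds == 0):
        raise ValueError("constant column in input")
    R = np.corrcoef(vals, rowvar=False)
    if mode == "exact":
        if n <= p:
            raise ValueError("n <= p: exact mode unavailable, use mode='ridge'")
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0 or logdet < -700:
            raise ValueError("singular correlation matrix: use mode='ridge'")
        omega = np.linalg.inv(R)
    elif mode == "ridge":
        omega = np.linalg.inv(R + ridge_lambda * np.eye(p))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    d = np.sqrt(np.diag(omega))
    rho = -omega / np.outer(d, d)
    np.fill_diagonal(rho, 1.0)
    rho = np.clip(rho, -1.0, 1.0)

    dfree = n - p
    if dfree > 0:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt(dfree / np.maximum(1.0 - rho**2, 1e-300))
        pmat = 2.0 * stats.t.sf(np.abs(t), dfree)
        np.fill_diagonal(pmat, np.nan)
    else:
        pmat = np.full_like(rho, np.nan)
    cols = Xdf.columns
    return PartialCorrMatrix(
        rho=pd.DataFrame(rho, index=cols, columns=cols),
        p=pd.DataFrame(pmat, index=cols, columns=cols),
        n=n,
        mode=mode,
    )


def partial_spearman(x, y, covariates: pd.DataFrame | None = None) -> tuple[float, float]:
    """Partial Spearman correlation of x and y given covariates.

    All variables, covariates included, are rank-transformed (average
    ranks); x and y ranks are residualized on the covariate ranks (with
    intercept) and the Pearson correlation of the residuals is returned with
    a t-transform p-value at ``df = n - n_covariates - 2``.  With no
    covariates this reduces to plain Spearman.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    n = xv.size
    k = 0 if covariates is None else covariates.shape[1]
    if n <= k + 2:
        raise ValueError("need n > n_covariates + 2")
    if np.all(xv == xv[0]) or np.all(yv == yv[0]):
        raise ValueError("constant input")
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    if covariates is not None and k:
        rz = np.apply_along_axis(
            lambda c: stats.rankdata(c, method="average"), 0,
            covariates.to_numpy(dtype=float),
        )
        Z = np.column_stack([np.ones(n), rz])
        rx = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
        ry = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    else:
        rx = rx - rx.mean()
        ry = ry - ry.mean()
    denom = np.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("degenerate residuals")
    rho = float(rx @ ry / denom)
    dfree = n - k - 2
    t = rho * np.sqrt(dfree / max(1.0 - rho**2, 1e-300))
    p = float(2.0 * stats.t.sf(abs(t), dfree))
    return rho, p


def energy_adjust(intake, energy_nonalcoholic):
    """Energy-adjusted intake: intake divided by non-alcoholic energy intake."""
    intake_v = np.asarray(intake, dtype=float)
    energy_v = np.asarray(energy_nonalcoholic, dtype=float)
    if np.any(energy_v <= 0):
        raise ValueError("non-alcoholic energy intake must be > 0")
    return intake_v / energy_v
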