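"""Injection-order drift correction and batch handling (QC-RLSC style).

A locally weighted ("LOESS") curve is fitted per plate and feature to the
repeated QC injections as a function of injection order, and analytical
samples are normalized by dividing by the fitted curve and rescaling to the
QC median.  "Low-order" smoothing means local degree-1 (linear) regression
with tricube weights by default; local quadratic is available.  Evaluation
is clamped to the observed QC order range so the correction never
extrapolates the local polynomial.

A simple per-plate median alignment is provided as the batch-correction
stage, and an iterative regression-tree imputer (with a half-minimum
fallback) for the continuous feature block.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io_model import FeatureTable

__all__ = [
    "InsufficientQCError",
    "DriftCurve",
    "DriftModel",
    "QcReport",
    "fit_drift_curve",
    "fit_drift_model",
    "apply_drift_correction",
    "qc_rsd",
    "qc_report",
    "correct_batch",
    "impute_continuous",
]

logger = logging.getLogger(__name__)

DEFAULT_SPAN = 2.0 / 3.0


class InsufficientQCError(ValueError):
    """Fewer QC points than needed to fit a drift curve."""


def _loess_eval(
    x: np.ndarray, y: np.ndarray, x0: np.ndarray, span: float, degree: int
) -> np.ndarray:
    """Evaluate a tricube-weighted local polynomial fit of y on x at points x0.

    For each evaluation point the ``ceil(span * n)`` nearest data points get
    tricube weights ``(1 - (d/dmax)^3)^3`` and a degree-``degree`` weighted
    least squares polynomial is evaluated at the point.  Fully vectorized
    over evaluation points.
    """
    n = x.size
    k = max(degree + 1, int(math.ceil(span * n)))
    k = min(k, n)
    d = np.abs(x0[:, None] - x[None, :])  # (e, n)
    # distance to the k-th nearest point per evaluation point
    dmax = np.partition(d, k - 1, axis=1)[:, k - 1]
    dmax = np.where(dmax == 0, 1.0, dmax)
    u = np.clip(d / dmax[:, None], 0.0, 1.0)
    w = (1.0 - u**3) ** 3  # points beyond dmax get zero weight

    xc = x[None, :] - x0[:, None]  # center at evaluation point: intercept = fit
    if degree == 1:
        sw = w.sum(axis=1)
        swx = (w * xc).sum(axis=1)
        swxx = (w * xc * xc).sum(axis=1)
        swy = (w * y[None, :]).sum(axis=1)
        swxy = (w * xc * y[None, :]).sum(axis=1)
        det = sw * swxx - swx * swx
        # fall back to the weighted mean where the design is degenerate
        safe = np.abs(det) > 1e-12 * np.maximum(sw * swxx, 1e-300)
        out = np.where(sw > 0, swy / np.where(sw > 0, sw, 1.0), np.nan)
        b0 = (swxx * swy - swx * swxy) / np.where(safe, det, 1.0)
        return np.where(safe, b0, out)
    if degree == 2:
        cols = np.stack([np.ones_like(xc), xc, xc * xc], axis=2)  # (e, n, 3)
        A = np.einsum("enp,en,enq->epq", cols, w, cols)
        b = np.einsum("enp,en,n->ep", cols, w, y)
        A += 1e-10 * np.eye(3)[None, :, :]
        sol = np.linalg.solve(A, b[..., None])[..., 0]
        return sol[:, 0]
    raise ValueError("degree must be 1 or 2")


@dataclass
class DriftCurve:
    """Fitted drift curve for one (plate, feature): evaluable at any order."""

    qc_orders: np.ndarray
    qc_values: np.ndarray
    span: float = DEFAULT_SPAN
    degree: int = 1
    reference: float = field(init=False)

    def __post_init__(self) -> None:
        self.qc_orders = np.asarray(self.qc_orders, dtype=float)
        self.qc_values = np.asarray(self.qc_values, dtype=float)
        if self.qc_orders.size < 4:
            raise InsufficientQCError(
                f"need >= 4 QC points, got {self.qc_orders.size}"
            )
        if np.any(self.qc_values <= 0):
            raise ValueError("QC values must be strictly positive")
        if not (0 < self.span <= 1):
            raise ValueError("span must be in (0, 1]")
        order = np.argsort(self.qc_orders)
        self.qc_orders = self.qc_orders[order]
        self.qc_values = self.qc_values[order]
        self.reference = float(np.median(self.qc_values))

    def __call__(self, orders: np.ndarray | float) -> np.ndarray:
        """Fitted value at (clamped) injection orders."""
        x0 = np.atleast_1d(np.asarray(orders, dtype=float))
        x0 = np.clip(x0, self.qc_orders[0], self.qc_orders[-1])
        return _loess_eval(self.qc_orders, self.qc_values, x0, self.span, self.degree)


def fit_drift_curve(
    qc_orders: Sequence[float],
    qc_values: Sequence[float],
    span: float = DEFAULT_SPAN,
    degree: int = 1,
) -> DriftCurve:
    """Fit a tricube local-polynomial drift curve to QC injections."""
    return DriftCurve(np.asarray(qc_orders), np.asarray(qc_values), span=span, degree=degree)


@dataclass
class DriftModel:
    """Per (plate, feature) drift curves plus features passed through."""

    curves: dict[tuple[str, str], DriftCurve] = field(default_factory=dict)
    skipped: list[tuple[str, str, str]] = field(default_factory=list)  # plate, feature, reason
    reference: dict[str, float] = field(default_factory=dict)  # run-wide QC median per feature
    span: float = DEFAULT_SPAN
    degree: int = 1
    per_plate: bool = True


def fit_drift_model(
    table: FeatureTable,
    span: float = DEFAULT_SPAN,
    degree: int = 1,
    qc_kinds: Sequence[str] = ("plate_pool",),
    per_plate: bool = True,
) -> DriftModel:
    """Fit drift curves from a table's QC rows.

    ``per_plate=True`` (default; QC pools are plate-specific) fits one curve
    per plate and feature; ``per_plate=False`` fits a single global curve
    per feature across the run ordered by (plate, order).  Features with
    fewer than 4 usable QC points on a plate are passed through and logged.
    """
    model = DriftModel(span=span, degree=degree, per_plate=per_plate)
    qc = table.qc_rows(qc_kinds)
    if per_plate:
        groups = [(pl, qc.subset(qc.intensities.index[qc.plate == pl])) for pl in qc.plate.unique()]
    else:
        groups = [("__global__", qc)]
    for plate, sub in groups:
        orders = sub.injection_order.to_numpy(dtype=float)
        for fid in sub.feature_ids:
            vals = sub.intensities[fid].to_numpy(dtype=float)
            ok = np.isfinite(vals) & (vals > 0)
            if ok.sum() < 4:
                model.skipped.append((plate, fid, "insufficient QC"))
                logger.info("drift fit skipped: plate=%s feature=%s (insufficient QC)", plate, fid)
                continue
            model.curves[(plate, fid)] = DriftCurve(
                orders[ok], vals[ok], span=span, degree=degree
            )
    # a single run-wide reference per feature keeps plates on a common scale
    for fid in qc.feature_ids:
        vals = qc.intensities[fid].to_numpy(dtype=float)
        ok = np.isfinite(vals) & (vals > 0)
        if ok.any():
            model.reference[fid] = float(np.median(vals[ok]))
    return model


def apply_drift_correction(table: FeatureTable, model: DriftModel) -> FeatureTable:
    """Normalize by the fitted curve: ``corrected = raw * reference / f(order)``.

    Missing cells remain missing; QC rows are corrected identically.
    Features whose curve is non-positive at any needed order are skipped for
    that plate and logged.
    """
    out = table.intensities.copy()
    plates = table.plate if model.per_plate else pd.Series("__global__", index=table.intensities.index)
    for plate in plates.unique():
        rows = table.intensities.index[plates == plate]
        orders = table.injection_order.loc[rows].to_numpy(dtype=float)
        for fid in table.feature_ids:
            curve = model.curves.get((plate, fid))
            if curve is None:
                continue
            f = curve(orders)
            if np.any(~np.isfinite(f)) or np.any(f <= 0):
                logger.info(
                    "drift correction skipped: plate=%s feature=%s (non-positive fit)", plate, fid
                )
                continue
            ref = model.reference.get(fid, curve.reference)
            out.loc[rows, fid] = table.intensities.loc[rows, fid].to_numpy() * ref / f
    return table.with_intensities(out)


def qc_rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sample SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("RSD needs >= 2 values")
    if np.any(v <= 0):
        raise ValueError("RSD is defined for strictly positive values")
    return float(100.0 * v.std(ddof=1) / v.mean())


def qc_report(table: FeatureTable, qc_kinds: Sequence[str] = ("plate_pool",)) -> pd.DataFrame:
    """Per-feature QC replicate RSD (%) and QC count over the whole run."""
    qc = table.qc_rows(qc_kinds)
    rows = {}
    for fid in qc.feature_ids:
        v = qc.intensities[fid].dropna()
        v = v[v > 0]
        rows[fid] = {
            "rsd": qc_rsd(v.to_numpy()) if len(v) >= 2 else math.nan,
            "n_qc": int(len(v)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def correct_batch(table: FeatureTable, method: str = "plate_median") -> FeatureTable:
    """Per-plate batch alignment of feature intensities.

    ``plate_median``: for each feature, multiply each plate's values by the
    factor that moves the plate's median log intensity (over analytical
    samples) to the grand median.  Missingness is unchanged; measured zeros
    stay zero.  ``none`` is the identity.
    """
    if method == "none":
        return table.with_intensities(table.intensities.copy())
    if method != "plate_median":
        raise ValueError(f"unknown batch method {method!r}")
    out = table.intensities.copy()
    analytical = table.qc_flag == "analytical"
    for fid in table.feature_ids:
        col = table.intensities[fid]
        pos = analytical & col.notna() & (col > 0)
        if pos.sum() == 0:
            continue
        grand = float(np.median(np.log(col[pos].to_numpy())))
        for plate in table.plate.unique():
            in_plate = table.plate == plate
            sel = pos & in_plate
            if sel.sum() == 0:
                logger.info("batch correction skipped: plate=%s feature=%s (all missing)", plate, fid)
                continue
            plate_med = float(np.median(np.log(col[sel].to_numpy())))
            factor = math.exp(grand - plate_med)
            out.loc[in_plate, fid] = col[in_plate] * factor
    return table.with_intensities(out)


def impute_continuous(
    table: FeatureTable,
    feature_ids: Sequence[str] | None = None,
    method: str = "tree",
    n_iter: int = 2,
    max_depth: int = 5,
    seed: int = 0,
) -> FeatureTable:
    """Impute missing values of (near-)complete continuous features.

    ``half_min``: each missing cell gets half the feature's minimum observed
    positive intensity (a standard left-censoring surrogate).  ``tree``:
    half-minimum initialization followed by ``n_iter`` sweeps in which each
    feature with missing cells is re-predicted from the other continuous
    features by a depth-limited regression tree, on the log scale.
    """
    fids = list(feature_ids) if feature_ids is not None else table.feature_ids
    out = table.intensities.copy()
    half_min = {}
    for fid in fids:
        col = out[fid]
        obs = col[col.notna() & (col > 0)]
        fill = float(obs.min()) / 2.0 if len(obs) else np.nan
        half_min[fid] = fill
        out[fid] = col.fillna(fill)
    if method == "half_min":
        return table.with_intensities(out)
    if method != "tree":
        raise ValueError(f"unknown imputation method {method!r}")

    from sklearn.tree import DecisionTreeRegressor

    mask = table.intensities[fids].isna()
    need = [f for f in fids if mask[f].any() and not mask[f].all()]
    logmat = np.log(np.maximum(out[fids].to_numpy(dtype=float), 1e-300))
    colpos = {f: j for j, f in enumerate(fids)}
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        for fid in need:
            j = colpos[fid]
            miss = mask[fid].to_numpy()
            X = np.delete(logmat, j, axis=1)
            tree = DecisionTreeRegressor(max_depth=max_depth, random_state=int(rng.integers(2**31)))
            tree.fit(X[~miss], logmat[~miss, j])
            logmat[miss, j] = tree.predict(X[miss])
    for fid in need:
        out[fid] = np.exp(logmat[:, colpos[fid]])
    return table.with_intensities(out)
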