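"""Leverage-based applicability domain (Williams-plot analysis).

A fitted model's applicability domain is characterized by plotting
standardized residuals δ* against leverages h. The warning leverage is
``h* = 3(k + 1)/n``; interpretation rules:

- |δ*| > 3 — potential outlier;
- a *training* compound with h > h* exerts significant influence on the fit;
- a *query/validation* compound with h > h* is predicted by extrapolation
  (flagged, never blocked).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .regression import MLRResults, SingularDesignError

OUTLIER_THRESHOLD = 3.0


def warning_leverage(k: int, n: int) -> float:
    """h* = 3(k + 1)/n for k descriptors and n training compounds."""
    if n <= 0:
        raise ValueError("n must be positive")
    return 3.0 * (k + 1) / n


def leverages(X_train, X_query=None) -> np.ndarray:
    """Hat-matrix diagonal entries, with the intercept column included.

    With ``X_query`` given, query rows are scored against the *training*
    cross-product matrix: ``h = x'(X'X)^{-1}x``.
    """
    Xt = sm.add_constant(
        pd.DataFrame(np.asarray(X_train, dtype=float)), has_constant="add"
    ).to_numpy()
    xtx = Xt.T @ Xt
    try:
        xtx_inv = np.linalg.inv(xtx)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError("X'X is singular") from exc
    target = (
        Xt
        if X_query is None
        else sm.add_constant(
            pd.DataFrame(np.asarray(X_query, dtype=float)), has_constant="add"
        ).to_numpy()
    )
    return np.einsum("ij,jk,ik->i", target, xtx_inv, target)


def standardized_residuals(
    results: MLRResults, X=None, y=None
) -> np.ndarray:
    """Residuals divided by the training residual scale sqrt(SSE/(n-k-1)).

    Without arguments, the training residuals are standardized; with an
    external (X, y), prediction residuals are standardized by the *training*
    scale, so the |δ*| > 3 rule is applied on a common footing.
    """
    scale = results.residual_scale
    if X is None:
        resid = results.resid
    else:
        resid = np.asarray(y, dtype=float) - results.predict(X)
    # an (numerically) exact fit has no residual scale to standardize by
    y_scale = float(np.sqrt(np.mean(results.model.y**2)))
    if scale <= 1e-10 * max(1.0, y_scale):
        return np.zeros_like(resid)
    return resid / scale


@dataclass
class ADReport:
    """Williams-plot data: one row per compound plus the warning leverage."""

    table: pd.DataFrame  # id, h, delta, set, outlier, high_leverage
    h_star: float
    k: int
    n_train: int

    def flagged_outliers(self) -> pd.DataFrame:
        return self.table[self.table["outlier"]]

    def influential_training(self) -> pd.DataFrame:
        t = self.table
        return t[(t["set"] == "training") & t["high_leverage"]]

    def extrapolations(self) -> pd.DataFrame:
        t = self.table
        return t[(t["set"] != "training") & t["high_leverage"]]


def ad_report(
    results: MLRResults,
    ids=None,
    X_val=None,
    y_val=None,
    val_ids=None,
) -> ADReport:
    """Assemble the applicability-domain report for a fitted model."""
    n, k = results.nobs, results.k
    h_star = warning_leverage(k, n)
    frames = []
    h_t = results.leverage
    d_t = standardized_residuals(results)
    frames.append(
        pd.DataFrame(
            {
                "id": list(ids) if ids is not None else list(range(n)),
                "h": h_t,
                "delta": d_t,
                "set": "training",
            }
        )
    )
    if X_val is not None:
        h_v = leverages(results.model.X, X_val)
        d_v = (
            standardized_residuals(results, X_val, y_val)
            if y_val is not None
            else np.full(len(h_v), np.nan)
        )
        frames.append(
            pd.DataFrame(
                {
                    "id": list(val_ids)
                    if val_ids is not None
                    else list(range(n, n + len(h_v))),
                    "h": h_v,
                    "delta": d_v,
                    "set": "validation",
                }
            )
        )
    tab = pd.concat(frames, ignore_index=True)
    tab["outlier"] = tab["delta"].abs() > OUTLIER_THRESHOLD
    tab["high_leverage"] = tab["h"] > h_star
    return ADReport(table=tab, h_star=h_star, k=k, n_train=n)


def williams_data(report: ADReport) -> pd.DataFrame:
    """Tidy plotting table with the guide values echoed on every row."""
    out = report.table.copy()
    out["h_star"] = report.h_star
    out["delta_limit"] = OUTLIER_THRESHOLD
    return out


def williams_plot(report: ADReport, path=None, ax=None):
    """Render the Williams plot (δ* vs h with the h* and ±3 guides)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    for subset, marker in (("training", "o"), ("validation", "s")):
        part = report.table[report.table["set"] == subset]
        if len(part):
            ax.scatter(part["h"], part["delta"], marker=marker, label=subset)
    ax.axvline(report.h_star, ls="--", c="k", lw=0.8)
    ax.axhline(OUTLIER_THRESHOLD, ls=":", c="r", lw=0.8)
    ax.axhline(-OUTLIER_THRESHOLD, ls=":", c="r", lw=0.8)
    ax.set_xlabel("leverage h")
    ax.set_ylabel("standardized residual")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
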