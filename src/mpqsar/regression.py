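"""Ordinary-least-squares QSAR modelling with the standard validation suite.

The central objects follow the statsmodels convention: :class:`MLRModel` is
built from a response vector and a named descriptor matrix; ``fit()`` returns
an :class:`MLRResults` carrying the estimates, their uncertainties and the
QSAR diagnostics — R², RMSE, F, per-descriptor t/p/VIF, standardized
coefficients — plus methods for leave-one-out Q², external validation and
y-randomization. Coefficient estimation and the overall F test are delegated
to ``statsmodels.OLS``; the QSAR-specific statistics are computed here.

Conventions
-----------
- ``RMSE = sqrt(SSE / n)`` (the population form; this is the form under which
  the published training RMSE values are reproduced).
- ``Q²_LOO = 1 - PRESS / SST`` with PRESS from the hat-matrix shortcut
  ``e_i / (1 - h_ii)`` (algebraically identical to literally refitting n
  times; the equivalence is exercised in the test suite).
- ``Q²_ext`` defaults to the F1 form, ``1 - Σ(ŷ-y)² / Σ(y - ȳ_train)²``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _as_design(X, names=None) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X.astype(float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    return pd.DataFrame(X, columns=list(names))


class MLRModel:
    """Multiple linear regression of a response on named descriptors.

    Parameters
    ----------
    y : array-like, shape (n,)
        Response (e.g. adsorption energies in kcal/mol).
    X : DataFrame or array-like, shape (n, k)
        Descriptor matrix, without intercept column (added internally).
    names : sequence of str, optional
        Column names when ``X`` is a bare array.
    """

    def __init__(self, y, X, names=None):
        self.X = _as_design(X, names)
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 1 or len(self.y) != len(self.X):
            raise ValueError("y and X have incompatible shapes")
        if np.isnan(self.y).any() or self.X.isna().any().any():
            raise ValueError("missing values in y or X")
        n, k = self.X.shape
        if n <= k + 1:
            raise ValueError(f"need n > k + 1 (got n={n}, k={k})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response: str, descriptors):
        return cls(df[response].to_numpy(), df[list(descriptors)])

    def fit(self) -> "MLRResults":
        Xc = sm.add_constant(self.X, has_constant="add")
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            raise SingularDesignError(
                "design matrix (with intercept) is rank deficient"
            )
        res = sm.OLS(self.y, Xc).fit()
        return MLRResults(self, res)


@dataclass(frozen=True)
class ValidationReport:
    """External-set statistics: Q²_ext (F1 by default), R²_ext, RMSE_v."""

    q2_ext: float
    r2_ext: float
    rmse_v: float
    n_v: int
    variant: str = "F1"
    r2_ext_defined: bool = True


@dataclass(frozen=True)
class YRandomization:
    """Summary of refits on permuted responses (chance-correlation control)."""

    mean_r2: float
    min_r2: float
    max_r2: float
    r2_values: tuple[float, ...]
    n_perm: int
    seed: int | None


class MLRResults:
    """Fitted MLR with QSAR diagnostics; returned by :meth:`MLRModel.fit`."""

    def __init__(self, model: MLRModel, sm_results):
        self.model = model
        self._sm = sm_results
        self.nobs = int(sm_results.nobs)
        self.k = model.X.shape[1]
        self.names = list(model.X.columns)
        self.params = sm_results.params  # includes 'const'
        self.bse = sm_results.bse
        self.tvalues = sm_results.tvalues
        self.pvalues = sm_results.pvalues
        self.fittedvalues = np.asarray(sm_results.fittedvalues)
        self.resid = np.asarray(sm_results.resid)
        self.sse = float(self.resid @ self.resid)
        y = model.y
        self.sst = float(((y - y.mean()) ** 2).sum())
        self.degenerate = self.sst == 0.0
        self.rsquared = 0.0 if self.degenerate else 1.0 - self.sse / self.sst
        self.rmse = float(np.sqrt(self.sse / self.nobs))
        self.fvalue = np.nan if self.degenerate else float(sm_results.fvalue)
        self.f_pvalue = np.nan if self.degenerate else float(
            sm_results.f_pvalue
        )

    # -- derived quantities ------------------------------------------------

    @property
    def leverage(self) -> np.ndarray:
        """Hat-matrix diagonal of the (intercept-augmented) training design."""
        return np.asarray(self._sm.get_influence().hat_matrix_diag)

    @property
    def residual_scale(self) -> float:
        """sqrt(SSE / (n - k - 1)); the standardized-residual denominator."""
        return float(np.sqrt(self.sse / (self.nobs - self.k - 1)))

    @property
    def std_coefficients(self) -> pd.Series:
        """Coefficients scaled by sd(x)/sd(y) (comparable across descriptors)."""
        sy = self.model.y.std(ddof=1)
        out = {
            name: float(self.params[name] * self.model.X[name].std(ddof=1) / sy)
            for name in self.names
        }
        return pd.Series(out)

    def vif(self) -> pd.Series:
        return vif(self.model.X)

    def predict(self, X) -> np.ndarray:
        X = _as_design(X, self.names)[self.names]
        Xc = sm.add_constant(X, has_constant="add")
        return np.asarray(self._sm.predict(Xc))

    # -- internal validation ----------------------------------------------

    @property
    def press(self) -> float:
        """Predicted residual sum of squares via the hat-matrix shortcut."""
        h = self.leverage
        if np.any(h >= 1.0 - 1e-12):
            raise ValueError(
                "a leverage equals 1; leave-one-out prediction is undefined "
                "for that observation"
            )
        return float(((self.resid / (1.0 - h)) ** 2).sum())

    def q2_loo(self) -> float:
        """Leave-one-out cross-validated Q² = 1 - PRESS/SST."""
        if self.nobs <= self.k + 2:
            raise ValueError("need n > k + 2 for leave-one-out validation")
        return 1.0 - self.press / self.sst

    def validate(self, X_val, y_val, variant: str = "F1") -> ValidationReport:
        """External validation on a held-out set.

        ``variant="F1"`` (default) scales the prediction error by the
        deviance of the validation responses around the *training* mean;
        ``"F2"`` uses the validation mean instead.
        """
        y_val = np.asarray(y_val, dtype=float)
        if len(y_val) == 0:
            raise ValueError("validation set is empty")
        yhat = self.predict(X_val)
        sse_v = float(((yhat - y_val) ** 2).sum())
        if variant == "F1":
            ref = self.model.y.mean()
        elif variant == "F2":
            ref = y_val.mean()
        else:
            raise ValueError(f"unknown Q2_ext variant {variant!r}")
        denom = float(((y_val - ref) ** 2).sum())
        q2 = 1.0 - sse_v / denom if denom > 0 else np.nan
        defined = y_val.std() > 0 and np.std(yhat) > 0
        r2 = float(np.corrcoef(yhat, y_val)[0, 1] ** 2) if defined else np.nan
        return ValidationReport(
            q2_ext=q2,
            r2_ext=r2,
            rmse_v=float(np.sqrt(sse_v / len(y_val))),
            n_v=len(y_val),
            variant=variant,
            r2_ext_defined=bool(defined),
        )

    def y_randomize(
        self, n_perm: int = 100, seed: int | None = None, permutations=None
    ) -> YRandomization:
        """Refit on permuted responses and collect the null R² values.

        A sound model's R² should sit far above the permuted mean. The
        ``permutations`` override (an iterable of index arrays) exists for
        deterministic controls.
        """
        if n_perm < 1 and permutations is None:
            raise ValueError("n_perm must be >= 1")
        Xc = sm.add_constant(self.model.X, has_constant="add")
        y = self.model.y
        if permutations is None:
            rng = np.random.default_rng(seed)
            permutations = (rng.permutation(len(y)) for _ in range(n_perm))
        r2s = []
        for perm in permutations:
            r2s.append(float(sm.OLS(y[np.asarray(perm)], Xc).fit().rsquared))
        r2s = tuple(r2s)
        return YRandomization(
            mean_r2=float(np.mean(r2s)),
            min_r2=float(np.min(r2s)),
            max_r2=float(np.max(r2s)),
            r2_values=r2s,
            n_perm=len(r2s),
            seed=seed,
        )

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        p_txt = (
            "<0.001"
            if np.isfinite(self.f_pvalue) and self.f_pvalue < 0.001
            else f"{self.f_pvalue:.3g}"
        )
        lines = [
            "MLR fit"
            f" (n={self.nobs}, k={self.k})",
            f"  R2={self.rsquared:.4f}  RMSE={self.rmse:.4f}"
            f"  F={self.fvalue:.2f}  p={p_txt}",
            f"  {'term':<12}{'coef':>12}{'se':>10}{'t':>9}{'p':>10}"
            f"{'VIF':>8}{'std coef':>10}",
        ]
        vifs = self.vif() if self.k >= 2 else pd.Series(dtype=float)
        stdc = self.std_coefficients
        for name in ["const"] + self.names:
            v = f"{vifs[name]:8.2f}" if name in vifs.index else " " * 8
            s = f"{stdc[name]:10.3f}" if name in stdc.index else " " * 10
            p = self.pvalues[name]
            p_s = "<0.001" if p < 0.001 else f"{p:.3f}"
            lines.append(
                f"  {name:<12}{self.params[name]:>12.4f}"
                f"{self.bse[name]:>10.4f}{self.tvalues[name]:>9.2f}"
                f"{p_s:>10}{v}{s}"
            )
        return "\n".join(lines)


def fit_mlr(X, y, names=None) -> MLRResults:
    """Functional convenience wrapper: ``MLRModel(y, X, names).fit()``."""
    return MLRModel(y, X, names).fit()


def vif(X) -> pd.Series:
    """Variance inflation factors: VIF_j = 1/(1 - R²_j) from regressing
    descriptor j on the remaining descriptors (with intercept).

    Perfectly collinear columns are reported as ``inf``.
    """
    X = _as_design(X)
    if X.shape[1] < 2:
        raise ValueError("VIF requires at least two descriptors")
    out = {}
    for col in X.columns:
        others = sm.add_constant(X.drop(columns=[col]), has_constant="add")
        r2 = sm.OLS(X[col], others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class StepwiseTrace:
    steps: list = field(default_factory=list)  # (action, name, pvalue)

    def record(self, action: str, name: str, p: float):
        self.steps.append((action, name, float(p)))


def stepwise_select(
    X,
    y,
    p_enter: float = 0.05,
    p_remove: float = 0.10,
    max_steps: int = 200,
) -> tuple[list[str], StepwiseTrace]:
    """Bidirectional stepwise descriptor selection on t-test p-values.

    At each step the candidate with the smallest entry p-value below
    ``p_enter`` is added, then any included descriptor whose p-value has
    drifted above ``p_remove`` is dropped. Deterministic given the thresholds
    and column order (ties broken by column order). Returns the selected names
    and the full entry/removal trace.
    """
    if not 0 < p_enter < 1 or not 0 < p_remove < 1:
        raise ValueError("thresholds must lie in (0, 1)")
    X = _as_design(X)
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    trace = StepwiseTrace()

    def pvals(cols):
        Xc = sm.add_constant(X[cols], has_constant="add")
        return sm.OLS(y, Xc).fit().pvalues

    for _ in range(max_steps):
        changed = False
        candidates = [c for c in X.columns if c not in selected]
        best, best_p = None, p_enter
        for c in candidates:
            try:
                p = pvals(selected + [c])[c]
            except Exception:
                continue
            if p < best_p:
                best, best_p = c, p
        if best is not None:
            selected.append(best)
            trace.record("enter", best, best_p)
            changed = True
        if selected:
            p = pvals(selected).drop("const")
            worst = p.idxmax()
            if p[worst] > p_remove:
                selected.remove(worst)
                trace.record("remove", worst, p[worst])
                changed = True
        if not changed:
            break
    return selected, trace
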