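"""Shared Model / Results machinery.

Every estimator in this package follows the same two-object pattern:
a *Model* is constructed from data (arrays or a DataFrame), its
``fit()`` method runs a least-squares estimation and returns a
*Results* object carrying parameter estimates, standard errors where
available, goodness of fit and a plain-text ``summary()`` table.
"""

from __future__ import annotations

import numpy as np


class FitWarningFlag:
    """Lightweight warning attached to a fit (degenerate data, clipped
    parameter, questionable identifiability)."""

    def __init__(self, code: str, message: str):
        self.code = code
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FitWarningFlag({self.code!r}: {self.message!r})"


class FitResults:
    """Base results container.

    Parameters
    ----------
    params : dict
        Parameter name -> point estimate.
    bse : dict, optional
        Parameter name -> standard error (absent entries mean the error
        was not estimable).
    rsquared : float, optional
        Coefficient of determination on the fitted observable.
    nobs : int, optional
        Number of observations entering the fit.
    """

    _title = "Least-squares fit"

    def __init__(self, params, bse=None, rsquared=None, nobs=None,
                 success=True, message="", warnings=()):
        self.params = dict(params)
        self.bse = dict(bse or {})
        self.rsquared = rsquared
        self.nobs = nobs
        self.success = bool(success)
        self.message = message
        self.warnings = list(warnings)

    def __getattr__(self, name):
        params = self.__dict__.get("params", {})
        if name in params:
            return params[name]
        raise AttributeError(name)

    def add_warning(self, code: str, message: str) -> None:
        self.warnings.append(FitWarningFlag(code, message))

    def summary(self) -> str:
        lines = [self._title, "=" * len(self._title)]
        if self.nobs is not None:
            lines.append(f"No. observations: {self.nobs}")
        if self.rsquared is not None:
            lines.append(f"R-squared:        {self.rsquared:.4f}")
        lines.append(f"Converged:        {self.success}")
        lines.append("-" * 44)
        lines.append(f"{'parameter':<18}{'estimate':>14}{'std err':>12}")
        for name, value in self.params.items():
            se = self.bse.get(name)
            se_s = f"{se:.4g}" if se is not None and np.isfinite(se) else "--"
            lines.append(f"{name:<18}{value:>14.6g}{se_s:>12}")
        for w in self.warnings:
            lines.append(f"[warning] {w.code}: {w.message}")
        if self.message:
            lines.append(self.message)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        body = ", ".join(f"{k}={v:.4g}" for k, v in self.params.items())
        return f"{type(self).__name__}({body})"


def rsquared(observed, predicted) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res == 0.0 else 0.0
    return 1.0 - ss_res / ss_tot


def ols_line(x, y):
    """Slope/intercept with standard errors for a simple straight-line
    regression; returns (slope, intercept, se_slope, se_intercept, r2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("at least two points are required for a line fit")
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0.0:
        raise ValueError("all abscissa values identical; line fit undefined")
    slope = float(np.sum((x - xm) * (y - ym)) / sxx)
    intercept = float(ym - slope * xm)
    resid = y - (intercept + slope * x)
    dof = max(n - 2, 1)
    s2 = float(np.sum(resid**2) / dof)
    se_slope = float(np.sqrt(s2 / sxx))
    se_intercept = float(np.sqrt(s2 * (1.0 / n + xm**2 / sxx)))
    return slope, intercept, se_slope, se_intercept, rsquared(y, intercept + slope * x)
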