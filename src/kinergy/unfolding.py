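"""Three-state equilibrium chemical denaturation (N <-> I <-> U).

The observed CD signal at denaturant concentration [D] is the
population-weighted average of three states, each with its own linear
baseline (linear extrapolation method):

    K1 = exp(-(dG_ni - m_ni*[D]) / RT)        (N -> I)
    K2 = exp(-(dG_iu - m_iu*[D]) / RT)        (I -> U)

    y([D]) = [(y_n + m_n*[D]) + (y_i + m_i*[D])*K1
              + (y_u + m_u*[D])*K1*K2] / (1 + K1 + K1*K2)

State populations are evaluated in log space so that large free
energies never overflow the exponentials.  Transition midpoints are
C_m1 = dG_ni/m_ni and C_m2 = dG_iu/m_iu.

RT uses R = 1.986e-3 kcal mol-1 K-1; the default temperature is 293 K
(far-UV CD at 20 C).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .base import FitResults, rsquared
from .constants import R_KCAL

__all__ = [
    "ThreeStateParams",
    "DenaturationCurve",
    "three_state_signal",
    "population_fractions",
    "ThreeStateUnfoldingModel",
    "ThreeStateResults",
    "fit_three_state",
]

DEFAULT_T = 293.0


@dataclass(frozen=True)
class ThreeStateParams:
    """Parameters of the three-state LEM model.

    Signals (y_*) and baseline slopes (m_n, m_i, m_u) are in the units
    of the observable (e.g. molar ellipticity at 222 nm); free energies
    dG_* in kcal/mol; m-values m_ni, m_iu in kcal/mol/M.
    """

    y_n: float
    y_i: float
    y_u: float
    m_n: float
    m_i: float
    m_u: float
    dG_ni: float
    m_ni: float
    dG_iu: float
    m_iu: float
    T: float = DEFAULT_T

    def __post_init__(self):
        if self.m_ni <= 0 or self.m_iu <= 0:
            raise ValueError("m-values must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be in kelvin")

    @property
    def cm1(self) -> float:
        """First transition midpoint dG_ni/m_ni, M."""
        return self.dG_ni / self.m_ni

    @property
    def cm2(self) -> float:
        """Second transition midpoint dG_iu/m_iu, M."""
        return self.dG_iu / self.m_iu


@dataclass
class DenaturationCurve:
    """Signal vs denaturant concentration (strictly increasing, M)."""

    denaturant: np.ndarray
    signal: np.ndarray

    def __post_init__(self):
        self.denaturant = np.asarray(self.denaturant, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.denaturant.shape != self.signal.shape:
            raise ValueError("denaturant and signal must have equal length")
        if np.any(self.denaturant < 0):
            raise ValueError("denaturant concentrations must be >= 0")
        if np.any(np.diff(self.denaturant) <= 0):
            raise ValueError("denaturant must be strictly increasing")


def _log_weights(d, p: ThreeStateParams):
    """Log Boltzmann weights of (N, I, U) relative to N at [D]=d."""
    d = np.asarray(d, dtype=float)
    rt = R_KCAL * p.T
    e1 = -(p.dG_ni - p.m_ni * d) / rt          # ln K1
    e2 = -(p.dG_iu - p.m_iu * d) / rt          # ln K2
    return np.stack([np.zeros_like(e1), e1, e1 + e2])


def population_fractions(d, p: ThreeStateParams):
    """Fractions (f_n, f_i, f_u) at denaturant concentration(s) d.

    Computed as a log-space softmax over the three Boltzmann weights,
    so the result is overflow-safe and sums to 1 exactly.
    """
    logw = _log_weights(d, p)
    return np.exp(logw - logsumexp(logw, axis=0))


def three_state_signal(d, p: ThreeStateParams):
    """Observed signal at denaturant concentration(s) d."""
    d = np.asarray(d, dtype=float)
    f = population_fractions(d, p)
    baselines = np.stack([p.y_n + p.m_n * d,
                          p.y_i + p.m_i * d,
                          p.y_u + p.m_u * d])
    return np.sum(f * baselines, axis=0)


class ThreeStateResults(FitResults):
    _title = "Three-state equilibrium unfolding fit"

    def __init__(self, fitted: ThreeStateParams, **kw):
        params = {"y_n": fitted.y_n, "y_i": fitted.y_i, "y_u": fitted.y_u,
                  "m_n": fitted.m_n, "m_i": fitted.m_i, "m_u": fitted.m_u,
                  "dG_ni": fitted.dG_ni, "m_ni": fitted.m_ni,
                  "dG_iu": fitted.dG_iu, "m_iu": fitted.m_iu,
                  "Cm1": fitted.cm1, "Cm2": fitted.cm2}
        super().__init__(params, **kw)
        self.fitted = fitted

    def predict(self, d):
        return three_state_signal(d, self.fitted)

    def populations(self, d):
        return population_fractions(d, self.fitted)

    def plot(self, curve: DenaturationCurve | None = None, ax=None):
        """Fitted curve with state populations on a twin axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        hi = 1.1 * self.fitted.cm2 + 1.0
        grid = np.linspace(0.0, hi, 200)
        if curve is not None:
            ax.plot(curve.denaturant, curve.signal, "o", ms=3, alpha=0.6)
            hi = max(hi, curve.denaturant.max())
        ax.plot(grid, self.predict(grid), "-", color="C3")
        ax.set_xlabel("[GdmCl] (M)")
        ax.set_ylabel("signal")
        ax2 = ax.twinx()
        for frac, lab in zip(self.populations(grid), ("N", "I", "U")):
            ax2.plot(grid, frac, "--", lw=0.8, label=lab)
        ax2.set_ylabel("population fraction")
        ax2.legend(loc="center right", fontsize=8)
        return ax


class ThreeStateUnfoldingModel:
    """Nonlinear least-squares fit of a denaturation curve.

    All nine signal/energy parameters float by default; set
    ``fix_m_i=True`` to pin the intermediate baseline slope at its
    initial value when it is poorly determined.  Initial guesses are
    data driven: native/unfolded baselines from the first/last three
    points, midpoints from the extrema of the numerical derivative of
    the curve.
    """

    def __init__(self, curve: DenaturationCurve, T: float = DEFAULT_T,
                 init: ThreeStateParams | None = None,
                 fix_m_i: bool = False):
        if not isinstance(curve, DenaturationCurve):
            curve = DenaturationCurve(*curve)
        if curve.denaturant.size < 12:
            raise ValueError("need >= 12 points spanning both transitions")
        self.curve = curve
        self.T = float(T)
        self.fix_m_i = fix_m_i
        self.init = init if init is not None else self._initial_guess()

    def _initial_guess(self) -> ThreeStateParams:
        d, y = self.curve.denaturant, self.curve.signal
        # native baseline from first 3 points, unfolded from last 3
        mn, yn = np.polyfit(d[:3], y[:3], 1)
        mu, yu = np.polyfit(d[-3:], y[-3:], 1)
        # midpoints: two strongest extrema of the numerical derivative
        dy = np.gradient(y, d)
        order = np.argsort(-np.abs(dy))
        picks: list[float] = []
        for i in order:
            if all(abs(d[i] - q) > 0.5 for q in picks):
                picks.append(d[i])
            if len(picks) == 2:
                break
        while len(picks) < 2:
            picks.append(d[len(d) // 2])
        cm1, cm2 = sorted(picks)
        mid = 0.5 * (cm1 + cm2)
        yi = float(np.interp(mid, d, y))
        m_guess = 3.0  # kcal/mol/M, typical for a ~300-residue domain
        return ThreeStateParams(
            y_n=yn, y_i=yi, y_u=yu, m_n=mn, m_i=0.0, m_u=mu,
            dG_ni=m_guess * cm1, m_ni=m_guess,
            dG_iu=m_guess * cm2, m_iu=m_guess, T=self.T)

    def fit(self) -> ThreeStateResults:
        d, y = self.curve.denaturant, self.curve.signal
        p0 = self.init
        names = ["y_n", "y_i", "y_u", "m_n", "m_i", "m_u",
                 "dG_ni", "m_ni", "dG_iu", "m_iu"]
        if self.fix_m_i:
            names.remove("m_i")
        x0 = np.array([getattr(p0, n) for n in names])
        lo = np.full(x0.size, -np.inf)
        hi = np.full(x0.size, np.inf)
        for bounded in ("dG_ni", "m_ni", "dG_iu", "m_iu"):
            lo[names.index(bounded)] = 1e-6

        def build(x) -> ThreeStateParams:
            kw = dict(zip(names, x))
            return replace(p0, **kw)

        def resid(x):
            return three_state_signal(d, build(x)) - y

        sol = least_squares(resid, x0, bounds=(lo, hi), ftol=1e-10,
                            xtol=1e-10, gtol=1e-10, max_nfev=20000)
        fitted = build(sol.x)
        pred = three_state_signal(d, fitted)
        se = {}
        try:
            dof = max(d.size - x0.size, 1)
            cov = np.linalg.pinv(sol.jac.T @ sol.jac) * 2 * sol.cost / dof
            se = dict(zip(names, np.sqrt(np.abs(np.diag(cov)))))
        except np.linalg.LinAlgError:
            pass
        res = ThreeStateResults(fitted, bse=se, rsquared=rsquared(y, pred),
                                nobs=d.size, success=bool(sol.success),
                                message=sol.message)
        if not sol.success:
            res.add_warning("non-convergence", sol.message)
        # flag a collinear/invisible intermediate
        f_i_max = float(population_fractions(
            np.linspace(d.min(), d.max(), 200), fitted)[1].max())
        if f_i_max < 0.05:
            res.add_warning("flat-intermediate",
                            "intermediate never exceeds 5% population; "
                            "its parameters are poorly determined")
        return res


def fit_three_state(curve, T: float = DEFAULT_T, init=None,
                    fix_m_i: bool = False) -> ThreeStateResults:
    """Convenience wrapper: ``ThreeStateUnfoldingModel(...).fit()``."""
    return ThreeStateUnfoldingModel(curve, T=T, init=init,
                                    fix_m_i=fix_m_i).fit()
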