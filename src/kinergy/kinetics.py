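"""SPR binding kinetics: 1:1 interaction model and pH dependence.

The central object is the pseudo-first-order 1:1 (Langmuir) interaction
model used by Biacore-style evaluation software.  During an association
phase at analyte concentration ``C`` the surface response obeys

    dR/dt = kon * C * (Rmax - R) - koff * R

whose solution from initial response ``R0`` is

    R(t) = Req + (R0 - Req) * exp(-(kon*C + koff) * t),
    Req  = kon * C * Rmax / (kon * C + koff)

and during dissociation (C = 0)

    R(t) = R0 * exp(-koff * t).

Single-cycle (kinetic titration) experiments chain several association
phases of increasing concentration with short dissociation gaps and no
regeneration; each phase simply inherits the previous phase's final
response.  Global fitting shares (kon, koff, Rmax) across every phase
and every trace.

No mass-transport limitation or bulk refractive-index terms are
modelled: traces are assumed blank-referenced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .base import FitResults, rsquared

__all__ = [
    "RateConstants",
    "Phase",
    "InjectionSchedule",
    "Sensorgram",
    "DegenerateDataError",
    "simulate_1to1",
    "OneToOneBindingModel",
    "OneToOneBindingResults",
    "fit_1to1",
    "derive_affinity",
    "half_life",
    "fold_change",
    "FourPLModel",
    "FourPLResults",
    "fit_4pl_ph",
]


class DegenerateDataError(ValueError):
    """Raised when the data carry no binding signal to fit."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateConstants:
    """Association/dissociation rate constants for one ligand-protein
    pair at one condition.

    ``KD`` (M) and ``t_half`` (s) are derived, so they are consistent
    with ``kon`` and ``koff`` by construction.
    """

    kon: float          # M-1 s-1
    koff: float         # s-1
    se_kon: float | None = None
    se_koff: float | None = None

    def __post_init__(self):
        if not (self.kon > 0):
            raise ValueError(f"kon must be positive, got {self.kon}")
        if not (self.koff > 0):
            raise ValueError(f"koff must be positive, got {self.koff}")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant koff/kon, M."""
        return self.koff / self.kon

    @property
    def t_half(self) -> float:
        """Complex half-life ln(2)/koff, s."""
        return math.log(2.0) / self.koff


@dataclass(frozen=True)
class Phase:
    kind: str            # "association" | "dissociation"
    start: float         # s
    duration: float      # s
    concentration: float  # M (0 for dissociation)

    def __post_init__(self):
        if self.kind not in ("association", "dissociation"):
            raise ValueError(f"unknown phase kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("phase duration must be positive")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        # an association phase at C = 0 is a buffer blank: allowed, and
        # kinetically identical to dissociation
        if self.kind == "dissociation" and self.concentration != 0:
            raise ValueError("dissociation phase must have concentration 0")

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered, contiguous list of association/dissociation phases."""

    phases: tuple[Phase, ...]

    def __post_init__(self):
        phases = tuple(self.phases)
        if not phases:
            raise ValueError("schedule must contain at least one phase")
        for prev, nxt in zip(phases, phases[1:]):
            if not math.isclose(prev.end, nxt.start, rel_tol=0, abs_tol=1e-9):
                raise ValueError(
                    f"phases must be contiguous: {prev.end} != {nxt.start}")
        object.__setattr__(self, "phases", phases)

    @property
    def start(self) -> float:
        return self.phases[0].start

    @property
    def end(self) -> float:
        return self.phases[-1].end

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(p.concentration for p in self.phases
                     if p.kind == "association")

    @classmethod
    def single_cycle(cls, concentrations: Sequence[float],
                     contact_time: float = 120.0, gap: float = 60.0,
                     final_dissociation: float = 3600.0) -> "InjectionSchedule":
        """Kinetic-titration schedule: sequential injections of
        increasing concentration, constant contact time, short
        dissociation gaps, and a long final dissociation."""
        conc = sorted(float(c) for c in concentrations)
        if any(c <= 0 for c in conc):
            raise ValueError("injection concentrations must be > 0")
        phases: list[Phase] = []
        t = 0.0
        for i, c in enumerate(conc):
            phases.append(Phase("association", t, contact_time, c))
            t += contact_time
            d = final_dissociation if i == len(conc) - 1 else gap
            phases.append(Phase("dissociation", t, d, 0.0))
            t += d
        return cls(tuple(phases))

    @classmethod
    def multi_cycle(cls, concentration: float, contact_time: float = 120.0,
                    dissociation: float = 600.0) -> "InjectionSchedule":
        """One association + dissociation cycle at a single concentration."""
        return cls((
            Phase("association", 0.0, contact_time, float(concentration)),
            Phase("dissociation", contact_time, dissociation, 0.0),
        ))


@dataclass
class Sensorgram:
    """Blank-referenced biosensor trace with its injection schedule."""

    time: np.ndarray       # s
    response: np.ndarray   # RU
    schedule: InjectionSchedule
    noise_sd: float = 0.0

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.shape != self.response.shape:
            raise ValueError("time and response must have the same length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.response)):
            raise ValueError("response must be finite")

    def plot(self, ax=None):
        """Quick diagnostic plot (RU vs time, phase boundaries marked)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.time, self.response, lw=0.8)
        for p in self.schedule.phases:
            if p.kind == "association":
                ax.axvspan(p.start, p.end, alpha=0.08, color="C1")
        ax.set_xlabel("time (s)")
        ax.set_ylabel("response (RU)")
        return ax


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _predict_response(time: np.ndarray, schedule: InjectionSchedule,
                      kon: float, koff: float, rmax: float,
                      r_start: float = 0.0) -> np.ndarray:
    """Piecewise closed-form 1:1 response on an arbitrary time grid.

    Phases chain exactly: each phase's initial response is the previous
    phase's response evaluated at its end point.
    """
    out = np.empty_like(time, dtype=float)
    r0 = float(r_start)
    for phase in schedule.phases:
        # include t == end in the *next* phase's domain except for the last
        last = phase is schedule.phases[-1]
        if last:
            mask = (time >= phase.start) & (time <= phase.end + 1e-12)
        else:
            mask = (time >= phase.start) & (time < phase.end)
        tau = time[mask] - phase.start
        if phase.kind == "association":
            kobs = kon * phase.concentration + koff
            req = kon * phase.concentration * rmax / kobs
            out[mask] = req + (r0 - req) * np.exp(-kobs * tau)
            r0 = req + (r0 - req) * math.exp(-kobs * phase.duration)
        else:
            out[mask] = r0 * np.exp(-koff * tau)
            r0 = r0 * math.exp(-koff * phase.duration)
    return out


def simulate_1to1(kon: float, koff: float, rmax: float,
                  schedule: InjectionSchedule, noise_sd: float = 0.0,
                  seed: int | None = None, dt: float = 1.0,
                  time: np.ndarray | None = None) -> Sensorgram:
    """Simulate a 1:1 interaction sensorgram on a regular grid.

    Parameters
    ----------
    kon, koff : float
        True rate constants (M-1 s-1, s-1).
    rmax : float
        Surface binding capacity, RU.
    schedule : InjectionSchedule
        Phase layout; single- and multi-cycle layouts both work.
    noise_sd : float
        Gaussian noise standard deviation in RU (0 = noise free).
    seed : int, optional
        Seed for the noise generator; required for reproducibility when
        ``noise_sd > 0``.
    dt : float
        Sampling interval of the generated grid, s.
    time : ndarray, optional
        Explicit grid overriding ``dt``.
    """
    if kon <= 0 or koff <= 0:
        raise ValueError("rate constants must be positive")
    if rmax <= 0:
        raise ValueError("rmax must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if time is None:
        n = int(round((schedule.end - schedule.start) / dt)) + 1
        time = schedule.start + dt * np.arange(n)
        time = time[time <= schedule.end + 1e-9]
    else:
        time = np.asarray(time, dtype=float)
    response = _predict_response(time, schedule, kon, koff, rmax)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        response = response + rng.normal(0.0, noise_sd, size=time.shape)
    return Sensorgram(time=time, response=response, schedule=schedule,
                      noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# global 1:1 fit
# ---------------------------------------------------------------------------

class OneToOneBindingResults(FitResults):
    """Global 1:1 fit results: kon, koff, rmax plus derived KD/t_half."""

    _title = "1:1 interaction model (global fit)"

    def __init__(self, rates: RateConstants, rmax: float, se_rmax, rss,
                 **kw):
        params = {"kon": rates.kon, "koff": rates.koff, "rmax": rmax,
                  "KD": rates.KD, "t_half": rates.t_half}
        bse = {"kon": rates.se_kon, "koff": rates.se_koff, "rmax": se_rmax}
        super().__init__(params, bse=bse, **kw)
        self.rates = rates
        self.rmax = rmax
        self.rss = rss

    def predict(self, sensorgram: Sensorgram) -> np.ndarray:
        return _predict_response(sensorgram.time, sensorgram.schedule,
                                 self.rates.kon, self.rates.koff, self.rmax)


class OneToOneBindingModel:
    """Global least-squares estimator for the 1:1 interaction model.

    Accepts one or more sensorgrams (e.g. a single-cycle trace, or a set
    of multi-cycle traces at different concentrations) and fits shared
    (kon, koff, Rmax).

    Fitting is performed on log10-parameters (positivity by
    construction) with ``scipy.optimize.least_squares``; relative
    tolerances 1e-8, at most 10,000 function evaluations, and three
    deterministic perturbed restarts if the first attempt fails.
    Initial guesses are data driven: koff from a log-linear fit of the
    final dissociation tail, kon from the equilibrium-response
    linearisation at the top injection.
    """

    def __init__(self, sensorgrams: Sensorgram | Iterable[Sensorgram]):
        if isinstance(sensorgrams, Sensorgram):
            sensorgrams = [sensorgrams]
        self.sensorgrams = list(sensorgrams)
        if not self.sensorgrams:
            raise ValueError("at least one sensorgram required")
        concs = set()
        has_assoc = has_dissoc = False
        for sg in self.sensorgrams:
            for p in sg.schedule.phases:
                if p.kind == "association":
                    has_assoc = True
                    concs.add(p.concentration)
                else:
                    has_dissoc = True
        if not (has_assoc and has_dissoc):
            raise ValueError("data must cover association and dissociation")
        if len(concs) < 2:
            raise ValueError("need >= 2 distinct analyte concentrations "
                             "for a well-determined global fit")
        self._concs = sorted(concs)

    # -- initial guesses ----------------------------------------------------
    def _guess(self) -> tuple[float, float, float]:
        sg = self.sensorgrams[0]
        rmax0 = 1.5 * max(float(np.max(np.abs(s.response)))
                          for s in self.sensorgrams)
        # koff: log-linear tail of the last dissociation phase
        tail = sg.schedule.phases[-1]
        koff0 = 1e-3
        if tail.kind == "dissociation":
            mask = sg.time >= tail.start
            t, r = sg.time[mask], sg.response[mask]
            pos = r > max(1e-3, 0.01 * np.max(np.abs(sg.response)))
            if pos.sum() >= 3:
                slope = np.polyfit(t[pos], np.log(r[pos]), 1)[0]
                if slope < 0:
                    koff0 = -slope
        # kon: end-of-injection response at the top concentration treated
        # as Req: kon = koff * R / (C * (rmax - R))
        kon0 = 1e5
        top = max((p for p in sg.schedule.phases if p.kind == "association"),
                  key=lambda p: p.concentration)
        idx = np.searchsorted(sg.time, top.end) - 1
        r_end = float(sg.response[idx])
        if 0 < r_end < rmax0:
            kon0 = max(koff0 * r_end / (top.concentration * (rmax0 - r_end)),
                       1e-2)
        return kon0, koff0, rmax0

    def _residuals(self, x: np.ndarray) -> np.ndarray:
        kon, koff, rmax = 10.0 ** x
        parts = [sg.response - _predict_response(sg.time, sg.schedule,
                                                 kon, koff, rmax)
                 for sg in self.sensorgrams]
        return np.concatenate(parts)

    def fit(self) -> OneToOneBindingResults:
        resp_scale = max(float(np.ptp(sg.response))
                         for sg in self.sensorgrams)
        if resp_scale <= 1e-9:
            raise DegenerateDataError(
                "sensorgram responses are flat; nothing to fit")
        kon0, koff0, rmax0 = self._guess()
        x0 = np.log10([kon0, koff0, rmax0])
        attempts = [x0]
        # deterministic multi-start perturbations
        for shift in ((0.5, -0.5, 0.0), (-0.5, 0.5, 0.2), (1.0, 0.0, -0.2)):
            attempts.append(x0 + np.array(shift))
        best = None
        for x_start in attempts:
            sol = least_squares(self._residuals, x_start, method="lm",
                                ftol=1e-8, xtol=1e-8, gtol=1e-8,
                                max_nfev=10000)
            if best is None or sol.cost < best.cost:
                best = sol
            if sol.success and best.cost < 1e2 * resp_scale**2:
                break
        sol = best
        kon, koff, rmax = 10.0 ** sol.x
        nobs = sum(sg.time.size for sg in self.sensorgrams)
        rss = float(2.0 * sol.cost)
        # covariance of log10-params -> delta method to linear scale
        se = {}
        try:
            jtj = sol.jac.T @ sol.jac
            cov = np.linalg.inv(jtj) * rss / max(nobs - 3, 1)
            sd_log = np.sqrt(np.diag(cov))
            ln10 = math.log(10.0)
            se = {"kon": kon * ln10 * sd_log[0],
                  "koff": koff * ln10 * sd_log[1],
                  "rmax": rmax * ln10 * sd_log[2]}
        except np.linalg.LinAlgError:
            se = {"kon": None, "koff": None, "rmax": None}
        rates = RateConstants(kon=kon, koff=koff,
                              se_kon=se.get("kon"), se_koff=se.get("koff"))
        obs = np.concatenate([sg.response for sg in self.sensorgrams])
        pred = obs - self._residuals(sol.x)
        res = OneToOneBindingResults(
            rates=rates, rmax=rmax, se_rmax=se.get("rmax"), rss=rss,
            rsquared=rsquared(obs, pred), nobs=nobs,
            success=bool(sol.success), message=sol.message)
        if not sol.success:
            res.add_warning("non-convergence",
                            "optimiser did not report convergence; "
                            "best of 4 starts returned")
        return res


def fit_1to1(sensorgrams) -> OneToOneBindingResults:
    """Convenience wrapper: ``OneToOneBindingModel(sensorgrams).fit()``."""
    return OneToOneBindingModel(sensorgrams).fit()


# ---------------------------------------------------------------------------
# derived scalar quantities
# ---------------------------------------------------------------------------

def derive_affinity(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant KD = koff/kon, M."""
    if kon <= 0:
        raise ValueError("kon must be positive")
    if koff <= 0:
        raise ValueError("koff must be positive")
    return koff / kon


def half_life(koff: float) -> float:
    """Complex half-life t1/2 = ln(2)/koff, s."""
    if koff <= 0:
        raise ValueError("koff must be positive")
    return math.log(2.0) / koff


def fold_change(a: RateConstants, b: RateConstants, quantity: str) -> float:
    """Ratio a/b of a named kinetic quantity (kon, koff or KD)."""
    if quantity not in ("kon", "koff", "KD"):
        raise ValueError(f"unknown quantity {quantity!r}; "
                         "expected 'kon', 'koff' or 'KD'")
    return getattr(a, quantity) / getattr(b, quantity)


# ---------------------------------------------------------------------------
# 4PL pH dependence
# ---------------------------------------------------------------------------

def four_pl(ph, k_low_ph: float, k_high_ph: float, pka: float,
            hill: float):
    """Four-parameter logistic in pH (base-10):

        k(pH) = k_high + (k_low - k_high) / (1 + 10**(hill*(pH - pKa)))

    With ``hill > 0`` the curve runs from the acidic plateau ``k_low_ph``
    to the basic plateau ``k_high_ph``; the inflection is at ``pKa``.
    """
    ph = np.asarray(ph, dtype=float)
    return k_high_ph + (k_low_ph - k_high_ph) / (
        1.0 + 10.0 ** (hill * (ph - pka)))


class FourPLResults(FitResults):
    _title = "4PL pH-dependence fit"

    def __init__(self, k_low_ph, k_high_ph, pka, hill, reliable=True, **kw):
        params = {"k_low_pH": k_low_ph, "k_high_pH": k_high_ph,
                  "pKa": pka, "hill": hill}
        super().__init__(params, **kw)
        self.reliable = reliable

    def predict(self, ph):
        return four_pl(ph, self.params["k_low_pH"], self.params["k_high_pH"],
                       self.params["pKa"], self.params["hill"])


class FourPLModel:
    """Least-squares 4PL fit of a rate constant against pH.

    The inflection point is reported as the effective pKa of the
    titrating group; ``hill`` is a free slope factor.
    """

    def __init__(self, ph, k):
        self.ph = np.asarray(ph, dtype=float)
        self.k = np.asarray(k, dtype=float)
        if self.ph.shape != self.k.shape:
            raise ValueError("ph and k must have the same length")
        if self.ph.size < 5:
            raise ValueError("need >= 5 pH points spanning the inflection")
        if np.any(self.k <= 0):
            raise ValueError("rate constants must be positive")

    def fit(self) -> FourPLResults:
        ph, k = self.ph, self.k
        flat = float(np.ptp(k)) < 0.05 * float(np.median(k))
        p0 = np.array([k.max(), k.min(), float(np.median(ph)), 1.0])

        def resid(x):
            return four_pl(ph, *x) - k

        sol = least_squares(resid, p0, ftol=1e-8, xtol=1e-8, gtol=1e-8,
                            max_nfev=10000,
                            bounds=([1e-30, 1e-30, 0.0, -20.0],
                                    [np.inf, np.inf, 14.0, 20.0]))
        if not sol.success:
            for fac in (0.5, 1.5, 2.0):
                p0b = p0.copy()
                p0b[2] = np.clip(p0[2] * fac, 0.1, 13.9)
                solb = least_squares(resid, p0b, ftol=1e-8, xtol=1e-8,
                                     gtol=1e-8, max_nfev=10000,
                                     bounds=([1e-30, 1e-30, 0.0, -20.0],
                                             [np.inf, np.inf, 14.0, 20.0]))
                if solb.cost < sol.cost:
                    sol = solb
                if sol.success:
                    break
        k_low, k_high, pka, hill = sol.x
        pred = four_pl(ph, *sol.x)
        se = {}
        try:
            dof = max(ph.size - 4, 1)
            cov = np.linalg.inv(sol.jac.T @ sol.jac) * 2 * sol.cost / dof
            sd = np.sqrt(np.diag(cov))
            se = dict(zip(("k_low_pH", "k_high_pH", "pKa", "hill"), sd))
        except np.linalg.LinAlgError:
            pass
        res = FourPLResults(k_low, k_high, pka, hill,
                            reliable=not flat, bse=se,
                            rsquared=rsquared(k, pred), nobs=ph.size,
                            success=bool(sol.success), message=sol.message)
        if flat:
            res.add_warning("flat-data", "no detectable pH dependence; "
                            "pKa estimate unreliable")
        return res


def fit_4pl_ph(ph, kon) -> FourPLResults:
    """Convenience wrapper: ``FourPLModel(ph, kon).fit()``."""
    return FourPLModel(ph, kon).fit()
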