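"""Equilibrium and transition-state binding thermodynamics.

Three estimators, all operating on temperature series measured by SPR
or ITC:

* integrated van't Hoff analysis with a fixed, temperature-independent
  heat-capacity change,

      ln KA(T) = ln KA0 + (dH0/R)(1/T0 - 1/T)
                 + (dCp/R)(T0/T - 1 + ln(T/T0)),

  yielding the standard binding enthalpy dH0 and, through
  dG0 = -R*T0*ln KA0, the full (dH, -T*dS, dG) ground-state triple;

* linear Eyring analysis of a rate constant,

      ln(k*h/(kB*T)) = -dH_ts/(R*T) + dS_ts/R,

  yielding activation enthalpy/entropy and the free-energy barrier
  dG_ts(T0) (a transmission coefficient of 1 and, for bimolecular kon,
  the 1 M standard state are assumed so the logarithm is dimensionless);

* heat-capacity regression dCp = d(dH)/dT from ITC enthalpies.

Ground and transition states are combined into a thermodynamic reaction
pathway (free -> transition state -> bound), in which the dissociation
barrier is the association barrier minus the ground-state value,
component by component.

All energies are in kcal mol-1 with R = 1.986 cal mol-1 K-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .base import FitResults, ols_line, rsquared
from .constants import H_PLANCK, K_BOLTZMANN, R_CAL, R_KCAL, T0_DEFAULT

__all__ = [
    "ThermoState",
    "PathwayModel",
    "VantHoffModel",
    "VantHoffResults",
    "vant_hoff_fit",
    "EyringModel",
    "EyringResults",
    "eyring_fit",
    "heat_capacity_fit",
    "assemble_pathway",
    "barrier_from_rate_ratio",
]

#: rounding tolerance (kcal/mol) for the dG = dH + (-T dS) identity
TRIPLE_ATOL = 0.05


@dataclass(frozen=True)
class ThermoState:
    """(dH, -T*dS, dG) triple at the reference temperature, kcal/mol.

    ``label`` distinguishes the bound ground state from association /
    dissociation transition states.
    """

    dH: float
    minus_TdS: float
    dG: float
    label: str = "ground"
    T0: float = T0_DEFAULT

    def __post_init__(self):
        gap = abs(self.dG - (self.dH + self.minus_TdS))
        if gap > TRIPLE_ATOL + 1e-12:
            raise ValueError(
                f"inconsistent state: dG={self.dG} differs from "
                f"dH + (-TdS) = {self.dH + self.minus_TdS} by {gap:.3f} "
                f"kcal/mol (> {TRIPLE_ATOL})")

    @classmethod
    def from_enthalpy_entropy(cls, dH: float, minus_TdS: float,
                              label: str = "ground",
                              T0: float = T0_DEFAULT) -> "ThermoState":
        return cls(dH=dH, minus_TdS=minus_TdS, dG=dH + minus_TdS,
                   label=label, T0=T0)

    def __sub__(self, other: "ThermoState") -> "ThermoState":
        if self.T0 != other.T0:
            raise ValueError("states must share the reference temperature")
        return ThermoState.from_enthalpy_entropy(
            self.dH - other.dH, self.minus_TdS - other.minus_TdS,
            label=f"{self.label}-{other.label}", T0=self.T0)


@dataclass(frozen=True)
class PathwayModel:
    """Thermodynamic reaction pathway free -> TS -> bound.

    ``ground`` is the bound state relative to free; ``ts_assoc`` the
    association barrier; ``ts_dissoc`` the dissociation barrier.  The
    closure ts_assoc - ts_dissoc == ground holds per component.
    """

    ground: ThermoState
    ts_assoc: ThermoState
    ts_dissoc: ThermoState

    def __post_init__(self):
        for name in ("dG", "dH", "minus_TdS"):
            gap = abs(getattr(self.ts_assoc, name)
                      - getattr(self.ts_dissoc, name)
                      - getattr(self.ground, name))
            if gap > 0.1 + 1e-12:
                raise ValueError(
                    f"pathway closure violated for {name}: "
                    f"assoc - dissoc differs from ground by {gap:.3f}")

    def components(self) -> dict:
        """Nine energy components as a nested dict (kcal/mol)."""
        return {
            state.label: {"dH": state.dH, "minus_TdS": state.minus_TdS,
                          "dG": state.dG}
            for state in (self.ground, self.ts_assoc, self.ts_dissoc)
        }


# ---------------------------------------------------------------------------
# van't Hoff
# ---------------------------------------------------------------------------

def vant_hoff_ln_ka(T, ln_ka0: float, dH0_kcal: float, dcp_cal: float,
                    t0: float = T0_DEFAULT):
    """Integrated van't Hoff model for ln KA(T); dH0 in kcal/mol, dCp in
    cal/mol/K."""
    T = np.asarray(T, dtype=float)
    dh_cal = dH0_kcal * 1000.0
    return (ln_ka0
            + (dh_cal / R_CAL) * (1.0 / t0 - 1.0 / T)
            + (dcp_cal / R_CAL) * (t0 / T - 1.0 + np.log(T / t0)))


class VantHoffResults(FitResults):
    _title = "Integrated van't Hoff fit"

    def __init__(self, ka0, dH0, ground: ThermoState, dcp, t0, **kw):
        params = {"KA0": ka0, "dH0": dH0, "dG0": ground.dG,
                  "minus_TdS0": ground.minus_TdS}
        super().__init__(params, **kw)
        self.ground = ground
        self.dcp = dcp
        self.t0 = t0

    @property
    def KD_implied(self) -> float:
        """Dissociation constant implied by dG0: KD = exp(dG0/(R*T0)), M."""
        return math.exp(self.ground.dG / (R_KCAL * self.t0))

    def predict(self, T):
        return vant_hoff_ln_ka(T, math.log(self.params["KA0"]),
                               self.params["dH0"], self.dcp, self.t0)


class VantHoffModel:
    """Fit of ln KA against temperature with fixed heat capacity change.

    ``dcp`` (cal/mol/K) is a constrained input, never co-fitted; with
    ``dcp = 0`` the model reduces to the classical straight line in
    (1/T, ln KA).  Because dCp is fixed, the least-squares problem is
    linear in (ln KA0, dH0) and is solved exactly.
    """

    def __init__(self, temperatures, ka, dcp: float = 0.0,
                 t0: float = T0_DEFAULT):
        self.T = np.asarray(temperatures, dtype=float)
        self.ka = np.asarray(ka, dtype=float)
        if self.T.shape != self.ka.shape:
            raise ValueError("temperatures and KA must have equal length")
        if self.T.size < 3:
            raise ValueError("need at least 3 temperatures")
        if np.any(self.ka <= 0):
            raise ValueError("association constants must be positive")
        if np.any(self.T <= 0):
            raise ValueError("temperatures must be in kelvin (> 0)")
        self.dcp = float(dcp)
        self.t0 = float(t0)

    def fit(self) -> VantHoffResults:
        y = np.log(self.ka)
        offset = (self.dcp / R_CAL) * (self.t0 / self.T - 1.0
                                       + np.log(self.T / self.t0))
        x = (1.0 / self.t0 - 1.0 / self.T)
        # y - offset = ln KA0 + (dH0_cal/R) * x
        slope, intercept, se_slope, se_intercept, _ = ols_line(x, y - offset)
        dh0 = slope * R_CAL / 1000.0           # kcal/mol
        ln_ka0 = intercept
        ka0 = math.exp(ln_ka0)
        dg0 = -R_KCAL * self.t0 * ln_ka0       # kcal/mol
        ground = ThermoState(dH=dh0, minus_TdS=dg0 - dh0, dG=dg0,
                             label="ground", T0=self.t0)
        pred = vant_hoff_ln_ka(self.T, ln_ka0, dh0, self.dcp, self.t0)
        bse = {"dH0": se_slope * R_CAL / 1000.0,
               "dG0": R_KCAL * self.t0 * se_intercept,
               "KA0": ka0 * se_intercept}
        return VantHoffResults(ka0=ka0, dH0=dh0, ground=ground,
                               dcp=self.dcp, t0=self.t0, bse=bse,
                               rsquared=rsquared(y, pred), nobs=self.T.size)


def vant_hoff_fit(temperatures, ka, dcp: float = 0.0,
                  t0: float = T0_DEFAULT) -> VantHoffResults:
    """Convenience wrapper: ``VantHoffModel(...).fit()``."""
    return VantHoffModel(temperatures, ka, dcp=dcp, t0=t0).fit()


# ---------------------------------------------------------------------------
# Eyring
# ---------------------------------------------------------------------------

def eyring_rate(T, dH_ts_kcal: float, dS_ts_cal: float):
    """Forward Eyring model k(T) = (kB*T/h) exp(-dH/(R T) + dS/R)."""
    T = np.asarray(T, dtype=float)
    return (K_BOLTZMANN * T / H_PLANCK) * np.exp(
        -dH_ts_kcal * 1000.0 / (R_CAL * T) + dS_ts_cal / R_CAL)


class EyringResults(FitResults):
    _title = "Linear Eyring fit"

    def __init__(self, dH_ts, dS_ts, ts: ThermoState, t0, **kw):
        params = {"dH_ts": dH_ts, "dS_ts": dS_ts, "dG_ts": ts.dG,
                  "minus_TdS_ts": ts.minus_TdS}
        super().__init__(params, **kw)
        self.ts = ts
        self.t0 = t0

    def predict_ln(self, T):
        T = np.asarray(T, dtype=float)
        return (-self.params["dH_ts"] * 1000.0 / (R_CAL * T)
                + self.params["dS_ts"] / R_CAL)


class EyringModel:
    """Linear regression of ln(k*h/(kB*T)) on 1/T.

    Slope = -dH_ts/R, intercept = dS_ts/R; the free-energy barrier is
    evaluated at ``t0``: dG_ts = dH_ts - T0*dS_ts.  ``k`` may be kon
    (M-1 s-1, 1 M standard state) or koff (s-1).
    """

    def __init__(self, temperatures, k, t0: float = T0_DEFAULT):
        self.T = np.asarray(temperatures, dtype=float)
        self.k = np.asarray(k, dtype=float)
        if self.T.shape != self.k.shape:
            raise ValueError("temperatures and k must have equal length")
        if self.T.size < 3:
            raise ValueError("need at least 3 temperatures")
        if np.any(self.k <= 0):
            raise ValueError("rate constants must be positive")
        self.t0 = float(t0)

    def fit(self) -> EyringResults:
        y = np.log(self.k * H_PLANCK / (K_BOLTZMANN * self.T))
        x = 1.0 / self.T
        slope, intercept, se_slope, se_intercept, r2 = ols_line(x, y)
        dh_ts = -slope * R_CAL / 1000.0        # kcal/mol
        ds_ts = intercept * R_CAL              # cal/mol/K
        minus_tds = -self.t0 * ds_ts / 1000.0  # kcal/mol
        ts = ThermoState.from_enthalpy_entropy(dh_ts, minus_tds,
                                               label="transition",
                                               T0=self.t0)
        bse = {"dH_ts": se_slope * R_CAL / 1000.0,
               "dS_ts": se_intercept * R_CAL}
        return EyringResults(dH_ts=dh_ts, dS_ts=ds_ts, ts=ts, t0=self.t0,
                             bse=bse, rsquared=r2, nobs=self.T.size)


def eyring_fit(temperatures, k, t0: float = T0_DEFAULT) -> EyringResults:
    """Convenience wrapper: ``EyringModel(...).fit()``."""
    return EyringModel(temperatures, k, t0=t0).fit()


# ---------------------------------------------------------------------------
# heat capacity and pathway assembly
# ---------------------------------------------------------------------------

def heat_capacity_fit(temperatures, dH_kcal) -> dict:
    """Heat-capacity change as the OLS slope of dH (kcal/mol) against T
    (K); returned in cal mol-1 K-1 with its standard error and R^2."""
    T = np.asarray(temperatures, dtype=float)
    dh = np.asarray(dH_kcal, dtype=float)
    if T.size < 2:
        raise ValueError("need at least 2 points for the dCp regression")
    slope, intercept, se_slope, _, r2 = ols_line(T, dh * 1000.0)
    return {"dCp": slope, "se_dCp": se_slope, "intercept_cal": intercept,
            "r_squared": r2}


def assemble_pathway(ground: ThermoState,
                     ts_assoc: ThermoState) -> PathwayModel:
    """Build the full reaction pathway; the dissociation barrier is
    computed component-wise as ts_assoc - ground."""
    diff = ts_assoc - ground
    ts_dissoc = ThermoState.from_enthalpy_entropy(
        diff.dH, diff.minus_TdS, label="transition_dissoc", T0=ground.T0)
    ts_assoc = ThermoState(dH=ts_assoc.dH, minus_TdS=ts_assoc.minus_TdS,
                           dG=ts_assoc.dG, label="transition_assoc",
                           T0=ts_assoc.T0)
    return PathwayModel(ground=ground, ts_assoc=ts_assoc,
                        ts_dissoc=ts_dissoc)


def barrier_from_rate_ratio(k_fast: float, k_slow: float,
                            T: float = T0_DEFAULT) -> float:
    """Free-energy barrier difference implied by a rate ratio,
    ddG = R*T*ln(k_fast/k_slow), kcal/mol."""
    if k_fast <= 0 or k_slow <= 0:
        raise ValueError("rates must be positive")
    return R_KCAL * T * math.log(k_fast / k_slow)
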