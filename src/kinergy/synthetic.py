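"""Seeded synthetic-data generators for every pipeline input.

Each generator is the exact forward model of the estimator that will
consume its output, so a generate -> fit round trip at zero noise
recovers the scenario truth to optimiser tolerance.  Noise models:

* sensorgrams — additive Gaussian in RU;
* KA / rate temperature tables and pH series — multiplicative
  log-normal (rate constants are strictly positive and their replicate
  scatter is proportional);
* denaturation curves — additive Gaussian in ellipticity;
* NMR peak lists — Gaussian ppm jitter per nucleus;
* HDX centroids — Gaussian Da jitter per replicate.

Two built-in scenarios bundle realistic parameter regimes for a slow,
entropy-driven type II binder (``ponatinib``) and a fast,
enthalpy-driven type I binder (``pda``); both bind a ~300-residue
kinase domain with nM affinity.  The same seed always reproduces the
same output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import R_KCAL, T0_DEFAULT
from .kinetics import InjectionSchedule, Sensorgram, four_pl, simulate_1to1
from .thermo import eyring_rate, vant_hoff_ln_ka
from .unfolding import DenaturationCurve, ThreeStateParams, \
    three_state_signal

__all__ = [
    "NoiseSpec",
    "ScenarioSpec",
    "scenario",
    "SCENARIO_NAMES",
    "gen_sensorgrams",
    "gen_temperature_series",
    "gen_ph_series",
    "gen_denaturation_curve",
    "gen_peaklists",
    "HDXMapData",
    "gen_hdx_map",
    "random_protein_sequence",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Noise levels of the individual generators."""

    sensorgram_ru: float = 0.5         # additive, RU (~1% of rmax)
    ka_lognormal: float = 0.03         # multiplicative, 3%
    rate_lognormal: float = 0.03       # multiplicative, 3%
    ph_lognormal: float = 0.05         # multiplicative, 5%
    ellipticity: float = 0.2           # additive, signal units
    ppm_h: float = 0.004               # 1H jitter, ppm
    ppm_n: float = 0.03                # 15N jitter, ppm
    centroid_da: float = 0.02          # HDX centroid jitter, Da


@dataclass(frozen=True)
class ScenarioSpec:
    """True parameters of one ligand scenario plus noise levels.

    The kinetic, thermodynamic and transition-state parameters describe
    a 1:1 binder; ``unfolding`` describes the protein's denaturation
    behaviour (shared across ligand scenarios).
    """

    name: str
    # kinetics
    kon: float                          # M-1 s-1
    koff: float                         # s-1
    rmax: float = 50.0                  # RU
    # ground-state thermodynamics (kcal/mol at T0)
    dH0: float = 0.0
    dG0: float = -10.0
    dcp: float = 0.0                    # cal/mol/K, fixed in the fit
    # association transition state (kcal/mol at T0)
    dH_ts: float = 15.0
    minus_TdS_ts: float = -5.0
    # pH dependence of kon (4PL); plateau_ratio = k(acidic)/k(basic)
    pka: float | None = None
    hill: float = 1.0
    plateau_ratio: float = 7.0
    # unfolding (protein property)
    unfolding: ThreeStateParams = field(default_factory=lambda:
                                        ThreeStateParams(
                                            y_n=-20.0, y_i=-12.0, y_u=-4.0,
                                            m_n=0.05, m_i=0.1, m_u=0.05,
                                            dG_ni=4.2, m_ni=3.0,
                                            dG_iu=7.8, m_iu=3.0, T=293.0))
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    t0: float = T0_DEFAULT
    seed: int = 0

    @property
    def KD(self) -> float:
        return self.koff / self.kon

    @property
    def ka0(self) -> float:
        """Association constant at T0 implied by dG0, M-1."""
        return math.exp(-self.dG0 / (R_KCAL * self.t0))

    @property
    def dS_ts(self) -> float:
        """Association activation entropy, cal/mol/K."""
        return -self.minus_TdS_ts * 1000.0 / self.t0


def _ponatinib_like() -> ScenarioSpec:
    # slow, entropy-driven type II binder: kon 2.4e4 M-1 s-1,
    # koff 1.9e-4 s-1 (KD 7.9 nM, t1/2 ~61 min); endothermic binding
    # (dH0 +10.1 kcal/mol) and a high association barrier (dG_ts 11.0);
    # kon titrates with an effective pKa of 6.25 (sevenfold range).
    return ScenarioSpec(
        name="ponatinib", kon=2.4e4, koff=1.9e-4,
        dH0=10.1, dG0=-10.9, dcp=0.0,
        dH_ts=22.2, minus_TdS_ts=-11.2,
        pka=6.25, hill=1.0, plateau_ratio=7.0)


def _pda_like() -> ScenarioSpec:
    # fast, enthalpy-driven type I binder: kon 1.6e6, koff 9.2e-3
    # (KD 5.7 nM, t1/2 1.3 min); exothermic (dH0 -11.5 kcal/mol,
    # dCp -359 cal/mol/K) with a lower barrier (dG_ts 8.7); kon is
    # pH independent.
    return ScenarioSpec(
        name="pda", kon=1.6e6, koff=9.2e-3,
        dH0=-11.5, dG0=-11.1, dcp=-359.0,
        dH_ts=16.6, minus_TdS_ts=-7.9,
        pka=None)


def _su5402_like() -> ScenarioSpec:
    # weaker exothermic type I binder used for the dCp -172 regime
    return ScenarioSpec(
        name="su5402", kon=2.0e6, koff=2.0e-1,
        dH0=-14.2, dG0=-9.4, dcp=-172.0,
        dH_ts=14.0, minus_TdS_ts=-5.0,
        pka=None)


_SCENARIOS = {"ponatinib": _ponatinib_like, "pda": _pda_like,
              "su5402": _su5402_like}
SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario(name: str, **overrides) -> ScenarioSpec:
    """Built-in scenario by name ('ponatinib', 'pda', 'su5402'), with
    optional field overrides."""
    try:
        spec = _SCENARIOS[name.lower()]()
    except KeyError:
        raise ValueError(f"unknown scenario {name!r}; "
                         f"choose from {SCENARIO_NAMES}") from None
    return replace(spec, **overrides) if overrides else spec


# ---------------------------------------------------------------------------
# SPR
# ---------------------------------------------------------------------------

def default_schedule(spec: ScenarioSpec, n_injections: int = 5,
                     contact_time: float = 120.0, gap: float = 60.0,
                     top_fold_kd: float = 20.0,
                     dilution: float = 3.0) -> InjectionSchedule:
    """Single-cycle schedule: ``n_injections`` sequential injections
    with constant contact time and dilution factor, short gaps, and a
    final dissociation long enough to decay the complex substantially
    (capped at 20,000 s)."""
    top = top_fold_kd * spec.KD
    conc = [top / dilution**i for i in range(n_injections)]
    final = float(np.clip(3.0 / spec.koff, 1000.0, 20000.0))
    return InjectionSchedule.single_cycle(conc, contact_time=contact_time,
                                          gap=gap,
                                          final_dissociation=final)


def gen_sensorgrams(spec: ScenarioSpec, seed: int | None = None,
                    mode: str = "single_cycle", dt: float = 1.0,
                    noise_sd: float | None = None) -> list[Sensorgram]:
    """Simulated sensorgram set for the scenario's rate constants.

    ``mode='single_cycle'`` returns one chained kinetic-titration trace;
    ``mode='multi_cycle'`` one trace per concentration.
    """
    if seed is None:
        seed = spec.seed
    if noise_sd is None:
        noise_sd = spec.noise.sensorgram_ru
    rng = np.random.default_rng(seed)
    if mode == "single_cycle":
        sched = default_schedule(spec)
        return [simulate_1to1(spec.kon, spec.koff, spec.rmax, sched,
                              noise_sd=noise_sd,
                              seed=int(rng.integers(2**31)), dt=dt)]
    if mode == "multi_cycle":
        sched0 = default_schedule(spec)
        out = []
        for c in sched0.concentrations:
            sched = InjectionSchedule.multi_cycle(
                c, contact_time=120.0,
                dissociation=float(np.clip(3.0 / spec.koff, 600.0, 20000.0)))
            out.append(simulate_1to1(spec.kon, spec.koff, spec.rmax, sched,
                                     noise_sd=noise_sd,
                                     seed=int(rng.integers(2**31)), dt=dt))
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# temperature series
# ---------------------------------------------------------------------------

def gen_temperature_series(spec: ScenarioSpec, seed: int | None = None,
                           n_temps: int = 7, t_min: float = 281.0,
                           t_max: float = 308.0,
                           noise: float | None = None) -> pd.DataFrame:
    """KA(T), kon(T) and koff(T) tables from the integrated van't Hoff
    and Eyring forward models, with multiplicative log-normal noise.

    Columns: T_K, KA_per_M, kon_per_M_s, koff_per_s.
    """
    if n_temps < 6:
        raise ValueError("use at least 6 temperatures")
    if seed is None:
        seed = spec.seed
    if noise is None:
        noise = spec.noise.ka_lognormal
    rng = np.random.default_rng(seed)
    T = np.linspace(t_min, t_max, n_temps)
    ln_ka = vant_hoff_ln_ka(T, math.log(spec.ka0), spec.dH0, spec.dcp,
                            t0=spec.t0)
    ka = np.exp(ln_ka)
    kon = eyring_rate(T, spec.dH_ts, spec.dS_ts)
    koff = kon / ka
    if noise > 0:
        ka = ka * np.exp(rng.normal(0.0, noise, size=T.shape))
        kon = kon * np.exp(rng.normal(0.0, spec.noise.rate_lognormal,
                                      size=T.shape))
        koff = koff * np.exp(rng.normal(0.0, spec.noise.rate_lognormal,
                                        size=T.shape))
    return pd.DataFrame({"T_K": T, "KA_per_M": ka, "kon_per_M_s": kon,
                         "koff_per_s": koff})


# ---------------------------------------------------------------------------
# pH series
# ---------------------------------------------------------------------------

def gen_ph_series(spec: ScenarioSpec, seed: int | None = None,
                  n_points: int = 8, ph_min: float = 5.5,
                  ph_max: float = 7.4,
                  noise: float | None = None) -> pd.DataFrame:
    """kon as a function of pH from the 4PL forward model.

    The basic plateau is the scenario kon; the acidic plateau is
    ``plateau_ratio`` times faster.  Scenarios without a pKa produce a
    flat (pH-independent) series.  Columns: pH, kon_per_M_s.
    """
    if seed is None:
        seed = spec.seed
    if noise is None:
        noise = spec.noise.ph_lognormal
    rng = np.random.default_rng(seed)
    ph = np.linspace(ph_min, ph_max, n_points)
    if spec.pka is None:
        k = np.full(ph.shape, spec.kon)
    else:
        k = four_pl(ph, spec.plateau_ratio * spec.kon, spec.kon,
                    spec.pka, spec.hill)
    if noise > 0:
        k = k * np.exp(rng.normal(0.0, noise, size=ph.shape))
    return pd.DataFrame({"pH": ph, "kon_per_M_s": k})


# ---------------------------------------------------------------------------
# denaturation curve
# ---------------------------------------------------------------------------

def gen_denaturation_curve(spec: ScenarioSpec, seed: int | None = None,
                           n_points: int = 31, d_max: float = 4.5,
                           noise: float | None = None) -> DenaturationCurve:
    """CD ellipticity vs denaturant from the three-state forward model
    with additive Gaussian noise."""
    if seed is None:
        seed = spec.seed
    if noise is None:
        noise = spec.noise.ellipticity
    rng = np.random.default_rng(seed)
    d = np.linspace(0.0, d_max, n_points)
    y = three_state_signal(d, spec.unfolding)
    if noise > 0:
        y = y + rng.normal(0.0, noise, size=d.shape)
    return DenaturationCurve(denaturant=d, signal=y)


# ---------------------------------------------------------------------------
# NMR peak lists
# ---------------------------------------------------------------------------

def gen_peaklists(spec: ScenarioSpec, seed: int | None = None,
                  n_residues: int = 300,
                  planted: dict[int, tuple[float, float]] | None = None,
                  n_planted: int = 10,
                  bound_only: tuple[int, ...] = (),
                  apo_only: tuple[int, ...] = ()) -> dict:
    """Apo and bound amide peak lists with planted perturbations.

    ``planted`` maps residue -> (ddH, ddN) offsets applied to the bound
    state; when omitted, ``n_planted`` residues receive offsets large
    enough to exceed the 0.25 ppm weighted-CSP threshold.  Residues in
    ``bound_only`` / ``apo_only`` appear in only one list (an
    observability difference, e.g. activation-loop amides sharpening on
    binding).  Returns dict with 'apo', 'bound' DataFrames and
    'planted'.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    residues = np.arange(1, n_residues + 1)
    aa = rng.choice(list("ACDEFGHIKLMNQRSTVWY"), size=n_residues)
    dh = rng.normal(8.3, 0.45, size=n_residues)
    dn = rng.normal(119.0, 4.0, size=n_residues)
    if planted is None:
        # exclude single-state residues from the planting pool
        pool = np.setdiff1d(residues, np.array(bound_only + apo_only,
                                               dtype=int))
        chosen = rng.choice(pool, size=n_planted, replace=False)
        planted = {}
        for res in sorted(int(r) for r in chosen):
            sign = rng.choice([-1.0, 1.0])
            planted[res] = (sign * rng.uniform(0.4, 0.8),
                            sign * rng.uniform(1.0, 3.0))
    apo = pd.DataFrame({"residue": residues, "aa": aa,
                        "dH": dh, "dN": dn})
    dh_b = dh + rng.normal(0.0, spec.noise.ppm_h, size=n_residues)
    dn_b = dn + rng.normal(0.0, spec.noise.ppm_n, size=n_residues)
    bound = pd.DataFrame({"residue": residues, "aa": aa,
                          "dH": dh_b, "dN": dn_b})
    for res, (ddh, ddn) in planted.items():
        bound.loc[bound["residue"] == res, "dH"] += ddh
        bound.loc[bound["residue"] == res, "dN"] += ddn
    apo = apo[~apo["residue"].isin(bound_only)].reset_index(drop=True)
    bound = bound[~bound["residue"].isin(apo_only)].reset_index(drop=True)
    return {"apo": apo, "bound": bound, "planted": planted}


# ---------------------------------------------------------------------------
# HDX map
# ---------------------------------------------------------------------------

def random_protein_sequence(n_residues: int, seed: int = 0) -> str:
    """Deterministic random amino-acid sequence (synthetic stand-in for
    a real kinase-domain construct; ~5% proline)."""
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNQRSTVWY")
    seq = list(rng.choice(aas, size=n_residues))
    n_pro = max(1, n_residues // 20)
    pos = rng.choice(np.arange(1, n_residues), size=n_pro, replace=False)
    for p in pos:
        seq[p] = "P"
    return "".join(seq)


#: default labelling time grid: nine log-spaced points, 10 s .. 2 h
DEFAULT_HDX_TIMES = tuple(np.round(
    np.geomspace(10.0, 7200.0, 9), 1).tolist())


@dataclass
class HDXMapData:
    """Synthetic HDX experiment: uptake table, sequence, ground truth."""

    table: pd.DataFrame                 # flat uptake-table dialect
    sequence: str
    rates: dict                         # state -> per-residue k_ex (s-1)
    peptides: list                      # list of Peptide
    regions: dict                       # state -> {residue: factor}


def _tile_peptides(n_residues: int, rng, coverage: float = 0.97):
    """Overlapping 8-18-mer tiling with one uncovered stretch of
    ~(1 - coverage) of the sequence (a pepsin blind spot)."""
    n_gap = max(0, int(round(n_residues * (1.0 - coverage))))
    gap_start = int(rng.integers(n_residues // 2, n_residues - n_gap - 10))
    gap = set(range(gap_start, gap_start + n_gap))
    segments = [(1, gap_start - 1), (gap_start + n_gap, n_residues)]
    spans: list[tuple[int, int]] = []
    for seg_start, seg_end in segments:
        start = seg_start
        while start <= seg_end - 2:
            length = int(rng.integers(8, 19))
            end = min(start + length - 1, seg_end)
            if end - start + 1 >= 3:
                spans.append((start, end))
            start += int(rng.integers(4, 9))
        if spans and spans[-1][1] < seg_end:   # cover the segment tail
            tail_start = max(seg_start, seg_end - int(rng.integers(8, 15)))
            spans.append((tail_start, seg_end))
    return spans, gap


def gen_hdx_map(spec: ScenarioSpec, seed: int | None = None,
                n_residues: int = 310,
                states: tuple[str, ...] = ("apo", "bound"),
                protection_regions: dict | None = None,
                times: tuple = DEFAULT_HDX_TIMES,
                n_replicates: int = 2,
                noise: float | None = None) -> HDXMapData:
    """Forward-simulated peptide-level HDX uptake table.

    Each residue exchanges as u(t) = 1 - exp(-k*t); a peptide centroid
    at time t is its undeuterated centroid plus the summed uptake of its
    exchangeable amides.  ``protection_regions`` maps a state name to
    {residue: rate factor} (factor > 1 = deprotected relative to apo,
    < 1 = protected).  Defaults plant one protected and one deprotected
    segment in the 'bound' state.  The peptide map tiles ~97% of the
    sequence with overlapping 8-18-mers.
    """
    from .hdx import Peptide, exchangeable_amides

    if seed is None:
        seed = spec.seed
    if noise is None:
        noise = spec.noise.centroid_da
    rng = np.random.default_rng(seed)
    sequence = random_protein_sequence(n_residues,
                                       seed=int(rng.integers(2**31)))
    base_k = 10.0 ** rng.uniform(-3.5, -1.0, size=n_residues + 1)  # 1-based
    if protection_regions is None:
        # one protected and one deprotected segment, placed relative to
        # the sequence length
        protected = range(max(2, n_residues // 15), n_residues // 8 + 1)
        deprotected = range(int(0.58 * n_residues),
                            int(0.65 * n_residues) + 1)
        protection_regions = {s: {} for s in states}
        for s in states:
            if s != "apo":
                protection_regions[s] = (
                    {r: 0.1 for r in protected}
                    | {r: 10.0 for r in deprotected})
    spans, _gap = _tile_peptides(n_residues, rng)
    peptides = [Peptide(s, e, sequence[s - 1:e]) for s, e in spans]
    rates = {}
    rows = []
    for state in states:
        k = base_k.copy()
        for res, factor in protection_regions.get(state, {}).items():
            k[res] *= factor
        rates[state] = {r: float(k[r]) for r in range(1, n_residues + 1)}
        for pep in peptides:
            c0 = 110.0 * len(pep.sequence) + 18.0
            exch = pep.exchangeable_residues()
            for t in (0.0,) + tuple(times):
                uptake = 0.0 if t == 0 else float(
                    np.sum(1.0 - np.exp(-k[np.array(exch)] * t)))
                for rep in range(1, n_replicates + 1):
                    jitter = rng.normal(0.0, noise) if noise > 0 else 0.0
                    rows.append({
                        "start": pep.start, "end": pep.end,
                        "sequence": pep.sequence, "state": state,
                        "time_s": t, "replicate": rep,
                        "centroid_Da": c0 + uptake + jitter,
                    })
    table = pd.DataFrame(rows)
    return HDXMapData(table=table, sequence=sequence, rates=rates,
                      peptides=peptides, regions=protection_regions)
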