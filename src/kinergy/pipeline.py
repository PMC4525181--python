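"""End-to-end analysis pipeline.

``run_pipeline`` executes the full analysis chain for one or more
ligand scenarios — 1:1 kinetics, pH-dependence pKa, van't Hoff and
Eyring thermodynamics, pathway assembly, equilibrium unfolding, CSP
classification and HDX difference mapping — writing per-stage CSV
outputs and a YAML summary.  Inputs are taken from the seeded synthetic
generators unless the configuration points at CSV files on disk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hdx as hdx_mod
from . import io as io_mod
from .kinetics import fit_1to1, fit_4pl_ph
from .nmr import classify_csp
from .synthetic import (ScenarioSpec, gen_denaturation_curve, gen_hdx_map,
                        gen_peaklists, gen_ph_series, gen_sensorgrams,
                        gen_temperature_series, scenario)
from .thermo import assemble_pathway, barrier_from_rate_ratio, eyring_fit, \
    vant_hoff_fit
from .unfolding import fit_three_state

__all__ = ["AnalysisConfig", "run_pipeline"]

log = logging.getLogger("kinergy")


@dataclass
class AnalysisConfig:
    """Pipeline configuration.

    ``inputs`` may map stage names ('temperature_series', 'ph_series',
    'denaturation', 'peaklists', 'hdx') to CSV paths per scenario;
    stages without inputs run on synthetic data generated with
    ``seed``.
    """

    out_dir: str | Path = "kinergy_out"
    seed: int = 0
    scenarios: tuple[str, ...] = ("ponatinib", "pda")
    csp_threshold: float = 0.25       # ppm
    hdx_threshold_da: float = 0.4     # Da
    t0: float = 298.0                 # K
    unfold_temperature: float = 293.0  # K
    inputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.csp_threshold <= 0 or self.hdx_threshold_da <= 0:
            raise ValueError("thresholds must be positive")
        for stage, path in self.inputs.items():
            if isinstance(path, (str, Path)) and not Path(path).exists():
                raise FileNotFoundError(f"{stage} input not found: {path}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "scenarios" in data:
            data["scenarios"] = tuple(data["scenarios"])
        return cls(**data)


def _ligand_stage(spec: ScenarioSpec, cfg: AnalysisConfig, out: Path,
                  seed: int) -> dict:
    res: dict = {}
    log.info("[%s] fitting 1:1 kinetics", spec.name)
    sgs = gen_sensorgrams(spec, seed=seed)
    io_mod.write_sensorgram_csv(out / f"{spec.name}_sensorgram.csv", sgs)
    kin = fit_1to1(sgs)
    log.info("[%s] kinetics: %s", spec.name, kin.message or "converged")
    res["kinetics"] = {
        "kon_per_M_s": kin.rates.kon, "koff_per_s": kin.rates.koff,
        "KD_M": kin.rates.KD, "t_half_s": kin.rates.t_half,
        "rmax_RU": kin.rmax, "r_squared": kin.rsquared,
    }

    if spec.pka is not None:
        ph_df = gen_ph_series(spec, seed=seed + 1)
        ph_df.to_csv(out / f"{spec.name}_ph_series.csv", index=False)
        pka = fit_4pl_ph(ph_df["pH"], ph_df["kon_per_M_s"])
        res["pka"] = {"pKa": pka.params["pKa"],
                      "hill": pka.params["hill"],
                      "r_squared": pka.rsquared,
                      "reliable": pka.reliable}

    ts_path = cfg.inputs.get("temperature_series", {}).get(spec.name) \
        if isinstance(cfg.inputs.get("temperature_series"), dict) else None
    tdf = io_mod.read_temperature_series_csv(ts_path) if ts_path \
        else gen_temperature_series(spec, seed=seed + 2)
    io_mod.write_temperature_series_csv(
        out / f"{spec.name}_temperature_series.csv", tdf)
    vh = vant_hoff_fit(tdf["T_K"], tdf["KA_per_M"], dcp=spec.dcp, t0=cfg.t0)
    res["vant_hoff"] = {"dH0_kcal": vh.params["dH0"],
                        "dG0_kcal": vh.ground.dG,
                        "minus_TdS0_kcal": vh.ground.minus_TdS,
                        "KD_implied_M": vh.KD_implied,
                        "r_squared": vh.rsquared}

    ey_on = eyring_fit(tdf["T_K"], tdf["kon_per_M_s"], t0=cfg.t0)
    ey_off = eyring_fit(tdf["T_K"], tdf["koff_per_s"], t0=cfg.t0)
    res["eyring"] = {
        "assoc": {"dH_ts_kcal": ey_on.ts.dH,
                  "minus_TdS_ts_kcal": ey_on.ts.minus_TdS,
                  "dG_ts_kcal": ey_on.ts.dG},
        "dissoc": {"dH_ts_kcal": ey_off.ts.dH,
                   "minus_TdS_ts_kcal": ey_off.ts.minus_TdS,
                   "dG_ts_kcal": ey_off.ts.dG},
    }
    pathway = assemble_pathway(vh.ground, ey_on.ts)
    res["pathway"] = pathway.components()
    pd.DataFrame(pathway.components()).T.to_csv(
        out / f"{spec.name}_pathway.csv",
        index_label="state")
    return res


def _protein_stages(cfg: AnalysisConfig, out: Path, seed: int) -> dict:
    res: dict = {}
    base = scenario(cfg.scenarios[0])

    log.info("fitting three-state unfolding")
    curve = gen_denaturation_curve(base, seed=seed + 10)
    io_mod.write_denaturation_csv(out / "denaturation.csv", curve)
    unf = fit_three_state(curve, T=cfg.unfold_temperature)
    res["unfolding"] = {"Cm1_M": unf.params["Cm1"],
                        "Cm2_M": unf.params["Cm2"],
                        "dG_ni_kcal": unf.params["dG_ni"],
                        "dG_iu_kcal": unf.params["dG_iu"],
                        "r_squared": unf.rsquared}

    log.info("classifying CSPs")
    res["csp"] = {}
    for name in cfg.scenarios:
        spec = scenario(name)
        peaks = gen_peaklists(spec, seed=seed + 20)
        csp = classify_csp(peaks["apo"], peaks["bound"],
                           threshold=cfg.csp_threshold)
        csp.table.to_csv(out / f"{name}_csp.csv", index=False)
        res["csp"][name] = {
            "n_significant": len(csp.significant),
            "significant_residues": [int(r) for r in csp.significant],
        }

    log.info("building HDX difference maps")
    res["hdx"] = {}
    data = gen_hdx_map(base, seed=seed + 30,
                       states=("apo",) + tuple(cfg.scenarios))
    io_mod.write_hdx_csv(out / "hdx_uptake.csv", data.table)
    averaged = hdx_mod.average_replicates(data.table)
    stats = hdx_mod.map_statistics(data.peptides, data.sequence)
    res["hdx"]["coverage"] = stats["coverage"]
    res["hdx"]["redundancy"] = stats["redundancy"]
    apo = averaged[averaged["state"] == "apo"]
    for name in cfg.scenarios:
        bound = averaged[averaged["state"] == name]
        diff = hdx_mod.difference_map(bound, apo,
                                      threshold_da=cfg.hdx_threshold_da)
        diff.per_peptide.to_csv(out / f"{name}_hdx_diff.csv", index=False)
        diff.per_residue.to_csv(out / f"{name}_hdx_residue.csv",
                                index=False)
        res["hdx"][name] = {
            "n_peptides": int(len(diff.per_peptide)),
            "n_significant": int(diff.per_peptide["significant"].sum()),
        }
    return res


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run every stage and return (and write) the summary dict."""
    if not config.scenarios:
        raise ValueError("no scenarios configured")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "scenarios": {}}
    for i, name in enumerate(config.scenarios):
        spec = scenario(name)
        try:
            summary["scenarios"][name] = _ligand_stage(
                spec, config, out, seed=config.seed + 100 * i)
        except Exception as exc:
            raise RuntimeError(
                f"ligand stage failed for scenario {name!r}: {exc}") from exc

    if len(config.scenarios) >= 2:
        a = summary["scenarios"][config.scenarios[0]]
        b = summary["scenarios"][config.scenarios[1]]
        ka, kb = a["kinetics"], b["kinetics"]
        ratio = kb["kon_per_M_s"] / ka["kon_per_M_s"]
        summary["comparison"] = {
            "kon_fold": ratio,
            "koff_fold": kb["koff_per_s"] / ka["koff_per_s"],
            "KD_fold": kb["KD_M"] / ka["KD_M"],
            "ddG_ts_from_rates_kcal": barrier_from_rate_ratio(
                max(kb["kon_per_M_s"], ka["kon_per_M_s"]),
                min(kb["kon_per_M_s"], ka["kon_per_M_s"]), T=config.t0),
            "ddG_ts_from_eyring_kcal": (
                a["eyring"]["assoc"]["dG_ts_kcal"]
                - b["eyring"]["assoc"]["dG_ts_kcal"]),
        }

    try:
        summary.update(_protein_stages(config, out, seed=config.seed))
    except Exception as exc:
        raise RuntimeError(f"protein stage failed: {exc}") from exc

    summary = _plain(summary)
    with open(out / "summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=False)
    log.info("pipeline complete; summary written to %s",
             out / "summary.yaml")
    return summary


def _plain(obj):
    """Recursively convert numpy scalars for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
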