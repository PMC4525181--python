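"""Readers and writers for the package's plain-text interchange formats.

All tables are comma-separated UTF-8 with a mandatory header row and
'.' decimals; column names carry explicit units.  Dialects:

* sensorgram CSV — time_s, response_RU, phase (assoc|dissoc), conc_M,
  optional cycle_id (one trace per cycle);
* rate-table CSV — ligand, condition, kon_per_M_s, se_kon, koff_per_s,
  se_koff;
* temperature-series CSV — T_K, KA_per_M [, kon_per_M_s, koff_per_s];
* denaturation CSV — gdmcl_M, ellipticity;
* peak-list CSV — residue, aa, state, dH_ppm, dN_ppm;
* relaxation CSV — residue, field_MHz, R2_s;
* HDX uptake CSV — start, end, sequence, state, time_s, replicate,
  centroid_Da (a DynamX-like flat export);
* protein sequences — FASTA (Biopython);
* schedules and configuration — YAML.

Every writer's output round-trips losslessly through its reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .kinetics import InjectionSchedule, Phase, Sensorgram
from .unfolding import DenaturationCurve

__all__ = [
    "read_sensorgram_csv", "write_sensorgram_csv",
    "read_temperature_series_csv", "write_temperature_series_csv",
    "read_denaturation_csv", "write_denaturation_csv",
    "read_peaklist_csv", "write_peaklist_csv",
    "read_relaxation_csv", "write_relaxation_csv",
    "read_hdx_csv", "write_hdx_csv",
    "read_fasta", "read_schedule_yaml", "write_schedule_yaml",
    "read_rate_table_csv", "write_rate_table_csv",
]

_PHASE_NAMES = {"assoc": "association", "dissoc": "dissociation"}
_PHASE_CODES = {v: k for k, v in _PHASE_NAMES.items()}


def _schedule_from_frame(df: pd.DataFrame) -> InjectionSchedule:
    """Reconstruct the phase layout from per-sample phase/conc labels."""
    time = df["time_s"].to_numpy(dtype=float)
    phase = df["phase"].to_numpy()
    conc = df["conc_M"].to_numpy(dtype=float)
    boundaries = [0]
    for i in range(1, len(df)):
        if phase[i] != phase[i - 1] or conc[i] != conc[i - 1]:
            boundaries.append(i)
    phases = []
    for j, b in enumerate(boundaries):
        t_start = time[b]
        if j + 1 < len(boundaries):
            t_end = time[boundaries[j + 1]]
        else:
            dt = time[-1] - time[-2] if len(time) > 1 else 1.0
            t_end = time[-1] + dt
        phases.append(Phase(_PHASE_NAMES[phase[b]], float(t_start),
                            float(t_end - t_start), float(conc[b])))
    return InjectionSchedule(tuple(phases))


def read_sensorgram_csv(path) -> list[Sensorgram]:
    """Read one or more sensorgrams; the optional cycle_id column
    splits the file into traces."""
    df = pd.read_csv(path)
    required = {"time_s", "response_RU", "phase", "conc_M"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sensorgram CSV missing columns {sorted(missing)}")
    groups = df.groupby("cycle_id") if "cycle_id" in df.columns \
        else [(0, df)]
    out = []
    for _, sub in groups:
        sub = sub.sort_values("time_s")
        out.append(Sensorgram(
            time=sub["time_s"].to_numpy(dtype=float),
            response=sub["response_RU"].to_numpy(dtype=float),
            schedule=_schedule_from_frame(sub)))
    return out


def write_sensorgram_csv(path, sensorgrams) -> None:
    if isinstance(sensorgrams, Sensorgram):
        sensorgrams = [sensorgrams]
    frames = []
    for cycle, sg in enumerate(sensorgrams):
        phase_code = np.empty(sg.time.size, dtype=object)
        conc = np.zeros(sg.time.size)
        for p in sg.schedule.phases:
            last = p is sg.schedule.phases[-1]
            mask = (sg.time >= p.start) & (
                (sg.time <= p.end) if last else (sg.time < p.end))
            phase_code[mask] = _PHASE_CODES[p.kind]
            conc[mask] = p.concentration
        frames.append(pd.DataFrame({
            "time_s": sg.time, "response_RU": sg.response,
            "phase": phase_code, "conc_M": conc, "cycle_id": cycle}))
    pd.concat(frames).to_csv(path, index=False)


def read_temperature_series_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "T_K" not in df.columns:
        raise ValueError("temperature-series CSV needs a T_K column")
    return df


def write_temperature_series_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_denaturation_csv(path) -> DenaturationCurve:
    df = pd.read_csv(path)
    return DenaturationCurve(denaturant=df["gdmcl_M"].to_numpy(float),
                             signal=df["ellipticity"].to_numpy(float))


def write_denaturation_csv(path, curve: DenaturationCurve) -> None:
    pd.DataFrame({"gdmcl_M": curve.denaturant,
                  "ellipticity": curve.signal}).to_csv(path, index=False)


def read_peaklist_csv(path) -> pd.DataFrame:
    """Peak list with columns residue, aa, state, dH_ppm, dN_ppm;
    returned with the in-memory names dH/dN."""
    df = pd.read_csv(path)
    return df.rename(columns={"dH_ppm": "dH", "dN_ppm": "dN"})


def write_peaklist_csv(path, df: pd.DataFrame, state: str | None = None
                       ) -> None:
    out = df.rename(columns={"dH": "dH_ppm", "dN": "dN_ppm"}).copy()
    if state is not None:
        out["state"] = state
    out.to_csv(path, index=False)


def read_relaxation_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"residue", "field_MHz", "R2_s"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"relaxation CSV missing columns {sorted(missing)}")
    return df


def write_relaxation_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_hdx_csv(path) -> pd.DataFrame:
    from .hdx import UPTAKE_COLUMNS

    df = pd.read_csv(path)
    missing = set(UPTAKE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"HDX CSV missing columns {sorted(missing)}")
    return df


def write_hdx_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_rate_table_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_rate_table_csv(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_fasta(path) -> dict[str, str]:
    """FASTA file -> {record id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_schedule_yaml(path) -> InjectionSchedule:
    """Schedule YAML: a list of phase mappings with keys kind, start_s,
    duration_s, conc_M."""
    data = yaml.safe_load(Path(path).read_text())
    phases = tuple(Phase(p["kind"], float(p["start_s"]),
                         float(p["duration_s"]), float(p.get("conc_M", 0.0)))
                   for p in data["phases"])
    return InjectionSchedule(phases)


def write_schedule_yaml(path, schedule: InjectionSchedule) -> None:
    data = {"phases": [
        {"kind": p.kind, "start_s": p.start, "duration_s": p.duration,
         "conc_M": p.concentration} for p in schedule.phases]}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
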