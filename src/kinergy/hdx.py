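"""HDX-MS per-residue aggregation and state-difference maps.

Peptide-level deuterium uptake is the centroid-mass shift relative to
the undeuterated (t = 0) reference; dividing by the number of
exchangeable amides ``q`` gives the fractional uptake.  The per-residue
deuteration level is the unweighted mean of the fractional uptakes of
every peptide whose exchangeable amides cover that residue — no
sub-peptide localisation is attempted, and uncovered residues are
reported as missing, never as zero.

Exchangeable-amide convention (configurable through
:func:`exchangeable_amides`): a peptide's N-terminal amide is excluded
(it back-exchanges too fast to retain label) and prolines beyond the
first position carry no amide proton, so

    q = len(sequence) - 1 - (# Pro at positions 2..end).

State-difference maps compare two liganded states per peptide and per
labelling time point; a peptide is significant when |dD(t)| exceeds
0.4 Da at any single time point (the summed dD across time points is
also reported).  No back-exchange correction is applied: uptake values
are relative deuterium levels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "exchangeable_amides",
    "Peptide",
    "peptide_fractional_uptake",
    "average_replicates",
    "fractional_uptake_table",
    "residue_mean_deuteration",
    "DifferenceMap",
    "difference_map",
    "map_statistics",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: default single-time-point significance threshold, Da
DEFAULT_THRESHOLD_DA = 0.4

#: columns of the flat uptake-table dialect (DynamX-like export)
UPTAKE_COLUMNS = ("start", "end", "sequence", "state", "time_s",
                  "replicate", "centroid_Da")


def exchangeable_amides(sequence: str,
                        exclude_nterm: bool = True) -> int:
    """Number of exchangeable backbone amides ``q`` of a peptide.

    The N-terminal residue is excluded by default (set
    ``exclude_nterm=False`` to count it, e.g. for a fragment that
    retains the intact protein N terminus), and prolines after position
    1 never count.
    """
    if not sequence:
        raise ValueError("empty sequence")
    bad = set(sequence.upper()) - AMINO_ACIDS
    if bad:
        raise ValueError(f"non-amino-acid characters: {sorted(bad)}")
    seq = sequence.upper()
    q = len(seq) - seq[1:].count("P")
    if exclude_nterm:
        q -= 1
    if q <= 0:
        raise ValueError(f"peptide {sequence!r} has no exchangeable amides")
    return q


@dataclass(frozen=True)
class Peptide:
    """A peptic peptide located on the protein sequence (1-based,
    inclusive coordinates)."""

    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if self.end < self.start:
            raise ValueError("end must be >= start")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValueError(
                f"sequence length {len(self.sequence)} does not match "
                f"span {self.start}-{self.end}")
        # validates the alphabet and that q > 0
        exchangeable_amides(self.sequence)

    @property
    def q(self) -> int:
        return exchangeable_amides(self.sequence)

    def exchangeable_residues(self) -> tuple[int, ...]:
        """Absolute indices of residues whose amide this peptide reports
        on (positions 2..end, prolines excluded)."""
        seq = self.sequence.upper()
        return tuple(self.start + i for i in range(1, len(seq))
                     if seq[i] != "P")


def peptide_fractional_uptake(centroid_t: float, centroid_0: float,
                              q: int, negative_tolerance: float = 0.2):
    """Fractional uptake (centroid_t - centroid_0) / q, dimensionless.

    Small negative shifts (within ``negative_tolerance`` Da, expected
    from centroid noise) pass through; larger ones raise.
    """
    if q <= 0:
        raise ValueError("q must be positive")
    shift = centroid_t - centroid_0
    if shift < -negative_tolerance:
        raise ValueError(
            f"deuterium uptake {shift:.3f} Da below -{negative_tolerance} "
            "Da tolerance; check the undeuterated reference")
    return shift / q


def _validate_table(df: pd.DataFrame, need_replicate: bool = True):
    cols = set(UPTAKE_COLUMNS) if need_replicate \
        else set(UPTAKE_COLUMNS) - {"replicate"}
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"uptake table missing columns: {sorted(missing)}")


def average_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Mean centroid (and SD) over replicates for each
    (peptide, state, time) cell."""
    _validate_table(df)
    keys = ["start", "end", "sequence", "state", "time_s"]
    out = (df.groupby(keys, as_index=False)
             .agg(centroid_Da=("centroid_Da", "mean"),
                  centroid_sd_Da=("centroid_Da", "std"),
                  n_replicates=("centroid_Da", "size")))
    out["centroid_sd_Da"] = out["centroid_sd_Da"].fillna(0.0)
    return out


def fractional_uptake_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide fractional uptake at every labelling time > 0.

    ``df`` is a replicate-averaged table (see
    :func:`average_replicates`); each (peptide, state) must include a
    t = 0 undeuterated reference row.
    """
    _validate_table(df, need_replicate=False)
    keys = ["start", "end", "sequence", "state"]
    ref = df[df["time_s"] == 0].set_index(keys)["centroid_Da"]
    rows = []
    for key, sub in df[df["time_s"] > 0].groupby(keys):
        if key not in ref.index:
            raise ValueError(f"no undeuterated (t=0) reference for {key}")
        c0 = float(ref.loc[key])
        q = exchangeable_amides(key[2])
        for _, r in sub.iterrows():
            rows.append({
                "start": key[0], "end": key[1], "sequence": key[2],
                "state": key[3], "time_s": r["time_s"], "q": q,
                "uptake_Da": r["centroid_Da"] - c0,
                "frac_uptake": peptide_fractional_uptake(
                    r["centroid_Da"], c0, q),
            })
    return pd.DataFrame(rows)


def residue_mean_deuteration(uptake: pd.DataFrame,
                             n_residues: int | None = None) -> pd.DataFrame:
    """Aggregate peptide fractional uptakes to per-residue means.

    ``uptake`` needs columns start, end, sequence, frac_uptake (one row
    per peptide, i.e. already averaged over times or at one time).
    Returns a frame with one row per *covered* residue: residue,
    mean_frac_uptake, n_peptides.  Residues absent from the frame are
    uncovered (missing, not zero).
    """
    for col in ("start", "end", "sequence", "frac_uptake"):
        if col not in uptake.columns:
            raise ValueError(f"uptake table missing column {col!r}")
    # duplicate rows for the same peptide species are repeat measurements:
    # average them so n_peptides counts distinct overlapping peptides
    uptake = (uptake.groupby(["start", "end", "sequence"], as_index=False)
              ["frac_uptake"].mean())
    acc: dict[int, list[float]] = {}
    for _, r in uptake.iterrows():
        pep = Peptide(int(r["start"]), int(r["end"]), r["sequence"])
        if n_residues is not None and pep.end > n_residues:
            raise ValueError(f"peptide {pep.start}-{pep.end} outside the "
                             f"{n_residues}-residue sequence")
        for res in pep.exchangeable_residues():
            acc.setdefault(res, []).append(float(r["frac_uptake"]))
    rows = [{"residue": res, "mean_frac_uptake": float(np.mean(v)),
             "n_peptides": len(v)}
            for res, v in sorted(acc.items())]
    return pd.DataFrame(rows, columns=["residue", "mean_frac_uptake",
                                       "n_peptides"])


@dataclass
class DifferenceMap:
    """State-difference map between two liganded states."""

    per_time: pd.DataFrame      # peptide x time: delta_Da
    per_peptide: pd.DataFrame   # summed delta_Da + significance flag
    per_residue: pd.DataFrame   # projected mean delta fractional uptake
    threshold_da: float
    times: tuple

    def significant_peptides(self) -> pd.DataFrame:
        return self.per_peptide[self.per_peptide["significant"]]

    def summary(self) -> str:
        n_sig = int(self.per_peptide["significant"].sum())
        return (f"Difference map over {len(self.times)} time points: "
                f"{len(self.per_peptide)} peptides, {n_sig} significant "
                f"(|dD| > {self.threshold_da} Da at any time point)")


def difference_map(state_a: pd.DataFrame, state_b: pd.DataFrame,
                   threshold_da: float = DEFAULT_THRESHOLD_DA
                   ) -> DifferenceMap:
    """Per-peptide deuteration difference (state_a - state_b).

    Both inputs are replicate-averaged uptake tables for a single state
    each (columns start, end, sequence, time_s, centroid_Da); their
    peptide sets and time grids must match.  A positive difference
    means state_a is more deuterated (deprotected) than state_b.
    """
    keys = ["start", "end", "sequence", "time_s"]
    a = state_a[state_a["time_s"] > 0]
    b = state_b[state_b["time_s"] > 0]
    ta = set(map(tuple, a[keys].itertuples(index=False)))
    tb = set(map(tuple, b[keys].itertuples(index=False)))
    if ta != tb:
        raise ValueError("peptide sets / time grids differ between states")
    merged = a.merge(b, on=keys, suffixes=("_a", "_b"))
    merged["delta_Da"] = merged["centroid_Da_a"] - merged["centroid_Da_b"]
    per_time = merged[keys + ["delta_Da"]].sort_values(keys).reset_index(
        drop=True)
    grp = per_time.groupby(["start", "end", "sequence"])
    per_peptide = grp["delta_Da"].agg(
        sum_delta_Da="sum",
        max_abs_delta_Da=lambda s: float(np.max(np.abs(s)))).reset_index()
    per_peptide["significant"] = \
        per_peptide["max_abs_delta_Da"] > threshold_da
    times = tuple(sorted(per_time["time_s"].unique()))
    # per-residue projection: summed difference as a fraction of q
    proj = per_peptide.copy()
    proj["frac_uptake"] = [
        r["sum_delta_Da"] / exchangeable_amides(r["sequence"]) / len(times)
        for _, r in proj.iterrows()]
    per_residue = residue_mean_deuteration(proj).rename(
        columns={"mean_frac_uptake": "mean_delta_frac"})
    return DifferenceMap(per_time=per_time, per_peptide=per_peptide,
                         per_residue=per_residue, threshold_da=threshold_da,
                         times=times)


def map_statistics(peptides, sequence: str) -> dict:
    """Coverage fraction and mean redundancy of a peptide map.

    Coverage counts every residue inside any peptide span; redundancy
    is the mean number of peptides covering each covered residue.  An
    empty map returns coverage 0 and redundancy 0 with ``empty=True``.
    """
    n = len(sequence)
    if n == 0:
        raise ValueError("empty protein sequence")
    peptides = list(peptides)
    if not peptides:
        return {"coverage": 0.0, "redundancy": 0.0, "n_peptides": 0,
                "empty": True}
    counts = np.zeros(n + 1, dtype=int)   # 1-based
    for pep in peptides:
        if not isinstance(pep, Peptide):
            pep = Peptide(*pep)
        if pep.start < 1 or pep.end > n:
            raise ValueError(f"peptide {pep.start}-{pep.end} outside the "
                             f"{n}-residue sequence")
        counts[pep.start:pep.end + 1] += 1
    covered = counts[1:] > 0
    return {
        "coverage": float(covered.mean()),
        "redundancy": float(counts[1:][covered].mean()),
        "n_peptides": len(peptides),
        "empty": False,
    }
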