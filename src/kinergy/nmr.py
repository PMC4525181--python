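"""Backbone-amide NMR observables: chemical-shift perturbation (CSP)
mapping and field-dependent exchange-broadening screening.

The weighted CSP combines amide 1H and 15N shift changes as

    dd_ave = sqrt(dd(N)**2 / 50 + dd(H)**2 / 2)     (ppm)

and residues with dd_ave above a threshold (0.25 ppm by default) are
classified as significantly perturbed.  Residues observable in only one
state (e.g. exchange-broadened activation-loop amides) are reported as
explicit absences, never as zero perturbations — differential
observability is itself a result.

The exchange contribution to 15N transverse relaxation is screened with
the fast-exchange quadratic field dependence

    R2(B) = R2_0 + Phi * B**2,

with B the 15N Larmor frequency implied by the spectrometer's 1H MHz
label.  Outputs are exchange contributions under this fast-exchange
model; Phi is clipped at zero (with a flag) since a negative exchange
term is unphysical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import GAMMA_RATIO_15N_1H

__all__ = [
    "weighted_csp",
    "CSPResult",
    "classify_csp",
    "R2ExResult",
    "r2ex_screen",
]


def weighted_csp(dn_apo, dn_bound, dh_apo, dh_bound):
    """Weighted average CSP in ppm.

    Accepts scalars or arrays; symmetric in (apo, bound) and invariant
    to any global referencing offset applied to both states.
    """
    ddn = np.asarray(dn_bound, dtype=float) - np.asarray(dn_apo, dtype=float)
    ddh = np.asarray(dh_bound, dtype=float) - np.asarray(dh_apo, dtype=float)
    if not (np.all(np.isfinite(ddn)) and np.all(np.isfinite(ddh))):
        raise ValueError("chemical shifts must be finite")
    return np.sqrt(ddn**2 / 50.0 + ddh**2 / 2.0)


@dataclass
class CSPResult:
    """Outcome of a per-residue CSP classification."""

    table: pd.DataFrame          # residue, d_dH, d_dN, csp, significant
    significant: tuple           # residues with csp > threshold
    apo_only: tuple              # observable only in the apo state
    bound_only: tuple            # observable only in the bound state
    threshold: float

    def summary(self) -> str:
        lines = [
            "CSP classification",
            f"threshold: {self.threshold} ppm",
            f"matched residues:   {len(self.table)}",
            f"significant (> {self.threshold}): {len(self.significant)}",
            f"apo-only residues:   {len(self.apo_only)}",
            f"bound-only residues: {len(self.bound_only)}",
        ]
        return "\n".join(lines)


def _peak_frame(peaks) -> pd.DataFrame:
    df = pd.DataFrame(peaks) if not isinstance(peaks, pd.DataFrame) \
        else peaks.copy()
    required = {"residue", "dH", "dN"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"peak list missing columns: {sorted(missing)}")
    if df["residue"].duplicated().any():
        dupes = df.loc[df["residue"].duplicated(), "residue"].tolist()
        raise ValueError(f"duplicate residue entries: {dupes}")
    return df


def classify_csp(apo, bound, threshold: float = 0.25) -> CSPResult:
    """Match apo/bound peak lists by residue and flag residues whose
    weighted CSP exceeds ``threshold`` (ppm).

    ``apo`` and ``bound`` are DataFrames (or records) with columns
    ``residue``, ``dH``, ``dN``.  Unmatched residues are returned in
    ``apo_only`` / ``bound_only``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    apo = _peak_frame(apo)
    bound = _peak_frame(bound)
    merged = apo.merge(bound, on="residue", suffixes=("_apo", "_bound"))
    csp = weighted_csp(merged["dN_apo"], merged["dN_bound"],
                       merged["dH_apo"], merged["dH_bound"])
    table = pd.DataFrame({
        "residue": merged["residue"],
        "d_dH_ppm": merged["dH_bound"] - merged["dH_apo"],
        "d_dN_ppm": merged["dN_bound"] - merged["dN_apo"],
        "csp_ppm": csp,
        "significant": csp > threshold,
    }).sort_values("residue").reset_index(drop=True)
    apo_only = tuple(sorted(set(apo["residue"]) - set(bound["residue"])))
    bound_only = tuple(sorted(set(bound["residue"]) - set(apo["residue"])))
    significant = tuple(table.loc[table["significant"], "residue"])
    return CSPResult(table=table, significant=significant,
                     apo_only=apo_only, bound_only=bound_only,
                     threshold=threshold)


@dataclass
class R2ExResult:
    """Fast-exchange screen for one residue across static fields."""

    r2_0: float                  # field-independent rate, s-1
    phi: float                   # quadratic coefficient, s-1 / (rad MHz)^2
    r2ex_at_field: dict          # 1H-MHz label -> exchange contribution, s-1
    clipped: bool = False        # True when a negative Phi was clipped to 0

    def summary(self) -> str:
        lines = ["Exchange contribution (fast-exchange model)",
                 f"R2,0 = {self.r2_0:.3f} s-1"]
        for field, val in self.r2ex_at_field.items():
            lines.append(f"R2,ex at {field:g} MHz = {val:.3f} s-1")
        if self.clipped:
            lines.append("[warning] negative Phi clipped to 0")
        return "\n".join(lines)


def r2ex_screen(fields_mhz, r2) -> R2ExResult:
    """Fit R2(B) = R2_0 + Phi*B^2 across >= 2 static fields.

    ``fields_mhz`` are the spectrometer 1H frequency labels (e.g. 600,
    800, 950); the fit abscissa is the implied 15N frequency.  Only
    field *ratios* matter, so the gyromagnetic conversion constant does
    not affect the reported exchange contributions Phi*B^2.
    """
    fields = np.asarray(fields_mhz, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if fields.shape != r2.shape:
        raise ValueError("fields and R2 must have equal length")
    if np.unique(fields).size < 2:
        raise ValueError("need R2 at >= 2 distinct static fields")
    if np.any(r2 <= 0):
        raise ValueError("R2 rates must be positive")
    b = fields * GAMMA_RATIO_15N_1H
    design = np.column_stack([np.ones_like(b), b**2])
    (r2_0, phi), *_ = np.linalg.lstsq(design, r2, rcond=None)
    clipped = False
    if phi < 0:
        phi = 0.0
        r2_0 = float(np.mean(r2))
        clipped = True
    r2ex = {float(f): float(phi * (f * GAMMA_RATIO_15N_1H) ** 2)
            for f in np.unique(fields)}
    return R2ExResult(r2_0=float(r2_0), phi=float(phi),
                      r2ex_at_field=r2ex, clipped=clipped)
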