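# kinergy

Kinetic and thermodynamic dissection of conformational energetics in
protein–ligand binding.

Some protein kinases bind "type II" inhibitors only after a slow
rearrangement of the activation loop (the DFG flip), which leaves a
distinctive fingerprint across several biophysical measurements: slow
association in SPR, endothermic entropy-driven binding in van't Hoff
analysis, a high enthalpic barrier in Eyring analysis, a pH-titratable
on-rate reporting on the DFG aspartate, and redistributed flexibility
visible by NMR and HDX-MS. `kinergy` implements the full quantitative
analysis chain needed to assemble that picture, for biophysicists and
medicinal chemists characterising slow-binding inhibitors:

* **SPR kinetics** — simulation and global fitting of the 1:1
  (Langmuir) interaction model for multi-cycle and single-cycle
  (kinetic titration) experiments; KD = k_off/k_on, t½ = ln2/k_off,
  fold-changes; 4PL fitting of k_on(pH) for an effective pKa.
* **Thermodynamics** — integrated van't Hoff analysis
  ln K_A(T) = ln K_A0 + (ΔH₀/R)(1/T₀ − 1/T) + (ΔC_p/R)(T₀/T − 1 + ln T/T₀)
  with fixed ΔC_p; linear Eyring analysis
  ln(kh/k_B T) = −ΔH‡/RT + ΔS‡/R; ΔC_p regression from ITC ΔH(T);
  assembly of complete free → ‡ → bound reaction-pathway models.
* **Equilibrium unfolding** — three-state (N ⇌ I ⇌ U) chemical
  denaturation of CD data with linear baselines and log-space
  populations; midpoints C_m = ΔG/m.
* **NMR** — weighted amide CSPs, Δδ_ave = (Δδ²(N)/50 + Δδ²(H)/2)^½,
  classified at a 0.25 ppm threshold; fast-exchange screening of
  R₂(B) = R₂,₀ + Φ·B² across static fields.
* **HDX-MS** — per-residue mean deuteration from overlapping peptic
  peptides (mean of (m_t − m_0)/q over covering peptides), state
  difference maps with a 0.4 Da per-time-point significance rule, and
  coverage/redundancy statistics.
* **Synthetic data** — seeded generators that are exact forward models
  of every estimator above, so the whole chain is testable without
  instrument data.

Everything follows a Model/Results pattern: build a model from data,
call `fit()`, read estimates, standard errors and `summary()` from the
results object. Functional wrappers (`fit_1to1`, `vant_hoff_fit`, …)
and a CLI (`kinergy …`) cover the same operations.

## Worked example

Characterise a slow type II binder from a simulated single-cycle SPR
experiment, then build its thermodynamic reaction pathway:

```python
import pandas as pd
from kinergy import fit_1to1, vant_hoff_fit, eyring_fit, assemble_pathway
from kinergy.synthetic import scenario, gen_sensorgrams, gen_temperature_series

spec = scenario("ponatinib")          # kon 2.4e4 M-1 s-1, koff 1.9e-4 s-1
res = fit_1to1(gen_sensorgrams(spec, seed=42))
print(res.summary())
```

```
1:1 interaction model (global fit)
==================================
No. observations: 16630
R-squared:        0.9936
Converged:        True
--------------------------------------------
parameter               estimate     std err
kon                      24540.9       416.8
koff                 0.000189854   1.603e-07
rmax                     49.2087      0.5885
KD                   7.73624e-09          --
t_half                   3650.95          --
```

The global fit of the noisy five-injection titration recovers the
generating rates within ~2%: KD ≈ 7.7 nM and a complex half-life of
3651 s (≈61 min) — the slow-dissociation signature of the DFG-out
binding mode. Temperature-series analysis then resolves the energetics:

```python
df = gen_temperature_series(spec, seed=42)
vh = vant_hoff_fit(df["T_K"], df["KA_per_M"], dcp=spec.dcp)
ey = eyring_fit(df["T_K"], df["kon_per_M_s"])
print(pd.DataFrame(assemble_pathway(vh.ground, ey.ts).components()).T.round(2))
```

```
                      dH  minus_TdS     dG
ground              9.95     -20.84 -10.89
transition_assoc   22.45     -11.46  10.99
transition_dissoc  12.50       9.38  21.89
```

All energies are kcal·mol⁻¹ at 298 K. Binding is endothermic
(ΔH₀ ≈ +10) yet favourable (ΔG₀ ≈ −10.9) because it is entropy driven
(−TΔS₀ ≈ −21); the association barrier of ≈11 kcal·mol⁻¹ is enthalpic
(ΔH‡ ≈ 22) — the energetic cost of the conformational rearrangement —
and the dissociation barrier (≈21.9) is their difference from pathway
closure, matching the long residence time.

The same chain is available from the shell:

```bash
kinergy synth sensorgrams --scenario ponatinib --seed 42 -o data/
kinergy fit-kinetics data/ponatinib_sensorgrams.csv
kinergy run --seed 11 -o out/        # full multi-stage pipeline
```

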