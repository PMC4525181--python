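# Methods

This note records the models implemented in `kinergy`, their
assumptions, the conventions and defaults that matter, what the
synthetic generators do and do not emulate, and the numerical choices
behind the fits.

## Units and constants

All energies are handled in calorie units and reported in kcal·mol⁻¹,
the convention of the SPR/ITC literature: R = 1.986 cal·mol⁻¹·K⁻¹,
h = 6.63×10⁻³⁴ J·s, k_B = 1.38×10⁻²³ J·K⁻¹ (the SI constants appear
only inside the dimensionless Eyring ordinate). The thermodynamic
reference temperature T₀ defaults to 298 K; equilibrium unfolding uses
293 K (far-UV CD at 20 °C).

## 1:1 interaction model (SPR)

Association phases at analyte concentration C obey
dR/dt = k_on·C·(R_max − R) − k_off·R, solved in closed form per phase;
dissociation is R(t) = R₀·e^(−k_off·t). Phases chain exactly — each
inherits the previous phase's final response — which makes single-cycle
(kinetic titration) traces a single piecewise trajectory. Assumptions:
no mass-transport limitation, no bulk refractive-index jumps, traces
already blank-referenced. A zero-concentration "association" phase is
treated as a buffer blank.

Global fitting shares (k_on, k_off, R_max) across all phases and
traces, in log₁₀ parameters (positivity by construction) with
`scipy.optimize.least_squares` (Levenberg–Marquardt, relative
tolerances 1e-8, ≤10,000 evaluations). Initial guesses are data
driven and deterministic: k_off from a log-linear fit of the final
dissociation tail, k_on by solving the equilibrium-response relation
at the top injection, R_max at 1.5× the peak response. Three
deterministically perturbed restarts run if the first attempt fails;
flat traces raise a degenerate-data error rather than fitting noise.
Standard errors come from the Gauss–Newton covariance with the delta
method back to linear scale.

KD = k_off/k_on and t½ = ln2/k_off are derived properties of the
results object, so they are exactly consistent with the rates.

## pH dependence (4PL)

k(pH) = k_high + (k_low − k_high)/(1 + 10^(hill·(pH − pKa))), a
base-10 logistic with free Hill slope; the inflection is reported as
the effective pKa of the titrating group. A ≥5-point titration
spanning the inflection is required; flat series return a fit with an
explicit "unreliable pKa" flag instead of failing. R² is reported on
the rate scale.

## van't Hoff analysis

ln K_A(T) = ln K_A0 + (ΔH₀/R)(1/T₀ − 1/T) + (ΔC_p/R)(T₀/T − 1 + ln(T/T₀))

with a *fixed*, temperature-independent ΔC_p (a constrained input,
never co-fitted; with ΔC_p = 0 this is the classical straight line in
1/T). Because ΔC_p is fixed the problem is linear in (ln K_A0, ΔH₀)
and is solved exactly by ordinary least squares — the same optimum an
iterative optimiser would find, but deterministic and with analytic
standard errors. Outputs: ΔH₀, ΔG₀ = −RT₀ ln K_A0, −T₀ΔS₀ = ΔG₀ − ΔH₀,
and the implied dissociation constant exp(ΔG₀/RT₀) for cross-checks
against kinetic KD values.

## Eyring analysis

ln(k·h/(k_B·T)) regressed on 1/T: slope = −ΔH‡/R, intercept = ΔS‡/R;
ΔG‡(T₀) = ΔH‡ − T₀ΔS‡. The transmission coefficient is fixed at 1.
Applied to k_on (M⁻¹·s⁻¹) the 1 M standard state makes the logarithm's
argument dimensionless; only differences of barriers are interpreted,
so the standard-state offset cancels where it matters. ΔC_p‡ (curved
Eyring) is out of scope.

## Reaction pathways

A pathway is (ground, ‡_assoc, ‡_dissoc) with the dissociation barrier
computed component-wise as ‡_assoc − ground, so closure
(‡_assoc − ‡_dissoc = ground) holds for ΔG, ΔH and −TΔS by
construction. Each (ΔH, −TΔS, ΔG) triple must satisfy
ΔG = ΔH + (−TΔS) within 0.05 kcal·mol⁻¹ (rounding tolerance of
printed tables); pathway closure is checked at 0.1.

## Three-state equilibrium unfolding

K₁ = e^(−(ΔG_ni − m_ni[D])/RT), K₂ = e^(−(ΔG_iu − m_iu[D])/RT);
the observed signal is the population-weighted average of three linear
baselines (linear extrapolation method). Populations are computed as a
log-space softmax, so arbitrarily large free energies cannot overflow.
Midpoints are C_m1 = ΔG_ni/m_ni and C_m2 = ΔG_iu/m_iu.

The fit floats all nine signal/energy parameters by default;
`fix_m_i=True` pins the intermediate baseline slope at its initial
value. For noisy curves the constrained mode is the recommended
protocol: with a short intermediate plateau the floating slope is a
poorly determined nuisance parameter that roughly halves midpoint
precision without improving the fit (verified by comparing against
truth-initialised fits, which reach the same optimum). Initialisation
is deterministic: native/unfolded baselines from the first/last three
points, midpoint guesses from the extrema of the numerical derivative,
m-values started at 3 kcal·mol⁻¹·M⁻¹ (typical for a ~300-residue
domain). A fit whose intermediate never exceeds 5% population is
flagged as collinear.

## NMR observables

Weighted CSP: Δδ_ave = (Δδ²(N)/50 + Δδ²(H)/2)^½ ppm, symmetric in the
two states and invariant to global referencing offsets. Classification
uses a 0.25 ppm threshold by default; residues observable in only one
state are reported as explicit absences (differential observability of
activation-loop amides is itself a result), never as zero CSPs.

Exchange screening adopts the fast-exchange quadratic law
R₂(B) = R₂,₀ + Φ·B², with B the ¹⁵N Larmor frequency implied by the
spectrometer's ¹H MHz label (γ_N/γ_H ≈ 0.1014 — only field ratios
enter, so this constant is documented rather than critical). Φ is
clipped at zero with a flag, since a negative exchange contribution is
unphysical. Outputs are labelled exchange contributions *under the
fast-exchange model*; CPMG-style dispersion fitting is out of scope,
and the module starts from fitted R₂ values, not raw decay curves.

## HDX-MS aggregation

Exchangeable amides per peptide: q = length − 1 − (# Pro at positions
2..end); the N-terminal amide is excluded because it back-exchanges too
fast to retain label (configurable for fragments retaining the intact
protein N terminus). Fractional uptake is (m_t − m_0)/q with no
back-exchange correction — values are relative deuterium levels. The
per-residue level is the unweighted mean over all covering peptides,
assigned uniformly to every residue with an exchangeable amide in the
peptide (no sub-peptide localisation); duplicate entries for the same
peptide species are averaged first so the peptide count reflects
distinct peptides. Uncovered residues are missing, not zero.

Difference maps compare states per peptide and per labelling time; a
peptide is significant when |ΔD(t)| > 0.4 Da at any single time point
(the per-data-point reading of the threshold), and the summed ΔD
across the nine-point time grid is reported alongside so a
summed-value criterion can also be applied. Replicates (≥2 by default)
are mean-averaged with SDs carried.

## Synthetic data

Each generator is the exact forward model of its consumer, so
generate → fit at zero noise recovers truth to optimiser tolerance —
this round-trip property is what the test suite leans on. Two bundled
scenarios describe the study conditions: a slow entropy-driven type II
binder (k_on 2.4×10⁴ M⁻¹s⁻¹, k_off 1.9×10⁻⁴ s⁻¹, ΔH₀ +10.1,
ΔG₀ −10.9, ΔH‡ 22.2, −T₀ΔS‡ −11.2 kcal·mol⁻¹, pKa 6.25 with a
sevenfold k_on range over pH 5.5–7.4) and a fast enthalpy-driven
type I binder (1.6×10⁶, 9.2×10⁻³, ΔH₀ −11.5, ΔG₀ −11.1,
ΔC_p −359 cal·mol⁻¹·K⁻¹, ΔH‡ 16.6, −T₀ΔS‡ −7.9, pH independent); a
third weaker binder covers the ΔC_p −172 regime (its ΔG₀ is set to the
self-consistent −9.4 = −14.2 + 4.8). The type II scenario's ΔC_p is 0,
as no constrained value exists for it.

Defaults mirror the experimental designs: five sequential 120 s
injections (3-fold dilution from 20×KD) with 60 s gaps and a final
dissociation of 3/k_off clipped to 1,000–20,000 s; seven temperatures
in 281–308 K; eight pH points in 5.5–7.4; 31-point denaturation curves
over 0–4.5 M with transitions centred at 1.4 and 2.6 M so the
intermediate accumulates near 2 M; 300-residue peak lists with ten
planted perturbations above the CSP threshold; overlapping 8–18-mer
peptide maps tiling ~97% of a synthetic 310-residue sequence with nine
log-spaced labelling times from 10 s to 2 h and two replicates. Noise
levels: 0.5 RU additive (≈1% of R_max), 3% log-normal on K_A and
rates, 5% log-normal on k_on(pH), 0.2 ellipticity units, 0.004/0.03
ppm jitter on ¹H/¹⁵N, 0.02 Da on centroids — the order of magnitude of
the printed error bars. All generators draw from
`numpy.random.default_rng(seed)`; identical (spec, seed) gives
byte-identical output.

What the generators do *not* emulate: instrument drift, spikes and
carry-over; heterogeneous-ligand or mass-transport kinetics;
sequence-dependent intrinsic exchange rates (the HDX generator
specifies a per-residue protection profile directly, since the
pipeline never computes protection factors); EX1/bimodal exchange;
spectral processing artefacts. Passing tests therefore demonstrate
correctness of the estimators under the stated statistical models, not
robustness to instrument pathology. The HDX protein sequence is a
deterministic random sequence (a synthetic stand-in, ~5% proline), not
a real construct.

## Problem sizes

The test suite and the reproduction script run entirely at desk scale:
single-cycle traces of ~10³–10⁴ points, 7-temperature series,
Monte-Carlo ensembles of 50–200 replicates (chosen so medians are
stable to well under the tolerances they are compared at), 31-point
denaturation curves, 300-residue peak lists and ~50-peptide HDX maps.
Everything completes in seconds to a few minutes on one CPU.

## Known limitations

* The 1:1 fit assumes blank-referenced, single-analyte data; it will
  happily fit a mass-transport-limited trace with biased rates.
* Eyring and van't Hoff analyses assume temperature-independent ΔH‡
  and ΔC_p respectively over the 27 K window.
* The three-state fit's intermediate parameters are weakly identified
  when the intermediate plateau is short; use the constrained mode
  and inspect the collinearity flag.
* CSP classification uses a fixed global threshold, not a per-residue
  error model; the HDX significance rule likewise uses the fixed
  0.4 Da convention rather than replicate-derived confidence limits.
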