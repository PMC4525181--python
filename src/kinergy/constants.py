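"""Physical constants and unit conventions.

Energies are handled in calorie units throughout (R in cal mol-1 K-1,
results reported in kcal mol-1), which is the convention of the SPR /
ITC literature this package serves.  Planck and Boltzmann constants are
only ever used inside the dimensionless Eyring ordinate ln(k*h/(kB*T)),
so their SI units cancel.
"""

#: Gas constant, cal mol-1 K-1.
R_CAL = 1.986

#: Gas constant, kcal mol-1 K-1.
R_KCAL = 1.986e-3

#: Planck constant, J s.
H_PLANCK = 6.63e-34

#: Boltzmann constant, J K-1.
K_BOLTZMANN = 1.38e-23

#: Default thermodynamic reference temperature, K.
T0_DEFAULT = 298.0

#: |gamma(15N)| / |gamma(1H)| — converts a spectrometer's 1H frequency
#: label (e.g. "600 MHz") into the 15N Larmor frequency.  Only ratios of
#: fields enter the quadratic exchange-broadening fit, so the precision
#: of this constant is not critical.
GAMMA_RATIO_15N_1H = 0.10136767
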