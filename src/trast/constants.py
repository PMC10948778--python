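"""Physical constants and literature default parameters for tyrosine TRAST analysis.

All rates are in s⁻¹, cross sections in cm², lengths in nm unless noted.
"""

# CODATA, exact by SI definition
H_PLANCK = 6.62607015e-34  # J s
C_LIGHT = 2.99792458e8  # m/s

#: Tyrosine excitation cross section at 280 nm (cm²).
SIGMA_TYR_CM2 = 4.47e-18

#: Excited-singlet decay rate, 1/(3.4 ns) fluorescence lifetime of tyrosine.
K10_DEFAULT = 2.941e8

#: Triplet decay rate of tyrosine in air-saturated water (s⁻¹).
KT_DEFAULT = 5.75e6

#: Photo-oxidation rate with concomitant proton transfer (s⁻¹), free Tyr average.
KOX_TYR = 19.2e6

#: Radical reduction/recovery rate without added reductant (s⁻¹), free Tyr average.
KRED0_TYR = 3.7e3

#: Bimolecular quenching (reduction) constant of the tyrosine radical by
#: sodium ascorbate (M⁻¹ s⁻¹).
KQRED_NAAC = 5.8e7

#: Excitation wavelength (nm).
WAVELENGTH_DEFAULT_NM = 280.0

#: Lateral 1/e² excitation beam radius in the focal plane (nm).
BEAM_RADIUS_DEFAULT_NM = 400.0
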