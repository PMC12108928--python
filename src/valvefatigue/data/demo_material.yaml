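# Demo material card for glutaraldehyde-treated bovine pericardium leaflets.
#
# PLACEHOLDER CONSTANTS: the fitted fatigue/fracture parameters of the
# leaflet tissue are proprietary to the originating cyclic-test campaign and
# are not packaged here.  The values below are order-of-magnitude plausible
# for fixed pericardium and exist so the pipeline can be exercised end to
# end; absolute lives computed with them are demonstrations, not
# predictions.  Replace every value with calibrated data before use.
#
# Units: stresses MPa, lengths mm; paris_c in mm/(cycle*(MPa*sqrt(mm))^m).
# The Basquin pair (sigma_f, beta) must come from fully pulsatile (R = 0)
# tests: the Gerber correction maps every cycle onto that reference curve.
fatigue:
  su: 15.0            # nominal ultimate tensile strength, MPa
  sigma_f: 16.0       # single-cycle fatigue strength limit, MPa
  beta: -0.17         # fatigue life exponent (S-N slope), dimensionless
  e_modulus: 2.0      # elastic modulus, MPa
  hardening_exp: 0.15 # work hardening exponent, dimensionless
  strength_coeff: 20.0 # cyclic strength coefficient, MPa
  paris_c: 1.0e-6     # crack growth coefficient, mm/(cycle*(MPa*sqrt(mm))^m)
  paris_m: 3.0        # crack growth exponent, dimensionless
hyperelastic:
  mu0: 0.667          # initial shear modulus, MPa
  nu: 0.49            # Poisson's ratio
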