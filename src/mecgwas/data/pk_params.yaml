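# Named parameter sets for the three-compartment effect-site model.
# Units: v1 in litres, rate constants in 1/min.
#
# "shafer_fentanyl" is the commonly cited adult fentanyl parameterization of
# the Shafer three-compartment model as distributed with STANPUMP, with a
# first-order effect-site equilibration constant of 0.147/min.  These values
# are configuration, not ground truth: the engine accepts any parameter set,
# and simulation programs differ in how demographic inputs adjust them.
shafer_fentanyl:
  v1: 6.09
  k10: 0.0827
  k12: 0.4714
  k21: 0.2250
  k13: 0.1538
  k31: 0.0166
  ke0: 0.147

# One-compartment teaching configuration (k12 = k13 = 0 collapses the model).
one_compartment_demo:
  v1: 10.0
  k10: 0.1
  k12: 0.0
  k21: 0.05
  k13: 0.0
  k31: 0.01
  ke0: 0.5
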