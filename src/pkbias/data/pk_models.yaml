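# Named pharmacokinetic parameter sets.
#
# Each block defines a linear mammillary three-compartment model by its
# central volume and micro rate constants.  Volumes are litres (or L/kg via
# v1_per_kg, scaled by patient weight at load time); rate constants 1/min.
#
# shafer_fentanyl: the adult fentanyl population set of Shafer and
# colleagues, as used by the STANPUMP / TivaTrainer simulators (fixed
# central volume, not weight-scaled); transcribed from the published set.
shafer_fentanyl:
  v1: 6.09
  k10: 0.0827
  k12: 0.4710
  k21: 0.2250
  k13: 0.1610
  k31: 0.0077

# generic_3cpt: a documented synthetic three-compartment set with
# well-separated eigenvalues, used by the test-suite so it is
# self-contained; not a published population model.
generic_3cpt:
  v1: 10.0
  k10: 0.10
  k12: 0.30
  k21: 0.15
  k13: 0.05
  k31: 0.01

# generic_1cpt: one-compartment limit with a mono-exponential closed form.
generic_1cpt:
  v1: 10.0
  k10: 0.10
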