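# Per-water-model constants used by the summation correction and the
# continuum/profile analyses.
#   gamma_s: trace of the quadrupole moment relative to the van der
#            Waals interaction site, e nm^2
#   eps:     relative dielectric permittivity of the model
#   dipole:  molecular dipole moment, e nm
SPC:
  gamma_s: 0.0082
  eps: 66.6
  dipole: 0.0506
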