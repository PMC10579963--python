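# pKa values for ionizable groups (Bjellqvist set, as used for pI
# calculation in common proteomics tools). Edit to swap pKa conventions.
sidechain_acidic:   # deprotonation gives -1
  D: 4.05
  E: 4.45
  C: 9.0
  Y: 10.0
sidechain_basic:    # protonation gives +1
  K: 10.0
  R: 12.0
  H: 5.98
n_terminus: 7.5
c_terminus: 3.55
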