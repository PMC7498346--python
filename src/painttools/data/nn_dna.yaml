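# Unified nearest-neighbor parameters for DNA/DNA duplexes (SantaLucia 1998).
# Stacks are keyed by the 5'->3' top-strand dinucleotide over its Watson-Crick
# complement; dH in kcal/mol, dS in cal/(mol K). Override by passing a custom
# YAML path to load_thermo_params().
stacks:
  AA: {dH: -7.9,  dS: -22.2}
  AT: {dH: -7.2,  dS: -20.4}
  TA: {dH: -7.2,  dS: -21.3}
  CA: {dH: -8.5,  dS: -22.7}
  GT: {dH: -8.4,  dS: -22.4}
  CT: {dH: -7.8,  dS: -21.0}
  GA: {dH: -8.2,  dS: -22.2}
  CG: {dH: -10.6, dS: -27.2}
  GC: {dH: -9.8,  dS: -24.4}
  GG: {dH: -8.0,  dS: -19.9}
initiation:
  per_duplex:  {dH: 0.0, dS: 0.0}
  terminal_AT: {dH: 2.3, dS: 4.1}
  terminal_GC: {dH: 0.1, dS: -2.8}
  symmetry:    {dH: 0.0, dS: -1.4}
salt:
  # entropy correction dS += coeff * (N-1) * ln([Na+]/M); Mg handled by the
  # equivalent-sodium conversion Na_eq = Na + mg_coeff * sqrt(Mg) (concentrations in mM)
  entropy_coefficient: 0.368
  mg_equivalent_coefficient: 120.0
# Screening-grade per-LNA Tm increments (deg C per modified base, by base identity).
# Non-negative by construction: adding an LNA never lowers the approximate Tm.
lna_increments:
  A: 2.4
  C: 3.1
  G: 2.7
  T: 2.2
# Refined-mode stack perturbations for a stack whose 5' base is LNA-modified:
# ddH (kcal/mol) and ddS (cal/(mol K)) added to the unmodified stack values.
# These are screening-grade estimates shipped as configuration; positions whose
# stack key is absent fall back to the additive increment above.
lna_stacks:
  "A": {ddH: -1.0, ddS: -0.6}
  "C": {ddH: -1.6, ddS: -1.1}
  "G": {ddH: -1.4, ddS: -0.9}
  "T": {ddH: -0.9, ddS: -0.5}
# Flat hairpin-loop penalty (kcal/mol) added to the stem stack sum.
hairpin_loop_penalty: 3.0
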