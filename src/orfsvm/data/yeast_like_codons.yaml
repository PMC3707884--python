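codon_probs:
  AAA: 0.02906673
  AAC: 0.00862592
  AAG: 0.00862592
  AAT: 0.02906673
  ACA: 0.02344768
  ACC: 0.0069584
  ACG: 0.0069584
  ACT: 0.02344768
  AGA: 0.02344768
  AGC: 0.0069584
  AGG: 0.0069584
  AGT: 0.02344768
  ATA: 0.02906673
  ATC: 0.00862592
  ATG: 0.00862592
  ATT: 0.02906673
  CAA: 0.02344768
  CAC: 0.0069584
  CAG: 0.0069584
  CAT: 0.02344768
  CCA: 0.01891489
  CCC: 0.00561323
  CCG: 0.00561323
  CCT: 0.01891489
  CGA: 0.01891489
  CGC: 0.00561323
  CGG: 0.00561323
  CGT: 0.01891489
  CTA: 0.02344768
  CTC: 0.0069584
  CTG: 0.0069584
  CTT: 0.02344768
  GAA: 0.03165107
  GAC: 0.00939286
  GAG: 0.00939286
  GAT: 0.03165106
  GCA: 0.02553243
  GCC: 0.00757707
  GCG: 0.00757707
  GCT: 0.02553243
  GGA: 0.02553243
  GGC: 0.00757707
  GGG: 0.00757707
  GGT: 0.02553243
  GTA: 0.03165106
  GTC: 0.00939286
  GTG: 0.00939286
  GTT: 0.03165106
  TAC: 0.00862592
  TAT: 0.02906673
  TCA: 0.02344768
  TCC: 0.0069584
  TCG: 0.0069584
  TCT: 0.02344768
  TGC: 0.0069584
  TGG: 0.0069584
  TGT: 0.02344768
  TTA: 0.02906673
  TTC: 0.00862592
  TTG: 0.00862592
  TTT: 0.02906673
description: 'Illustrative moderately biased sense-codon usage at coding GC around
  0.40: third-position A/T preferred, G-leading codons boosted. Synthetic default
  values, not measured usage.'
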