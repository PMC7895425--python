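# Closed, versioned registry of protein domains, dimerizer ligands and
# constitutive promoters.  Adding a part is a config change, not a code change.
version: 1

domains:
  VP16: {category: activation-domain}
  VP64: {category: activation-domain}
  ZF1: {category: dna-binding}
  ZF2: {category: dna-binding}
  ZF3: {category: dna-binding}
  ZF4: {category: dna-binding}
  ZF5: {category: dna-binding}
  ZF6: {category: dna-binding}
  ZF7: {category: dna-binding}
  ZF8: {category: dna-binding}
  ZF9: {category: dna-binding}
  ZF10: {category: dna-binding}
  intN: {category: intein-N}
  intC: {category: intein-C}
  # Excised / fused intein pair left over after trans-splicing.  Internal
  # species only: it is catalytically spent and carries no regulatory role.
  intC/intN: {category: spent-intein}
  DsRed: {category: fluorophore-inhibitory}
  DsRed-Express2: {category: fluorophore-inhibitory}
  # DsRed-Express2 R95K: chromophore ablated, inhibition mechanism unchanged.
  DsDed: {category: fluorophore-inhibitory}
  FRB: {category: dimerizer-half, ligand_partner: FKBP}
  FKBP: {category: dimerizer-half, ligand_partner: FRB}
  PYL1: {category: dimerizer-half, ligand_partner: ABI1}
  ABI1: {category: dimerizer-half, ligand_partner: PYL1}
  PEST: {category: degron}
  mKate2: {category: reporter}
  EYFP: {category: reporter}
  EBFP2: {category: reporter}

# Ligand -> the unordered pair of dimerizer halves it bridges.
ligands:
  rapamycin: [FRB, FKBP]
  rapalog: [FRB, FKBP]
  ABA: [PYL1, ABI1]

# Constitutive promoters and their activity (transcription rate units per
# gene copy, same arbitrary scale as the COMET promoter transfer function).
constitutive_promoters:
  CMV: 30.0
  EF1a: 12.0
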