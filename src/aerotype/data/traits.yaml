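# Anaerobic / bioenergetic trait panel. Each trait lists its detector
# subunit profiles and the quorum of accepted subunits required to call the
# trait present (fewer accepted subunits, or ambiguous-only evidence, yields
# an ambiguous state). The anaerobic set feeds the strict-anaerobe override;
# aerobic_chain lists traits whose presence vetoes that override. Version 1.
version: 1
traits:
  FeFe_hydrogenase: {subunits: [HydA], quorum: 1}
  HydEFG: {subunits: [HydE, HydF, HydG], quorum: 2}
  ASCT: {subunits: [Asct], quorum: 1}
  malic_enzyme: {subunits: [MaeB], quorum: 1}
  fumarase: {subunits: [FumB], quorum: 1}
  complex_I: {subunits: [NuoB, NuoF], quorum: 2}
  complex_II: {subunits: [SdhA], quorum: 1}
  complex_III: {subunits: [PetB], quorum: 1}
  quinone_biosynthesis: {subunits: [UbiA], quorum: 1}
anaerobic: [FeFe_hydrogenase, HydEFG, ASCT, malic_enzyme, fumarase]
aerobic_chain: [complex_III]
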