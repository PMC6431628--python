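# Operon synteny-subtype signatures (binomial nomenclature: the oxidase
# type plays the role of a genus name, the synteny subtype that of a
# species name). Patterns are ordered role strings read in genome
# coordinate direction; reverse-strand operons are matched against the
# reversed pattern. 'required' roles must occur anywhere in the cluster,
# 'forbidden' roles must not. Entries marked comparative describe operon
# layouts from lineages outside alphaproteobacteria, shipped for context.
# Version 1.
version: 1
signatures:
  - {family: A1, subtype: a-III, pattern: [COX2, COX1, COX3, COX3]}
  - {family: A1, subtype: a, pattern: [COX2, COX1, COX3]}
  - {family: A1, subtype: b, pattern: [COX2, COX1, CtaB, CtaG]}
  # Magnetospirillum variant of subtype b: CtaB, normally inserted between
  # the COX1 and CtaG genes, is missing.
  - {family: A1, subtype: b-Magnetospirillum, pattern: [COX2, COX1, CtaG], forbidden: [CtaB]}
  # CyoCAB gene order (subunit III - II - I), rich in SCO genes.
  - {family: A2, subtype: CyoCAB, pattern: [COX3, COX2, COX1], required: [SCO]}
  # Gene cluster fused with the Alternative Complex III (Act).
  - {family: A2, subtype: a-I, pattern: [ActB, ActA, COX1, COX2], required: [SCO]}
  - {family: A2, subtype: delta, pattern: [COX1, COX2, SCO], comparative: true}
  - {family: A2, subtype: CyoBAC, pattern: [COX1, COX2, COX3], comparative: true}
  - {family: A2, subtype: chloroflexian, pattern: [COX2, COX3, COX1], comparative: true}
  # Putative B-family (ba3-a1) operon of Magnetospirilli: B-type subunit I
  # with at least one SCO gene; no fixed accessory order is assumed.
  - {family: B, subtype: ba3-a1, pattern: [COX1], required: [SCO]}
  - {family: bd_I, subtype: bd-I, pattern: [CydA, CydB]}
  - {family: Cio, subtype: Cio, pattern: [CydA, CydB]}
  - {family: C_cbb3, subtype: cbb3, pattern: [CcoN, CcoO, CcoP]}
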