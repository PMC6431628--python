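# Controlled vocabulary for terminal-oxidase families, oxygen-affinity tiers
# and reference Km annotations. Version 1. Consumed read-only by all modules.
version: 1

# Subfamily-level labels. counts_as_o2_reductase marks the labels that enter
# the oxygen-reductase repertoire of a genome; NOR reduces NO, not O2, and
# degenerate B sequences lack the catalytic tyrosine so their O2-reductase
# function is questioned.
subfamilies:
  A1:           {family: A,   counts_as_o2_reductase: true}
  A2:           {family: A,   counts_as_o2_reductase: true}
  B:            {family: B,   counts_as_o2_reductase: true}
  C_cbb3:       {family: C,   counts_as_o2_reductase: true}
  bd_I:         {family: bd,  counts_as_o2_reductase: true}
  Cio:          {family: bd,  counts_as_o2_reductase: true}
  AOX:          {family: AOX, counts_as_o2_reductase: true}
  NOR:          {family: NOR, counts_as_o2_reductase: false}
  B_degenerate: {family: B,   counts_as_o2_reductase: false}

# Oxygen-affinity tier per O2-reductase subfamily.
affinity_tiers:
  bd_I: high
  C_cbb3: high
  B: intermediate
  A1: low
  A2: low
  Cio: low
  AOX: low

# Curated Km-for-O2 annotations used in reports. 'value' in uM where a
# number is reported; qualitative entries carry only a note. A value of
# null with note 'not reported' is the explicit not-reported sentinel;
# no number is ever fabricated for those entries.
km_annotations:
  A1:     {value: 4.0, unit: uM, note: "example value, mitochondrial-type aa3; bo3 quinol oxidases span 3-7 uM"}
  A2:     {value: 0.62, unit: uM, note: "example value, Desulfovibrio"}
  B:      {value: null, unit: uM, note: "not reported"}
  C_cbb3: {value: null, unit: uM, note: "nanomolar range"}
  bd_I:   {value: null, unit: uM, note: "nanomolar range"}
  Cio:    {value: null, unit: uM, note: "not reported; low affinity"}
  AOX:    {value: null, unit: uM, note: "clearly above the Pasteur point (~2 uM)"}

# Aerobic-lifestyle categories. I: no oxidases; II: only high-affinity
# oxidases; III: mixed affinities; IV: only low-affinity oxidases.
categories: [I, II, III, IV]
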