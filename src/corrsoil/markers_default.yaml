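# Default corrinoid marker configuration (editable).
#
# The rule engine treats identifiers as opaque strings matched against each
# genome's detected annotations. The biosynthesis markers are the three
# corrin-ring steps with anaerobic/aerobic orthologue pairs (cbiC/cobH,
# cbiF/cobM, cbiL/cobI). The class II (corrinoid-dependent) RNR is detected
# via Pfam PF08471 because KO K00525 conflates class I and class II RNRs and
# must not appear among dependent markers.
#
# The dependent/independent identifier lists below cover the four paired
# functions with their conventional KEGG orthologues and are expected to be
# replaced or extended with the user's own annotation vocabulary (e.g. a
# curated cobamide-annotation catalogue) where it differs;
# "queH" is a gene-symbol placeholder for the corrinoid-independent
# epoxyqueuosine reductase.
biosynthesis_markers:
- K03394   # cbiL / cobI
- K05936   # cbiF / cobM
- K06042   # cbiC / cobH
dependent_markers:
  epoxyqueuosine_reductase:
  - K18979   # QueG
  methionine_synthase:
  - K00548   # MetH
  methylmalonyl_coa_mutase:
  - K01847
  - K01848
  - K01849
  ribonucleotide_reductase:
  - PF08471  # class II RNR
independent_alternatives:
  epoxyqueuosine_reductase:
  - queH
  methionine_synthase:
  - K00549   # MetE
  methylmalonyl_coa_mutase:   # methylcitrate pathway
  - K01659
  - K01720
  - K03417
  ribonucleotide_reductase:   # class I RNR
  - K00525
  - K00526
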