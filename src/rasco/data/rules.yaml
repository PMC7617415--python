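# Codon rule tables for driver classification.
# Editable: the annotation code reads this file at import; pass a modified copy
# to ClassificationRules.from_yaml() to change the sets without touching code.
braf:
  class1_codons: [600]
  class2_codons: [464, 469, 597, 601]
  class3_codons: [466, 581, 594, 595, 596]
  # Positional (functional-domain) scheme: A = codon 600, B = codons flanking
  # 600 (581-601 excluding 600), C = ATP-binding site.
  domain_A: [600]
  domain_B_range: [581, 601]   # inclusive; codon 600 excluded below
  domain_B_exclude: [600]
  domain_C: [464, 466, 469]
kras:
  typical_codons: [12, 13, 61]
  atypical_codons: [14, 19, 22, 33, 34, 59, 60, 68, 117, 146, 147]
nras:
  pathogenic_codons: [12, 13, 61]
nf1:
  # Protein-truncating consequences that count as pathogenic NF1 loss.
  truncating_consequences: [nonsense, frameshift]
  # Whether splice-site variants count as truncating is not settled in the
  # literature this scheme derives from; configurable, default included.
  include_splice: true
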