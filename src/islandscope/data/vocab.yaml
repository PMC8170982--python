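# Keyword vocabulary for genomic-island feature scanning.
# All entries are matched case-insensitively as substrings of gene product
# annotations.  Precedence at scan time: phage > mobility > tRNA > unknown.
phage_keywords:
  - phage
  - capsid
  - tail
  - terminase
  - portal
  - baseplate
  - holin
  - lysin
  - virion
mobility_keywords:
  - integrase
  - transposase
  - recombinase
  - mobile element
  - conjugal
  - conjugative
trna_keywords:
  - trna
  - transfer rna
unknown_function_markers:
  - hypothetical protein
  - uncharacterized
  - unknown function
  - putative uncharacterized
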