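# Amyloid-beta C-terminal species on APP (P05067, 770-aa numbering).
# Abeta 1-40 ends at APP residue 711, Abeta 1-42 at residue 713; a peptide is
# counted for a species only when its C-terminus matches the defining residue.
analytes:
  - {name: Abeta40, accession: P05067, c_term_position: 711}
  - {name: Abeta42, accession: P05067, c_term_position: 713}
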