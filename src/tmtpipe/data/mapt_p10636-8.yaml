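# Tau (MAPT) domain coordinates on isoform P10636-8 (441 aa)
accession: P10636-8
length: 441
regions:
  - {name: N-terminal, start: 1, end: 126}
  - {name: PRD, start: 127, end: 242}
  - {name: MTBR, start: 243, end: 369}
  - {name: C-terminal, start: 370, end: 441}
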