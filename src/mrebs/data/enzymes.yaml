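# Restriction enzymes used for reduced-representation and MRE digestion.
# cut_offset: 0-based offset within the recognition site; the cut falls
# immediately before that base. cpg_offset: offset of the CpG dinucleotide
# whose methylation blocks cutting (for methylation-sensitive enzymes).
- name: MspI
  recognition: CCGG
  cut_offset: 1
  cpg_offset: 1
  methylation_sensitive: false
- name: HpaII
  recognition: CCGG
  cut_offset: 1
  cpg_offset: 1
  methylation_sensitive: true
- name: HinP1I
  recognition: GCGC
  cut_offset: 1
  cpg_offset: 1
  methylation_sensitive: true
- name: AciI
  recognition: CCGC
  cut_offset: 1
  cpg_offset: 1
  methylation_sensitive: true
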