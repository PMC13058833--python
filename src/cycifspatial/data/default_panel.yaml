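# Default gating panel for cycifspatial.
#
# The three CXCL13+ CD4 T-cell gates (Tfh, Tph, Tph_like) follow the marker
# logic of the source study.  All other gates are conventional surrogate
# definitions expressed over the same 14-marker immunophenotyping panel and
# are meant to be edited to match the antibody panel actually used: lineage
# markers such as CD20 (B cells), CD68/CD163 (macrophages) or panCK (tumour)
# are deliberately absent here and should be added for real data.
#
# Semantics: a cell matches a rule when every `positive` marker has
# z >= z_threshold_pos and every `negative` marker fails positivity.  Lower
# `priority` = evaluated first (most specific gates first).
markers: [B7H3, B7H4, BCL6, CCR2, CD4, CD45RO, CD69, CD8, CXCL13, CXCR5, GAL3, HLADR, PD1, PDL1]
channels: [ch488, ch555, ch647, ch750]
rules:
- name: Tfh
  positive: [CD4, PD1, CXCL13, BCL6, CXCR5]
  negative: [CD8]
  priority: 1
- name: Tph
  positive: [CD4, PD1, CXCL13, CCR2]
  negative: [CXCR5, BCL6, CD8]
  priority: 2
- name: Tph_like
  positive: [CD4, PD1, CXCL13]
  negative: [CCR2, CXCR5, BCL6, CD8]
  priority: 3
- name: Th1
  positive: [CD4, CD45RO, CD69]
  negative: [CD8, CXCL13, CXCR5, CCR2]
  priority: 4
- name: Th17
  positive: [CD4, CD45RO, CCR2]
  negative: [CD8, CXCL13, CXCR5, CD69]
  priority: 5
- name: CD8_T
  positive: [CD8]
  negative: [CD4]
  priority: 6
- name: B_mem_unswitched
  positive: [HLADR, CXCR5, CD45RO]
  negative: [CD4, CD8]
  priority: 7
- name: B_naive
  positive: [HLADR, CXCR5]
  negative: [CD4, CD8, CD45RO]
  priority: 8
- name: B_DN2
  positive: [HLADR, CD69]
  negative: [CD4, CD8, CXCR5, GAL3]
  priority: 9
- name: M1_mac
  positive: [HLADR, PDL1]
  negative: [CD4, CD8, CXCR5, CD69, GAL3]
  priority: 10
- name: M2_mac
  positive: [GAL3, HLADR]
  negative: [CD4, CD8, CXCR5]
  priority: 11
- name: CD4_T
  positive: [CD4]
  negative: [CD8]
  priority: 12
- name: Cancer
  positive: [B7H3, B7H4]
  negative: [CD4, CD8, HLADR, CXCR5]
  priority: 13
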