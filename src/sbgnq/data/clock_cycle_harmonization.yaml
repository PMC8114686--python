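# Example harmonization script for merging a circadian-clock map with the
# RB/E2F cell-cycle map.  Data, not code: it covers only the edits
# inferable from the published map descriptions (nomenclature updates and
# phosphosite granularity); the full curated edit list of the original
# merge is external supplementary material and is not reproduced here.
- kind: rename-label
  old: BMAL1
  new: ARNTL
- kind: rename-label
  old: Wee1
  new: WEE1
- kind: rename-label
  old: p21
  new: CDKN1A
- kind: rename-label
  old: p53
  new: TP53
# the clock map carries phosphorylated CDK6 without the residue; align it
# with the cell-cycle map's site-level granularity
- kind: add-state-variable
  entity: CDK6
  value: P
  site: Thr
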