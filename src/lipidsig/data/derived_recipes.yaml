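# Default derived-variable recipes appended to a raw mol-% profile.
#
# Each entry adds one column.  kinds:
#   sum   - sum of the mol-% of the raw FA columns matched by `select`
#   ratio - sum(numerator) / sum(denominator)
#   index - sum(mol-% * weight_field) / 100 over the matched columns,
#           weight_field is a FAName attribute (double_bonds or carbons)
#
# Selector fields (all optional, combined with AND):
#   labels: explicit list of raw FA labels (missing labels are an error
#           unless compute_derived(..., missing="zero"))
#   min_carbons / max_carbons, double_bonds, min_double_bonds,
#   series: list of n-x series, is_dma: true/false
#
# The n-6 and n-3 product/precursor ratios divide the long-chain (C20-22)
# products of each essential-PUFA family by its dietary precursor
# (18:2n-6 and 18:3n-3 respectively).  The double bond index and average
# chain length are mol-%-weighted means of double-bond count and chain
# length over all measured chains.

- name: SFA sum
  kind: sum
  select: {double_bonds: 0, is_dma: false}
- name: MUFA sum
  kind: sum
  select: {double_bonds: 1, is_dma: false}
- name: PUFA sum
  kind: sum
  select: {min_double_bonds: 2, is_dma: false}
- name: n-3 PUFA sum
  kind: sum
  select: {series: [n-3], min_double_bonds: 2, is_dma: false}
- name: n-6 PUFA sum
  kind: sum
  select: {series: [n-6], min_double_bonds: 2, is_dma: false}
- name: Total DMA
  kind: sum
  select: {is_dma: true}
- name: C20-24 SFA sum
  kind: sum
  select: {double_bonds: 0, min_carbons: 20, max_carbons: 24, is_dma: false}
- name: n-3/n-6 ratio
  kind: ratio
  numerator: {series: [n-3], min_double_bonds: 2, is_dma: false}
  denominator: {series: [n-6], min_double_bonds: 2, is_dma: false}
- name: n-6 product/precursor ratio
  kind: ratio
  numerator: {series: [n-6], min_double_bonds: 2, min_carbons: 20, max_carbons: 22, is_dma: false}
  denominator: {labels: ["18:2n-6"]}
- name: n-3 product/precursor ratio
  kind: ratio
  numerator: {series: [n-3], min_double_bonds: 2, min_carbons: 20, max_carbons: 22, is_dma: false}
  denominator: {labels: ["18:3n-3"]}
- name: Double bond index
  kind: index
  weight: double_bonds
- name: Average chain length
  kind: index
  weight: carbons
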