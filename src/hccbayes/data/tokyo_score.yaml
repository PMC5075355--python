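# Tokyo Score point table.  Four markers — serum albumin (g/dL), total
# bilirubin (mg/dL), largest tumor size (cm) and number of tumors —
# each mapped to integer points; the total is compared against a
# diagnosis cutoff (score >= 2 flags possible recurrence).
# The table is editable config: only the marker set and the standard
# worked-example point values are treated as fixed by this package.
name: Tokyo Score
cutoff: 2
direction: ge
markers:
  - name: albumin
    points:
      - {rule: {op: gt, value: 3.5}, points: 0}
      - {rule: {op: between, low: 2.8, high: 3.5}, points: 1}
      - {rule: {op: lt, value: 2.8}, points: 2}
  - name: bilirubin
    points:
      - {rule: {op: lt, value: 1.0}, points: 0}
      - {rule: {op: between, low: 1.0, high: 2.0}, points: 1}
      - {rule: {op: gt, value: 2.0}, points: 2}
  - name: tumor_size
    points:
      - {rule: {op: lt, value: 2.0}, points: 0}
      - {rule: {op: between, low: 2.0, high: 5.0}, points: 1}
      - {rule: {op: gt, value: 5.0}, points: 2}
  - name: tumor_number
    points:
      - {rule: {op: le, value: 3}, points: 0}
      - {rule: {op: gt, value: 3}, points: 2}
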