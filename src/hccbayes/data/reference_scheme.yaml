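# Reference cutoff scheme for the 10 hepatectomy-cohort markers.
# Cutoff values were fixed by physicians in advance; units are those of
# routine clinical reporting and values are treated as unitless here.
version: reference-v1
markers:
  - id: 1
    name: ALB
    divisions:
      - label: "ALB > 3.5"
        rule: {op: gt, value: 3.5}
      - label: "ALB <= 3.5"
        rule: {op: le, value: 3.5}
  - id: 2
    name: tumor_burden   # tumor number x tumor size
    divisions:
      - label: "Tumor number x tumor size < 4"
        rule: {op: lt, value: 4}
      - label: "Tumor number x tumor size 4~9"
        rule: {op: between, low: 4, high: 9}
      - label: "Tumor number x tumor size > 9"
        rule: {op: gt, value: 9}
  - id: 3
    name: vp             # portal vein invasion
    divisions:
      - label: "vp+"
        rule: {op: eq, value: "+"}
      - label: "vp-"
        rule: {op: eq, value: "-"}
  - id: 4
    name: ICG            # indocyanine green retention
    divisions:
      - label: "ICG < 15"
        rule: {op: lt, value: 15}
      - label: "ICG >= 15"
        rule: {op: ge, value: 15}
  - id: 5
    name: vv             # hepatic vein invasion
    divisions:
      - label: "vv+"
        rule: {op: eq, value: "+"}
      - label: "vv-"
        rule: {op: eq, value: "-"}
  - id: 6
    name: platelets
    divisions:
      - label: "Number of platelets >= 10"
        rule: {op: ge, value: 10}
      - label: "Number of platelets < 10"
        rule: {op: lt, value: 10}
  - id: 7
    name: PT             # prothrombin time
    divisions:
      - label: "PT >= 80"
        rule: {op: ge, value: 80}
      - label: "PT < 80"
        rule: {op: lt, value: 80}
  - id: 8
    name: bilirubin
    divisions:
      - label: "Bilirubin < 1"
        rule: {op: lt, value: 1}
      - label: "Bilirubin >= 1"
        rule: {op: ge, value: 1}
  - id: 9
    name: differentiation
    divisions:
      - label: "Degree of differentiation non-por"
        rule: {op: eq, value: "non-por"}
      - label: "Degree of differentiation por"
        rule: {op: eq, value: "por"}
  - id: 10
    name: liver_damage
    divisions:
      - label: "Liver damage A"
        rule: {op: eq, value: "A"}
      - label: "Liver damage B"
        rule: {op: eq, value: "B"}
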