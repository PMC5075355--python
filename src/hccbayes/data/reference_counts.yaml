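# Reference division-count table: training cohort of 29 patients with
# recurrence within one year and 89 without, tallied into the divisions
# of the reference cutoff scheme.  For each marker the first row is the
# recurrence class, the second the nonrecurrence class; each row sums to
# its class size.  These are within-class marginals only: the one known
# joint datum (7 recurrence patients fall in both "ALB > 3.5" and
# "tumor burden > 9") is recorded here for reference but not encoded,
# since marginals do not determine a joint distribution.
class_sizes: [29, 89]
counts:
  1:  [[15, 14], [60, 29]]     # ALB
  2:  [[6, 11, 12], [47, 29, 13]]  # tumor_burden
  3:  [[10, 19], [18, 71]]     # vp
  4:  [[14, 15], [44, 45]]     # ICG
  5:  [[9, 20], [16, 73]]      # vv
  6:  [[16, 13], [70, 19]]     # platelets
  7:  [[18, 11], [67, 22]]     # PT
  8:  [[17, 12], [61, 28]]     # bilirubin
  9:  [[25, 4], [79, 10]]      # differentiation
  10: [[15, 14], [60, 29]]     # liver_damage
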