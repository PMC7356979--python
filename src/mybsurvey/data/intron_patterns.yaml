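# Canonical intron-pattern catalog (configuration artifact).
#
# Letters follow the lettered-pattern convention of earlier MYB family
# surveys ('k' is deliberately absent).  The canonical signatures below —
# (repeat slot, domain column, phase) triples over the 52-column repeat
# profile, slots 0-based from the N-terminal repeat — are this package's
# own plausible defaults, editable per study; they are not measured data.
patterns:
  a: []                                   # intronless
  b:
    - {slot: 0, column: 10, phase: 0}
  c:
    - {slot: 0, column: 31, phase: 1}
  d:
    - {slot: 1, column: 13, phase: 2}
  e:
    - {slot: 0, column: 10, phase: 0}
    - {slot: 1, column: 31, phase: 1}
  f:
    - {slot: 0, column: 31, phase: 1}
    - {slot: 1, column: 31, phase: 1}
  g:
    - {slot: 0, column: 5, phase: 0}
    - {slot: 1, column: 20, phase: 0}
  h:
    - {slot: 1, column: 44, phase: 2}
  i:
    - {slot: 0, column: 22, phase: 1}
  j:
    - {slot: 0, column: 10, phase: 0}
    - {slot: 0, column: 40, phase: 2}
    - {slot: 1, column: 31, phase: 1}
  l:
    - {slot: 0, column: 5, phase: 1}
    - {slot: 1, column: 10, phase: 0}
    - {slot: 1, column: 44, phase: 0}
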