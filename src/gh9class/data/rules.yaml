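# Default class-assignment intervals on the ANN score (beta'') with the
# alpha13 side condition separating classes A and C in their shared band.
# Derived from the screened reference set of expression-backed sequences;
# anything outside every interval is left unassigned.
rules:
  - label: A
    lo: 9.95
    hi: 10.779
    lo_open: true
    hi_open: true
    alpha13: {op: lt, value: 0.02}
  - label: B_high
    lo: 3.45
    hi: 5.55
    lo_open: true
    hi_open: true
    alpha13: null
  - label: B_low
    lo: 5.55
    hi: 8.2052
    lo_open: false
    hi_open: true
    alpha13: null
  - label: C
    lo: 8.2052
    hi: 9.95
    lo_open: false
    hi_open: false
    alpha13: null
  - label: C
    lo: 9.95
    hi: 10.779
    lo_open: true
    hi_open: true
    alpha13: {op: gt, value: 0.02}
  - label: C
    lo: 10.779
    hi: 11.371
    lo_open: false
    hi_open: false
    alpha13: null
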