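# Six-anchorage toy circuit on a 7x8 grid: a single fork deciding the
# input x.  The upper branch (labelled x) leads to the TRUE final, the
# lower branch falls straight from the fork onto the FALSE final.
inputs: [x]
function: x
vertices:
  - {id: v0, x: 4, y: 1, type: INIT}
  - {id: n1, x: 4, y: 3, type: NORM}
  - {id: g1, x: 4, y: 5, type: FORK}
  - {id: n2, x: 2, y: 6, type: NORM, label: x}
  - {id: fT, x: 2, y: 8, type: FINAL, out: T}
  - {id: fF, x: 6, y: 7, type: FINAL, out: F}
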