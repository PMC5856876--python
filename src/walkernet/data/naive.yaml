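# Compact ("naive") layout of the three-input OR circuit x|y|z.
# Reconstructed transcription of a published origami-tile design: the
# defining figure is available only graphically, so the layout was
# rebuilt from the circuit's DSD structure and validated against its
# published structural counts (the short-distance column of the
# transition classification: Track 64, Fork 12, Join 8, Leak 8 directed
# transitions; see the test suite).  The four short-distance leak pairs
# sit at the three fork sibling cones and at the tight first join.
# Branch anchorages carry their branch literal, so blocking shields the
# paths not taken.
inputs: [x, y, z]
function: x | y | z
vertices:
- {id: xh, x: 1, y: 5, type: NORM, label: x}
- {id: a1, x: 1, y: 7, type: NORM, label: x}
- {id: a2, x: 1, y: 10, type: NORM, label: x}
- {id: a4, x: 1, y: 13, type: NORM, label: x}
- {id: v00, x: 2, y: 1, type: INIT}
- {id: f1, x: 2, y: 3, type: FORK}
- {id: a5, x: 2, y: 15, type: NORM, label: x}
- {id: nxh, x: 4, y: 5, type: NORM, label: '!x'}
- {id: a6, x: 4, y: 16, type: NORM, label: x}
- {id: b1, x: 6, y: 5, type: NORM, label: '!x'}
- {id: t1, x: 6, y: 17, type: NORM, label: x}
- {id: f2, x: 8, y: 5, type: FORK, label: '!x'}
- {id: y2, x: 8, y: 9, type: NORM, label: y}
- {id: y3, x: 8, y: 12, type: NORM, label: y}
- {id: t2, x: 8, y: 15, type: NORM, label: y}
- {id: j1, x: 8, y: 17, type: JOIN}
- {id: yh, x: 9, y: 7, type: NORM, label: y}
- {id: nyh, x: 11, y: 5, type: NORM, label: '!y'}
- {id: c1, x: 11, y: 17, type: NORM}
- {id: b2, x: 13, y: 5, type: NORM, label: '!y'}
- {id: c2b, x: 14, y: 17, type: NORM}
- {id: f3, x: 16, y: 5, type: FORK, label: '!y'}
- {id: zh, x: 17, y: 7, type: NORM, label: z}
- {id: z2, x: 17, y: 9, type: NORM, label: z}
- {id: z4, x: 17, y: 14, type: NORM, label: z}
- {id: j2, x: 17, y: 17, type: JOIN}
- {id: fT, x: 17, y: 20, type: FINAL, out: T}
- {id: nzh, x: 19, y: 5, type: NORM, label: '!z'}
- {id: zj1, x: 19, y: 10, type: NORM, label: z}
- {id: zj2, x: 19, y: 12, type: NORM, label: z}
- {id: b3, x: 21, y: 5, type: NORM, label: '!z'}
- {id: b3b, x: 23, y: 6, type: NORM, label: '!z'}
- {id: b4, x: 25, y: 7, type: NORM, label: '!z'}
- {id: b5, x: 25, y: 9, type: NORM, label: '!z'}
- {id: b6, x: 25, y: 11, type: NORM, label: '!z'}
- {id: b7, x: 25, y: 13, type: NORM, label: '!z'}
- {id: b8, x: 25, y: 15, type: NORM, label: '!z'}
- {id: b9, x: 25, y: 17, type: NORM, label: '!z'}
- {id: b10, x: 25, y: 19, type: NORM, label: '!z'}
- {id: b11, x: 25, y: 21, type: NORM, label: '!z'}
- {id: b12, x: 25, y: 23, type: NORM, label: '!z'}
- {id: fF, x: 25, y: 25, type: FINAL, out: F}
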