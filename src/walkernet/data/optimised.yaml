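# Spread-out ("optimised") layout of the three-input OR circuit x|y|z.
# Reconstructed transcription (see naive.yaml).  A single short-distance
# leak pair remains, at the first fork's sibling cone (short column:
# Track 66, Fork 12, Join 8, Leak 2 directed transitions).  The fork
# spine and the join column run as straight lines through the junctions,
# and parallel tracks are separated beyond the medium interaction range.
inputs: [x, y, z]
function: x | y | z
vertices:
- {id: a1, x: 1, y: 7, type: NORM, label: x}
- {id: a3, x: 1, y: 10, type: NORM, label: x}
- {id: a4, x: 1, y: 13, type: NORM, label: x}
- {id: a5, x: 1, y: 15, type: NORM, label: x}
- {id: a6, x: 1, y: 17, type: NORM, label: x}
- {id: xh, x: 3, y: 5, type: NORM, label: x}
- {id: a7, x: 3, y: 18, type: NORM, label: x}
- {id: v00, x: 4, y: 1, type: INIT}
- {id: f1, x: 4, y: 3, type: FORK}
- {id: a8, x: 5, y: 19, type: NORM, label: x}
- {id: nxh, x: 6, y: 5, type: NORM, label: '!x'}
- {id: t1, x: 7, y: 20, type: NORM, label: x}
- {id: b1, x: 8, y: 5, type: NORM, label: '!x'}
- {id: ys2, x: 9, y: 9, type: NORM, label: y}
- {id: y2, x: 9, y: 11, type: NORM, label: y}
- {id: y3, x: 9, y: 14, type: NORM, label: y}
- {id: t2, x: 9, y: 17, type: NORM, label: y}
- {id: j1, x: 9, y: 20, type: JOIN}
- {id: b2, x: 10, y: 5, type: NORM, label: '!x'}
- {id: ys1, x: 11, y: 8, type: NORM, label: y}
- {id: c1, x: 12, y: 20, type: NORM}
- {id: f2, x: 13, y: 5, type: FORK, label: '!x'}
- {id: yh, x: 13, y: 8, type: NORM, label: y}
- {id: c3, x: 15, y: 20, type: NORM}
- {id: nyh, x: 16, y: 5, type: NORM, label: '!y'}
- {id: b4, x: 18, y: 5, type: NORM, label: '!y'}
- {id: z2, x: 18, y: 11, type: NORM, label: z}
- {id: z3, x: 18, y: 14, type: NORM, label: z}
- {id: t3, x: 18, y: 17, type: NORM, label: z}
- {id: j2, x: 18, y: 20, type: JOIN}
- {id: zs2, x: 19, y: 9, type: NORM, label: z}
- {id: b5, x: 20, y: 5, type: NORM, label: '!y'}
- {id: fT, x: 20, y: 20, type: FINAL, out: T}
- {id: zs1, x: 21, y: 8, type: NORM, label: z}
- {id: f3, x: 23, y: 5, type: FORK, label: '!y'}
- {id: zh, x: 23, y: 8, type: NORM, label: z}
- {id: nzh, x: 26, y: 5, type: NORM, label: '!z'}
- {id: b7, x: 28, y: 5, type: NORM, label: '!z'}
- {id: b8, x: 29, y: 7, type: NORM, label: '!z'}
- {id: b9, x: 29, y: 9, type: NORM, label: '!z'}
- {id: b10, x: 29, y: 11, type: NORM, label: '!z'}
- {id: b11, x: 29, y: 13, type: NORM, label: '!z'}
- {id: fF, x: 29, y: 15, type: FINAL, out: F}
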