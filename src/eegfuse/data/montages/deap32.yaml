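# 32-channel DEAP montage (international 10/20 system), acquisition channel order.
# grid: head seen from above; row 0 = front of head, col 0 = left ear,
# midline (z) electrodes in col 4 of the 9x9 plane.
name: deap32
grid_shape: [9, 9]
channels:
  Fp1: [0, 3]
  AF3: [1, 3]
  F3: [2, 2]
  F7: [2, 0]
  FC5: [3, 1]
  FC1: [3, 3]
  C3: [4, 2]
  T7: [4, 0]
  CP5: [5, 1]
  CP1: [5, 3]
  P3: [6, 2]
  P7: [6, 0]
  PO3: [7, 3]
  O1: [8, 3]
  Oz: [8, 4]
  Pz: [6, 4]
  Fp2: [0, 5]
  AF4: [1, 5]
  Fz: [2, 4]
  F4: [2, 6]
  F8: [2, 8]
  FC6: [3, 7]
  FC2: [3, 5]
  Cz: [4, 4]
  C4: [4, 6]
  T8: [4, 8]
  CP6: [5, 7]
  CP2: [5, 5]
  P4: [6, 6]
  P8: [6, 8]
  PO4: [7, 5]
  O2: [8, 5]
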