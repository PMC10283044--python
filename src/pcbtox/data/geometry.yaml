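# Default exposure-well geometry: 24-well format, 500 uL medium,
# 2000 uL headspace, 2e5 cells, 37 C.  Cell composition is the measured
# C6 glioma per-cell protein/lipid/water volume (uL/cell).
v_m: 500.0
v_a: 2000.0
n_cells: 200000.0
t: 310.15
composition:
  v_pro: 1.18e-4
  v_lip: 9.57e-5
  v_wat: 2.84e-6
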