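# Default PP-LFER coefficient registry.  These are illustrative package
# defaults in the shape of published storage-lipid/water, structural-
# protein/water and air/water systems; swap in the coefficient sets of
# your choice for production predictions.
lipid/water:
  c: 0.58
  e: 0.91
  s: -1.20
  a: -1.46
  b: -4.15
  v: 4.05
  basis: L_per_kg
  density: 0.905
  provenance: "storage lipid / water system; illustrative package default"
protein/water:
  c: -0.59
  e: 0.73
  s: -0.44
  a: -0.40
  b: -3.38
  v: 3.21
  basis: L_per_kg
  density: 1.36
  provenance: "structural protein / water system; illustrative package default"
air/water:
  c: -0.50
  e: -0.45
  s: -1.30
  a: -3.60
  b: -4.90
  l: 0.30
  basis: volume
  provenance: "air / water system; illustrative package default"
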