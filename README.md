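# pcbtox

Equilibrium partitioning and cytotoxicity dose–response modelling for
lower-chlorinated polychlorinated biphenyls (LC-PCBs) and their
human-relevant hydroxylated (OH-PCB) and sulfated (PCB sulfate)
metabolites in cell-culture exposure systems.

## The problem

LC-PCBs are semi-volatile indoor-air contaminants; in the body they are
oxidised to OH-PCBs and conjugated to PCB sulfates.  When these
chemicals are tested in vitro, the nominal medium concentration is a
poor proxy for what cells actually experience: a lipophilic congener
sorbs almost entirely into cellular lipid, while a charged sulfate
conjugate stays in the medium, and a volatile congener escapes into the
head-space air.  `pcbtox` provides:

1. **An equilibrium mass-balance partitioning model** of an exposure
   well — medium, head-space air, and three intracellular phases
   (storage lipid, protein, cytosolic water).  With dimensionless
   partition coefficients `K_lip/w`, `K_pro/w`, `K_air/w` and phase
   loadings `[Lip] = n·v_lip/V_m`, `[Pro] = n·v_pro/V_m`,
   `r = V_a/V_m`, the fractions are

   ```
   D      = 1 + K_pro/w·[Pro] + K_lip/w·[Lip] + K_air/w·r
   f_fre  = 1/D        f_pro = K_pro/w·[Pro]/D
   f_lip  = K_lip/w·[Lip]/D   f_air = K_air/w·r/D
   f_cell = f_pro + f_lip + f_fre·(n·v_wat/V_m)
   ```

   Condensed-phase K's come from polyparameter linear free-energy
   relationships (PP-LFERs) over Abraham solute descriptors
   (`log K = c + eE + sS + aA + bB + vV|lL`); the air/water K from a
   van't-Hoff temperature-corrected Henry's law constant divided by RT.

2. **A dose–response toxicity workflow** — MTT viability and LDH
   cytotoxicity plate normalization, four-parameter logistic (4PL)
   IC50 estimation with range censoring (">50 µM" when the half-effect
   is not reached inside the tested range), and per-concentration exact
   rank-sum comparison of two cell models (e.g. male vs female primary
   astrocytes) with Holm adjustment.

3. **A seeded synthetic-data generator** that emulates the study
   design (7-point 0–50 µM series, DMSO vehicle controls, 3 biological
   × 3 technical replicates, 10 % CV multiplicative noise) so the whole
   pipeline is testable without any external data.

## Worked example

Predict partitioning for the shipped illustrative 15-compound library
(five parent congener profiles with matched OH- and sulfate
metabolites) and fit IC50s to a simulated study:

```sh
pcbtox partition --out-dir out/part
pcbtox simulate --seed 1 --out-dir out/sim
pcbtox fit --plates out/sim/plates.csv --out-dir out/fit
```

`out/part/partition_profile.csv` (abridged):

| id                 | class        | n_cl | f_medium | f_cell | g_lip | g_pro | g_wat |
|--------------------|--------------|------|----------|--------|-------|-------|-------|
| pcb_1cl_01         | parent       | 1    | 0.0001   | 0.9998 | 0.952 | 0.048 | 0.000 |
| pcb_4cl_05         | parent       | 4    | 0.0000   | 1.0000 | 0.968 | 0.032 | 0.000 |
| oh_pcb_1cl_01      | hydroxylated | 1    | 0.0183   | 0.9817 | 0.565 | 0.435 | 0.000 |
| pcb_sulfate_1cl_01 | sulfated     | 1    | 0.9972   | 0.0028 | 0.030 | 0.560 | 0.411 |
| pcb_sulfate_4cl_05 | sulfated     | 4    | 0.9600   | 0.0400 | 0.073 | 0.900 | 0.027 |

Parents are almost entirely cell-associated (and increasingly so with
chlorination, mostly in storage lipid), the mono-chlorinated parent
carries the largest air fraction, and every sulfate stays > 96 % in the
medium — the qualitative structure–activity picture the model is built
to capture.

`out/fit/ic50_table.csv` (abridged; simulation truths were 21.4, 2.2
and 200 µM respectively):

| compound      | ic50_display | hill  | top   | bottom | censored |
|---------------|--------------|-------|-------|--------|----------|
| oh_pcb_1cl_01 | 19.5         | −1.09 | 106.2 | 0.0    | False    |
| oh_pcb_4cl_05 | 2.1          | −1.24 | 103.3 | 0.6    | False    |
| pcb_1cl_01    | >50          | —     | 97.0  | 78.9   | True     |

A compound whose fitted viability never crosses 50 % inside the tested
range is reported censored as `>50` with a separate comparator column
(`cmp=">"`, `value=50`), so downstream code never parses strings.

## Layout

- `pcbtox.chem_props` — Abraham descriptors, PP-LFER evaluation,
  Henry's law temperature correction, partition-coefficient assembly.
- `pcbtox.partition_model` — phase loadings, system and intracellular
  fractions, the per-compound partition profile.
- `pcbtox.dose_response` — MTT/LDH normalization, 4PL fitting and
  censored IC50 reporting, exact rank-sum group comparison.
- `pcbtox.synthetic_data` — seeded plate and compound-library
  generators, full study bundles.
- `pcbtox.cli` — `pcbtox simulate | partition | fit | compare`.

See `docs/methods.md` for the model assumptions, parameter defaults,
and numerical choices.
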