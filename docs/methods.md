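# Methods

## Equilibrium partitioning model

The exposure well is treated as a closed system at chemical
equilibrium with five phases: culture medium (the freely dissolved
pool), head-space air, and — inside the cells — storage lipid, protein
and cytosolic water.  For a chemical *i* the mass balance

m_tot = m_fre + m_pro + m_lip + m_air

is rewritten with the dimensionless partition coefficients
K_pro/w = C_pro/C_fre, K_lip/w = C_lip/C_fre and K_air/w = C_air/C_fre,
divided by C_fre·V_m, giving the closed-form fractions implemented in
`partition_model.system_fractions` (denominator
D = 1 + K_pro/w·[Pro] + K_lip/w·[Lip] + K_air/w·V_a/V_m).  The
closed-form algebra is guarded in the test suite by an independent
numerical route that root-finds the free concentration from a fixed
total mass and recomputes each phase mass directly; the two agree to
1e-10 relative on a thousand random systems spanning ten orders of
magnitude in K.

Assumptions inherited by everything downstream:

- equilibrium is reached within the exposure window; no uptake or
  clearance kinetics;
- no saturation or solubility cap (fractions are
  concentration-independent);
- no sorption to the plastic well walls (slow diffusion into
  polystyrene relative to the exposure time);
- the cytosol behaves as free water, so its concentration equals the
  medium's freely dissolved concentration.  The grouped cell fraction
  is therefore f_cell = f_pro + f_lip + f_fre·(n·v_wat/V_m), and the
  medium share is its complement within f_fre.

### Parameters and defaults

| parameter | default | units | note |
|---|---|---|---|
| v_pro | 1.18e-4 | µL/cell | measured C6 glioma protein volume |
| v_lip | 9.57e-5 | µL/cell | measured C6 glioma lipid volume |
| v_wat | 2.84e-6 | µL/cell | measured C6 glioma water volume |
| V_m | 500 | µL | 24-well exposure format |
| V_a | 2000 | µL | head-space above the medium |
| n_cells | 2e5 | – | cells per well |
| T | 310.15 | K | incubation temperature (37 °C) |
| ΔU_aw | 55 000 | J/mol | air–water transfer energy used when a compound record has none |
| ρ_lip | 0.905 | kg/L | converts L/kg lipid-water K's to volume basis |
| ρ_pro | 1.36 | kg/L | converts L/kg protein-water K's to volume basis |

The measured per-cell water volume is smaller than the protein and
lipid volumes, which is physically surprising; the value is used as
configured and can be overridden in the geometry file.  The well
geometry (V_m, V_a, n_cells) is a package default chosen for a 24-well
format — it is echoed into every output so a run is reproducible from
its config alone.

### Partition coefficients

Condensed-phase coefficients are polyparameter linear free-energy
relationships over the Abraham descriptors,
log10 K = c + e·E + s·S + a·A + b·B + (v·V | l·L), with the coefficient
sets held in a YAML registry keyed by phase pair.  Published systems
are frequently mass-based (L/kg); the registry records the basis and a
phase density, and `build_partition_set` converts to the dimensionless
volume basis the mass balance needs.  The registry shipped with the
package is an illustrative default in the shape of published
storage-lipid/water, structural-protein/water and air/water systems;
production use should substitute the coefficient sets of record.  Which
protein (muscle vs serum albumin) and which lipid (storage vs membrane)
system to use is deliberately left to configuration rather than being
hard-wired.

The air/water coefficient for parent congeners uses a Henry's law
constant, corrected from its reference temperature with the van't Hoff
relation H(T) = H_ref·exp(−ΔU_aw/R·(1/T − 1/T_ref)) and divided by RT.
Sulfated metabolites are permanently ionised under assay conditions and
are assigned K_air/w = 0 by class (their PP-LFER K's are computed from
the neutral-form descriptors supplied); hydroxylated metabolites fall
back to the air/water PP-LFER.

## Dose–response workflow

**MTT.**  Per well the blank-handled signal is A570 − A650; percent
viability is 100 × signal / mean(DMSO-control signal).  A missing
control set is a normalization error; a non-positive control mean a
data-quality error.  **LDH.**  Percent cytotoxicity is
100 × (signal − low̄)/(high̄ − low̄) between the plate's spontaneous- and
full-lysis controls, following the kit convention.  In both assays
technical replicates are averaged within biological replicate before
any fitting or testing — the biological replicate is the unit of
analysis.

**4PL fitting.**  y = bottom + (top − bottom)/(1 + 10^(hill·(log10 IC50
− log10 x))) is fitted by bounded least squares (trust-region
reflective) on log10 concentration, multi-started from a deterministic
7 × 6 grid over (log10 IC50, hill sign/steepness).  Both plateaus are
floored at 0 % (a viability cannot be negative); the hill slope is
free, so the fit handles decreasing viability and increasing
cytotoxicity alike.  The vehicle control (concentration 0) anchors the
normalization and is excluded from the fitted points.  After fitting,
the parameterization is canonicalised to top ≥ bottom (the 4PL is
invariant under swapping plateaus and negating the slope).

**Censoring.**  The reported IC50 is censored to ">max tested" when the
optimiser fails, when the fitted midpoint exceeds the highest tested
concentration, or when the fitted curve never crosses the absolute 50 %
response level inside the tested range.  The last rule is what turns a
shallow, noise-driven dip in an essentially non-toxic compound into the
conventional ">50 µM" entry instead of a spurious midpoint between two
high plateaus.  Censored values are serialized with an explicit
comparator column (cmp=">", value=bound) beside the display string.

**Group comparison.**  Per concentration, a two-sided rank-sum test
with mid-ranks for ties, evaluated by complete enumeration of all
C(n1+n2, n1) assignments for up to 9 per group (normal approximation
beyond).  The two-sided p-value is the null fraction of assignments
whose rank-sum deviates from its mean at least as much as observed;
with two fully separated groups of three this gives exactly
p = 2/20 = 0.1.  P-values are Holm-adjusted across the concentration
grid (conservative and valid for discrete exact tests); the adjustment
method is recorded in every output.

## Synthetic data

The generator emulates the study design: 7-point concentration series
(0, 0.5, 1, 5, 10, 20, 50 µM), three biological × three technical
replicates, DMSO controls, 24-well MTT or 96-well LDH layouts.  Well
signals sit on a ground-truth Hill curve and are perturbed by
mean-one multiplicative lognormal noise (default CV 10 %; an additive
Gaussian model is available).  Control signal (1.0 AU) and blank
(0.05 AU) are arbitrary instrument-scale constants, never interpreted
as biology.  All draws flow from a single integer seed through one
`numpy` Generator, so output is byte-reproducible.

The compound-library generator produces parent/hydroxylated/sulfated
triads whose descriptors follow class and chlorination trends (V and L
grow with each chlorine; hydroxylation adds hydrogen-bond acidity and
basicity; sulfation adds strong basicity and polarity).  The shipped
fixture table `pcbtox/data/compounds.csv` was produced by this
generator and carries a provenance column marking it as synthetic
illustrative values — the trends, not the absolute numbers, are the
content.  What passing tests show is therefore that the *model
machinery* reproduces the expected qualitative structure (cell
association rising with chlorination, sulfates remaining in the medium,
the mono-chlorinated parent most volatile) — not that any specific real
congener's fractions are predicted correctly, which would require
descriptors and PP-LFER systems of record.

Features of real plate data that are *not* emulated: edge effects,
drift within a plate, correlated technical replicates, hormetic
low-dose stimulation, and solvent carry-over.

## Numerical choices

- Mass-balance fractions are evaluated in closed form; the 1e-12
  conservation tolerance is far above double-precision rounding for
  the magnitudes involved.
- 4PL multi-start grid: log10 IC50 centres span the tested range ± 0.5
  decades (7 points); hill starts at ±0.5, ±1, ±2.  Convergence flags
  come from the optimiser and are reported honestly; a singular fit
  yields a censored result, never an exception.
- The exact rank-sum enumeration caps at 9 per group
  (C(18,9) = 48 620 assignments) before switching to the tie-corrected
  normal approximation.
- Degenerate inputs fail loudly and specifically: all-zero
  intracellular volumes, missing coefficient sets (named by phase
  pair), inverted LDH controls, fewer than four positive
  concentrations.

## Problem sizes used in the checks

The shipped verification runs use 1000 random partition systems for
the conservation/oracle checks, 100 simulation seeds per true potency
(2.2, 8.8, 25 µM) for IC50 recovery, 2000 null comparisons at five
replicates per group for exact-test calibration (at three per group the
discrete test cannot reject at α = 0.05 at all, so calibration is
checked where the level is non-trivial), and duplicate end-to-end CLI
runs for byte-stability.

## Known limitations

- Equilibrium is assumed, not demonstrated; slowly equilibrating
  congeners will be mis-predicted early in an exposure.
- Serum-free exposure is assumed; medium proteins/lipids would add
  binding phases the model does not include.
- Sulfate speciation is handled as a class-level volatility override,
  not via charged-species descriptors.
- The IC50 of a partial-effect compound (plateau above 50 %) is
  reported censored by design; a relative-IC50 convention would differ.
- The fixture descriptors and registry coefficients are illustrative;
  quantitative predictions require values of record for each compound
  and phase system.
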