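# Methods

## The evaluation scenario

The package models a deterministic, conservative carry-over scenario for
contaminants entering the PET bottle-to-bottle recycling stream from
non-food containers:

* a fraction *f* of the feed stream is non-food PET (default 0.05 — the
  value obtained from resin-market shares: 4% non-food container resin
  joining 77% beverage-bottle resin gives 4/81 ≈ 4.94%, conventionally
  displayed as 5%; `estimate_nonfood_fraction` reproduces this arithmetic);
* super-clean recycling removes a fraction *η* of any contaminant
  (default 0.90, the worst case of the 90–99% range such processes
  achieve);
* the resulting bottle-wall residue `c_P,0 = c_nonfood · f · (1 − η)`
  migrates into the beverage over one year at 25 °C, with the conventional
  6 dm² of bottle surface per litre of beverage and a partition coefficient
  of 1 (no solubility limitation — a worst case);
* the infant water-consumption scenario (0.75 L/day, 5 kg body weight)
  converts the beverage concentration into a dietary exposure. The 5 kg
  body weight is implied by the scenario arithmetic (0.00107 × 0.75 /
  0.000161 ≈ 5) and matches the standard infant scenario.

Beverage concentrations are reported in µg/L and treated as equal to µg/kg
(water density 1), as is conventional for bottled-water scenarios.

## Diffusion models

**Piringer A_P model** (conservative upper bound, the regulatory default):

    D = 1e4 · exp(A_P′ − τ/T − 0.1351·M^(2/3) + 0.003·M − 10454/T)  [cm²/s]

with M in g/mol, T in kelvin and the PET upper-bound parameters A_P′ = 3.1,
τ = 1577 K. The admissible domain is M ∈ (40, 600) g/mol and
T ∈ (273, 473) K. 25 °C is always taken as 298.15 K.

**Welle-type PET correlation** (realistic). The PET-specific
activation-energy correlation is shipped as a two-point log-linear
calibration at 25 °C,

    ln D = α + β·M,

anchored at two back-calculated room-temperature diffusion coefficients:
D(78.1 g/mol) = 7.1686e-15 cm²/s and D(150.2 g/mol) = 1.4118e-17 cm²/s,
obtained by inverting the semi-infinite migration formula against the
corresponding one-year migration predictions of the realistic model
(0.000338 µg/L at c_P,0 = 7.5e-4 mg/kg, and 0.001 µg/L at c_P,0 =
0.05 mg/kg). This choice makes predictions at the anchor masses exact by
construction and predictions between them (e.g. the pooled-unknowns
surrogate at M = 145 g/mol) genuine interpolations. The calibration is
valid only at 298.15 K; querying another temperature raises an error
rather than extrapolating. A full Arrhenius parameterization
(pre-exponential and activation energy as functions of M) is an anticipated
alternative source but is not bundled, because no transcription of those
constants was available to verify.

## Migration solver

Both solvers assume a uniform initial wall concentration, a constant
diffusion coefficient, release from the food-contact face only, and a
perfectly mixed beverage imposing zero surface concentration (partition
coefficient 1, infinite-bath limit).

* **Semi-infinite** (default): migrated mass per area `2·c_vol·√(Dt/π)`,
  where `c_vol = c_P,0 · ρ_PET · 1e-3` converts the mass-fraction
  concentration (mg/kg) to a volumetric one (mg/cm³) with ρ_PET =
  1.4 g/cm³. Valid while only a thin skin of the wall is depleted; the
  most mobile surveyed substance (benzene, D ≈ 7.1e-14 cm²/s) reaches a
  fractional depletion of 5.6% of a 300 µm wall after one year, and the
  two solvers agree to better than 0.01% there. A depletion above 50%
  triggers a warning recommending the series solver; the migrated mass is
  additionally capped at the wall inventory so the approximation can never
  violate mass conservation.
* **Eigenfunction series**: for a one-sided slab of thickness L,
  `M_t/M_∞ = 1 − Σ_n 8/((2n+1)²π²) · exp(−D(2n+1)²π²t/(4L²))`, truncated
  when the next term falls below 1e-6 of the remaining release. The series
  is cross-checked in the test suite against an independent
  method-of-lines finite-difference solution of the same boundary-value
  problem.

The wall thickness (0.03 cm, a typical bottle wall) only matters through
the depletion correction of the series solver, which is negligible in
every default scenario. Migration is exactly linear in c_P,0 and hence in
the non-food fraction, so scenario rescaling (`scale_migration`) is exact:
a 20% fraction quadruples every migration and divides every safety factor
by four.

## Survey tables and group statistics

The bundled fixture transcribes the published survey verbatim: 110
substance rows over six categories with sample counts 6, 4, 6, 7, 6, 7.
Group means are arithmetic means over **all** samples of a category with
non-detects counted as zero — the only convention that reproduces the
published summary values (benzene: 0.9 mg/kg in one of six samples →
0.15 mg/kg).

Four rows carry a `discrepancy` flag where the printed source disagrees
with itself: a nonanal row printed with octanal's molecular weight and CAS
number, and three printed group means that arithmetic over the printed
sample values cannot reproduce (2-butanone 20.7 vs 20.37 in the sanitary
category; benzaldehyde 1.29 vs 0.13 and benzoic acid 0.96 vs 1.37 in the
shower-gel category). The fixture stores the printed values and the tests
exempt exactly the flagged rows from the ±0.05 mg/kg reproduction check.

Pooling of a category's unknowns (`aggregate_unknowns`) sums the printed
per-substance group means where available, because the published pooled
value (1.82 mg/kg for the seven sanitary-category unknowns, rounded up to
2 mg/kg) is the sum of the printed — not the recomputed — means;
`use_printed_means=False` selects recomputed means instead. The
representative molecular weight is the midpoint of the union of the
constituents' estimated ranges (130–160 g/mol → 145 g/mol). Unknowns
outside the sanitary category carry the same default 130–160 g/mol range,
explicitly as an assumption.

## Safety routing

The operative screening rule is deliberately simple:

* substances with (corrected) genotoxic potential — and all unidentified
  substances, under the worst-case assumption that they are genotoxic —
  are compared as exposures against the TTC-derived benchmark of
  0.0025 µg/kg bw/day;
* every other identified substance is screened against a flat 1 µg/L
  migration limit regardless of Cramer class. Cramer classes and
  class-specific TTC values are carried in the data model but not used for
  verdicts.

Curated alert overrides take precedence over the raw decision-tree flags:
benzene (a known human carcinogen missed by the rule base) and
2-ethylacrolein (mutagenic in vitro) route genotoxic; the spurious alerts
on aliphatic aldehydes, benzaldehyde, carvone, eugenol, anisaldehyde and
2-hydroxybiphenyl are dismissed.

**Volatile solvents.** Ethanol, 2-butanone and similar very volatile
substances reach 100–1000 mg/kg in the containers but are removed by
super-clean processes at ≥ 99% efficiency. Rather than dropping them, the
verdict re-applies a 99% cleaning efficiency before screening, which keeps
the "safe after realistic cleaning" claim testable. Identified solvents
are recognized by name (configurable list); unidentified substances are
classified volatile when they elute at ≤ 2.2 min in the survey's GC
method — the solvent window (ethanol 1.8 min, 2-butanone 2.1 min). This
retention-time convention is this package's design choice: the
solvent-region unknowns of the antifreeze category (up to 23 mg/kg at
1.7–2.2 min) are physically volatile solvents, and evaluating them as
non-volatile genotoxic unknowns at an assumed 145 g/mol would
misrepresent both their identity and their removal behaviour.

`evaluate_all` issues one verdict per substance at its group-mean
concentration, plus one pooled-unknowns verdict per category over the
non-volatile unknowns. Records that cannot be evaluated are reported as
such, never raised mid-sweep.

## Synthetic surveys

`generate_tables` emulates the fixture's statistical shape: per-category
substance counts ~ Poisson(18); each substance detected in a given sample
with probability 0.35; ordinary concentrations log-normal with median
1.5 mg/kg and log-dispersion 1.0 (so > 95% of detected values fall below
10 mg/kg, matching the observed predominance of sub-10 mg/kg levels);
one sparse volatile-solvent record per category with log-uniform
100–1000 mg/kg hits; 20% of substances emitted unidentified with a ±15
g/mol molecular-weight range; left-censoring at the 1 mg/kg detection
limit. One integer seed drives a single generator stream, so equal seeds
give bit-identical tables. It does not emulate instrument response,
retention-time structure beyond the volatility convention, co-elution, or
between-category composition differences — so passing pipeline tests on
synthetic tables demonstrates schema and logic closure, not chemical
realism. `recover_summaries` closes the loop by re-estimating the
log-normal parameters from a generated table and reporting the censored
fraction (the naive estimates are biased upward under censoring, which the
report makes visible rather than correcting).

## Numerical and scale choices

* Series truncation at 1e-6 relative; solver cross-validation tolerance
  1%; all scenario quantities double-precision.
* Test-suite problem sizes: parameter-recovery and distribution-shape
  checks use ~1e4 generated concentration values, which keeps the whole
  suite under half a minute while leaving Monte-Carlo error far below the
  asserted tolerances.
* The degenerate inputs are defined, not fatal: zero source migrates
  nothing; a substance with zero observed exposure has an infinite safety
  margin; a category without unknowns pools to an empty aggregate; an
  all-censored synthetic table reports recovery as undefined.

## Known limitations

* Single-temperature storage only; no temperature profiles, multilayer
  walls or swelling/plasticization effects.
* The Welle-type correlation is a room-temperature calibration, not the
  full activation-energy model; at 25 °C and 40–300 g/mol it is an
  interpolation between two anchors, and it refuses other temperatures.
* Exposure is the single deterministic infant scenario; no probabilistic
  exposure, no adult scenarios, no margin-of-exposure comparison.
* Cramer classification is carried as curated data; the decision-tree
  software that produced it is not re-implemented.
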