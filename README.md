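# rpetsafe

Safety evaluation of recycled-PET (rPET) beverage bottles contaminated by
co-collected **non-food PET containers**.

When post-consumer PET bottles are recollected for bottle-to-bottle
recycling, containers whose first use was a non-food product (dishwashing
detergents, antifreeze, mouthwashes, sanitary cleaners, shampoos, shower
gels) inevitably enter the feed stream, carrying absorbed product
ingredients — solvents, flavours, and occasionally substances with
genotoxic potential. `rpetsafe` implements the full evaluation chain that
turns measured contaminant concentrations in such containers into a
consumer-risk verdict:

1. **Survey tables** — a bundled transcription of a 36-container market
   survey across six non-food product categories: per-sample concentrations
   in the PET wall (mg/kg), Cramer classes, structural alerts for
   (non-)genotoxic carcinogenicity, and curated corrections of spurious or
   missed alerts.
2. **Scenario chain** — dilution by the non-food fraction *f* of the feed
   stream and attenuation by the super-clean cleaning efficiency *η*:
   `c_P,0 = c_nonfood · f · (1 − η)`.
3. **Migration modelling** — Fickian release of the wall residue into the
   beverage over the storage period, with diffusion coefficients from
   either the conservative **Piringer A_P model**
   (`D = 10⁴ · exp(A_P′ − τ/T − 0.1351·M^⅔ + 0.003·M − 10454/T)` cm²/s,
   with A_P′ = 3.1 and τ = 1577 K for PET) or a more realistic PET-specific
   **Welle-type correlation** calibrated log-linearly in molecular weight at
   25 °C. The solver offers the semi-infinite square-root-of-time closed
   form (`m/A = 2·c_vol·√(Dt/π)`) and a finite-slab eigenfunction series.
4. **Exposure and TTC routing** — infant dietary exposure
   (`migration × 0.75 L/day ÷ 5 kg`), screened against the genotoxic TTC
   benchmark of 0.0025 µg/kg bw/day or, for non-genotoxic substances, a
   flat 1 µg/L migration limit. Unidentified substances are treated as
   genotoxic worst cases, individually and pooled per category.

A synthetic-survey generator with the same CSV schema (log-normal bulk
concentrations, sparse 100–1000 mg/kg volatile-solvent hits, censoring at
the ~1 mg/kg detection limit, a configurable share of unknowns) supports
testing and sensitivity experiments without the fixture.

Intended users: packaging-migration modellers, recycling-process evaluators
and food-safety risk assessors who want the published scenario arithmetic as
inspectable, re-runnable code.

## Worked example: benzene

Benzene (M = 78.1 g/mol) was found at 0.9 mg/kg in one of six dishwashing
containers — a group mean of 0.15 mg/kg — and is a known human carcinogen,
so it is routed against the genotoxic TTC benchmark:

```python
from rpetsafe import (ScenarioConfig, load_tables, get_model, group_mean,
                      chain_concentration, migrate, exposure, safety_factor)

survey = load_tables()
cfg = ScenarioConfig()              # 5% non-food, 90% cleaning, 365 d at 25 °C
piringer = get_model("piringer")

benzene = survey.find("Benzene", "i")
c_mean = group_mean(benzene, survey.categories["i"])
c_p0 = chain_concentration(c_mean, cfg.nonfood_fraction, cfg.cleaning_efficiency)
result = migrate(c_p0, piringer(benzene.molecular_weight, cfg.temperature), cfg)
expo = exposure(result.migration, cfg.consumption, cfg.body_weight)
```

which prints

```
group mean          : 0.15 mg/kg PET
c_P,0 in bottle wall: 7.50e-04 mg/kg
D (Piringer, 25 °C) : 7.10e-14 cm²/s
migration (1 year)  : 0.00106 µg/L
infant exposure     : 0.000160 µg/kg bw/day
margin below TTC    : 15.7×
```

i.e. even under the conservative diffusion model and worst-case 90%
cleaning, benzene from a 5% non-food fraction stays more than an order of
magnitude below the genotoxic TTC benchmark; with the realistic Welle-type
model the margin grows to ~49×. The whole-table sweep
(`evaluate_all(survey)`) returns `no_concern` for every substance and every
pooled-unknowns surrogate, and migrations scale exactly fourfold when the
non-food fraction is raised from 5% to 20%.

## Command line

```bash
rpetsafe evaluate --model piringer --fraction 0.05 --cleaning 0.90
rpetsafe curve --model piringer --model welle --m-min 50 --m-max 250
rpetsafe simulate --seed 1
rpetsafe recover --seed 1
```

`evaluate` writes a verdict CSV, a summary JSON and a manifest sufficient
to reproduce the report; `curve` exports the generic migration-vs-molecular-
weight curves (optionally as a PNG).

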