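# rubiscotemp

A toolkit for working with the temperature dependence of Rubisco kinetics.
It standardizes published kinetic parameters — the CO2/O2 specificity factor
(Sc/o), the Michaelis constants for CO2 and O2 (Kc, Ko) and the carboxylase
turnover rate (kcat) — onto a common aqueous-chemistry basis, fits Arrhenius
temperature responses per species, aggregates species into plant functional
groups, and simulates Rubisco-limited photosynthesis from the resulting group
parameters.

## Why standardization matters

In vitro Rubisco assays depend on two aqueous-chemistry constants that many
original studies approximated:

* the **acidity constant of dissolved CO2**, pKa(T, Is), used to convert the
  bicarbonate added to an assay into dissolved CO2.  Assay buffers have
  substantial ionic strength (database average 0.117 M), which lowers pKa
  well below its pure-water value.  At 35 °C and pH 8.17, using the
  pure-water pKa of 6.32 instead of the corrected 6.067 overstates dissolved
  CO2 — and hence Kc — **1.78-fold**;
* **Henry's law constants** for O2 and CO2, used to convert gas mixing ratios
  into dissolved concentrations.  Assay media salt gases out: the O2 constant
  in a chloroplast-like medium at 25 °C is 83 950 Pa m³ mol⁻¹, so studies
  that used the common pure-water value of 80 040 overstated Ko by 4.9%.

This package implements both corrections (plus gas/liquid basis conversion),
applies them record-by-record, and propagates the standardized values through
Arrhenius fitting and functional-group aggregation.

## Worked example

```python
from rubiscotemp import physchem, fvcb
from rubiscotemp.standardize import AssayConditions, AssayRecord, standardize_record

# aqueous-chemistry constants at assay conditions
print(round(physchem.pka_co2(308.15, 0.117), 3))            # pKa at 35 °C, Is 0.117 M
print(round(physchem.henry_constant("O2", 298.15, 0.11), 0))  # H_O2, chloroplast medium

# standardize a reported Kc measured at 35 °C with the pure-water pKa
rec = AssayRecord(
    species="Oryza sativa", trait="Kc", t_meas=308.15, value=41.0,
    conditions=AssayConditions(pH=8.17, pKa_used=6.32, ionic_strength=0.117))
res = standardize_record(rec)
print(f"corrected Kc = {res.value_corrected:.1f} uM (factor {res.factor:.3f})")

# simulate Rubisco-limited assimilation for two functional groups
cool = fvcb.curve(fvcb.group_params("C3-cool"), 400.0)
warm = fvcb.curve(fvcb.group_params("C3-warm"), 400.0)
print(f"A(25 C): cool {cool.a[cool.temps_c == 25.0][0]:.1f}, warm {warm.a[warm.temps_c == 25.0][0]:.1f}")
sa, ss = fvcb.compare_curves(cool, warm)
print(f"sigma_A = {sa:.2f}, sigma_S = {ss:.2f}")
```

Output:

```
6.067
83950.0
corrected Kc = 23.0 uM (factor 0.562)
A(25 C): cool 26.7, warm 29.0
sigma_A = 4.17, sigma_S = 27.28
```

## Command line

```
rubiscotemp constants --temp-c 25 --ionic-strength 0.117
rubiscotemp standardize-value --trait Kc --value 41 --temp-c 35 --ph 8.17 --pka-used 6.32
rubiscotemp synth --seed 5                     # synthetic compilation + truth sidecar
rubiscotemp pipeline synthetic_records.csv     # standardize -> fit -> summarize
rubiscotemp simulate --group C3-cool --cc 400
rubiscotemp compare --group-a C3-cool --group-b C3-warm --cc 400
```

## Modules

| Module | Contents |
| --- | --- |
| `physchem` | pKa(T, Is), Henry's law constants, salting-out, buffer-speciation ionic strength |
| `standardize` | record-level corrections, gas/liquid phase conversion |
| `tempresponse` | Arrhenius and polynomial fitting, Q10, standard 5–45 °C responses |
| `compendium` | functional-group classification, species deduplication, group summaries, full pipeline |
| `fvcb` | Rubisco-limited FvCB photosynthesis simulation and curve comparison |
| `synthetic` | seed-deterministic synthetic compilations with known truth |
| `datasets` | embedded reference tables (Henry constants, per-source fits, group summaries) |

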