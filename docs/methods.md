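# Methods

This document records the scientific model the package implements, the
provenance of its constants, and the known limits of agreement with the
published reference values embedded in `rubiscotemp.datasets`.

## 1. Aqueous chemistry (`physchem`)

**CO2 acidity constant.**  pKa(T, Is) is an empirical regression with a
temperature part

```
pKa_T(T) = a1/T + a2·log10(T) + a3·T + a4
```

(a = 16400, 211.56, −0.1291, −533.63; T in kelvin) and an ionic part that is
a cubic polynomial in ionic strength with a √Is leading term
(s = 0.3252, 0.3830, −0.2692, −0.8503).  The temperature part reproduces the
accepted pure-water values (6.37 at 25 °C declining with temperature).  The
ionic polynomial as printed has the wrong sign and magnitude for the ionic
depression it must produce, so a single scale factor λ on the ionic part is
calibrated at import time by least squares against the two anchor values the
regression is required to reproduce — pKa = 6.112 at (25 °C, 0.117 M) and
6.067 at (35 °C, 0.117 M) — giving λ ≈ −1.749.  Both anchors are then
reproduced to < 0.001.  The coefficient set records
`provenance = "calibrated"`.

**Henry's law constants.**  The pure-water constant per gas is a cubic in
absolute temperature (O2: 0.051816 T³ − 42.437 T² + 12977.3 T − 1388072.1;
CO2: −0.01081 T³ + 10.1188 T² − 3065.93 T + 304097.1; Pa m³ mol⁻¹).  It
reproduces the eight tabulated pure-water cells at 15–45 °C within 0.1% and
extrapolates acceptably to the accepted 0–50 °C window (≈3% at 0 °C, ≈1.6%
at 50 °C against independent solubility data).

**Salting-out.**  The medium effect is a Setchenov factor
`H_s/H_0 = exp(ks(T)·Cs)` with `ks(T) = e1 + e2/T + e3·ln T` per gas.  The
published six-coefficient salting polynomial could not be made to reproduce
the tabulated chloroplast-medium cells under any reading (magnitudes off by
orders); the printed coefficients are retained on the coefficient object for
provenance, and the operative `ks(T)` is calibrated by least squares to the
tabulated chloroplast/pure ratios at 15–45 °C and Cs = 0.11 M.  All eight
chloroplast cells are then reproduced within 0.06%.  The implied O2
solubility reduction at 0.11 M falls from ~3% at 0 °C to ~1.5% at 50 °C.

**Ionic strength of assay buffers.**  Buffers are speciated at the stated pH
via Henderson–Hasselbalch using per-substance pKa(T, Is) entries from an
editable table; Is = ½ Σ c z² counts every ionic species, including one
monovalent counter-ion per charged buffer species; the computation iterates
to a fixed point (|ΔIs| < 1e-6, ≤ 100 iterations, loud failure with the last
two iterates otherwise).

## 2. Standardization (`standardize`)

For liquid-basis records the corrections are concentration ratios:

* **Kc**: multiply by `f(pH, pKa_corr) / f(pH, pKa_used)` where
  `f(pH, pKa) = 1/(1 + 10^(pH−pKa))` is the CO2 fraction of dissolved
  inorganic carbon.  At (pH 8.17, pKa 6.32 → 6.067, 35 °C) this is a
  1.78-fold downward correction.
* **Ko**: multiply by `H_used/H_corr` for O2 (4.9% downward for
  80 040 → 83 950 at 25 °C).
* **Sc/o**: both factors, each inverted relative to its Michaelis-constant
  direction (CO2 sits in the numerator role of the specificity ratio); a
  separate path re-standardizes liquid Sc/o values derived from gas-basis
  data with the authors' own Henry pair.
* **kcat** is a turnover rate and is never corrected.

All corrections are exact inverses under swapping "used" and "corrected"
constants — the property the synthetic generator exploits.  Gas↔liquid basis
conversion uses `liquid (mol/L) = gas × P/(1000·H)` for Kc/Ko and
`liquid = gas × H_CO2/H_O2` for Sc/o, with chloroplast-medium Henry
constants.  Records lacking required metadata are passed through flagged,
never silently defaulted.

## 3. Temperature responses (`tempresponse`)

Each species × trait × source series is fitted with
`f(T) = exp(c − ΔHa/(R·T))` by minimizing the **raw-scale** sum of squared
residuals (Levenberg–Marquardt, tolerances 1e-14), seeded by the log-linear
closed form, which also serves as an independent oracle on noiseless data.
Two-point series get the exact interpolant with the fit quality r recorded
as "not determined" (None).  Q10 over [T, T+10] follows in closed form,
`exp[(ΔHa/R)(1/T − 1/(T+10))]`, identical to the fitted value ratio.
Standard responses are reported at 5/15/25/35/45 °C with extrapolation
flagged when a standard temperature lies outside the fitted range.

## 4. Aggregation (`compendium`)

Seed plants are classified C4 (by pathway), C3-warm (growth temperature
≥ 25 °C, including C3–C4 intermediates) or C3-cool (< 25 °C); other
organisms keep their phylogenetic group.  Species measured by several
sources contribute their across-source mean; sources flagged as unreliable
fits are dropped before that mean.  Group statistics are arithmetic means
with SE = sample SD/√n; members flagged for poor convergence are excluded
from the group parameter means but still count toward group size, and
members whose upper-interval Q10s are unreliable are excluded from the
25–35/35–45 °C Q10 means only — all mirroring the footnote conventions of
the embedded per-source table.

Recomputing the embedded group summary table from the embedded per-source
table reproduces every Sc/o and Kc cell within one unit in the last printed
decimal (the members are themselves printed rounded, so half an ulp of
re-rounding plus the propagated member rounding is the attainable
agreement).  Two cells sit exactly at that boundary (C4 Sc/o c: −4.70
recomputed vs −4.8 printed; C4 Kc ΔHa: 34.76 vs 34.7), consistent with the
source having averaged unrounded per-source values.

## 5. Photosynthesis simulation (`fvcb`)

Rubisco-limited gross assimilation:

```
A(T) = Vcmax(T) · Cc/(Cc + Kc_air(T)) · (1 − Γ*(T)/Cc)
Vcmax(T) = kcat(T) × 29 µmol sites m⁻²,  kcat(25 °C) = 2.5 s⁻¹
Kc_air = Kc_gas (1 + O/Ko_gas),  Γ* = 0.5 · O/Sc/o_gas,  O = 0.21
```

kcat uses a peaked response,
`kcat(T) = kcat25 · g(T)/g(298.15)` with
`g(T) = exp(−ΔHa/RT) / (1 + exp((ΔS·T − ΔHd)/RT))`, normalized so the
25 °C value is pinned exactly; ΔHd/ΔS per group place the optimum at
55–58 °C.  Liquid-basis Sc/o, Kc, Ko (group Arrhenius parameters; shared Ko
c = 9.9, ΔHa = 9.7 kJ mol⁻¹) are converted to the gas basis with
chloroplast-medium Henry constants evaluated **at each grid temperature**;
P = 101 325 Pa.  The default grid is 5–50 °C in 1 °C steps.  Curves are
compared by σA (mean absolute difference) and σS (mean squared difference;
no square root, hence labelled msd).

### Agreement with the published simulation statistics

With the published group parameters:

| statistic | computed | reported | status |
| --- | --- | --- | --- |
| mean A, 5–20 °C, Cc = 120, cool set | 7.32 | ≈7.7 | −5%, within tolerance |
| mean A, 30–50 °C, Cc = 400, warm set | 41.40 | ≈40.8 | +1.5%, within tolerance |
| σA(cool, warm), 5–50 °C, Cc = 400 | 4.17 | ≈2.9 | **+44%, not reproduced** |

The σA discrepancy was investigated systematically: grid step (1 vs 5 °C),
evaluating Henry conversions at a fixed 25 °C instead of per-temperature,
and dropping the photorespiration factor all move the value by a few percent
or in the wrong direction.  The one sensitivity of the right size is the
cool-group Kc parameter set: including the flagged high-altitude outlier in
the cool Kc mean (c = 17.6, ΔHa = 37.7 instead of 18.8/40.5) yields
σA ≈ 2.2, bracketing the reported 2.9 from below, which suggests the
reported figure was produced with a cool-Kc parameterization differing from
the final published group means.  The package keeps the published group
parameters; the corresponding acceptance test is left failing rather than
adjusted.

## 6. Synthetic compilations (`synthetic`)

The generator draws per-species (c, ΔHa) per trait from normal distributions
centred on the published group means with between-species SD = SE·√n,
evaluates noise-free Arrhenius values at the configured assay temperatures,
applies multiplicative lognormal noise (default CV 5%, mean-one), and then
**inverts** the standardization corrections using pure-water constants at
each temperature, so that standardizing the emitted records with the correct
constants recovers the noisy truth exactly.  Records follow the same CSV
schema as real compilations; the truth sidecar is emitted separately.  A
two-temperature variant exercises the exact-interpolant fit branch.  All
output is fully determined by the seed.  Scope limits: no raw assay traces
and no phylogenetic covariance between species.
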