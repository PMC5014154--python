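"""Published reference values used as inputs and cross-checks.

Three small tables from the Rubisco temperature-response compendium are
embedded here as plain data:

* ``HENRY_TABLE`` — Henry's law constants for CO2 and O2 in pure water and in
  chloroplast-like medium (Cs = 0.11 M) at 15/25/35/45 degC;
* ``source_fits()`` — the per-source Arrhenius fits (scaling constant ``c``,
  activation energy ``dha_kj`` in kJ mol-1, goodness-of-fit ``r``, the four
  Q10 values and the species' growth temperature) for Sc/o, Kc and Ko,
  including the exclusion flags from the published footnotes;
* ``GROUP_SUMMARY`` — the group-level means +- SE of the same parameters, plus the
  kcat rows, which parameterize the photosynthesis simulation.

These are printed values, recorded to the precision they were published at;
they serve as inputs to the aggregation and simulation layers and as anchors
for the physchem calibration, never as a stand-in for computation.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "HENRY_TABLE",
    "source_fits",
    "GROUP_SUMMARY",
    "KO_SHARED",
    "SIMULATION_GROUPS",
    "PKA_PURE_WATER_35C",
    "TYPICAL_HENRY_O2_USED",
    "MEAN_ASSAY_PH",
    "MEAN_ASSAY_IS",
]

#: Henry's law constants (Pa m3 mol-1) at 15/25/35/45 degC.
HENRY_TABLE = {
    "CO2": {"pure": (2186.0, 2982.0, 3867.0, 4777.0),
            "chloroplast": (2230.0, 3041.0, 3944.0, 4873.0)},
    "O2": {"pure": (67510.0, 82080.0, 97430.0, 113870.0),
           "chloroplast": (69260.0, 83950.0, 99370.0, 115840.0)},
}
HENRY_TABLE_TEMPS_C = (15.0, 25.0, 35.0, 45.0)

#: Pure-water pKa of dissolved CO2 at 35 degC as used by early assay studies.
PKA_PURE_WATER_35C = 6.32
#: Pure-water pKa range commonly used at 25 degC.
PKA_PURE_WATER_25C_RANGE = (6.35, 6.37)
#: Typical pure-water Henry constant for O2 used in original studies at 25 degC.
TYPICAL_HENRY_O2_USED = 80040.0
#: Database-average Kc-assay pH and ionic strength at 25 degC.
MEAN_ASSAY_PH = 8.17
MEAN_ASSAY_IS = 0.117


# ---------------------------------------------------------------------------
# Per-source Arrhenius fits (trait, group, species, source, Tmeas range degC,
# c, dHa kJ/mol, r, Q10 x4, Tgrowth degC, flags)
# ---------------------------------------------------------------------------
# flags: "2T" = only two assay temperatures (r not determined, upper Q10s
# absent); "xgroup" = excluded from group averages (poor solver convergence);
# "xspecies" = excluded from the species' across-source average.

_SOURCE_ROWS = [
    # --- Sc/o ---
    ("Sc/o", "Proteobacteria", "Rhodospirillum rubrum", "Jordan & Ogren 1984", 2, 25,
     -5.2, -18.8, None, (0.75, 0.77, None, None), 33, "2T"),
    ("Sc/o", "Cyanobacteria", "Thermosynechococcus elongatus", "Gubernator et al. 2008", 15, 45,
     -13.0, -43.0, 0.998, (0.52, 0.55, 0.57, 0.59), 56, ""),
    ("Sc/o", "Cyanobacteria", "Synechococcus lividus", "Zhu et al. 1998", 15, 35,
     -0.9, -11.7, 0.999, (0.84, 0.85, 0.86, 0.87), 45, ""),
    ("Sc/o", "Rhodophyta", "Galdieria partita", "Uemura et al. 1997", 15, 45,
     -10.3, -38.7, 0.991, (0.56, 0.58, 0.60, 0.62), 45, ""),
    ("Sc/o", "Bacillariophyta", "Chaetoceros socialis", "Haslam et al. 2005", 10, 25,
     -3.2, -18.7, 0.975, (0.76, 0.77, 0.78, 0.80), 10, ""),
    ("Sc/o", "Bacillariophyta", "Skeletonema costatum", "Haslam et al. 2005", 10, 25,
     -7.1, -28.1, 0.992, (0.66, 0.67, 0.69, 0.71), 20, ""),
    ("Sc/o", "Bacillariophyta", "Thalassiosira antarctica", "Haslam et al. 2005", 10, 25,
     -3.8, -20.3, 0.963, (0.74, 0.75, 0.77, 0.78), -0.5, ""),
    ("Sc/o", "Bacillariophyta", "Thalassiosira hyalina", "Haslam et al. 2005", 10, 25,
     -2.9, -18.1, 0.991, (0.76, 0.78, 0.79, 0.80), 2, ""),
    ("Sc/o", "C3-cool", "Atriplex glabriuscula", "Badger & Collatz 1977", 15, 35,
     -0.1, -12.1, 0.984, (0.76, 0.81, 0.90, 1.05), 20, "xgroup,xq10hi"),
    ("Sc/o", "C3-cool", "Avena sativa", "Hermida-Carrera et al. 2016", 15, 35,
     -2.9, -18.4, 0.998, (0.76, 0.77, 0.79, 0.80), 20, ""),
    ("Sc/o", "C3-cool", "Hordeum vulgare", "Orr et al. 2016", 15, 35,
     -2.5, -17.4, 0.997, (0.77, 0.78, 0.80, 0.81), 20, ""),
    ("Sc/o", "C3-cool", "Lysimachia minoricensis", "Galmes et al. 2005", 15, 35,
     -4.2, -21.4, 0.989, (0.73, 0.74, 0.76, 0.77), 20, ""),
    ("Sc/o", "C3-cool", "Mentha aquatica", "Galmes et al. 2005", 15, 35,
     -4.2, -21.4, 0.996, (0.73, 0.74, 0.76, 0.77), 20, ""),
    ("Sc/o", "C3-cool", "Spinacia oleracea", "Uemura et al. 1997", 15, 35,
     -3.5, -19.8, 0.996, (0.74, 0.76, 0.77, 0.78), 16, ""),
    ("Sc/o", "C3-cool", "Spinacia oleracea", "Zhu et al. 1998", 15, 35,
     -2.6, -17.6, 0.999, (0.77, 0.78, 0.79, 0.81), 16, ""),
    ("Sc/o", "C3-cool", "Spinacia oleracea", "Jordan & Ogren 1984", 7, 25,
     -3.8, -20.5, 0.999, (0.77, 0.75, 0.74, 0.74), 16, ""),
    ("Sc/o", "C3-cool", "Spinacia oleracea", "Yokota & Kitaoka 1985", 5, 45,
     -1.4, -14.7, 0.987, (0.80, 0.81, 0.83, 0.84), 16, "xspecies"),
    ("Sc/o", "C3-cool", "Triticum aestivum", "Haslam et al. 2005", 10, 25,
     -3.7, -20.5, 0.997, (0.74, 0.75, 0.76, 0.78), 20, ""),
    ("Sc/o", "C3-cool", "Triticum aestivum", "Hermida-Carrera et al. 2016", 15, 35,
     -3.4, -19.7, 0.999, (0.74, 0.76, 0.77, 0.79), 20, ""),
    ("Sc/o", "C3-cool", "Urtica atrovirens", "Galmes et al. 2005", 15, 35,
     -4.1, -21.1, 0.999, (0.73, 0.74, 0.76, 0.77), 20, ""),
    ("Sc/o", "C3-warm", "Beta maritima ssp. marcosii", "Galmes et al. 2005", 15, 35,
     -4.4, -22.0, 0.999, (0.72, 0.73, 0.75, 0.76), 25, ""),
    ("Sc/o", "C3-warm", "Beta maritima ssp. maritima", "Galmes et al. 2005", 15, 35,
     -4.5, -22.4, 0.994, (0.71, 0.73, 0.75, 0.76), 25, ""),
    ("Sc/o", "C3-warm", "Diplotaxis ibicensis", "Galmes et al. 2005", 15, 35,
     -5.6, -24.9, 0.998, (0.69, 0.71, 0.72, 0.74), 25, ""),
    ("Sc/o", "C3-warm", "Flaveria cronquistii", "Perdomo et al. 2015", 10, 40,
     -3.5, -19.5, 0.985, (0.75, 0.76, 0.77, 0.79), 30, ""),
    ("Sc/o", "C3-warm", "Flaveria pringlei", "Zhu et al. 1998", 15, 35,
     -3.0, -18.9, 0.999, (0.75, 0.77, 0.78, 0.79), 30, ""),
    ("Sc/o", "C3-warm", "Flaveria pringlei", "Perdomo et al. 2015", 10, 40,
     -4.0, -20.8, 0.991, (0.73, 0.75, 0.76, 0.77), 30, ""),
    ("Sc/o", "C3-warm", "Hypericum balearicum", "Galmes et al. 2005", 15, 35,
     -4.7, -22.6, 0.999, (0.71, 0.73, 0.74, 0.76), 25, ""),
    ("Sc/o", "C3-warm", "Kundmannia sicula", "Galmes et al. 2005", 15, 35,
     -4.9, -23.2, 0.996, (0.71, 0.72, 0.74, 0.75), 25, ""),
    ("Sc/o", "C3-warm", "Limonium gibertii", "Galmes et al. 2005", 15, 35,
     -5.1, -24.1, 0.999, (0.70, 0.71, 0.73, 0.74), 25, ""),
    ("Sc/o", "C3-warm", "Limonium magallufianum", "Galmes et al. 2005", 15, 35,
     -5.2, -24.3, 0.998, (0.69, 0.71, 0.73, 0.74), 25, ""),
    ("Sc/o", "C3-warm", "Pistacia lentiscus", "Galmes et al. 2005", 15, 35,
     -4.4, -22.0, 0.999, (0.72, 0.74, 0.75, 0.76), 25, ""),
    ("Sc/o", "C3-warm", "Rhamnus alaternus", "Galmes et al. 2005", 15, 35,
     -4.7, -22.8, 0.998, (0.71, 0.73, 0.74, 0.76), 25, ""),
    ("Sc/o", "C3-warm", "Rhamnus ludovici-salvatoris", "Galmes et al. 2005", 15, 35,
     -5.2, -24.0, 0.993, (0.70, 0.71, 0.73, 0.74), 25, ""),
    ("Sc/o", "C3-warm", "Trifolium repens", "Lehnherr et al. 1985", 10, 25,
     -2.8, -18.0, 0.983, (0.76, 0.78, 0.79, 0.80), 25, ""),
    ("Sc/o", "C3-warm", "Urtica membranacea", "Galmes et al. 2005", 15, 35,
     -3.7, -20.4, 0.998, (0.74, 0.75, 0.77, 0.78), 25, ""),
    ("Sc/o", "C3-warm", "Flaveria angustifolia", "Perdomo et al. 2015", 10, 40,
     -4.3, -21.6, 0.978, (0.72, 0.74, 0.75, 0.77), 30, ""),
    ("Sc/o", "C3-warm", "Flaveria floridana", "Perdomo et al. 2015", 10, 40,
     -3.8, -20.4, 0.989, (0.74, 0.75, 0.77, 0.78), 30, ""),
    ("Sc/o", "C4", "Amaranthus hybridus", "Jordan & Ogren 1984", 5, 35,
     -7.0, -27.9, 0.998, (0.66, 0.68, 0.69, 0.71), 30, ""),
    ("Sc/o", "C4", "Flaveria bidentis", "Perdomo et al. 2015", 10, 40,
     -3.8, -20.0, 0.994, (0.74, 0.76, 0.77, 0.78), 30, ""),
    ("Sc/o", "C4", "Flaveria trinervia", "Perdomo et al. 2015", 10, 40,
     -4.3, -21.4, 0.999, (0.73, 0.74, 0.76, 0.77), 30, ""),
    ("Sc/o", "C4", "Saccharum officinarum", "Hermida-Carrera et al. 2016", 15, 35,
     -4.9, -23.0, 0.997, (0.71, 0.72, 0.74, 0.75), 30, ""),
    ("Sc/o", "C4", "Setaria viridis", "Boyd et al. 2015", 10, 40,
     -4.6, -21.3, 0.950, (0.73, 0.74, 0.76, 0.77), 25, ""),
    ("Sc/o", "C4", "Zea mays", "Hermida-Carrera et al. 2016", 15, 35,
     -3.6, -20.1, 0.999, (0.74, 0.75, 0.77, 0.78), 30, ""),
    # --- Kc ---
    ("Kc", "Cyanobacteria", "Anabaena variabilis", "Badger 1980", 15, 40,
     20.8, 38.8, 0.989, (1.79, 1.72, 1.66, 1.61), 35, ""),
    ("Kc", "Bacillariophyta", "Fragilariopsis cylindrus", "Young et al. 2015", 0, 20,
     17.7, 34.9, None, (1.69, 1.63, None, None), 5, "2T"),
    ("Kc", "Bacillariophyta", "Thalassiosira weissflogii", "Young et al. 2015", 0, 20,
     21.1, 43.0, None, (1.91, 1.83, None, None), 22, "2T"),
    ("Kc", "C3-cool", "Atriplex glabriuscula", "Badger & Collatz 1977", 5, 35,
     15.9, 32.4, 0.987, (1.63, 1.57, 1.53, 1.49), 20, ""),
    ("Kc", "C3-cool", "Avena sativa", "Hermida-Carrera et al. 2016", 15, 35,
     20.2, 44.2, 0.999, (1.94, 1.86, 1.78, 1.72), 20, ""),
    ("Kc", "C3-cool", "Espeletia schultzii", "Castrillo 1995", 5, 35,
     11.9, 23.7, 0.988, (1.50, 1.38, 1.31, 1.26), 20, "xgroup"),
    ("Kc", "C3-cool", "Hordeum vulgare", "Hermida-Carrera et al. 2016", 15, 35,
     16.2, 34.6, 0.999, (1.68, 1.62, 1.57, 1.53), 20, ""),
    ("Kc", "C3-cool", "Spinacia oleracea", "Jordan & Ogren 1984", 7, 35,
     22.4, 50.2, 0.994, (2.12, 2.02, 1.93, 1.85), 16, ""),
    ("Kc", "C3-cool", "Triticum aestivum", "Hermida-Carrera et al. 2016", 15, 35,
     19.0, 41.3, 0.990, (1.86, 1.78, 1.72, 1.66), 20, ""),
    ("Kc", "C3-warm", "Flaveria cronquistii", "Perdomo et al. 2015", 10, 40,
     22.9, 51.8, 0.996, (2.18, 2.07, 1.97, 1.89), 30, ""),
    ("Kc", "C3-warm", "Flaveria pringlei", "Perdomo et al. 2015", 10, 40,
     17.7, 38.6, 0.983, (1.78, 1.72, 1.66, 1.60), 30, ""),
    ("Kc", "C3-warm", "Glycine max", "Laing et al. 1974", 15, 35,
     17.8, 37.0, 0.963, (1.74, 1.68, 1.62, 1.57), 25, ""),
    ("Kc", "C3-warm", "Oryza sativa", "Wei et al. 1994", 20, 40,
     25.6, 58.4, 0.978, (2.40, 2.26, 2.15, 2.05), 25, ""),
    ("Kc", "C3-warm", "Trifolium repens", "Lehnherr et al. 1985", 10, 25,
     22.5, 48.9, 0.999, (2.08, 1.98, 1.90, 1.82), 25, ""),
    ("Kc", "C3-warm", "Flaveria angustifolia", "Perdomo et al. 2015", 10, 40,
     20.0, 44.0, 0.998, (1.93, 1.85, 1.78, 1.71), 30, ""),
    ("Kc", "C3-warm", "Flaveria floridana", "Perdomo et al. 2015", 10, 40,
     19.9, 44.1, 0.999, (1.94, 1.85, 1.78, 1.72), 30, ""),
    ("Kc", "C4", "Flaveria bidentis", "Perdomo et al. 2015", 10, 40,
     15.4, 31.6, 0.993, (1.61, 1.56, 1.51, 1.47), 30, ""),
    ("Kc", "C4", "Flaveria trinervia", "Perdomo et al. 2015", 10, 40,
     15.4, 31.7, 0.992, (1.61, 1.56, 1.51, 1.47), 30, ""),
    ("Kc", "C4", "Saccharum officinarum", "Hermida-Carrera et al. 2016", 15, 35,
     17.8, 35.8, 0.998, (1.71, 1.65, 1.60, 1.55), 30, ""),
    ("Kc", "C4", "Setaria viridis", "Boyd et al. 2015", 10, 40,
     24.7, 51.8, 0.990, (2.17, 2.06, 1.97, 1.89), 25, ""),
    ("Kc", "C4", "Zea mays", "Hermida-Carrera et al. 2016", 15, 35,
     12.6, 22.9, 0.971, (1.41, 1.38, 1.35, 1.32), 30, ""),
    # --- Ko ---
    ("Ko", "C3-cool", "Atriplex glabriuscula", "Badger & Collatz 1977", 15, 35,
     19.7, 34.6, 0.996, (1.68, 1.62, 1.57, 1.53), 20, ""),
    ("Ko", "C3-cool", "Spinacia oleracea", "Jordan & Ogren 1984", 7, 35,
     6.2, 0.0, None, (1.00, 1.00, 1.00, 1.00), 16, ""),
    ("Ko", "C3-warm", "Glycine max", "Laing et al. 1974", 15, 35,
     3.7, -5.5, 0.989, (0.92, 0.93, 0.93, 0.94), 25, ""),
    ("Ko", "C3-warm", "Trifolium repens", "Lehnherr et al. 1985", 10, 25,
     10.1, 9.3, 0.927, (1.15, 1.14, 1.13, 1.12), 25, ""),
    ("Ko", "C4", "Setaria viridis", "Boyd et al. 2015", 10, 40,
     4.5, -4.0, 0.738, (0.94, 0.95, 0.95, 0.95), 25, ""),
]


def source_fits() -> pd.DataFrame:
    """Per-source Arrhenius temperature-response fits as a tidy frame.

    Columns: trait, group, species, source, tmin_c, tmax_c, c, dha_kj, r,
    q10_5_15 ... q10_35_45, tgrowth_c, exclude_from_group,
    exclude_from_species, two_temperatures.
    """
    rows = []
    for (trait, group, species, source, tmin, tmax, c, dha, r, q10, tg, flags) in _SOURCE_ROWS:
        rows.append({
            "trait": trait, "group": group, "species": species, "source": source,
            "tmin_c": float(tmin), "tmax_c": float(tmax),
            "c": c, "dha_kj": dha, "r": r,
            "q10_5_15": q10[0], "q10_15_25": q10[1],
            "q10_25_35": q10[2], "q10_35_45": q10[3],
            "tgrowth_c": float(tg),
            "exclude_from_group": "xgroup" in flags,
            "exclude_from_species": "xspecies" in flags,
            "q10_upper_unreliable": "xq10hi" in flags,
            "two_temperatures": "2T" in flags,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Group-level summaries (means +- SE); dHa in kJ mol-1
# ---------------------------------------------------------------------------

GROUP_SUMMARY = {
    "Sc/o": {
        "C3-cool": {"n": 8, "c": -3.5, "c_se": 0.3, "dha_kj": -19.9, "dha_se": 0.6,
                    "q10": (0.74, 0.77, 0.78, 0.79)},
        "C3-warm": {"n": 16, "c": -4.4, "c_se": 0.2, "dha_kj": -22.0, "dha_se": 0.5,
                    "q10": (0.72, 0.74, 0.75, 0.76)},
        "C3-average": {"n": 24, "c": -4.1, "c_se": 0.2, "dha_kj": -21.4, "dha_se": 0.4,
                       "q10": (0.73, 0.75, 0.76, 0.77)},
        "C4": {"n": 6, "c": -4.8, "c_se": 0.5, "dha_kj": -22.3, "dha_se": 1.2,
               "q10": (0.72, 0.73, 0.75, 0.76)},
    },
    "Kc": {
        "C3-cool": {"n": 6, "c": 18.8, "c_se": 1.2, "dha_kj": 40.5, "dha_se": 3.2,
                    "q10": (1.79, 1.71, 1.64, 1.58)},
        "C3-warm": {"n": 7, "c": 20.9, "c_se": 1.1, "dha_kj": 46.1, "dha_se": 2.8,
                    "q10": (2.01, 1.92, 1.84, 1.77)},
        "C3-average": {"n": 12, "c": 20.0, "c_se": 0.8, "dha_kj": 43.8, "dha_se": 2.2,
                       "q10": (1.91, 1.82, 1.75, 1.68)},
        "C4": {"n": 5, "c": 17.2, "c_se": 2.0, "dha_kj": 34.7, "dha_se": 4.7,
               "q10": (1.70, 1.64, 1.59, 1.54)},
    },
    "kcat": {
        "C3-cool": {"n": 12, "c": 22.3, "c_se": 0.8, "dha_kj": 55.3, "dha_se": 2.0,
                    "q10": (2.30, 2.18, 2.07, 1.98)},
        "C3-warm": {"n": 14, "c": 26.0, "c_se": 1.4, "dha_kj": 64.5, "dha_se": 3.5,
                    "q10": (2.68, 2.51, 2.36, 2.23)},
        "C3-average": {"n": 26, "c": 24.3, "c_se": 0.9, "dha_kj": 60.2, "dha_se": 2.3,
                       "q10": (2.51, 2.35, 2.23, 2.11)},
        "C4": {"n": 10, "c": 21.3, "c_se": 0.5, "dha_kj": 52.8, "dha_se": 1.3,
               "q10": (2.22, 2.10, 2.00, 1.91)},
    },
}

#: Ko temperature parameters shared across plant functional groups (average of
#: the four in vitro C3 sources; liquid molar basis, value in uM).
KO_SHARED = {"c": 9.9, "dha_kj": 9.7}

#: Deactivation energy (J mol-1) and entropy term (J mol-1 K-1) of kcat per
#: functional group, plus the Arrhenius parameter sets the simulation consumes.
SIMULATION_GROUPS = {
    "C3-cool": {"dhd": 305000.0, "ds": 929.0},
    "C3-warm": {"dhd": 220000.0, "ds": 664.0},
    "C3-average": {"dhd": 258000.0, "ds": 782.0},
}
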