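"""Standardization of reported Rubisco kinetic values.

Published Kc, Ko and Sc/o values depend on the aqueous-chemistry constants
each lab assumed: the CO2 acidity constant used to convert added bicarbonate
into dissolved CO2 (affects Kc and Sc/o) and the Henry's law constants used
to convert gas mixing ratios into dissolved O2/CO2 (affects Ko and Sc/o).
This module rescales reported values onto a common set of constants and
converts between gas- and liquid-phase bases.

Conventions: liquid-phase Kc/Ko are molar (mol L-1), gas-phase values are
mixing ratios (mol mol-1); Sc/o is dimensionless on either basis (the basis
changes its scale ~30-fold).  kcat is a turnover rate and is never corrected.
All corrections are exact inverses of themselves under swapping the "used"
and "corrected" constant sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from . import physchem
from .physchem import CHLOROPLAST_CS, REFERENCE_IS

__all__ = [
    "AssayConditions",
    "AssayRecord",
    "StandardizationResult",
    "co2_fraction",
    "correct_kc",
    "correct_ko",
    "correct_sco",
    "convert_phase",
    "restandardize_sco_liquid",
    "standardization_error",
    "standardize_record",
]

TRAITS = ("Sc/o", "Kc", "Ko", "kcat")
PHASES = ("liquid", "gas")
ATM = 101325.0


class StandardizationError(ValueError):
    """A correction was requested but a required assay constant is unknown."""


def _require(name: str, value) -> float:
    if value is None:
        raise StandardizationError(f"cannot standardize: {name} is unknown")
    return float(value)


@dataclass(frozen=True)
class AssayConditions:
    """Assay metadata needed to standardize one reported value.

    Any field may be ``None`` ("unknown"); corrections that need it fail
    loudly rather than defaulting silently.
    """

    pH: Optional[float] = None
    pKa_used: Optional[float] = None
    henry_used_O2: Optional[float] = None
    henry_used_CO2: Optional[float] = None
    ionic_strength: Optional[float] = None
    solute_conc: Optional[float] = None
    pressure: float = ATM

    def __post_init__(self) -> None:
        if self.pKa_used is not None and not 5.5 < self.pKa_used < 7.0:
            raise ValueError(f"pKa_used {self.pKa_used} outside the plausible (5.5, 7.0)")
        for name in ("henry_used_O2", "henry_used_CO2"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class AssayRecord:
    """One reported kinetic value at one measurement temperature."""

    species: str
    trait: str
    t_meas: float  # K
    value: float
    phase: str = "liquid"
    conditions: AssayConditions = field(default_factory=AssayConditions)
    phylo_group: str = "Spermatophyta"
    pathway: str = "C3"
    tgrowth: Optional[float] = None  # degC
    source: str = ""

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.value <= 0:
            raise ValueError("kinetic values must be positive")


# ---------------------------------------------------------------------------
# Elementary corrections
# ---------------------------------------------------------------------------

def co2_fraction(pH: float, pKa: float) -> float:
    """Fraction of dissolved inorganic carbon present as CO2 under the
    single-equilibrium (bicarbonate-only) model: 1 / (1 + 10^(pH - pKa))."""
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    return 1.0 / (1.0 + 10.0 ** (pH - pKa))


def correct_kc(kc_reported: float, pH, pKa_used, pKa_corrected) -> float:
    """Rescale a reported liquid-phase Kc to the corrected acidity constant.

    The reported value inherits the CO2 concentration its authors computed
    from added bicarbonate with their pKa; rescaling by the ratio of CO2
    fractions replaces that with the corrected constant.  Identity when the
    two constants agree.
    """
    pH = _require("pH", pH)
    pKa_used = _require("pKa_used", pKa_used)
    return kc_reported * co2_fraction(pH, pKa_corrected) / co2_fraction(pH, pKa_used)


def correct_ko(ko_reported: float, henry_used_O2, henry_corrected_O2) -> float:
    """Rescale a reported liquid-phase Ko between O2 Henry constants."""
    hu = _require("henry_used_O2", henry_used_O2)
    return ko_reported * hu / henry_corrected_O2


def correct_sco(sco_reported: float, pH, pKa_used, pKa_corrected,
                henry_used_O2, henry_corrected_O2) -> float:
    """Rescale a reported Sc/o for both the CO2 acidity constant (inverse of
    the Kc correction — CO2 appears in Sc/o's numerator role) and the O2
    Henry constant (as in the Ko correction)."""
    pH = _require("pH", pH)
    pKa_used = _require("pKa_used", pKa_used)
    hu = _require("henry_used_O2", henry_used_O2)
    return (sco_reported
            * co2_fraction(pH, pKa_used) / co2_fraction(pH, pKa_corrected)
            * hu / henry_corrected_O2)


def restandardize_sco_liquid(sco_reported: float, henry_used_O2, henry_used_CO2,
                             henry_corrected_O2, henry_corrected_CO2) -> float:
    """Re-standardize a liquid-phase Sc/o whose authors converted from the gas
    phase with their own pair of Henry constants."""
    hu_o2 = _require("henry_used_O2", henry_used_O2)
    hu_co2 = _require("henry_used_CO2", henry_used_CO2)
    return sco_reported * (hu_o2 * henry_corrected_CO2) / (hu_co2 * henry_corrected_O2)


def standardization_error(corrected: float, reported: float) -> float:
    """Percent deviation 100 (corrected - reported) / reported."""
    if reported <= 0:
        raise ValueError("reported value must be positive")
    return 100.0 * (corrected - reported) / reported


# ---------------------------------------------------------------------------
# Phase conversion
# ---------------------------------------------------------------------------

def convert_phase(trait: str, value: float, direction: str, temperature: float,
                  solute_conc: float = CHLOROPLAST_CS, pressure: float = ATM,
                  coeffs=None) -> float:
    """Convert a trait value between gas (mol mol-1) and liquid (molar) bases.

    Kc/Ko:  liquid [mol L-1] = gas x P / (1000 Hpc);  Sc/o:  liquid = gas x
    Hpc,CO2 / Hpc,O2.  ``direction`` is ``"gas->liquid"`` or
    ``"liquid->gas"``; round trips are identities.  kcat has no phase.
    """
    if trait == "kcat":
        raise ValueError("kcat is phase-free and cannot be converted")
    if trait not in ("Kc", "Ko", "Sc/o"):
        raise ValueError(f"unknown trait {trait!r}")
    if direction not in ("gas->liquid", "liquid->gas"):
        raise ValueError(f"unknown direction {direction!r}")
    coeffs = coeffs or physchem.DEFAULT_COEFFICIENTS
    h_co2 = physchem.henry_constant("CO2", temperature, solute_conc, coeffs)
    h_o2 = physchem.henry_constant("O2", temperature, solute_conc, coeffs)
    if trait == "Sc/o":
        factor = h_co2 / h_o2
    else:
        gas = "CO2" if trait == "Kc" else "O2"
        h = h_co2 if gas == "CO2" else h_o2
        # gas mixing ratio -> partial pressure -> mol m-3 -> mol L-1
        factor = pressure / h / 1000.0
    return value * factor if direction == "gas->liquid" else value / factor


# ---------------------------------------------------------------------------
# Record-level dispatch
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardizationResult:
    """Outcome of standardizing one record: the value on the common liquid
    basis, the multiplicative factor applied, and status flags."""

    record: AssayRecord
    value_corrected: float
    factor: float
    standardized: bool
    note: str = ""


def _corrected_constants(record: AssayRecord, coeffs):
    cond = record.conditions
    ionic = cond.ionic_strength if cond.ionic_strength is not None else REFERENCE_IS
    cs = cond.solute_conc if cond.solute_conc is not None else CHLOROPLAST_CS
    pka_c = physchem.pka_co2(record.t_meas, ionic, coeffs)
    h_o2 = physchem.henry_constant("O2", record.t_meas, cs, coeffs)
    h_co2 = physchem.henry_constant("CO2", record.t_meas, cs, coeffs)
    return pka_c, h_o2, h_co2


def standardize_record(record: AssayRecord, coeffs=None) -> StandardizationResult:
    """Standardize one record to the common constant set.

    kcat records pass through untouched.  Gas-phase records are converted to
    the liquid basis with chloroplast-medium Henry constants.  Liquid-phase
    records are rescaled from the constants their authors used; records
    lacking the needed metadata are passed through flagged "not standardized".
    """
    coeffs = coeffs or physchem.DEFAULT_COEFFICIENTS
    cond = record.conditions

    if record.trait == "kcat":
        return StandardizationResult(record, record.value, 1.0, True,
                                     "turnover rate: no chemistry correction")

    if record.phase == "gas":
        cs = cond.solute_conc if cond.solute_conc is not None else CHLOROPLAST_CS
        out = convert_phase(record.trait, record.value, "gas->liquid",
                            record.t_meas, cs, cond.pressure, coeffs)
        return StandardizationResult(record, out, out / record.value, True,
                                     "gas basis converted to liquid")

    pka_c, h_o2_c, h_co2_c = _corrected_constants(record, coeffs)
    try:
        if record.trait == "Kc":
            out = correct_kc(record.value, cond.pH, cond.pKa_used, pka_c)
        elif record.trait == "Ko":
            out = correct_ko(record.value, cond.henry_used_O2, h_o2_c)
        else:  # Sc/o
            if cond.henry_used_CO2 is not None and cond.pKa_used is None:
                out = restandardize_sco_liquid(
                    record.value, cond.henry_used_O2, cond.henry_used_CO2,
                    h_o2_c, h_co2_c)
            else:
                out = correct_sco(record.value, cond.pH, cond.pKa_used,
                                  pka_c, cond.henry_used_O2, h_o2_c)
    except StandardizationError as exc:
        return StandardizationResult(record, record.value, 1.0, False, str(exc))
    return StandardizationResult(record, out, out / record.value, True)
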