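"""Aqueous chemistry of Rubisco assay media.

The three physico-chemical quantities every standardization step needs are

* the first acidity constant of dissolved CO2, pKa(T, Is), which sets how much
  of the bicarbonate added to an assay exists as CO2 at the assay pH;
* Henry's law constants Hpc (Pa m3 mol-1) for O2 and CO2 in pure water, which
  set how gas mixing ratios map to dissolved concentrations; and
* the salting-out factor by which solutes raise Hpc (gases are less soluble in
  ionic media).

pKa is an empirical Debye-Hueckel-style regression in absolute temperature and
ionic strength; Hpc,0 is a cubic in absolute temperature per gas; salting-out
is a Setchenov-type exponential in solute concentration with a
temperature-dependent coefficient.  The ionic part of the pKa regression and
the Setchenov coefficients are calibrated at import time by least squares
against the anchor values the regressions are required to reproduce (pKa 6.112
at 25 degC / 6.067 at 35 degC for the database-average ionic strength 0.117 M,
and the chloroplast-medium Henry constants at 15-45 degC for Cs = 0.11 M);
their provenance is recorded as "calibrated" on the coefficient set.

Buffer speciation (the fixed-point ionic-strength computation) lives here as
well, driven by a small editable table of buffer-substance pKa values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "R",
    "T25",
    "CHLOROPLAST_CS",
    "REFERENCE_IS",
    "PhyschemCoefficients",
    "BufferComponent",
    "BufferComposition",
    "DEFAULT_COEFFICIENTS",
    "DEFAULT_BUFFER_TABLE",
    "load_buffer_table",
    "pka_co2",
    "henry_pure",
    "salting_factor",
    "henry_constant",
    "ionic_strength",
]

#: Universal gas constant, J mol-1 K-1.
R = 8.314
#: Reference temperature, K (25 degC).
T25 = 298.15
#: Default chloroplast solute concentration, mol L-1 (KCl equivalent).
CHLOROPLAST_CS = 0.11
#: Database-average assay ionic strength, mol L-1.
REFERENCE_IS = 0.117

GASES = ("O2", "CO2")

# pKa anchor values: (temperature K, ionic strength M, pKa).
_PKA_ANCHORS = ((298.15, 0.117, 6.112), (308.15, 0.117, 6.067))

# Henry's law constants (Pa m3 mol-1) at 15/25/35/45 degC used to calibrate the
# salting-out coefficients: pure water vs chloroplast medium (Cs = 0.11 M).
_HENRY_ANCHOR_TEMPS = (288.15, 298.15, 308.15, 318.15)
_HENRY_ANCHORS = {
    "CO2": {"pure": (2186.0, 2982.0, 3867.0, 4777.0),
            "chloroplast": (2230.0, 3041.0, 3944.0, 4873.0)},
    "O2": {"pure": (67510.0, 82080.0, 97430.0, 113870.0),
           "chloroplast": (69260.0, 83950.0, 99370.0, 115840.0)},
}


@dataclass(frozen=True)
class PhyschemCoefficients:
    """Empirical coefficient sets for the aqueous-chemistry regressions.

    ``pka_a``/``pka_s`` are the temperature and ionic coefficients of the pKa
    regression; ``henry_pure`` maps gas -> cubic coefficients; ``henry_salt``
    maps gas -> the six published salting coefficients (kept for provenance).
    ``pka_ionic_scale`` and ``setchenov`` hold the calibrated operative values
    (see module docstring); ``provenance`` records whether they came from the
    printed coefficients directly or from anchor calibration.
    """

    pka_a: tuple[float, float, float, float] = (16400.0, 211.56, -0.1291, -533.63)
    pka_s: tuple[float, float, float, float] = (0.3252, 0.3830, -0.2692, -0.8503)
    henry_pure: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            "O2": (0.051816, -42.437, 12977.3, -1388072.1),
            "CO2": (-0.01081, 10.1188, -3065.93, 304097.1),
        }
    )
    henry_salt: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "O2": (1.4565, -178.90, -6.0556, -0.7818, 54.240, 0.10796),
            "CO2": (-2.8858, -173.31, 18.718, 0.41177, -32.719, -0.050167),
        }
    )
    pka_ionic_scale: float = field(default=float("nan"))
    setchenov: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    provenance: str = "printed"

    def with_calibration(self) -> "PhyschemCoefficients":
        """Return a copy with the ionic/salting coefficients calibrated to the
        anchor values (least squares); provenance becomes ``"calibrated"``."""
        scale = _calibrate_pka_scale(self)
        setch = {gas: _calibrate_setchenov(self, gas) for gas in GASES}
        return PhyschemCoefficients(
            pka_a=self.pka_a,
            pka_s=self.pka_s,
            henry_pure=self.henry_pure,
            henry_salt=self.henry_salt,
            pka_ionic_scale=scale,
            setchenov=setch,
            provenance="calibrated",
        )


def _pka_temperature_part(coeffs: PhyschemCoefficients, tk) -> np.ndarray:
    a1, a2, a3, a4 = coeffs.pka_a
    tk = np.asarray(tk, dtype=float)
    return a1 / tk + a2 * np.log10(tk) + a3 * tk + a4


def _pka_ionic_poly(coeffs: PhyschemCoefficients, ionic) -> np.ndarray:
    s1, s2, s3, s4 = coeffs.pka_s
    ionic = np.asarray(ionic, dtype=float)
    return s1 * np.sqrt(ionic) + s2 * ionic + s3 * ionic**2 + s4 * ionic**3


def _calibrate_pka_scale(coeffs: PhyschemCoefficients) -> float:
    # One scale factor on the ionic polynomial, least squares on the anchors.
    p = np.array([_pka_ionic_poly(coeffs, a[1]) for a in _PKA_ANCHORS])
    resid = np.array([a[2] - _pka_temperature_part(coeffs, a[0]) for a in _PKA_ANCHORS])
    return float(p @ resid / (p @ p))


def _henry_pure_raw(coeffs: PhyschemCoefficients, gas: str, tk) -> np.ndarray:
    c1, c2, c3, c4 = coeffs.henry_pure[gas]
    tk = np.asarray(tk, dtype=float)
    return c1 * tk**3 + c2 * tk**2 + c3 * tk + c4


def _calibrate_setchenov(coeffs: PhyschemCoefficients, gas: str) -> tuple[float, float, float]:
    # ks(T) = e1 + e2/T + e3 ln T fitted to ln(H_chloroplast/H_pure)/0.11 at
    # the four anchor temperatures (H_pure from the cubic itself so that the
    # product reproduces the chloroplast anchors).
    tk = np.array(_HENRY_ANCHOR_TEMPS)
    chl = np.array(_HENRY_ANCHORS[gas]["chloroplast"])
    pure = _henry_pure_raw(coeffs, gas, tk)
    y = np.log(chl / pure) / CHLOROPLAST_CS
    design = np.column_stack([np.ones_like(tk), 1.0 / tk, np.log(tk)])
    e, *_ = np.linalg.lstsq(design, y, rcond=None)
    return tuple(float(v) for v in e)


#: Default coefficient set: printed values with anchor-calibrated ionic terms.
DEFAULT_COEFFICIENTS = PhyschemCoefficients().with_calibration()


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def _check_gas(gas: str) -> None:
    if gas not in GASES:
        raise ValueError(f"unknown gas {gas!r}: expected one of {GASES}")


def pka_co2(temperature: float, ionic_strength: float,
            coeffs: PhyschemCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """First acidity constant of dissolved CO2 at ``temperature`` (K) and
    ``ionic_strength`` (mol L-1).

    Valid for 268 < T < 333 K and 0 <= Is <= 1.05 M (slightly beyond the
    0-50 degC / 0-1.042 M range of the source data).
    """
    if not 268.0 < temperature < 333.0:
        raise ValueError(
            f"temperature {temperature} K outside the valid window (268, 333) K")
    if not 0.0 <= ionic_strength <= 1.05:
        raise ValueError(
            f"ionic strength {ionic_strength} M outside the valid window [0, 1.05] M")
    scale = coeffs.pka_ionic_scale
    if math.isnan(scale):
        scale = _calibrate_pka_scale(coeffs)
    return float(_pka_temperature_part(coeffs, temperature)
                 + scale * _pka_ionic_poly(coeffs, ionic_strength))


def henry_pure(gas: str, temperature: float,
               coeffs: PhyschemCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Henry's law constant (Pa m3 mol-1) of ``gas`` in pure water.

    Cubic in absolute temperature; calibrated over 10-45 degC and verified to
    extrapolate within ~3% down to 0 degC and ~1.6% up to 50 degC, so the
    accepted window is 273.15-323.15 K (0-50 degC).
    """
    _check_gas(gas)
    if not 273.15 <= temperature <= 323.15 + 1e-9:
        raise ValueError(
            f"temperature {temperature} K outside the valid window "
            "[273.15, 323.15] K")
    return float(_henry_pure_raw(coeffs, gas, temperature))


def salting_factor(gas: str, temperature: float, solute_conc: float,
                   coeffs: PhyschemCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Salting-out ratio Hpc,s / Hpc,0 at ``solute_conc`` mol L-1 of
    non-dissociated salt (KCl basis).

    Equals 1 in pure water and grows with solute concentration; the implied
    O2 solubility reduction at 0.11 M falls from ~3% at 0 degC to ~1.5% at
    50 degC.
    """
    _check_gas(gas)
    if solute_conc < 0:
        raise ValueError("solute concentration must be non-negative")
    if solute_conc > 1.0:
        raise ValueError("solute concentration above the 1.0 M validity limit")
    setch = coeffs.setchenov.get(gas) or _calibrate_setchenov(coeffs, gas)
    e1, e2, e3 = setch
    ks = e1 + e2 / temperature + e3 * math.log(temperature)
    return float(math.exp(ks * solute_conc))


def henry_constant(gas: str, temperature: float, solute_conc: float = CHLOROPLAST_CS,
                   coeffs: PhyschemCoefficients = DEFAULT_COEFFICIENTS) -> float:
    """Henry's law constant (Pa m3 mol-1) in a solute-bearing medium:
    pure-water value times the salting-out factor.  The chloroplast preset is
    ``solute_conc = 0.11`` M."""
    return henry_pure(gas, temperature, coeffs) * salting_factor(
        gas, temperature, solute_conc, coeffs)


# ---------------------------------------------------------------------------
# Buffer speciation / ionic strength
# ---------------------------------------------------------------------------

#: Default buffer-substance table.  Weak (monoprotic) substances carry the
#: 25 degC pKa, its temperature slope (per K) and an optional sqrt(Is) slope
#: plus the charge of the *acid* form; strong electrolytes carry the full
#: dissociation charge set as (charge, stoichiometry) pairs.  Values are
#: standard literature figures; zwitterionic buffers default to
#: Is-independent pKa.
DEFAULT_BUFFER_TABLE: dict[str, dict] = {
    "tris": {"pka25": 8.07, "dpka_dt": -0.028, "dpka_dsqrt_is": -0.10, "z_acid": 1},
    "hepes": {"pka25": 7.55, "dpka_dt": -0.014, "dpka_dsqrt_is": 0.0, "z_acid": 0},
    "bicine": {"pka25": 8.35, "dpka_dt": -0.018, "dpka_dsqrt_is": 0.0, "z_acid": 0},
    "phosphate": {"pka25": 7.20, "dpka_dt": -0.0028, "dpka_dsqrt_is": -0.5, "z_acid": -1},
    "kcl": {"charges": [[1, 1], [-1, 1]]},
    "nacl": {"charges": [[1, 1], [-1, 1]]},
    "mgcl2": {"charges": [[2, 1], [-1, 2]]},
    "nahco3": {"charges": [[1, 1], [-1, 1]]},
}


def load_buffer_table(path) -> dict[str, dict]:
    """Load a buffer-substance table from a YAML file (same schema as
    :data:`DEFAULT_BUFFER_TABLE`)."""
    with open(path) as fh:
        table = yaml.safe_load(fh)
    if not isinstance(table, dict):
        raise ValueError("buffer table must be a mapping of substance -> entry")
    return {str(k).lower(): v for k, v in table.items()}


@dataclass(frozen=True)
class BufferComponent:
    """One substance in an assay buffer: name (keys the substance table) and
    total concentration in mol L-1."""

    substance: str
    concentration: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError(f"{self.substance}: concentration must be >= 0")


@dataclass(frozen=True)
class BufferComposition:
    """An assay buffer: its components, pH and temperature (K)."""

    components: tuple[BufferComponent, ...]
    pH: float
    temperature: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if not 0.0 < self.pH < 14.0:
            raise ValueError(f"pH {self.pH} outside (0, 14)")


def _component_pka(entry: dict, temperature: float, ionic: float) -> float:
    pka = entry["pka25"] + entry.get("dpka_dt", 0.0) * (temperature - T25)
    pka += entry.get("dpka_dsqrt_is", 0.0) * math.sqrt(max(ionic, 0.0))
    return pka


def _component_contribution(entry: dict, conc: float, pH: float,
                            temperature: float, ionic: float) -> tuple[float, float | None]:
    """Ionic-strength contribution (1/2 sum c z^2 including a monovalent
    counter-ion per charged buffer species) and converged pKa (None for strong
    electrolytes)."""
    if "charges" in entry:
        contrib = 0.5 * sum(conc * stoich * z * z for z, stoich in entry["charges"])
        return contrib, None
    pka = _component_pka(entry, temperature, ionic)
    f_base = 1.0 / (1.0 + 10.0 ** (pka - pH))  # deprotonated fraction
    z_acid = entry.get("z_acid", 0)
    z_base = z_acid - 1
    contrib = 0.0
    for z, frac in ((z_acid, 1.0 - f_base), (z_base, f_base)):
        if z != 0:
            c_ion = conc * frac
            # charged buffer species plus its monovalent counter-ions
            contrib += 0.5 * (c_ion * z * z + c_ion * abs(z))
    return contrib, pka


def ionic_strength(buffer: BufferComposition,
                   table: Mapping[str, dict] | None = None,
                   start: float = 0.0,
                   tol: float = 1e-6,
                   max_iter: int = 100) -> tuple[float, dict[str, float]]:
    """Fixed-point ionic strength of an assay buffer.

    Speciates every weak component at the given pH (Henderson-Hasselbalch)
    using pKa(T, Is) at the current ionic strength, recomputes
    Is = 1/2 sum(c z^2) over all ionic species (counting monovalent
    counter-ions of charged buffer species), and iterates to |dIs| < ``tol``.
    Returns the converged Is and the per-component pKa at convergence.
    """
    table = dict(DEFAULT_BUFFER_TABLE if table is None else table)
    for comp in buffer.components:
        if comp.substance.lower() not in table:
            raise KeyError(f"no buffer-table entry for substance {comp.substance!r}")

    is_now = float(start)
    prev = is_now
    for _ in range(max_iter):
        total = 0.0
        pka_table: dict[str, float] = {}
        for comp in buffer.components:
            entry = table[comp.substance.lower()]
            contrib, pka = _component_contribution(
                entry, comp.concentration, buffer.pH, buffer.temperature, is_now)
            total += contrib
            if pka is not None:
                pka_table[comp.substance] = pka
        prev, is_now = is_now, total
        if abs(is_now - prev) < tol:
            return is_now, pka_table
    raise RuntimeError(
        f"ionic strength iteration did not converge in {max_iter} steps; "
        f"last iterates {prev:.8f}, {is_now:.8f}")
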