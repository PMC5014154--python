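"""Rubisco-limited photosynthesis simulation (FvCB model).

Given a functional group's Arrhenius parameters for Sc/o, Kc and kcat (plus
the shared Ko response and the peaked deactivation of kcat), the simulator
evaluates the Farquhar-von Caemmerer-Berry Rubisco-limited gross assimilation

    A(T) = Vcmax(T) * Cc / (Cc + Kc,air(T)) * (1 - Gamma*(T) / Cc)

on a temperature grid at fixed chloroplastic CO2 mixing ratio Cc.  Vcmax is
kcat(T) times the catalytic-site density; Kc,air = Kc,gas (1 + O / Ko,gas) is
the effective Michaelis constant in ambient O2; Gamma* = 0.5 O / Sc/o,gas is
the photorespiratory compensation point.  Liquid-basis kinetics are converted
to the gas basis with chloroplast-medium Henry constants evaluated at each
grid temperature.  Gross assimilation is simulated (no mitochondrial
respiration term).  Curves are compared by their mean absolute difference
(sigma_A) and mean squared difference (sigma_S, labelled msd: the published
definition carries no square root).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import datasets, physchem
from .physchem import CHLOROPLAST_CS, R, T25
from .standardize import ATM
from .tempresponse import arrhenius_value

__all__ = [
    "PhotoParams",
    "SimulationCurve",
    "group_params",
    "kcat_peaked",
    "gas_kinetics_at",
    "a_rubisco",
    "curve",
    "compare_curves",
]

#: Default temperature grid, degC.
DEFAULT_GRID_C = np.arange(5.0, 50.0 + 1e-9, 1.0)


@dataclass(frozen=True)
class PhotoParams:
    """Kinetic parameter set for one simulated Rubisco.

    Arrhenius pairs are (scaling constant, activation energy J mol-1); Kc and
    Ko are on the liquid molar basis with values in uM, Sc/o on the liquid
    basis (dimensionless).  ``kcat25`` (s-1) pins the turnover rate at 25
    degC; ``site_density`` is the areal concentration of catalytic sites
    (umol m-2), so Vcmax(25 degC) = kcat25 x site_density (umol m-2 s-1).
    ``dhd``/``ds`` are the deactivation energy (J mol-1) and entropy term
    (J mol-1 K-1) of the peaked kcat response.
    """

    sco: tuple[float, float]
    kc: tuple[float, float]
    kcat_dha: float
    dhd: float
    ds: float
    ko: tuple[float, float] = (
        datasets.KO_SHARED["c"], datasets.KO_SHARED["dha_kj"] * 1000.0)
    kcat25: float = 2.5
    site_density: float = 29.0
    o2: float = 0.21
    pressure: float = ATM
    solute_conc: float = CHLOROPLAST_CS

    @property
    def vcmax25(self) -> float:
        return self.kcat25 * self.site_density


def group_params(group: str) -> PhotoParams:
    """Build the published parameter set for ``"C3-cool"``, ``"C3-warm"`` or
    ``"C3-average"``."""
    if group not in datasets.SIMULATION_GROUPS:
        raise ValueError(
            f"unknown simulation group {group!r}: expected one of "
            f"{tuple(datasets.SIMULATION_GROUPS)}")
    deact = datasets.SIMULATION_GROUPS[group]
    sco = datasets.GROUP_SUMMARY["Sc/o"][group]
    kc = datasets.GROUP_SUMMARY["Kc"][group]
    kcat = datasets.GROUP_SUMMARY["kcat"][group]
    return PhotoParams(
        sco=(sco["c"], sco["dha_kj"] * 1000.0),
        kc=(kc["c"], kc["dha_kj"] * 1000.0),
        kcat_dha=kcat["dha_kj"] * 1000.0,
        dhd=deact["dhd"],
        ds=deact["ds"],
    )


@dataclass(frozen=True)
class SimulationCurve:
    """A_Rubisco (umol m-2 s-1) on a temperature grid at fixed Cc."""

    temps_c: np.ndarray
    cc: float
    a: np.ndarray

    def mean_over(self, t_lo: float, t_hi: float) -> float:
        """Mean assimilation over the inclusive temperature window [t_lo, t_hi]."""
        mask = (self.temps_c >= t_lo - 1e-9) & (self.temps_c <= t_hi + 1e-9)
        if not mask.any():
            raise ValueError("window contains no grid points")
        return float(self.a[mask].mean())


def kcat_peaked(temperature: float, params: PhotoParams):
    """Peaked (optimum-bearing) turnover rate, s-1.

    kcat(T) = kcat25 * g(T)/g(298.15) with
    g(T) = exp(-dHa/(R T)) / (1 + exp((dS T - dHd)/(R T))), guaranteeing
    kcat(25 degC) = kcat25 exactly; the deactivation term creates a thermal
    optimum near dHd/dS.
    """
    def g(tk):
        tk = np.asarray(tk, dtype=float)
        return (np.exp(-params.kcat_dha / (R * tk))
                / (1.0 + np.exp((params.ds * tk - params.dhd) / (R * tk))))
    out = params.kcat25 * g(temperature) / g(T25)
    return float(out) if np.isscalar(temperature) else out


def gas_kinetics_at(temperature: float, params: PhotoParams,
                    coeffs=None) -> tuple[float, float]:
    """Effective gas-basis kinetics at one temperature (K): (Kc,air in
    umol mol-1, Gamma* in umol mol-1).

    Liquid-basis Kc (uM), Ko (uM) and Sc/o are evaluated from their Arrhenius
    parameters and converted to the gas basis with chloroplast-medium Henry
    constants at the same temperature.
    """
    coeffs = coeffs or physchem.DEFAULT_COEFFICIENTS
    h_co2 = physchem.henry_constant("CO2", temperature, params.solute_conc, coeffs)
    h_o2 = physchem.henry_constant("O2", temperature, params.solute_conc, coeffs)
    # uM -> mol m-3 is a factor 1e-3; mixing ratio = conc * H / P
    kc_gas = arrhenius_value(*params.kc, temperature) * 1e-3 * h_co2 / params.pressure
    ko_gas = arrhenius_value(*params.ko, temperature) * 1e-3 * h_o2 / params.pressure
    sco_gas = arrhenius_value(*params.sco, temperature) * h_o2 / h_co2
    kc_air = kc_gas * (1.0 + params.o2 / ko_gas)
    gamma_star = 0.5 * params.o2 / sco_gas
    return kc_air * 1e6, gamma_star * 1e6


def a_rubisco(temperature: float, cc: float, params: PhotoParams,
              coeffs=None) -> float:
    """Rubisco-limited gross assimilation (umol m-2 s-1) at one temperature
    (K) and chloroplastic CO2 mixing ratio ``cc`` (umol mol-1)."""
    if cc <= 0:
        raise ValueError("Cc must be positive")
    kc_air, gamma_star = gas_kinetics_at(temperature, params, coeffs)
    vcmax = kcat_peaked(temperature, params) * params.site_density
    return float(vcmax * cc / (cc + kc_air) * (1.0 - gamma_star / cc))


def curve(params: PhotoParams, cc: float,
          temps_c=None, coeffs=None) -> SimulationCurve:
    """Simulate A_Rubisco over a temperature grid (default 5-50 degC in
    1 degC steps) at fixed Cc (umol mol-1)."""
    temps_c = DEFAULT_GRID_C if temps_c is None else np.asarray(temps_c, dtype=float)
    if temps_c.min() < 0.0 or temps_c.max() > 60.0:
        raise ValueError("temperature grid must lie within 0-60 degC")
    a = np.array([a_rubisco(tc + 273.15, cc, params, coeffs) for tc in temps_c])
    return SimulationCurve(temps_c=temps_c, cc=float(cc), a=a)


def compare_curves(curve1: SimulationCurve, curve2: SimulationCurve) -> tuple[float, float]:
    """Mean absolute difference sigma_A and mean squared difference sigma_S
    (msd) between two curves on identical grids."""
    if curve1.temps_c.shape != curve2.temps_c.shape or \
            not np.allclose(curve1.temps_c, curve2.temps_c):
        raise ValueError("curves must share the same temperature grid")
    diff = curve1.a - curve2.a
    return float(np.mean(np.abs(diff))), float(np.mean(diff**2))
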