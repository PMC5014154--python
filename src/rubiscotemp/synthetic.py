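"""Synthetic assay compilations with known truth.

The generator emulates the structure of the published compilation: per
species, group-level Arrhenius parameters (c, dHa) are drawn for Sc/o, Kc and
kcat from normal distributions centred on the published group means with
between-species spreads of SE * sqrt(n); each species is "assayed" at a few
discrete temperatures with multiplicative lognormal noise; and the
"as-published" values are then deliberately distorted by inverting the
standardization corrections with wrong (pure-water) equilibrium constants.
Standardizing the distorted records with the correct constants therefore
recovers the noisy truth exactly, and fitting recovers the drawn parameters
up to noise — giving the whole standardize -> fit -> summarize pipeline a
known target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import datasets, physchem
from .physchem import CHLOROPLAST_CS, REFERENCE_IS
from .standardize import ATM, co2_fraction
from .tempresponse import arrhenius_value

__all__ = ["GeneratorConfig", "gen_truth", "gen_records", "gen_two_temperature_edge"]

_DEFAULT_TRAITS = ("Sc/o", "Kc", "kcat")


def _default_group_truth() -> dict:
    """Per-group (mean, SD) of c and dHa (J mol-1) per trait, with SD the
    published SE scaled back to a between-species SD."""
    out: dict = {}
    for group in ("C3-cool", "C3-warm", "C4"):
        out[group] = {}
        for trait in _DEFAULT_TRAITS:
            row = datasets.GROUP_SUMMARY[trait][group]
            sqrt_n = math.sqrt(row["n"])
            out[group][trait] = {
                "c": (row["c"], row["c_se"] * sqrt_n),
                "dha": (row["dha_kj"] * 1000.0, row["dha_se"] * 1000.0 * sqrt_n),
            }
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic compilation.

    ``species_per_group`` sets group sizes; ``truth`` the per-group normal
    (mean, SD) for each trait's (c, dHa); ``temps_c`` the assay temperatures;
    ``noise_cv`` the multiplicative lognormal coefficient of variation;
    ``corruption`` is ``"purewater"`` (records published with pure-water
    pKa/Henry constants) or ``"none"``; ``missing_metadata_fraction`` makes
    that share of records lack the assay metadata needed to standardize.
    The seed fully determines the output.
    """

    seed: int = 0
    species_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"C3-cool": 8, "C3-warm": 16, "C4": 6})
    truth: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]] = field(
        default_factory=_default_group_truth)
    traits: tuple[str, ...] = _DEFAULT_TRAITS
    temps_c: tuple[float, ...] = (15.0, 25.0, 35.0)
    noise_cv: float = 0.05
    corruption: str = "purewater"
    missing_metadata_fraction: float = 0.0
    assay_ph: float = datasets.MEAN_ASSAY_PH
    ionic_strength: float = REFERENCE_IS
    solute_conc: float = CHLOROPLAST_CS

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be >= 0")
        if self.corruption not in ("none", "purewater"):
            raise ValueError(f"unknown corruption mode {self.corruption!r}")
        if not 0.0 <= self.missing_metadata_fraction <= 1.0:
            raise ValueError("missing_metadata_fraction must be in [0, 1]")


_TGROWTH_RANGE = {"C3-cool": (10.0, 24.0), "C3-warm": (25.0, 35.0), "C4": (25.0, 35.0)}


def gen_truth(config: GeneratorConfig) -> pd.DataFrame:
    """Draw per-species true Arrhenius parameters and metadata.

    One row per species x trait: species, group, pathway, tgrowth_c, trait,
    c_true, dha_true (J mol-1).  Growth temperatures are drawn consistently
    with the group (cool < 25 <= warm).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for group in sorted(config.species_per_group):
        n = config.species_per_group[group]
        lo, hi = _TGROWTH_RANGE.get(group, (15.0, 30.0))
        pathway = "C4" if group == "C4" else "C3"
        for i in range(n):
            species = f"{group.replace('-', '_')}_sp{i:03d}"
            tgrowth = float(rng.uniform(lo, hi))
            for trait in config.traits:
                dist = config.truth[group][trait]
                c = float(rng.normal(*dist["c"]))
                dha = float(rng.normal(*dist["dha"]))
                rows.append({
                    "species": species, "group": group, "pathway": pathway,
                    "phylo_group": "Spermatophyta", "tgrowth_c": tgrowth,
                    "trait": trait, "c_true": c, "dha_true": dha,
                })
    return pd.DataFrame(rows)


def _used_constants(trait: str, temp_k: float, config: GeneratorConfig,
                    coeffs) -> dict:
    """The (possibly wrong) constants the synthetic 'study' published with."""
    pka_c = physchem.pka_co2(temp_k, config.ionic_strength, coeffs)
    h_o2_c = physchem.henry_constant("O2", temp_k, config.solute_conc, coeffs)
    if config.corruption == "purewater":
        return {"pKa_used": physchem.pka_co2(temp_k, 0.0, coeffs),
                "henry_used_O2": physchem.henry_pure("O2", temp_k, coeffs)}
    return {"pKa_used": pka_c, "henry_used_O2": h_o2_c}


def _distort(trait: str, value: float, temp_k: float, used: dict,
             config: GeneratorConfig, coeffs) -> float:
    """Invert the standardization correction: produce the value a study using
    the ``used`` constants would have published, such that standardizing with
    the correct constants returns ``value`` exactly."""
    pka_c = physchem.pka_co2(temp_k, config.ionic_strength, coeffs)
    h_o2_c = physchem.henry_constant("O2", temp_k, config.solute_conc, coeffs)
    ph = config.assay_ph
    if trait == "Kc":
        return value * co2_fraction(ph, used["pKa_used"]) / co2_fraction(ph, pka_c)
    if trait == "Ko":
        return value * h_o2_c / used["henry_used_O2"]
    if trait == "Sc/o":
        return (value
                * co2_fraction(ph, pka_c) / co2_fraction(ph, used["pKa_used"])
                * h_o2_c / used["henry_used_O2"])
    return value  # kcat: never corrected


def gen_records(truth: pd.DataFrame, config: GeneratorConfig,
                coeffs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the as-published assay-record table and the truth sidecar.

    Returns ``(records, sidecar)``: ``records`` follows the pipeline CSV
    schema (one row per species x trait x temperature, value distorted and
    noisy); ``sidecar`` additionally carries the noise-free true value so
    recovery can be scored.  The truth column never appears in ``records``.
    """
    coeffs = coeffs or physchem.DEFAULT_COEFFICIENTS
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    rec_rows, side_rows = [], []
    for _, row in truth.iterrows():
        for tc in config.temps_c:
            tk = tc + 273.15
            v_true = arrhenius_value(row["c_true"], row["dha_true"], tk)
            noise = math.exp(rng.normal(-0.5 * sigma**2, sigma)) if sigma else 1.0
            v_noisy = v_true * noise
            used = _used_constants(row["trait"], tk, config, coeffs)
            v_pub = _distort(row["trait"], v_noisy, tk, used, config, coeffs)
            missing = rng.random() < config.missing_metadata_fraction
            rec = {
                "species": row["species"], "trait": row["trait"],
                "t_meas_c": tc, "value": v_pub, "phase": "liquid",
                "phylo_group": row["phylo_group"], "pathway": row["pathway"],
                "tgrowth_c": row["tgrowth_c"],
                "source": "synthetic-study",
                "pH": None if missing else config.assay_ph,
                "pKa_used": None if missing else used["pKa_used"],
                "henry_used_O2": None if missing else used["henry_used_O2"],
                "henry_used_CO2": None,
                "ionic_strength": config.ionic_strength,
                "solute_conc": config.solute_conc,
                "pressure": ATM,
            }
            rec_rows.append(rec)
            side_rows.append({**rec, "value_true": v_noisy,
                              "value_noise_free": v_true,
                              "c_true": row["c_true"],
                              "dha_true": row["dha_true"]})
    return pd.DataFrame(rec_rows), pd.DataFrame(side_rows)


def gen_two_temperature_edge(config: GeneratorConfig,
                             temps_c: tuple[float, float] = (15.0, 25.0),
                             coeffs=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """A compilation measured at exactly two temperatures, exercising the
    exact-interpolant fit branch and the "r not determined" sentinel."""
    cfg = GeneratorConfig(
        seed=config.seed, species_per_group=config.species_per_group,
        truth=config.truth, traits=config.traits, temps_c=tuple(temps_c),
        noise_cv=config.noise_cv, corruption=config.corruption,
        missing_metadata_fraction=config.missing_metadata_fraction,
        assay_ph=config.assay_ph, ionic_strength=config.ionic_strength,
        solute_conc=config.solute_conc)
    if len(cfg.temps_c) != 2:
        raise ValueError("edge generator requires exactly two temperatures")
    return gen_records(gen_truth(cfg), cfg, coeffs)
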