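"""Functional-group aggregation and the standardize -> fit -> summarize pipeline.

Species are grouped phylogenetically; within seed plants (Spermatophyta) the
split is by photosynthetic pathway and growth temperature: C4 plants, C3
plants from warm habitats (Tgrowth >= 25 degC, including C3-C4 intermediates)
and C3 plants from cool habitats (Tgrowth < 25 degC).  Species measured by
several sources contribute their across-source average; sources flagged for
poor fit convergence are excluded from the group parameter means (but the
species still counts toward group size, mirroring the published treatment).
Group statistics are arithmetic means with standard errors (sample SD /
sqrt(n)); the mean Q10 is the mean of member Q10s, not the Q10 of the mean
activation energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import standardize as _std
from . import tempresponse as _tr
from .standardize import AssayConditions, AssayRecord

__all__ = [
    "FUNCTIONAL_GROUPS",
    "classify",
    "dedupe_species",
    "summarize_group",
    "summarize_groups",
    "fit_records",
    "run_pipeline",
    "read_records_csv",
]

FUNCTIONAL_GROUPS = ("C3-cool", "C3-warm", "C4")
_PARAM_COLS = ("c", "dha_kj", "q10_5_15", "q10_15_25", "q10_25_35", "q10_35_45")

#: Columns the assay-record CSV must provide; the remainder of the schema
#: (assay metadata, exclusion flags) is optional and defaults to unknown.
REQUIRED_CSV_COLUMNS = ("species", "trait", "t_meas_c", "value")
OPTIONAL_CSV_COLUMNS = (
    "phase", "phylo_group", "pathway", "tgrowth_c", "source", "pH", "pKa_used",
    "henry_used_O2", "henry_used_CO2", "ionic_strength", "solute_conc",
    "pressure", "exclude_from_group", "exclude_from_species",
)


def classify(pathway: str, tgrowth: Optional[float],
             phylo_group: str = "Spermatophyta") -> str:
    """Functional-group label for one species.

    Non-seed-plant groups keep their phylogenetic name.  Within Spermatophyta
    the pathway decides first (C4 -> "C4"; C3-C4 intermediates -> "C3-warm");
    pure C3 species split at Tgrowth 25 degC, the boundary itself warm.
    """
    if phylo_group != "Spermatophyta" or pathway in (None, "", "none"):
        return phylo_group
    pathway = pathway.replace("–", "-")
    if pathway == "C4":
        return "C4"
    if pathway == "C3-C4":
        return "C3-warm"
    if pathway != "C3":
        raise ValueError(f"unknown photosynthetic pathway {pathway!r}")
    if tgrowth is None or (isinstance(tgrowth, float) and math.isnan(tgrowth)):
        raise ValueError("Tgrowth is required to classify a C3 seed plant")
    return "C3-warm" if tgrowth >= 25.0 else "C3-cool"


def dedupe_species(fits: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-source fits to one row per species x trait.

    Sources flagged ``exclude_from_species`` (unreliable fits) are dropped
    before averaging; the across-source arithmetic mean is taken for the
    scaling constant, activation energy and Q10s.  Boolean flags survive as
    "all remaining sources flagged".
    """
    if fits.empty:
        return fits.copy()
    df = fits.copy()
    for col in ("exclude_from_species", "exclude_from_group", "q10_upper_unreliable"):
        if col not in df:
            df[col] = False
    df = df[~df["exclude_from_species"].astype(bool)]

    def _collapse(sub: pd.DataFrame) -> pd.Series:
        out = {"n_sources": len(sub)}
        for col in _PARAM_COLS:
            if col in sub:
                out[col] = sub[col].mean()
        for col in ("group", "trait", "species", "tgrowth_c", "pathway", "phylo_group"):
            if col in sub:
                out[col] = sub[col].iloc[0]
        for col in ("exclude_from_group", "q10_upper_unreliable"):
            out[col] = bool(sub[col].astype(bool).all())
        return pd.Series(out)

    collapsed = (df.groupby(["species", "trait"], sort=True)
                   .apply(_collapse, include_groups=False)
                   .reset_index())
    return collapsed


@dataclass(frozen=True)
class GroupKinetics:
    """Mean +- SE of the temperature parameters for one functional group.

    ``stats`` maps trait -> {n, c, c_se, dha_kj, dha_se, q10 (4-tuple),
    q10_se (4-tuple)}; SEs are None when n = 1.  ``ko`` carries the shared
    (group-invariant) Ko Arrhenius parameters and ``kcat_deactivation`` the
    (dHd J mol-1, dS J mol-1 K-1) pair where known for the group.
    """

    group: str
    stats: Mapping[str, dict]
    ko: Mapping[str, float] = field(default_factory=dict)
    kcat_deactivation: Optional[tuple[float, float]] = None


def _mean_se(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size == 0:
        return None, None
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else None
    return mean, se


def summarize_group(fits: pd.DataFrame, group: str) -> GroupKinetics:
    """Table-3-style summary of deduped fits for one functional group."""
    from . import datasets

    sub = fits[fits["group"] == group]
    if sub.empty:
        raise ValueError(f"no fits for group {group!r}")
    stats: dict[str, dict] = {}
    for trait, tsub in sub.groupby("trait"):
        entry: dict = {"n": int(len(tsub))}
        ok = tsub[~tsub.get("exclude_from_group", False).astype(bool)]
        entry["c"], entry["c_se"] = _mean_se(ok["c"])
        entry["dha_kj"], entry["dha_se"] = _mean_se(ok["dha_kj"])
        q10_means, q10_ses = [], []
        for i, col in enumerate(_PARAM_COLS[2:]):
            vals = tsub[col]
            if i >= 2 and "q10_upper_unreliable" in tsub:
                vals = vals[~tsub["q10_upper_unreliable"].astype(bool)]
            m, s = _mean_se(vals)
            q10_means.append(m)
            q10_ses.append(s)
        entry["q10"] = tuple(q10_means)
        entry["q10_se"] = tuple(q10_ses)
        stats[trait] = entry
    deact = datasets.SIMULATION_GROUPS.get(group)
    return GroupKinetics(
        group=group,
        stats=stats,
        ko=dict(datasets.KO_SHARED),
        kcat_deactivation=(deact["dhd"], deact["ds"]) if deact else None,
    )


def summarize_groups(fits: pd.DataFrame) -> pd.DataFrame:
    """Tidy frame of group summaries (one row per group x trait)."""
    rows = []
    for group in sorted(fits["group"].dropna().unique()):
        gk = summarize_group(fits, group)
        for trait, st in gk.stats.items():
            row = {"group": group, "trait": trait, "n": st["n"],
                   "c": st["c"], "c_se": st["c_se"],
                   "dha_kj": st["dha_kj"], "dha_se": st["dha_se"]}
            for (lo, hi), m, s in zip(_tr.Q10_INTERVALS, st["q10"], st["q10_se"]):
                key = f"q10_{int(lo)}_{int(hi)}"
                row[key] = m
                row[key + "_se"] = s
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def read_records_csv(path) -> list[AssayRecord]:
    """Parse the assay-record CSV schema into records, reporting schema
    violations with 1-based data row numbers."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"records CSV lacks required columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(_record_from_row(row))
        except (ValueError, KeyError) as exc:
            raise ValueError(f"records CSV row {idx + 1}: {exc}") from exc
    return records


def _opt(row, key) -> Optional[float]:
    v = row.get(key)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _record_from_row(row) -> AssayRecord:
    cond = AssayConditions(
        pH=_opt(row, "pH"),
        pKa_used=_opt(row, "pKa_used"),
        henry_used_O2=_opt(row, "henry_used_O2"),
        henry_used_CO2=_opt(row, "henry_used_CO2"),
        ionic_strength=_opt(row, "ionic_strength"),
        solute_conc=_opt(row, "solute_conc"),
        pressure=_opt(row, "pressure") or _std.ATM,
    )
    return AssayRecord(
        species=str(row["species"]),
        trait=str(row["trait"]),
        t_meas=float(row["t_meas_c"]) + 273.15,
        value=float(row["value"]),
        phase=str(row.get("phase", "liquid") or "liquid"),
        conditions=cond,
        phylo_group=str(row.get("phylo_group", "Spermatophyta") or "Spermatophyta"),
        pathway=str(row.get("pathway", "C3") or "C3"),
        tgrowth=_opt(row, "tgrowth_c"),
        source=str(row.get("source", "") or ""),
    )


def fit_records(standardized: pd.DataFrame, log: Optional[list] = None) -> pd.DataFrame:
    """Fit one Arrhenius temperature response per species x trait x source
    from standardized values and attach the standard-temperature response."""
    rows = []
    for (species, trait, source), sub in standardized.groupby(
            ["species", "trait", "source"], sort=True):
        sub = sub.sort_values("t_meas_k")
        if len(sub) < 2:
            if log is not None:
                log.append(f"skipped {species}/{trait}/{source}: "
                           f"{len(sub)} temperature(s)")
            continue
        fit = _tr.fit_arrhenius(sub["t_meas_k"].to_numpy(),
                                sub["value_corrected"].to_numpy())
        resp = _tr.standard_response(fit)
        row = {
            "species": species, "trait": trait, "source": source,
            "phylo_group": sub["phylo_group"].iloc[0],
            "pathway": sub["pathway"].iloc[0],
            "tgrowth_c": sub["tgrowth_c"].iloc[0],
            "group": classify(sub["pathway"].iloc[0],
                              sub["tgrowth_c"].iloc[0],
                              sub["phylo_group"].iloc[0]),
            "n_temps": len(sub),
            "c": fit.c, "dha_kj": fit.dha / 1000.0, "r": fit.r,
        }
        for tc, val in zip(_tr.STANDARD_TEMPS_C, resp.values):
            row[f"value_{int(tc)}c"] = val
        for (lo, hi), q in zip(_tr.Q10_INTERVALS, resp.q10):
            row[f"q10_{int(lo)}_{int(hi)}"] = q
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(records: Sequence[AssayRecord] | str,
                 coeffs=None) -> dict:
    """Execute standardize -> fit -> standard response -> dedupe -> classify
    -> summarize on an assay-record collection (or CSV path).

    Returns ``{"standardized": DataFrame, "fits": DataFrame,
    "species_fits": DataFrame, "groups": DataFrame, "log": list[str]}``.
    Deterministic for a given input; the log records per-record correction
    factors and any exclusions.
    """
    if isinstance(records, (str, bytes)) or hasattr(records, "__fspath__"):
        records = read_records_csv(records)
    if not records:
        raise ValueError("no input records")

    log: list[str] = []
    std_rows = []
    n_unstandardized = 0
    for rec in records:
        res = _std.standardize_record(rec, coeffs)
        if not res.standardized:
            n_unstandardized += 1
            log.append(f"not standardized: {rec.species}/{rec.trait}"
                       f"@{rec.t_meas:.2f}K ({res.note})")
        else:
            log.append(f"standardized {rec.species}/{rec.trait}"
                       f"@{rec.t_meas:.2f}K factor={res.factor:.6f}")
        std_rows.append({
            "species": rec.species, "trait": rec.trait, "source": rec.source,
            "phylo_group": rec.phylo_group, "pathway": rec.pathway,
            "tgrowth_c": rec.tgrowth, "t_meas_k": rec.t_meas,
            "value_reported": rec.value, "value_corrected": res.value_corrected,
            "factor": res.factor, "standardized": res.standardized,
            "error_pct": _std.standardization_error(res.value_corrected, rec.value),
        })
    standardized = pd.DataFrame(std_rows).sort_values(
        ["species", "trait", "source", "t_meas_k"]).reset_index(drop=True)
    log.append(f"records: {len(records)} total, "
               f"{len(records) - n_unstandardized} standardized, "
               f"{n_unstandardized} passed through unstandardized")

    fits = fit_records(standardized, log)
    if fits.empty:
        raise ValueError("pipeline produced no fits: every series was too short")
    species_fits = dedupe_species(fits)
    groups = summarize_groups(species_fits)
    return {"standardized": standardized, "fits": fits,
            "species_fits": species_fits, "groups": groups, "log": log}
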