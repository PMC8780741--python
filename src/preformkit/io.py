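"""Shared table I/O, configuration and pipeline orchestration.

All concentrations are normalized at the boundary to ug/mL (solubilities) and
uM (assay concentrations); permeabilities are cm/s, volumes mL, times
minutes.  Tables are RFC-4180 CSV with a header row and '.' decimal
separator.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bcs as bcs_mod
from . import jm20
from .perfusion import PerfusionAssay, analyze_assay, summarize_segments
from .speciation import SolubilityPoint, SpeciationModel, refine_model
from .spectro_pka import (SpectralSeries, average_replicates,
                          pka_from_crossing, select_analytical_wavelengths)
from .transwell import TranswellAssay, fit_papp

__all__ = [
    "TableSchema",
    "read_table",
    "StudyConfig",
    "StudyReport",
    "run_pipeline",
    "read_spectra_csv",
    "read_solubility_csv",
    "read_transwell_csv",
    "read_perfusion_csv",
]


class SchemaError(ValueError):
    """A table does not match its declared schema."""


@dataclass
class TableSchema:
    """Required columns with their units and permissible unit aliases.

    ``conversions`` maps an alternate column name to (canonical name,
    multiplicative factor), e.g. solubility_mg_per_mL -> ug/mL at x1000.
    """

    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    string_cols: tuple[str, ...] = ()
    conversions: dict[str, tuple[str, float]] = field(default_factory=dict)


def read_table(path, schema: TableSchema) -> pd.DataFrame:
    """Read and validate a CSV against a schema, normalizing units.

    Raises :class:`SchemaError` naming the missing column or the offending
    row/column for unparseable numbers.
    """
    df = pd.read_csv(path)
    for alt, (canonical, factor) in schema.conversions.items():
        if alt in df.columns and canonical not in df.columns:
            df[canonical] = pd.to_numeric(df[alt], errors="coerce") * factor
            df = df.drop(columns=[alt])
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{schema.name}: missing required column(s) {missing}")
    for col in schema.required:
        if col in schema.string_cols:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header is line 1
            raise SchemaError(
                f"{schema.name}: unparseable number in column {col!r}, "
                f"line {row}")
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 2
            raise SchemaError(
                f"{schema.name}: empty value in column {col!r}, line {row}")
        df[col] = coerced
    return df


SPECTRA_SCHEMA = TableSchema(
    name="spectra", required=("wavelength_nm", "pH", "absorbance"),
    optional=("replicate",))
SOLUBILITY_SCHEMA = TableSchema(
    name="solubility", required=("pH", "solubility_ug_per_mL"),
    optional=("sd", "temperature_C", "chloride_M"),
    conversions={"solubility_mg_per_mL": ("solubility_ug_per_mL", 1000.0)})
TRANSWELL_SCHEMA = TableSchema(
    name="transwell",
    required=("replicate", "direction", "time_min", "compartment",
              "concentration_uM"),
    string_cols=("direction", "compartment"))
PERFUSION_SCHEMA = TableSchema(
    name="perfusion",
    required=("animal_id", "segment", "time_min", "concentration_uM"),
    optional=("v_t_mL", "length_cm"),
    string_cols=("animal_id", "segment"))


def read_spectra_csv(path, temperature_C: float = 23.0) -> list[SpectralSeries]:
    """Long-format spectra CSV -> one SpectralSeries per replicate."""
    df = pd.read_csv(path)
    for col in ("wavelength_nm", "pH", "absorbance"):
        if col not in df.columns:
            raise SchemaError(f"spectra: missing required column(s) ['{col}']")
    if "replicate" not in df.columns:
        df["replicate"] = 1
    series = []
    for _, group in df.groupby("replicate"):
        pivot = group.pivot_table(index="pH", columns="wavelength_nm",
                                  values="absorbance").sort_index()
        series.append(SpectralSeries(
            wavelengths_nm=pivot.columns.to_numpy(float),
            ph_values=pivot.index.to_numpy(float),
            absorbance=pivot.to_numpy(float),
            temperature_C=temperature_C))
    return series


def read_solubility_csv(path) -> list[SolubilityPoint]:
    df = read_table(path, SOLUBILITY_SCHEMA)

    def opt(row, col, default):
        value = row.get(col, default)
        return float(value) if pd.notna(value) else default

    return [
        SolubilityPoint(
            ph=row["pH"], solubility=row["solubility_ug_per_mL"],
            sd=opt(row, "sd", 0.0),
            temperature_C=opt(row, "temperature_C", 37.0),
            chloride_background=opt(row, "chloride_M", 0.0))
        for _, row in df.iterrows()
    ]


def read_transwell_csv(path, *, v_receiver: float = 2.0, v_donor: float = 2.0,
                       membrane_area: float = 4.2,
                       sample_volume: float = 0.2) -> list[TranswellAssay]:
    """Transwell CSV -> one assay per (replicate, direction)."""
    df = read_table(path, TRANSWELL_SCHEMA)
    assays = []
    for (rep, direction), group in df.groupby(["replicate", "direction"]):
        rec = group[group["compartment"] == "receiver"].sort_values("time_min")
        don = group[group["compartment"] == "donor"].sort_values("time_min")
        donor = None
        if len(don) >= 2:
            donor = (float(don["concentration_uM"].iloc[0]),
                     float(don["concentration_uM"].iloc[-1]))
        assays.append(TranswellAssay(
            direction=str(direction), v_receiver=v_receiver, v_donor=v_donor,
            receiver_concentrations=rec["concentration_uM"].to_numpy(float),
            sample_times=rec["time_min"].to_numpy(float),
            membrane_area=membrane_area, sample_volume=sample_volume,
            donor_concentrations=donor))
    return assays


def read_perfusion_csv(path, *, v0: float = 10.0,
                       default_length_cm: float = 30.0) -> list[PerfusionAssay]:
    df = read_table(path, PERFUSION_SCHEMA)
    assays = []
    for (animal, segment), group in df.groupby(["animal_id", "segment"]):
        group = group.sort_values("time_min")
        v_t = (group["v_t_mL"].to_numpy(float)
               if "v_t_mL" in group.columns and group["v_t_mL"].notna().all()
               else None)
        length = (float(group["length_cm"].iloc[0])
                  if "length_cm" in group.columns else default_length_cm)
        assays.append(PerfusionAssay(
            segment=str(segment), times=group["time_min"].to_numpy(float),
            concentrations_measured=group["concentration_uM"].to_numpy(float),
            v0=v0, v_t=v_t, length_cm=length, perfusion_volume=v0))
    return assays


@dataclass
class StudyConfig:
    """Inputs and settings for a full preformulation study run."""

    compound: str = "JM-20"
    molecular_weight: float = jm20.MOLECULAR_WEIGHT
    pka1: float = jm20.PKA1_37C
    pka2: float = jm20.PKA2_37C
    dose_mg_per_kg: float = jm20.DOSE_MG_PER_KG
    body_weight_kg: float = jm20.BODY_WEIGHT_KG
    spectra_csv: str | None = None
    solubility_csv: str | None = None
    transwell_csv: str | None = None
    perfusion_csv: str | None = None
    exclude_ph: tuple[float, ...] = jm20.DEFAULT_EXCLUDE_PH
    initial_s0: float = 20.0
    initial_pksp: float | None = 7.0
    reference_papp: dict[str, float] = field(default_factory=dict)
    out_dir: str = "results"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        if "exclude_ph" in known:
            known["exclude_ph"] = tuple(known["exclude_ph"])
        return cls(**known)

    def config_hash(self) -> str:
        payload = json.dumps(
            {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items()}, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class StudyReport:
    config_hash: str
    stages: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"config_hash": self.config_hash,
                           "stages": self.stages, "skipped": self.skipped},
                          indent=2, sort_keys=True, default=float)


def run_pipeline(config: StudyConfig) -> StudyReport:
    """Execute the available stages in dependency order.

    pKa -> solubility refinement -> dose numbers -> solubility class;
    transwell / perfusion -> permeability class; both -> provisional BCS
    class.  Stages without inputs are recorded as skipped; downstream stages
    degrade gracefully (the BCS class is reported as undetermined when either
    leg is missing).
    """
    report = StudyReport(config_hash=config.config_hash())
    pka1, pka2 = config.pka1, config.pka2

    if config.spectra_csv:
        replicates = read_spectra_csv(config.spectra_csv)
        est1, est2 = [], []
        for series in replicates:
            wl = select_analytical_wavelengths(series, k=1)[0]
            a = series.column(wl)
            lo = series.ph_values <= (pka1 + pka2) / 2
            est1.append(pka_from_crossing(series.ph_values[lo], a[lo],
                                          wavelength_nm=wl))
            est2.append(pka_from_crossing(series.ph_values[~lo], a[~lo],
                                          wavelength_nm=wl))
        m1, m2 = average_replicates(est1), average_replicates(est2)
        report.stages["pka"] = {"pka1": m1.value, "pka1_sd": m1.sd,
                                "pka2": m2.value, "pka2_sd": m2.sd}
    else:
        report.skipped.append("pka")

    solubility_points = None
    if config.solubility_csv:
        solubility_points = read_solubility_csv(config.solubility_csv)
    elif config.compound == "JM-20":
        solubility_points = jm20.solubility_points()

    solubility_class = None
    if solubility_points:
        initial = SpeciationModel(
            s0=config.initial_s0, pka1=pka1, pka2=pka2,
            pksp=config.initial_pksp,
            molecular_weight=config.molecular_weight)
        free = ("s0", "pksp") if config.initial_pksp is not None else ("s0",)
        result = refine_model(solubility_points, initial, free,
                              exclude_ph=config.exclude_ph)
        dose_mg = bcs_mod.highest_dose_from_weight(
            config.dose_mg_per_kg, config.body_weight_kg)
        do_by_ph = {
            p.ph: bcs_mod.dose_number(bcs_mod.DoseInputs(
                dose_mg=dose_mg, cs_mg_per_mL=p.solubility / 1000.0))
            for p in solubility_points
        }
        solubility_class = bcs_mod.solubility_class(do_by_ph)
        # internal consistency audit: Do must follow from its own S column
        for p in solubility_points:
            expected = dose_mg / (250.0 * p.solubility / 1000.0)
            assert abs(do_by_ph[p.ph] - expected) < 1e-9
        report.stages["solubility"] = {
            "s0_ug_per_mL": result.model.s0,
            "pksp": result.model.pksp,
            "weighted_sse": result.weighted_sse,
            "converged": result.converged,
            "dose_mg": dose_mg,
            "do_by_ph": {str(k): v for k, v in do_by_ph.items()},
            "solubility_class": solubility_class,
        }
    else:
        report.skipped.append("solubility")

    perm_evidence: dict[str, tuple[float, float]] = {}
    if config.transwell_csv:
        assays = read_transwell_csv(config.transwell_csv)
        by_direction: dict[str, list[float]] = {}
        for assay in assays:
            by_direction.setdefault(assay.direction, []).append(
                fit_papp(assay).papp)
        stage = {d: {"mean": float(np.mean(v)),
                     "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
                     "n": len(v)}
                 for d, v in by_direction.items()}
        report.stages["transwell"] = stage
        if "A-B" in by_direction and "transwell" in config.reference_papp:
            perm_evidence["transwell"] = (stage["A-B"]["mean"],
                                          config.reference_papp["transwell"])
    else:
        report.skipped.append("transwell")

    if config.perfusion_csv:
        fits = [analyze_assay(a) for a in read_perfusion_csv(config.perfusion_csv)]
        summary = summarize_segments(fits)
        report.stages["perfusion"] = {
            seg: {"peff_mean": m, "peff_sd": s, "n": n}
            for seg, (m, s, n) in summary.items()}
        for seg, (mean, _, _) in summary.items():
            key = f"rat_{seg}"
            if key in config.reference_papp:
                perm_evidence[key] = (mean, config.reference_papp[key])
    else:
        report.skipped.append("perfusion")

    if solubility_class and perm_evidence:
        perm_class, evidence = bcs_mod.permeability_class(perm_evidence)
        final = bcs_mod.bcs_class(solubility_class, perm_class)
        report.stages["bcs"] = {"solubility_class": solubility_class,
                                "permeability_class": perm_class,
                                "bcs_class": final,
                                "evidence": evidence}
    else:
        report.stages["bcs"] = {"bcs_class": None,
                                "note": "undetermined: missing solubility or "
                                        "permeability evidence"}
    return report
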