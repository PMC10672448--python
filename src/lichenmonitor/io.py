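"""Delimited-text readers and writers for the five biomonitoring table kinds.

All tables are plain CSV (comma default; tab accepted via ``sep``) with a
header row. Readers validate every row against the domain invariants and
report the 1-based data line number of the first offending row. Absence of a
species on a tree is encoded by the row being absent; frequency-0 survey rows
are accepted on read but normalized away.

Spectra are stored as a wide CSV (first column ``sample_id``, remaining
columns integer nm headers) or a long CSV (``sample_id, wavelength_nm,
value``); sample labels travel in a companion CSV.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AirQualityRecord,
    SpeciesObservation,
    SpectraMatrix,
    SymptomRecord,
    ThallusRecord,
    TraitRecord,
    ValidationError,
    normalize_species,
)

SURVEY_COLUMNS = ["station_id", "tree_id", "year", "species", "frequency"]
TRAIT_COLUMNS = [
    "species",
    "ph_indicator",
    "eutrophication_tolerance",
    "growth_form",
    "reproductive_structure",
]
THALLI_COLUMNS = [
    "thallus_id",
    "station_id",
    "tree_id",
    "year",
    "species",
    "size_cm",
    "symptom_type",
    "affected_fraction",
    "location",
    "category",
]
AIRQUALITY_COLUMNS = ["station_id", "year", "variable", "value"]


def _read_table(path: str | os.PathLike, sep: str, columns: Sequence[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _row_error(path: str | os.PathLike, line: int, field: str, msg: str) -> ValidationError:
    return ValidationError(f"{path}, data line {line}, field {field!r}: {msg}")


def _parse_int(raw: str, path, line: int, field: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise _row_error(path, line, field, f"not an integer: {raw!r}") from None


def _parse_float(raw: str, path, line: int, field: str) -> float:
    try:
        return float(raw)
    except ValueError:
        raise _row_error(path, line, field, f"not a number: {raw!r}") from None


# Survey --------------------------------------------------------------------

def read_survey(path: str | os.PathLike, sep: str = ",") -> list[SpeciesObservation]:
    """Read a community-survey table into validated observations.

    Species names are normalized (trimmed, genus capitalized); frequency-0
    rows are dropped; (station, tree, year, species) must be unique.
    """
    df = _read_table(path, sep, SURVEY_COLUMNS)
    out: list[SpeciesObservation] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        freq = _parse_int(row.frequency, path, i, "frequency")
        if not (0 <= freq <= 10):
            raise _row_error(path, i, "frequency", f"must be in [0, 10], got {freq}")
        if freq == 0:
            continue
        year = _parse_int(row.year, path, i, "year")
        try:
            species = normalize_species(row.species)
        except ValidationError as e:
            raise _row_error(path, i, "species", str(e)) from None
        key = (row.station_id, row.tree_id, year, species)
        if key in seen:
            raise _row_error(path, i, "species", f"duplicate observation {key}")
        seen.add(key)
        out.append(
            SpeciesObservation(
                station_id=row.station_id,
                tree_id=row.tree_id,
                year=year,
                species=species,
                frequency=freq,
            )
        )
    return out


def write_survey(
    observations: Iterable[SpeciesObservation], path: str | os.PathLike, sep: str = ","
) -> None:
    df = pd.DataFrame(
        [
            (o.station_id, o.tree_id, o.year, o.species, o.frequency)
            for o in observations
        ],
        columns=SURVEY_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


# Traits --------------------------------------------------------------------

def read_traits(path: str | os.PathLike, sep: str = ",") -> list[TraitRecord]:
    """Read the species ecological-indicator trait table (one row per species)."""
    df = _read_table(path, sep, TRAIT_COLUMNS)
    out: list[TraitRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        species = normalize_species(row.species)
        if species in seen:
            raise _row_error(path, i, "species", f"duplicate trait record for {species}")
        seen.add(species)
        try:
            out.append(
                TraitRecord(
                    species=species,
                    ph_indicator=_parse_float(row.ph_indicator, path, i, "ph_indicator"),
                    eutrophication_tolerance=_parse_float(
                        row.eutrophication_tolerance, path, i, "eutrophication_tolerance"
                    ),
                    growth_form=row.growth_form,
                    reproductive_structure=row.reproductive_structure,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}, data line {i}: {e}") from None
    return out


def write_traits(traits: Iterable[TraitRecord], path: str | os.PathLike, sep: str = ",") -> None:
    df = pd.DataFrame(
        [
            (
                t.species,
                t.ph_indicator,
                t.eutrophication_tolerance,
                t.growth_form,
                t.reproductive_structure,
            )
            for t in traits
        ],
        columns=TRAIT_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


# Thalli ---------------------------------------------------------------------

def read_thalli(path: str | os.PathLike, sep: str = ",") -> list[ThallusRecord]:
    """Read thallus damage records from the long (one row per symptom) layout.

    A thallus with no symptoms is a single row with empty symptom fields.
    """
    df = _read_table(path, sep, THALLI_COLUMNS)
    groups: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        tid = row.thallus_id
        if tid not in groups:
            groups[tid] = {
                "station_id": row.station_id,
                "tree_id": row.tree_id,
                "year": _parse_int(row.year, path, i, "year"),
                "species": normalize_species(row.species),
                "size": _parse_float(row.size_cm, path, i, "size_cm"),
                "symptoms": [],
            }
            order.append(tid)
        if row.symptom_type == "":
            continue
        try:
            groups[tid]["symptoms"].append(
                SymptomRecord(
                    symptom_type=row.symptom_type,
                    affected_fraction=_parse_float(
                        row.affected_fraction, path, i, "affected_fraction"
                    ),
                    location=row.location,
                    category=_parse_int(row.category, path, i, "category"),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}, data line {i}: {e}") from None
    out = []
    for tid in order:
        g = groups[tid]
        out.append(
            ThallusRecord(
                station_id=g["station_id"],
                tree_id=g["tree_id"],
                year=g["year"],
                species=g["species"],
                size=g["size"],
                symptoms=tuple(g["symptoms"]),
            )
        )
    return out


def write_thalli(
    records: Iterable[ThallusRecord], path: str | os.PathLike, sep: str = ","
) -> None:
    rows = []
    for k, r in enumerate(records):
        base = (f"T{k:06d}", r.station_id, r.tree_id, r.year, r.species, r.size)
        if not r.symptoms:
            rows.append((*base, "", "", "", ""))
        for s in r.symptoms:
            rows.append((*base, s.symptom_type, s.affected_fraction, s.location, s.category))
    pd.DataFrame(rows, columns=THALLI_COLUMNS).to_csv(path, sep=sep, index=False)


# Air quality ----------------------------------------------------------------

def read_airquality(path: str | os.PathLike, sep: str = ",") -> list[AirQualityRecord]:
    df = _read_table(path, sep, AIRQUALITY_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            out.append(
                AirQualityRecord(
                    station_id=row.station_id,
                    year=_parse_int(row.year, path, i, "year"),
                    variable=row.variable,
                    value=_parse_float(row.value, path, i, "value"),
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}, data line {i}: {e}") from None
    return out


def write_airquality(
    records: Iterable[AirQualityRecord], path: str | os.PathLike, sep: str = ","
) -> None:
    df = pd.DataFrame(
        [(r.station_id, r.year, r.variable, r.value) for r in records],
        columns=AIRQUALITY_COLUMNS,
    )
    df.to_csv(path, sep=sep, index=False)


# Spectra ---------------------------------------------------------------------

def read_spectra(
    path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    sep: str = ",",
    layout: str = "wide",
) -> SpectraMatrix:
    """Read a spectra table (wide or long layout) and optional label table.

    The wavelength grid must be integer nm, strictly increasing in 1-nm steps,
    with no missing cells.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"spectra table not found: {path}")
    if layout == "wide":
        df = pd.read_csv(path, sep=sep)
        if df.columns[0] != "sample_id":
            raise ValidationError(f"{path}: first column must be 'sample_id'")
        wl_cols = list(df.columns[1:])
        if len(set(wl_cols)) != len(wl_cols):
            raise ValidationError(f"{path}: duplicate wavelength columns")
        try:
            wl = np.array([int(c) for c in wl_cols])
        except ValueError:
            raise ValidationError(f"{path}: wavelength headers must be integer nm") from None
        values = df[wl_cols].to_numpy(dtype=float)
        sample_ids = df["sample_id"].astype(str).tolist()
    elif layout == "long":
        df = pd.read_csv(path, sep=sep)
        for c in ("sample_id", "wavelength_nm", "value"):
            if c not in df.columns:
                raise ValidationError(f"{path}: long layout requires column {c!r}")
        pivot = df.pivot(index="sample_id", columns="wavelength_nm", values="value")
        if pivot.isna().any().any():
            raise ValidationError(f"{path}: missing cells in long spectra table")
        wl = pivot.columns.to_numpy(dtype=int)
        values = pivot.to_numpy(dtype=float)
        sample_ids = pivot.index.astype(str).tolist()
    else:
        raise ValueError(f"unknown spectra layout {layout!r}")
    if np.isnan(values).any():
        raise ValidationError(f"{path}: spectra table has missing cells")
    labels = None
    if labels_path is not None:
        ldf = pd.read_csv(labels_path, sep=sep, dtype=str)
        if "sample_id" not in ldf.columns:
            raise ValidationError(f"{labels_path}: missing 'sample_id' column")
        labels = ldf.set_index("sample_id")
    return SpectraMatrix(sample_ids, wl, values, labels)


def write_spectra(
    spectra: SpectraMatrix,
    path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    sep: str = ",",
) -> None:
    """Write spectra in the wide layout, with labels to a companion CSV."""
    df = pd.DataFrame(
        spectra.values,
        columns=[str(w) for w in spectra.wavelengths_nm],
    )
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, sep=sep, index=False)
    if labels_path is not None and len(spectra.labels.columns) > 0:
        spectra.labels.reset_index().to_csv(labels_path, sep=sep, index=False)
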