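"""Shared domain types for lichen biomonitoring data.

The record types mirror the field protocol of a long-term epiphytic-lichen
biomonitoring network: community surveys scored as per-grid frequencies
(the basis of the Index of Atmospheric Purity), thallus-level visible-damage
records (the basis of the ordinal 1-5 Damage Index), species ecological-trait
tables, air-quality time series, and Vis-NIR reflectance spectra of thalli.

All types validate their invariants on construction and raise
:class:`ValidationError` on violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """A record or table violates a domain invariant."""


# Categorical vocabularies -------------------------------------------------

GROWTH_FORMS = ("crustose", "foliose_broad", "foliose_narrow", "fruticose")
REPRODUCTIVE_STRUCTURES = ("apothecia", "isidia", "soredia")
SYMPTOM_TYPES = (
    "colour_change",
    "necrosis",
    "twisting",
    "stain",
    "parasite",
    "excessive_reproductive_structures",
    "surface_loss",
)
SYMPTOM_LOCATIONS = ("centre", "lobes")
AIR_VARIABLES = ("SO2", "O3", "temperature")

#: The five categorical fields attached to each NIR spectrum, with their
#: admissible values.
SPECTRA_LABEL_FIELDS: dict[str, tuple[str, ...]] = {
    "reproductive_structures": ("normal", "excessive"),
    "growth_form": ("foliose", "fruticose"),
    "reproduction_strategy": ("apothecia", "isidia", "soredia"),
    "phorophyte": ("Pinus", "Quercus"),
    "bioclimatic_belt": ("19c", "22a"),
}

#: The nine foliose/fruticose macrolichens targeted by the damage protocol.
TARGET_SPECIES = (
    "Pleurosticta acetabulum",
    "Parmelina carporrhizans",
    "Parmelia serrana",
    "Xanthoria parietina",
    "Pseudevernia furfuracea",
    "Physcia aipolia",
    "Anaptychia ciliaris",
    "Ramalina fraxinea",
    "Ramalina farinacea",
)


def normalize_species(name: str) -> str:
    """Normalize a binomial: trim, capitalize the genus, lower-case the rest.

    >>> normalize_species("  xanthoria  PARIETINA ")
    'Xanthoria parietina'
    """
    parts = str(name).strip().split()
    if not parts:
        raise ValidationError("empty species name")
    genus = parts[0].capitalize()
    rest = [p.lower() for p in parts[1:]]
    return " ".join([genus, *rest])


@dataclass(frozen=True)
class SpeciesObservation:
    """One lichen species on one tree in one campaign.

    ``frequency`` counts occupied squares of the 10-square sampling quadrat,
    so a recorded presence takes values 1..10.
    """

    station_id: str
    tree_id: str
    year: int
    species: str
    frequency: int

    def __post_init__(self) -> None:
        if not (0 <= self.frequency <= 10):
            raise ValidationError(
                f"frequency must be in [0, 10], got {self.frequency} "
                f"for {self.species} on {self.station_id}/{self.tree_id}"
            )


@dataclass(frozen=True)
class TraitRecord:
    """Ecological-indicator traits of one species (Nimis-style ordinal values)."""

    species: str
    ph_indicator: float
    eutrophication_tolerance: float
    growth_form: str
    reproductive_structure: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.ph_indicator) or not np.isfinite(
            self.eutrophication_tolerance
        ):
            raise ValidationError(f"non-finite trait value for {self.species}")
        if self.growth_form not in GROWTH_FORMS:
            raise ValidationError(
                f"unknown growth form {self.growth_form!r} for {self.species}"
            )
        if self.reproductive_structure not in REPRODUCTIVE_STRUCTURES:
            raise ValidationError(
                f"unknown reproductive structure {self.reproductive_structure!r} "
                f"for {self.species}"
            )


@dataclass(frozen=True)
class SymptomRecord:
    """One visible symptom on a thallus with its 1-5 damage category."""

    symptom_type: str
    affected_fraction: float
    location: str
    category: int

    def __post_init__(self) -> None:
        if self.symptom_type not in SYMPTOM_TYPES:
            raise ValidationError(f"unknown symptom type {self.symptom_type!r}")
        if not (0.0 <= self.affected_fraction <= 1.0):
            raise ValidationError(
                f"affected_fraction must be in [0, 1], got {self.affected_fraction}"
            )
        if self.location not in SYMPTOM_LOCATIONS:
            raise ValidationError(f"unknown symptom location {self.location!r}")
        if self.category not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"damage category must be in 1..5, got {self.category}"
            )


@dataclass(frozen=True)
class ThallusRecord:
    """One measured thallus with its symptom set and max-rule damage category.

    ``max_di`` is 1 for a symptom-free thallus (no visible damage), otherwise
    the maximum category over its symptoms.
    """

    station_id: str
    tree_id: str
    year: int
    species: str
    size: float
    symptoms: tuple[SymptomRecord, ...] = ()
    max_di: int = field(default=0)  # 0 sentinel: derive in __post_init__

    def __post_init__(self) -> None:
        derived = max((s.category for s in self.symptoms), default=1)
        if self.max_di == 0:
            object.__setattr__(self, "max_di", derived)
        elif self.max_di != derived:
            raise ValidationError(
                f"max_di {self.max_di} inconsistent with symptoms (expect {derived})"
            )
        if self.size <= 0 or not np.isfinite(self.size):
            raise ValidationError(f"thallus size must be positive, got {self.size}")


@dataclass(frozen=True)
class IAPResult:
    """Index of Atmospheric Purity for one station and campaign.

    The station value is the arithmetic mean of the per-tree values
    (sum of per-species grid frequencies on the tree).
    """

    station_id: str
    year: int
    per_tree: Mapping[str, float]
    station_value: float
    n_trees: int

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.n_trees != len(self.per_tree):
            raise ValidationError("n_trees must equal the number of per-tree values")
        mean = float(np.mean(list(self.per_tree.values())))
        if abs(mean - self.station_value) > 1e-9:
            raise ValidationError("station_value must be the mean of per-tree values")


@dataclass(frozen=True)
class AirQualityRecord:
    """One air-quality measurement (gas in ug/m3, temperature in degC)."""

    station_id: str
    year: int
    variable: str
    value: float

    def __post_init__(self) -> None:
        if self.variable not in AIR_VARIABLES:
            raise ValidationError(f"unknown air-quality variable {self.variable!r}")
        if self.variable in ("SO2", "O3") and self.value < 0:
            raise ValidationError(
                f"gas concentration must be >= 0, got {self.value} for {self.variable}"
            )


class SpectraMatrix:
    """Reflectance spectra on a shared 1-nm wavelength grid with sample labels.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers (row order of ``values``).
    wavelengths_nm
        Strictly increasing integer grid with 1-nm steps.
    values
        ``(n_samples, n_wavelengths)`` reflectance matrix, all finite.
    labels
        DataFrame indexed like ``sample_ids`` carrying the five categorical
        fields of :data:`SPECTRA_LABEL_FIELDS` (any subset is allowed for
        intermediate objects; a full acquisition carries all five).
    """

    def __init__(
        self,
        sample_ids: Sequence[str],
        wavelengths_nm: np.ndarray,
        values: np.ndarray,
        labels: pd.DataFrame | None = None,
    ) -> None:
        self.sample_ids = [str(s) for s in sample_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("sample ids must be unique")
        wl = np.asarray(wavelengths_nm, dtype=int)
        if wl.ndim != 1 or wl.size < 2:
            raise ValidationError("wavelength grid must be 1-D with >= 2 points")
        steps = np.diff(wl)
        if not np.all(steps == 1):
            raise ValidationError("wavelength grid must be strictly increasing in 1-nm steps")
        vals = np.asarray(values, dtype=float)
        if vals.shape != (len(self.sample_ids), wl.size):
            raise ValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.sample_ids)} samples x {wl.size} wavelengths"
            )
        if not np.all(np.isfinite(vals)):
            raise ValidationError("spectra contain non-finite or missing values")
        self.wavelengths_nm = wl
        self.values = vals
        if labels is None:
            labels = pd.DataFrame(index=pd.Index(self.sample_ids, name="sample_id"))
        else:
            labels = labels.copy()
            labels.index = pd.Index([str(i) for i in labels.index], name="sample_id")
            if list(labels.index) != self.sample_ids:
                labels = labels.reindex(self.sample_ids)
            if labels.isna().any().any():
                raise ValidationError("labels missing for some samples")
            for col in labels.columns:
                allowed = SPECTRA_LABEL_FIELDS.get(col)
                if allowed is not None:
                    bad = set(labels[col].unique()) - set(allowed)
                    if bad:
                        raise ValidationError(
                            f"label field {col!r} has unknown values {sorted(bad)}"
                        )
        self.labels = labels

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_wavelengths(self) -> int:
        return int(self.wavelengths_nm.size)

    def select_band(self, low_nm: int, high_nm: int) -> "SpectraMatrix":
        """Return the sub-matrix restricted to wavelengths in [low, high] inclusive."""
        if self.wavelengths_nm[0] > low_nm or self.wavelengths_nm[-1] < high_nm:
            raise ValidationError(
                f"grid {self.wavelengths_nm[0]}-{self.wavelengths_nm[-1]} nm does not "
                f"cover the requested band {low_nm}-{high_nm} nm"
            )
        mask = (self.wavelengths_nm >= low_nm) & (self.wavelengths_nm <= high_nm)
        return SpectraMatrix(
            self.sample_ids, self.wavelengths_nm[mask], self.values[:, mask], self.labels
        )

    def subset(self, indices: Sequence[int]) -> "SpectraMatrix":
        """Return the row subset at integer ``indices`` (order preserved)."""
        idx = list(indices)
        return SpectraMatrix(
            [self.sample_ids[i] for i in idx],
            self.wavelengths_nm,
            self.values[idx],
            self.labels.iloc[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpectraMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and np.array_equal(self.wavelengths_nm, other.wavelengths_nm)
            and np.allclose(self.values, other.values, rtol=0, atol=1e-12)
            and self.labels.equals(other.labels)
        )

    def __repr__(self) -> str:
        return (
            f"SpectraMatrix({self.n_samples} samples, "
            f"{self.wavelengths_nm[0]}-{self.wavelengths_nm[-1]} nm, "
            f"{self.n_wavelengths} wavelengths)"
        )


@dataclass(frozen=True)
class ClassMetrics:
    """Per-class classification figures of merit.

    ``error`` is the balanced error ``1 - (sensitivity + specificity) / 2``.
    ``phase`` distinguishes cross-validation ('cv') from test-set prediction
    ('prediction').
    """

    class_label: str
    n_latent: int
    sensitivity: float
    specificity: float
    error: float
    phase: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValidationError("sensitivity and specificity must be in [0, 1]")
        expected = 1.0 - (self.sensitivity + self.specificity) / 2.0
        if abs(self.error - expected) > 1e-9:
            raise ValidationError("error must equal 1 - (Sn + Sp)/2")
        if self.phase not in ("cv", "prediction"):
            raise ValidationError(f"unknown phase {self.phase!r}")
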