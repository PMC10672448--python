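"""Synthetic biomonitoring data with known ground truth.

Each generator emulates one of the field data streams of a two-campaign
(1997 vs 2022) epiphytic-lichen monitoring network:

* community surveys — per-square presence draws, so each species' quadrat
  frequency is Binomial(10, p) with an occupancy p tied to its ecological
  traits through a logistic model;
* thallus damage records — ordered five-category symptom draws whose latent
  location follows a per-(station, year) stress level;
* air-quality series — declining SO2, flat O3 and slowly warming temperature;
* Vis-NIR reflectance spectra — smooth baseline plus Gaussian water-band
  peaks (first OH-stretch overtone region) with class-dependent amplitudes,
  degraded by multiplicative scatter (b*x + a) and white noise. The scatter
  model is exactly the affine model that multiplicative scatter correction
  inverts.

Every generator consumes a single ``numpy`` Generator seeded from its config,
so identical configs give bit-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AirQualityRecord,
    SPECTRA_LABEL_FIELDS,
    SpeciesObservation,
    SpectraMatrix,
    SymptomRecord,
    TARGET_SPECIES,
    ThallusRecord,
    TraitRecord,
    ValidationError,
)

DEFAULT_STATIONS = (
    "Toro-Pinus",
    "Toro-Quercus",
    "Cinctorres",
    "Corachar",
    "Bojar",
    "Collado Gavilan",
    "Villarroya Pinares",
)

DEFAULT_YEARS = (1997, 2022)

#: Canonical first-overtone OH-stretch coordinates used as default synthetic
#: water-band peak centres (nm). The aquaphotomics literature assigns these
#: to distinct water molecular species (free water, hydration shells,
#: strongly bound water, ...).
DEFAULT_PEAK_CENTRES_NM = (1342, 1364, 1382, 1412, 1440, 1462, 1476, 1494)


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=float)))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


# Community surveys ----------------------------------------------------------

@dataclass(frozen=True)
class SpeciesSpec:
    """One species of the simulated pool: traits plus occupancy parameters.

    ``base_occupancy`` is the per-square presence probability in the first
    campaign; ``year_effect`` is the shift, on the logit scale, applied in the
    second campaign (positive = the species gains ground).
    """

    species: str
    traits: TraitRecord
    base_occupancy: float
    year_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.base_occupancy <= 1.0):
            raise ValidationError(
                f"base_occupancy must be in [0, 1], got {self.base_occupancy}"
            )


@dataclass(frozen=True)
class CommunitySimConfig:
    """Configuration of the two-campaign community-survey simulator."""

    species_pool: tuple[SpeciesSpec, ...]
    n_stations: int = 7
    trees_per_station: int = 10
    n_squares: int = 10
    years: tuple[int, int] = DEFAULT_YEARS
    station_ids: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stations < 1 or self.trees_per_station < 1:
            raise ValidationError("need at least one station and one tree")
        if self.n_squares < 1:
            raise ValidationError("n_squares must be >= 1")
        if not self.species_pool:
            raise ValidationError("species pool is empty")

    def stations(self) -> tuple[str, ...]:
        if self.station_ids is not None:
            if len(self.station_ids) != self.n_stations:
                raise ValidationError("station_ids length must equal n_stations")
            return self.station_ids
        base = list(DEFAULT_STATIONS)
        while len(base) < self.n_stations:
            base.append(f"Station-{len(base) + 1}")
        return tuple(base[: self.n_stations])


def default_species_pool(
    n_species: int = 30,
    eutrophication_effect: float = 0.0,
    seed: int = 0,
) -> tuple[SpeciesSpec, ...]:
    """Build a plausible species pool with Nimis-style ordinal traits.

    ``eutrophication_effect`` couples each species' between-campaign occupancy
    shift (logit scale) to its centred eutrophication-tolerance indicator:
    ``year_effect = eutrophication_effect * (tolerance - 3)``. With a positive
    coupling, nitrogen-tolerant species expand in the second campaign and
    sensitive ones retreat — the trait-linked community change the trait
    regression is meant to recover.
    """
    rng = np.random.default_rng(seed)
    genera = [
        "Physcia", "Parmelia", "Xanthoria", "Melanelixia", "Hyperphyscia",
        "Ramalina", "Pseudevernia", "Anaptychia", "Pleurosticta", "Melanohalea",
        "Evernia", "Flavoparmelia", "Lecanora", "Candelaria", "Phaeophyscia",
    ]
    epithets = [
        "adscendens", "tenella", "sulcata", "parietina", "glabratula",
        "exasperatula", "farinacea", "furfuracea", "ciliaris", "acetabulum",
        "prunastri", "caperata", "chlarotera", "concolor", "orbicularis",
        "serrana", "aipolia", "fraxinea", "carporrhizans", "stellaris",
    ]
    names = [f"{g} {e}" for g, e in itertools.product(genera, epithets)]
    rng.shuffle(names)
    growth_forms = ("crustose", "foliose_broad", "foliose_narrow", "fruticose")
    repro = ("apothecia", "isidia", "soredia")
    pool = []
    for k in range(n_species):
        tol = float(rng.integers(1, 6))  # ordinal 1..5
        ph = float(rng.integers(1, 6))
        traits = TraitRecord(
            species=names[k],
            ph_indicator=ph,
            eutrophication_tolerance=tol,
            growth_form=growth_forms[int(rng.integers(0, 4))],
            reproductive_structure=repro[int(rng.integers(0, 3))],
        )
        pool.append(
            SpeciesSpec(
                species=names[k],
                traits=traits,
                base_occupancy=float(rng.uniform(0.15, 0.7)),
                year_effect=eutrophication_effect * (tol - 3.0),
            )
        )
    return tuple(pool)


def generate_survey(cfg: CommunitySimConfig) -> list[SpeciesObservation]:
    """Simulate both campaigns of a community survey.

    For species s on a tree in year y the per-square occupancy is
    ``p = logistic(logit(base_occupancy_s) + [y == year2] * year_effect_s)``
    and the recorded frequency is Binomial(n_squares, p); frequency-0
    draws produce no row (absence is encoded by absence).
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[SpeciesObservation] = []
    year1, year2 = cfg.years
    for station in cfg.stations():
        for t in range(cfg.trees_per_station):
            tree_id = f"{station}/tree{t + 1:02d}"
            for year in (year1, year2):
                for spec in cfg.species_pool:
                    p0 = min(max(spec.base_occupancy, 1e-12), 1 - 1e-12)
                    z = _logit(p0) + (year == year2) * spec.year_effect
                    p = float(_logistic(z))
                    if spec.base_occupancy == 0.0:
                        p = 0.0
                    elif spec.base_occupancy == 1.0 and spec.year_effect == 0.0:
                        p = 1.0
                    freq = int(rng.binomial(cfg.n_squares, p))
                    if freq > 0:
                        out.append(
                            SpeciesObservation(
                                station_id=station,
                                tree_id=tree_id,
                                year=year,
                                species=spec.species,
                                frequency=min(freq, 10),
                            )
                        )
    return out


# Thallus damage --------------------------------------------------------------

#: Affected-surface breakpoints mapping symptom extent to categories 1..5;
#: category 5 anchored at necrosis over >= 90% of the thallus.
DI_EXTENT_BREAKPOINTS = (0.0, 0.1, 0.25, 0.5, 0.9)

_SYMPTOM_TYPES = (
    "colour_change",
    "necrosis",
    "twisting",
    "stain",
    "parasite",
    "excessive_reproductive_structures",
    "surface_loss",
)


@dataclass(frozen=True)
class DamageSimConfig:
    """Configuration of the thallus damage-record simulator.

    ``stress`` maps (station_id, year) to the latent stress level mu that
    locates the ordered five-category symptom distribution: a symptom's
    category is ``1 + #{cutpoints below mu + size_effect*(size - median) + N(0,1)}``
    with cutpoints (0.5, 1.5, 2.5, 3.5). ``symptom_rate`` is the Poisson mean
    number of symptoms per thallus.
    """

    stress: Mapping[tuple[str, int], float]
    species: tuple[str, ...] = TARGET_SPECIES
    trees_per_station: int = 5
    thalli_per_species_per_tree: int = 10
    symptom_rate: float = 1.0
    size_log_mean: float = 1.8   # median ~ 6 cm
    size_log_sd: float = 0.4
    size_effect: float = 0.0
    thalli_counts: Mapping[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.thalli_per_species_per_tree <= 10):
            raise ValidationError("thalli_per_species_per_tree must be in 1..10")
        if self.symptom_rate < 0:
            raise ValidationError("symptom_rate must be >= 0")
        if self.size_log_sd < 0:
            raise ValidationError("size_log_sd must be >= 0")
        if not self.stress:
            raise ValidationError("stress map is empty")


_CUTPOINTS = np.array([0.5, 1.5, 2.5, 3.5])


def _draw_symptoms(
    rng: np.random.Generator, mu: float, size_shift: float, rate: float
) -> tuple[SymptomRecord, ...]:
    n_sym = int(rng.poisson(rate))
    symptoms = []
    for _ in range(n_sym):
        z = mu + size_shift + rng.standard_normal()
        category = int(1 + np.sum(z > _CUTPOINTS))
        lo = DI_EXTENT_BREAKPOINTS[category - 1]
        hi = DI_EXTENT_BREAKPOINTS[category] if category < 5 else 1.0
        symptoms.append(
            SymptomRecord(
                symptom_type=_SYMPTOM_TYPES[int(rng.integers(0, len(_SYMPTOM_TYPES)))],
                affected_fraction=float(rng.uniform(lo, hi)),
                location=("centre", "lobes")[int(rng.integers(0, 2))],
                category=category,
            )
        )
    return tuple(symptoms)


def generate_thalli(cfg: DamageSimConfig) -> list[ThallusRecord]:
    """Simulate thallus damage records for every (station, year) in ``stress``.

    With ``thalli_counts`` given, exactly that many thalli are drawn per year,
    allocated at random over (station, tree, species) cells subject to the
    10-per-cell protocol cap; otherwise every cell yields
    ``thalli_per_species_per_tree`` thalli.
    """
    rng = np.random.default_rng(cfg.seed)
    out: list[ThallusRecord] = []
    stations_by_year: dict[int, list[str]] = {}
    for (station, year) in cfg.stress:
        stations_by_year.setdefault(year, []).append(station)

    for year in sorted(stations_by_year):
        stations = sorted(stations_by_year[year])
        cells = [
            (st, f"{st}/tree{t + 1:02d}", sp)
            for st in stations
            for t in range(cfg.trees_per_station)
            for sp in cfg.species
        ]
        if cfg.thalli_counts is not None:
            n_total = int(cfg.thalli_counts[year])
            capacity = len(cells) * cfg.thalli_per_species_per_tree
            if n_total > capacity:
                raise ValidationError(
                    f"requested {n_total} thalli for {year} exceeds capacity {capacity}"
                )
            slots = np.repeat(
                np.arange(len(cells)), cfg.thalli_per_species_per_tree
            )
            chosen = rng.permutation(slots)[:n_total]
            counts = np.bincount(chosen, minlength=len(cells))
        else:
            counts = np.full(len(cells), cfg.thalli_per_species_per_tree)
        for (st, tree, sp), n_cell in zip(cells, counts):
            mu = float(cfg.stress[(st, year)])
            for _ in range(int(n_cell)):
                size = float(np.exp(cfg.size_log_mean + cfg.size_log_sd * rng.standard_normal()))
                size_shift = cfg.size_effect * (size - float(np.exp(cfg.size_log_mean)))
                out.append(
                    ThallusRecord(
                        station_id=st,
                        tree_id=tree,
                        year=year,
                        species=sp,
                        size=size,
                        symptoms=_draw_symptoms(rng, mu, size_shift, cfg.symptom_rate),
                    )
                )
    return out


# Air quality -----------------------------------------------------------------

@dataclass(frozen=True)
class AirQualitySimConfig:
    """Annual air-quality series: exponentially declining SO2 (halving time
    set by ``so2_decay``), flat O3, and linearly warming temperature."""

    station_ids: tuple[str, ...] = DEFAULT_STATIONS
    years: tuple[int, int] = (1996, 2023)
    records_per_year: int = 12
    so2_start: float = 25.0
    so2_decay: float = 0.12      # per-year exponential decline rate
    o3_mean: float = 70.0
    temp_start: float = 12.0
    temp_trend: float = 0.03     # degC per year
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.so2_start < 0 or self.o3_mean < 0:
            raise ValidationError("air-quality config values must be non-negative")
        if self.records_per_year < 1:
            raise ValidationError("records_per_year must be >= 1")


def generate_airquality(cfg: AirQualitySimConfig) -> list[AirQualityRecord]:
    """Simulate the monitoring-network series; gas values are clipped at 0."""
    rng = np.random.default_rng(cfg.seed)
    out: list[AirQualityRecord] = []
    y0, y1 = cfg.years
    for station in cfg.station_ids:
        for year in range(y0, y1 + 1):
            t = year - y0
            means = {
                "SO2": cfg.so2_start * np.exp(-cfg.so2_decay * t),
                "O3": cfg.o3_mean,
                "temperature": cfg.temp_start + cfg.temp_trend * t,
            }
            for var, mean in means.items():
                noise = cfg.noise_sd * rng.standard_normal(cfg.records_per_year)
                vals = mean + noise
                if var != "temperature":
                    vals = np.clip(vals, 0.0, None)
                for v in vals:
                    out.append(
                        AirQualityRecord(
                            station_id=station, year=year, variable=var, value=float(v)
                        )
                    )
    return out


# Vis-NIR spectra --------------------------------------------------------------

def _default_label_scheme() -> dict[str, dict[str, float]]:
    return {
        "reproductive_structures": {"normal": 0.835, "excessive": 0.165},
        "growth_form": {"foliose": 0.65, "fruticose": 0.35},
        "reproduction_strategy": {"apothecia": 0.40, "isidia": 0.25, "soredia": 0.35},
        "phorophyte": {"Pinus": 0.5, "Quercus": 0.5},
        "bioclimatic_belt": {"19c": 0.5, "22a": 0.5},
    }


def _default_class_effects() -> dict[str, dict[str, dict[int, float]]]:
    # label field -> class -> {peak centre nm: additive amplitude shift}
    return {
        "reproductive_structures": {"excessive": {1412: 0.040, 1462: -0.030}},
        "growth_form": {"fruticose": {1342: 0.045, 1440: -0.035}},
        "reproduction_strategy": {
            "isidia": {1364: 0.040},
            "soredia": {1494: 0.040, 1382: -0.025},
        },
        "phorophyte": {"Quercus": {1382: 0.030, 1476: -0.030}},
        "bioclimatic_belt": {"22a": {1440: 0.035, 1494: -0.025}},
    }


@dataclass(frozen=True)
class SpectraSimConfig:
    """Configuration of the Vis-NIR thallus-spectra simulator.

    Each clean spectrum is a smooth reflectance baseline plus Gaussian peaks
    at ``peak_centres_nm`` whose amplitudes carry additive class effects; the
    recorded spectrum is ``b * clean + a + noise`` with ``b`` log-normal
    around 1 (sigma ``scatter_sd``) and ``a`` normal (sd ``offset_sd``).
    """

    n_samples: int = 195
    wavelength_range_nm: tuple[int, int] = (350, 2500)
    label_scheme: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_label_scheme
    )
    #: optional conditional proportions of reproduction_strategy given
    #: growth_form, to mimic trait confounding; None = independent draws
    strategy_given_growth_form: Mapping[str, Mapping[str, float]] | None = None
    peak_centres_nm: tuple[int, ...] = DEFAULT_PEAK_CENTRES_NM
    peak_width_nm: float = 16.0
    peak_amplitude: float = 0.10
    class_effects: Mapping[str, Mapping[str, Mapping[int, float]]] = field(
        default_factory=_default_class_effects
    )
    scatter_sd: float = 0.10
    offset_sd: float = 0.02
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise ValidationError("need at least 4 samples")
        for sd in (self.scatter_sd, self.offset_sd, self.noise_sd):
            if sd < 0:
                raise ValidationError("spread parameters must be >= 0")
        for fld, props in self.label_scheme.items():
            if fld not in SPECTRA_LABEL_FIELDS:
                raise ValidationError(f"unknown label field {fld!r}")
            total = sum(props.values())
            if abs(total - 1.0) > 1e-6 or any(p < 0 for p in props.values()):
                raise ValidationError(f"class proportions for {fld!r} must sum to 1")


def _draw_labels(cfg: SpectraSimConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_samples
    cols: dict[str, np.ndarray] = {}
    for fld, props in cfg.label_scheme.items():
        classes = sorted(props)
        p = np.array([props[c] for c in classes])
        cols[fld] = np.array(classes, dtype=object)[rng.choice(len(classes), size=n, p=p)]
    if cfg.strategy_given_growth_form is not None:
        strat = np.empty(n, dtype=object)
        for i in range(n):
            cond = cfg.strategy_given_growth_form[str(cols["growth_form"][i])]
            classes = sorted(cond)
            p = np.array([cond[c] for c in classes])
            strat[i] = classes[int(rng.choice(len(classes), p=p))]
        cols["reproduction_strategy"] = strat
    labels = pd.DataFrame(cols, index=[f"S{i + 1:03d}" for i in range(n)])
    for fld in labels.columns:
        counts = labels[fld].value_counts()
        if (counts < 2).any() or len(counts) < 2:
            raise ValidationError(
                f"label field {fld!r} needs >= 2 samples in >= 2 classes; "
                f"got {counts.to_dict()}"
            )
    return labels


def _baseline(wl: np.ndarray) -> np.ndarray:
    # gently sloping reflectance with two broad absorption troughs (1930,
    # 2450 nm combination bands) so the full grid looks plausibly NIR-like
    x = (wl - 350.0) / 2150.0
    base = 0.60 - 0.10 * x
    base -= 0.08 * np.exp(-0.5 * ((wl - 1930.0) / 90.0) ** 2)
    base -= 0.05 * np.exp(-0.5 * ((wl - 2450.0) / 120.0) ** 2)
    return base


def generate_spectra(cfg: SpectraSimConfig) -> SpectraMatrix:
    """Simulate a labelled reflectance matrix on the full 1-nm grid."""
    rng = np.random.default_rng(cfg.seed)
    labels = _draw_labels(cfg, rng)
    lo, hi = cfg.wavelength_range_nm
    wl = np.arange(lo, hi + 1)
    n = cfg.n_samples
    centres = np.asarray(cfg.peak_centres_nm, dtype=float)
    shapes = np.exp(
        -0.5 * ((wl[None, :] - centres[:, None]) / cfg.peak_width_nm) ** 2
    )  # (n_peaks, n_wl)

    amplitudes = np.full((n, centres.size), cfg.peak_amplitude)
    for fld, per_class in cfg.class_effects.items():
        if fld not in labels.columns:
            continue
        for cls, shifts in per_class.items():
            members = (labels[fld].to_numpy() == cls)
            for centre, delta in shifts.items():
                idx = np.where(centres == float(centre))[0]
                if idx.size == 0:
                    raise ValidationError(
                        f"class effect references unknown peak centre {centre} nm"
                    )
                amplitudes[members, idx[0]] += delta

    clean = _baseline(wl)[None, :] - amplitudes @ shapes  # peaks absorb
    b = np.exp(cfg.scatter_sd * rng.standard_normal(n))
    a = cfg.offset_sd * rng.standard_normal(n)
    noise = cfg.noise_sd * rng.standard_normal((n, wl.size))
    values = clean * b[:, None] + a[:, None] + noise
    return SpectraMatrix(list(labels.index), wl, values, labels)
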