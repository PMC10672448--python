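"""Damage Index (DI) scoring and between-campaign damage comparisons.

The DI is an ordinal 1-5 category of visible thallus injury: 1 = no visible
damage, 5 = necrosis over >= 90% of the thallus / dead. A thallus presenting
several symptoms takes the maximum category over them (the max rule). The
module summarizes DI per locality and campaign, tests between-campaign change
with the shared pooled t-test, builds the per-species change matrix, and
checks for a thallus-size effect.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .biodiversity import TraitEffectResult, compare_years, trait_effect
from .datamodel import SymptomRecord, TARGET_SPECIES, ThallusRecord, ValidationError

logger = logging.getLogger(__name__)

#: Affected-fraction breakpoints for categories 1..5 (configurable stand-in
#: for species-specific field range tables; category 5 anchored at necrosis
#: over >= 90% of the thallus).
DEFAULT_EXTENT_BREAKPOINTS = (0.0, 0.1, 0.25, 0.5, 0.9)


def category_from_extent(
    affected_fraction: float,
    breakpoints: Sequence[float] = DEFAULT_EXTENT_BREAKPOINTS,
) -> int:
    """Map an affected-surface fraction to a 1-5 damage category."""
    if not (0.0 <= affected_fraction <= 1.0):
        raise ValidationError(f"affected fraction must be in [0, 1], got {affected_fraction}")
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size != 5 or bp[0] != 0.0 or np.any(np.diff(bp) <= 0):
        raise ValidationError("breakpoints must be 5 increasing values starting at 0")
    return int(np.searchsorted(bp, affected_fraction, side="right"))


def assign_di(symptoms: Iterable[SymptomRecord]) -> int:
    """Max-rule damage category of a thallus: 1 when symptom-free, else the
    maximum category over its symptoms."""
    cats = []
    for s in symptoms:
        if s.category not in (1, 2, 3, 4, 5):
            raise ValidationError(f"damage category must be in 1..5, got {s.category}")
        cats.append(s.category)
    return max(cats, default=1)


def di_summary(
    records: Iterable[ThallusRecord],
    by: Sequence[str] = ("station_id", "year"),
) -> pd.DataFrame:
    """Per-group (n, mean, sd) of max-rule DI; empty input yields an empty table."""
    rows = [
        (r.station_id, r.year, r.species, r.max_di) for r in records
    ]
    df = pd.DataFrame(rows, columns=["station_id", "year", "species", "max_di"])
    if df.empty:
        logger.warning("di_summary called with no records")
        return pd.DataFrame(columns=[*by, "n", "mean", "sd"])
    grouped = df.groupby(list(by))["max_di"].agg(n="count", mean="mean", sd="std")
    grouped["sd"] = grouped["sd"].fillna(0.0)
    return grouped.reset_index()


def di_compare(
    records: Iterable[ThallusRecord],
    year1: int,
    year2: int,
    per_species: bool = False,
) -> pd.DataFrame:
    """Per-locality pooled t-test of DI between campaigns.

    Thalli are pooled across species and trees within each locality (one
    comparison per locality); with ``per_species`` an additional breakdown per
    (station, species) is emitted where both campaigns have >= 2 thalli.
    """
    df = pd.DataFrame(
        [(r.station_id, r.year, r.species, r.max_di) for r in records],
        columns=["station_id", "year", "species", "max_di"],
    )
    keys = ["station_id", "species"] if per_species else ["station_id"]
    rows = []
    for key, grp in df.groupby(keys):
        x = grp.loc[grp["year"] == year1, "max_di"].to_numpy(dtype=float)
        y = grp.loc[grp["year"] == year2, "max_di"].to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            logger.warning("skipping group %s: fewer than 2 thalli in a campaign", key)
            continue
        try:
            t, dof, p = compare_years(x, y)
        except ValidationError as e:
            logger.warning("skipping group %s: %s", key, e)
            continue
        base = key if isinstance(key, tuple) else (key,)
        rows.append((*base, x.size, y.size, x.mean(), y.mean(), t, dof, p))
    return pd.DataFrame(
        rows, columns=[*keys, "n1", "n2", "mean1", "mean2", "t", "df", "p"]
    )


def di_change(
    records: Iterable[ThallusRecord],
    year1: int = 1997,
    year2: int = 2022,
    target_species: Sequence[str] = TARGET_SPECIES,
) -> pd.DataFrame:
    """Species x station matrix of mean-DI change between campaigns.

    Cells with no thalli in either campaign are NaN; rows are ordered from
    larger to smaller absolute change (row-mean over observed stations).
    Species outside the configured target list warn and are excluded.
    """
    recs = list(records)
    years = {r.year for r in recs}
    if year1 not in years or year2 not in years:
        raise ValidationError(f"both campaigns {year1} and {year2} must be present")
    targets = set(target_species)
    unknown = sorted({r.species for r in recs} - targets)
    if unknown:
        logger.warning("excluding non-target species from DI change: %s", unknown)
    df = pd.DataFrame(
        [
            (r.station_id, r.year, r.species, r.max_di)
            for r in recs
            if r.species in targets
        ],
        columns=["station_id", "year", "species", "max_di"],
    )
    means = df.groupby(["species", "station_id", "year"])["max_di"].mean()
    pivot = means.unstack("year")
    change = (pivot.get(year2) - pivot.get(year1)).unstack("station_id")
    order = change.abs().mean(axis=1, skipna=True).sort_values(ascending=False).index
    change = change.loc[order]
    change.index.name = "species"
    change.columns.name = "station_id"
    return change


def size_effect(
    records: Iterable[ThallusRecord],
    per_species: bool = False,
) -> TraitEffectResult | dict[str, TraitEffectResult]:
    """OLS of max-rule DI on thallus size (cm), pooled or per species.

    A constant-DI group yields a degenerate result (r undefined, flagged)
    rather than an exception; zero size variance is an error.
    """
    recs = list(records)
    if per_species:
        out: dict[str, TraitEffectResult] = {}
        by_species: dict[str, list[ThallusRecord]] = {}
        for r in recs:
            by_species.setdefault(r.species, []).append(r)
        for sp, group in sorted(by_species.items()):
            if len(group) >= 3:
                out[sp] = size_effect(group)
        return out
    if len(recs) < 3:
        raise ValidationError("need >= 3 thalli with size for a size-effect fit")
    sizes = [r.size for r in recs]
    dis = [float(r.max_di) for r in recs]
    if np.allclose(np.var(sizes), 0.0):
        raise ValidationError("zero variance in thallus size")
    return trait_effect(dis, sizes, trait="size")
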