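"""Community-level analysis: IAP, campaign comparisons, ordination, traits.

The Index of Atmospheric Purity (IAP) summarizes the epiphytic lichen
community of a tree as the sum of per-species quadrat frequencies
(``IAP_tree = sum_i f_i``) and of a station as the mean over its m sampled
trees (``IAP_station = sum IAP_tree / m``). Between-campaign change is tested
per locality with a pooled-variance Student's t over trees; community
composition is ordinated with nonmetric multidimensional scaling on
Bray-Curtis dissimilarities; trait-linked change is quantified with ordinary
least squares (numeric indicators) and one-way ANOVA (categorical traits).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _scipy_braycurtis, pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .datamodel import IAPResult, SpeciesObservation, ValidationError


# IAP -------------------------------------------------------------------------

def iap_tree(observations: Iterable[SpeciesObservation]) -> float:
    """Sum of species frequencies on one tree in one campaign (empty set -> 0)."""
    obs = list(observations)
    if obs:
        keys = {(o.tree_id, o.year) for o in obs}
        if len(keys) > 1:
            raise ValidationError(f"observations span several trees/years: {sorted(keys)}")
    return float(sum(o.frequency for o in obs))


def iap_station(
    per_tree: Mapping[str, float], station_id: str = "", year: int = 0
) -> IAPResult:
    """Station IAP = arithmetic mean of per-tree IAP values (m recorded)."""
    if len(per_tree) == 0:
        raise ValidationError(f"no trees for station {station_id!r}")
    values = dict(per_tree)
    return IAPResult(
        station_id=station_id,
        year=year,
        per_tree=values,
        station_value=float(np.mean(list(values.values()))),
        n_trees=len(values),
    )


def iap_by_station(observations: Iterable[SpeciesObservation]) -> list[IAPResult]:
    """Compute IAP per (station, year) from a full survey."""
    obs = list(observations)
    if not obs:
        return []
    df = pd.DataFrame(
        [(o.station_id, o.tree_id, o.year, o.frequency) for o in obs],
        columns=["station_id", "tree_id", "year", "frequency"],
    )
    per_tree = (
        df.groupby(["station_id", "year", "tree_id"])["frequency"].sum().reset_index()
    )
    out = []
    for (station, year), grp in per_tree.groupby(["station_id", "year"]):
        out.append(
            iap_station(
                dict(zip(grp["tree_id"], grp["frequency"].astype(float))),
                station_id=str(station),
                year=int(year),
            )
        )
    return out


# Between-campaign comparison --------------------------------------------------

def compare_years(
    values_year1: Sequence[float],
    values_year2: Sequence[float],
    welch: bool = False,
) -> tuple[float, int, float]:
    """Two-sided Student's t between two campaigns' values.

    Pooled-variance by default (``df = n1 + n2 - 2``); Welch behind a flag.
    Zero pooled variance with equal means returns (0, df, 1).
    """
    x = np.asarray(values_year1, dtype=float)
    y = np.asarray(values_year2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each campaign needs at least 2 values")
    df = int(x.size + y.size - 2)
    sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if sp2 <= 0:
        if np.isclose(x.mean(), y.mean()):
            return 0.0, df, 1.0
        raise ValidationError("zero pooled variance with unequal means")
    if welch:
        res = stats.ttest_ind(x, y, equal_var=False)
        return float(res.statistic), int(np.floor(res.df)), float(res.pvalue)
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), df, float(p)


def compare_stations_by_year(
    observations: Iterable[SpeciesObservation],
    year1: int,
    year2: int,
    holm: bool = False,
) -> pd.DataFrame:
    """Per-locality t-test of per-tree IAP values between campaigns.

    Returns a table (station_id, n1, n2, mean1, mean2, t, df, p); raw p values
    by default, Holm-adjusted in an extra column when ``holm`` is set.
    """
    results = iap_by_station(observations)
    by_station: dict[str, dict[int, list[float]]] = {}
    for r in results:
        by_station.setdefault(r.station_id, {})[r.year] = list(r.per_tree.values())
    rows = []
    for station in sorted(by_station):
        vals = by_station[station]
        if year1 not in vals or year2 not in vals:
            continue
        t, df, p = compare_years(vals[year1], vals[year2])
        rows.append(
            (
                station,
                len(vals[year1]),
                len(vals[year2]),
                float(np.mean(vals[year1])),
                float(np.mean(vals[year2])),
                t,
                df,
                p,
            )
        )
    out = pd.DataFrame(
        rows, columns=["station_id", "n1", "n2", "mean1", "mean2", "t", "df", "p"]
    )
    if holm and len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(1.0, running)
        out["p_holm"] = adj
    return out


# Frequency change --------------------------------------------------------------

def frequency_change(
    observations: Iterable[SpeciesObservation], year1: int, year2: int
) -> pd.DataFrame:
    """Species x station matrix of mean-frequency change between campaigns.

    Each cell is mean frequency in ``year2`` minus mean frequency in ``year1``,
    the means taken over the trees sampled at that station in that campaign
    (a species absent from a tree contributes 0). Cells for species never
    observed at a station in either campaign are NaN (not observed).
    """
    obs = list(observations)
    years = {o.year for o in obs}
    for y in (year1, year2):
        if y not in years:
            raise ValidationError(f"campaign year {y} not present in survey")
    df = pd.DataFrame(
        [(o.station_id, o.tree_id, o.year, o.species, o.frequency) for o in obs],
        columns=["station_id", "tree_id", "year", "species", "frequency"],
    )
    n_trees = (
        df.groupby(["station_id", "year"])["tree_id"].nunique().rename("n_trees")
    )
    sums = (
        df.groupby(["station_id", "year", "species"])["frequency"].sum().rename("sum_f")
    )
    means = (sums / n_trees).rename("mean_f").reset_index()
    pivot = means.pivot_table(
        index="species", columns=["station_id", "year"], values="mean_f"
    )
    stations = sorted(df["station_id"].unique())
    out = pd.DataFrame(index=pivot.index, columns=stations, dtype=float)
    for st in stations:
        m1 = pivot.get((st, year1))
        m2 = pivot.get((st, year2))
        m1 = m1 if m1 is not None else pd.Series(np.nan, index=pivot.index)
        m2 = m2 if m2 is not None else pd.Series(np.nan, index=pivot.index)
        observed = m1.notna() | m2.notna()
        diff = m2.fillna(0.0) - m1.fillna(0.0)
        out[st] = diff.where(observed)
    out.index.name = "species"
    out.columns.name = "station_id"
    return out


# Dissimilarity and ordination ---------------------------------------------------

def bray_curtis(profile_a: Sequence[float], profile_b: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity ``1 - 2 sum(min) / (sum a + sum b)`` in [0, 1]."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("profiles must share a species index")
    if (a < 0).any() or (b < 0).any():
        raise ValidationError("frequency profiles must be non-negative")
    if a.sum() == 0 and b.sum() == 0:
        raise ValidationError("both profiles are all-zero")
    return float(_scipy_braycurtis(a, b))


def tree_profiles(
    observations: Iterable[SpeciesObservation],
) -> pd.DataFrame:
    """Per-(tree, year) species frequency profiles (trees x species, 0-filled)."""
    df = pd.DataFrame(
        [(f"{o.tree_id}@{o.year}", o.species, o.frequency) for o in observations],
        columns=["tree", "species", "frequency"],
    )
    return df.pivot_table(
        index="tree", columns="species", values="frequency", fill_value=0.0
    )


def dissimilarity_matrix(profiles: pd.DataFrame, metric: str = "braycurtis") -> np.ndarray:
    """Square dissimilarity matrix over profile rows (braycurtis or euclidean)."""
    if metric not in ("braycurtis", "euclidean"):
        raise ValidationError(f"unknown dissimilarity metric {metric!r}")
    return squareform(pdist(profiles.to_numpy(dtype=float), metric=metric))


@dataclass(frozen=True)
class OrdinationResult:
    """NMDS embedding with its Kruskal stress-1."""

    coordinates: np.ndarray
    stress: float
    converged: bool
    n_restarts: int
    seed: int


def _stress1(dissim: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration: isotonic disparities vs distances."""
    iu = np.triu_indices(dissim.shape[0], k=1)
    d_obs = dissim[iu]
    d_emb = squareform(pdist(coords))[iu]
    order = np.argsort(d_obs, kind="stable")
    iso = IsotonicRegression(increasing=True)
    dhat = np.empty_like(d_emb)
    dhat[order] = iso.fit_transform(np.arange(order.size), d_emb[order])
    denom = float(np.sum(d_emb**2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_emb - dhat) ** 2) / denom))


def nmds(
    dissimilarity: np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    eps: float = 1e-6,
) -> OrdinationResult:
    """Nonmetric multidimensional scaling, best of ``n_restarts`` SMACOF runs.

    Each run alternates monotone (isotonic) regression of disparities on the
    embedding distances with majorization updates of the configuration; the
    restart with the lowest Kruskal stress-1 is returned.
    """
    D = np.asarray(dissimilarity, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise ValidationError("dissimilarity matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-12):
        raise ValidationError("dissimilarity matrix must have a zero diagonal")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if D.shape[0] <= k:
        # trivially embeddable; place points by classical scaling of ranks
        coords, _ = smacof(
            D, metric=True, n_components=k, n_init=1, random_state=seed,
            max_iter=max_iter, eps=eps, normalized_stress=False,
        )
        return OrdinationResult(coords, _stress1(D, coords), True, 1, seed)
    best_coords = None
    best_stress = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        rs = int(rng.integers(0, 2**31 - 1))
        coords, _ = smacof(
            D,
            metric=False,
            n_components=k,
            n_init=1,
            random_state=rs,
            max_iter=max_iter,
            eps=eps,
            normalized_stress=False,
        )
        s1 = _stress1(D, coords)
        if s1 < best_stress:
            best_stress = s1
            best_coords = coords
    return OrdinationResult(
        coordinates=best_coords,
        stress=best_stress,
        converged=bool(np.isfinite(best_stress)),
        n_restarts=n_restarts,
        seed=seed,
    )


# Trait models --------------------------------------------------------------------

@dataclass(frozen=True)
class TraitEffectResult:
    """OLS fit of per-species abundance (or damage) change on a numeric trait."""

    trait: str
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_species: int
    degenerate: bool = False


def trait_effect(
    change: Sequence[float],
    trait_values: Sequence[float],
    trait: str = "trait",
) -> TraitEffectResult:
    """Least-squares slope/intercept with Pearson r and its two-sided p."""
    y = np.asarray(change, dtype=float)
    x = np.asarray(trait_values, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need >= 3 species with both change and trait values")
    if np.allclose(x.var(), 0.0):
        raise ValidationError(f"trait {trait!r} has zero variance")
    if np.allclose(y.var(), 0.0):
        # constant response: slope 0, correlation undefined
        return TraitEffectResult(trait, 0.0, float(y.mean()), float("nan"), 1.0,
                                 int(x.size), degenerate=True)
    fit = stats.linregress(x, y)
    return TraitEffectResult(
        trait=trait,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_species=int(x.size),
    )


def trait_anova(
    change: Sequence[float], groups: Sequence[str]
) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA of change across categorical trait groups."""
    y = np.asarray(change, dtype=float)
    g = np.asarray(groups)
    if y.size != g.size:
        raise ValidationError("change and group labels differ in length")
    samples = [y[g == lvl] for lvl in pd.unique(g)]
    if len(samples) < 2:
        raise ValidationError("need >= 2 trait groups")
    for lvl, s in zip(pd.unique(g), samples):
        if s.size < 2:
            raise ValidationError(f"group {lvl!r} has fewer than 2 members")
    f, p = stats.f_oneway(*samples)
    df1 = len(samples) - 1
    df2 = int(y.size - len(samples))
    if not np.isfinite(f):  # all values equal
        f, p = 0.0, 1.0
    return float(f), df1, df2, float(p)
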