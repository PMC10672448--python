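"""End-to-end orchestration: simulate -> indices -> damage -> air -> spectra.

Every stage is runnable standalone from intermediate CSV files, so real field
tables can be substituted for any simulated one; ``run_all`` chains them from
a single YAML configuration and records a JSON run manifest (config snapshot,
seeds, per-stage outputs with row counts, package version).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import AirQualityRecord, TARGET_SPECIES, ValidationError
from . import biodiversity, chemometrics, damage, io, synthetic

logger = logging.getLogger(__name__)


def annual_means(records: Iterable[AirQualityRecord]) -> pd.DataFrame:
    """Arithmetic mean per (station, year, variable); empty cells are omitted."""
    df = pd.DataFrame(
        [(r.station_id, r.year, r.variable, r.value) for r in records],
        columns=["station_id", "year", "variable", "value"],
    )
    if df.empty:
        return pd.DataFrame(columns=["station_id", "year", "variable", "mean"])
    out = (
        df.groupby(["station_id", "year", "variable"])["value"]
        .mean()
        .rename("mean")
        .reset_index()
    )
    return out


def default_config(seed: int = 0) -> dict[str, Any]:
    """Demo configuration exercising every stage at modest problem sizes."""
    return {
        "seed": seed,
        "years": [1997, 2022],
        "community": {
            "n_stations": 7,
            "trees_per_station": 10,
            "n_species": 30,
            "eutrophication_effect": -0.4,
        },
        "damage": {
            "trees_per_station": 5,
            "thalli_per_species_per_tree": 4,
            "symptom_rate": 1.0,
            "stress_1997": 1.0,
            "stress_2022": 1.6,
        },
        "airquality": {},
        "spectra": {
            "n_samples": 195,
            "label_fields": ["growth_form", "reproductive_structures"],
            "n_test": 58,
            "max_lv": 15,
            "k_folds": 10,
        },
    }


def load_config(path: str | Path | None, seed: int | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the defaults; ``seed`` overrides both."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    if seed is not None:
        cfg["seed"] = int(seed)
    return cfg


@dataclass
class RunManifest:
    """What a run did: config, seeds, outputs with row counts, version."""

    config: dict[str, Any]
    seed: int
    version: str = __version__
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add_stage(self, name: str, outputs: Mapping[str, int], elapsed_s: float) -> None:
        self.stages.append(
            {
                "stage": name,
                "outputs": {str(k): int(v) for k, v in outputs.items()},
                "elapsed_s": round(elapsed_s, 3),
            }
        )

    def write(self, path: str | Path) -> None:
        for stage in self.stages:
            for out in stage["outputs"]:
                if not Path(out).exists():
                    raise ValidationError(f"manifest lists missing output {out}")
        with open(path, "w") as fh:
            json.dump(
                {
                    "version": self.version,
                    "seed": self.seed,
                    "config": self.config,
                    "stages": self.stages,
                },
                fh,
                indent=2,
                default=str,
            )


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> int:
    df.to_csv(path, index=index, float_format="%.3f")
    return len(df)


class _Stage:
    """Context manager logging a stage's wall time into the manifest."""

    def __init__(self, manifest: RunManifest, name: str) -> None:
        self.manifest = manifest
        self.name = name
        self.outputs: dict[str, int] = {}

    def __enter__(self) -> "_Stage":
        self.t0 = time.perf_counter()
        logger.info("stage %s: started", self.name)
        return self

    def __exit__(self, exc_type, exc, tb) -> None:
        elapsed = time.perf_counter() - self.t0
        if exc_type is not None:
            logger.error("stage %s: failed after %.2fs", self.name, elapsed)
            return
        self.manifest.add_stage(self.name, self.outputs, elapsed)
        logger.info("stage %s: done in %.2fs", self.name, elapsed)


def simulate_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    """Generate all five table kinds into ``outdir``."""
    seed = int(cfg["seed"])
    year1, year2 = cfg["years"]
    com = cfg["community"]
    with _Stage(manifest, "simulate") as st:
        pool = synthetic.default_species_pool(
            n_species=int(com["n_species"]),
            eutrophication_effect=float(com["eutrophication_effect"]),
            seed=seed,
        )
        survey = synthetic.generate_survey(
            synthetic.CommunitySimConfig(
                species_pool=pool,
                n_stations=int(com["n_stations"]),
                trees_per_station=int(com["trees_per_station"]),
                years=(year1, year2),
                seed=seed,
            )
        )
        io.write_survey(survey, outdir / "survey.csv")
        st.outputs[str(outdir / "survey.csv")] = len(survey)

        io.write_traits([s.traits for s in pool], outdir / "traits.csv")
        st.outputs[str(outdir / "traits.csv")] = len(pool)

        dmg = cfg["damage"]
        stations = synthetic.DEFAULT_STATIONS[: int(com["n_stations"])]
        stress = {(s, year1): float(dmg["stress_1997"]) for s in stations}
        stress.update({(s, year2): float(dmg["stress_2022"]) for s in stations})
        thalli = synthetic.generate_thalli(
            synthetic.DamageSimConfig(
                stress=stress,
                trees_per_station=int(dmg["trees_per_station"]),
                thalli_per_species_per_tree=int(dmg["thalli_per_species_per_tree"]),
                symptom_rate=float(dmg["symptom_rate"]),
                seed=seed + 1,
            )
        )
        io.write_thalli(thalli, outdir / "thalli.csv")
        st.outputs[str(outdir / "thalli.csv")] = len(thalli)

        air = synthetic.generate_airquality(
            synthetic.AirQualitySimConfig(noise_sd=2.0, seed=seed + 2)
        )
        io.write_airquality(air, outdir / "airquality.csv")
        st.outputs[str(outdir / "airquality.csv")] = len(air)

        spec_cfg = cfg["spectra"]
        spectra = synthetic.generate_spectra(
            synthetic.SpectraSimConfig(
                n_samples=int(spec_cfg["n_samples"]), seed=seed + 3
            )
        )
        io.write_spectra(
            spectra, outdir / "spectra.csv", labels_path=outdir / "spectra_labels.csv"
        )
        st.outputs[str(outdir / "spectra.csv")] = spectra.n_samples
        st.outputs[str(outdir / "spectra_labels.csv")] = spectra.n_samples


def iap_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    year1, year2 = cfg["years"]
    with _Stage(manifest, "iap") as st:
        survey = io.read_survey(outdir / "survey.csv")
        results = biodiversity.iap_by_station(survey)
        table = pd.DataFrame(
            [
                (r.station_id, r.year, r.n_trees, round(r.station_value, 3))
                for r in results
            ],
            columns=["station_id", "year", "n_trees", "iap_station"],
        )
        st.outputs[str(outdir / "iap_station.csv")] = _write_csv(
            table, outdir / "iap_station.csv"
        )
        comp = biodiversity.compare_stations_by_year(survey, year1, year2)
        st.outputs[str(outdir / "iap_comparison.csv")] = _write_csv(
            comp.round(3), outdir / "iap_comparison.csv"
        )


def traits_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    year1, year2 = cfg["years"]
    with _Stage(manifest, "traits") as st:
        survey = io.read_survey(outdir / "survey.csv")
        traits_path = outdir / "traits.csv"
        traits = {t.species: t for t in io.read_traits(traits_path)}
        change = biodiversity.frequency_change(survey, year1, year2)
        st.outputs[str(outdir / "frequency_change.csv")] = _write_csv(
            change.round(3), outdir / "frequency_change.csv", index=True
        )
        per_species = change.mean(axis=1, skipna=True)
        matched = [sp for sp in per_species.index if sp in traits]
        unmatched = sorted(set(per_species.index) - set(matched))
        if unmatched:
            logger.warning("species without trait records: %s", unmatched)
        rows = []
        for name, getter in (
            ("ph_indicator", lambda t: t.ph_indicator),
            ("eutrophication_tolerance", lambda t: t.eutrophication_tolerance),
        ):
            res = biodiversity.trait_effect(
                [per_species[sp] for sp in matched],
                [getter(traits[sp]) for sp in matched],
                trait=name,
            )
            rows.append(
                (name, round(res.slope, 3), round(res.intercept, 3),
                 round(res.pearson_r, 3), res.p_value, res.n_species)
            )
        effects = pd.DataFrame(
            rows, columns=["trait", "slope", "intercept", "pearson_r", "p", "n_species"]
        )
        st.outputs[str(outdir / "trait_effects.csv")] = _write_csv(
            effects, outdir / "trait_effects.csv"
        )
        anova_rows = []
        for name, getter in (
            ("growth_form", lambda t: t.growth_form),
            ("reproductive_structure", lambda t: t.reproductive_structure),
        ):
            groups = [getter(traits[sp]) for sp in matched]
            counts = pd.Series(groups).value_counts()
            keep = [i for i, g in enumerate(groups) if counts[g] >= 2]
            if len(set(groups[i] for i in keep)) < 2:
                logger.warning("ANOVA for %s skipped: not enough groups", name)
                continue
            f, df1, df2, p = biodiversity.trait_anova(
                [per_species[matched[i]] for i in keep], [groups[i] for i in keep]
            )
            anova_rows.append((name, round(f, 3), df1, df2, p))
        anova = pd.DataFrame(anova_rows, columns=["trait", "F", "df1", "df2", "p"])
        st.outputs[str(outdir / "trait_anova.csv")] = _write_csv(
            anova, outdir / "trait_anova.csv"
        )

        profiles = biodiversity.tree_profiles(survey)
        D = biodiversity.dissimilarity_matrix(profiles)
        ord_res = biodiversity.nmds(D, k=2, n_restarts=5, seed=int(cfg["seed"]))
        coords = pd.DataFrame(
            ord_res.coordinates, columns=["NMDS1", "NMDS2"], index=profiles.index
        )
        coords["stress"] = round(ord_res.stress, 4)
        st.outputs[str(outdir / "nmds_coordinates.csv")] = _write_csv(
            coords.round(4), outdir / "nmds_coordinates.csv", index=True
        )


def damage_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    year1, year2 = cfg["years"]
    with _Stage(manifest, "damage") as st:
        thalli = io.read_thalli(outdir / "thalli.csv")
        summary = damage.di_summary(thalli)
        st.outputs[str(outdir / "di_summary.csv")] = _write_csv(
            summary.round(3), outdir / "di_summary.csv"
        )
        comp = damage.di_compare(thalli, year1, year2)
        st.outputs[str(outdir / "di_comparison.csv")] = _write_csv(
            comp.round(3), outdir / "di_comparison.csv"
        )
        change = damage.di_change(thalli, year1, year2, TARGET_SPECIES)
        st.outputs[str(outdir / "di_change.csv")] = _write_csv(
            change.round(3), outdir / "di_change.csv", index=True
        )


def airquality_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    with _Stage(manifest, "airquality") as st:
        records = io.read_airquality(outdir / "airquality.csv")
        means = annual_means(records)
        st.outputs[str(outdir / "airquality_annual_means.csv")] = _write_csv(
            means.round(3), outdir / "airquality_annual_means.csv"
        )


def spectra_stage(cfg: dict[str, Any], outdir: Path, manifest: RunManifest) -> None:
    spec_cfg = cfg["spectra"]
    with _Stage(manifest, "spectra") as st:
        spectra = io.read_spectra(
            outdir / "spectra.csv", labels_path=outdir / "spectra_labels.csv"
        )
        all_metrics = []
        for label_field in spec_cfg["label_fields"]:
            res = chemometrics.run_plsda_experiment(
                spectra,
                label_field,
                chemometrics.PLSDAExperimentConfig(
                    n_test=int(spec_cfg["n_test"]),
                    max_lv=int(spec_cfg["max_lv"]),
                    k_folds=int(spec_cfg["k_folds"]),
                    seed=int(cfg["seed"]),
                ),
            )
            all_metrics.append(res.metrics)
            scores_path = outdir / f"pca_scores_{label_field}.csv"
            st.outputs[str(scores_path)] = _write_csv(
                res.pca_scores.round(4), scores_path, index=True
            )
        metrics = pd.concat(all_metrics, ignore_index=True)
        st.outputs[str(outdir / "plsda_metrics.csv")] = _write_csv(
            metrics, outdir / "plsda_metrics.csv"
        )


def run_all(
    config_path: str | Path | None = None,
    outdir: str | Path = "lichenmonitor_run",
    seed: int | None = None,
) -> RunManifest:
    """Run simulate -> iap -> traits -> damage -> airquality -> spectra -> report."""
    cfg = load_config(config_path, seed=seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg, seed=int(cfg["seed"]))
    for stage_fn in (
        simulate_stage,
        iap_stage,
        traits_stage,
        damage_stage,
        airquality_stage,
        spectra_stage,
    ):
        try:
            stage_fn(cfg, out, manifest)
        except Exception as e:
            raise RuntimeError(f"stage {stage_fn.__name__} failed: {e}") from e
    manifest.write(out / "manifest.json")
    return manifest
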