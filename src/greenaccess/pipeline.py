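"""End-to-end pipeline: configuration, file I/O, and orchestration.

A run goes: generate (or load) the city -> 2SFCA accessibility under
both travel modes -> street/district Gini coefficients -> assemble the
street-level feature table -> boosted-tree fit per response (mean
accessibility and Gini, per mode) with importance, key variables,
partial-dependence curves and an OLS comparison -> four-way scenario
classification.  Every artefact is written as CSV/JSON plus a run
manifest and a human-readable summary; a fixed seed makes the whole
run bit-reproducible.

One integer seed governs everything; per-stage streams are derived
with fixed offsets so that, e.g., changing boosting settings never
perturbs city generation.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from greenaccess import __version__ as _pkg_version
from greenaccess.access import (
    DemandCell,
    Gaussian2SFCA,
    Park,
    TravelTimeMatrix,
    aggregate_by_zone,
)
from greenaccess.effects import (
    compare_models,
    ols_fit,
    partial_dependence,
    select_key_variables,
)
from greenaccess.equity import zone_gini
from greenaccess.gbdt import GBDTHyperparams, GradientBoostedTrees, cross_validate
from greenaccess.scenarios import ScenarioThresholds, classify_all
from greenaccess.synthetic import (
    PREDICTORS,
    CityConfig,
    CityDataset,
    build_travel_time_matrix,
    generate_city,
    sample_predictors,
)

RESPONSES = ("ai_walking", "ai_driving", "gini_walking", "gini_driving")


@dataclass(frozen=True)
class EffectsSettings:
    """Partial-dependence and key-variable settings."""

    n_grid: int = 50
    quantile_range: tuple[float, float] = (0.01, 0.99)
    span: float = 0.5
    key_threshold_pct: float = 7.0

    def __post_init__(self) -> None:
        lo, hi = self.quantile_range
        if not (0 <= lo < hi <= 1):
            raise ValueError("quantile_range must satisfy 0 <= lo < hi <= 1")
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a full run.

    An empty config file yields the documented defaults: t0 = 15 min
    for both modes, capacity standards 60/50/40/30 m^2/person, 5000
    trees at learning rate 0.001 with quintuple cross-validation,
    simple-mean street aggregation, A_i*P_i Gini service mass, and the
    scenario cutoffs (walking 10, driving 1, Gini 0.5).
    """

    city: CityConfig = field(default_factory=CityConfig)
    t0: Mapping[str, float] = field(
        default_factory=lambda: {"walking": 15.0, "driving": 15.0}
    )
    aggregation_scheme: str = "simple-mean"
    gini_service_mass: str = "access_mass"
    gbdt: GBDTHyperparams = field(default_factory=GBDTHyperparams)
    effects: EffectsSettings = field(default_factory=EffectsSettings)
    scenarios: ScenarioThresholds = field(default_factory=ScenarioThresholds)
    write_travel_times: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for mode, v in self.t0.items():
            if not v > 0:
                raise ValueError(f"t0[{mode!r}] must be > 0, got {v}")
        if self.aggregation_scheme not in ("simple-mean", "population-weighted-mean"):
            raise ValueError(f"unknown aggregation_scheme {self.aggregation_scheme!r}")
        if self.gini_service_mass not in ("access_mass", "access"):
            raise ValueError(f"unknown gini_service_mass {self.gini_service_mass!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["city"]["n_parks_by_type"] = dict(self.city.n_parks_by_type)
        d["city"]["mode_speeds"] = dict(self.city.mode_speeds)
        d["city"]["area_ranges"] = {
            k: list(v) for k, v in self.city.area_ranges.items()
        }
        d["t0"] = dict(self.t0)
        d["effects"]["quantile_range"] = list(self.effects.quantile_range)
        d["scenarios"]["accessibility"] = dict(self.scenarios.accessibility)
        return d


_SECTIONS = {
    "city",
    "t0",
    "aggregation_scheme",
    "gini_service_mass",
    "gbdt",
    "effects",
    "scenarios",
    "write_travel_times",
    "seed",
}


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file, filling documented defaults.

    Unknown keys raise with the offending key named; an empty (or
    absent) file yields all defaults.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def build(cls, section: str):
        sub = raw.get(section, {}) or {}
        fields_ = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(sub) - fields_
        if bad:
            raise ValueError(f"unknown keys in {section!r}: {sorted(bad)}")
        if "quantile_range" in sub:
            sub["quantile_range"] = tuple(sub["quantile_range"])
        return cls(**sub)

    kwargs: dict = {}
    kwargs["city"] = build(CityConfig, "city")
    kwargs["gbdt"] = build(GBDTHyperparams, "gbdt")
    kwargs["effects"] = build(EffectsSettings, "effects")
    kwargs["scenarios"] = build(ScenarioThresholds, "scenarios")
    for key in ("t0", "aggregation_scheme", "gini_service_mass",
                "write_travel_times", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "t0" in kwargs and not isinstance(kwargs["t0"], Mapping):
        kwargs["t0"] = {"walking": float(kwargs["t0"]), "driving": float(kwargs["t0"])}
    return PipelineConfig(**kwargs)


def save_config(config: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# tabular readers for real-data runs


def read_cells_csv(path: str | Path) -> list[DemandCell]:
    """Cells from CSV with columns cell_id, x, y, population, street_id."""
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y", "population", "street_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cells file missing columns: {sorted(missing)}")
    return [
        DemandCell(str(r.cell_id), float(r.x), float(r.y), float(r.population),
                   str(r.street_id))
        for r in df.itertuples()
    ]


def read_parks_csv(path: str | Path) -> list[Park]:
    """Parks from CSV: park_id, type, area_m2, entrances (JSON list column)."""
    df = pd.read_csv(path)
    required = {"park_id", "type", "area_m2", "entrances"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"parks file missing columns: {sorted(missing)}")
    return [
        Park(str(r.park_id), str(r.type), float(r.area_m2),
             np.asarray(json.loads(r.entrances), dtype=float))
        for r in df.itertuples()
    ]


def read_travel_times_csv(
    path: str | Path, cells: list[DemandCell], parks: list[Park]
) -> dict[str, TravelTimeMatrix]:
    """Long-format (cell_id, park_id, mode, minutes) -> per-mode matrices."""
    df = pd.read_csv(path)
    out: dict[str, TravelTimeMatrix] = {}
    cell_ids = [c.id for c in cells]
    park_ids = [p.id for p in parks]
    for mode, grp in df.groupby("mode"):
        wide = grp.pivot(index="cell_id", columns="park_id", values="minutes")
        wide = wide.reindex(index=cell_ids, columns=park_ids)
        if wide.isna().any().any():
            raise ValueError(f"travel-time matrix for {mode!r} is incomplete")
        out[str(mode)] = TravelTimeMatrix(str(mode), wide.to_numpy(),
                                          cell_ids, park_ids)
    return out


def write_cells_geojson(city: CityDataset, path: str | Path) -> None:
    """Demand cells as a GeoJSON point collection with population."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [c.x, c.y]},
            "properties": {"cell_id": c.id, "population": c.population,
                           "street_id": c.street_id},
        }
        for c in city.cells
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


# ---------------------------------------------------------------------------
# street-level feature assembly


def assemble_features(city: CityDataset, seed: int) -> pd.DataFrame:
    """Street-level predictor table for a generated city.

    Park-characteristic predictors (PCAR, PTN, SAD) and population
    density (PD) are computed from the city's own geometry; the
    remaining built-environment and socioeconomic predictors are drawn
    from calibrated marginals, since the generator carries no land-use
    rasters or economic accounts.
    """
    streets = sorted(city.streets)
    X = sample_predictors(len(streets), seed)
    X.insert(0, "street_id", streets)
    X = X.set_index("street_id")

    cells = city.cells_frame()
    cell_area = city.config.cell_size**2
    grp = cells.groupby("street_id")
    pop = grp["population"].sum()
    area = grp.size() * cell_area

    # park membership by nearest street via the containing cell tile
    park_pts = np.array([p.entrances.mean(axis=0) for p in city.parks])
    step = city.config.street_cells * city.config.cell_size
    n_streets_side = int(np.ceil(city.config.grid_extent / city.config.street_cells))
    sx = np.clip((park_pts[:, 0] // step).astype(int), 0, n_streets_side - 1)
    sy = np.clip((park_pts[:, 1] // step).astype(int), 0, n_streets_side - 1)
    park_street = [f"S{a:02d}_{b:02d}" for a, b in zip(sx, sy)]
    parks = city.parks_frame().assign(street_id=park_street)

    park_area = parks.groupby("street_id")["area_m2"].sum().reindex(streets).fillna(0)
    ptn = parks.groupby("street_id")["type"].nunique().reindex(streets).fillna(0)

    # mean distance (km) from member cells to the nearest park entrance
    pts = cells[["x", "y"]].to_numpy()
    all_entrances = np.vstack([p.entrances for p in city.parks])
    d = np.sqrt(
        ((pts[:, None, :] - all_entrances[None, :, :]) ** 2).sum(axis=2)
    ).min(axis=1)
    cells = cells.assign(nearest_km=d / 1000.0)
    sad = cells.groupby("street_id")["nearest_km"].mean()

    X["PD"] = (pop / area).reindex(X.index).fillna(0.0)
    X["PCAR"] = (park_area / pop.where(pop > 0)).reindex(X.index).fillna(0.0)
    X["PTN"] = ptn.reindex(X.index).fillna(0.0)
    X["SAD"] = sad.reindex(X.index).fillna(0.0)
    return X.reset_index()


# ---------------------------------------------------------------------------
# orchestration


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    data_paths: Mapping[str, str] | None = None,
) -> dict:
    """Execute the full analysis and write all artefacts to ``outdir``.

    ``data_paths`` (keys ``cells``, ``parks``, optionally
    ``travel_times``) switches to real-data mode; otherwise the city is
    generated synthetically from ``config.city`` with the run seed.
    Returns the manifest dictionary.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": [],
        "log": [],
    }
    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
    stage = "setup"

    def log(msg: str) -> None:
        manifest["log"].append(msg)

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"].append(name)

    try:
        # -- city ----------------------------------------------------
        stage = "city"
        if data_paths is None:
            city_cfg = replace(config.city, seed=config.seed)
            city = generate_city(city_cfg)
            log(f"generated city: {len(city.cells)} cells, {len(city.parks)} parks, "
                f"{len(city.streets)} streets")
        else:
            for key in ("cells", "parks"):
                if key not in data_paths:
                    raise FileNotFoundError(f"real-data mode requires a {key!r} path")
            cells = read_cells_csv(data_paths["cells"])
            parks = read_parks_csv(data_paths["parks"])
            streets = {c.street_id: c.street_id for c in cells}
            if "travel_times" in data_paths:
                travel = read_travel_times_csv(data_paths["travel_times"], cells, parks)
            else:
                travel = {
                    mode: build_travel_time_matrix(cells, parks, mode, config.city)
                    for mode in config.city.mode_speeds
                }
            city = CityDataset(cells, parks, streets, travel, config.city)
            log(f"loaded city: {len(cells)} cells, {len(parks)} parks")
        emit("cells.csv", lambda p: city.cells_frame().to_csv(p, index=False))
        emit("parks.csv", lambda p: city.parks_frame().to_csv(p, index=False))
        emit("streets.csv", lambda p: pd.DataFrame(
            sorted(city.streets.items()), columns=["street_id", "district_id"]
        ).to_csv(p, index=False))
        emit("cells.geojson", lambda p: write_cells_geojson(city, p))
        if config.write_travel_times:
            tt = pd.concat([m.to_frame() for m in city.travel_times.values()])
            emit("travel_times.csv", lambda p: tt.to_csv(p, index=False))

        # -- accessibility -------------------------------------------
        stage = "access"
        street_of = city.street_of
        pops = {c.id: c.population for c in city.cells}
        results = {}
        street_access: dict[str, pd.Series] = {}
        for mode in sorted(city.travel_times):
            res = Gaussian2SFCA(
                city.cells, city.parks, city.travel_times[mode],
                t0=config.t0.get(mode),
            ).fit()
            results[mode] = res
            emit(f"access_{mode}.csv", lambda p, r=res: r.to_frame().to_csv(p, index=False))
            street_access[mode] = res.aggregate_by_zone(
                street_of, config.aggregation_scheme
            )
            log(f"{mode}: mean A_i = {res.access_.mean():.4f}, "
                f"{len(res.unreached_parks)} unreached parks")

        # -- equity --------------------------------------------------
        stage = "equity"
        district_of = city.district_of_cell
        street_gini: dict[str, dict] = {}
        gini_rows, district_rows = [], []
        for mode, res in results.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                per_street, _ = zone_gini(res.access, pops, street_of,
                                          config.gini_service_mass)
                per_district, overall = zone_gini(res.access, pops, district_of,
                                                  config.gini_service_mass)
            street_gini[mode] = {z: g.value for z, g in per_street.items()}
            gini_rows += [
                {"zone_id": z, "mode": mode, "gini": g.value, "n_units": g.n_units}
                for z, g in per_street.items()
            ]
            district_rows += [
                {"zone_id": z, "mode": mode, "gini": g.value, "n_units": g.n_units}
                for z, g in list(per_district.items()) + [("overall", overall)]
            ]
            log(f"{mode}: overall Gini = {overall.value:.4f}")
        emit("gini_street.csv", lambda p: pd.DataFrame(gini_rows).to_csv(p, index=False))
        emit("gini_district.csv",
             lambda p: pd.DataFrame(district_rows).to_csv(p, index=False))

        # -- feature table -------------------------------------------
        stage = "features"
        feats = assemble_features(city, seed=config.seed + 1)
        feats = feats.set_index("street_id")
        resp = pd.DataFrame(
            {
                "ai_walking": street_access.get("walking"),
                "ai_driving": street_access.get("driving"),
                "gini_walking": pd.Series(street_gini.get("walking", {})),
                "gini_driving": pd.Series(street_gini.get("driving", {})),
            }
        )
        table = feats.join(resp).dropna()
        emit("features.csv", lambda p: table.reset_index().to_csv(p, index=False))
        log(f"feature table: {len(table)} streets x {len(PREDICTORS)} predictors")

        # -- boosted-tree effect analysis ----------------------------
        stage = "gbdt"
        X = table[list(PREDICTORS)]
        hp = replace(config.gbdt, seed=config.seed + 2)
        key_vars: dict[str, list[str]] = {}
        comparisons: dict[str, dict] = {}
        for response in RESPONSES:
            if response not in table.columns or table[response].isna().any():
                continue
            y = table[response].to_numpy()
            fit = GradientBoostedTrees(y, X).fit(hp)
            cv = cross_validate(X, y, hp)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                imp = fit.feature_importance()
            emit(f"importance_{response}.csv",
                 lambda p, s=imp: s.rename_axis("feature").to_csv(p))
            emit(f"model_{response}.json", lambda p, f=fit: f.to_json(p))
            emit(f"cv_{response}.json", lambda p, c=cv: Path(p).write_text(
                json.dumps({"fold_r2": c.fold_r2, "mean_r2": c.mean_r2})))
            if imp.sum() > 0:
                key_vars[response] = select_key_variables(
                    imp, config.effects.key_threshold_pct
                )
            else:
                key_vars[response] = []
            curves = pd.concat(
                [
                    partial_dependence(
                        fit, X, f,
                        n_grid=config.effects.n_grid,
                        quantile_range=config.effects.quantile_range,
                        span=config.effects.span,
                    ).to_frame()
                    for f in key_vars[response]
                ]
            ) if key_vars[response] else pd.DataFrame(
                columns=["feature", "grid", "raw", "smoothed", "density"]
            )
            emit(f"pd_{response}.csv", lambda p, c=curves: c.to_csv(p, index=False))
            ols = ols_fit(X, y)
            comparisons[response] = compare_models(ols, cv).to_dict()
            log(f"{response}: GBDT CV R2 = {cv.mean_r2:.3f}, "
                f"OLS R2 = {ols.r_squared:.3f}, key vars = {key_vars[response]}")
        emit("key_variables.json",
             lambda p: Path(p).write_text(json.dumps(key_vars, indent=2)))
        emit("ols_comparison.json",
             lambda p: Path(p).write_text(json.dumps(comparisons, indent=2)))

        # -- scenarios -----------------------------------------------
        stage = "scenarios"
        rows = []
        for mode in sorted(results):
            for sid, a in street_access[mode].items():
                if sid in street_gini[mode]:
                    rows.append({"street_id": sid, "mode": mode, "mean_access": a,
                                 "gini": street_gini[mode][sid]})
        labelled, counts = classify_all(pd.DataFrame(rows), config.scenarios)
        emit("scenarios.csv", lambda p: labelled.to_csv(p, index=False))
        emit("scenario_counts.csv", lambda p: counts.to_csv(p, index=False))
        for _, r in counts.iterrows():
            log(f"{r['mode']}: {r['label']} x {r['n_streets']}")

        # -- manifest & summary --------------------------------------
        stage = "report"
        summary = "\n".join(
            ["greenaccess pipeline summary", "=" * 40] + manifest["log"]
        )
        emit("summary.txt", lambda p: Path(p).write_text(summary + "\n"))
        manifest["files"].append("manifest.json")
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:  # annotate with the failing stage
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise PipelineError(stage, exc) from exc
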