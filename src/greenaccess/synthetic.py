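"""Synthetic city generator with known statistical structure.

Real inputs for this kind of analysis — a population grid, typed parks
with entrances, travel times, and street-level predictor tables — are
administrative data that are rarely public.  This module generates all
of them reproducibly so every downstream stage (2SFCA accessibility,
Gini equity, boosted-tree effect analysis) can be tested against known
ground truth:

* a square grid of 500 m demand cells whose population is spatially
  clustered around a few Gaussian "city cores" (emulating concentration
  along river corridors), allocated so cell populations sum exactly to
  the configured total;
* parks of four types (comprehensive, theme, community, amusement) with
  areas drawn log-uniformly from type-specific ranges and 1-4 entrances
  on the footprint-circle boundary; default type counts follow the
  observed proportions of a large central-city park system
  (36:31:236:395);
* straight-line travel-time matrices per mode (distance to the nearest
  entrance, times a detour factor, over the mode speed);
* a street-level table of 15 predictors whose marginals are calibrated
  to published street-level descriptive statistics, with a response
  built from a configurable additive nonlinear function (linear /
  plateau / peak / null effects) plus Gaussian noise — the noiseless
  ground truth is returned alongside so effect recovery is testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from greenaccess.access import DemandCell, Park, TravelTimeMatrix

#: The 15 street-level predictors (park characteristics, built
#: environment, socioeconomic factors).
PREDICTORS: tuple[str, ...] = (
    "PCAR",   # per-capita park area (m^2/person)
    "PTN",    # number of park types present
    "SAD",    # shortest average distance to nearest park (km)
    "P-NDVI", # per-capita normalised difference vegetation index
    "RD",     # road network density
    "RI",     # number of road intersections
    "PC",     # proportion of commercial land
    "PR",     # proportion of residential land
    "PI",     # proportion of industrial land
    "LUM",    # degree of land-use mix
    "PD",     # population density
    "GDP",    # gross domestic product
    "RCG",    # retail sales of consumer goods
    "PFBR",   # public-finance budget revenue
    "IFA",    # investment in fixed assets
)

# (mean, sd, kind) per predictor, calibrated to street-level descriptive
# statistics; kind selects the marginal family used to draw it.
_MARGINALS: dict[str, tuple[float, float, str]] = {
    "PCAR": (0.994, 2.596, "lognormal"),
    "PTN": (2.0, 1.0, "count"),
    "SAD": (0.318, 0.365, "lognormal"),
    "P-NDVI": (0.091, 0.264, "lognormal"),
    "RD": (0.005, 0.003, "positive-normal"),
    "RI": (116.0, 176.0, "lognormal"),
    "PC": (0.108, 0.182, "lognormal"),
    "PR": (0.398, 0.956, "lognormal"),
    "PI": (0.904, 1.744, "lognormal"),
    "LUM": (0.587, 0.158, "unit-normal"),
    "PD": (0.026, 0.024, "lognormal"),
    "GDP": (11.578, 18.257, "lognormal"),
    "RCG": (9.210, 14.263, "lognormal"),
    "PFBR": (0.790, 1.222, "lognormal"),
    "IFA": (20.565, 45.772, "lognormal"),
}

#: Default park counts per type; proportions follow the 36:31:236:395
#: split of a large central-city park system, scaled to desk size.
DEFAULT_PARK_COUNTS: dict[str, int] = {
    "comprehensive": 5,
    "theme": 4,
    "community": 30,
    "amusement": 49,
}

#: Log-uniform park-area ranges per type in m^2 (comprehensive largest).
DEFAULT_AREA_RANGES: dict[str, tuple[float, float]] = {
    "comprehensive": (1.0e5, 1.0e6),
    "theme": (5.0e4, 3.0e5),
    "community": (1.0e4, 1.0e5),
    "amusement": (2.0e3, 3.0e4),
}


@dataclass(frozen=True)
class CityConfig:
    """Knobs of the synthetic city.

    grid_extent
        Cells per side of the square demand grid.
    cell_size
        Cell edge length in metres (500 m grid convention).
    n_parks_by_type
        Park counts per type.
    population_total
        Total residents, conserved exactly across cells.
    clustering
        Spatial concentration (>= 0): 0 gives a uniform city, larger
        values pile population onto the Gaussian core kernels.
    n_cores, core_bandwidth
        Number of population kernels and their s.d. in metres
        (default: a sixth of the city span).
    mode_speeds
        km/h per travel mode.
    detour_factor
        Network detour multiplier on straight-line distance (>= 1).
    street_cells, district_streets
        Regular-tiling sizes: cells per street side, streets per
        district side.
    """

    grid_extent: int = 30
    cell_size: float = 500.0
    n_parks_by_type: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PARK_COUNTS)
    )
    population_total: int = 1_650_000
    clustering: float = 4.0
    n_cores: int = 3
    core_bandwidth: float | None = None
    mode_speeds: Mapping[str, float] = field(
        default_factory=lambda: {"walking": 5.0, "driving": 30.0}
    )
    detour_factor: float = 1.2
    street_cells: int = 5
    district_streets: int = 2
    area_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_AREA_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        # normalise range containers so YAML round-trips compare equal
        object.__setattr__(
            self, "area_ranges",
            {k: tuple(float(x) for x in v) for k, v in self.area_ranges.items()},
        )
        if self.grid_extent <= 0:
            raise ValueError("grid_extent must be positive")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.population_total < 0:
            raise ValueError("population_total must be >= 0")
        if self.clustering < 0:
            raise ValueError("clustering must be >= 0")
        if self.detour_factor < 1:
            raise ValueError("detour_factor must be >= 1")
        if self.n_cores <= 0 or self.street_cells <= 0 or self.district_streets <= 0:
            raise ValueError("n_cores, street_cells, district_streets must be positive")
        for t, n in self.n_parks_by_type.items():
            if n < 0:
                raise ValueError(f"n_parks_by_type[{t!r}] must be >= 0")
        for m, v in self.mode_speeds.items():
            if v <= 0:
                raise ValueError(f"mode_speeds[{m!r}] must be > 0")

    @property
    def span(self) -> float:
        """City side length in metres."""
        return self.grid_extent * self.cell_size


@dataclass
class CityDataset:
    """A generated city: cells, parks, zone nesting, travel times."""

    cells: list[DemandCell]
    parks: list[Park]
    streets: dict[str, str]  # street_id -> district_id
    travel_times: dict[str, TravelTimeMatrix]  # mode -> matrix
    config: CityConfig

    @property
    def street_of(self) -> dict[str, str]:
        """cell_id -> street_id mapping."""
        return {c.id: c.street_id for c in self.cells}

    @property
    def district_of_cell(self) -> dict[str, str]:
        return {c.id: self.streets[c.street_id] for c in self.cells}

    def validate(self) -> None:
        for c in self.cells:
            if c.street_id not in self.streets:
                raise ValueError(f"cell {c.id} references unknown street {c.street_id}")
        total = sum(c.population for c in self.cells)
        if abs(total - self.config.population_total) > len(self.cells):
            raise ValueError("cell populations do not sum to population_total")

    def cells_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": [c.id for c in self.cells],
                "x": [c.x for c in self.cells],
                "y": [c.y for c in self.cells],
                "population": [c.population for c in self.cells],
                "street_id": [c.street_id for c in self.cells],
            }
        )

    def parks_frame(self) -> pd.DataFrame:
        import json

        return pd.DataFrame(
            {
                "park_id": [p.id for p in self.parks],
                "type": [p.type for p in self.parks],
                "area_m2": [p.area_m2 for p in self.parks],
                "capacity": [p.capacity for p in self.parks],
                "entrances": [json.dumps(p.entrances.tolist()) for p in self.parks],
            }
        )


def _allocate_population(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment: integer counts summing to total."""
    if total == 0 or weights.sum() == 0:
        return np.zeros_like(weights)
    share = weights / weights.sum() * total
    base = np.floor(share).astype(int)
    rem = total - base.sum()
    if rem > 0:
        # deterministic tie-break: larger fraction first, then lower index
        order = np.lexsort((np.arange(len(share)), -(share - base)))
        base[order[:rem]] += 1
    return base


def generate_city(config: CityConfig) -> CityDataset:
    """Generate a reproducible synthetic city from a configuration.

    Deterministic for a fixed seed; all random draws go through one
    ``numpy`` generator in a fixed order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.grid_extent
    span = config.span
    half = config.cell_size / 2.0

    # cell centroids, row-major from the south-west corner
    ix, iy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    xs = (ix.ravel() * config.cell_size + half).astype(float)
    ys = (iy.ravel() * config.cell_size + half).astype(float)

    # population: uniform baseline plus Gaussian city-core kernels
    cores = rng.uniform(0.15 * span, 0.85 * span, size=(config.n_cores, 2))
    bw = config.core_bandwidth if config.core_bandwidth is not None else span / 6.0
    kern = np.zeros(n * n)
    for cx, cy in cores:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        kern += np.exp(-0.5 * d2 / bw**2)
    if kern.max() > 0:
        kern /= kern.max()
    weights = 1.0 + config.clustering * kern
    pops = _allocate_population(weights, config.population_total)

    street_side = config.street_cells
    district_side = config.district_streets
    cells: list[DemandCell] = []
    streets: dict[str, str] = {}
    for k in range(n * n):
        sx, sy = int(ix.ravel()[k]) // street_side, int(iy.ravel()[k]) // street_side
        street = f"S{sx:02d}_{sy:02d}"
        district = f"D{sx // district_side:02d}_{sy // district_side:02d}"
        streets[street] = district
        cells.append(
            DemandCell(
                id=f"C{k:04d}",
                x=float(xs[k]),
                y=float(ys[k]),
                population=float(pops[k]),
                street_id=street,
            )
        )

    parks: list[Park] = []
    idx = 0
    for ptype in ("comprehensive", "theme", "community", "amusement"):
        count = int(config.n_parks_by_type.get(ptype, 0))
        lo, hi = config.area_ranges[ptype]
        for _ in range(count):
            cx, cy = rng.uniform(0, span, size=2)
            area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            radius = math.sqrt(area / math.pi)
            n_ent = int(rng.integers(1, 5))
            angles = rng.uniform(0, 2 * math.pi, size=n_ent)
            entrances = np.column_stack(
                [cx + radius * np.cos(angles), cy + radius * np.sin(angles)]
            )
            parks.append(
                Park(id=f"P{idx:03d}", type=ptype, area_m2=area, entrances=entrances)
            )
            idx += 1

    travel = {
        mode: build_travel_time_matrix(cells, parks, mode, config)
        for mode in config.mode_speeds
    }
    city = CityDataset(cells=cells, parks=parks, streets=streets,
                       travel_times=travel, config=config)
    city.validate()
    return city


def build_travel_time_matrix(
    cells: list[DemandCell],
    parks: list[Park],
    mode: str,
    config: CityConfig,
) -> TravelTimeMatrix:
    """Straight-line travel times in minutes to the nearest park entrance.

    ``t = (euclidean distance to nearest entrance * detour_factor) /
    speed``; halving the mode speed doubles every entry.
    """
    if mode not in config.mode_speeds:
        raise ValueError(
            f"unknown mode {mode!r}; configured modes: {sorted(config.mode_speeds)}"
        )
    if not cells or not parks:
        raise ValueError("need at least one cell and one park")
    speed_m_per_min = config.mode_speeds[mode] * 1000.0 / 60.0
    pts = np.array([[c.x, c.y] for c in cells])
    minutes = np.empty((len(cells), len(parks)))
    for j, p in enumerate(parks):
        d = np.sqrt(
            ((pts[:, None, :] - p.entrances[None, :, :]) ** 2).sum(axis=2)
        ).min(axis=1)
        minutes[:, j] = d * config.detour_factor / speed_m_per_min
    return TravelTimeMatrix(
        mode=mode,
        minutes=minutes,
        cell_ids=[c.id for c in cells],
        park_ids=[p.id for p in parks],
    )


# ---------------------------------------------------------------------------
# street-level feature table with known generative effects


@dataclass(frozen=True)
class Effect:
    """One predictor's contribution to the generative response.

    Kinds: ``linear`` (slope * x), ``plateau`` (ramps to ``level`` at
    ``threshold`` and stays flat above it), ``peak`` (Gaussian bump of
    ``amplitude`` at ``location`` with s.d. ``width``), ``null``.
    """

    kind: str
    slope: float = 0.0
    threshold: float = 0.0
    level: float = 0.0
    location: float = 0.0
    width: float = 1.0
    amplitude: float = 1.0

    @classmethod
    def linear(cls, slope: float) -> "Effect":
        return cls("linear", slope=slope)

    @classmethod
    def plateau(cls, threshold: float, level: float) -> "Effect":
        if threshold <= 0:
            raise ValueError("plateau threshold must be > 0")
        return cls("plateau", threshold=threshold, level=level)

    @classmethod
    def peak(cls, location: float, width: float, amplitude: float = 1.0) -> "Effect":
        if width <= 0:
            raise ValueError("peak width must be > 0")
        return cls("peak", location=location, width=width, amplitude=amplitude)

    @classmethod
    def null(cls) -> "Effect":
        return cls("null")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "linear":
            return self.slope * x
        if self.kind == "plateau":
            return self.level * np.clip(x / self.threshold, 0.0, 1.0)
        if self.kind == "peak":
            return self.amplitude * np.exp(-0.5 * ((x - self.location) / self.width) ** 2)
        if self.kind == "null":
            return np.zeros_like(x)
        raise ValueError(f"unknown effect kind {self.kind!r}")


@dataclass(frozen=True)
class EffectsSpec:
    """Additive generative model for the street-level response.

    Exactly one :class:`Effect` per predictor; the response is
    ``intercept + sum_p effect_p(x_p) + N(0, noise_sd)``.
    """

    effects: Mapping[str, Effect]
    noise_sd: float = 0.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        missing = [p for p in PREDICTORS if p not in self.effects]
        if missing:
            raise ValueError(f"EffectsSpec missing predictors: {missing}")
        extra = [p for p in self.effects if p not in PREDICTORS]
        if extra:
            raise ValueError(f"EffectsSpec has unknown predictors: {extra}")

    @classmethod
    def all_null(cls, noise_sd: float = 0.0, intercept: float = 0.0) -> "EffectsSpec":
        return cls({p: Effect.null() for p in PREDICTORS}, noise_sd, intercept)

    @classmethod
    def single(
        cls, predictor: str, effect: Effect, noise_sd: float = 0.0,
        intercept: float = 0.0,
    ) -> "EffectsSpec":
        effects = {p: Effect.null() for p in PREDICTORS}
        effects[predictor] = effect
        return cls(effects, noise_sd, intercept)

    def ground_truth(self, X: pd.DataFrame) -> np.ndarray:
        """Noiseless response at the rows of ``X``."""
        out = np.full(len(X), self.intercept, dtype=float)
        for p in PREDICTORS:
            out += self.effects[p](X[p].to_numpy())
        return out


@dataclass
class FeatureTable:
    """Street-level predictors, response, and generative ground truth."""

    data: pd.DataFrame  # street_id, 15 predictors, response, ground_truth
    spec: EffectsSpec

    @property
    def X(self) -> pd.DataFrame:
        return self.data[list(PREDICTORS)]

    @property
    def y(self) -> np.ndarray:
        return self.data["response"].to_numpy()

    @property
    def ground_truth(self) -> np.ndarray:
        return self.data["ground_truth"].to_numpy()


def _draw_predictor(rng: np.random.Generator, name: str, n: int) -> np.ndarray:
    mean, sd, kind = _MARGINALS[name]
    if kind == "lognormal":
        sigma2 = math.log(1.0 + (sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return rng.lognormal(mu, math.sqrt(sigma2), size=n)
    if kind == "positive-normal":
        return np.abs(rng.normal(mean, sd, size=n))
    if kind == "unit-normal":
        return np.clip(rng.normal(mean, sd, size=n), 0.0, 1.0)
    if kind == "count":
        return np.clip(np.round(rng.normal(mean, sd, size=n)), 0, 4)
    raise AssertionError(kind)


def sample_predictors(n: int, seed: int) -> pd.DataFrame:
    """Draw n street records of the 15 predictors from calibrated marginals."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame({p: _draw_predictor(rng, p, n) for p in PREDICTORS})


def generate_feature_table(
    city: CityDataset | int,
    spec: EffectsSpec,
    seed: int = 0,
) -> FeatureTable:
    """Street-level feature table with a known generative response.

    ``city`` may be a :class:`CityDataset` (one record per street) or an
    integer number of streets.  Predictors are drawn from marginals
    calibrated to published street-level descriptive statistics; the
    response is the spec's additive nonlinear function of the predictors
    plus Gaussian noise, and the noiseless ground truth is stored in the
    ``ground_truth`` column for recovery tests.
    """
    if isinstance(city, CityDataset):
        street_ids = sorted(city.streets)
    else:
        street_ids = [f"S{k:04d}" for k in range(int(city))]
    n = len(street_ids)
    X = sample_predictors(n, seed)
    truth = spec.ground_truth(X)
    noise_rng = np.random.default_rng(seed + 1)
    y = truth + noise_rng.normal(0.0, spec.noise_sd, size=n)
    data = X.copy()
    data.insert(0, "street_id", street_ids)
    data["response"] = y
    data["ground_truth"] = truth
    return FeatureTable(data=data, spec=spec)
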