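"""Gaussian-based two-step floating catchment area (2SFCA) accessibility.

The 2SFCA method measures potential spatial access of a population to
facilities in two passes over a travel-time matrix:

1. each park ``j`` receives a supply-demand ratio
   ``R_j = S_j / sum_k G(t_kj, t0) * P_k`` over the demand cells ``k``
   within its catchment (``t_kj <= t0``), where ``S_j`` is the park's
   service capacity in persons and ``P_k`` the cell population;
2. each demand cell ``i`` sums the decay-weighted ratios of the parks it
   can reach: ``A_i = sum_j G(t_ij, t0) * R_j``.

``G`` is the normalised Gaussian impedance weight, 1 at ``t = 0`` and 0
at the catchment threshold ``t0`` (15 minutes by default, applied to
both walking and driving).  Park capacity is the park area divided by a
per-capita area standard that depends on the park type (comprehensive
60, theme 50, community 40, amusement 30 m^2/person).

The resulting accessibility ``A_i`` is dimensionless service capacity
per person.  When every park has at least one populated cell in its
catchment, total population-weighted accessibility conserves total
capacity: ``sum_i P_i * A_i = sum_j S_j``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Per-capita park-area standards in m^2/person, by park type (classes I-IV).
DEFAULT_STANDARDS: dict[str, float] = {
    "comprehensive": 60.0,
    "theme": 50.0,
    "community": 40.0,
    "amusement": 30.0,
}

PARK_TYPES = tuple(DEFAULT_STANDARDS)

#: Default catchment travel-time threshold in minutes (both modes).
DEFAULT_T0 = 15.0


def park_capacity(
    area: float,
    park_type: str,
    standards: Mapping[str, float] | None = None,
) -> float:
    """Service capacity of a park in persons: area / per-capita standard.

    Parameters
    ----------
    area : float
        Park area in m^2; must be strictly positive.
    park_type : str
        One of the configured park types.
    standards : mapping, optional
        Per-type m^2/person table; defaults to the class I-IV standards
        ``{comprehensive: 60, theme: 50, community: 40, amusement: 30}``.
    """
    standards = DEFAULT_STANDARDS if standards is None else standards
    if park_type not in standards:
        raise ValueError(
            f"unknown park type {park_type!r}; valid types: {sorted(standards)}"
        )
    if not area > 0:
        raise ValueError(f"park area must be > 0, got {area}")
    return area / standards[park_type]


def gaussian_decay(t, t0: float = DEFAULT_T0):
    """Normalised Gaussian impedance weight G(t, t0) in [0, 1].

    ``G = (exp(-(t/t0)^2 / 2) - exp(-1/2)) / (1 - exp(-1/2))`` for
    ``t <= t0`` and 0 beyond, so the weight is 1 at zero travel time,
    declines smoothly, and vanishes continuously at the threshold.
    Accepts scalars or arrays.
    """
    if not t0 > 0:
        raise ValueError(f"t0 must be > 0, got {t0}")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("travel times must be >= 0")
    denom = 1.0 - math.exp(-0.5)
    w = (np.exp(-0.5 * (t / t0) ** 2) - math.exp(-0.5)) / denom
    w = np.where(t <= t0, w, 0.0)
    return float(w) if w.ndim == 0 else w


@dataclass
class Park:
    """A supply point: typed park with entrances and derived capacity."""

    id: str
    type: str
    area_m2: float
    entrances: np.ndarray  # (k, 2) planar coordinates in metres
    standards: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        self.entrances = np.atleast_2d(np.asarray(self.entrances, dtype=float))
        if self.entrances.shape[0] < 1 or self.entrances.shape[1] != 2:
            raise ValueError(f"park {self.id}: needs >= 1 entrance with (x, y)")
        # validates type and positivity
        self.capacity = park_capacity(self.area_m2, self.type, self.standards)


@dataclass
class DemandCell:
    """A grid cell: centroid, resident population, and street membership."""

    id: str
    x: float
    y: float
    population: float
    street_id: str

    def __post_init__(self) -> None:
        if self.population < 0:
            raise ValueError(f"cell {self.id}: population must be >= 0")


@dataclass
class TravelTimeMatrix:
    """Minutes between every (cell, park) pair for one travel mode."""

    mode: str
    minutes: np.ndarray  # (n_cells, n_parks)
    cell_ids: list[str]
    park_ids: list[str]
    t0: float = DEFAULT_T0

    def __post_init__(self) -> None:
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != (len(self.cell_ids), len(self.park_ids)):
            raise ValueError(
                f"travel-time matrix shape {self.minutes.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.park_ids)} parks"
            )
        if np.any(self.minutes < 0):
            raise ValueError("travel times must be >= 0")

    def to_frame(self) -> pd.DataFrame:
        """Long-format (cell_id, park_id, mode, minutes) table."""
        idx = pd.MultiIndex.from_product(
            [self.cell_ids, self.park_ids], names=["cell_id", "park_id"]
        )
        df = pd.DataFrame({"minutes": self.minutes.ravel()}, index=idx).reset_index()
        df.insert(2, "mode", self.mode)
        return df


def _capacities(parks: Sequence[Park]) -> np.ndarray:
    return np.array([p.capacity for p in parks], dtype=float)


def supply_demand_ratios(
    parks: Sequence[Park],
    cells: Sequence[DemandCell],
    ttm: TravelTimeMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Step 1: per-park supply-demand ratios R_j.

    Returns ``(ratios, unreached)`` where ``unreached`` flags parks whose
    Gaussian-weighted catchment demand is zero (no populated cell within
    t0); those parks get ``R_j = 0`` rather than a division error, which
    breaks capacity conservation and is therefore surfaced via a warning.
    """
    _check_alignment(parks, cells, ttm)
    S = _capacities(parks)
    P = np.array([c.population for c in cells], dtype=float)
    W = gaussian_decay(ttm.minutes, ttm.t0)  # (cells, parks)
    demand = W.T @ P  # Gaussian-weighted demand per park
    unreached = demand <= 0.0
    ratios = np.zeros_like(S)
    ratios[~unreached] = S[~unreached] / demand[~unreached]
    if unreached.any():
        names = [parks[j].id for j in np.flatnonzero(unreached)]
        warnings.warn(
            f"{unreached.sum()} park(s) with no populated cell within "
            f"t0={ttm.t0} min set to R_j=0: {names[:10]}",
            stacklevel=2,
        )
    return ratios, unreached


def accessibility_scores(
    cells: Sequence[DemandCell],
    parks: Sequence[Park],
    ratios: np.ndarray,
    ttm: TravelTimeMatrix,
) -> np.ndarray:
    """Step 2: per-cell accessibility A_i = sum_j G(t_ij, t0) * R_j."""
    _check_alignment(parks, cells, ttm)
    ratios = np.asarray(ratios, dtype=float)
    if ratios.shape != (len(parks),):
        raise ValueError(
            f"ratios length {ratios.shape} does not match {len(parks)} parks"
        )
    W = gaussian_decay(ttm.minutes, ttm.t0)
    return W @ ratios


def _check_alignment(parks, cells, ttm: TravelTimeMatrix) -> None:
    if [c.id for c in cells] != list(ttm.cell_ids):
        raise ValueError("cell ids do not match the travel-time matrix rows")
    if [p.id for p in parks] != list(ttm.park_ids):
        raise ValueError("park ids do not match the travel-time matrix columns")


def aggregate_by_zone(
    access: Mapping[str, float] | pd.Series,
    zones: Mapping[str, str],
    scheme: str = "simple-mean",
    populations: Mapping[str, float] | pd.Series | None = None,
) -> pd.Series:
    """Zone-level mean accessibility over member cells.

    ``scheme`` is ``"simple-mean"`` (default; an unweighted average,
    matching how street/district averages are usually reported) or
    ``"population-weighted-mean"`` (requires ``populations``).  Zones with
    no member cells are absent from the output; a cell without a zone
    mapping is an error.
    """
    access = pd.Series(access, dtype=float)
    missing = [cid for cid in access.index if cid not in zones]
    if missing:
        raise KeyError(f"cells not mapped to any zone: {missing[:10]}")
    zone_of = pd.Series({cid: zones[cid] for cid in access.index})
    if scheme == "simple-mean":
        return access.groupby(zone_of).mean().rename("mean_access")
    if scheme == "population-weighted-mean":
        if populations is None:
            raise ValueError("population-weighted-mean requires populations")
        pop = pd.Series(populations, dtype=float).reindex(access.index)
        mass = (access * pop).groupby(zone_of).sum()
        tot = pop.groupby(zone_of).sum()
        out = mass / tot.where(tot > 0)
        return out.rename("mean_access")
    raise ValueError(
        f"unknown scheme {scheme!r}; use 'simple-mean' or 'population-weighted-mean'"
    )


class Gaussian2SFCA:
    """Gaussian-based 2SFCA accessibility model for one travel mode.

    Parameters
    ----------
    cells, parks
        Demand cells and typed parks; ids must align with ``travel_times``.
    travel_times : TravelTimeMatrix
        Complete minutes matrix for the mode; its ``t0`` bounds both steps
        unless overridden here.
    t0 : float, optional
        Catchment threshold in minutes (default: the matrix's own t0).

    ``fit()`` runs both steps and returns an :class:`AccessibilityResults`.
    """

    def __init__(
        self,
        cells: Sequence[DemandCell],
        parks: Sequence[Park],
        travel_times: TravelTimeMatrix,
        t0: float | None = None,
    ) -> None:
        self.cells = list(cells)
        self.parks = list(parks)
        if not self.cells or not self.parks:
            raise ValueError("need at least one cell and one park")
        if t0 is not None:
            travel_times = TravelTimeMatrix(
                travel_times.mode,
                travel_times.minutes,
                travel_times.cell_ids,
                travel_times.park_ids,
                t0=t0,
            )
        self.travel_times = travel_times
        _check_alignment(self.parks, self.cells, travel_times)

    def fit(self) -> "AccessibilityResults":
        ratios, unreached = supply_demand_ratios(
            self.parks, self.cells, self.travel_times
        )
        access = accessibility_scores(self.cells, self.parks, ratios, self.travel_times)
        return AccessibilityResults(self, ratios, unreached, access)


@dataclass
class AccessibilityResults:
    """Fitted accessibility field: per-cell A_i and per-park R_j."""

    model: Gaussian2SFCA
    ratios_: np.ndarray
    unreached_: np.ndarray
    access_: np.ndarray

    @property
    def mode(self) -> str:
        return self.model.travel_times.mode

    @property
    def access(self) -> pd.Series:
        """Per-cell accessibility A_i (service capacity per person)."""
        return pd.Series(
            self.access_, index=[c.id for c in self.model.cells], name="access"
        )

    @property
    def ratios(self) -> pd.Series:
        """Per-park supply-demand ratio R_j."""
        return pd.Series(
            self.ratios_, index=[p.id for p in self.model.parks], name="ratio"
        )

    @property
    def unreached_parks(self) -> list[str]:
        """Parks with no populated cell inside their catchment."""
        return [
            p.id for p, u in zip(self.model.parks, self.unreached_) if u
        ]

    def aggregate_by_zone(
        self, zones: Mapping[str, str], scheme: str = "simple-mean"
    ) -> pd.Series:
        pops = {c.id: c.population for c in self.model.cells}
        return aggregate_by_zone(self.access, zones, scheme, pops)

    def summary(self) -> str:
        pops = np.array([c.population for c in self.model.cells])
        caps = _capacities(self.model.parks)
        served = caps[~self.unreached_].sum()
        lines = [
            "Gaussian 2SFCA accessibility results",
            "=" * 40,
            f"mode:                 {self.mode}",
            f"t0 (min):             {self.model.travel_times.t0:g}",
            f"cells / parks:        {len(self.model.cells)} / {len(self.model.parks)}",
            f"total population:     {pops.sum():.0f}",
            f"total capacity S:     {caps.sum():.2f}",
            f"distributed capacity: {served:.2f}",
            f"unreached parks:      {len(self.unreached_parks)}",
            f"mean A_i:             {self.access_.mean():.4f}",
            f"pop-weighted mean A:  "
            f"{(self.access_ * pops).sum() / pops.sum():.4f}"
            if pops.sum() > 0
            else "pop-weighted mean A:  n/a",
            f"cells with A_i = 0:   {(self.access_ == 0).sum()}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        cells = self.model.cells
        return pd.DataFrame(
            {
                "cell_id": [c.id for c in cells],
                "x": [c.x for c in cells],
                "y": [c.y for c in cells],
                "population": [c.population for c in cells],
                "street_id": [c.street_id for c in cells],
                "mode": self.mode,
                "access": self.access_,
            }
        )
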