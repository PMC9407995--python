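"""Lorenz curves and Gini coefficients of accessibility versus population.

Equity of park-service access is measured the way income inequality is:
units (demand cells) are sorted ascending by per-capita service, the
cumulative population share X_k and cumulative service share Y_k are
accumulated, and the Gini coefficient follows the trapezoidal
approximation

    G1 = 1 - sum_k (X_k - X_{k-1}) * (Y_k + Y_{k-1}),   X_0 = Y_0 = 0.

G1 = 0 means every unit enjoys identical per-capita service (perfect
equality); G1 -> 1 means all service is concentrated in a vanishing
population share.  The service mass of a cell defaults to A_i * P_i
(its accessibility times its population) so that "equality" means equal
per-capita accessibility; plain A_i is available via ``service_mass``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass
class LorenzCurve:
    """Ordered Lorenz points: cumulative population vs. service shares."""

    x: np.ndarray  # cumulative population share, X_0=0 .. X_n=1
    y: np.ndarray  # cumulative service share, Y_0=0 .. Y_n=1

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D and the same length")


@dataclass
class GiniResult:
    """Gini coefficient G1 of one zone (0 = equality, 1 = inequality)."""

    value: float
    zone: str
    n_units: int
    total_population: float
    total_service: float


def _validate(populations, services) -> tuple[np.ndarray, np.ndarray]:
    pop = np.asarray(populations, dtype=float)
    svc = np.asarray(services, dtype=float)
    if pop.shape != svc.shape or pop.ndim != 1:
        raise ValueError("populations and services must be 1-D and aligned")
    if np.any(pop < 0) or np.any(svc < 0):
        raise ValueError("populations and services must be >= 0")
    keep = pop > 0  # zero-population units have no per-capita service
    pop, svc = pop[keep], svc[keep]
    if pop.size == 0:
        raise ValueError("at least one unit must have population > 0")
    return pop, svc


def lorenz_points(populations: Sequence[float], services: Sequence[float]) -> LorenzCurve:
    """Lorenz curve of service against population.

    Units are sorted ascending by service per capita before cumulation,
    which yields the standard convex-below-diagonal Lorenz construction
    (Y_k <= X_k).  Zero-population units are dropped.  With zero total
    service the curve degenerates to the diagonal (treated as equality).
    """
    pop, svc = _validate(populations, services)
    order = np.argsort(svc / pop, kind="stable")
    pop, svc = pop[order], svc[order]
    x = np.concatenate([[0.0], np.cumsum(pop) / pop.sum()])
    total = svc.sum()
    if total > 0:
        y = np.concatenate([[0.0], np.cumsum(svc) / total])
    else:
        y = x.copy()
    return LorenzCurve(x, y)


def gini(
    populations: Sequence[float],
    services: Sequence[float],
    zone: str = "overall",
) -> GiniResult:
    """Gini coefficient via the trapezoidal Lorenz formula.

    Zero if and only if per-capita service is identical across populated
    units; bounded by 1 from below (tiny negative round-off is clipped).
    """
    pop, svc = _validate(populations, services)
    curve = lorenz_points(pop, svc)
    dx = np.diff(curve.x)
    g1 = 1.0 - float(np.sum(dx * (curve.y[1:] + curve.y[:-1])))
    g1 = min(max(g1, 0.0), 1.0)
    return GiniResult(
        value=g1,
        zone=zone,
        n_units=int(pop.size),
        total_population=float(pop.sum()),
        total_service=float(svc.sum()),
    )


def zone_gini(
    access: Mapping[str, float] | pd.Series,
    populations: Mapping[str, float] | pd.Series,
    zones: Mapping[str, str],
    service_mass: str = "access_mass",
) -> tuple[dict[str, GiniResult], GiniResult]:
    """Per-zone and overall Gini of accessibility over member cells.

    Each cell is one Lorenz unit.  ``service_mass="access_mass"``
    (default) uses A_i * P_i as the cell's service; ``"access"`` uses
    A_i alone.  Zones whose cells all have zero population are omitted
    with a warning.

    Returns ``(per_zone, overall)``.
    """
    access = pd.Series(access, dtype=float)
    pop = pd.Series(populations, dtype=float).reindex(access.index)
    if pop.isna().any():
        raise KeyError("every cell needs a population entry")
    if service_mass == "access_mass":
        svc = access * pop
    elif service_mass == "access":
        svc = access.copy()
    else:
        raise ValueError(
            f"unknown service_mass {service_mass!r}; use 'access_mass' or 'access'"
        )
    missing = [cid for cid in access.index if cid not in zones]
    if missing:
        raise KeyError(f"cells not mapped to any zone: {missing[:10]}")
    zone_of = pd.Series({cid: zones[cid] for cid in access.index})

    per_zone: dict[str, GiniResult] = {}
    for z, idx in access.groupby(zone_of).groups.items():
        p, s = pop.loc[idx].to_numpy(), svc.loc[idx].to_numpy()
        if not np.any(p > 0):
            warnings.warn(f"zone {z!r} has no populated cell; omitted", stacklevel=2)
            continue
        per_zone[str(z)] = gini(p, s, zone=str(z))
    overall = gini(pop.to_numpy(), svc.to_numpy(), zone="overall")
    return per_zone, overall
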