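"""Four-way street classification crossing accessibility with equity.

Each street, per travel mode, is labelled by whether its mean
accessibility is high (strictly above a mode-specific cutoff: 10 for
walking, 1 for driving) and whether its Gini coefficient marks low
equity (strictly above 0.5):

    HA-LE  high accessibility, low equity
    LA-HE  low accessibility, high equity
    LA-LE  low accessibility, low equity
    HA-HE  high accessibility, high equity

Values exactly at a cutoff count as low accessibility / high equity
(the cutoffs are strict "greater than" rules).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

LABELS = ("HA-HE", "HA-LE", "LA-HE", "LA-LE")


@dataclass(frozen=True)
class ScenarioThresholds:
    """High-accessibility cutoffs per mode and the low-equity Gini cutoff."""

    accessibility: Mapping[str, float] = field(
        default_factory=lambda: {"walking": 10.0, "driving": 1.0}
    )
    gini: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.gini < 1:
            raise ValueError(f"gini cutoff must be in (0, 1), got {self.gini}")
        for m, v in self.accessibility.items():
            if not math.isfinite(v):
                raise ValueError(f"accessibility cutoff for {m!r} must be finite")


def classify_street(
    mean_access: float,
    gini: float,
    mode: str,
    thresholds: ScenarioThresholds | None = None,
) -> str:
    """Scenario label for one street under one travel mode."""
    thresholds = thresholds or ScenarioThresholds()
    if mode not in thresholds.accessibility:
        raise ValueError(
            f"unknown mode {mode!r}; configured: {sorted(thresholds.accessibility)}"
        )
    if not (math.isfinite(mean_access) and math.isfinite(gini)):
        raise ValueError("mean_access and gini must be finite")
    high_access = mean_access > thresholds.accessibility[mode]
    low_equity = gini > thresholds.gini
    return ("HA" if high_access else "LA") + "-" + ("LE" if low_equity else "HE")


def classify_all(
    streets: pd.DataFrame,
    thresholds: ScenarioThresholds | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label every (street, mode) row and tally labels per mode.

    ``streets`` needs columns ``street_id``, ``mode``, ``mean_access``,
    ``gini``.  Returns the labelled table and a per-mode count summary
    whose rows partition the streets.
    """
    thresholds = thresholds or ScenarioThresholds()
    required = {"street_id", "mode", "mean_access", "gini"}
    missing = required - set(streets.columns)
    if missing:
        raise KeyError(f"street table missing columns: {sorted(missing)}")
    out = streets.copy()
    out["label"] = [
        classify_street(r.mean_access, r.gini, r.mode, thresholds)
        for r in streets.itertuples()
    ]
    counts = (
        out.groupby(["mode", "label"]).size().rename("n_streets").reset_index()
    )
    return out, counts
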