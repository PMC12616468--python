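"""Projection of standardized effects onto CO2 concentrations and scenarios.

Because effects are standardized to a linear response over the 350 -> 550
ppm window, any concentration ``C`` maps to a fraction of the modeled shift:

    f(C) = (C - 350) / (550 - 350)

``f`` is not clamped: concentrations below the baseline give negative
fractions (nutrition recovering past its baseline values) and
concentrations above 550 ppm exceed 1 (the modeled window is exceeded).
A group's effect at ``C`` scales on the log scale,
``pct(C) = (exp(f(C) * L) - 1) * 100`` for standardized log response ``L``.

Built-in trajectories carry only published (year, ppm) anchor points of the
shared socioeconomic pathways (SSPs); full curves are user-supplied as
(year, ppm) tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from co2ionome.standardization import StandardizationConfig

__all__ = [
    "ScenarioTrajectory",
    "fraction_of_effect",
    "avoided_fraction",
    "effect_at_concentration",
    "trajectory_report",
    "builtin_trajectories",
]


@dataclass(frozen=True)
class ScenarioTrajectory:
    """A named CO2 pathway as (year, ppm) anchor points.

    peak : the pathway's maximum (year, ppm), if it has one.
    crossing_550_year : the year the pathway first exceeds 550 ppm, if any.
    """

    name: str
    points: tuple[tuple[int, float], ...]
    peak: Optional[tuple[int, float]] = None
    crossing_550_year: Optional[int] = None

    def __post_init__(self) -> None:
        years = [y for y, _ in self.points]
        if years != sorted(years):
            raise ValueError("trajectory points must be sorted by year")
        if any(ppm <= 0 for _, ppm in self.points):
            raise ValueError("ppm values must be positive")


def fraction_of_effect(ppm, config: StandardizationConfig | None = None):
    """Fraction of the modeled 350->550 ppm shift at concentration ``ppm``.

    Linear and unclamped: negative below the baseline, above 1 beyond the
    modeled elevated level.
    """
    if config is None:
        config = StandardizationConfig()
    ppm = np.asarray(ppm, dtype=float)
    out = (ppm - config.baseline_ppm) / config.window_ppm
    return out.item() if out.ndim == 0 else out


def avoided_fraction(peak_ppm, config: StandardizationConfig | None = None):
    """Share of the modeled effect avoided by peaking at ``peak_ppm``."""
    frac = fraction_of_effect(peak_ppm, config)
    return 1.0 - frac


def effect_at_concentration(group_adj_log_rr, ppm,
                            config: StandardizationConfig | None = None):
    """Percent change of a group's effect projected to concentration ``ppm``.

    Scales the standardized log response by the concentration fraction and
    back-transforms: 0% at the baseline, the group's full percent change at
    the modeled elevated level.
    """
    frac = np.asarray(fraction_of_effect(ppm, config), dtype=float)
    out = (np.exp(frac * np.asarray(group_adj_log_rr, dtype=float)) - 1.0) * 100.0
    return out.item() if out.ndim == 0 else out


def trajectory_report(trajectory: ScenarioTrajectory,
                      config: StandardizationConfig | None = None,
                      ) -> pd.DataFrame:
    """Tabulate the effect fraction along a trajectory.

    One row per (year, ppm) point with the unrounded fraction and its
    percent rendering at one-decimal and nearest-integer precision; the
    peak row (if any) is flagged.
    """
    if not trajectory.points:
        raise ValueError("empty trajectory")
    rows = []
    pts = list(trajectory.points)
    if trajectory.peak is not None and trajectory.peak not in pts:
        pts = sorted(pts + [trajectory.peak])
    for year, ppm in pts:
        frac = fraction_of_effect(ppm, config)
        rows.append({
            "year": year,
            "ppm": ppm,
            "fraction": frac,
            "pct_of_effect_1dp": round(frac * 100, 1),
            "pct_of_effect_int": int(round(frac * 100)),
            "is_peak": trajectory.peak is not None
            and (year, ppm) == trajectory.peak,
        })
    return pd.DataFrame(rows)


def builtin_trajectories() -> dict[str, ScenarioTrajectory]:
    """Published SSP anchor points.

    Only the peak/endpoint concentrations and 550-ppm crossing years that
    are commonly quoted are included; these are anchors, not full curves.
    """
    return {
        "SSP1-1.9": ScenarioTrajectory(
            name="SSP1-1.9",
            points=((2041, 440.2), (2100, 393.5), (2150, 350.0)),
            peak=(2041, 440.2),
        ),
        "SSP1-2.6": ScenarioTrajectory(
            name="SSP1-2.6",
            points=((2063, 474.0),),
            peak=(2063, 474.0),
        ),
        "SSP4-3.4": ScenarioTrajectory(
            name="SSP4-3.4",
            points=((2079, 490.6),),
            peak=(2079, 490.6),
        ),
        "SSP2-4.5": ScenarioTrajectory(
            name="SSP2-4.5", points=((2065, 550.0),),
            crossing_550_year=2065,
        ),
        "SSP3-7.0": ScenarioTrajectory(
            name="SSP3-7.0", points=((2052, 550.0),),
            crossing_550_year=2052,
        ),
        "SSP4-6.0": ScenarioTrajectory(
            name="SSP4-6.0", points=((2060, 550.0),),
            crossing_550_year=2060,
        ),
        "SSP5-3.4": ScenarioTrajectory(
            name="SSP5-3.4", points=((2051, 550.0),),
            crossing_550_year=2051,
        ),
        "SSP5-8.5": ScenarioTrajectory(
            name="SSP5-8.5", points=((2049, 550.0),),
            crossing_550_year=2049,
        ),
    }
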