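"""Synthetic observation-pair databases with known group-level truth.

The generator emulates the design spread of real CO2-enrichment
experiments — ambient levels over roughly 310-455 ppm, added CO2 mostly in
{150, 200, 300} ppm increments, small integer replicate counts — while
defining the true effect mechanistically: each group has a per-ppm relative
response slope ``s``, so the noiseless response line anchored at 350 ppm is

    r(x) = r350 * (1 + s * (x - 350))

Entry-level heterogeneity perturbs the slope multiplicatively
(sign-preserving, so response positivity stays tractable), and measurement
noise is multiplicative log-normal on both members of a pair.  Defining
truth on the response line in concentration space (rather than on log
ratios) means the standardization step is exercised nontrivially across
heterogeneous (A, E) designs: with zero noise it must recover the true
standardized effect exactly, whatever (A, E) was "measured".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from co2ionome.data_model import COLUMNS
from co2ionome.standardization import StandardizationConfig

__all__ = [
    "SyntheticGroup",
    "SyntheticConfig",
    "SyntheticTruth",
    "true_standardized_effect",
    "generate_dataset",
]

_ANCHOR_PPM = 350.0  # the response line is anchored at the default baseline


@dataclass(frozen=True)
class SyntheticGroup:
    """One generative cell: its metadata levels and true response slope."""

    nutrient: str
    species: str
    family: str = ""
    pathway: str = "C3"
    tissue_label: str = "grain"
    study_type: str = "FACE"
    container: str = "field"
    true_slope: float = 0.0  # per-ppm relative change of the response


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for generation.

    Defaults mirror the observed experimental designs: ambient levels
    uniform over 310-455 ppm, added CO2 drawn from {150, 200, 300} ppm,
    3-8 replicates per entry.  Heterogeneity (tau) perturbs each entry's
    slope on the log scale; noise (sigma) is multiplicative log-normal
    measurement error applied independently to both members of a pair.
    """

    groups: tuple[SyntheticGroup, ...]
    entries_per_group: int = 50
    heterogeneity_sd: float = 0.02
    noise_sd: float = 0.02
    ambient_range: tuple[float, float] = (310.0, 455.0)
    added_co2_choices: tuple[float, ...] = (150.0, 200.0, 300.0)
    replicate_range: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ambient_range
        if lo < 280:
            raise ValueError("ambient_range low must be >= 280 ppm")
        if hi < lo:
            raise ValueError("ambient_range must be (low, high)")
        if any(inc <= 0 for inc in self.added_co2_choices):
            raise ValueError("added CO2 increments must be positive")
        if self.heterogeneity_sd < 0 or self.noise_sd < 0:
            raise ValueError("tau and sigma must be >= 0")
        if self.entries_per_group < 1:
            raise ValueError("entries_per_group must be >= 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for recovery tests: group -> true standardized effect."""

    effects: dict[SyntheticGroup, float]

    def true_pct(self, group: SyntheticGroup) -> float:
        return (np.exp(self.effects[group]) - 1.0) * 100.0


def true_standardized_effect(slope: float,
                             config: StandardizationConfig | None = None,
                             ) -> float:
    """Standardized log response implied by a per-ppm slope.

    The response line is anchored at 350 ppm, so
    ``L = ln((1 + s*(E* - 350)) / (1 + s*(A* - 350)))``, which at the
    default baseline A* = 350 reduces to ``ln(1 + s*(E* - A*))``.
    """
    if config is None:
        config = StandardizationConfig()
    num = 1.0 + slope * (config.elevated_ppm - _ANCHOR_PPM)
    den = 1.0 + slope * (config.baseline_ppm - _ANCHOR_PPM)
    if num <= 0 or den <= 0:
        raise ValueError("response line non-positive at a standard level")
    return float(np.log(num / den))


_MAX_RETRIES = 100


def generate_dataset(config: SyntheticConfig,
                     ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate an entry table plus its ground truth.

    The table has the standard database columns and satisfies all entry
    invariants; identical seeds give identical tables.  Entries whose
    perturbed response line would cross zero inside the measured window are
    redrawn (bounded retries).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    truth: dict[SyntheticGroup, float] = {}
    counter = itertools.count(1)
    for g_idx, group in enumerate(config.groups):
        truth[group] = true_standardized_effect(group.true_slope)
        for _ in range(config.entries_per_group):
            for attempt in range(_MAX_RETRIES):
                a = rng.uniform(*config.ambient_range)
                e = a + config.added_co2_choices[
                    rng.integers(len(config.added_co2_choices))]
                eta = rng.normal(0.0, config.heterogeneity_sd)
                s_i = group.true_slope * np.exp(eta)
                r350 = 100.0
                r_a_line = r350 * (1.0 + s_i * (a - _ANCHOR_PPM))
                r_e_line = r350 * (1.0 + s_i * (e - _ANCHOR_PPM))
                if r_a_line > 0 and r_e_line > 0:
                    break
            else:
                raise RuntimeError(
                    "response line crosses zero; slope too steep for the "
                    "configured CO2 range")
            r_a = r_a_line * np.exp(rng.normal(0.0, config.noise_sd))
            r_e = r_e_line * np.exp(rng.normal(0.0, config.noise_sd))
            n_rep = int(rng.integers(config.replicate_range[0],
                                     config.replicate_range[1] + 1))
            eid = next(counter)
            rows.append({
                "entry_id": f"syn{eid:06d}",
                "source_id": f"study{g_idx:03d}",
                "species": group.species,
                "cultivar": None,
                "genus": group.species.split()[0],
                "family": group.family,
                "pathway": group.pathway,
                "tissue_label": group.tissue_label,
                "nutrient": group.nutrient,
                "ambient_ppm": a,
                "elevated_ppm": e,
                "response_ambient": r_a,
                "response_elevated": r_e,
                "n_replicates": n_rep,
                "study_type": group.study_type,
                "container": group.container,
                "country": None,
                "year": None,
                "timepoint_rank": None,
                "is_primary_edible_part": True,
            })
    frame = pd.DataFrame(rows)
    for name in COLUMNS:
        if name not in frame.columns:
            frame[name] = np.nan
    frame = frame[list(COLUMNS)]
    return frame, SyntheticTruth(effects=truth)
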