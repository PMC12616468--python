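"""Model/results interface tying the pipeline together.

:class:`CO2MetaAnalysis` holds an observation-pair table plus the
standardization window and partition layout; :meth:`CO2MetaAnalysis.fit`
standardizes the entries, splits them into groups, and runs replicate-
weighted bootstrap inference in each, returning a :class:`CO2MetaResults`
with per-group estimates, a summary table, forest-style filtering, funnel
diagnostics, and plotting.

Example
-------
>>> from co2ionome import CO2MetaAnalysis, PartitionSpec
>>> model = CO2MetaAnalysis.from_csv("entries.csv",
...                                  partition=PartitionSpec(("nutrient",)))
>>> res = model.fit(seed=42)
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from co2ionome import data_model
from co2ionome.bootstrap import BootstrapConfig, GroupResult, analyze_group
from co2ionome.diagnostics import funnel_data, funnel_frame, size_bias_test
from co2ionome.partitioning import (
    UNCLASSIFIED,
    GroupKey,
    PartitionSpec,
    partition_entries,
)
from co2ionome.standardization import StandardizationConfig, standardize_entries

__all__ = ["CO2MetaAnalysis", "CO2MetaResults", "ForestRow", "forest_table"]


class CO2MetaAnalysis:
    """Replicate-weighted bootstrap meta-analysis of CO2-response pairs.

    Parameters
    ----------
    data : DataFrame
        Observation-pair table with the standard database columns (see
        :mod:`co2ionome.data_model`).
    partition : PartitionSpec
        How to split entries into analysis groups.
    standardization : StandardizationConfig
        The common CO2 window (defaults: 350 -> 550 ppm).
    apply_independence_filter : bool
        Run the curation-time entry-independence filters before analysis.
    """

    def __init__(self, data: pd.DataFrame,
                 partition: PartitionSpec | None = None,
                 standardization: StandardizationConfig | None = None,
                 apply_independence_filter: bool = False):
        self.partition = partition or PartitionSpec()
        self.standardization = standardization or StandardizationConfig()
        if apply_independence_filter:
            entries, rej = self._validate_frame(data)
            entries = data_model.select_independent_entries(entries)
            data = data_model.entries_to_frame(entries)
        self.data = data.reset_index(drop=True)

    @staticmethod
    def _validate_frame(data: pd.DataFrame):
        rows = data.to_dict("records")
        entries = []
        for row in rows:
            entries.append(data_model._row_to_entry(pd.Series(row)))
        return entries, []

    @classmethod
    def from_csv(cls, path, strict: bool = False, **kwargs
                 ) -> "CO2MetaAnalysis":
        """Build the model from a database CSV, dropping invalid rows."""
        entries, _ = data_model.read_database(path, strict=strict)
        return cls(data_model.entries_to_frame(entries), **kwargs)

    @classmethod
    def from_entries(cls, entries, **kwargs) -> "CO2MetaAnalysis":
        return cls(data_model.entries_to_frame(entries), **kwargs)

    def fit(self, n_resamples: int = 10_000, alpha: float = 0.05,
            power_effect: float = 0.05, seed: int = 0,
            small_sample_threshold: int = 20) -> "CO2MetaResults":
        """Standardize, partition, and bootstrap every group.

        The whole-dataset SD (unweighted, over all standardized entries) is
        used as the small-sample power floor.  Returns a
        :class:`CO2MetaResults`.
        """
        config = BootstrapConfig(
            n_resamples=n_resamples, alpha=alpha, power_effect=power_effect,
            seed=seed, small_sample_threshold=small_sample_threshold)
        std = standardize_entries(self.data, self.standardization)
        usable = std[std["adj_log_rr"].notna()]
        dataset_sd = (float(usable["adj_log_rr"].std(ddof=1))
                      if len(usable) > 1 else 0.0)
        groups = partition_entries(usable, self.partition)
        results: list[GroupResult] = []
        unclassified_n = 0
        for key in sorted(groups, key=str):
            cell = groups[key]
            if key.levels and key.levels[0][0] == UNCLASSIFIED:
                unclassified_n = len(cell)
                continue
            if not len(cell):
                continue
            results.append(analyze_group(
                key,
                cell["adj_log_rr"].to_numpy(),
                cell["n_replicates"].to_numpy(),
                config,
                dataset_sd=dataset_sd,
            ))
        return CO2MetaResults(
            model=self, config=config, standardized=std, results=results,
            dataset_sd=dataset_sd, n_unclassified=unclassified_n)


class CO2MetaResults:
    """Fitted per-group bootstrap estimates and diagnostics."""

    def __init__(self, model: CO2MetaAnalysis, config: BootstrapConfig,
                 standardized: pd.DataFrame, results: list[GroupResult],
                 dataset_sd: float, n_unclassified: int = 0):
        self.model = model
        self.config = config
        self.standardized = standardized
        self.results = results
        self.dataset_sd = dataset_sd
        self.n_unclassified = n_unclassified

    @property
    def frame(self) -> pd.DataFrame:
        """Results as a DataFrame, one row per group."""
        rows = []
        for r in self.results:
            row = {"group": str(r.key)}
            row.update(r.key.as_dict())
            row.update({
                "n_entries": r.n_entries,
                "n_obs_pairs": r.n_obs_pairs,
                "mean_pct": r.mean_pct,
                "ci_low_pct": r.ci_low_pct,
                "ci_high_pct": r.ci_high_pct,
                "p_value": r.p_value,
                "power": r.power,
                "power_class": r.power_class,
                "significant": r.significant,
                "direction": r.direction,
            })
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary table of all groups."""
        lines = [
            "CO2 ionome meta-analysis "
            f"({self.model.standardization.baseline_ppm:.0f} -> "
            f"{self.model.standardization.elevated_ppm:.0f} ppm window)",
            f"groups: {len(self.results)}   "
            f"resamples: {self.config.n_resamples}   "
            f"alpha: {self.config.alpha}   "
            f"power effect: {self.config.power_effect:.0%}",
        ]
        if self.n_unclassified:
            lines.append(f"unclassified entries excluded: "
                         f"{self.n_unclassified}")
        header = (f"{'group':<34}{'n':>5}{'pairs':>7}{'mean%':>9}"
                  f"{'CI low':>9}{'CI high':>9}{'p':>8}{'power':>7}  class")
        lines += ["", header, "-" * len(header)]
        for r in self.results:
            lines.append(
                f"{str(r.key)[:33]:<34}{r.n_entries:>5}{r.n_obs_pairs:>7}"
                f"{r.mean_pct:>9.2f}{r.ci_low_pct:>9.2f}{r.ci_high_pct:>9.2f}"
                f"{r.p_value:>8.4f}{r.power:>7.3f}  {r.power_class}"
            )
        return "\n".join(lines)

    def forest_table(self, power_floor: Optional[float] = 0.8
                     ) -> list["ForestRow"]:
        """Forest-style rows, optionally keeping only high-power groups."""
        return forest_table(self.results, power_floor)

    def funnel(self) -> pd.DataFrame:
        """Funnel data: effect vs. replicate count, one row per entry."""
        usable = self.standardized[self.standardized["adj_log_rr"].notna()]
        return funnel_frame(funnel_data(usable))

    def publication_bias_test(self) -> tuple[float, float, float]:
        """Size-bias regression over all standardized entries."""
        usable = self.standardized[self.standardized["adj_log_rr"].notna()]
        return size_bias_test(funnel_data(usable))

    def to_csv(self, path) -> None:
        data_model.write_results_table(self.results, path)

    def plot_forest(self, power_floor: Optional[float] = 0.8, ax=None):
        """Horizontal forest plot of means and CIs, color-coded by code."""
        import matplotlib.pyplot as plt

        rows = self.forest_table(power_floor)
        if ax is None:
            _, ax = plt.subplots(figsize=(7, max(2, 0.35 * len(rows))))
        colors = {"sig_decrease": "crimson", "sig_increase": "seagreen",
                  "not_significant": "gray"}
        for i, row in enumerate(rows):
            ax.plot([row.ci_low_pct, row.ci_high_pct], [i, i],
                    color=colors[row.code], lw=2)
            ax.plot(row.mean_pct, i, "|", color=colors[row.code], ms=12)
        ax.axvline(0, color="k", lw=0.8, ls=":")
        ax.set_yticks(range(len(rows)))
        ax.set_yticklabels([r.label for r in rows])
        ax.set_xlabel("percent change (350 -> 550 ppm)")
        return ax

    def plot_funnel(self, ax=None):
        """Effect vs. replicate count scatter."""
        import matplotlib.pyplot as plt

        data = self.funnel()
        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(data["effect"], data["n_replicates"], s=10, alpha=0.5)
        ax.axvline(0, color="k", lw=0.8, ls=":")
        ax.set_xlabel("standardized log response ratio")
        ax.set_ylabel("number of replicates")
        return ax


@dataclass(frozen=True)
class ForestRow:
    """One displayable row of the forest table."""

    label: str
    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    code: str  # sig_decrease | sig_increase | not_significant
    power_class: str
    ci_excludes_zero: bool


def forest_table(results: Sequence[GroupResult],
                 power_floor: Optional[float] = 0.8) -> list[ForestRow]:
    """Filter results by power and code them by significance and direction.

    Groups with power at or below ``power_floor`` are dropped (pass None to
    keep everything); retained values are never altered.  The code couples
    color to the p-value decision; ``ci_excludes_zero`` is carried as a
    secondary check for the occasional disagreement between the two.
    """
    rows = []
    for r in sorted(results, key=lambda r: str(r.key)):
        if power_floor is not None and r.power <= power_floor:
            continue
        if r.significant and r.mean_pct < 0:
            code = "sig_decrease"
        elif r.significant and r.mean_pct > 0:
            code = "sig_increase"
        else:
            code = "not_significant"
        rows.append(ForestRow(
            label=str(r.key),
            mean_pct=r.mean_pct,
            ci_low_pct=r.ci_low_pct,
            ci_high_pct=r.ci_high_pct,
            code=code,
            power_class=r.power_class,
            ci_excludes_zero=not (r.ci_low_pct <= 0.0 <= r.ci_high_pct),
        ))
    return rows
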