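"""Replicate-weighted bootstrap inference for one analysis group.

The effect sizes within a group are standardized log response ratios; the
replicate count of each entry is its resampling weight, so experiments with
more replicates have a proportionally higher chance of being (re-)selected.
Inference is fully nonparametric: the group samples are neither normal nor
homoscedastic, so the mean, its 95% percentile confidence interval, a
two-sided bootstrap p-value against "no effect", and a shift-based
statistical power are all computed from the resampling distribution.

Power here is operational: shift every effect by the target effect size
(default a 5% decrease, ``ln(0.95)`` on the log scale), re-bootstrap, and
report the fraction of shifted resample means that fall outside the original
sample's confidence interval.  Small groups (< 20 entries) underestimate
their spread, which overestimates power; when a small group's SD is below
the whole-dataset SD, deviations around the shifted mean are inflated to the
dataset SD first — the conservative choice.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from co2ionome.partitioning import GroupKey
from co2ionome.standardization import percent_change

__all__ = [
    "BootstrapConfig",
    "GroupResult",
    "weighted_resample_means",
    "percentile_ci",
    "bootstrap_p_value",
    "bootstrap_power",
    "classify_power",
    "analyze_group",
    "derive_group_seed",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Knobs of the bootstrap procedure.

    n_resamples : resamples drawn per statistic (default 10,000).
    alpha : significance level for the CI and the decision rule (0.05).
    power_effect : relative effect size power is computed for (0.05 = 5%).
    power_direction : -1 shifts toward a decrease (the dominant observed
        direction), +1 toward an increase.
    seed : master RNG seed; per-group seeds are derived from it.
    small_sample_threshold : groups smaller than this use the SD floor.
    """

    n_resamples: int = 10_000
    alpha: float = 0.05
    power_effect: float = 0.05
    power_direction: int = -1
    seed: int = 0
    small_sample_threshold: int = 20

    def __post_init__(self) -> None:
        if self.n_resamples < 1:
            raise ValueError("n_resamples must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not self.power_effect > 0:
            raise ValueError("power_effect must be > 0")

    @property
    def power_shift(self) -> float:
        """The log-scale shift used for power: ln(1 - effect) or ln(1 + effect)."""
        if self.power_direction < 0:
            return float(np.log1p(-self.power_effect))
        return float(np.log1p(self.power_effect))


@dataclass(frozen=True)
class GroupResult:
    """Bootstrap inference for one partition cell, on the percent scale."""

    key: GroupKey
    n_entries: int
    n_obs_pairs: int
    mean_pct: float
    ci_low_pct: float
    ci_high_pct: float
    p_value: float
    power: float
    power_class: str
    significant: bool
    direction: str
    sd_floor_applied: bool = False


def _prep(values, weights):
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("empty sample")
    if weights.shape != values.shape:
        raise ValueError("weights must match values in length")
    if np.any(weights <= 0):
        raise ValueError("weights must be positive")
    return values, weights


def weighted_resample_means(values, weights, n_resamples: int,
                            seed) -> np.ndarray:
    """Means of weighted bootstrap resamples.

    Each resample draws ``len(values)`` items with replacement with
    selection probability proportional to ``weights`` and contributes its
    unweighted mean.  ``seed`` may be an int or a ``numpy.random.Generator``.
    """
    values, weights = _prep(values, weights)
    rng = seed if isinstance(seed, np.random.Generator) else (
        np.random.default_rng(seed))
    p = weights / weights.sum()
    n = values.size
    idx = rng.choice(n, size=(int(n_resamples), n), replace=True, p=p)
    return values[idx].mean(axis=1)


def percentile_ci(means, alpha: float = 0.05) -> tuple[float, float]:
    """Percentile confidence interval of a resampling distribution.

    Empirical quantiles at alpha/2 and 1 - alpha/2 with linear interpolation
    between order statistics.
    """
    means = np.asarray(means, dtype=float)
    if means.size == 0:
        raise ValueError("empty resample distribution")
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2], method="linear")
    return float(lo), float(hi)


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    return float(np.average(values, weights=weights))


def bootstrap_p_value(values, weights, config: BootstrapConfig,
                      rng: Optional[np.random.Generator] = None) -> float:
    """Two-sided bootstrap p-value against the null of no effect.

    The test statistic is the standardized weighted mean
    ``Z_obs = |mean_w| / SE`` with SE the standard deviation of the resample
    means.  The null distribution is obtained by recentering the sample at
    zero, resampling it identically, and computing the same statistic; the
    p-value is the fraction of null statistics at least as extreme:
    ``p = #{|Z*| >= |Z_obs|} / n_resamples``.
    """
    values, weights = _prep(values, weights)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    wmean = _weighted_mean(values, weights)
    obs_means = weighted_resample_means(values, weights,
                                        config.n_resamples, rng)
    se = float(obs_means.std(ddof=1)) if obs_means.size > 1 else 0.0
    if se == 0.0:
        # degenerate zero-spread group: limiting behavior
        return 0.0 if wmean != 0.0 else 1.0
    z_obs = abs(wmean) / se
    null_values = values - wmean
    null_means = weighted_resample_means(null_values, weights,
                                         config.n_resamples, rng)
    null_se = float(null_means.std(ddof=1))
    if null_se == 0.0:
        return 1.0
    z_star = np.abs(null_means) / null_se
    return float(np.mean(z_star >= z_obs))


def bootstrap_power(values, weights, config: BootstrapConfig,
                    observed_ci: tuple[float, float],
                    dataset_sd: Optional[float] = None,
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[float, bool]:
    """Shift-based bootstrap power at the configured effect size.

    Shifts every value by ``config.power_shift`` on the log scale,
    re-bootstraps, and returns the fraction of shifted resample means that
    fall outside ``observed_ci`` (the original sample's percentile CI on the
    same scale), together with a flag marking whether the small-sample SD
    floor was applied.

    For groups smaller than ``small_sample_threshold`` whose sample SD is
    below ``dataset_sd``, deviations around the shifted mean are inflated by
    ``dataset_sd / sample_sd`` before resampling; ``dataset_sd`` is required
    in that situation.
    """
    values, weights = _prep(values, weights)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    shifted = values + config.power_shift

    floored = False
    if values.size < config.small_sample_threshold:
        sample_sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        if dataset_sd is None:
            raise ValueError("dataset_sd required for small-sample groups")
        if sample_sd < dataset_sd:
            center = shifted.mean()
            if sample_sd > 0:
                shifted = center + (shifted - center) * (dataset_sd / sample_sd)
            else:
                # zero-spread sample: replace by a symmetric two-point
                # sample at +-SD around the shifted center
                shifted = center + dataset_sd * np.array([-1.0, 1.0])
                weights = np.ones(2)
            floored = True

    means = weighted_resample_means(shifted, weights, config.n_resamples, rng)
    lo, hi = observed_ci
    outside = (means < lo) | (means > hi)
    return float(outside.mean()), floored


def classify_power(power: float) -> str:
    """Rubric: < 0.4 low; 0.4-0.8 medium (boundaries inclusive); > 0.8 high."""
    if not 0.0 <= power <= 1.0:
        raise ValueError("power must lie in [0, 1]")
    if power < 0.4:
        return "low"
    if power <= 0.8:
        return "medium"
    return "high"


def derive_group_seed(master_seed: int, key: GroupKey) -> int:
    """Stable per-group seed so results do not depend on iteration order."""
    digest = hashlib.sha256(f"{master_seed}|{key}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def analyze_group(key: GroupKey, adj_log_rr, n_replicates,
                  config: BootstrapConfig,
                  dataset_sd: Optional[float] = None) -> GroupResult:
    """Full bootstrap inference for one group.

    ``adj_log_rr`` are the standardized log response ratios of the group's
    entries and ``n_replicates`` their resampling weights.  All log-scale
    statistics are back-transformed to percent change for reporting.  The
    group's RNG seed is derived from the master seed and the group key, so
    results are reproducible regardless of analysis order; the p-value,
    CI, and power use distinct substreams.
    """
    values, weights = _prep(adj_log_rr, n_replicates)
    group_seed = derive_group_seed(config.seed, key)
    ss = np.random.SeedSequence(group_seed)
    rng_ci, rng_p, rng_power = (np.random.default_rng(s)
                                for s in ss.spawn(3))

    wmean = _weighted_mean(values, weights)
    if values.size > 1 and float(values.std(ddof=1)) > 0:
        obs_means = weighted_resample_means(values, weights,
                                            config.n_resamples, rng_ci)
        lo, hi = percentile_ci(obs_means, config.alpha)
        mean_log = float(obs_means.mean())
        p = bootstrap_p_value(values, weights, config, rng_p)
        power, floored = bootstrap_power(values, weights, config, (lo, hi),
                                         dataset_sd, rng_power)
    else:
        # degenerate group: zero spread (or single entry with no spread)
        lo = hi = mean_log = wmean
        p = 0.0 if wmean != 0.0 else 1.0
        if dataset_sd is not None and dataset_sd > 0:
            power, floored = bootstrap_power(values, weights, config,
                                             (lo, hi), dataset_sd, rng_power)
        else:
            power, floored = 0.0, False

    mean_pct = percent_change(mean_log)
    significant = p < config.alpha
    if not significant:
        direction = "none"
    else:
        direction = "decrease" if mean_pct < 0 else "increase"
    return GroupResult(
        key=key,
        n_entries=int(values.size),
        n_obs_pairs=int(np.asarray(n_replicates).sum()),
        mean_pct=mean_pct,
        ci_low_pct=percent_change(lo),
        ci_high_pct=percent_change(hi),
        p_value=p,
        power=power,
        power_class=classify_power(power),
        significant=significant,
        direction=direction,
        sd_floor_applied=floored,
    )
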