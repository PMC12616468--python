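"""Splitting standardized entries into analysis groups.

Groups are formed by crossing any subset of the recorded factors (nutrient,
photosynthetic pathway, tissue group, study type, container, taxonomy).
Two special curation rules apply before splitting:

* the nitrogen proxy — nitrogen and protein measure the same underlying
  quantity (protein is linearly related to N), so a combined ``N_proxy``
  nutrient stream is built using nitrogen when available and protein
  otherwise, never both for one data point;
* rice separation — rice grains are grown flooded, under conditions unlike
  other crops, and can optionally be held out as their own stratum before
  any other split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

__all__ = [
    "PartitionSpec",
    "GroupKey",
    "TISSUE_GROUPS",
    "assign_tissue_group",
    "resolve_nitrogen_proxy",
    "partition_entries",
    "UNCLASSIFIED",
]

VALID_FACTORS = (
    "nutrient",
    "pathway",
    "tissue_group",
    "study_type",
    "container",
    "country",
    "family",
    "genus",
    "species",
    "cultivar",
)

#: Fixed tissue vocabulary -> aggregate group.  Extensible by passing an
#: augmented mapping to assign_tissue_group / partition_entries.
TISSUE_GROUPS: dict[str, str] = {
    "tuber": "belowground",
    "root": "belowground",
    "grain": "reproductive",
    "seed": "reproductive",
    "fruit": "reproductive",
    "fruit juice": "reproductive",
    "pod": "reproductive",
    "shoot": "aboveground",
    "stem": "aboveground",
}

#: Key of the bucket for entries whose factor levels cannot be resolved.
UNCLASSIFIED = "unclassified"

#: Species names recognized as rice for the rice stratum.
RICE_SPECIES = {"rice", "oryza sativa"}


@dataclass(frozen=True)
class PartitionSpec:
    """How to split the dataset into analysis groups.

    factors : ordered unique factor names (empty = whole-dataset analysis).
    separate_rice : hold rice-grain entries out as their own stratum first.
    use_nitrogen_proxy : build the combined N/protein stream before splitting.
    """

    factors: tuple[str, ...] = ()
    separate_rice: bool = False
    use_nitrogen_proxy: bool = False

    def __post_init__(self) -> None:
        facs = tuple(self.factors)
        object.__setattr__(self, "factors", facs)
        if len(set(facs)) != len(facs):
            raise ValueError("factors must be unique")
        unknown = set(facs) - set(VALID_FACTORS)
        if unknown:
            raise ValueError(f"unknown factors: {sorted(unknown)}; "
                             f"valid: {VALID_FACTORS}")


@dataclass(frozen=True, order=True)
class GroupKey:
    """Identity of one analysis cell: factor levels plus optional strata."""

    levels: tuple[tuple[str, str], ...] = ()
    rice_stratum: Optional[bool] = None

    def as_dict(self) -> dict[str, str]:
        d = dict(self.levels)
        if self.rice_stratum is not None:
            d["rice_stratum"] = str(self.rice_stratum)
        return d

    def __str__(self) -> str:
        parts = [f"{k}={v}" for k, v in self.levels]
        if self.rice_stratum:
            parts.insert(0, "rice")
        elif self.rice_stratum is False:
            parts.insert(0, "non-rice")
        return "|".join(parts) if parts else "all"


def assign_tissue_group(tissue_label: str,
                        mapping: Mapping[str, str] | None = None) -> str:
    """Map a raw tissue label to {aboveground, reproductive, belowground}."""
    table = TISSUE_GROUPS if mapping is None else mapping
    key = tissue_label.strip().lower()
    if key not in table:
        raise KeyError(
            f"unknown tissue label {tissue_label!r}; known labels: "
            f"{sorted(table)}"
        )
    return table[key]


def _point_key(row: pd.Series) -> tuple:
    # finest granularity at which N and protein could duplicate
    return (
        row["source_id"], row["species"], row.get("cultivar"),
        row["tissue_label"], row["ambient_ppm"], row["elevated_ppm"],
        row.get("timepoint_rank"),
    )


def resolve_nitrogen_proxy(frame: pd.DataFrame) -> pd.DataFrame:
    """Append the combined nitrogen/protein stream as nutrient ``N_proxy``.

    For each underlying data point, exactly one record feeds the proxy:
    the nitrogen record when present, otherwise the protein record.  The
    originals remain under their own nutrient codes so element-level
    analyses are unaffected.
    """
    mask = frame["nutrient"].isin(["N", "protein"])
    if not mask.any():
        return frame.copy()
    cand = frame[mask]
    keys = cand.apply(_point_key, axis=1)
    take_idx: list = []
    for _, grp in cand.groupby(keys.rename("point"), sort=False):
        has_n = grp["nutrient"] == "N"
        chosen = grp[has_n] if has_n.any() else grp
        take_idx.extend(chosen.index)
    proxy = frame.loc[take_idx].copy()
    proxy["nutrient"] = "N_proxy"
    proxy["entry_id"] = proxy["entry_id"].astype(str) + ":N_proxy"
    out = pd.concat([frame, proxy], ignore_index=True)
    return out


def _is_rice_grain(row: pd.Series) -> bool:
    sp = str(row["species"]).strip().lower()
    return sp in RICE_SPECIES and str(row["tissue_label"]).strip().lower() == "grain"


def partition_entries(frame: pd.DataFrame, spec: PartitionSpec,
                      tissue_mapping: Mapping[str, str] | None = None,
                      ) -> dict[GroupKey, pd.DataFrame]:
    """Split a standardized entry table into disjoint analysis groups.

    Entries whose factor levels cannot be resolved (unknown tissue label,
    missing value) go to a single ``UNCLASSIFIED`` bucket, reported under
    the key ``GroupKey((("unclassified", "unclassified"),))`` and excluded
    from inference by callers.
    """
    work = frame.copy()
    if spec.use_nitrogen_proxy:
        work = resolve_nitrogen_proxy(work)

    unclassified_mask = pd.Series(False, index=work.index)
    if "tissue_group" in spec.factors:
        table = TISSUE_GROUPS if tissue_mapping is None else tissue_mapping
        labels = work["tissue_label"].astype(str).str.strip().str.lower()
        work["tissue_group"] = labels.map(table)
        unclassified_mask |= work["tissue_group"].isna()
    for factor in spec.factors:
        if factor == "tissue_group":
            continue
        unclassified_mask |= work[factor].isna()

    groups: dict[GroupKey, pd.DataFrame] = {}
    bad = work[unclassified_mask]
    if len(bad):
        groups[GroupKey(levels=((UNCLASSIFIED, UNCLASSIFIED),))] = bad
    good = work[~unclassified_mask]

    strata: list[tuple[Optional[bool], pd.DataFrame]]
    if spec.separate_rice:
        rice_mask = good.apply(_is_rice_grain, axis=1) if len(good) else (
            pd.Series(False, index=good.index))
        strata = [(True, good[rice_mask]), (False, good[~rice_mask])]
    else:
        strata = [(None, good)]

    for rice_flag, sub in strata:
        if not len(sub):
            continue
        if not spec.factors:
            groups[GroupKey(levels=(), rice_stratum=rice_flag)] = sub
            continue
        for levels, cell in sub.groupby(list(spec.factors), sort=True):
            if not isinstance(levels, tuple):
                levels = (levels,)
            key = GroupKey(
                levels=tuple(zip(spec.factors, map(str, levels))),
                rice_stratum=rice_flag,
            )
            groups[key] = cell
    return groups
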