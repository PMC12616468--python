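"""Observation-pair schema, CSV I/O, validation, and independence filters.

One :class:`ObservationEntry` is a single paired measurement: a nutrient
concentration in an edible plant part measured at an ambient and at an
elevated CO2 level, with the replicate count and the grouping metadata
(taxonomy, photosynthetic pathway, tissue, study design) used downstream.

The on-disk format is a UTF-8 comma-delimited table with one header row and
one column per schema field; the six experiment cofactors (temperature,
irrigation, sowing time, N/P application, ozone) are stored as optional
``cofactor_*`` columns.  Cofactors are carried through but never analyzed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationEntry",
    "RejectedRow",
    "COLUMNS",
    "COFACTOR_NAMES",
    "read_database",
    "write_database",
    "entries_to_frame",
    "select_independent_entries",
    "write_results_table",
    "read_results_table",
]

Pathway = Literal["C3", "C4"]
StudyType = Literal["FACE", "OTC", "chamber", "greenhouse", "tunnel"]
Container = Literal["field", "pot"]

COFACTOR_NAMES = (
    "temperature",
    "irrigation",
    "sowing_time",
    "n_application",
    "p_application",
    "o3_application",
)

#: Fixed column order of the delimited database.
COLUMNS = (
    "entry_id",
    "source_id",
    "species",
    "cultivar",
    "genus",
    "family",
    "pathway",
    "tissue_label",
    "nutrient",
    "ambient_ppm",
    "elevated_ppm",
    "response_ambient",
    "response_elevated",
    "n_replicates",
    "study_type",
    "container",
    "country",
    "year",
    "timepoint_rank",
    "is_primary_edible_part",
) + tuple(f"cofactor_{name}" for name in COFACTOR_NAMES)


class ObservationEntry(BaseModel):
    """One ambient/elevated response pair with replicates and metadata."""

    model_config = ConfigDict(frozen=True)

    entry_id: str
    source_id: str
    species: str
    cultivar: Optional[str] = None
    genus: str = ""
    family: str = ""
    pathway: Pathway
    tissue_label: str
    nutrient: str
    ambient_ppm: float
    elevated_ppm: float
    response_ambient: float
    response_elevated: float
    n_replicates: int
    study_type: StudyType
    container: Container
    country: Optional[str] = None
    year: Optional[int] = None
    timepoint_rank: Optional[int] = None
    is_primary_edible_part: bool = True
    cofactors: dict[str, float] = {}

    @field_validator("ambient_ppm", "response_ambient")
    @classmethod
    def _positive(cls, v: float) -> float:
        if not v > 0:
            raise ValueError("must be > 0")
        return v

    @field_validator("response_elevated")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("n_replicates")
    @classmethod
    def _at_least_one(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @field_validator("cofactors")
    @classmethod
    def _known_cofactors(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(COFACTOR_NAMES)
        if unknown:
            raise ValueError(f"unknown cofactors: {sorted(unknown)}")
        return v

    @model_validator(mode="after")
    def _elevated_above_ambient(self) -> "ObservationEntry":
        if not self.elevated_ppm > self.ambient_ppm:
            raise ValueError("elevated not above ambient")
        return self

    def to_row(self) -> dict:
        row = {
            col: getattr(self, col)
            for col in COLUMNS
            if not col.startswith("cofactor_")
        }
        for name in COFACTOR_NAMES:
            row[f"cofactor_{name}"] = self.cofactors.get(name)
        return row


@dataclass(frozen=True)
class RejectedRow:
    """A database row that failed validation, with the offending reason."""

    row_index: int
    reason: str


_REQUIRED = [c for c in COLUMNS
             if c not in ("cultivar", "country", "year", "timepoint_rank")
             and not c.startswith("cofactor_")]


def _row_to_entry(row: pd.Series) -> ObservationEntry:
    def _opt(col):
        v = row.get(col)
        if v is None or (isinstance(v, float) and math.isnan(v)) or v == "":
            return None
        return v

    cofactors = {}
    for name in COFACTOR_NAMES:
        v = _opt(f"cofactor_{name}")
        if v is not None:
            cofactors[name] = float(v)

    year = _opt("year")
    rank = _opt("timepoint_rank")
    edible = row.get("is_primary_edible_part", True)
    if isinstance(edible, str):
        edible = edible.strip().lower() in ("true", "1", "yes")
    return ObservationEntry(
        entry_id=str(row["entry_id"]),
        source_id=str(row["source_id"]),
        species=str(row["species"]),
        cultivar=_opt("cultivar") and str(row["cultivar"]),
        genus=str(_opt("genus") or ""),
        family=str(_opt("family") or ""),
        pathway=row["pathway"],
        tissue_label=str(row["tissue_label"]),
        nutrient=str(row["nutrient"]),
        ambient_ppm=float(row["ambient_ppm"]),
        elevated_ppm=float(row["elevated_ppm"]),
        response_ambient=float(row["response_ambient"]),
        response_elevated=float(row["response_elevated"]),
        n_replicates=int(row["n_replicates"]),
        study_type=row["study_type"],
        container=row["container"],
        country=_opt("country") and str(row["country"]),
        year=None if year is None else int(year),
        timepoint_rank=None if rank is None else int(rank),
        is_primary_edible_part=bool(edible),
        cofactors=cofactors,
    )


def read_database(path, strict: bool = False,
                  ) -> tuple[list[ObservationEntry], list[RejectedRow]]:
    """Read a delimited observation-pair database.

    Parameters
    ----------
    path : path-like
        CSV file with the documented header.
    strict : bool
        If True, any malformed row raises instead of being collected as a
        rejection.  A missing required column is always a hard error.

    Returns
    -------
    (entries, rejections)
        Validated entries in file order and per-row rejection records.
    """
    frame = pd.read_csv(path, dtype={"entry_id": str, "source_id": str})
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    entries: list[ObservationEntry] = []
    rejections: list[RejectedRow] = []
    for idx, row in frame.iterrows():
        try:
            entries.append(_row_to_entry(row))
        except Exception as exc:  # validation or coercion failure
            reason = _short_reason(exc)
            if strict:
                raise ValueError(f"row {idx}: {reason}") from exc
            rejections.append(RejectedRow(row_index=int(idx), reason=reason))
    if rejections:
        counts: dict[str, int] = {}
        for r in rejections:
            counts[r.reason] = counts.get(r.reason, 0) + 1
        for reason, n in sorted(counts.items()):
            logger.info("rejected %d row(s): %s", n, reason)
    return entries, rejections


def _short_reason(exc: Exception) -> str:
    msg = str(exc)
    if "elevated not above ambient" in msg:
        return "elevated not above ambient"
    if "n_replicates" in msg and ">= 1" in msg:
        return "n_replicates below 1"
    first = msg.splitlines()[0] if msg else type(exc).__name__
    return first[:120]


def entries_to_frame(entries: Iterable[ObservationEntry]) -> pd.DataFrame:
    """Tabulate entries with the fixed database column order."""
    rows = [e.to_row() for e in entries]
    frame = pd.DataFrame(rows, columns=list(COLUMNS))
    return frame


def write_database(entries: Sequence[ObservationEntry], path) -> None:
    """Write entries as the standard CSV (round-trips with read_database)."""
    entries_to_frame(entries).to_csv(path, index=False)


def select_independent_entries(
    entries: Sequence[ObservationEntry],
) -> list[ObservationEntry]:
    """Apply the entry-independence filters used at curation time.

    Repeated harvests of one experiment are reduced to the latest (maximal
    ``timepoint_rank``) so the most mature edible part is kept, and entries
    flagged as not the primary edible part of the plant are dropped.  The
    operation is idempotent.
    """
    kept = [e for e in entries if e.is_primary_edible_part]

    def exp_key(e: ObservationEntry):
        return (e.source_id, e.species, e.cultivar, e.nutrient,
                e.ambient_ppm, e.elevated_ppm)

    latest: dict[tuple, int] = {}
    for e in kept:
        rank = e.timepoint_rank if e.timepoint_rank is not None else 0
        k = exp_key(e)
        if k not in latest or rank > latest[k]:
            latest[k] = rank
    return [
        e for e in kept
        if (e.timepoint_rank if e.timepoint_rank is not None else 0)
        == latest[exp_key(e)]
    ]


RESULT_COLUMNS = (
    "group",
    "n_entries",
    "n_obs_pairs",
    "mean_pct",
    "ci_low_pct",
    "ci_high_pct",
    "p_value",
    "power",
    "power_class",
    "significant",
    "direction",
)


def write_results_table(results, path) -> None:
    """Write per-group bootstrap results as a fixed-column CSV.

    ``results`` is an iterable of :class:`co2ionome.bootstrap.GroupResult`.
    """
    rows = []
    for r in results:
        rows.append({
            "group": str(r.key),
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
    pd.DataFrame(rows, columns=list(RESULT_COLUMNS)).to_csv(path, index=False)


def read_results_table(path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results_table`."""
    return pd.read_csv(path)
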