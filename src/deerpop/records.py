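"""Encounter-history records for telemetered deer and their CSV serialization.

An :class:`EncounterRecord` is one monitored animal: its life stage at
capture, the calendar day it entered the monitored sample (staggered entry),
the day monitoring ended, and its fate.  Fawn records may carry a ``dam_id``
linking them to the collared female they were born to.

The on-disk format is a plain CSV with header
``animal_id,stage,entry_day,exit_day,fate,dam_id`` (``dam_id`` empty for
non-fawns).  ``read_records``/``write_records`` round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

STAGES = ("fawn", "yearling", "adult")
FATES = ("alive_at_end", "natural_death", "harvest_death", "censored_other")

CSV_COLUMNS = ["animal_id", "stage", "entry_day", "exit_day", "fate", "dam_id"]


class RecordFormatError(ValueError):
    """A malformed encounter-history row (bad label, bad times)."""


@dataclass(frozen=True)
class EncounterRecord:
    """One monitored animal.

    Parameters
    ----------
    animal_id : str
        Opaque identifier, unique within a dataset.
    stage : str
        One of ``fawn``, ``yearling``, ``adult``.
    entry_time : float
        Days since study origin at which the animal joined the risk set
        (its capture day, or birth day for fawns).
    exit_time : float
        Days since study origin at which monitoring ended (death, censoring,
        or end of study).
    fate : str
        ``alive_at_end``, ``natural_death``, ``harvest_death`` or
        ``censored_other``.
    dam_id : str or None
        For fawns, the identifier of the dam's record.
    """

    animal_id: str
    stage: str
    entry_time: float
    exit_time: float
    fate: str
    dam_id: str | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise RecordFormatError(f"unknown stage {self.stage!r}")
        if self.fate not in FATES:
            raise RecordFormatError(f"unknown fate {self.fate!r}")
        if self.exit_time < self.entry_time:
            raise RecordFormatError(
                f"exit_time {self.exit_time} precedes entry_time "
                f"{self.entry_time} for animal {self.animal_id!r}"
            )

    @property
    def is_death(self) -> bool:
        return self.fate in ("natural_death", "harvest_death")


def validate_records(records: Sequence[EncounterRecord]) -> None:
    """Check cross-record invariants: unique ids, dam links resolve."""
    ids = [r.animal_id for r in records]
    if len(set(ids)) != len(ids):
        raise RecordFormatError("duplicate animal_id in record collection")
    parents = {r.animal_id for r in records if r.stage in ("yearling", "adult")}
    if parents:
        # dam links are only checkable when the dam records travel with the
        # fawns; a standalone fawn file keeps its dam_ids as opaque labels
        for r in records:
            if r.dam_id is not None and r.dam_id not in parents:
                raise RecordFormatError(
                    f"fawn {r.animal_id!r} references unknown dam {r.dam_id!r}"
                )


def to_frame(records: Iterable[EncounterRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame with the CSV column layout."""
    rows = [
        {
            "animal_id": r.animal_id,
            "stage": r.stage,
            "entry_day": r.entry_time,
            "exit_day": r.exit_time,
            "fate": r.fate,
            "dam_id": r.dam_id if r.dam_id is not None else "",
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def from_frame(df: pd.DataFrame, *, source: str = "<frame>") -> list[EncounterRecord]:
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise RecordFormatError(f"{source}: missing columns {missing}")
    out: list[EncounterRecord] = []
    for idx, row in df.iterrows():
        dam = row["dam_id"]
        if pd.isna(dam) or dam == "":
            dam = None
        try:
            rec = EncounterRecord(
                animal_id=str(row["animal_id"]),
                stage=str(row["stage"]),
                entry_time=float(row["entry_day"]),
                exit_time=float(row["exit_day"]),
                fate=str(row["fate"]),
                dam_id=None if dam is None else str(dam),
            )
        except (RecordFormatError, ValueError) as exc:
            # +2: header line plus 1-based indexing
            raise RecordFormatError(f"{source}, line {idx + 2}: {exc}") from exc
        out.append(rec)
    return out


def write_records(records: Sequence[EncounterRecord], path: str | Path) -> None:
    """Write records to ``path`` as CSV (header always present)."""
    validate_records(records)
    # %.17g round-trips IEEE doubles exactly
    to_frame(records).to_csv(path, index=False, float_format="%.17g")


def read_records(path: str | Path) -> list[EncounterRecord]:
    """Read an encounter-history CSV; raises :class:`RecordFormatError`
    naming the offending line on malformed input."""
    df = pd.read_csv(
        path,
        dtype={"animal_id": str, "dam_id": str},
        keep_default_na=True,
        float_precision="round_trip",
    )
    records = from_frame(df, source=str(path))
    validate_records(records)
    return records
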