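"""Long-format EMA data model: validated records and CSV round-tripping.

One row per scheduled prompt.  Unanswered prompts are kept as explicit rows
(``answered=False``) so that per-cycle missingness can be computed without
reconstructing the prompt schedule.  Activities are serialized as a single
semicolon-delimited field so the table stays one-row-per-prompt despite the
variable-length multi-select.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .catalog import ActivityCatalog

N_SYMPTOM_ITEMS = 5
SYMPTOM_MIN, SYMPTOM_MAX = 1, 7

#: CSV column order for the EMA schema.
EMA_COLUMNS = (
    "participant_id",
    "group",
    "day",
    "prompt",
    "answered",
    "activities",
    "sym1",
    "sym2",
    "sym3",
    "sym4",
    "sym5",
)

_ACTIVITY_SEP = ";"


class EMAValidationError(ValueError):
    """Raised when a record violates the EMA data model."""


@dataclass(frozen=True)
class EMARecord:
    """One scheduled EMA prompt for one participant.

    Attributes
    ----------
    participant_id : str
        Stable participant identifier.
    group : str
        Diagnostic group label (e.g. ``control``, ``bipolar``,
        ``schizophrenia``).
    day : int
        1-based study day.
    prompt : int
        1-based prompt index within the day.
    answered : bool
        Whether the prompt was completed.  Unanswered prompts carry no
        activities and no symptom ratings.
    activities : frozenset of str
        Activities checked at this prompt (catalog labels).  May be empty
        only when the prompt is unanswered.
    symptom_items : tuple of int
        Five psychotic-symptom ratings, each on the 1-7 scale; empty when
        unanswered.
    """

    participant_id: str
    group: str
    day: int
    prompt: int
    answered: bool
    activities: frozenset[str] = field(default_factory=frozenset)
    symptom_items: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.day < 1:
            raise EMAValidationError(f"day must be >= 1, got {self.day}")
        if self.prompt < 1:
            raise EMAValidationError(f"prompt must be >= 1, got {self.prompt}")
        if self.answered:
            if len(self.symptom_items) != N_SYMPTOM_ITEMS:
                raise EMAValidationError(
                    f"answered record needs {N_SYMPTOM_ITEMS} symptom items, "
                    f"got {len(self.symptom_items)}"
                )
            for v in self.symptom_items:
                if not (SYMPTOM_MIN <= v <= SYMPTOM_MAX):
                    raise EMAValidationError(
                        f"symptom item {v} outside {SYMPTOM_MIN}..{SYMPTOM_MAX}"
                    )
        else:
            if self.activities:
                raise EMAValidationError(
                    "unanswered record cannot carry activities"
                )
            if self.symptom_items:
                raise EMAValidationError(
                    "unanswered record cannot carry symptom ratings"
                )

    @property
    def symptom_sum(self) -> int | None:
        """Sum of the five item ratings (5..35), or None when unanswered."""
        return sum(self.symptom_items) if self.answered else None


def _validate_against_catalog(
    records: Sequence[EMARecord], catalog: ActivityCatalog | None
) -> None:
    seen: set[tuple[str, int, int]] = set()
    for rec in records:
        key = (rec.participant_id, rec.day, rec.prompt)
        if key in seen:
            raise EMAValidationError(
                f"duplicate (participant, day, prompt) = {key}"
            )
        seen.add(key)
        if catalog is not None:
            unknown = [a for a in rec.activities if a not in catalog]
            if unknown:
                raise EMAValidationError(
                    f"activities not in catalog for {key}: {unknown}"
                )


def read_ema(
    path: str | Path | io.TextIOBase, catalog: ActivityCatalog | None = None
) -> list[EMARecord]:
    """Read a long-format EMA CSV into validated records.

    Parameters
    ----------
    path : path-like or text stream
        CSV with the documented header.
    catalog : ActivityCatalog, optional
        When given, activities outside the catalog are rejected.

    Returns
    -------
    list of EMARecord
        Every scheduled prompt, answered or not, in file order.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str})
    missing_cols = [c for c in EMA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise EMAValidationError(
            f"EMA CSV is missing required columns: {missing_cols}"
        )
    records: list[EMARecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        answered = bool(row.answered)
        try:
            if answered:
                raw = row.activities
                acts = (
                    frozenset(a for a in str(raw).split(_ACTIVITY_SEP) if a)
                    if isinstance(raw, str) and raw
                    else frozenset()
                )
                items = tuple(
                    int(getattr(row, f"sym{k}")) for k in range(1, 6)
                )
            else:
                acts = frozenset()
                items = ()
            rec = EMARecord(
                participant_id=str(row.participant_id),
                group=str(row.group),
                day=int(row.day),
                prompt=int(row.prompt),
                answered=answered,
                activities=acts,
                symptom_items=items,
            )
        except (EMAValidationError, ValueError, TypeError) as exc:
            raise EMAValidationError(f"row {i}: {exc}") from exc
        records.append(rec)
    _validate_against_catalog(records, catalog)
    return records


def write_ema(records: Iterable[EMARecord], path: str | Path) -> None:
    """Write records to CSV in the documented schema (inverse of read_ema)."""
    to_frame(records).to_csv(path, index=False)


def to_frame(records: Iterable[EMARecord]) -> pd.DataFrame:
    """Records as a DataFrame in the CSV schema (activities ';'-joined,
    sorted for determinism; symptom columns empty when unanswered)."""
    rows = []
    for rec in records:
        row: dict = {
            "participant_id": rec.participant_id,
            "group": rec.group,
            "day": rec.day,
            "prompt": rec.prompt,
            "answered": rec.answered,
            "activities": _ACTIVITY_SEP.join(sorted(rec.activities)),
        }
        for k in range(1, 6):
            row[f"sym{k}"] = (
                rec.symptom_items[k - 1] if rec.answered else pd.NA
            )
        rows.append(row)
    return pd.DataFrame(rows, columns=list(EMA_COLUMNS))
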