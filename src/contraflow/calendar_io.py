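"""Reading respondent records and expanding contraceptive calendars.

A respondent record carries two fixed-width strings — the state calendar and
the parallel reasons calendar — plus the interview date and the calendar
start date as century-month codes (CMC; months since January 1900, with
January 1900 = 1).  This module validates those records, expands each one
into a chronologically ordered sequence of person-months, and reads/writes
the person-month *event file*, the long-format table every downstream step
consumes.

Calendar direction: DHS recode extracts store the most recent month first
(the interview month sits at the left end of the non-blank region).  Some
exported extracts are already chronological, so the direction is a config
switch rather than an assumption.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

from .codes import BLANK, CodeMap

CalendarDirection = Literal["recent_first", "oldest_first"]

#: DHS stores the sampling weight as an integer scaled by one million.
DHS_WEIGHT_SCALE = 1_000_000

EVENT_FILE_COLUMNS = ["woman_id", "cmc", "month_index", "state", "reason", "weight"]

#: Default column mapping for a raw DHS individual-recode extract.
DHS_SCHEMA: dict[str, str] = {
    "woman_id": "caseid",
    "weight": "v005",
    "cmc_interview": "v008",
    "cmc_calendar_start": "v017",
    "calendar_states": "vcal_1",
    "calendar_reasons": "vcal_2",
}


class CalendarValidationError(ValueError):
    """A record or file violates a calendar invariant."""


class ConfigurationError(ValueError):
    """The schema/config does not match the input file."""


@dataclass(frozen=True)
class RespondentRecord:
    """One woman's calendar as delivered by the survey extract.

    ``weight`` is the analysis weight (already divided by 10^6 when the
    source column follows the DHS convention).
    """

    woman_id: str
    weight: float
    cmc_interview: int
    cmc_calendar_start: int
    calendar_states: str
    calendar_reasons: str

    @property
    def window_length(self) -> int:
        """Number of observed months, interview month inclusive."""
        return self.cmc_interview - self.cmc_calendar_start + 1

    def validate(self, codes: CodeMap | None = None) -> None:
        if self.weight < 0:
            raise CalendarValidationError(
                f"woman {self.woman_id}: negative weight {self.weight}"
            )
        if len(self.calendar_states) != len(self.calendar_reasons):
            raise CalendarValidationError(
                f"woman {self.woman_id}: state calendar width "
                f"{len(self.calendar_states)} != reasons calendar width "
                f"{len(self.calendar_reasons)}"
            )
        if self.cmc_calendar_start > self.cmc_interview:
            raise CalendarValidationError(
                f"woman {self.woman_id}: calendar start CMC "
                f"{self.cmc_calendar_start} after interview CMC {self.cmc_interview}"
            )
        span = self.calendar_states.strip(BLANK)
        if len(span) != self.window_length:
            raise CalendarValidationError(
                f"woman {self.woman_id}: calendar span of {len(span)} months "
                f"does not match CMC window of {self.window_length} months"
            )
        if codes is not None:
            alphabet = codes.state_alphabet
            for ch in span:
                if ch != BLANK and ch not in alphabet:
                    raise CalendarValidationError(
                        f"woman {self.woman_id}: state character {ch!r} outside "
                        "the configured alphabet"
                    )


@dataclass(frozen=True)
class PersonMonth:
    """One woman-month of the expanded calendar.

    ``reason`` is non-null only at months where the reasons calendar carries
    a code (in the survey dialect, the month a discontinued method ended).
    ``state`` may be None for unobserved (blank) months inside the window.
    """

    woman_id: str
    cmc: int
    month_index: int
    state: str | None
    reason: str | None
    weight: float = 1.0


def _observed_span(record: RespondentRecord) -> tuple[str, str]:
    """The window-aligned slices of both calendars, padding stripped.

    Uses the state calendar's blank envelope to locate the window so a
    reasons calendar that is blank at its edges stays aligned column for
    column with the states.
    """
    s = record.calendar_states
    lead = len(s) - len(s.lstrip(BLANK))
    span = s.strip(BLANK)
    return span, record.calendar_reasons[lead : lead + len(span)]


def expand_calendar(
    record: RespondentRecord,
    codes: CodeMap,
    direction: CalendarDirection = "recent_first",
) -> list[PersonMonth]:
    """Expand one record into chronological person-months.

    Returns exactly ``window_length`` months with CMC running from
    ``cmc_calendar_start`` up to ``cmc_interview``.  With the default
    ``recent_first`` direction the stored string is reversed: its first
    non-blank character is the interview month and its last the earliest
    month.

    Raises
    ------
    CalendarValidationError
        If the record violates an invariant or contains a state character
        outside the configured alphabet.
    """
    record.validate()
    states, reasons = _observed_span(record)
    if direction == "recent_first":
        states, reasons = states[::-1], reasons[::-1]
    elif direction != "oldest_first":
        raise ConfigurationError(f"unknown calendar_direction {direction!r}")

    alphabet = codes.state_alphabet
    months: list[PersonMonth] = []
    for i, (st, rs) in enumerate(zip(states, reasons)):
        cmc = record.cmc_calendar_start + i
        if st == BLANK:
            state: str | None = None
        elif st in alphabet:
            state = st
        else:
            raise CalendarValidationError(
                f"woman {record.woman_id}: state {st!r} at CMC {cmc} outside "
                "the configured alphabet"
            )
        months.append(
            PersonMonth(
                woman_id=record.woman_id,
                cmc=cmc,
                month_index=i,
                state=state,
                reason=None if rs == BLANK else rs,
                weight=record.weight,
            )
        )
    return months


def pack_calendar(
    months: Sequence[PersonMonth],
    direction: CalendarDirection = "recent_first",
    pad_to: int | None = None,
) -> tuple[str, str]:
    """Inverse of :func:`expand_calendar`: rebuild the two calendar strings.

    Padding, when requested, is appended after the interview-month end of
    the string so the non-blank region keeps the stored convention.
    """
    states = "".join(BLANK if m.state is None else m.state for m in months)
    reasons = "".join(BLANK if m.reason is None else m.reason for m in months)
    if direction == "recent_first":
        states, reasons = states[::-1], reasons[::-1]
    if pad_to is not None:
        if pad_to < len(states):
            raise ValueError(f"pad_to={pad_to} shorter than calendar ({len(states)})")
        states = states.ljust(pad_to, BLANK)
        reasons = reasons.ljust(pad_to, BLANK)
    return states, reasons


def read_respondents(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    dhs_weight: bool = True,
    delimiter: str = ",",
) -> list[RespondentRecord]:
    """Read respondent records from a delimited text file.

    Parameters
    ----------
    schema
        Maps logical field names (``woman_id``, ``weight``, ``cmc_interview``,
        ``cmc_calendar_start``, ``calendar_states``, ``calendar_reasons``) to
        column names in the file.  Defaults to the DHS recode names
        (caseid, v005, v008, v017, vcal_1, vcal_2).
    dhs_weight
        When true the weight column is an integer scaled by 10^6 (DHS
        convention) and is rescaled; otherwise it is taken as-is.

    Raises
    ------
    ConfigurationError
        If a mapped column is absent from the header.
    CalendarValidationError
        If any row violates a record invariant; the message names the
        offending row number (1-based, header excluded).
    """
    schema = dict(DHS_SCHEMA if schema is None else schema)
    missing = set(DHS_SCHEMA) - set(schema)
    if missing:
        raise ConfigurationError(f"schema missing logical fields: {sorted(missing)}")

    path = Path(path)
    records: list[RespondentRecord] = []
    errors: list[str] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        absent = [col for col in schema.values() if col not in header]
        if absent:
            raise ConfigurationError(
                f"{path.name}: mapped columns not in header: {absent}"
            )
        for rownum, row in enumerate(reader, start=1):
            raw_weight = float(row[schema["weight"]])
            record = RespondentRecord(
                woman_id=row[schema["woman_id"]],
                weight=raw_weight / DHS_WEIGHT_SCALE if dhs_weight else raw_weight,
                cmc_interview=int(row[schema["cmc_interview"]]),
                cmc_calendar_start=int(row[schema["cmc_calendar_start"]]),
                calendar_states=row[schema["calendar_states"]],
                calendar_reasons=row[schema["calendar_reasons"]],
            )
            try:
                record.validate()
            except CalendarValidationError as exc:
                errors.append(f"row {rownum}: {exc}")
                continue
            records.append(record)
    if errors:
        raise CalendarValidationError(
            f"{path.name}: {len(errors)} invalid record(s): " + "; ".join(errors)
        )
    return records


def write_respondents(
    records: Iterable[RespondentRecord],
    path: str | Path,
    dhs_weight: bool = True,
) -> None:
    """Write records in the DHS-dialect CSV accepted by :func:`read_respondents`."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["caseid", "v005", "v008", "v017", "vcal_1", "vcal_2"])
        for r in records:
            weight = round(r.weight * DHS_WEIGHT_SCALE) if dhs_weight else r.weight
            writer.writerow(
                [
                    r.woman_id,
                    weight,
                    r.cmc_interview,
                    r.cmc_calendar_start,
                    r.calendar_states,
                    r.calendar_reasons,
                ]
            )


def write_event_file(months: Sequence[PersonMonth], path: str | Path) -> None:
    """Write person-months as the long-format event file (CSV).

    The input must already be sorted by (woman_id, month_index); silent
    reordering is refused so files stay diffable against their source.
    """
    keys = [(m.woman_id, m.month_index) for m in months]
    if keys != sorted(keys):
        raise ValueError("person-months not sorted by (woman_id, month_index)")
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(EVENT_FILE_COLUMNS)
        for m in months:
            writer.writerow(
                [
                    m.woman_id,
                    m.cmc,
                    m.month_index,
                    "" if m.state is None else m.state,
                    "" if m.reason is None else m.reason,
                    repr(m.weight),
                ]
            )


def read_event_file(path: str | Path) -> list[PersonMonth]:
    """Read an event file back into person-months (lossless round trip)."""
    path = Path(path)
    months: list[PersonMonth] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(EVENT_FILE_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ConfigurationError(
                f"{path.name}: event file missing columns {sorted(missing)}"
            )
        for row in reader:
            months.append(
                PersonMonth(
                    woman_id=row["woman_id"],
                    cmc=int(row["cmc"]),
                    month_index=int(row["month_index"]),
                    state=row["state"] or None,
                    reason=row["reason"] or None,
                    weight=float(row["weight"]),
                )
            )
    return months


def group_by_woman(months: Iterable[PersonMonth]) -> dict[str, list[PersonMonth]]:
    """Split a person-month stream into per-woman chronological sequences."""
    by_woman: dict[str, list[PersonMonth]] = {}
    for m in months:
        by_woman.setdefault(m.woman_id, []).append(m)
    for woman, seq in by_woman.items():
        seq.sort(key=lambda m: m.month_index)
        for prev, cur in zip(seq, seq[1:]):
            if cur.cmc != prev.cmc + 1:
                raise CalendarValidationError(
                    f"woman {woman}: CMC not contiguous at month {cur.month_index}"
                )
    return by_woman


__all__ = [
    "CalendarDirection",
    "CalendarValidationError",
    "ConfigurationError",
    "DHS_SCHEMA",
    "EVENT_FILE_COLUMNS",
    "PersonMonth",
    "RespondentRecord",
    "expand_calendar",
    "group_by_woman",
    "pack_calendar",
    "read_event_file",
    "read_respondents",
    "write_event_file",
    "write_respondents",
]
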