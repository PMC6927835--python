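"""End-to-end convenience: records -> person-months -> pairs -> matrices.

Each step is available separately in its own module; these helpers chain
them with one code map and one set of analysis options, which is how the
CLI, the examples, and most tests drive the package.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

from .calendar_io import (
    CalendarDirection,
    PersonMonth,
    RespondentRecord,
    expand_calendar,
    group_by_woman,
)
from .codes import CodeMap
from .episodes import (
    Exclusion,
    TransitionPair,
    apply_exclusions,
    count_never_users,
    extract_pairs,
)
from .transitions import FlowMatrix, build_flow_matrix


def expand_all(
    records: Iterable[RespondentRecord],
    codes: CodeMap,
    direction: CalendarDirection = "recent_first",
) -> list[PersonMonth]:
    """Expand every record; output sorted by (woman_id, month_index)."""
    months: list[PersonMonth] = []
    for record in sorted(records, key=lambda r: r.woman_id):
        months.extend(expand_calendar(record, codes, direction))
    return months


def pairs_from_records(
    records: Iterable[RespondentRecord],
    codes: CodeMap,
    direction: CalendarDirection = "recent_first",
    horizon: int = 12,
    pregnant_as_state: bool = False,
) -> tuple[list[TransitionPair], Counter[str], list[Exclusion]]:
    """Full episode pipeline: retained pairs, exclusion tally, raw exclusions."""
    by_woman = group_by_woman(expand_all(records, codes, direction))
    raw_pairs, exclusions = extract_pairs(
        by_woman, codes, horizon=horizon, pregnant_as_state=pregnant_as_state
    )
    never = count_never_users(by_woman, codes)
    retained, tally = apply_exclusions(
        raw_pairs, codes, never_user_count=never, prior_exclusions=exclusions
    )
    return retained, tally, exclusions


def flow_matrix_from_records(
    records: Sequence[RespondentRecord],
    codes: CodeMap,
    direction: CalendarDirection = "recent_first",
    horizon: int = 12,
    pregnant_as_state: bool = False,
) -> tuple[FlowMatrix, Counter[str]]:
    """Records straight to the weighted flow matrix plus the exclusion tally."""
    retained, tally, _ = pairs_from_records(
        records, codes, direction, horizon, pregnant_as_state
    )
    matrix = build_flow_matrix(retained, codes, pregnant_as_state=pregnant_as_state)
    return matrix, tally


__all__ = ["expand_all", "flow_matrix_from_records", "pairs_from_records"]
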