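"""New-use episodes and their 12-month outcomes.

The unit of analysis is the *new-use episode*: a month in which a woman
reports a contraceptive method immediately after an observed month of
non-use.  Each episode is paired with the state observed a fixed horizon
later (12 months by default); episodes without an observed state at both
endpoints are excluded.  A paired episode becomes a transition: continue
(same method), switch (different method), or quit (no method), and for
switches and quits the discontinuation reason is read from the reasons
calendar at the month the baseline method ended.

Two analysis-population rules apply downstream of pairing: women who never
report use contribute no episodes by construction, and pairs whose
discontinuation reason is "wanted to become pregnant" are dropped so the
analysis focuses on women trying to avoid pregnancy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .calendar_io import PersonMonth
from .codes import NONUSE_LABEL, PREGNANT_LABEL, WANTED_PREGNANCY_REASON, CodeMap

Outcome = Literal["continue", "switch", "quit"]

#: Exclusion tags used in tallies.
EXCLUSION_NO_FOLLOWUP = "no 12-month observation"
EXCLUSION_WANTED_PREGNANCY = "wanted to become pregnant"
EXCLUSION_NEVER_USER = "never reported use"


@dataclass(frozen=True)
class NewUseEpisode:
    """A baseline month of method use preceded by an observed non-use month."""

    woman_id: str
    baseline_month_index: int
    baseline_cmc: int
    method: str
    weight: float


@dataclass(frozen=True)
class TransitionPair:
    """An episode's origin method joined with its state one horizon later.

    ``reason`` is the label read at the first month after baseline at which
    the woman was no longer on the origin method; it is None for continuers
    (and, in degenerate real extracts, for discontinuations whose reasons
    calendar is blank).
    """

    woman_id: str
    origin_method: str
    destination: str
    weight: float
    switch_or_quit: Outcome
    reason: str | None = None
    reason_cmc: int | None = None

    def __post_init__(self) -> None:
        if (self.switch_or_quit == "continue") != (self.origin_method == self.destination):
            raise ValueError(
                f"outcome {self.switch_or_quit!r} inconsistent with "
                f"{self.origin_method!r} -> {self.destination!r}"
            )
        if self.switch_or_quit == "continue" and self.reason is not None:
            raise ValueError("continue pair cannot carry a reason")


@dataclass(frozen=True)
class Exclusion:
    """A paired episode dropped from the analysis, with the rule that fired."""

    woman_id: str
    baseline_month_index: int
    tag: str


def find_new_use_episodes(
    months: Sequence[PersonMonth], codes: CodeMap
) -> list[NewUseEpisode]:
    """Scan one woman's chronological months for new-use baselines.

    Every index ``m >= 1`` whose state is a method code while the state at
    ``m - 1`` is the non-use code starts an episode.  Month 0 can never be a
    baseline: there is no observed prior month, so "use after one month of
    non-use" cannot be established.  A woman may contribute several episodes.
    """
    episodes: list[NewUseEpisode] = []
    for prev, cur in zip(months, months[1:]):
        if prev.state == codes.nonuse_code and cur.state is not None and codes.is_method(cur.state):
            episodes.append(
                NewUseEpisode(
                    woman_id=cur.woman_id,
                    baseline_month_index=cur.month_index,
                    baseline_cmc=cur.cmc,
                    method=codes.method_name(cur.state),
                    weight=cur.weight,
                )
            )
    return episodes


def pair_with_followup(
    episode: NewUseEpisode,
    months: Sequence[PersonMonth],
    codes: CodeMap,
    horizon: int = 12,
    pregnant_as_state: bool = False,
) -> TransitionPair | Exclusion:
    """Pair an episode with the state ``horizon`` months after baseline.

    Returns an :class:`Exclusion` tagged ``"no 12-month observation"`` when
    the follow-up month lies beyond the observed window or is blank — the
    both-endpoints rule: only episodes with reported values at baseline and
    at follow-up enter the analysis.

    Pregnancy-related states at follow-up collapse to non-use by default;
    with ``pregnant_as_state=True`` they keep a separate "pregnant"
    destination.  For switches and quits the reason is taken from the FIRST
    month after baseline at which the woman was no longer on the origin
    method (the end of this episode, not any later discontinuation).
    """
    if horizon <= 0:
        raise ValueError(f"horizon must be positive, got {horizon}")
    base = episode.baseline_month_index - months[0].month_index
    if not (0 <= base < len(months)) or months[base].month_index != episode.baseline_month_index:
        raise ValueError("episode does not belong to the given months")
    follow = base + horizon
    if follow >= len(months) or months[follow].state is None:
        return Exclusion(episode.woman_id, episode.baseline_month_index, EXCLUSION_NO_FOLLOWUP)

    dest_state = months[follow].state
    assert dest_state is not None
    if codes.is_method(dest_state):
        destination = codes.method_name(dest_state)
    elif dest_state == codes.nonuse_code:
        destination = NONUSE_LABEL
    elif dest_state in codes.pregnancy_codes:
        destination = PREGNANT_LABEL if pregnant_as_state else NONUSE_LABEL
    else:
        raise ValueError(f"unmapped state {dest_state!r} at follow-up")

    if destination == episode.method:
        return TransitionPair(
            woman_id=episode.woman_id,
            origin_method=episode.method,
            destination=destination,
            weight=episode.weight,
            switch_or_quit="continue",
        )

    outcome: Outcome = "switch" if destination not in (NONUSE_LABEL, PREGNANT_LABEL) else "quit"
    origin_code = codes.code_for_method(episode.method)
    reason: str | None = None
    reason_cmc: int | None = None
    # End of the baseline method's episode: first observed month after
    # baseline with a different state carries the reported reason, if any.
    for m in months[base + 1 :]:
        if m.state is not None and m.state != origin_code:
            if m.reason is not None:
                reason = codes.reason_label(m.reason)
                reason_cmc = m.cmc
            break
    return TransitionPair(
        woman_id=episode.woman_id,
        origin_method=episode.method,
        destination=destination,
        weight=episode.weight,
        switch_or_quit=outcome,
        reason=reason,
        reason_cmc=reason_cmc,
    )


def extract_pairs(
    by_woman: dict[str, list[PersonMonth]],
    codes: CodeMap,
    horizon: int = 12,
    pregnant_as_state: bool = False,
) -> tuple[list[TransitionPair], list[Exclusion]]:
    """Episodes + pairing over a whole dataset, in deterministic woman order."""
    pairs: list[TransitionPair] = []
    exclusions: list[Exclusion] = []
    for woman_id in sorted(by_woman):
        months = by_woman[woman_id]
        for episode in find_new_use_episodes(months, codes):
            result = pair_with_followup(
                episode, months, codes, horizon=horizon, pregnant_as_state=pregnant_as_state
            )
            (pairs if isinstance(result, TransitionPair) else exclusions).append(result)  # type: ignore[arg-type]
    return pairs, exclusions


def apply_exclusions(
    pairs: Iterable[TransitionPair],
    codes: CodeMap,
    never_user_count: int = 0,
    prior_exclusions: Iterable[Exclusion] = (),
) -> tuple[list[TransitionPair], Counter[str]]:
    """Drop wanted-pregnancy pairs; tally every exclusion rule for reporting.

    The wanted-pregnancy rule fires at the pair level: this episode's own
    discontinuation reason.  Never-users hold no episodes by construction
    and enter the tally only as a reported count.
    """
    tally: Counter[str] = Counter()
    if never_user_count:
        tally[EXCLUSION_NEVER_USER] = never_user_count
    for exc in prior_exclusions:
        tally[exc.tag] += 1
    retained: list[TransitionPair] = []
    for pair in pairs:
        if pair.reason == WANTED_PREGNANCY_REASON:
            tally[EXCLUSION_WANTED_PREGNANCY] += 1
        else:
            retained.append(pair)
    return retained, tally


PAIRS_CSV_COLUMNS = [
    "woman_id",
    "origin",
    "destination",
    "weight",
    "switch_or_quit",
    "reason",
    "reason_cmc",
]


def write_pairs_csv(pairs: Iterable[TransitionPair], path) -> None:
    """Write transition pairs as CSV (lossless against :func:`read_pairs_csv`)."""
    import csv
    from pathlib import Path

    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIRS_CSV_COLUMNS)
        for p in pairs:
            writer.writerow(
                [
                    p.woman_id,
                    p.origin_method,
                    p.destination,
                    repr(p.weight),
                    p.switch_or_quit,
                    "" if p.reason is None else p.reason,
                    "" if p.reason_cmc is None else p.reason_cmc,
                ]
            )


def read_pairs_csv(path) -> list[TransitionPair]:
    import csv
    from pathlib import Path

    pairs: list[TransitionPair] = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            pairs.append(
                TransitionPair(
                    woman_id=row["woman_id"],
                    origin_method=row["origin"],
                    destination=row["destination"],
                    weight=float(row["weight"]),
                    switch_or_quit=row["switch_or_quit"],  # type: ignore[arg-type]
                    reason=row["reason"] or None,
                    reason_cmc=int(row["reason_cmc"]) if row["reason_cmc"] else None,
                )
            )
    return pairs


def count_never_users(by_woman: dict[str, list[PersonMonth]], codes: CodeMap) -> int:
    """Women with no method month anywhere in their observed window."""
    n = 0
    for months in by_woman.values():
        if not any(m.state is not None and codes.is_method(m.state) for m in months):
            n += 1
    return n


__all__ = [
    "EXCLUSION_NEVER_USER",
    "EXCLUSION_NO_FOLLOWUP",
    "EXCLUSION_WANTED_PREGNANCY",
    "Exclusion",
    "NewUseEpisode",
    "Outcome",
    "TransitionPair",
    "apply_exclusions",
    "count_never_users",
    "extract_pairs",
    "find_new_use_episodes",
    "pair_with_followup",
    "read_pairs_csv",
    "write_pairs_csv",
]
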