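"""New-use episode detection, 12-month pairing, and exclusion rules."""

import numpy as np
import pytest

from contraflow.calendar_io import PersonMonth
from contraflow.codes import NONUSE_LABEL
from contraflow.episodes import (
    EXCLUSION_NO_FOLLOWUP,
    EXCLUSION_WANTED_PREGNANCY,
    Exclusion,
    TransitionPair,
    apply_exclusions,
    count_never_users,
    find_new_use_episodes,
    pair_with_followup,
    read_pairs_csv,
    write_pairs_csv,
)

from conftest import random_calendar


def months_from(states, woman_id="w", cmc0=1300, reasons=None):
    reasons = reasons or {}
    return [
        PersonMonth(
            woman_id=woman_id,
            cmc=cmc0 + i,
            month_index=i,
            state=None if s == " " else s,
            reason=reasons.get(i),
        )
        for i, s in enumerate(states)
    ]


class TestFindEpisodes:
    def test_use_after_nonuse_is_one_episode(self, codes):
        eps = find_new_use_episodes(months_from("0033"), codes)
        assert len(eps) == 1
        assert eps[0].baseline_month_index == 2
        assert eps[0].method == "injections"

    def test_use_at_window_start_is_not_an_episode(self, codes):
        """Month 0 has no observed prior month, so it cannot be a baseline."""
        assert find_new_use_episodes(months_from("333"), codes) == []

    def test_multiple_episodes_per_woman(self, codes):
        eps = find_new_use_episodes(months_from("0303"), codes)
        assert [e.baseline_month_index for e in eps] == [1, 3]

    def test_blank_prior_month_disqualifies(self, codes):
        assert find_new_use_episodes(months_from(" 333"), codes) == []

    def test_pregnancy_prior_month_disqualifies(self, codes):
        assert find_new_use_episodes(months_from("P333"), codes) == []

    def test_empty_input(self, codes):
        assert find_new_use_episodes([], codes) == []


class TestPairWithFollowup:
    def test_continuer(self, codes):
        months = months_from("0" + "3" * 13)
        (ep,) = find_new_use_episodes(months, codes)
        pair = pair_with_followup(ep, months, codes)
        assert isinstance(pair, TransitionPair)
        assert (pair.destination, pair.switch_or_quit, pair.reason) == (
            "injections", "continue", None
        )

    def test_followup_beyond_window_excluded(self, codes):
        months = months_from("0333")
        (ep,) = find_new_use_episodes(months, codes)
        result = pair_with_followup(ep, months, codes)
        assert isinstance(result, Exclusion)
        assert result.tag == EXCLUSION_NO_FOLLOWUP

    def test_blank_followup_excluded(self, codes):
        months = months_from("0333333333333 ")  # baseline+12 unobserved
        (ep,) = find_new_use_episodes(months, codes)
        assert isinstance(pair_with_followup(ep, months, codes), Exclusion)

    def test_quit_with_reason_at_discontinuation(self, codes):
        # use ends at month 3; reason recorded there; non-use at +12
        months = months_from("033" + "0" * 11, reasons={3: "4"})
        (ep,) = find_new_use_episodes(months, codes)
        pair = pair_with_followup(ep, months, codes)
        assert pair.switch_or_quit == "quit"
        assert pair.destination == NONUSE_LABEL
        assert pair.reason == "side effects"
        assert pair.reason_cmc == 1303

    def test_switch_reads_reason_from_first_discontinuation(self, codes):
        # injections -> pill at month 4 (reason 7), pill -> implants at
        # month 8 (reason 4): the pair's reason is the injections episode end
        states = "0333" + "1111" + "NNNNNN"
        months = months_from(states, reasons={4: "7", 8: "4"})
        (ep,) = find_new_use_episodes(months, codes)
        pair = pair_with_followup(ep, months, codes)
        assert pair.destination == "implants"
        assert pair.switch_or_quit == "switch"
        assert pair.reason == "wanted more effective method"

    def test_pregnancy_collapses_to_nonuse_by_default(self, codes):
        months = months_from("0" + "3" * 12 + "P", reasons={13: "1"})
        (ep,) = find_new_use_episodes(months, codes)
        pair = pair_with_followup(ep, months, codes)
        assert pair.destination == NONUSE_LABEL and pair.switch_or_quit == "quit"
        kept = pair_with_followup(ep, months, codes, pregnant_as_state=True)
        assert kept.destination == "pregnant"

    def test_nonpositive_horizon_rejected(self, codes):
        months = months_from("0" + "3" * 13)
        (ep,) = find_new_use_episodes(months, codes)
        with pytest.raises(ValueError, match="horizon"):
            pair_with_followup(ep, months, codes, horizon=0)

    def test_shorter_horizon(self, codes):
        months = months_from("03330000")
        (ep,) = find_new_use_episodes(months, codes)
        pair = pair_with_followup(ep, months, codes, horizon=3)
        assert pair.destination == NONUSE_LABEL


class TestApplyExclusions:
    def _quit(self, reason):
        return TransitionPair("w", "injections", NONUSE_LABEL, 1.0, "quit", reason, 1303)

    def test_wanted_pregnancy_pair_dropped_and_tallied(self, codes):
        retained, tally = apply_exclusions(
            [self._quit("wanted to become pregnant")], codes
        )
        assert retained == []
        assert tally[EXCLUSION_WANTED_PREGNANCY] == 1

    def test_continue_pair_retained_unchanged(self, codes):
        pair = TransitionPair("w", "pill", "pill", 2.0, "continue")
        retained, tally = apply_exclusions([pair], codes)
        assert retained == [pair] and sum(tally.values()) == 0

    def test_empty_input(self, codes):
        retained, tally = apply_exclusions([], codes)
        assert retained == [] and not tally

    def test_conservation(self, codes):
        pairs = [self._quit("side effects"), self._quit("wanted to become pregnant"),
                 self._quit("cost")]
        retained, tally = apply_exclusions(pairs, codes)
        assert len(retained) + tally[EXCLUSION_WANTED_PREGNANCY] == len(pairs)

    def test_never_users_enter_tally_only(self, codes):
        retained, tally = apply_exclusions([], codes, never_user_count=5)
        assert retained == [] and tally["never reported use"] == 5

    def test_count_never_users(self, codes):
        by_woman = {
            "a": months_from("0000", woman_id="a"),
            "b": months_from("0300", woman_id="b"),
        }
        assert count_never_users(by_woman, codes) == 1


class TestPairsCsv:
    def test_round_trip(self, tmp_path, codes):
        pairs = [
            TransitionPair("w1", "injections", "implants", 1.5, "switch", "side effects", 1307),
            TransitionPair("w2", "pill", "pill", 0.8, "continue"),
        ]
        path = tmp_path / "pairs.csv"
        write_pairs_csv(pairs, path)
        assert read_pairs_csv(path) == pairs


def brute_force_pairs(states, reasons, codes, horizon=12):
    """Literal nested-loop restatement of the inclusion rules, kept naive.

    For every month: a baseline is a method month whose previous month is
    the non-use code; the pair's destination is the state exactly
    ``horizon`` months later when observed; the reason is read at the first
    later observed month off the baseline method.
    """
    out = []
    n = len(states)
    for m in range(1, n):
        if states[m - 1] != codes.nonuse_code:
            continue
        if states[m] not in codes.method_codes:
            continue
        origin = codes.method_codes[states[m]]
        f = m + horizon
        if f >= n or states[f] == " ":
            out.append(("excluded", m))
            continue
        sf = states[f]
        if sf in codes.method_codes:
            dest = codes.method_codes[sf]
        else:
            dest = NONUSE_LABEL  # non-use or pregnancy both collapse
        reason = None
        for t in range(m + 1, n):
            if states[t] != " " and states[t] != states[m]:
                reason = reasons.get(t)
                break
        if dest == origin:
            out.append((origin, dest, "continue", None))
        else:
            kind = "quit" if dest == NONUSE_LABEL else "switch"
            label = codes.reason_codes[reason] if reason else None
            out.append((origin, dest, kind, label))
    return out


def test_episode_rules_match_brute_force_on_random_calendars(codes):
    """The extractor agrees with a literal scan of the rules on 500 calendars."""
    rng = np.random.default_rng(20214)
    for trial in range(500):
        length = int(rng.integers(1, 40))
        states = random_calendar(rng, codes, length)
        reasons = {
            i: str(rng.choice(list(codes.reason_codes)))
            for i in range(length)
            if rng.random() < 0.2
        }
        months = months_from(states, reasons=reasons)
        expected = brute_force_pairs(states, reasons, codes)

        got = []
        for ep in find_new_use_episodes(months, codes):
            res = pair_with_followup(ep, months, codes)
            if isinstance(res, Exclusion):
                got.append(("excluded", res.baseline_month_index))
            else:
                got.append(
                    (res.origin_method, res.destination, res.switch_or_quit, res.reason)
                )
        assert got == expected, f"trial {trial}: {states!r}"
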