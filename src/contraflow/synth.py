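"""Synthetic respondent cohorts with DHS-dialect contraceptive calendars.

Two generators:

* :func:`simulate_cohort` draws each woman's monthly state sequence from a
  first-order Markov chain over method / non-use (and optionally pregnancy)
  states, writes a discontinuation reason into the reasons calendar at every
  month the chain leaves a method, and emits records that pass all calendar
  validation.  Per-woman substreams are derived from the seed by counter, so
  a woman's calendar does not depend on iteration order.

* :func:`cohort_from_flow_table` deterministically realizes a printed
  origin-by-destination table as unit-weight calendars: one woman per
  trajectory instance, each with one non-use month, a baseline method
  month, and the tabulated destination exactly twelve months later.
  Running the full pipeline on the emitted cohort reproduces the table
  cell for cell.

The Markov model emulates the structure of retrospective calendar data —
monthly states, reasons at discontinuation, design weights — but none of
its behavioral texture (postpartum dynamics, duration dependence, recall
error).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calendar_io import RespondentRecord, pack_calendar, PersonMonth
from .codes import BLANK, NONUSE_LABEL, CodeMap
from .transitions import FlowMatrix

#: Default calendar start: CMC 1300 (April 2008); arbitrary but fixed.
DEFAULT_CMC_START = 1300


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated cohort.

    ``states`` are calendar state characters (methods, non-use, optional
    pregnancy codes); ``monthly_transition`` is row-stochastic over them in
    the same order.  ``reason_distribution`` maps each origin method
    character to a categorical over reason characters, drawn i.i.d. at each
    discontinuation.  ``weight_distribution`` is either a constant or
    ``("lognormal", sigma)`` for mean-one design-weight heterogeneity.
    """

    n_women: int
    states: tuple[str, ...]
    monthly_transition: tuple[tuple[float, ...], ...]
    initial_distribution: tuple[float, ...]
    reason_distribution: Mapping[str, Mapping[str, float]]
    window_months: int = 60
    weight_distribution: float | tuple[str, float] = 1.0
    seed: int = 0
    cmc_start: int = DEFAULT_CMC_START

    def __post_init__(self) -> None:
        P = np.asarray(self.monthly_transition, dtype=float)
        pi0 = np.asarray(self.initial_distribution, dtype=float)
        k = len(self.states)
        if P.shape != (k, k):
            raise ValueError(f"transition matrix shape {P.shape} != ({k}, {k})")
        if (P < 0).any() or (pi0 < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if not np.isclose(pi0.sum(), 1.0, atol=1e-12):
            raise ValueError("initial distribution must sum to 1")
        if self.n_women < 0 or self.window_months < 1:
            raise ValueError("n_women must be >= 0 and window_months >= 1")
        for origin, dist in self.reason_distribution.items():
            total = sum(dist.values())
            if not np.isclose(total, 1.0, atol=1e-9):
                raise ValueError(f"reason distribution for {origin!r} sums to {total}")

    @property
    def transition_array(self) -> np.ndarray:
        return np.asarray(self.monthly_transition, dtype=float)


def _woman_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substream: record i is reproducible regardless of order
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def simulate_cohort(spec: CohortSpec, codes: CodeMap) -> list[RespondentRecord]:
    """Draw a cohort of respondent records from the Markov model."""
    P = spec.transition_array
    pi0 = np.asarray(spec.initial_distribution, dtype=float)
    cum_P = P.cumsum(axis=1)
    cum_pi0 = pi0.cumsum()
    states = spec.states
    method_chars = {s for s in states if codes.is_method(s)}
    reason_choices = {
        origin: (list(dist.keys()), np.cumsum(list(dist.values())))
        for origin, dist in spec.reason_distribution.items()
    }
    cmc_interview = spec.cmc_start + spec.window_months - 1
    width = len(str(max(spec.n_women - 1, 0)))

    records: list[RespondentRecord] = []
    for i in range(spec.n_women):
        rng = _woman_rng(spec.seed, i)
        u = rng.random(spec.window_months)
        seq = np.empty(spec.window_months, dtype=np.int64)
        seq[0] = np.searchsorted(cum_pi0, u[0], side="right")
        for t in range(1, spec.window_months):
            seq[t] = np.searchsorted(cum_P[seq[t - 1]], u[t], side="right")

        chars = [states[s] for s in seq]
        reasons = [BLANK] * spec.window_months
        for t in range(1, spec.window_months):
            prev, cur = chars[t - 1], chars[t]
            if prev in method_chars and cur != prev:
                labels, cum = reason_choices.get(prev, (None, None))
                if labels is not None:
                    reasons[t] = labels[int(np.searchsorted(cum, rng.random(), side="right"))]

        if isinstance(spec.weight_distribution, tuple):
            kind, sigma = spec.weight_distribution
            if kind != "lognormal":
                raise ValueError(f"unknown weight distribution {kind!r}")
            weight = float(rng.lognormal(mean=-sigma**2 / 2, sigma=sigma))
        else:
            weight = float(spec.weight_distribution)

        months = [
            PersonMonth(
                woman_id="",
                cmc=spec.cmc_start + t,
                month_index=t,
                state=chars[t],
                reason=None if reasons[t] == BLANK else reasons[t],
            )
            for t in range(spec.window_months)
        ]
        cal_states, cal_reasons = pack_calendar(months)
        records.append(
            RespondentRecord(
                woman_id=f"sim-{i:0{width}d}",
                weight=weight,
                cmc_interview=cmc_interview,
                cmc_calendar_start=spec.cmc_start,
                calendar_states=cal_states,
                calendar_reasons=cal_reasons,
            )
        )
    return records


@dataclass(frozen=True)
class FlowTableCohortOptions:
    """Knobs for the deterministic table-realizing cohort."""

    horizon: int = 12
    change_month: int = 6  # months after baseline at which switches/quits happen
    reason_code: str = "4"  # side effects: retained by the exclusion rules
    cmc_start: int = DEFAULT_CMC_START


def cohort_from_flow_table(
    table: FlowMatrix | Mapping[tuple[str, str], int],
    codes: CodeMap,
    options: FlowTableCohortOptions | None = None,
) -> list[RespondentRecord]:
    """Realize an origin x destination count table as unit-weight calendars.

    For each cell (origin, destination) with integer value ``v``, emits
    ``v`` women whose chronological calendar is: one non-use month, the
    origin method at baseline, and a trajectory whose state exactly
    ``horizon`` months after baseline is the destination.  Continuers keep
    the origin method throughout; switchers change method, and quitters
    drop to non-use, at ``change_month`` months after baseline with the
    configured reason recorded.  Weights are 1.

    Raises on non-integer cell values.
    """
    opts = options or FlowTableCohortOptions()
    if isinstance(table, Mapping):
        items = list(table.items())
    else:
        items = [
            ((o, d), table.cell(o, d))
            for o in table.origin_labels
            if o != NONUSE_LABEL
            for d in table.destination_labels
        ]
    window = opts.horizon + 2  # non-use month + baseline + horizon
    cmc_interview = opts.cmc_start + window - 1

    records: list[RespondentRecord] = []
    for (origin, destination), value in items:
        if value == 0:
            continue
        if float(value) != int(value):
            raise ValueError(f"cell ({origin}, {destination}) is not an integer: {value}")
        origin_code = codes.code_for_method(origin)
        if destination == NONUSE_LABEL:
            dest_code = codes.nonuse_code
        else:
            dest_code = codes.code_for_method(destination)

        chars = [codes.nonuse_code] + [origin_code] * (window - 1)
        reasons = [BLANK] * window
        if dest_code != origin_code:
            for t in range(1 + opts.change_month, window):
                chars[t] = dest_code
            reasons[1 + opts.change_month] = opts.reason_code
        cal = "".join(chars)[::-1]
        cal_r = "".join(reasons)[::-1]

        slug = f"{origin[:3]}-{'none' if destination == NONUSE_LABEL else destination[:3]}"
        for k in range(int(value)):
            records.append(
                RespondentRecord(
                    woman_id=f"t-{slug}-{k:04d}",
                    weight=1.0,
                    cmc_interview=cmc_interview,
                    cmc_calendar_start=opts.cmc_start,
                    calendar_states=cal,
                    calendar_reasons=cal_r,
                )
            )
    return records


def demo_cohort_spec(
    n_women: int = 2000, seed: int = 0, window_months: int = 60
) -> CohortSpec:
    """A stock four-state monthly chain for demos and smoke runs.

    States: non-use, injections, pill, implants.  Monthly hazards are of
    the order seen in high-churn calendar data — a few percent of non-users
    start a method each month, injection and pill users discontinue at
    roughly 4-6% per month, implants are sticky.  Reasons at
    discontinuation skew toward side effects, with a minority wanting to
    become pregnant (those pairs are excluded downstream).
    """
    reasons = {"4": 0.45, "5": 0.10, "6": 0.10, "7": 0.10, "8": 0.05, "2": 0.15, "9": 0.05}
    return CohortSpec(
        n_women=n_women,
        states=("0", "3", "1", "N"),
        monthly_transition=(
            (0.930, 0.040, 0.020, 0.010),  # non-use
            (0.040, 0.950, 0.005, 0.005),  # injections
            (0.060, 0.005, 0.930, 0.005),  # pill
            (0.020, 0.000, 0.000, 0.980),  # implants
        ),
        initial_distribution=(0.80, 0.12, 0.05, 0.03),
        reason_distribution={"3": reasons, "1": reasons, "N": reasons},
        window_months=window_months,
        seed=seed,
    )


def tutorial_flow_table() -> FlowMatrix:
    """The hypothetical worked-example table of contraceptive use dynamics.

    Five methods at baseline crossed with the method (or non-use) reported
    twelve months later; 1,207 hypothetical women in total, 439 of them
    injection users at baseline.
    """
    labels = ["implants", "injections", "pill", "condom", "rhythm"]
    cells = np.array(
        [
            #  imp  inj  pill cond rhy  non-use
            [100,   0,   0,   0,   0,  24],  # implants
            [161, 100,   0,   0,   0, 178],  # injections
            [  0,   0,  36,   0,   0, 100],  # pill
            [  0,   0,   0, 202,   0, 158],  # condom
            [  0,   0,   0,   0, 148,   0],  # rhythm
        ],
        dtype=float,
    )
    return FlowMatrix(
        origin_labels=labels,
        destination_labels=labels + [NONUSE_LABEL],
        cells=cells,
    )


__all__ = [
    "CohortSpec",
    "DEFAULT_CMC_START",
    "FlowTableCohortOptions",
    "cohort_from_flow_table",
    "demo_cohort_spec",
    "simulate_cohort",
    "tutorial_flow_table",
]
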