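"""Weighted flow and reason matrices aggregated from transition pairs.

A :class:`FlowMatrix` is the origin-by-destination table of weighted
transition counts — the object a bipartite chord diagram draws.  Rows are
baseline methods in typical-use effectiveness order (plus a zero row for
non-use so both halves of the diagram share one label set); columns are the
destination states with non-use last.  A :class:`ReasonFlowMatrix` crosses
origin methods with discontinuation reasons, separately for switchers and
quitters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .codes import NONUSE_LABEL, PREGNANT_LABEL, CodeMap
from .episodes import TransitionPair

Population = Literal["switchers", "quitters"]
NeedClass = Literal["in_need", "not_in_need"]


@dataclass
class FlowMatrix:
    """Weighted origin x destination totals.

    ``cells[i, j]`` is the total weight of pairs flowing from
    ``origin_labels[i]`` to ``destination_labels[j]``.
    """

    origin_labels: list[str]
    destination_labels: list[str]
    cells: np.ndarray

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.shape != (len(self.origin_labels), len(self.destination_labels)):
            raise ValueError(
                f"cells shape {self.cells.shape} does not match labels "
                f"({len(self.origin_labels)} x {len(self.destination_labels)})"
            )
        if (self.cells < 0).any():
            raise ValueError("flow matrix cells must be non-negative")
        for labels in (self.origin_labels, self.destination_labels):
            if len(set(labels)) != len(labels):
                raise ValueError(f"duplicate labels: {labels}")

    @property
    def grand_total(self) -> float:
        return float(self.cells.sum())

    def row_marginal(self, origin: str) -> float:
        return float(self.cells[self.origin_labels.index(origin)].sum())

    def column_marginal(self, destination: str) -> float:
        return float(self.cells[:, self.destination_labels.index(destination)].sum())

    def cell(self, origin: str, destination: str) -> float:
        return float(
            self.cells[
                self.origin_labels.index(origin),
                self.destination_labels.index(destination),
            ]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells, index=self.origin_labels, columns=self.destination_labels
        )

    def to_dict(self, meta: Mapping[str, object] | None = None) -> dict:
        return {
            "origin_labels": list(self.origin_labels),
            "destination_labels": list(self.destination_labels),
            "cells": self.cells.tolist(),
            "meta": dict(meta or {}),
        }

    def to_json(self, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
        Path(path).write_text(json.dumps(self.to_dict(meta), indent=1) + "\n")

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index_label="origin")

    @classmethod
    def from_dict(cls, payload: Mapping) -> "FlowMatrix":
        return cls(
            origin_labels=list(payload["origin_labels"]),
            destination_labels=list(payload["destination_labels"]),
            cells=np.asarray(payload["cells"], dtype=float),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FlowMatrix":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class ReasonFlowMatrix(FlowMatrix):
    """Origin methods x discontinuation reasons, for one population.

    ``population`` says whether switch pairs or quit pairs were aggregated;
    ``need_map`` classifies each reason column as in-need or not.
    """

    population: Population = "quitters"
    need_map: dict[str, str] = field(default_factory=dict)

    @property
    def reason_labels(self) -> list[str]:
        return self.destination_labels

    def to_dict(self, meta: Mapping[str, object] | None = None) -> dict:
        payload = super().to_dict(meta)
        payload["population"] = self.population
        payload["need_map"] = dict(self.need_map)
        return payload


def _destination_labels(codes: CodeMap, pregnant_as_state: bool = False) -> list[str]:
    labels = list(codes.effectiveness_order)
    if pregnant_as_state:
        labels.append(PREGNANT_LABEL)
    labels.append(NONUSE_LABEL)
    return labels


def build_flow_matrix(
    pairs: Iterable[TransitionPair],
    codes: CodeMap,
    pregnant_as_state: bool = False,
    include_nonuse_origin: bool = True,
) -> FlowMatrix:
    """Aggregate pairs into the weighted origin x destination matrix.

    Labels follow the effectiveness order with non-use last; by default the
    origin side carries a zero-weight non-use row so both halves of the
    chord diagram show the same label set.  The grand total equals the total
    weight of the input pairs.
    """
    destinations = _destination_labels(codes, pregnant_as_state)
    origins = destinations if include_nonuse_origin else list(codes.effectiveness_order)
    cells = np.zeros((len(origins), len(destinations)))
    o_idx = {label: i for i, label in enumerate(origins)}
    d_idx = {label: j for j, label in enumerate(destinations)}
    for pair in pairs:
        try:
            i, j = o_idx[pair.origin_method], d_idx[pair.destination]
        except KeyError as exc:
            raise ValueError(f"pair label {exc.args[0]!r} not in the code map") from None
        cells[i, j] += pair.weight
    return FlowMatrix(origin_labels=list(origins), destination_labels=destinations, cells=cells)


def build_reason_matrix(
    pairs: Iterable[TransitionPair],
    population: Population,
    codes: CodeMap,
) -> ReasonFlowMatrix:
    """Aggregate switch (resp. quit) pairs into origin x reason totals.

    Continue pairs never contribute.  A switch/quit pair with no recorded
    reason is an upstream invariant breach and raises.
    Reason columns are ordered in-need first (dark half of the palette),
    then not-in-need, alphabetically within each class.
    """
    wanted: Population = population
    outcome = "switch" if wanted == "switchers" else "quit"
    need_map = dict(codes.need_map)
    reasons = sorted(
        need_map, key=lambda r: (0 if need_map[r] == "in_need" else 1, r)
    )
    origins = list(codes.effectiveness_order)
    cells = np.zeros((len(origins), len(reasons)))
    o_idx = {label: i for i, label in enumerate(origins)}
    r_idx = {label: j for j, label in enumerate(reasons)}
    for pair in pairs:
        if pair.switch_or_quit != outcome:
            continue
        if pair.reason is None:
            raise ValueError(
                f"{outcome} pair for woman {pair.woman_id} has no reason; "
                "upstream invariant breach"
            )
        try:
            j = r_idx[pair.reason]
        except KeyError:
            raise ValueError(f"reason {pair.reason!r} not in the need map") from None
        cells[o_idx[pair.origin_method], j] += pair.weight
    return ReasonFlowMatrix(
        origin_labels=origins,
        destination_labels=reasons,
        cells=cells,
        population=wanted,
        need_map=need_map,
    )


def classify_reason_need(
    reason_label: str, need_map: Mapping[str, str]
) -> NeedClass:
    """Classify a discontinuation reason as "in need" of contraception or not."""
    try:
        klass = need_map[reason_label]
    except KeyError:
        raise KeyError(f"reason {reason_label!r} missing from the need map") from None
    if klass not in ("in_need", "not_in_need"):
        raise ValueError(f"need map value {klass!r} for {reason_label!r} invalid")
    return klass  # type: ignore[return-value]


def collapse_methods(
    matrix: FlowMatrix,
    grouping: Mapping[str, str] | Callable[[str], str],
) -> FlowMatrix:
    """Collapse method labels into coarser groups (e.g. short-/long-acting).

    Grouped cells are sums of member cells and the grand total is preserved.
    Non-use maps to itself when the grouping omits it; any other ungrouped
    label raises.  Group order follows first appearance along each axis.
    """
    lookup: Callable[[str], str]
    if callable(grouping):
        lookup = grouping
    else:
        mapping = dict(grouping)
        mapping.setdefault(NONUSE_LABEL, NONUSE_LABEL)

        def lookup(label: str) -> str:
            try:
                return mapping[label]
            except KeyError:
                raise KeyError(f"label {label!r} has no group") from None

    def collapse_axis(labels: Sequence[str]) -> tuple[list[str], list[int]]:
        groups: list[str] = []
        index: list[int] = []
        for label in labels:
            g = lookup(label)
            if g not in groups:
                groups.append(g)
            index.append(groups.index(g))
        return groups, index

    o_groups, o_map = collapse_axis(matrix.origin_labels)
    d_groups, d_map = collapse_axis(matrix.destination_labels)
    cells = np.zeros((len(o_groups), len(d_groups)))
    np.add.at(cells, (np.array(o_map)[:, None], np.array(d_map)[None, :]), matrix.cells)
    return FlowMatrix(origin_labels=o_groups, destination_labels=d_groups, cells=cells)


def outcome_partition(pairs: Iterable[TransitionPair]) -> dict[str, float]:
    """Weighted totals by outcome; the three parts sum to the retained total."""
    totals = {"continue": 0.0, "switch": 0.0, "quit": 0.0}
    for pair in pairs:
        totals[pair.switch_or_quit] += pair.weight
    return totals


__all__ = [
    "FlowMatrix",
    "NeedClass",
    "Population",
    "ReasonFlowMatrix",
    "build_flow_matrix",
    "build_reason_matrix",
    "classify_reason_need",
    "collapse_methods",
    "outcome_partition",
]
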