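"""Run configuration: one YAML file driving the whole pipeline.

The file is validated eagerly — before any work — with explicit checks that
name the offending key, so a typo'd code map or an impossible gap fails the
run immediately.  Every field has a default, so an empty config is valid
and reproduces the stock DHS-dialect behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .chord_layout import DEFAULT_GAP
from .codes import (
    DEFAULT_EFFECTIVENESS_ORDER,
    DEFAULT_METHOD_CODES,
    DEFAULT_NEED_MAP,
    DEFAULT_REASON_CODES,
    CodeMap,
)

_KNOWN_KEYS = {
    "method_codes",
    "nonuse_code",
    "pregnancy_codes",
    "reason_codes",
    "effectiveness_order",
    "need_map",
    "calendar_direction",
    "dhs_weight",
    "horizon",
    "pregnant_as_state",
    "gap",
    "palette",
    "seed",
    "schema",
}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Validated settings shared by all CLI commands and pipeline helpers."""

    codes: CodeMap = field(default_factory=CodeMap)
    calendar_direction: str = "recent_first"
    dhs_weight: bool = True
    horizon: int = 12
    pregnant_as_state: bool = False
    gap: float = DEFAULT_GAP
    palette_overrides: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    schema: Mapping[str, str] | None = None


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


def build_config(raw: Mapping[str, Any] | None) -> RunConfig:
    """Validate a parsed mapping into a :class:`RunConfig`."""
    raw = dict(raw or {})
    unknown = set(raw) - _KNOWN_KEYS
    _require(not unknown, f"unknown config keys: {sorted(unknown)}")

    method_codes = dict(raw.get("method_codes", DEFAULT_METHOD_CODES))
    for code in method_codes:
        _require(
            isinstance(code, str) and len(code) == 1,
            f"method code {code!r} must be a single character",
        )
    reason_codes = {str(k): v for k, v in raw.get("reason_codes", DEFAULT_REASON_CODES).items()}
    effectiveness = list(raw.get("effectiveness_order", []))
    if not effectiveness:
        effectiveness = [
            m for m in DEFAULT_EFFECTIVENESS_ORDER if m in method_codes.values()
        ]
    need_map = dict(raw.get("need_map", DEFAULT_NEED_MAP))
    for reason, klass in need_map.items():
        _require(
            klass in ("in_need", "not_in_need"),
            f"need_map[{reason!r}] must be 'in_need' or 'not_in_need', got {klass!r}",
        )

    try:
        codes = CodeMap(
            method_codes=method_codes,
            nonuse_code=str(raw.get("nonuse_code", "0")),
            pregnancy_codes=frozenset(raw.get("pregnancy_codes", ("P", "B", "T"))),
            reason_codes=reason_codes,
            effectiveness_order=tuple(effectiveness),
            need_map=need_map,
        )
    except ValueError as exc:
        raise ConfigError(f"invalid code map: {exc}") from None

    direction = raw.get("calendar_direction", "recent_first")
    _require(
        direction in ("recent_first", "oldest_first"),
        f"calendar_direction must be recent_first or oldest_first, got {direction!r}",
    )
    horizon = int(raw.get("horizon", 12))
    _require(horizon > 0, f"horizon must be positive, got {horizon}")
    gap = float(raw.get("gap", DEFAULT_GAP))
    _require(0 <= gap < 0.5, f"gap must be in [0, 0.5) radians, got {gap}")
    seed = int(raw.get("seed", 0))
    _require(0 <= seed < 2**31, f"seed must be in [0, 2^31), got {seed}")

    schema = raw.get("schema")
    if schema is not None:
        schema = {str(k): str(v) for k, v in schema.items()}

    return RunConfig(
        codes=codes,
        calendar_direction=direction,
        dhs_weight=bool(raw.get("dhs_weight", True)),
        horizon=horizon,
        pregnant_as_state=bool(raw.get("pregnant_as_state", False)),
        gap=gap,
        palette_overrides=dict(raw.get("palette", {})),
        seed=seed,
        schema=schema,
    )


def load_config(path: str | Path | None) -> RunConfig:
    """Read and validate a YAML config file; None means all defaults."""
    if path is None:
        return build_config(None)
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    _require(isinstance(raw, dict), "config file must contain a YAML mapping")
    return build_config(raw)


__all__ = ["ConfigError", "RunConfig", "build_config", "load_config"]
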