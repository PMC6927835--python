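"""Method, reason, and state vocabularies for DHS-dialect contraceptive calendars.

The contraceptive calendar stores one character per month.  A :class:`CodeMap`
says what each character means: which characters are contraceptive methods,
which one is non-use, which are pregnancy-related (pregnancy, birth,
termination), and what the reason-for-discontinuation characters stand for.
It also carries the typical-use effectiveness ranking that drives arc order
and shading in the chord diagrams, and the classification of discontinuation
reasons into "in need" versus not "in need".

Defaults follow the DHS recode dialect; every piece is overridable through
the run configuration because code dialects drift across survey phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

NONUSE_LABEL = "non-use"
PREGNANT_LABEL = "pregnant"

#: Character used for months outside or unobserved within the calendar window.
BLANK = " "

DEFAULT_METHOD_CODES: dict[str, str] = {
    "1": "pill",
    "2": "IUD",
    "3": "injections",
    "4": "diaphragm",
    "5": "condom",
    "6": "female sterilization",
    "7": "male sterilization",
    "8": "rhythm",
    "9": "withdrawal",
    "N": "implants",
    "W": "other traditional",
    "M": "other modern",
    "L": "LAM",
    "C": "female condom",
    "E": "emergency contraception",
    "S": "standard days",
}

DEFAULT_REASON_CODES: dict[str, str] = {
    "1": "method failure",
    "2": "wanted to become pregnant",
    "3": "husband disapproved",
    "4": "side effects",
    "5": "health concerns",
    "6": "access/availability",
    "7": "wanted more effective method",
    "8": "inconvenient to use",
    "9": "infrequent sex",
    "W": "cost",
    "F": "fatalistic",
    "A": "difficult to get pregnant/menopausal",
    "D": "marital dissolution",
    "O": "other",
    "?": "don't know",
}

#: Typical-use effectiveness ranking, most effective first.  Non-use is not a
#: method and is always appended last when matrices and layouts are built.
DEFAULT_EFFECTIVENESS_ORDER: list[str] = [
    "implants",
    "female sterilization",
    "male sterilization",
    "IUD",
    "injections",
    "LAM",
    "pill",
    "condom",
    "female condom",
    "diaphragm",
    "emergency contraception",
    "other modern",
    "standard days",
    "rhythm",
    "withdrawal",
    "other traditional",
]

#: Repository convention: which discontinuation reasons signal that the woman
#: is still "in need" of contraception.  The source surveys publish no such
#: mapping, so this default is explicit and overridable.
DEFAULT_NEED_MAP: dict[str, str] = {
    "method failure": "in_need",
    "husband disapproved": "in_need",
    "side effects": "in_need",
    "health concerns": "in_need",
    "access/availability": "in_need",
    "wanted more effective method": "in_need",
    "inconvenient to use": "in_need",
    "cost": "in_need",
    "wanted to become pregnant": "not_in_need",
    "infrequent sex": "not_in_need",
    "difficult to get pregnant/menopausal": "not_in_need",
    "marital dissolution": "not_in_need",
    "fatalistic": "not_in_need",
    "other": "not_in_need",
    "don't know": "not_in_need",
}

#: Reason label whose pairs are excluded so the analysis focuses on women who
#: quit or switched while wanting to avoid pregnancy.
WANTED_PREGNANCY_REASON = "wanted to become pregnant"


@dataclass(frozen=True)
class CodeMap:
    """Vocabulary of calendar state and reason characters.

    Parameters
    ----------
    method_codes
        Mapping from a single state character to a method name.
    nonuse_code
        The state character meaning "using no method".
    pregnancy_codes
        State characters for pregnancy, birth, and termination months.
    reason_codes
        Mapping from a single reason character to a reason label.
    effectiveness_order
        Method names ordered most effective (typical use) first.  Every
        method in this list must be a value of ``method_codes``.
    need_map
        Reason label -> ``"in_need"`` or ``"not_in_need"``.
    """

    method_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_METHOD_CODES)
    )
    nonuse_code: str = "0"
    pregnancy_codes: frozenset[str] = frozenset({"P", "B", "T"})
    reason_codes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_REASON_CODES)
    )
    effectiveness_order: tuple[str, ...] = tuple(DEFAULT_EFFECTIVENESS_ORDER)
    need_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_NEED_MAP))

    def __post_init__(self) -> None:
        methods = set(self.method_codes)
        if self.nonuse_code in methods:
            raise ValueError("nonuse_code collides with a method code")
        overlap = methods & set(self.pregnancy_codes)
        if overlap:
            raise ValueError(f"method and pregnancy codes overlap: {sorted(overlap)}")
        if self.nonuse_code in self.pregnancy_codes:
            raise ValueError("nonuse_code collides with a pregnancy code")
        names = list(self.method_codes.values())
        for m in self.effectiveness_order:
            if names.count(m) != 1:
                raise ValueError(
                    f"effectiveness_order entry {m!r} must appear exactly once "
                    "among method names"
                )
        if len(set(self.effectiveness_order)) != len(self.effectiveness_order):
            raise ValueError("effectiveness_order contains duplicates")
        # tuple-ify mutable inputs defensively
        object.__setattr__(self, "effectiveness_order", tuple(self.effectiveness_order))
        object.__setattr__(self, "pregnancy_codes", frozenset(self.pregnancy_codes))

    @property
    def state_alphabet(self) -> frozenset[str]:
        """All legal state characters (methods, non-use, pregnancy)."""
        return (
            frozenset(self.method_codes)
            | {self.nonuse_code}
            | self.pregnancy_codes
        )

    def is_method(self, state: str) -> bool:
        return state in self.method_codes

    def method_name(self, state: str) -> str:
        return self.method_codes[state]

    def code_for_method(self, name: str) -> str:
        for code, method in self.method_codes.items():
            if method == name:
                return code
        raise KeyError(f"no code for method {name!r}")

    def reason_label(self, code: str) -> str:
        try:
            return self.reason_codes[code]
        except KeyError:
            raise KeyError(f"unknown reason code {code!r}") from None

    def effectiveness_rank(self, label: str) -> int:
        """Rank of a label: 0 = most effective; non-use ranks below all methods."""
        if label == NONUSE_LABEL:
            return len(self.effectiveness_order)
        try:
            return self.effectiveness_order.index(label)
        except ValueError:
            raise KeyError(f"label {label!r} has no effectiveness rank") from None


def tutorial_codemap() -> CodeMap:
    """CodeMap restricted to the five methods of the hypothetical worked example.

    The demonstration cohort uses implants, injections, pill, condom, and
    rhythm — already in typical-use effectiveness order — plus non-use.
    """
    keep = {"implants", "injections", "pill", "condom", "rhythm"}
    return CodeMap(
        method_codes={c: m for c, m in DEFAULT_METHOD_CODES.items() if m in keep},
        effectiveness_order=("implants", "injections", "pill", "condom", "rhythm"),
    )
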