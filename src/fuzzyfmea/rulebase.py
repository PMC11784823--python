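"""The 125-rule IF-THEN base relating (occurrence, severity, detection) to fRPN.

Each rule reads "IF o is O_i AND s is S_i AND d is D_i THEN RPN is R_i",
with five linguistic levels per input and ten output levels.  Rules are
indexed lexicographically with occurrence slowest-varying:
``index = (o-1)*25 + (s-1)*5 + d``, so rule 16 is (remote, high, certain)
and rule 50 is (low, very high, very low).

The shipped default base is a monotone reconstruction: the consequent level
is the rounded linear rescale of ``o + s + d`` from [3, 15] onto [1, 10],
with a single pinned override so that rule 50's consequent is "High"
(level 9).  Under this mapping rule 16's consequent is "Low" (level 3).
Any complete 125-rule base can be supplied instead via CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Union

import numpy as np

from .membership import (
    DETECTION_LABELS,
    OCCURRENCE_LABELS,
    RPN_LABELS,
    SEVERITY_LABELS,
)

__all__ = [
    "FuzzyRule",
    "RuleBase",
    "RuleBaseError",
    "ValidationReport",
    "rule_index",
    "levels_from_index",
    "default_rulebase",
    "validate_rulebase",
    "save_rulebase",
    "load_rulebase",
]

N_INPUT_LEVELS = 5
N_OUTPUT_LEVELS = 10
N_RULES = N_INPUT_LEVELS**3

# level-1 occurrence/severity is called both "remote" and "almost none"
_INPUT_SYNONYMS = {"remote": "almost none"}


class RuleBaseError(ValueError):
    """Raised for malformed rules, indices, or rule-base files."""


def _check_level(value: int, n: int, what: str) -> int:
    if not (isinstance(value, (int, np.integer)) and 1 <= value <= n):
        raise RuleBaseError(f"{what} level must be an integer in 1..{n}, got {value!r}")
    return int(value)


@dataclass(frozen=True)
class FuzzyRule:
    """One IF-THEN rule: antecedent levels (1-5 each) and consequent level (1-10)."""

    o_level: int
    s_level: int
    d_level: int
    rpn_level: int

    def __post_init__(self) -> None:
        _check_level(self.o_level, N_INPUT_LEVELS, "occurrence")
        _check_level(self.s_level, N_INPUT_LEVELS, "severity")
        _check_level(self.d_level, N_INPUT_LEVELS, "detection")
        _check_level(self.rpn_level, N_OUTPUT_LEVELS, "rpn")

    @property
    def antecedent(self) -> tuple[int, int, int]:
        return (self.o_level, self.s_level, self.d_level)

    @property
    def index(self) -> int:
        return rule_index(self.o_level, self.s_level, self.d_level)

    def labels(self) -> tuple[str, str, str, str]:
        return (
            OCCURRENCE_LABELS[self.o_level - 1],
            SEVERITY_LABELS[self.s_level - 1],
            DETECTION_LABELS[self.d_level - 1],
            RPN_LABELS[self.rpn_level - 1],
        )


def rule_index(o_level: int, s_level: int, d_level: int) -> int:
    """Lexicographic 1-based rule index, occurrence slowest-varying."""
    o = _check_level(o_level, N_INPUT_LEVELS, "occurrence")
    s = _check_level(s_level, N_INPUT_LEVELS, "severity")
    d = _check_level(d_level, N_INPUT_LEVELS, "detection")
    return (o - 1) * 25 + (s - 1) * 5 + d


def levels_from_index(index: int) -> tuple[int, int, int]:
    """Inverse of :func:`rule_index`."""
    if not 1 <= index <= N_RULES:
        raise RuleBaseError(f"rule index must be in 1..{N_RULES}, got {index}")
    i = index - 1
    return (i // 25 + 1, (i % 25) // 5 + 1, i % 5 + 1)


@dataclass(frozen=True)
class RuleBase:
    """Ordered, complete collection of the 125 rules."""

    rules: tuple[FuzzyRule, ...]

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def rule_at(self, index: int) -> FuzzyRule:
        """Rule with the given 1-based lexicographic index."""
        if not 1 <= index <= len(self.rules):
            raise RuleBaseError(f"rule index must be in 1..{len(self.rules)}")
        return self.rules[index - 1]

    def rule_for(self, o_level: int, s_level: int, d_level: int) -> FuzzyRule:
        return self.rule_at(rule_index(o_level, s_level, d_level))

    def consequent_array(self) -> np.ndarray:
        """Consequent levels as a (5, 5, 5) int array indexed [o-1, s-1, d-1]."""
        arr = np.zeros((N_INPUT_LEVELS,) * 3, dtype=int)
        for rule in self.rules:
            arr[rule.o_level - 1, rule.s_level - 1, rule.d_level - 1] = rule.rpn_level
        return arr


def _rescaled_level(o: int, s: int, d: int) -> int:
    # o+s+d in [3, 15] mapped linearly onto [1, 10], rounded half-up
    raw = 1.0 + (o + s + d - 3) * 0.75
    return int(Decimal(repr(raw)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


# pinned so that rule 50 (low, very high, very low) concludes "High" (9)
_CONSEQUENT_OVERRIDES = {(2, 5, 5): 9}


def default_rulebase() -> RuleBase:
    """The shipped monotone 125-rule base (see module docstring)."""
    rules = []
    for o in range(1, N_INPUT_LEVELS + 1):
        for s in range(1, N_INPUT_LEVELS + 1):
            for d in range(1, N_INPUT_LEVELS + 1):
                level = _CONSEQUENT_OVERRIDES.get((o, s, d), _rescaled_level(o, s, d))
                rules.append(FuzzyRule(o, s, d, level))
    return RuleBase(tuple(rules))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_rulebase`.

    ``complete`` and ``ordered`` are hard requirements for inference;
    monotonicity violations are informational (a hand-elicited base may
    legitimately be non-monotone).
    """

    n_rules: int
    missing: list[tuple[int, int, int]] = field(default_factory=list)
    duplicates: list[tuple[int, int, int]] = field(default_factory=list)
    order_violations: list[int] = field(default_factory=list)
    monotonicity_violations: list[str] = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not self.missing and not self.duplicates and self.n_rules == N_RULES

    @property
    def ordered(self) -> bool:
        return not self.order_violations

    @property
    def ok(self) -> bool:
        return self.complete and self.ordered

    def summary(self) -> str:
        lines = [f"{self.n_rules} rules; complete={self.complete}; ordered={self.ordered}"]
        for combo in self.missing:
            lines.append(f"missing combination (o,s,d)={combo}")
        for combo in self.duplicates:
            lines.append(f"duplicate combination (o,s,d)={combo}")
        for idx in self.order_violations:
            lines.append(f"rule at position {idx} out of lexicographic order")
        for msg in self.monotonicity_violations:
            lines.append(f"monotonicity: {msg}")
        return "\n".join(lines)


def validate_rulebase(rb: RuleBase) -> ValidationReport:
    """Check completeness, index order, and (informationally) monotonicity."""
    report = ValidationReport(n_rules=rb.n_rules)
    seen: dict[tuple[int, int, int], int] = {}
    for pos, rule in enumerate(rb.rules, start=1):
        combo = rule.antecedent
        if combo in seen:
            report.duplicates.append(combo)
        seen[combo] = pos
        if rule.index != pos:
            report.order_violations.append(pos)
    for o in range(1, N_INPUT_LEVELS + 1):
        for s in range(1, N_INPUT_LEVELS + 1):
            for d in range(1, N_INPUT_LEVELS + 1):
                if (o, s, d) not in seen:
                    report.missing.append((o, s, d))
    if report.complete:
        arr = rb.consequent_array()
        for axis, name in enumerate(("occurrence", "severity", "detection")):
            if np.any(np.diff(arr, axis=axis) < 0):
                report.monotonicity_violations.append(
                    f"consequent decreases along the {name} axis"
                )
    return report


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_LEVEL_COLUMNS = ("o_level", "s_level", "d_level", "rpn_level")


def _label_maps() -> dict[str, dict[str, int]]:
    def lut(labels: Iterable[str]) -> dict[str, int]:
        return {label: i + 1 for i, label in enumerate(labels)}

    maps = {
        "o_level": lut(OCCURRENCE_LABELS),
        "s_level": lut(SEVERITY_LABELS),
        "d_level": lut(DETECTION_LABELS),
        "rpn_level": lut(RPN_LABELS),
    }
    for syn, canonical in _INPUT_SYNONYMS.items():
        maps["o_level"][syn] = maps["o_level"][canonical]
        maps["s_level"][syn] = maps["s_level"][canonical]
    return maps


def _parse_cell(raw: str, column: str, maps: dict[str, dict[str, int]], line: int) -> int:
    text = raw.strip().lower()
    if text in maps[column]:
        return maps[column][text]
    try:
        return int(text)
    except ValueError:
        raise RuleBaseError(
            f"line {line}: cannot parse {column}={raw!r} as a level or known label"
        ) from None


def save_rulebase(rb: RuleBase, path: Union[str, Path]) -> None:
    """Write the base as CSV with columns o_level,s_level,d_level,rpn_level."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LEVEL_COLUMNS)
        for rule in rb.rules:
            writer.writerow([rule.o_level, rule.s_level, rule.d_level, rule.rpn_level])


def load_rulebase(path: Union[str, Path]) -> RuleBase:
    """Read a rule-base CSV (numeric levels or canonical labels) and validate it.

    Rules may appear in any row order; they are stored in lexicographic
    index order.  Incomplete or duplicated bases raise with the offending
    (o, s, d) triples named.
    """
    maps = _label_maps()
    parsed: dict[tuple[int, int, int], FuzzyRule] = {}
    duplicated: list[tuple[int, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_LEVEL_COLUMNS) - set(reader.fieldnames):
            raise RuleBaseError(
                f"{path}: header must contain columns {', '.join(_LEVEL_COLUMNS)}"
            )
        for line, row in enumerate(reader, start=2):
            levels = {
                col: _parse_cell(row[col], col, maps, line) for col in _LEVEL_COLUMNS
            }
            rule = FuzzyRule(**levels)
            if rule.antecedent in parsed:
                duplicated.append(rule.antecedent)
            parsed[rule.antecedent] = rule
    if duplicated:
        raise RuleBaseError(
            f"{path}: duplicate combination(s) (o,s,d)={sorted(set(duplicated))}"
        )
    ordered = tuple(
        parsed[levels_from_index(i)]
        for i in range(1, N_RULES + 1)
        if levels_from_index(i) in parsed
    )
    rb = RuleBase(ordered)
    report = validate_rulebase(rb)
    if not report.ok:
        raise RuleBaseError(f"{path}: invalid rule base\n{report.summary()}")
    return rb
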