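"""FMEA worksheet and rating-panel model, traditional RPN, and rankings.

The traditional risk priority number is RPN = O x S x D on 1-10 integer
scales, computed here on the unweighted arithmetic mean of a multi-expert
panel.  Values are reported rounded half-up to two decimals and ranked
densely (descending; ties share a rank, the next distinct value takes the
next integer).  Ranking operates on the rounded values — that is how
expert panels with slightly different raw products end up sharing a
printed rank.

``rpn_value_distribution`` quantifies the well-known lattice pathology of
the product score: on a 1-10 scale only 120 of the 1000 ordered (o, s, d)
triples yield distinct products, so unrelated failure modes collide on the
same RPN.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

__all__ = [
    "SUBSYSTEMS",
    "FailureMode",
    "PanelError",
    "RatingPanel",
    "round_half_up",
    "aggregate_ratings",
    "traditional_rpn",
    "rank_scores",
    "TieGroup",
    "RankComparison",
    "compare_rankings",
    "rpn_value_distribution",
    "build_risk_table",
    "load_worksheet",
    "save_worksheet",
    "save_risk_table",
    "load_risk_table",
]

SUBSYSTEMS = ("pretreatment", "production", "storage/distribution", "auxiliary")

WORKSHEET_COLUMNS = ("code", "hazard", "subsystem", "failure_mode", "effect", "cause")
RATING_COLUMNS = ("expert", "code", "O", "S", "D")
RISK_TABLE_COLUMNS = (
    "code",
    "mean_O",
    "mean_S",
    "mean_D",
    "rpn",
    "rank_rpn",
    "frpn",
    "rank_frpn",
)


class PanelError(ValueError):
    """Raised for malformed or incomplete rating panels."""


@dataclass(frozen=True)
class FailureMode:
    """One worksheet row: a hazard component and its failure mode."""

    code: str
    hazard: str
    subsystem: str
    failure_mode: str
    effect: str
    cause: str

    def __post_init__(self) -> None:
        if self.subsystem not in SUBSYSTEMS:
            raise ValueError(
                f"{self.code}: subsystem {self.subsystem!r} not one of {SUBSYSTEMS}"
            )


class RatingPanel:
    """Per-expert integer O/S/D scores for each failure mode.

    Wraps a long-form frame with columns (expert, code, O, S, D).  Scores
    must be integers in [1, 10]; every (expert, code) pair must carry all
    three scores; missing scores are an error, never imputed.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        missing_cols = set(RATING_COLUMNS) - set(frame.columns)
        if missing_cols:
            raise PanelError(f"ratings frame lacks columns {sorted(missing_cols)}")
        frame = frame[list(RATING_COLUMNS)]
        if frame[["O", "S", "D"]].isna().any().any():
            bad = frame[frame[["O", "S", "D"]].isna().any(axis=1)]
            where = ", ".join(
                f"(expert {r.expert}, {r.code})" for r in bad.itertuples()
            )
            raise PanelError(f"missing score(s) for {where}")
        scores = frame[["O", "S", "D"]].to_numpy()
        if not np.array_equal(scores, scores.astype(int)):
            raise PanelError("scores must be integers")
        scores = scores.astype(int)
        if scores.min() < 1 or scores.max() > 10:
            raise PanelError("scores must lie in [1, 10]")
        frame[["O", "S", "D"]] = scores
        if len(frame) == 0:
            raise PanelError("panel is empty")
        dup = frame.duplicated(subset=["expert", "code"])
        if dup.any():
            pair = frame.loc[dup.idxmax(), ["expert", "code"]].tolist()
            raise PanelError(f"duplicate rating for (expert {pair[0]}, {pair[1]})")
        # completeness: every expert rated every code
        pivot = frame.pivot(index="code", columns="expert", values="O")
        if pivot.isna().any().any():
            gaps = [
                f"(expert {e}, {c})"
                for c, row in pivot.iterrows()
                for e, v in row.items()
                if pd.isna(v)
            ]
            raise PanelError(f"missing rating(s) for {', '.join(gaps)}")
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    @property
    def codes(self) -> list[str]:
        return list(dict.fromkeys(self._frame["code"]))

    @property
    def experts(self) -> list:
        return sorted(self._frame["expert"].unique().tolist())

    @property
    def n_experts(self) -> int:
        return self._frame["expert"].nunique()

    def scores_for(self, code: str) -> pd.DataFrame:
        sub = self._frame[self._frame["code"] == code]
        if sub.empty:
            raise KeyError(f"no ratings for code {code!r}")
        return sub.set_index("expert")[["O", "S", "D"]]

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "RatingPanel":
        return cls(pd.read_csv(path))

    def to_csv(self, path: Union[str, Path]) -> None:
        self._frame.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatingPanel):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __len__(self) -> int:
        return len(self._frame)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01), the convention used in reports."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def aggregate_ratings(panel: RatingPanel) -> pd.DataFrame:
    """Unweighted per-code arithmetic mean of expert scores (unrounded).

    Returns a frame indexed by code with columns mean_O, mean_S, mean_D,
    preserving the panel's code order.
    """
    means = (
        panel.frame.groupby("code", sort=False)[["O", "S", "D"]]
        .mean()
        .rename(columns={"O": "mean_O", "S": "mean_S", "D": "mean_D"})
    )
    return means.loc[panel.codes]


def traditional_rpn(mean_o: float, mean_s: float, mean_d: float) -> float:
    """Traditional risk priority number: the product O x S x D (unrounded)."""
    for name, value in (("O", mean_o), ("S", mean_s), ("D", mean_d)):
        if not 1.0 <= value <= 10.0:
            raise ValueError(f"mean {name}={value} outside [1, 10]")
    return float(mean_o) * float(mean_s) * float(mean_d)


def rank_scores(values: pd.Series, precision: int = 2) -> pd.Series:
    """Dense descending ranks on values rounded to reporting precision.

    Highest value gets rank 1; equal rounded values share a rank; the next
    distinct value gets the previous rank + 1.
    """
    rounded = values.map(lambda v: round_half_up(v, precision))
    return rounded.rank(method="dense", ascending=False).astype(int)


@dataclass(frozen=True)
class TieGroup:
    """Codes tied under one score, with their values under the other score."""

    codes: tuple[str, ...]
    tied_value: float
    other_values: tuple[float, ...]

    @property
    def separated(self) -> bool:
        """True when the other score distinguishes all codes in the group."""
        return len(set(self.other_values)) == len(self.other_values)


@dataclass(frozen=True)
class RankComparison:
    rpn_ties: tuple[TieGroup, ...]
    frpn_ties: tuple[TieGroup, ...]


def _tie_groups(
    table: pd.DataFrame, on: str, other: str, precision: int
) -> tuple[TieGroup, ...]:
    rounded = table[on].map(lambda v: round_half_up(v, precision))
    other_rounded = table[other].map(lambda v: round_half_up(v, precision))
    groups = []
    for value, sub in table.groupby(rounded, sort=False):
        if len(sub) > 1:
            groups.append(
                TieGroup(
                    codes=tuple(sub["code"]),
                    tied_value=float(value),
                    other_values=tuple(other_rounded[sub.index]),
                )
            )
    return tuple(sorted(groups, key=lambda g: -g.tied_value))


def compare_rankings(table: pd.DataFrame, precision: int = 2) -> RankComparison:
    """Find code sets tied under rounded RPN but possibly separated by fRPN,
    and vice versa.

    ``table`` is a risk-score frame with at least columns code, rpn, frpn.
    """
    return RankComparison(
        rpn_ties=_tie_groups(table, "rpn", "frpn", precision),
        frpn_ties=_tie_groups(table, "frpn", "rpn", precision),
    )


def rpn_value_distribution(scale_max: int = 10) -> dict[int, int]:
    """Count ordered (o, s, d) integer triples per product value.

    Exhaustive enumeration of the scale_max**3 lattice; counts sum to
    scale_max**3.  On the standard 1-10 scale the product 120 arises from
    24 distinct ordered triples while 1 and 1000 are unique — the
    clustering that motivates the fuzzy RPN.
    """
    if not (isinstance(scale_max, int) and scale_max >= 1):
        raise ValueError(f"scale_max must be a positive integer, got {scale_max!r}")
    counts = Counter(
        o * s * d
        for o, s, d in itertools.product(range(1, scale_max + 1), repeat=3)
    )
    return dict(counts)


def build_risk_table(
    panel: RatingPanel,
    fis=None,
    precision: int = 2,
) -> pd.DataFrame:
    """Full per-code risk-score table: means, RPN, fRPN, and dense ranks.

    ``fis`` is a :class:`~fuzzyfmea.engine.FuzzySystem`; when None the
    default system is used.  RPN and fRPN are rounded half-up to
    ``precision`` decimals and ranked after rounding.
    """
    if fis is None:
        from .engine import FuzzySystem

        fis = FuzzySystem.default()
    means = aggregate_ratings(panel)
    rows = []
    for code, row in means.iterrows():
        rpn = traditional_rpn(row.mean_O, row.mean_S, row.mean_D)
        frpn = fis.infer(row.mean_O, row.mean_S, row.mean_D)
        rows.append(
            {
                "code": code,
                "mean_O": round_half_up(row.mean_O, precision),
                "mean_S": round_half_up(row.mean_S, precision),
                "mean_D": round_half_up(row.mean_D, precision),
                "rpn": round_half_up(rpn, precision),
                "frpn": round_half_up(frpn, precision),
            }
        )
    table = pd.DataFrame(rows)
    table["rank_rpn"] = rank_scores(table["rpn"], precision)
    table["rank_frpn"] = rank_scores(table["frpn"], precision)
    return table[list(RISK_TABLE_COLUMNS)]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def load_worksheet(path: Union[str, Path]) -> list[FailureMode]:
    frame = pd.read_csv(path, dtype=str).fillna("")
    missing = set(WORKSHEET_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"worksheet {path} lacks columns {sorted(missing)}")
    modes = [FailureMode(**row[list(WORKSHEET_COLUMNS)]) for _, row in frame.iterrows()]
    codes = [fm.code for fm in modes]
    if len(set(codes)) != len(codes):
        dup = next(c for c in codes if codes.count(c) > 1)
        raise ValueError(f"worksheet {path}: duplicate code {dup!r}")
    return modes


def save_worksheet(modes: list[FailureMode], path: Union[str, Path]) -> None:
    pd.DataFrame([vars(fm) for fm in modes])[list(WORKSHEET_COLUMNS)].to_csv(
        path, index=False
    )


def save_risk_table(table: pd.DataFrame, path: Union[str, Path]) -> None:
    table[list(RISK_TABLE_COLUMNS)].to_csv(path, index=False)


def load_risk_table(path: Union[str, Path]) -> pd.DataFrame:
    table = pd.read_csv(path)
    missing = set(RISK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"risk table {path} lacks columns {sorted(missing)}")
    return table[list(RISK_TABLE_COLUMNS)]
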