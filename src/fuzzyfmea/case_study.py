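"""The packaged membrane-based WFI case study.

Twenty-four failure modes (FM1-FM24) across the pretreatment, production,
storage/distribution and auxiliary subsystems of a membrane-based
water-for-injection plant, rated for occurrence, severity and detection by
a panel of three senior pharmaceutical water-system practitioners.

``reference_scores`` carries the originally reported RPN/fRPN values and
ranks as printed, for regression against the traditional-RPN pipeline.
The reported fRPN values depend on the original study's exact
membership-function breakpoints and rule consequents, which are not fully
published; they are reference metadata, not a reproduction target of the
shipped default fuzzy system.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .engine import FuzzySystem
from .fmea import (
    FailureMode,
    RatingPanel,
    aggregate_ratings,
    build_risk_table,
    load_worksheet,
    round_half_up,
    traditional_rpn,
)
from .rulebase import RuleBase

__all__ = ["CaseStudyBundle", "IntegrityError", "load_case_study", "run_case_study"]

N_FAILURE_MODES = 24
N_EXPERTS = 3


class IntegrityError(RuntimeError):
    """Raised when packaged fixtures fail their internal consistency checks."""


@dataclass(frozen=True)
class CaseStudyBundle:
    worksheet: tuple[FailureMode, ...]
    panel: RatingPanel
    reference_scores: pd.DataFrame

    @property
    def codes(self) -> list[str]:
        return [fm.code for fm in self.worksheet]


def _data_path(name: str):
    return resources.files("fuzzyfmea").joinpath("data", name)


def load_case_study() -> CaseStudyBundle:
    """Load and integrity-check the packaged worksheet, panel, and reference.

    Checks: exactly 24 codes FM1…FM24 in both files, exactly 3 experts, and
    every reported traditional RPN within 0.005 of the recomputed product
    of mean scores.
    """
    with resources.as_file(_data_path("worksheet.csv")) as p:
        worksheet = tuple(load_worksheet(p))
    with resources.as_file(_data_path("ratings.csv")) as p:
        panel = RatingPanel.from_csv(p)
    with resources.as_file(_data_path("reference_scores.csv")) as p:
        reference = pd.read_csv(p)

    expected_codes = [f"FM{i}" for i in range(1, N_FAILURE_MODES + 1)]
    if [fm.code for fm in worksheet] != expected_codes:
        raise IntegrityError("worksheet fixture does not list FM1…FM24 in order")
    if sorted(panel.codes, key=lambda c: int(c[2:])) != expected_codes:
        raise IntegrityError("ratings fixture does not cover FM1…FM24")
    if panel.n_experts != N_EXPERTS:
        raise IntegrityError(
            f"ratings fixture has {panel.n_experts} experts, expected {N_EXPERTS}"
        )
    if sorted(reference["code"], key=lambda c: int(c[2:])) != expected_codes:
        raise IntegrityError("reference fixture does not cover FM1…FM24")

    means = aggregate_ratings(panel)
    for row in reference.itertuples():
        m = means.loc[row.code]
        recomputed = round_half_up(traditional_rpn(m.mean_O, m.mean_S, m.mean_D))
        if abs(recomputed - row.rpn_reported) > 0.005:
            raise IntegrityError(
                f"{row.code}: recomputed RPN {recomputed} != "
                f"reported {row.rpn_reported}"
            )
    return CaseStudyBundle(worksheet=worksheet, panel=panel, reference_scores=reference)


def run_case_study(
    fis: Optional[FuzzySystem] = None,
    rules: Optional[RuleBase] = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Run the full pipeline on the packaged case study.

    Returns the 24-row risk-score table (code, means, rpn, rank_rpn, frpn,
    rank_frpn).  Deterministic for a fixed fuzzy configuration.
    """
    bundle = load_case_study()
    if fis is None:
        fis = FuzzySystem.default()
    if rules is not None:
        from dataclasses import replace

        fis = replace(fis, rules=rules)
    return build_risk_table(bundle.panel, fis=fis, precision=precision)
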