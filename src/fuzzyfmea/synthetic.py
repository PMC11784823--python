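"""Seeded generation of synthetic expert panels for testing and demonstration.

Panels mirror the structure of the packaged case study: K experts rate N
failure modes for occurrence, severity, and detection on integer 1-10
scales.  Three rating models are available:

``uniform``
    Scores i.i.d. uniform on {1, …, 10}.
``truncnorm``
    Scores drawn from a per-dimension normal, truncated to [0.5, 10.5] and
    rounded to the nearest integer.  Defaults (O: 3.5±2, S: 7±2, D: 3.5±2)
    imitate the case-study panel's marginals, where severity runs high and
    occurrence/detection sit in the low-to-mid bands.
``band``
    For each (failure mode, dimension) a latent 5-level linguistic band is
    drawn (bands {1}, {2,3}, {4,5,6}, {7,8}, {9,10}); each expert then
    rates an integer uniformly within that band.  This mimics a panel that
    agrees on the linguistic level but differs on the exact score.

``tie_injection`` forces pairs of failure modes to share all their ratings
(hence equal traditional RPN), reproducing the RPN-collision pathology on
demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .engine import FuzzySystem
from .fmea import (
    FailureMode,
    RatingPanel,
    build_risk_table,
    compare_rankings,
    round_half_up,
)

__all__ = ["PanelSpec", "generate_panel", "clustering_experiment", "RATING_MODELS"]

RATING_MODELS = ("uniform", "truncnorm", "band")

# linguistic bands of the 1-10 rating scales
_BANDS = ((1, 1), (2, 3), (4, 6), (7, 8), (9, 10))

# marginals imitating the case-study panel
_DEFAULT_MEANS = {"O": 3.5, "S": 7.0, "D": 3.5}
_DEFAULT_SDS = {"O": 2.0, "S": 2.0, "D": 2.0}


@dataclass(frozen=True)
class PanelSpec:
    """Parameters of one synthetic panel draw."""

    n_failure_modes: int = 24
    n_experts: int = 3
    seed: int = 0
    rating_model: str = "band"
    means: dict = field(default_factory=lambda: dict(_DEFAULT_MEANS))
    sds: dict = field(default_factory=lambda: dict(_DEFAULT_SDS))
    tie_injection: int = 0

    def __post_init__(self) -> None:
        if self.n_failure_modes < 1 or self.n_experts < 1:
            raise ValueError("n_failure_modes and n_experts must be positive")
        if self.rating_model not in RATING_MODELS:
            raise ValueError(
                f"rating_model must be one of {RATING_MODELS}, got {self.rating_model!r}"
            )
        if any(sd <= 0 for sd in self.sds.values()):
            raise ValueError("sds must be positive")
        if self.tie_injection < 0:
            raise ValueError("tie_injection must be >= 0")
        if 2 * self.tie_injection > self.n_failure_modes:
            raise ValueError(
                f"cannot inject {self.tie_injection} tie pair(s) into "
                f"{self.n_failure_modes} failure modes"
            )


def _draw_scores(spec: PanelSpec, rng: np.random.Generator) -> np.ndarray:
    """Integer scores with shape (n_experts, n_failure_modes, 3) in [1, 10]."""
    shape = (spec.n_experts, spec.n_failure_modes)
    if spec.rating_model == "uniform":
        return rng.integers(1, 11, size=shape + (3,))
    if spec.rating_model == "truncnorm":
        cols = []
        for dim in ("O", "S", "D"):
            mu, sd = spec.means[dim], spec.sds[dim]
            a, b = (0.5 - mu) / sd, (10.5 - mu) / sd
            draw = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=shape, random_state=rng)
            cols.append(np.clip(np.rint(draw), 1, 10).astype(int))
        return np.stack(cols, axis=-1)
    # band model: shared latent linguistic level per (mode, dimension)
    bands = rng.integers(0, 5, size=(spec.n_failure_modes, 3))
    lo = np.array([_BANDS[b][0] for b in bands.ravel()]).reshape(bands.shape)
    hi = np.array([_BANDS[b][1] for b in bands.ravel()]).reshape(bands.shape)
    return rng.integers(lo[None, :, :], hi[None, :, :] + 1, size=shape + (3,))


def generate_panel(spec: PanelSpec) -> tuple[list[FailureMode], RatingPanel]:
    """Draw one seeded panel plus a placeholder worksheet.

    Identical specs (including seed) give identical output.  Injected tie
    pairs share all three ratings across experts, so their traditional
    RPNs are equal exactly.
    """
    rng = np.random.default_rng(spec.seed)
    scores = _draw_scores(spec, rng)
    codes = [f"FM{i}" for i in range(1, spec.n_failure_modes + 1)]

    for k in range(spec.tie_injection):
        scores[:, 2 * k + 1, :] = scores[:, 2 * k, :]

    rows = [
        {
            "expert": e + 1,
            "code": codes[m],
            "O": int(scores[e, m, 0]),
            "S": int(scores[e, m, 1]),
            "D": int(scores[e, m, 2]),
        }
        for e in range(spec.n_experts)
        for m in range(spec.n_failure_modes)
    ]
    panel = RatingPanel(pd.DataFrame(rows))
    worksheet = [
        FailureMode(
            code=code,
            hazard=f"Synthetic component {i + 1}",
            subsystem="production",
            failure_mode="synthetic failure mode",
            effect="synthetic effect",
            cause="synthetic cause",
        )
        for i, code in enumerate(codes)
    ]
    return worksheet, panel


def _tie_fraction(values: pd.Series) -> float:
    """Fraction of unordered code pairs sharing the same rounded value."""
    n = len(values)
    if n < 2:
        return 0.0
    counts = values.value_counts()
    tied = float((counts * (counts - 1) // 2).sum())
    return tied / (n * (n - 1) / 2)


def clustering_experiment(
    n_panels: int,
    spec: PanelSpec,
    fis: Optional[FuzzySystem] = None,
    precision: int = 2,
) -> pd.DataFrame:
    """Tie frequency under traditional RPN vs fuzzy RPN over seeded replicates.

    Runs ``n_panels`` independent panels (seeds spec.seed, spec.seed+1, …)
    through the full pipeline and reports, per panel, the fraction of
    failure-mode pairs tied under the rounded traditional RPN and under the
    rounded fRPN.  Returns an empty frame for ``n_panels == 0``.
    """
    if n_panels < 0:
        raise ValueError("n_panels must be >= 0")
    if fis is None and n_panels > 0:
        fis = FuzzySystem.default()
    records = []
    for k in range(n_panels):
        _, panel = generate_panel(replace(spec, seed=spec.seed + k))
        table = build_risk_table(panel, fis=fis, precision=precision)
        records.append(
            {
                "seed": spec.seed + k,
                "tie_fraction_rpn": _tie_fraction(table["rpn"]),
                "tie_fraction_frpn": _tie_fraction(table["frpn"]),
                "n_rpn_tie_groups": len(compare_rankings(table, precision).rpn_ties),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=["seed", "tie_fraction_rpn", "tie_fraction_frpn", "n_rpn_tie_groups"],
    )
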