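"""Mamdani fuzzy inference: rule activation, min-max aggregation, centroid.

The pipeline mirrors the classic five-step Mamdani scheme: fuzzify the
crisp (occurrence, severity, detection) inputs; take the minimum of a
rule's three antecedent memberships as its activation weight α; clip the
rule's output term at α (min implication); combine all clipped outputs
with the pointwise maximum; and defuzzify the aggregated set by its
centroid on a uniform output-universe grid.

Inference is pure: no random state, deterministic for a fixed
configuration and grid step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .membership import (
    LinguisticVariable,
    MembershipFunction,
    TrapezoidalMF,
    TriangularMF,
    detection_variable,
    occurrence_variable,
    rpn_variable,
    severity_variable,
)
from .rulebase import RuleBase, default_rulebase

__all__ = [
    "NoRuleFiredError",
    "AggregatedOutput",
    "activate",
    "aggregate",
    "defuzzify_centroid",
    "FuzzySystem",
    "save_fis_config",
    "load_fis_config",
]

DEFAULT_GRID_STEP = 0.01


class NoRuleFiredError(RuntimeError):
    """Raised when no rule has positive activation (broken rule base)."""


@dataclass(frozen=True)
class AggregatedOutput:
    """Aggregated fuzzy output: membership degrees sampled on a grid."""

    grid: np.ndarray
    degrees: np.ndarray

    def __post_init__(self) -> None:
        if self.grid.shape != self.degrees.shape or self.grid.size < 2:
            raise ValueError("grid and degrees must be equal-length with >= 2 points")
        if np.any(self.degrees < 0) or np.any(self.degrees > 1):
            raise ValueError("aggregated degrees must lie in [0, 1]")


def activate(rule_degrees: Sequence[float]) -> float:
    """Activation weight of a rule: minimum of its three antecedent degrees."""
    if len(rule_degrees) != 3:
        raise ValueError(f"expected 3 antecedent degrees, got {len(rule_degrees)}")
    for deg in rule_degrees:
        if not 0.0 <= deg <= 1.0:
            raise ValueError(f"membership degree {deg} outside [0, 1]")
    return float(min(rule_degrees))


def aggregate(
    clipped_outputs: Sequence[tuple[float, MembershipFunction]],
    grid: np.ndarray,
) -> AggregatedOutput:
    """Max-combine rule outputs, each clipped at its activation weight.

    ``clipped_outputs`` pairs an activation weight α with the rule's
    output-term MF; the aggregated degree at each grid point is
    max over rules of min(α, µ_term).
    """
    if len(clipped_outputs) == 0:
        raise NoRuleFiredError("no rule fired: empty activation set")
    degrees = np.zeros_like(grid, dtype=float)
    for alpha, mf in clipped_outputs:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"activation weight {alpha} outside [0, 1]")
        np.maximum(degrees, np.minimum(alpha, mf(grid)), out=degrees)
    return AggregatedOutput(grid=grid, degrees=degrees)


def defuzzify_centroid(agg: AggregatedOutput) -> float:
    """Centroid of the aggregated set: Σ µ_j·x_j / Σ µ_j over the grid.

    The end grid points carry half weight (trapezoidal quadrature), which
    removes the O(step) bias that a plain sum acquires when the aggregated
    set touches a universe boundary.
    """
    if not np.any(agg.degrees > 0.0):
        raise NoRuleFiredError("no rule fired: aggregated membership is all zero")
    weights = np.ones_like(agg.degrees)
    weights[0] = weights[-1] = 0.5
    weighted = weights * agg.degrees
    return float(np.sum(weighted * agg.grid) / np.sum(weighted))


@dataclass(frozen=True)
class FuzzySystem:
    """A complete Mamdani system: four linguistic variables plus a rule base."""

    occurrence: LinguisticVariable
    severity: LinguisticVariable
    detection: LinguisticVariable
    output: LinguisticVariable
    rules: RuleBase
    grid_step: float = DEFAULT_GRID_STEP

    def __post_init__(self) -> None:
        lo, hi = self.output.universe
        if not 0 < self.grid_step < hi - lo:
            raise ValueError(
                f"grid step must lie in (0, {hi - lo}), got {self.grid_step}"
            )
        expected = (
            self.occurrence.n_terms * self.severity.n_terms * self.detection.n_terms
        )
        if self.rules.n_rules != expected:
            raise ValueError(
                f"rule base has {self.rules.n_rules} rules; "
                f"{expected} needed for these term counts"
            )

    @classmethod
    def default(cls, grid_step: float = DEFAULT_GRID_STEP) -> "FuzzySystem":
        """The default WFI risk system (1-10 universes, shipped rule base)."""
        return cls(
            occurrence=occurrence_variable(),
            severity=severity_variable(),
            detection=detection_variable(),
            output=rpn_variable(),
            rules=default_rulebase(),
            grid_step=grid_step,
        )

    def with_grid_step(self, step: float) -> "FuzzySystem":
        return replace(self, grid_step=step)

    def output_grid(self) -> np.ndarray:
        return self.output.grid(self.grid_step)

    def _output_term_matrix(self, grid: np.ndarray) -> np.ndarray:
        return np.array([mf(grid) for _, mf in self.output.terms])

    def aggregate_output(self, o: float, s: float, d: float) -> AggregatedOutput:
        """Fuzzify, evaluate all rules, and max-aggregate the clipped outputs."""
        mu_o = self.occurrence.fuzzify(o)
        mu_s = self.severity.fuzzify(s)
        mu_d = self.detection.fuzzify(d)
        # α for every rule at once: min over the antecedent lattice
        alpha = np.minimum(
            np.minimum(mu_o[:, None, None], mu_s[None, :, None]), mu_d[None, None, :]
        )
        # rules sharing a consequent collapse under max, so aggregate per
        # output level: β_level = max α over rules concluding that level
        consequents = self.rules.consequent_array()
        beta = np.zeros(self.output.n_terms)
        np.maximum.at(beta, consequents - 1, alpha)
        if not np.any(beta > 0):
            raise NoRuleFiredError(
                f"no rule fired for inputs (o={o}, s={s}, d={d})"
            )
        grid = self.output_grid()
        degrees = np.max(
            np.minimum(beta[:, None], self._output_term_matrix(grid)), axis=0
        )
        return AggregatedOutput(grid=grid, degrees=degrees)

    def infer(self, o: float, s: float, d: float) -> float:
        """Crisp fuzzy-RPN for mean occurrence/severity/detection scores."""
        return defuzzify_centroid(self.aggregate_output(o, s, d))

    def infer_many(self, o: np.ndarray, s: np.ndarray, d: np.ndarray) -> np.ndarray:
        return np.array([self.infer(*triple) for triple in zip(o, s, d)])

    # -- configuration serialisation ---------------------------------------

    def to_config_dict(self) -> dict:
        return {
            "grid_step": self.grid_step,
            "variables": {
                role: _variable_to_dict(getattr(self, role))
                for role in ("occurrence", "severity", "detection", "output")
            },
        }


_MF_FAMILIES = {"triangular": TriangularMF, "trapezoidal": TrapezoidalMF}


def _variable_to_dict(var: LinguisticVariable) -> dict:
    return {
        "name": var.name,
        "universe": list(var.universe),
        "terms": [
            {
                "label": label,
                "family": "triangular" if isinstance(mf, TriangularMF) else "trapezoidal",
                "breakpoints": mf.params(),
            }
            for label, mf in var.terms
        ],
    }


def _variable_from_dict(data: dict) -> LinguisticVariable:
    terms = []
    for term in data["terms"]:
        family = term["family"]
        if family not in _MF_FAMILIES:
            raise ValueError(f"unknown MF family {family!r}")
        terms.append((term["label"], _MF_FAMILIES[family](*term["breakpoints"])))
    return LinguisticVariable(
        name=data["name"],
        universe=tuple(float(v) for v in data["universe"]),
        terms=tuple(terms),
    )


def save_fis_config(fis: FuzzySystem, path: Union[str, Path]) -> None:
    """Write variables and grid step as JSON or YAML (by file suffix)."""
    path = Path(path)
    payload = fis.to_config_dict()
    with open(path, "w") as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            yaml.safe_dump(payload, fh, sort_keys=False)
        else:
            json.dump(payload, fh, indent=2)


def load_fis_config(
    path: Union[str, Path], rules: Optional[RuleBase] = None
) -> FuzzySystem:
    """Rebuild a :class:`FuzzySystem` from a config file.

    The rule base travels separately (rule-base CSV); when ``rules`` is not
    given the shipped default base is used.
    """
    path = Path(path)
    with open(path) as fh:
        if path.suffix.lower() in (".yaml", ".yml"):
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    variables = {
        role: _variable_from_dict(payload["variables"][role])
        for role in ("occurrence", "severity", "detection", "output")
    }
    return FuzzySystem(
        occurrence=variables["occurrence"],
        severity=variables["severity"],
        detection=variables["detection"],
        output=variables["output"],
        rules=rules if rules is not None else default_rulebase(),
        grid_step=float(payload.get("grid_step", DEFAULT_GRID_STEP)),
    )
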