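"""Mamdani inference kernel: activation, aggregation, centroid, full inference.

The independent oracle for single-rule inference is numeric quadrature of
min(α, µ_term) over the output universe, done with scipy on the raw MF
formula — a route that never touches the engine's grid machinery.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from fuzzyfmea import (
    AggregatedOutput,
    FuzzySystem,
    NoRuleFiredError,
    TriangularMF,
    activate,
    aggregate,
    defuzzify_centroid,
    load_fis_config,
    save_fis_config,
)


def clipped_centroid_oracle(mf, alpha, lo, hi):
    """Centroid of min(alpha, mf) by adaptive quadrature on the raw formula."""
    num, _ = integrate.quad(lambda x: x * min(alpha, mf(x)), lo, hi, limit=200)
    den, _ = integrate.quad(lambda x: min(alpha, mf(x)), lo, hi, limit=200)
    return num / den


@pytest.mark.parametrize(
    "degrees, expected",
    [((1.0, 1.0, 1.0), 1.0), ((0.4, 0.6, 1.0), 0.4), ((0.0, 0.9, 0.9), 0.0)],
)
def test_activation_is_minimum(degrees, expected):
    assert activate(degrees) == expected


def test_activation_rejects_invalid_degrees():
    with pytest.raises(ValueError):
        activate((0.5, 1.2, 0.1))
    with pytest.raises(ValueError):
        activate((0.5, 0.5))


class TestAggregate:
    grid = np.linspace(1, 10, 901)

    def test_single_rule_full_activation_is_identity(self):
        term = TriangularMF(2, 5, 8)
        agg = aggregate([(1.0, term)], self.grid)
        assert np.allclose(agg.degrees, term(self.grid))

    def test_clipping_creates_plateau(self):
        term = TriangularMF(2, 5, 8)
        agg = aggregate([(0.5, term)], self.grid)
        assert agg.degrees.max() == pytest.approx(0.5)
        assert np.allclose(agg.degrees, np.minimum(0.5, term(self.grid)))

    def test_max_absorbs_weaker_duplicate_rule(self):
        term = TriangularMF(2, 5, 8)
        both = aggregate([(0.3, term), (0.7, term)], self.grid)
        single = aggregate([(0.7, term)], self.grid)
        assert np.array_equal(both.degrees, single.degrees)

    def test_empty_activation_set_raises(self):
        with pytest.raises(NoRuleFiredError):
            aggregate([], self.grid)


class TestCentroid:
    def test_symmetric_clipped_term_centroid_is_peak(self):
        grid = np.linspace(1, 10, 9001)
        term = TriangularMF(2, 5, 8)
        for alpha in (0.1, 0.25, 0.5, 0.75, 1.0):
            agg = aggregate([(alpha, term)], grid)
            assert defuzzify_centroid(agg) == pytest.approx(5.0, abs=1e-9)

    def test_right_triangle_closed_form(self):
        # µ = 1 - x/3 on [0, 3]: centroid = ∫xµ/∫µ = (3/2)/(3/2) = 1
        grid = np.linspace(0, 3, 3001)
        agg = AggregatedOutput(grid=grid, degrees=1 - grid / 3)
        assert defuzzify_centroid(agg) == pytest.approx(1.0, abs=1e-3)

    def test_uniform_degrees_centroid_is_midpoint(self):
        grid = np.linspace(1, 10, 901)
        agg = AggregatedOutput(grid=grid, degrees=np.ones_like(grid))
        assert defuzzify_centroid(agg) == pytest.approx(5.5)

    def test_all_zero_degrees_raise(self):
        grid = np.linspace(1, 10, 901)
        with pytest.raises(NoRuleFiredError):
            defuzzify_centroid(AggregatedOutput(grid=grid, degrees=np.zeros_like(grid)))

    def test_result_within_support_of_positive_membership(self):
        grid = np.linspace(1, 10, 901)
        term = TriangularMF(6, 7, 9)
        agg = aggregate([(0.4, term)], grid)
        value = defuzzify_centroid(agg)
        positive = grid[agg.degrees > 0]
        assert positive.min() <= value <= positive.max()


class TestInference:
    def test_prototype_points_match_single_rule_oracle(self, fis):
        """At all 125 crisp prototype triples exactly one rule fires fully,
        so inference must equal the quadrature centroid of that rule's
        output term."""
        protos_o = fis.occurrence.prototypes()
        protos_s = fis.severity.prototypes()
        protos_d = fis.detection.prototypes()
        lo, hi = fis.output.universe
        for (i, o), (j, s), (k, d) in itertools.product(
            enumerate(protos_o), enumerate(protos_s), enumerate(protos_d)
        ):
            rule = fis.rules.rule_for(i + 1, j + 1, k + 1)
            _, out_mf = fis.output.terms[rule.rpn_level - 1]
            expected = clipped_centroid_oracle(out_mf, 1.0, lo, hi)
            assert fis.infer(o, s, d) == pytest.approx(expected, abs=5e-3)

    def test_partial_activation_matches_quadrature_oracle(self, fis):
        """With o on the limb between two occurrence terms, two rules fire
        partially; the engine must match quadrature of the max of the two
        clipped output terms."""
        o, s, d = 1.5, 1.0, 1.0
        mu_o = fis.occurrence.fuzzify(o)
        active = [(float(mu_o[t]), fis.rules.rule_for(t + 1, 1, 1)) for t in range(5)
                  if mu_o[t] > 0]
        assert len(active) == 2
        mfs = [(alpha, fis.output.terms[rule.rpn_level - 1][1]) for alpha, rule in active]

        def mu_agg(x):
            return max(min(alpha, mf(x)) for alpha, mf in mfs)

        lo, hi = fis.output.universe
        num, _ = integrate.quad(lambda x: x * mu_agg(x), lo, hi, limit=400)
        den, _ = integrate.quad(mu_agg, lo, hi, limit=400)
        assert fis.infer(o, s, d) == pytest.approx(num / den, abs=5e-3)

    def test_infer_matches_explicit_aggregate_route(self, fis):
        """The vectorised engine equals the literal per-rule min/max path."""
        rng = np.random.default_rng(42)
        grid = fis.output_grid()
        for o, s, d in rng.uniform(1, 10, size=(25, 3)):
            mu_o = fis.occurrence.fuzzify(o)
            mu_s = fis.severity.fuzzify(s)
            mu_d = fis.detection.fuzzify(d)
            clipped = []
            for rule in fis.rules.rules:
                alpha = activate(
                    (mu_o[rule.o_level - 1], mu_s[rule.s_level - 1], mu_d[rule.d_level - 1])
                )
                if alpha > 0:
                    clipped.append((alpha, fis.output.terms[rule.rpn_level - 1][1]))
            expected = defuzzify_centroid(aggregate(clipped, grid))
            assert fis.infer(o, s, d) == pytest.approx(expected, abs=1e-12)

    def test_grid_refinement_stability(self, fis):
        rng = np.random.default_rng(7)
        fine = fis.with_grid_step(fis.grid_step / 2)
        for o, s, d in rng.uniform(1, 10, size=(100, 3)):
            assert fis.infer(o, s, d) == pytest.approx(fine.infer(o, s, d), abs=1e-3)

    def test_monotone_in_each_risk_direction_at_prototypes(self, fis):
        protos = [
            fis.occurrence.prototypes(),
            fis.severity.prototypes(),
            fis.detection.prototypes(),
        ]
        for axis in range(3):
            others = [a for a in range(3) if a != axis]
            for i, j in itertools.product(range(5), repeat=2):
                values = []
                for k in range(5):
                    levels = [0, 0, 0]
                    levels[axis], levels[others[0]], levels[others[1]] = k, i, j
                    values.append(fis.infer(*(protos[a][levels[a]] for a in range(3))))
                assert np.all(np.diff(values) >= -1e-9)

    def test_output_always_within_universe(self, fis):
        rng = np.random.default_rng(123)
        lo, hi = fis.output.universe
        for o, s, d in rng.uniform(1, 10, size=(1000, 3)):
            assert lo <= fis.infer(o, s, d) <= hi

    def test_out_of_range_input_propagates(self, fis):
        from fuzzyfmea import OutOfRangeError

        with pytest.raises(OutOfRangeError):
            fis.infer(0.5, 5, 5)


class TestConfigRoundTrip:
    @pytest.mark.parametrize("suffix", [".json", ".yaml"])
    def test_save_load_identity(self, fis, tmp_path, suffix):
        path = tmp_path / f"fis{suffix}"
        save_fis_config(fis, path)
        loaded = load_fis_config(path)
        assert loaded.to_config_dict() == fis.to_config_dict()
        # load → save → load is stable
        path2 = tmp_path / f"fis2{suffix}"
        save_fis_config(loaded, path2)
        assert load_fis_config(path2).to_config_dict() == fis.to_config_dict()
        for o, s, d in [(1, 1, 1), (4.3, 9.0, 4.7), (10, 10, 10)]:
            assert loaded.infer(o, s, d) == fis.infer(o, s, d)


def test_invalid_grid_step_rejected(fis):
    with pytest.raises(ValueError):
        fis.with_grid_step(0.0)
    with pytest.raises(ValueError):
        fis.with_grid_step(20.0)
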