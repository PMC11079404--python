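"""Mamdani connectives, inference, and the two centroid routes."""

import numpy as np
import pytest

import pestsafe as ps
from pestsafe import (
    NOT_SAFE,
    SAFE,
    AggregatedConsequent,
    NoRuleFiredError,
    centroid_oracle,
    conjunction,
    defuzzify_centroid,
    disjunction,
    fuzzify,
    infer,
    trapezoidal,
)

OUTPUT_MFS = {
    NOT_SAFE: trapezoidal(0, 0, 3, 7),
    SAFE: trapezoidal(3, 7, 10, 10),
}


class TestConnectives:
    def test_conjunction_is_min(self):
        assert conjunction([1, 1, 1, 1, 1]) == 1
        assert conjunction([25 / 35, 1, 0.95, 1, 1]) == pytest.approx(25 / 35)
        assert conjunction([0.5, 0.9]) == 0.5

    def test_conjunction_empty_errors(self):
        with pytest.raises(ValueError):
            conjunction([])

    def test_disjunction_is_max_with_empty_zero(self):
        assert disjunction([0.78, 0.61, 0.38]) == 0.78
        assert disjunction([1, 0.26]) == 1
        assert disjunction([]) == 0.0

    def test_out_of_range_degrees_rejected(self):
        with pytest.raises(ValueError):
            conjunction([0.5, 1.2])
        with pytest.raises(ValueError):
            disjunction([-0.1])


class TestFuzzify:
    def test_sample_row_saturates_every_category(self, model):
        """A worst-case pesticide hits degree 1 in the worst category of all five."""
        values = dict(persistency=28, aeq=0.002, ld50_bee=0.03,
                      likely_exposure=3, mrl=0.02)
        fz = fuzzify(values, model.parameters)
        assert fz["persistency"]["non_persistent"] == 1.0
        assert fz["aeq"]["high_contaminate"] == 1.0
        assert fz["ld50_bee"]["high_toxicity"] == 1.0
        assert fz["likely_exposure"]["high_exposure"] == 1.0
        assert fz["mrl"]["low_residue_limit"] == 1.0

    def test_partial_membership_splits_categories(self, model):
        fz = fuzzify(dict(persistency=40, aeq=5, ld50_bee=150,
                          likely_exposure=3, mrl=5), model.parameters)
        assert fz["persistency"]["non_persistent"] == pytest.approx(25 / 35)
        assert fz["persistency"]["moderate_persistent"] == pytest.approx(0.5)
        assert fz["persistency"]["persistent"] == 0.0

    def test_left_plateau(self, model):
        fz = fuzzify(dict(persistency=0, aeq=5, ld50_bee=150,
                          likely_exposure=3, mrl=5), model.parameters)
        assert fz["persistency"] == {"non_persistent": 1.0,
                                     "moderate_persistent": 0.0, "persistent": 0.0}

    def test_missing_value_errors(self, model):
        with pytest.raises(ValueError, match="missing"):
            fuzzify(dict(persistency=10), model.parameters)


class TestInfer:
    def test_fully_not_safe_vector(self, model):
        fz = fuzzify(dict(persistency=28, aeq=0.002, ld50_bee=0.03,
                          likely_exposure=3, mrl=0.02), model.parameters)
        agg, fired = infer(fz, model.rule_base)
        assert agg.not_safe == 1.0
        assert agg.safe == 0.0
        assert len(fired) >= 1
        assert all(0.0 < act <= 1.0 for _, act in fired)

    def test_fully_safe_vector(self, model):
        # all-good antecedents except exposure and residue limit
        fz = fuzzify(dict(persistency=14, aeq=17.28, ld50_bee=200,
                          likely_exposure=3, mrl=10), model.parameters)
        agg, _ = infer(fz, model.rule_base)
        assert agg.safe == 1.0
        assert agg.not_safe == 0.0

    def test_single_active_combination_passes_through_degree(self, model):
        """With one positive category per parameter, the aggregate equals the min."""
        d = 0.37
        fz = {p.name: {c: 0.0 for c in p.categories} for p in model.parameters}
        for p in model.parameters:
            fz[p.name][p.categories[0]] = d
        agg, fired = infer(fz, model.rule_base)
        assert len(fired) == 1
        assert agg.degree(fired[0][0].consequent) == d

    def test_completeness_some_consequent_always_positive(self, model):
        """Anywhere on the universes at least one rule fires (coverage x completeness)."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            values = {
                p.name: rng.uniform(*p.universe) for p in model.parameters
            }
            agg, _ = infer(fuzzify(values, model.parameters), model.rule_base)
            assert agg.safe > 0.0 or agg.not_safe > 0.0


class TestCentroid:
    def test_full_not_safe(self):
        agg = AggregatedConsequent(safe=0.0, not_safe=1.0)
        assert defuzzify_centroid(agg, OUTPUT_MFS) == pytest.approx(2.63, abs=0.01)
        assert centroid_oracle(agg, OUTPUT_MFS) == pytest.approx(79 / 30, abs=1e-12)

    def test_full_safe(self):
        agg = AggregatedConsequent(safe=1.0, not_safe=0.0)
        assert defuzzify_centroid(agg, OUTPUT_MFS) == pytest.approx(7.37, abs=0.01)
        assert centroid_oracle(agg, OUTPUT_MFS) == pytest.approx(10 - 79 / 30, abs=1e-12)

    @pytest.mark.parametrize("h", [0.25, 0.5, 0.9, 1.0])
    def test_symmetric_activation_centres(self, h):
        """Equal activations of the mirror-image output sets centre the score."""
        agg = AggregatedConsequent(safe=h, not_safe=h)
        assert defuzzify_centroid(agg, OUTPUT_MFS) == pytest.approx(5.0, abs=1e-9)
        assert centroid_oracle(agg, OUTPUT_MFS) == pytest.approx(5.0, abs=1e-12)

    def test_mixed_activation_published_case(self):
        agg = AggregatedConsequent(safe=25 / 35, not_safe=0.5)
        assert centroid_oracle(agg, OUTPUT_MFS) == pytest.approx(5.44, abs=0.01)

    def test_no_rule_fired_is_an_error(self):
        agg = AggregatedConsequent(safe=0.0, not_safe=0.0)
        with pytest.raises(NoRuleFiredError):
            defuzzify_centroid(agg, OUTPUT_MFS)
        with pytest.raises(NoRuleFiredError):
            centroid_oracle(agg, OUTPUT_MFS)

    def test_continuity_vanishing_consequent(self):
        """As one activation vanishes the centroid tends to the other set's centroid."""
        full = centroid_oracle(AggregatedConsequent(safe=1.0, not_safe=0.0), OUTPUT_MFS)
        tiny = centroid_oracle(AggregatedConsequent(safe=1.0, not_safe=1e-9), OUTPUT_MFS)
        assert tiny == pytest.approx(full, abs=1e-6)

    def test_oracle_vs_discrete_random_aggregates(self):
        """The two routes agree within 1e-2 at step 0.01 and 1e-3 at step 0.001."""
        rng = np.random.default_rng(12345)
        pairs = rng.uniform(0.0, 1.0, size=(1000, 2))
        pairs[pairs.sum(axis=1) == 0.0] += 0.5  # exclude the no-fire point
        for hs, hn in pairs:
            agg = AggregatedConsequent(safe=float(hs), not_safe=float(hn))
            exact = centroid_oracle(agg, OUTPUT_MFS)
            assert defuzzify_centroid(agg, OUTPUT_MFS, step=0.01) == pytest.approx(
                exact, abs=1e-2
            )
        for hs, hn in pairs[:100]:
            agg = AggregatedConsequent(safe=float(hs), not_safe=float(hn))
            exact = centroid_oracle(agg, OUTPUT_MFS)
            assert defuzzify_centroid(agg, OUTPUT_MFS, step=0.001) == pytest.approx(
                exact, abs=1e-3
            )

    def test_output_bounded_by_full_centroids(self):
        """Any aggregate lands between the two full-activation centroids."""
        lo, hi = 79 / 30, 10 - 79 / 30
        rng = np.random.default_rng(99)
        for hs, hn in rng.uniform(0.01, 1.0, size=(300, 2)):
            agg = AggregatedConsequent(safe=float(hs), not_safe=float(hn))
            assert lo - 1e-9 <= centroid_oracle(agg, OUTPUT_MFS) <= hi + 1e-9

    def test_scaling_invariance_only_when_symmetric(self):
        sym = AggregatedConsequent(safe=0.8, not_safe=0.8)
        sym_scaled = AggregatedConsequent(safe=0.4, not_safe=0.4)
        assert centroid_oracle(sym, OUTPUT_MFS) == pytest.approx(
            centroid_oracle(sym_scaled, OUTPUT_MFS), abs=1e-12
        )
        asym = AggregatedConsequent(safe=0.8, not_safe=0.4)
        asym_scaled = AggregatedConsequent(safe=0.4, not_safe=0.2)
        assert centroid_oracle(asym, OUTPUT_MFS) != pytest.approx(
            centroid_oracle(asym_scaled, OUTPUT_MFS), abs=1e-6
        )
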