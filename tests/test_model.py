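import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kickout.errors import (
    IllPosedPropagationError,
    InconsistentInputsError,
    NoCrossingError,
    UndefinedOccupancyError,
    ValidationError,
)
from kickout.model import (
    CopyNumberParams,
    DimensionlessPoint,
    GuideSpec,
    KineticParams,
    PromoterPair,
    UncertainValue,
    alpha_crossing,
    gamma_star,
    gene_copy_number,
    infer_lambda_r,
    koff_upper_bound,
    kout_rate,
    lifetime_bound,
    occupancy,
    predict_promoter,
    propagate_uncertainty,
    relative_expression,
)


class TestRelativeExpression:
    def test_reference_roundtrip(self):
        # lambda*r = 0.4324 reproduces the 0.32 reference measurement
        assert gamma_star(0.4324, 0.0, 0.026) == pytest.approx(0.32, abs=5e-4)

    def test_saturated_limit_equals_r(self):
        pt = DimensionlessPoint(lambda_=0.0, alpha=0.0, r=0.5)
        assert relative_expression(pt) == 0.5

    def test_strong_promoter_value(self):
        assert gamma_star(1.124, 0.0, 0.026) == pytest.approx(0.5415, abs=5e-4)

    def test_large_lambda_limit(self):
        pt = DimensionlessPoint(lambda_=1e9, alpha=0.0, r=0.3)
        assert relative_expression(pt) == pytest.approx(1.0, abs=1e-6)

    @given(lam_r=st.floats(0.0, 1e3), alpha=st.floats(0.0, 1e3),
           r=st.floats(0.0, 1.0))
    def test_range_invariant(self, lam_r, alpha, r):
        g = gamma_star(lam_r, alpha, r)
        assert r - 1e-12 <= g <= 1.0 + 1e-12

    @given(r=st.floats(0.0, 0.99), alpha=st.floats(0.0, 10.0),
           lam_lo=st.floats(0.0, 50.0), bump=st.floats(1e-3, 50.0))
    def test_strictly_increasing_in_lambda(self, r, alpha, lam_lo, bump):
        g1 = gamma_star(lam_lo, alpha, r)
        g2 = gamma_star(lam_lo + bump, alpha, r)
        assert g2 > g1 or r == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            DimensionlessPoint(lambda_=-1.0, alpha=0.0, r=0.5)
        with pytest.raises(ValidationError):
            GuideSpec("g", 20, r=1.5)
        with pytest.raises(ValidationError):
            GuideSpec("g", 21, r=0.5)


class TestOccupancy:
    def test_never_leaves(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=1.0)
        assert occupancy(p, 0.0) == 1.0

    def test_symmetry(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=1.0)
        assert occupancy(p, 1.0) == 0.5

    def test_derived_value(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=1.0)
        assert occupancy(p, 0.43) == pytest.approx(0.6993, abs=1e-4)

    def test_both_zero_is_undefined(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=0.0)
        with pytest.raises(UndefinedOccupancyError):
            occupancy(p, 0.0)


class TestKoutRate:
    def test_no_collision_ejection(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=1.0, koff=0.1, delta=0.0)
        assert kout_rate(p, GuideSpec("g", 20, r=0.4)) == pytest.approx(0.1)

    def test_full_ejection(self):
        p = KineticParams(gamma0=20.0, rebinding_rate=1.0, koff=0.0, delta=1.0)
        assert kout_rate(p, GuideSpec("g", 20, r=0.026)) == pytest.approx(0.52)

    def test_combined(self):
        p = KineticParams(gamma0=10.0, rebinding_rate=1.0, koff=0.1, delta=1.0)
        assert kout_rate(p, GuideSpec("g", 20, r=1.0)) == pytest.approx(10.1)


class TestInferLambdaR:
    def test_reference_inference(self, full_guide):
        assert infer_lambda_r(0.32, full_guide, 0.0) == pytest.approx(0.4324, abs=5e-4)

    def test_saturated_floor_gives_zero(self):
        assert infer_lambda_r(0.1, 0.1, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_with_alpha(self):
        assert infer_lambda_r(0.5, 0.1, 0.1) == pytest.approx(0.70, abs=1e-12)

    def test_divergence_at_one(self):
        with pytest.raises(InconsistentInputsError):
            infer_lambda_r(1.0, 0.026, 0.0)

    def test_below_floor_rejected(self):
        with pytest.raises(InconsistentInputsError):
            infer_lambda_r(0.01, 0.026, 0.0)

    @given(r=st.floats(0.0, 0.95), alpha=st.floats(0.0, 5.0),
           lam_r=st.floats(0.0, 100.0))
    @settings(max_examples=200)
    def test_inverse_property(self, r, alpha, lam_r):
        g = gamma_star(lam_r, alpha, r)
        if g >= 1.0:  # saturated numerically, inverse ill-posed
            return
        assert gamma_star(infer_lambda_r(g, r, alpha), alpha, r) == pytest.approx(
            g, abs=1e-12)


class TestPredictPromoter:
    def test_paper_prediction(self, promoter_pair, full_guide):
        assert predict_promoter(promoter_pair, full_guide, 0.0) == pytest.approx(
            0.5415, abs=5e-4)

    def test_fold_one_is_identity(self, full_guide):
        pair = PromoterPair("a", "b", 1.0, 0.32)
        assert predict_promoter(pair, full_guide, 0.0) == pytest.approx(0.32)

    def test_alpha_014_value(self, promoter_pair, full_guide):
        assert predict_promoter(promoter_pair, full_guide, 0.14) == pytest.approx(
            0.487, abs=5e-4)

    def test_monotone_in_fold(self, full_guide):
        preds = [predict_promoter(PromoterPair("a", "b", f, 0.32), full_guide, 0.0)
                 for f in (0.5, 1.0, 2.0, 4.0)]
        assert all(a < b for a, b in zip(preds, preds[1:]))

    def test_decreasing_in_alpha(self, promoter_pair, full_guide):
        preds = [predict_promoter(promoter_pair, full_guide, a)
                 for a in (0.0, 0.05, 0.1, 0.2, 0.3)]
        assert all(a > b for a, b in zip(preds, preds[1:]))


class TestAlphaCrossing:
    def test_threshold_near_014(self, promoter_pair, full_guide):
        assert alpha_crossing(promoter_pair, full_guide, 0.487) == pytest.approx(
            0.14, abs=0.005)

    def test_bound_at_alpha_zero(self, promoter_pair, full_guide):
        bound = predict_promoter(promoter_pair, full_guide, 0.0)
        assert alpha_crossing(promoter_pair, full_guide, bound) == 0.0

    def test_roundtrip_035_six_mismatches(self, promoter_pair):
        r6 = 0.056
        bound = predict_promoter(promoter_pair, r6, 0.35)
        assert alpha_crossing(promoter_pair, r6, bound) == pytest.approx(
            0.35, abs=1e-6)

    def test_no_crossing(self, promoter_pair, full_guide):
        with pytest.raises(NoCrossingError):
            alpha_crossing(promoter_pair, full_guide, 0.2)  # below gamma*_ref


class TestBounds:
    def test_coefficient(self):
        lam = infer_lambda_r(0.32, 0.026, 0.0) / 0.026
        coef = koff_upper_bound(0.14, lam)
        assert coef == pytest.approx(8.4e-3, abs=2e-4)
        assert float(f"{coef:.0e}") == 8e-3  # one significant figure

    def test_zero_alpha(self):
        assert koff_upper_bound(0.0, 16.63) == 0.0

    def test_rate_at_gamma0_20(self):
        lam = infer_lambda_r(0.32, 0.026, 0.0) / 0.026
        assert koff_upper_bound(0.14, lam, 20.0) == pytest.approx(0.168, abs=1e-3)
        assert 8e-3 * 20.0 <= 1.0 / 6.0

    def test_lifetime_12_min(self):
        assert lifetime_bound(2.0, 1.0 / 6.0) == pytest.approx(12.0)

    def test_lifetime_trivial(self):
        assert lifetime_bound(1.0, 1.0) == 1.0

    def test_lifetime_6mm(self):
        assert lifetime_bound(2.0, 1.0 / 2.4) == pytest.approx(4.8)

    def test_infinite_lifetime(self):
        assert math.isinf(lifetime_bound(2.0, 0.0))

    def test_lambda_zero_rejected(self):
        with pytest.raises(ValidationError):
            koff_upper_bound(0.14, 0.0)


class TestGeneCopyNumber:
    def test_no_overlap(self):
        assert gene_copy_number(CopyNumberParams(0.0, 0.0, 30.0, 0.5)) == 1.0

    def test_locus_066(self):
        # printed "about 2" is not reproduced by the formula; see ledger
        assert gene_copy_number(CopyNumberParams(60.0, 20.0, 30.0, 0.66)) == \
            pytest.approx(2.543, abs=1e-3)

    def test_terminus(self):
        assert gene_copy_number(CopyNumberParams(60.0, 20.0, 30.0, 1.0)) == \
            pytest.approx(2.0 ** (2.0 / 3.0), abs=1e-12)


class TestPropagateUncertainty:
    def test_paper_prediction_uncertainty(self, promoter_pair, full_guide):
        def f(gamma_star_ref, strength_fold, r):
            pair = PromoterPair("a", "b", strength_fold, gamma_star_ref)
            return predict_promoter(pair, r, 0.0)

        out = propagate_uncertainty(
            {"gamma_star_ref": UncertainValue(0.32, 0.04),
             "strength_fold": UncertainValue(2.6, 0.2),
             "r": UncertainValue(0.026, 0.003)},
            f, n_draws=50_000, seed=3)
        assert out.mean == pytest.approx(0.54, abs=0.01)
        assert out.sd == pytest.approx(0.05, abs=0.01)

    def test_zero_sd_in_zero_sd_out(self):
        out = propagate_uncertainty(
            {"x": UncertainValue(2.0, 0.0)}, lambda x: 3.0 * x,
            n_draws=1000, seed=0)
        assert out.mean == 6.0 and out.sd == 0.0

    def test_identity(self):
        out = propagate_uncertainty(
            {"x": UncertainValue(1.0, 0.1)}, lambda x: x, n_draws=100_000, seed=0)
        assert out.mean == pytest.approx(1.0, abs=0.002)
        assert out.sd == pytest.approx(0.1, abs=0.002)

    def test_linear_matches_delta_method(self):
        # sd of 2x + 3y with sd_x=0.1, sd_y=0.2: sqrt(0.04+0.36)=0.6325
        n = 50_000
        out = propagate_uncertainty(
            {"x": UncertainValue(1.0, 0.1), "y": UncertainValue(1.0, 0.2)},
            lambda x, y: 2.0 * x + 3.0 * y, n_draws=n, seed=1)
        exact = math.sqrt(0.04 + 0.36)
        mc_se = 3.0 * exact / math.sqrt(2.0 * n)
        assert abs(out.sd - exact) < mc_se

    def test_deterministic(self):
        args = ({"x": UncertainValue(1.0, 0.5)}, lambda x: x * x)
        a = propagate_uncertainty(*args, n_draws=2000, seed=9)
        b = propagate_uncertainty(*args, n_draws=2000, seed=9)
        assert a == b

    def test_ill_posed(self):
        def domain_limited(x):
            return infer_lambda_r(x, 0.9, 0.0)  # rejects x below 0.9

        with pytest.raises(IllPosedPropagationError):
            propagate_uncertainty({"x": UncertainValue(0.5, 0.05)},
                                  domain_limited, n_draws=1000, seed=0)

    def test_n_draws_floor(self):
        with pytest.raises(ValidationError):
            propagate_uncertainty({"x": UncertainValue(1.0, 0.1)},
                                  lambda x: x, n_draws=10, seed=0)
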