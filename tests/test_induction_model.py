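import numpy as np
import pytest

import inductionscope as isc
from inductionscope.errors import (
    CollinearityError,
    DegenerateCurveError,
    InsufficientDataError,
    MissingReferenceError,
)
from inductionscope.induction_model import StandardizedFeatures
from inductionscope.sigmoid_fit import SigmoidFit, SigmoidParams


def _fit(c=15.0, b=40.0, d=2.0, e=0.2, well="P/A01", is_reference=False, induced=False):
    return SigmoidFit(
        params=SigmoidParams(a=2.0, b=b, c=c, d=d, e=e),
        r_squared=0.99,
        converged=True,
        n_points=448,
        residual_sum_squares=1.0,
        well_id=well,
        is_reference=is_reference,
        induced=induced,
    )


class TestReference:
    def test_single_reference(self):
        ref = isc.compute_reference([_fit(c=15.0, b=32.0, d=2.0, e=0.0)])  # slope 4
        assert (ref.c_ref, ref.slope_ref) == (15.0, 4.0)
        assert ref.aggregation == "single"

    def test_median_aggregation(self):
        fits = [_fit(c=14.0), _fit(c=15.0), _fit(c=16.0)]
        ref = isc.compute_reference(fits)
        assert ref.c_ref == 15.0
        assert ref.aggregation == "median" and ref.n_reference_cultures == 3

    def test_no_reference_is_error(self):
        with pytest.raises(MissingReferenceError):
            isc.compute_reference([])


class TestStandardize:
    def test_reference_standardizes_to_unity(self):
        fit = _fit()
        ref = isc.compute_reference([fit])
        f = isc.standardize(fit, ref)
        assert (f.c_std, f.slope_std) == (1.0, 1.0)

    def test_ratio_arithmetic(self):
        ref = isc.compute_reference([_fit(c=15.0, b=32.0, d=2.0, e=0.0)])  # slope 4
        f = isc.standardize(_fit(c=30.0, b=8.0, d=2.0, e=0.0), ref)  # slope 1
        assert f.c_std == pytest.approx(2.0)
        assert f.slope_std == pytest.approx(0.25)

    def test_nonpositive_inflection_time_flagged(self):
        ref = isc.compute_reference([_fit()])
        with pytest.raises(ValueError, match="not positive"):
            isc.standardize(_fit(c=-3.0), ref)


class TestClassification:
    @pytest.mark.parametrize(
        "c_std,slope_std,expected",
        [
            (1.5, 0.2, "optimal"),
            (2.5, 0.8, "too_strong"),
            (1.0, 1.0, "insufficient"),
            (1.95, 0.2, "indeterminate"),  # gap between optimal and too-strong edges
        ],
    )
    def test_rule_regions(self, c_std, slope_std, expected):
        cls = isc.classify_induction(StandardizedFeatures(c_std=c_std, slope_std=slope_std))
        assert cls.label == expected
        assert cls.rule_fired

    def test_too_strong_takes_precedence(self):
        # c_std beyond the too-strong edge wins regardless of slope
        cls = isc.classify_induction(StandardizedFeatures(c_std=2.5, slope_std=0.01))
        assert cls.label == "too_strong"


class TestPredictEP:
    def test_intercept_only(self):
        assert isc.evaluate_ep(0.0, 0.0) == pytest.approx(0.76)

    def test_reference_point(self):
        pred = isc.predict_ep(StandardizedFeatures(c_std=1.0, slope_std=1.0))
        assert pred.raw == pytest.approx(0.12)

    def test_optimal_regime_point(self):
        pred = isc.predict_ep(StandardizedFeatures(c_std=1.5, slope_std=0.1))
        assert pred.raw == pytest.approx(0.9265)
        assert pred.clipped == pred.raw

    def test_clipping(self):
        pred = isc.predict_ep(StandardizedFeatures(c_std=4.0, slope_std=2.0))
        assert 0.0 <= pred.clipped <= 1.0

    def test_pure_function(self):
        f = StandardizedFeatures(c_std=1.3, slope_std=0.4)
        assert isc.predict_ep(f).raw == isc.predict_ep(f).raw


class TestStandardizeExpression:
    def test_min_max_forced(self):
        out = isc.standardize_expression([10.0, 55.0, 100.0])
        assert [m.ep_standardized for m in out] == [0.0, 0.5, 1.0]

    def test_two_values(self):
        out = isc.standardize_expression([3.0, 7.0])
        assert [m.ep_standardized for m in out] == [0.0, 1.0]

    def test_all_equal_is_degenerate(self):
        with pytest.raises(DegenerateCurveError):
            isc.standardize_expression([5.0, 5.0, 5.0])


def _random_features(n, seed):
    rng = np.random.default_rng(seed)
    return [
        StandardizedFeatures(
            c_std=float(rng.uniform(0.8, 3.5)), slope_std=float(rng.uniform(0.05, 1.4))
        )
        for _ in range(n)
    ]


class TestRefitEPModel:
    def test_noiseless_recovery(self):
        features = _random_features(50, seed=5)
        y = [isc.evaluate_ep(f.c_std, f.slope_std) for f in features]
        model = isc.refit_ep_model(features, y)
        np.testing.assert_allclose(
            model.coefficients, isc.EPModel.default().coefficients, atol=1e-8
        )
        assert model.fitted_r_squared == pytest.approx(1.0, abs=1e-10)
        assert model.n_train == 50

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        features = [
            StandardizedFeatures(
                c_std=float(rng.uniform(0.8, 3.5)), slope_std=float(rng.uniform(0.05, 1.4))
            )
            for _ in range(600)
        ]
        y = np.array([isc.evaluate_ep(f.c_std, f.slope_std) for f in features])
        y = y + rng.normal(0.0, 0.10, y.size)
        model = isc.refit_ep_model(features, y)
        np.testing.assert_allclose(
            model.coefficients, isc.EPModel.default().coefficients, atol=0.05
        )

    def test_too_few_observations(self):
        features = _random_features(3, seed=1)
        with pytest.raises(InsufficientDataError):
            isc.refit_ep_model(features, [0.1, 0.2, 0.3])

    def test_collinear_design_rejected(self):
        # identical feature rows -> rank-deficient design
        features = [StandardizedFeatures(c_std=1.5, slope_std=0.2)] * 12
        with pytest.raises(CollinearityError):
            isc.refit_ep_model(features, list(np.linspace(0, 1, 12)))

    def test_ols_beats_default_model_on_training_sse(self):
        rng = np.random.default_rng(23)
        features = _random_features(80, seed=23)
        y = np.array([isc.evaluate_ep(f.c_std, f.slope_std) for f in features])
        y = np.clip(y + rng.normal(0, 0.2, y.size), 0, 1)
        refit = isc.refit_ep_model(features, y)

        def sse(model):
            pred = np.array([isc.evaluate_ep(f.c_std, f.slope_std, model) for f in features])
            return float(np.sum((pred - y) ** 2))

        assert sse(refit) <= sse(isc.EPModel.default()) + 1e-12


class TestScaleInvariance:
    def test_unit_change_leaves_everything_unchanged(self):
        """Multiplying all raw signals by k rescales a, b, e and the slope
        but leaves standardized features, class and EP untouched."""
        k = 7.3
        ref, culture = _fit(is_reference=True), _fit(c=25.0, b=12.0, d=3.0, e=0.1)

        def scaled(fit):
            p = fit.params
            return SigmoidFit(
                params=SigmoidParams(a=k * p.a, b=k * p.b, c=p.c, d=p.d, e=k * p.e),
                r_squared=fit.r_squared,
                converged=True,
                n_points=fit.n_points,
                residual_sum_squares=0.0,
                well_id=fit.well_id,
            )

        base_ref = isc.compute_reference([ref])
        scaled_ref = isc.compute_reference([scaled(ref)])
        f0 = isc.standardize(culture, base_ref)
        f1 = isc.standardize(scaled(culture), scaled_ref)
        assert f1.c_std == pytest.approx(f0.c_std, abs=1e-9)
        assert f1.slope_std == pytest.approx(f0.slope_std, abs=1e-9)
        assert isc.classify_induction(f1).label == isc.classify_induction(f0).label
        assert isc.predict_ep(f1).raw == pytest.approx(isc.predict_ep(f0).raw, abs=1e-9)
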