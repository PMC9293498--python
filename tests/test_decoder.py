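"""KDE densities and likelihood-ratio score fusion."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import quad

from lrbsf.cumulants import CumulantFeatureTable
from lrbsf.decoder import (
    LrbsfModel,
    decide_binary,
    fit_decoder,
    fit_kde,
    likelihood_ratio,
    predict_multiclass,
    predict_table,
    silverman_bandwidth,
)


def feature_table(values, labels, names=None):
    values = np.atleast_2d(np.asarray(values, float))
    if values.shape[0] == 1 and len(labels) > 1:
        values = values.T
    names = names or tuple(f"f{k}" for k in range(values.shape[1]))
    return CumulantFeatureTable(
        values=values,
        feature_names=tuple(names),
        labels=np.asarray(labels, int),
        trial_ids=np.arange(len(labels)),
    )


class TestKde:
    def test_silverman_rule_formula(self, rng):
        x = rng.normal(size=200)
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        expected = 0.9 * min(sd, iqr / 1.34) * 200 ** (-0.2)
        assert silverman_bandwidth(x) == pytest.approx(expected)

    def test_degenerate_samples_fall_back(self):
        h = silverman_bandwidth(np.full(10, 3.0))
        assert h == pytest.approx(1e-3 * (3.0 + 1.0))
        kde = fit_kde(np.full(10, 0.0))
        # density is maximized at the shared value
        ys = np.array([-0.01, 0.0, 0.01])
        dens = kde.pdf(ys)
        assert dens[1] == dens.max()

    def test_density_integrates_to_one(self, rng):
        kde = fit_kde(rng.normal(size=100))
        lo = kde.samples.min() - 10 * kde.bandwidth
        hi = kde.samples.max() + 10 * kde.bandwidth
        integral, _ = quad(lambda y: kde.pdf(np.array([y]))[0], lo, hi, limit=200)
        assert 0.99 <= integral <= 1.01

    def test_density_floored_far_from_support(self):
        kde = fit_kde(np.array([0.0, 0.1, -0.1, 0.05]))
        lp = kde.logpdf(np.array([1e6]))[0]
        assert np.isfinite(lp)
        assert lp == pytest.approx(np.log(1e-300))

    def test_kde_consistency_against_true_gaussian(self, rng):
        x = rng.normal(size=2000)
        kde = fit_kde(x)
        grid = np.linspace(-3, 3, 121)
        sup = np.max(np.abs(kde.pdf(grid) - stats.norm.pdf(grid)))
        assert sup < 0.05

    def test_matches_scipy_gaussian_kde_at_same_bandwidth(self, rng):
        """Independent cross-check of the density arithmetic."""
        x = rng.normal(size=300)
        kde = fit_kde(x)
        ref = stats.gaussian_kde(x, bw_method=kde.bandwidth / x.std(ddof=1))
        grid = np.linspace(-2, 2, 41)
        np.testing.assert_allclose(kde.pdf(grid), ref(grid), rtol=1e-8)

    def test_empty_samples_rejected(self):
        with pytest.raises(ValueError):
            fit_kde(np.array([]))


class TestFitDecoder:
    def test_density_counting_two_classes_five_features(self, rng):
        table = feature_table(
            rng.normal(size=(20, 5)), labels=[1] * 10 + [2] * 10
        )
        model = fit_decoder(table)
        assert sum(len(v) for v in model.densities.values()) == 10

    def test_density_counting_five_classes_eight_features(self, rng):
        table = feature_table(
            rng.normal(size=(25, 8)), labels=np.repeat([1, 2, 3, 4, 5], 5)
        )
        model = fit_decoder(table)
        assert sum(len(v) for v in model.densities.values()) == 40

    def test_training_is_deterministic(self, rng):
        vals = rng.normal(size=(12, 3))
        t = feature_table(vals, labels=[1] * 6 + [2] * 6)
        assert fit_decoder(t).to_json() == fit_decoder(t).to_json()

    def test_small_class_raises_with_class_name(self, rng):
        table = feature_table(rng.normal(size=(4, 2)), labels=[1, 1, 1, 2])
        with pytest.raises(ValueError, match="class 2"):
            fit_decoder(table)

    def test_single_class_raises(self, rng):
        with pytest.raises(ValueError, match="two classes"):
            fit_decoder(feature_table(rng.normal(size=(4, 2)), labels=[1] * 4))

    def test_model_json_round_trip(self, rng):
        t = feature_table(rng.normal(size=(10, 2)), labels=[1] * 5 + [2] * 5)
        model = fit_decoder(t, theta=2.0)
        back = LrbsfModel.from_json(model.to_json())
        y = rng.normal(size=2)
        assert back.class_log_likelihood(y, 1) == pytest.approx(
            model.class_log_likelihood(y, 1)
        )
        assert back.theta == 2.0


class TestLikelihoodRatio:
    def test_identical_class_densities_give_zero_log_lr(self, rng):
        shared = rng.normal(size=(6, 3))
        vals = np.vstack([shared, shared])
        model = fit_decoder(feature_table(vals, labels=[1] * 6 + [2] * 6))
        for _ in range(5):
            y = rng.normal(size=3)
            assert likelihood_ratio(model, y, 1, 2) == pytest.approx(0.0, abs=1e-12)

    def test_sign_follows_support(self, rng):
        a = rng.normal(0.0, 1.0, size=(50, 1))
        b = rng.normal(10.0, 1.0, size=(50, 1))
        model = fit_decoder(feature_table(np.vstack([a, b]), [1] * 50 + [2] * 50))
        assert likelihood_ratio(model, np.array([0.0]), 1, 2) > 0
        assert likelihood_ratio(model, np.array([10.0]), 1, 2) < 0

    def test_label_swap_negates_log_lr(self, rng):
        vals = rng.normal(size=(20, 2))
        vals[10:] += 2.0
        model = fit_decoder(feature_table(vals, [1] * 10 + [2] * 10))
        y = rng.normal(size=2)
        assert likelihood_ratio(model, y, 1, 2) == pytest.approx(
            -likelihood_ratio(model, y, 2, 1)
        )

    def test_unknown_class_raises(self, rng):
        model = fit_decoder(
            feature_table(rng.normal(size=(8, 1)), [1] * 4 + [2] * 4)
        )
        with pytest.raises(KeyError):
            likelihood_ratio(model, np.array([0.0]), 1, 9)

    def test_wrong_feature_width_raises(self, rng):
        model = fit_decoder(
            feature_table(rng.normal(size=(8, 2)), [1] * 4 + [2] * 4)
        )
        with pytest.raises(ValueError, match="length"):
            model.class_log_likelihood(np.zeros(3), 1)


class TestDecisions:
    def test_boundary_goes_to_null_side(self):
        assert decide_binary(0.0, 1.0, class_a=1, class_b=2) == 1

    def test_negative_log_lr_picks_alternative(self):
        assert decide_binary(-0.1, 1.0, class_a=1, class_b=2) == 2

    def test_threshold_shift(self):
        # theta = e^2: log threshold 2, so log LR = 1 is below it
        assert decide_binary(1.0, np.exp(2.0), class_a=1, class_b=2) == 2

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            decide_binary(0.0, 0.0, 1, 2)

    def test_multiclass_argmax_and_ties(self, rng):
        vals = np.vstack(
            [rng.normal(c * 3.0, 0.5, size=(8, 1)) for c in range(3)]
        )
        model = fit_decoder(feature_table(vals, np.repeat([1, 2, 3], 8)))
        assert predict_multiclass(model, np.array([3.0])) == 2
        # exact tie: identical densities for classes 1 and 3
        shared = rng.normal(size=(5, 1))
        tie_model = fit_decoder(
            feature_table(
                np.vstack([shared, shared + 50.0, shared]),
                np.repeat([1, 2, 3], 5),
            )
        )
        y = np.array([float(shared.mean())])
        assert predict_multiclass(tie_model, y) == 1  # lowest label wins

    def test_binary_multiclass_agreement_at_unit_theta(self, rng):
        a = rng.normal(0, 1, size=(40, 2))
        b = rng.normal(1.5, 1, size=(40, 2))
        model = fit_decoder(feature_table(np.vstack([a, b]), [1] * 40 + [2] * 40))
        for _ in range(25):
            y = rng.normal(0.75, 2.0, size=2)
            lr = likelihood_ratio(model, y, 1, 2)
            assert decide_binary(lr, 1.0, 1, 2) == predict_multiclass(model, y)

    def test_monotonicity_in_density_ratio(self, rng):
        """Increasing the evidence for class a never flips a to b."""
        a = rng.normal(0, 1, size=(30, 1))
        b = rng.normal(3, 1, size=(30, 1))
        model = fit_decoder(feature_table(np.vstack([a, b]), [1] * 30 + [2] * 30))
        ys = np.linspace(3, -3, 25)  # moving deeper into class a's support
        lrs = [likelihood_ratio(model, np.array([y]), 1, 2) for y in ys]
        decisions = [decide_binary(lr, 1.0, 1, 2) for lr in lrs]
        # once the decision reaches class a it stays there
        first_a = decisions.index(1) if 1 in decisions else len(decisions)
        assert all(d == 1 for d in decisions[first_a:])


class TestBayesOracle:
    def test_sign_agreement_with_closed_form_rule(self, rng):
        """N(0,1) vs N(3,1): the Bayes rule thresholds at 1.5."""
        n = 1000
        a = rng.normal(0, 1, size=(n, 1))
        b = rng.normal(3, 1, size=(n, 1))
        model = fit_decoder(
            feature_table(np.vstack([a, b]), [1] * n + [2] * n)
        )
        ytest = rng.uniform(-2, 5, size=400)
        agree = 0
        for y in ytest:
            kde_says = predict_multiclass(model, np.array([y]))
            bayes_says = 1 if y < 1.5 else 2
            agree += kde_says == bayes_says
        assert agree / len(ytest) >= 0.98


class TestPredictTable:
    def test_feature_name_mismatch_raises(self, rng):
        model = fit_decoder(
            feature_table(rng.normal(size=(8, 2)), [1] * 4 + [2] * 4)
        )
        other = feature_table(
            rng.normal(size=(4, 2)), [1, 1, 2, 2], names=("x", "y")
        )
        with pytest.raises(ValueError, match="mismatch"):
            predict_table(model, other)

    def test_joint_kde_mode_decodes(self, rng):
        a = rng.normal(0, 1, size=(60, 2))
        b = rng.normal(4, 1, size=(60, 2))
        table = feature_table(np.vstack([a, b]), [1] * 60 + [2] * 60)
        model = fit_decoder(table, joint=True)
        result = predict_table(model, table)
        assert result.accuracy > 95.0
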