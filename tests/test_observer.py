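"""Two-stage observer: likelihood mixtures, posteriors, variants."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dotlattice import (
    InvalidConditionError,
    InvalidParameterError,
    ObserverParams,
    TrialCondition,
    cumulative_mapping,
    l1_likelihood,
    l1_posterior,
    l1_response_probs,
    l2_predict,
    make_prior,
    perceptual_prior,
    predict_trial,
    predict_trial_averaged,
    stimulus_frequency,
    vm_pdf,
)
from dotlattice.observer import ar_weights, l1_mapping

from conftest import ARS, logit


class TestParams:
    def test_baseline_accepted(self, baseline):
        assert baseline.c_stim == 5.0
        assert baseline.kappa_sensL2 == 18.0
        assert baseline.w_stimL1 == 0.60

    @pytest.mark.parametrize(
        "kwargs",
        [dict(c_stim=0.0), dict(w_stimL1=1.2), dict(kappa_percL1=-1.0),
         dict(prior_kind="flat"), dict(variant="full")],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(InvalidParameterError):
            ObserverParams(**kwargs)

    def test_sensory_precision_ordering_warns(self):
        with pytest.warns(UserWarning, match="kappa_sensL2"):
            ObserverParams(kappa_sensL1=10.0)


class TestL1:
    def test_ar_weights_symmetric_at_one(self):
        assert ar_weights(1.0, 5.0) == (0.5, 0.5)

    def test_ar_weights_arithmetic(self):
        # 1/(1 + 1.3^-5) for the 0-deg component when AR favors it
        w0, w90 = ar_weights(1 / 1.3, 5.0)
        assert w0 == pytest.approx(0.7878177694, abs=1e-9)
        w0r, w90r = ar_weights(1.3, 5.0)
        assert w90r == pytest.approx(0.7878177694, abs=1e-9)

    def test_likelihood_bimodal(self, baseline, grid, uniform_prior):
        mapping = l1_mapping(baseline, grid)
        lik = l1_likelihood(TrialCondition(1.0, 0.0), baseline, mapping)
        peaks = np.argsort(lik.values)[-2:]
        assert set(grid.points[peaks]) == {0.0, 90.0}

    def test_uniform_prior_posterior_equals_likelihood(self, baseline, grid, uniform_prior):
        cond = TrialCondition(1 / 1.2, 0.0)
        mapping = l1_mapping(baseline, grid)
        lik = l1_likelihood(cond, baseline, mapping)
        post = l1_posterior(cond, baseline, uniform_prior, mapping)
        assert np.abs(post.values - lik.values).max() < 1e-12

    def test_natural_prior_pulls_to_cardinals(self, baseline, grid, natural_prior):
        params = baseline.with_(prior_kind="natural")
        mapping = l1_mapping(params, grid)
        post = l1_posterior(TrialCondition(1.0, 0.0), params, natural_prior, mapping)
        assert post.at(0.0) > post.at(45.0)

    def test_response_probs_sum_to_one(self, baseline):
        pred = predict_trial(baseline, 1.1)
        assert pred.p_l1.sum() == pytest.approx(1.0, abs=1e-12)

    def test_proximity_direction(self, baseline):
        p0 = [predict_trial(baseline, ar).p0_l1 for ar in ARS]
        assert np.all(np.diff(p0) < 0)

    def test_invalid_ar_rejected(self):
        with pytest.raises(InvalidConditionError):
            TrialCondition(-1.0)


class TestBetweenLattices:
    @given(w=st.floats(0, 1))
    def test_stimulus_frequency_is_convex_mixture(self, w):
        grid_prior = make_prior("uniform", __import__("dotlattice").OrientationGrid(2.0))
        bump = perceptual_prior(grid_prior, 30.0, 10.0, 1.0)
        mix = stimulus_frequency(grid_prior, bump, w)
        expected = (1 - w) * grid_prior.values + w * bump.values
        np.testing.assert_allclose(mix.values, expected, atol=1e-9)

    def test_mixture_weight_bounds(self, uniform_prior):
        with pytest.raises(InvalidParameterError):
            stimulus_frequency(uniform_prior, uniform_prior, 1.5)
        with pytest.raises(InvalidParameterError):
            perceptual_prior(uniform_prior, 0.0, 10.0, -0.1)

    def test_perceptual_prior_limits(self, uniform_prior, grid):
        same = perceptual_prior(uniform_prior, 20.0, 10.0, 0.0)
        np.testing.assert_allclose(same.values, uniform_prior.values, atol=1e-12)
        pure = perceptual_prior(uniform_prior, 20.0, 10.0, 1.0)
        np.testing.assert_allclose(
            pure.values, vm_pdf(grid.points, 20.0, 10.0), rtol=1e-6
        )

    def test_perceptual_prior_peaks_at_percept(self, uniform_prior):
        half = perceptual_prior(uniform_prior, 60.0, 10.0, 0.5)
        assert half.at(60.0) > half.at(150.0)


class TestL2:
    def test_probs_sum_to_one(self, baseline):
        pred = predict_trial(baseline, 1.2)
        for r1 in (0.0, 90.0):
            assert pred.p_l2[r1].sum() == pytest.approx(1.0, abs=1e-12)

    def test_hysteresis_direction(self, baseline):
        for ar in ARS:
            pred = predict_trial(baseline, ar)
            assert pred.p0_l2(0.0) > pred.p0_l2(90.0)

    def test_adaptation_direction(self, baseline):
        for r1 in (0.0, 90.0):
            p0 = [predict_trial(baseline, ar).p0_l2(r1) for ar in ARS]
            assert np.all(np.diff(p0) > 0)

    def test_missing_percept_rejected(self, baseline, uniform_prior, grid):
        mapping = l1_mapping(baseline, grid)
        post = l1_posterior(TrialCondition(1.0, 0.0), baseline, uniform_prior, mapping)
        with pytest.raises(InvalidConditionError):
            l2_predict(TrialCondition(1.0, 0.0, None), baseline, uniform_prior, post)

    def test_rotation_invariance_uniform_prior(self, baseline):
        ref = predict_trial(baseline, 1 / 1.3, 0.0)
        for phi in np.arange(0.0, 180.0, 10.0):
            pred = predict_trial(baseline, 1 / 1.3, phi)
            assert abs(pred.p0_l1 - ref.p0_l1) < 1e-9
            for r1 in (0.0, 90.0):
                np.testing.assert_allclose(
                    pred.p_l2[r1], ref.p_l2[r1], atol=1e-9
                )

    def test_natural_prior_averaging_keeps_effect_directions(self, baseline):
        params = baseline.with_(prior_kind="natural")
        # coarse grid keeps the full phi loop cheap
        grid = __import__("dotlattice").OrientationGrid(2.0)
        preds = [
            predict_trial_averaged(params, ar, grid, phis=np.arange(0.0, 180.0, 2.0))
            for ar in (1 / 1.3, 1.0, 1.3)
        ]
        p0_l1 = [p.p_l1[0] for p in preds]
        assert p0_l1[0] > p0_l1[1] > p0_l1[2]
        assert all(p.p_l2[0.0][0] > p.p_l2[90.0][0] for p in preds)


class TestVariants:
    def test_stimulus_prior_has_no_hysteresis(self):
        params = ObserverParams(variant="stimulus_prior", w_percL1=0.0)
        for ar in (1 / 1.3, 1.0, 1.3):
            pred = predict_trial(params, ar)
            np.testing.assert_allclose(
                pred.p_l2[0.0], pred.p_l2[90.0], atol=1e-12
            )

    def test_no_efficient_coding_has_no_adaptation(self):
        params = ObserverParams(variant="no_efficient_coding")
        per_r1 = {r1: [predict_trial(params, ar).p0_l2(r1) for ar in ARS]
                  for r1 in (0.0, 90.0)}
        for r1 in (0.0, 90.0):
            assert np.ptp(per_r1[r1]) < 1e-10
        assert per_r1[0.0][0] - per_r1[90.0][0] > 0

    def test_no_efficient_coding_uses_identity_mapping(self, grid):
        params = ObserverParams(variant="no_efficient_coding", prior_kind="natural")
        mapping = l1_mapping(params, grid)
        np.testing.assert_allclose(mapping.image, grid.points, atol=0)

    def test_stimulus_prior_predictions_ignore_percept_weight(self):
        # the percept route is absent, so w_percL1 cannot matter
        a = ObserverParams(variant="stimulus_prior", w_percL1=0.0)
        b = ObserverParams(variant="stimulus_prior", w_percL1=0.9)
        for ar in (1 / 1.2, 1.2):
            np.testing.assert_allclose(
                predict_trial(a, ar).p_l2[0.0], predict_trial(b, ar).p_l2[0.0],
                atol=1e-12,
            )
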