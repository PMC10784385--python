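import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import norm

import calyswe as c
from calyswe.statespace import encode_state
from calyswe.valuation_models import (
    CapabilityValuationModel,
    ModelParams,
    ModelSpec,
    anchor_term,
    dce_loglik,
    tto_loglik,
    tto_mean,
)

BETA = np.array(c.TrueValueConfig().beta_true)


def small_tto(states, weights, learning=None):
    learning = learning or [False] * len(states)
    return pd.DataFrame(
        {
            "participant_id": np.arange(len(states)),
            "state": states,
            "w": weights,
            "x_years": (np.asarray(weights) * 10).astype(int),
            "is_learning": learning,
        }
    )


def small_dce(pairs, chose):
    return pd.DataFrame(
        {
            "participant_id": np.arange(len(pairs)),
            "stateA": [p[0] for p in pairs],
            "stateB": [p[1] for p in pairs],
            "chose_A": chose,
            "is_consistency": False,
        }
    )


class TestModelSpec:
    def test_discapability_excludes_anchor_scale(self):
        with pytest.raises(ValueError, match="anchor"):
            ModelSpec(coding="discapability", anchor_scale=True)

    def test_unknown_coding_rejected(self):
        with pytest.raises(ValueError, match="coding"):
            ModelSpec(coding="utility")


class TestTTOMean:
    def test_attainment_pit_state_is_the_constant(self):
        spec = ModelSpec(anchor_scale=False)
        p = ModelParams(beta=BETA, mu=0.2, sigma=0.3, theta=1.0)
        assert tto_mean(p, encode_state("111111"), spec) == pytest.approx(0.2)

    def test_discapability_forces_best_state_to_one(self):
        spec = ModelSpec(coding="discapability", anchor_scale=False)
        p = ModelParams(beta=BETA, sigma=0.3)
        assert tto_mean(p, encode_state("333333"), spec) == pytest.approx(1.0)

    def test_anchor_scale_applies_to_levels_not_constant(self):
        spec = ModelSpec()
        p = ModelParams(beta=BETA, mu=0.114, sigma=0.3, s=0.545)
        assert tto_mean(p, encode_state("111111"), spec) == pytest.approx(0.114)
        expected = 0.114 + 0.545 * BETA.sum()
        assert tto_mean(p, encode_state("333333"), spec) == pytest.approx(expected)

    def test_invalid_params_rejected(self):
        spec = ModelSpec(anchor_scale=False)
        p = ModelParams(beta=-BETA, mu=0.2)
        with pytest.raises(ValueError, match="nonnegative"):
            tto_mean(p, encode_state("111111"), spec)


class TestTTOLoglik:
    """Brute-force oracles for the censored-normal likelihood."""

    states = ["111111", "222333", "321123", "333333", "222333", "131313"]
    weights = [0.1, 0.5, 0.6, 1.0, 0.2, 0.4]
    learning = [False, False, False, False, True, False]

    def params(self):
        return ModelParams(beta=BETA, mu=0.114, sigma=0.3)

    def oracle(self, spec):
        """Term-by-term evaluation with scipy.stats.norm."""
        p = self.params()
        total = 0.0
        for s, w, lrn in zip(self.states, self.weights, self.learning):
            m = p.mu + encode_state(s) @ p.beta
            lo, hi = (0.2, 0.9) if lrn else (0.1, 1.0)
            if spec.censoring and w == lo:
                total += norm.logcdf(lo, m, p.sigma)
            elif spec.censoring and w == hi:
                total += norm.logsf(hi, m, p.sigma)
            else:
                total += norm.logpdf(w, m, p.sigma)
        return total

    def test_matches_brute_force_with_censoring(self):
        spec = ModelSpec(anchor_scale=False, censoring=True)
        data = small_tto(self.states, self.weights, self.learning)
        assert tto_loglik(self.params(), data, spec) == pytest.approx(
            self.oracle(spec), abs=1e-8
        )

    def test_matches_plain_normal_without_censoring(self):
        spec = ModelSpec(anchor_scale=False, censoring=False)
        data = small_tto(self.states, self.weights, self.learning)
        assert tto_loglik(self.params(), data, spec) == pytest.approx(
            self.oracle(spec), abs=1e-8
        )

    def test_homoskedastic_nested_in_heteroskedastic(self):
        data = small_tto(self.states, self.weights, self.learning)
        base = ModelSpec(anchor_scale=False)
        het = ModelSpec(anchor_scale=False, heteroskedastic=True)
        p0 = self.params()
        p1 = ModelParams(
            beta=BETA, mu=0.114, mu_H=np.log(0.3), beta_H=np.zeros(12)
        )
        assert tto_loglik(p1, data, het) == pytest.approx(
            tto_loglik(p0, data, base), abs=1e-10
        )

    def test_heteroskedastic_sd_follows_the_coding(self):
        het = ModelSpec(anchor_scale=False, heteroskedastic=True)
        data = small_tto(["333333"], [0.5])
        bh = np.full(12, 0.1)
        p = ModelParams(beta=BETA, mu=0.114, mu_H=np.log(0.2), beta_H=bh)
        sd = np.exp(np.log(0.2) + encode_state("333333") @ bh)
        assert tto_loglik(p, data, het) == pytest.approx(
            norm.logpdf(0.5, 0.114 + BETA.sum(), sd), abs=1e-8
        )


class TestDCELoglik:
    def test_zero_scale_gives_log_half_per_choice(self):
        pairs = [("111111", "333333"), ("222333", "111111")]
        data = small_dce(pairs, [True, False])
        p = ModelParams(beta=BETA, mu=0.1, sigma=0.3, theta=1e-300)
        spec = ModelSpec(anchor_scale=False)
        assert dce_loglik(p, data, spec) == pytest.approx(2 * np.log(0.5))

    def test_matches_term_by_term_logit(self):
        rng = np.random.default_rng(4)
        states = [
            "".join(str(d) for d in rng.integers(1, 4, 6)) for _ in range(20)
        ]
        pairs = list(zip(states[:10], states[10:]))
        chose = rng.random(10) < 0.5
        data = small_dce(pairs, chose)
        p = ModelParams(beta=BETA, mu=0.1, sigma=0.3, theta=6.0)
        spec = ModelSpec(anchor_scale=False)
        expected = 0.0
        for (a, b), ch in zip(pairs, chose):
            prob = expit(6.0 * (encode_state(a) - encode_state(b)) @ BETA)
            expected += np.log(prob if ch else 1 - prob)
        assert dce_loglik(p, data, spec) == pytest.approx(expected, abs=1e-8)

    def test_anchor_scale_never_enters_the_logit(self):
        data = small_dce([("222333", "111111")], [True])
        spec = ModelSpec(anchor_scale=True)
        lls = [
            dce_loglik(ModelParams(beta=BETA, mu=0.1, sigma=0.3, theta=6.0, s=s),
                       data, spec)
            for s in (0.5, 1.0, 2.0)
        ]
        assert lls[0] == lls[1] == lls[2]


class TestAnchorTerm:
    def test_maximum_at_exact_anchor(self):
        p = ModelParams(beta=BETA, mu=1.0 - BETA.sum(), sigma=0.3)
        expected = -np.log(0.01) - 0.5 * np.log(2 * np.pi)
        assert anchor_term(p, 0.01) == pytest.approx(expected)

    def test_penalty_is_quadratic_in_the_miss(self):
        p0 = ModelParams(beta=BETA, mu=1.0 - BETA.sum(), sigma=0.3)
        p1 = ModelParams(beta=BETA, mu=1.03 - BETA.sum(), sigma=0.3)
        assert anchor_term(p0) - anchor_term(p1) == pytest.approx(
            (0.03 / 0.01) ** 2 / 2, rel=1e-6
        )


@pytest.fixture(scope="module")
def map_fit(engaged_survey):
    model = CapabilityValuationModel(method="map", random_state=0)
    return model.fit(engaged_survey["tto"], engaged_survey["dce"])


class TestFitting:
    def test_empty_tto_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            CapabilityValuationModel().fit(pd.DataFrame())

    def test_hybrid_requires_dce(self, engaged_survey):
        with pytest.raises(ValueError, match="DCE"):
            CapabilityValuationModel().fit(engaged_survey["tto"], None)

    def test_map_fit_recovers_plausible_scale(self, map_fit):
        p = map_fit.params_
        assert 0.15 < p.sigma < 0.45
        assert 0.0 < p.mu < 0.3
        # the anchor pseudo-observation pins the mode's summed weight
        m = map_fit.map_params_
        assert abs(m.mu + m.beta.sum() - 1.0) < 0.03

    def test_map_fit_is_deterministic(self, engaged_survey, map_fit):
        again = CapabilityValuationModel(method="map", random_state=0).fit(
            engaged_survey["tto"], engaged_survey["dce"]
        )
        pd.testing.assert_frame_equal(again.summary_, map_fit.summary_)

    def test_summary_brackets_the_mean(self, map_fit):
        s = map_fit.summary_
        assert (s["ci_low"] <= s["mean"] + 1e-12).all()
        assert (s["mean"] <= s["ci_high"] + 1e-12).all()

    def test_discapability_fit_pins_best_state(self, engaged_survey):
        model = CapabilityValuationModel(
            method="map", coding="discapability", anchor_scale=False,
            random_state=0,
        ).fit(engaged_survey["tto"], engaged_survey["dce"])
        tariff = model.predict_weights()
        w333333 = tariff.loc[tariff["state"] == "333333", "weight"].iloc[0]
        assert w333333 == pytest.approx(1.0, abs=1e-12)

    def test_varying_intercept_map_fit_runs(self, engaged_survey):
        model = CapabilityValuationModel(
            method="map", varying_intercept=True, anchor_scale=False,
            use_dce=False, random_state=0,
        ).fit(engaged_survey["tto"])
        assert model.params_.omega > 0
        assert len(model.params_.b) == engaged_survey["tto"][
            "participant_id"
        ].nunique()

    def test_unknown_method_rejected(self, engaged_survey):
        with pytest.raises(ValueError, match="method"):
            CapabilityValuationModel(method="vibes").fit(
                engaged_survey["tto"], engaged_survey["dce"]
            )


class TestPrediction:
    def test_tariff_covers_all_states_with_bands(self, map_fit):
        tariff = map_fit.predict_weights()
        assert len(tariff) == 729
        assert tariff["state"].is_unique
        assert (tariff["ci_low"] <= tariff["weight"]).all()
        assert (tariff["weight"] <= tariff["ci_high"]).all()

    def test_pit_weight_is_posterior_mean_constant(self, map_fit):
        tariff = map_fit.predict_weights()
        mu = map_fit.summary_.set_index("parameter").loc["mu", "mean"]
        w = tariff.loc[tariff["state"] == "111111", "weight"].iloc[0]
        assert w == pytest.approx(mu, abs=1e-9)

    def test_dominance_monotone_for_every_draw(self, map_fit):
        # nonnegative increments force monotonicity draw by draw
        draws = map_fit.samples_[[f"beta[{i}]" for i in range(12)]].to_numpy()
        assert (draws >= 0).all()
        assert c.interface.check_monotone(map_fit.predict_weights())

    def test_unfitted_model_refuses_to_predict(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            CapabilityValuationModel().predict_weights()

    def test_estimator_clones_with_sklearn(self):
        from sklearn.base import clone

        m = CapabilityValuationModel(censoring=False, random_state=3)
        m2 = clone(m)
        assert m2.get_params() == m.get_params()
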