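import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from kneebis import glmm
from kneebis import synthetic as syn
from kneebis.errors import EstimationError, UsageError
from kneebis.glmm import LATENT_RESIDUAL_VAR, ModelSpec, marginal_loglik


def dense_grid_loglik(y, X, groups, gamma, sigma_u, half_width=12.0, n=4001):
    """Brute-force oracle: per-group trapezoid integration on a fixed grid."""
    eta0 = X @ gamma
    J = int(groups.max()) + 1
    u = np.linspace(-half_width * sigma_u, half_width * sigma_u, n)
    phi = np.exp(-(u**2) / (2 * sigma_u**2)) / math.sqrt(2 * math.pi * sigma_u**2)
    total = 0.0
    for j in range(J):
        idx = groups == j
        eta = eta0[idx][:, None] + u[None, :]
        ll = y[idx][:, None] * eta - np.logaddexp(0.0, eta)
        integrand = np.exp(ll.sum(axis=0)) * phi
        total += math.log(np.trapezoid(integrand, u))
    return total


def _fixture_data(seed, n_groups=8, per_group=6):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(n_groups), per_group)
    X = np.column_stack([
        np.ones(len(groups)),
        rng.normal(0.0, 1.0, len(groups)),
    ])
    gamma = np.array([-0.4, 0.8])
    u = rng.normal(0.0, 1.0, n_groups)
    y = (rng.random(len(groups)) < expit(X @ gamma + u[groups])).astype(float)
    return y, X, groups, gamma


class TestMarginalLoglik:
    @pytest.mark.parametrize("sigma", [0.1, 1.0, 3.0])
    def test_matches_dense_grid_oracle(self, sigma):
        y, X, groups, gamma = _fixture_data(seed=5)
        ours = marginal_loglik(y, X, groups, gamma, sigma, n_nodes=25)
        oracle = dense_grid_loglik(y, X, groups, gamma, sigma)
        assert ours == pytest.approx(oracle, rel=1e-6)

    def test_sigma_zero_is_plain_logistic(self):
        y, X, groups, gamma = _fixture_data(seed=6)
        eta = X @ gamma
        plain = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        assert marginal_loglik(y, X, groups, gamma, 0.0) == plain

    def test_single_observation_against_trapezoid(self):
        # one participant, one y=1, intercept-only, gamma=0, sigma=1
        y = np.array([1.0])
        X = np.ones((1, 1))
        groups = np.array([0])
        u = np.linspace(-12, 12, 2001)
        phi = np.exp(-(u**2) / 2) / math.sqrt(2 * math.pi)
        oracle = math.log(np.trapezoid(expit(u) * phi, u))
        ours = marginal_loglik(y, X, groups, np.zeros(1), 1.0, n_nodes=25)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_doubling_participants_doubles_loglik(self):
        y, X, groups, gamma = _fixture_data(seed=7)
        y2 = np.concatenate([y, y])
        X2 = np.vstack([X, X])
        groups2 = np.concatenate([groups, groups + groups.max() + 1])
        one = marginal_loglik(y, X, groups, gamma, 1.3)
        two = marginal_loglik(y2, X2, groups2, gamma, 1.3)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_nonfinite_predictor_raises_with_row(self):
        y, X, groups, gamma = _fixture_data(seed=8)
        X = X.copy()
        X[3, 1] = np.inf
        with pytest.raises(FloatingPointError, match="row 3"):
            marginal_loglik(y, X, groups, gamma, 1.0)


class TestFit:
    def test_exp_bookkeeping(self, reference_cohort):
        fit = glmm.fit(ModelSpec(name="model1"), reference_cohort)
        for term in fit.terms:
            assert fit.odds_ratios[term] == pytest.approx(
                math.exp(fit.coefficients[term]), rel=1e-12)
        # a coefficient of 3.996 must be reported as OR exp(3.996) = 54.4
        assert math.exp(3.996) == pytest.approx(54.37, abs=0.05)

    def test_one_class_outcome_raises(self, reference_cohort):
        df = reference_cohort.copy()
        df["pain"] = 0
        with pytest.raises(EstimationError, match="single class"):
            glmm.fit(ModelSpec(name="model1"), df)

    def test_degenerate_column_named(self, reference_cohort):
        df = reference_cohort.copy()
        df["plr128_cv"] = 0.0
        with pytest.raises(EstimationError, match="plz_cv"):
            glmm.fit(ModelSpec(name="model1"), df)

    def test_group_term_refused_on_oa_only_data(self, reference_cohort):
        df = reference_cohort[reference_cohort["group"] == 1]
        with pytest.raises(EstimationError, match="group"):
            glmm.fit(ModelSpec(name="model1"), df)
        # model 3 runs fine on the same subset
        fit3 = glmm.fit(ModelSpec(name="model3"), df)
        assert fit3.n_groups == df["participant_id"].nunique()

    def test_deterministic(self, reference_cohort):
        f1 = glmm.fit(ModelSpec(name="null"), reference_cohort)
        f2 = glmm.fit(ModelSpec(name="null"), reference_cohort)
        assert f1.coefficients == f2.coefficients
        assert f1.sigma_u2 == f2.sigma_u2

    def test_group_coding_equivariance(self, reference_cohort):
        fit_a = glmm.fit(ModelSpec(name="model2"), reference_cohort)
        flipped = reference_cohort.copy()
        flipped["group"] = 1 - flipped["group"]
        fit_b = glmm.fit(ModelSpec(name="model2"), flipped)
        a, b = fit_a.coefficients, fit_b.coefficients
        assert b["group"] == pytest.approx(
            -(a["group"]), abs=2e-2)
        assert b["plz_mean"] == pytest.approx(
            a["plz_mean"] + a["plz_mean:group"], abs=1e-3)
        assert b["plz_mean:group"] == pytest.approx(
            -a["plz_mean:group"], abs=1e-3)
        assert fit_b.loglik == pytest.approx(fit_a.loglik, abs=1e-4)

    def test_quadrature_stability(self, reference_cohort):
        f25 = glmm.fit(ModelSpec(name="model2", quadrature_nodes=25),
                       reference_cohort)
        f51 = glmm.fit(ModelSpec(name="model2", quadrature_nodes=51),
                       reference_cohort)
        for term in f25.terms:
            assert f51.coefficients[term] == pytest.approx(
                f25.coefficients[term], abs=1e-4)

    def test_quasi_separation_flagged_not_fatal(self):
        rng = np.random.default_rng(3)
        n = 120
        x = rng.normal(400, 30, n)
        df = pd.DataFrame({
            "participant_id": np.repeat([f"S{i}" for i in range(10)], 12),
            "group": np.repeat([0, 1] * 5, 12),
            "config": "trans",
            "plr128_mean": x,
            "plr128_cv": np.abs(rng.normal(3, 1, n)),
            "plx40_mean": -x * 0.07,
            "plx40_cv": np.abs(rng.normal(3, 1, n)),
            "pain": (x > 400).astype(int),  # perfectly separated by plz
        })
        fit = glmm.fit(ModelSpec(name="model1"), df)
        assert fit.quasi_separated


class TestICC:
    def _null_fit_with_sigma2(self, sigma_u2, reference_cohort):
        fit = glmm.fit(ModelSpec(name="null"), reference_cohort)
        fit.sigma_u2 = sigma_u2
        return fit

    def test_equal_variances(self, reference_cohort):
        fit = self._null_fit_with_sigma2(LATENT_RESIDUAL_VAR, reference_cohort)
        assert glmm.icc(fit) == pytest.approx(0.5)

    def test_zero_variance(self, reference_cohort):
        fit = self._null_fit_with_sigma2(0.0, reference_cohort)
        assert glmm.icc(fit) == 0.0

    def test_printed_value_solved(self, reference_cohort):
        # oracle: sigma^2 = 0.586/(1-0.586) * pi^2/3 = 4.65667
        fit = self._null_fit_with_sigma2(4.657, reference_cohort)
        assert glmm.icc(fit) == pytest.approx(0.586, abs=5e-4)

    def test_monotone_in_sigma2(self, reference_cohort):
        fits = [self._null_fit_with_sigma2(s, reference_cohort)
                for s in (0.5, 1.0, 2.0, 4.0)]
        iccs = [glmm.icc(f) for f in fits]
        assert iccs == sorted(iccs)

    def test_non_null_spec_rejected(self, reference_cohort):
        fit = glmm.fit(ModelSpec(name="model1"), reference_cohort)
        with pytest.raises(UsageError):
            glmm.icc(fit)

    def test_complement_is_within_person_share(self, reference_cohort):
        fit = glmm.fit(ModelSpec(name="null"), reference_cohort)
        assert glmm.icc(fit) + (1 - glmm.icc(fit)) == 1.0
        assert 0 <= glmm.icc(fit) <= 1


@pytest.fixture(scope="module")
def family(recovery_truth):
    df = syn.simulate_reduced_cohort(
        40, recovery_truth, seed=19, calls_per_participant=16)
    # duplicate as both configurations so all 12 fits run
    other = df.copy()
    other["config"] = "long"
    return glmm.run_model_family(pd.concat([df, other], ignore_index=True))


class TestModelFamily:
    def test_cardinality_and_labels(self, family):
        assert len(family) == 12
        names = {k[0] for k in family}
        assert names == {"model1", "model2", "model3"}
        for (name, metric, cfg), fit in family.items():
            assert fit.spec.metric == metric
            assert fit.spec.configuration == cfg
            if name == "model3":
                assert fit.spec.subset == "oa_only"
                assert "group" not in fit.terms

    def test_family_table_shape(self, family):
        table = glmm.family_table(family)
        assert set(table.columns) == {"model", "metric", "config", "term",
                                      "estimate", "exp_estimate", "se", "p"}
        assert len(table) == sum(len(f.terms) for f in family.values())

    def test_interaction_power(self, recovery_truth):
        # strong PLZxGroup interaction: model 2 should reject at alpha=.05
        # in nearly every replicate (scaled-down power harness)
        truth = syn.GroundTruth(
            gamma00=-1.4, gamma01=-7.2, gamma10=0.0, gamma20=0.0,
            gamma11=0.02, gamma21=0.0, sigma_u=0.8)
        hits = 0
        n_rep = 8
        for rep in range(n_rep):
            df = syn.simulate_reduced_cohort(80, truth, seed=100 + rep)
            fit = glmm.fit(ModelSpec(name="model2"), df)
            hits += fit.p["plz_mean:group"] < 0.05
        assert hits >= math.ceil(0.8 * n_rep)


class TestLRT:
    def test_nested_pair(self, reference_cohort):
        full = glmm.fit(ModelSpec(name="model2"), reference_cohort)
        reduced = glmm.fit(ModelSpec(name="model1"), reference_cohort)
        stat, df, p = glmm.lrt(full, reduced)
        assert stat >= -1e-6
        assert df == 2
        assert 0 <= p <= 1
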