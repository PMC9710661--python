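import numpy as np
import pytest

from denvar._errors import DegenerateInputError
from denvar.association_tests import (
    _cox_fixed_ll,
    _CoxParts,
    cox_frailty_lrt,
    coxph_label_lrt,
    kaplan_meier_by_group,
    linear_wald_test,
    lmm_variance_lrt,
)
from denvar.cohort_clustering import ClusterLabels
from denvar.density_distance import (
    DistanceMatrix,
    estimate_cohort_densities,
    jsd_matrix,
    to_similarity,
)


def _labels(values):
    values = np.asarray(values)
    return ClusterLabels(
        subject_ids=[f"s{i}" for i in range(values.size)],
        labels=values,
        method="manual",
    )


def _flip(Z):
    return _labels(1 - Z.labels)


@pytest.fixture(scope="module")
def cohort_similarity(small_cohort):
    """exp(-JSD) similarity of the well-separated two-group cohort."""
    samples, truth = small_cohort
    D = jsd_matrix(estimate_cohort_densities(samples))
    return to_similarity(D), truth


class TestLinearWald:
    def test_equal_group_means_give_null_result(self):
        y = np.tile([1.0, 2.0, 3.0], 10)
        Z = _labels(np.tile([0, 1, 0], 10))
        res = linear_wald_test(y, Z)
        assert res.statistic < 0.5
        assert res.p_value > 0.4

    def test_strong_signal_detected(self, rng):
        Z = _labels(rng.integers(0, 2, 100))
        y = Z.labels + 0.05 * rng.normal(size=100)
        res = linear_wald_test(y, Z)
        assert res.p_value < 1e-6

    def test_relabeling_preserves_p_and_flips_coefficient(self, rng):
        Z = _labels(rng.integers(0, 2, 60))
        y = 0.5 * Z.labels + rng.normal(size=60)
        a = linear_wald_test(y, Z)
        b = linear_wald_test(y, _flip(Z))
        assert a.p_value == pytest.approx(b.p_value, rel=1e-9)
        ca, cb = a.effect["coef_group_1"], b.effect["coef_group_1"]
        assert ca == pytest.approx(-cb, rel=1e-9)

    def test_single_group_errors(self):
        with pytest.raises(DegenerateInputError):
            linear_wald_test(np.arange(10.0), _labels(np.zeros(10, dtype=int)))

    def test_collinear_design_errors(self, rng):
        Z = _labels(rng.integers(0, 2, 30))
        C = Z.labels.astype(float)  # duplicates the dummy column
        with pytest.raises(DegenerateInputError):
            linear_wald_test(rng.normal(size=30), Z, C)

    def test_covariate_adjustment_absorbs_confounding(self, rng):
        age = rng.normal(size=200)
        Z = _labels((age + 0.3 * rng.normal(size=200) > 0).astype(int))
        y = 2.0 * age + rng.normal(size=200)
        unadj = linear_wald_test(y, Z)
        adj = linear_wald_test(y, Z, C=age)
        assert unadj.p_value < 1e-6  # confounded
        assert adj.p_value > 0.01


def _exp_survival(rng, n, hr=2.0, base=0.1, censor_rate=0.03):
    z = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (base * hr**z))
    c = rng.exponential(1.0 / censor_rate, size=n)
    return np.minimum(t, c), (t <= c).astype(int), z


class TestCoxphLabelLrt:
    def test_gamma_matches_internal_breslow_newton(self, rng):
        # lifelines (Efron) vs our own Breslow fit: identical without ties
        time, event, z = _exp_survival(rng, 80)
        res = coxph_label_lrt(time, event, _labels(z))
        parts = _CoxParts(time, event)
        _, beta = _cox_fixed_ll(parts, z.astype(float))
        assert np.log(res.effect["hazard_ratio_group_1"]) == pytest.approx(
            beta[0], abs=1e-6
        )

    def test_relabeling_inverts_hazard_ratio(self, rng):
        time, event, z = _exp_survival(rng, 120)
        a = coxph_label_lrt(time, event, _labels(z))
        b = coxph_label_lrt(time, event, _flip(_labels(z)))
        assert a.p_value == pytest.approx(b.p_value, abs=1e-8)
        assert a.effect["hazard_ratio_group_1"] == pytest.approx(
            1.0 / b.effect["hazard_ratio_group_1"], rel=1e-6
        )

    def test_all_censored_errors(self):
        with pytest.raises(DegenerateInputError):
            coxph_label_lrt(
                np.arange(1.0, 11.0), np.zeros(10, dtype=int), _labels([0, 1] * 5)
            )

    def test_group_without_events_warns(self):
        time = np.arange(1.0, 11.0)
        event = np.r_[np.ones(5, dtype=int), np.zeros(5, dtype=int)]
        z = np.r_[np.zeros(5, dtype=int), np.ones(5, dtype=int)]
        with pytest.warns(UserWarning, match="no events"):
            res = coxph_label_lrt(time, event, _labels(z))
        assert res.messages


class TestLmmVarianceLrt:
    def test_identity_kernel_flagged(self, rng):
        with pytest.warns(UserWarning, match="identity"):
            res = lmm_variance_lrt(rng.normal(size=40), np.eye(40))
        assert res.messages

    def test_boundary_estimate_gives_p_one(self, cohort_similarity, rng):
        # y anti-structured: pure noise, most fits land on the boundary
        G, _ = cohort_similarity
        found_boundary = False
        for i in range(5):
            r = np.random.Generator(np.random.PCG64(100 + i))
            res = lmm_variance_lrt(r.normal(size=20), G)
            assert res.statistic >= 0.0
            if res.effect["sigma2_g"] == 0.0:
                assert res.statistic == 0.0
                assert res.p_value == 1.0
                found_boundary = True
        assert found_boundary

    def test_structured_signal_detected(self, cohort_similarity, rng):
        G, truth = cohort_similarity
        L = np.linalg.cholesky(G.values + 1e-8 * np.eye(20))
        y = 3.0 * (L @ rng.normal(size=20)) + 0.3 * rng.normal(size=20)
        res = lmm_variance_lrt(y, G)
        assert res.effect["sigma2_g"] > 0.0
        assert res.p_value < 0.05

    def test_unbiased_recovery_with_identified_kernel(self):
        # 40 blocks of 5 with rho=0.6: plenty of independent contrasts, so
        # ML should recover the variance component without material bias
        rng = np.random.Generator(np.random.PCG64(4))
        n = 200
        blocks = np.repeat(np.arange(40), 5)
        G = 0.6 * (blocks[:, None] == blocks[None, :]).astype(float)
        np.fill_diagonal(G, 1.0)
        L = np.linalg.cholesky(G)
        ests = []
        for _ in range(50):
            y = np.sqrt(2.0) * (L @ rng.normal(size=n)) + rng.normal(size=n)
            ests.append(lmm_variance_lrt(y, G).effect["sigma2_g"])
        ests = np.asarray(ests)
        mcse = ests.std(ddof=1) / np.sqrt(ests.size)
        assert abs(ests.mean() - 2.0) <= 2.0 * mcse

    def test_agrees_with_direct_mvn_likelihood_oracle(self, cohort_similarity, rng):
        # independent route: maximize the exact N(X beta, s2g*G + s2*I)
        # log-likelihood over (log s2g, log s2) with a generic optimizer
        from scipy import optimize
        from scipy.stats import multivariate_normal

        G, _ = cohort_similarity
        n = 20
        L = np.linalg.cholesky(G.values + 1e-8 * np.eye(n))
        y = 1.5 * (L @ rng.normal(size=n)) + rng.normal(size=n)
        ours = lmm_variance_lrt(y, G)

        X = np.ones((n, 1))

        def negll(params):
            s2g, s2 = np.exp(params)
            V = s2g * G.values + s2 * np.eye(n)
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
            return -multivariate_normal.logpdf(
                y, mean=(X @ beta).ravel(), cov=V, allow_singular=True
            )

        best = min(
            (
                optimize.minimize(negll, x0, method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12})
                for x0 in ([0.0, 0.0], [1.0, -1.0], [-1.0, 0.5])
            ),
            key=lambda r: r.fun,
        )
        s2g_oracle = float(np.exp(best.x[0]))
        assert ours.effect["sigma2_g"] == pytest.approx(
            s2g_oracle, rel=1e-3, abs=1e-3
        )


class TestCoxFrailtyLrt:
    def test_strong_frailty_detected(self):
        rng = np.random.Generator(np.random.PCG64(7))
        n = 200
        blocks = np.repeat([0, 1, 2, 3], n // 4)
        G = 0.9 * (blocks[:, None] == blocks[None, :]).astype(float)
        np.fill_diagonal(G, 1.0)
        L = np.linalg.cholesky(G + 1e-8 * np.eye(n))
        g = L @ rng.normal(size=n)  # sigma2 = 1
        t = rng.exponential(np.exp(-g) / 0.1)
        c = rng.exponential(1.0 / 0.02, size=n)
        res = cox_frailty_lrt(np.minimum(t, c), (t <= c).astype(int), G)
        assert res.effect["sigma2"] > 0.0
        assert res.p_value < 0.05

    def test_small_sample_warns(self, cohort_similarity, rng):
        G, _ = cohort_similarity
        t = rng.exponential(10.0, size=20)
        with pytest.warns(UserWarning, match="N=200"):
            cox_frailty_lrt(t, np.ones(20, dtype=int), G)

    def test_degenerate_input_errors(self):
        with pytest.raises(DegenerateInputError):
            cox_frailty_lrt(np.ones(10), np.ones(10, dtype=int), np.eye(10))

    def test_null_data_yields_valid_conservative_result(self, cohort_similarity):
        G, _ = cohort_similarity
        rng = np.random.Generator(np.random.PCG64(3))
        t = rng.exponential(10.0, size=20)
        with pytest.warns(UserWarning):
            res = cox_frailty_lrt(t, np.ones(20, dtype=int), G)
        assert res.statistic >= 0.0
        assert 0.0 <= res.p_value <= 1.0


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curves = kaplan_meier_by_group(
            np.arange(1.0, 6.0), np.zeros(5, dtype=int), _labels(np.zeros(5, int))
        )
        assert np.allclose(curves[0]["survival"], 1.0)

    def test_three_events_product_limit(self):
        curves = kaplan_meier_by_group(
            np.array([1.0, 2.0, 3.0]), np.ones(3, dtype=int), _labels([0, 0, 0])
        )
        sf = curves[0].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(2 / 3)
        assert sf.loc[2.0] == pytest.approx(1 / 3)
        assert sf.loc[3.0] == pytest.approx(0.0)

    def test_interleaved_censoring_matches_hand_table(self):
        # events at 1, 3, 5; censored at 2, 4:
        # S(1)=4/5, S(3)=4/5*(2/3)=8/15, S(5)=0
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 0, 1, 0, 1])
        curves = kaplan_meier_by_group(time, event, _labels([0] * 5))
        sf = curves[0].set_index("time")["survival"]
        assert sf.loc[1.0] == pytest.approx(0.8)
        assert sf.loc[3.0] == pytest.approx(8 / 15)
        assert sf.loc[5.0] == pytest.approx(0.0)

    def test_plot_written(self, tmp_path, rng):
        t, e, z = _exp_survival(rng, 40)
        out = tmp_path / "km.png"
        kaplan_meier_by_group(t, e, _labels(z), plot_path=str(out),
                              annotation="HR = 2.0")
        assert out.stat().st_size > 0
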