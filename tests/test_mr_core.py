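"""GLS-IVW estimation, heterogeneity, pruning and canonical orientation."""

import numpy as np
import pytest
from scipy import stats

from targetmr.mr_core import (
    MRInput,
    MVMRInput,
    gls_ivw,
    heterogeneity_q,
    mvmr_gls,
    orient_canonical,
    prune_leverage_outliers,
)
from targetmr.synthetic_data import gen_ld_ar1


def make_input(b_x, b_y, s_y, rho=None, **kw):
    b_x = np.asarray(b_x, dtype=float)
    m = b_x.size
    return MRInput(
        b_x=b_x,
        s_x=np.full(m, 0.01),
        b_y=np.asarray(b_y, dtype=float),
        s_y=np.asarray(s_y, dtype=float),
        rho=np.eye(m) if rho is None else rho,
        **kw,
    )


class TestGlsIvw:
    def test_single_instrument_is_wald_ratio(self):
        res = gls_ivw(make_input([0.5], [0.1], [0.05]))
        theta, se, _ = res.single()
        assert theta == pytest.approx(0.2, abs=1e-12)
        assert se == pytest.approx(0.1, abs=1e-12)

    def test_identity_rho_equals_textbook_ivw(self, rng):
        for _ in range(1000):
            m = int(rng.integers(2, 8))
            b_x = rng.normal(0, 0.3, m)
            b_y = rng.normal(0, 0.1, m)
            s_y = rng.uniform(0.01, 0.2, m)
            res = gls_ivw(make_input(b_x, b_y, s_y))
            w = b_x**2 / s_y**2
            expected = np.sum(b_x * b_y / s_y**2) / np.sum(w)
            assert res.theta[0] == pytest.approx(expected, abs=1e-10)
            assert res.se[0] == pytest.approx(1 / np.sqrt(np.sum(w)), abs=1e-10)

    def test_correlated_two_instrument_matrix_oracle(self):
        b_x = np.array([0.3, 0.2])
        b_y = np.array([0.06, 0.05])
        s_y = np.array([0.02, 0.03])
        rho = np.array([[1.0, 0.6], [0.6, 1.0]])
        omega = np.outer(s_y, s_y) * rho
        oi = np.linalg.inv(omega)
        expected = (b_x @ oi @ b_y) / (b_x @ oi @ b_x)
        expected_se = np.sqrt(1.0 / (b_x @ oi @ b_x))
        res = gls_ivw(make_input(b_x, b_y, s_y, rho=rho))
        assert res.theta[0] == pytest.approx(expected, abs=1e-10)
        assert res.se[0] == pytest.approx(expected_se, abs=1e-10)

    def test_scale_equivariance(self, rng):
        for _ in range(50):
            m = 5
            b_x = rng.normal(0, 0.3, m)
            b_y = rng.normal(0, 0.1, m)
            s_y = rng.uniform(0.01, 0.1, m)
            rho = gen_ld_ar1(m, 0.4).r
            base = gls_ivw(make_input(b_x, b_y, s_y, rho=rho))
            c = 3.7
            scaled = gls_ivw(make_input(c * b_x, b_y, s_y, rho=rho))
            assert scaled.theta[0] == pytest.approx(base.theta[0] / c, abs=1e-10)
            assert scaled.Q == pytest.approx(base.Q, abs=1e-10)

    def test_permutation_invariance(self, rng):
        m = 6
        b_x = rng.normal(0, 0.3, m)
        b_y = rng.normal(0, 0.1, m)
        s_y = rng.uniform(0.01, 0.1, m)
        rho = gen_ld_ar1(m, 0.5).r
        base = gls_ivw(make_input(b_x, b_y, s_y, rho=rho))
        perm = rng.permutation(m)
        permuted = gls_ivw(
            make_input(b_x[perm], b_y[perm], s_y[perm], rho=rho[np.ix_(perm, perm)])
        )
        assert permuted.theta[0] == pytest.approx(base.theta[0], abs=1e-10)
        assert permuted.se[0] == pytest.approx(base.se[0], abs=1e-10)
        assert permuted.Q == pytest.approx(base.Q, abs=1e-10)

    def test_overdispersion_inflates_se_only_when_q_large(self):
        b_x = np.array([0.3, 0.3, 0.3])
        s_y = np.array([0.01, 0.01, 0.01])
        good = gls_ivw(make_input(b_x, 0.2 * b_x, s_y), overdispersion=True)
        assert good.se[0] == pytest.approx(gls_ivw(make_input(b_x, 0.2 * b_x, s_y)).se[0])
        noisy = gls_ivw(make_input(b_x, [0.09, 0.02, 0.07], s_y), overdispersion=True)
        plain = gls_ivw(make_input(b_x, [0.09, 0.02, 0.07], s_y))
        assert noisy.se[0] > plain.se[0]


class TestMvmr:
    def test_k1_reduces_to_univariable(self, rng):
        m = 5
        b_x = rng.normal(0, 0.3, m)
        b_y = rng.normal(0, 0.1, m)
        s_y = rng.uniform(0.01, 0.1, m)
        rho = gen_ld_ar1(m, 0.3).r
        uni = gls_ivw(make_input(b_x, b_y, s_y, rho=rho))
        multi = mvmr_gls(
            MVMRInput(B_x=b_x[:, None], exposure_names=["x"], b_y=b_y, s_y=s_y, rho=rho)
        )
        assert multi.theta[0] == pytest.approx(uni.theta[0], abs=1e-12)
        assert multi.se[0] == pytest.approx(uni.se[0], abs=1e-12)

    def test_orthogonal_exposures_match_univariable(self):
        # weighted-orthogonal columns: each slope equals its own IVW fit
        s_y = np.array([0.1, 0.1, 0.1, 0.1])
        B = np.array([[1.0, 0.0], [-1.0, 0.0], [0.0, 1.0], [0.0, -1.0]])
        b_y = np.array([0.5, -0.5, 0.2, -0.2])
        multi = mvmr_gls(
            MVMRInput(B_x=B, exposure_names=["a", "b"], b_y=b_y, s_y=s_y, rho=np.eye(4))
        )
        assert multi.theta[0] == pytest.approx(0.5, abs=1e-12)
        assert multi.theta[1] == pytest.approx(0.2, abs=1e-12)

    def test_k2_normal_equations_oracle(self, rng):
        m, k = 7, 2
        B = rng.normal(0, 0.3, (m, k))
        b_y = rng.normal(0, 0.1, m)
        s_y = rng.uniform(0.02, 0.1, m)
        rho = gen_ld_ar1(m, 0.45).r
        oi = np.linalg.inv(np.outer(s_y, s_y) * rho)
        expected = np.linalg.solve(B.T @ oi @ B, B.T @ oi @ b_y)
        cov = np.linalg.inv(B.T @ oi @ B)
        res = mvmr_gls(MVMRInput(B_x=B, exposure_names=["a", "b"], b_y=b_y, s_y=s_y, rho=rho))
        assert res.theta == pytest.approx(expected, abs=1e-10)
        assert res.se == pytest.approx(np.sqrt(np.diag(cov)), abs=1e-10)

    def test_collinear_exposures_rejected(self):
        B = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6], [0.15, 0.3]])
        with pytest.raises(ValueError, match="collinear"):
            MVMRInput(
                B_x=B, exposure_names=["ldl", "apob"], b_y=np.zeros(4),
                s_y=np.full(4, 0.1), rho=np.eye(4),
            )

    def test_recovers_direct_effects_independent_mediators(self, rng):
        # 200 Monte-Carlo replicates with known direct effects
        m, k = 20, 2
        theta_true = np.array([0.4, -0.2])
        est = np.zeros((200, k))
        for it in range(200):
            B = rng.normal(0, 0.3, (m, k))
            s_y = np.full(m, 0.05)
            b_y = B @ theta_true + rng.normal(0, 0.05, m)
            res = mvmr_gls(
                MVMRInput(B_x=B, exposure_names=["m1", "m2"], b_y=b_y, s_y=s_y, rho=np.eye(m))
            )
            est[it] = res.theta
        mcse = est.std(axis=0) / np.sqrt(200)
        assert np.all(np.abs(est.mean(axis=0) - theta_true) < 3 * mcse)


class TestHeterogeneityQ:
    def test_perfect_fit_gives_zero(self):
        inp = make_input([0.1, 0.2, 0.3], [0.05, 0.10, 0.15], [0.01, 0.01, 0.01])
        res = gls_ivw(inp)
        q, df, p = heterogeneity_q(inp, res.theta)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert p == pytest.approx(1.0)

    def test_diagonal_case_matches_hand_sum(self, rng):
        m = 6
        inp = make_input(
            rng.normal(0, 0.3, m), rng.normal(0, 0.1, m), rng.uniform(0.01, 0.1, m)
        )
        res = gls_ivw(inp)
        q, df, _ = heterogeneity_q(inp, res.theta)
        hand = np.sum(((inp.b_y - res.theta[0] * inp.b_x) / inp.s_y) ** 2)
        assert q == pytest.approx(hand, abs=1e-10)
        assert df == m - 1

    def test_df_is_m_minus_k(self):
        inp = make_input([0.1] * 5, [0.02] * 5, [0.01] * 5)
        _, df, _ = heterogeneity_q(inp, np.array([0.2]))
        assert df == 4

    def test_df_below_one_withholds_p(self):
        inp = make_input([0.1], [0.02], [0.01])
        q, df, p = heterogeneity_q(inp, np.array([0.2]))
        assert df == 0 and p is None


class TestPruning:
    def _homogeneous(self, rng, m=12, theta=0.3):
        b_x = rng.uniform(0.2, 0.4, m) * rng.choice([-1, 1], m)
        s_y = np.full(m, 0.02)
        b_y = theta * b_x + rng.normal(0, 0.004, m)  # noise well below s_y
        return make_input(b_x, b_y, s_y)

    def test_homogeneous_data_no_exclusions(self, rng):
        pruned, excl = prune_leverage_outliers(self._homogeneous(rng))
        assert excl == []
        assert pruned.m == 12

    def test_planted_outlier_is_excluded(self, rng):
        inp = self._homogeneous(rng)
        inp.b_y[4] += 10 * inp.s_y[4]
        pruned, excl = prune_leverage_outliers(inp)
        assert any(key == inp.variant_keys[4] and why == "outlier" for key, why, _ in excl)
        assert inp.variant_keys[4] not in pruned.variant_keys

    def test_planted_leverage_is_flagged(self, rng):
        inp = self._homogeneous(rng)
        inp.b_x[7] *= 10.0
        inp.b_y[7] = 0.3 * inp.b_x[7] + rng.normal(0, 0.004)
        pruned, excl = prune_leverage_outliers(inp)
        assert any(key == inp.variant_keys[7] and why == "leverage" for key, why, _ in excl)

    def test_never_prunes_below_floor(self, rng):
        inp = self._homogeneous(rng, m=4)
        inp.b_y += rng.normal(0, 1.0, 4)  # everything looks like an outlier
        with pytest.warns(UserWarning, match="floor"):
            pruned, _ = prune_leverage_outliers(inp)
        assert pruned.m >= 3


class TestOrientation:
    def _result(self, theta=0.08):
        inp = make_input([0.5], [theta * 0.5], [0.05], exposure_name="CETP")
        return gls_ivw(inp)

    def test_decrease_negates_estimate(self):
        res = self._result(0.08)
        oriented = orient_canonical(res, {"CETP": "decrease"})
        assert oriented.theta[0] == pytest.approx(-res.theta[0])
        assert oriented.z[0] == pytest.approx(-res.z[0])
        assert oriented.p[0] == pytest.approx(res.p[0])
        assert oriented.orientation == "canonical"

    def test_increase_leaves_estimate(self):
        res = self._result()
        res.exposure_names = ["HDL-C"]
        oriented = orient_canonical(res, {"HDL-C": "increase"})
        assert oriented.theta[0] == res.theta[0]

    def test_orienting_twice_is_identity(self):
        res = self._result()
        once = orient_canonical(res, {"CETP": "decrease"})
        twice = orient_canonical(once, {"CETP": "decrease"})
        assert twice.theta[0] == once.theta[0]

    def test_missing_spec_errors(self):
        with pytest.raises(KeyError):
            orient_canonical(self._result(), {"PCSK9": "decrease"})


def test_wald_p_is_two_sided_normal():
    res = gls_ivw(make_input([0.5], [0.098], [0.05]))
    z = res.theta[0] / res.se[0]
    assert res.p[0] == pytest.approx(2 * stats.norm.sf(abs(z)))


def test_singular_omega_raises_helpful_error():
    rho = np.array([[1.0, 1.0], [1.0, 1.0]])
    with pytest.raises(np.linalg.LinAlgError, match="clump"):
        gls_ivw(make_input([0.3, 0.3], [0.06, 0.06], [0.01, 0.01], rho=rho))
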