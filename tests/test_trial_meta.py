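"""Trial effect extraction, pooling, heterogeneity and meta-regression."""

import math

import numpy as np
import pytest

from targetmr.gwas_io import ExclusionRecord
from targetmr.trial_meta import (
    MetaEstimate,
    PointEstimate,
    TrialOutcome,
    between_compound_q,
    compound_meta,
    effect_from_trial,
    funnel_coords,
    meta_regress,
    pool_fixed,
    pool_random,
    se_from_or_ci,
    trials_from_frame,
)


def pe(effect, se, study="s", compound="c", outcome="o", scale="logOR"):
    return PointEstimate(study, compound, outcome, effect, se, scale)


class TestEffectExtraction:
    def test_two_by_two_closed_form(self):
        t = TrialOutcome("s1", "drugA", "CVD", "binary", 10, 100, 20, 100)
        est = effect_from_trial(t)
        assert est.effect == pytest.approx(math.log(10 * 80 / (90 * 20)), abs=1e-12)
        assert est.effect == pytest.approx(-0.8109, abs=5e-5)
        assert est.se == pytest.approx(math.sqrt(1 / 10 + 1 / 90 + 1 / 20 + 1 / 80), abs=1e-12)
        assert est.se == pytest.approx(0.4167, abs=5e-5)

    def test_zero_cell_continuity_correction(self):
        t = TrialOutcome("s1", "drugA", "CVD", "binary", 0, 50, 5, 50)
        est = effect_from_trial(t)
        a, b, c, d = 0.5, 50.5, 5.5, 45.5
        assert est.effect == pytest.approx(math.log(a * d / (b * c)))
        assert est.se == pytest.approx(math.sqrt(1 / a + 1 / b + 1 / c + 1 / d))

    def test_double_zero_excluded_not_fatal(self):
        t = TrialOutcome("s1", "drugA", "CVD", "binary", 0, 50, 0, 50)
        res = effect_from_trial(t)
        assert isinstance(res, ExclusionRecord)
        assert res.reason == "double-zero-events"

    def test_se_back_transform_from_or_ci(self):
        # printed OR CI (1.14, 2.12) -> se(log-OR)
        se = se_from_or_ci(1.14, 2.12)
        assert se == pytest.approx((math.log(2.12) - math.log(1.14)) / 3.919928, abs=1e-6)
        assert se == pytest.approx(0.1583, abs=5e-5)

    def test_continuous_md_with_ci(self):
        t = TrialOutcome("s1", "drugA", "HDL-C", "continuous", md=130.0, ci_low=127.0, ci_high=133.0)
        est = effect_from_trial(t)
        assert est.effect == 130.0
        assert est.se == pytest.approx(6.0 / (2 * 1.959964))
        assert est.scale == "MD%"


class TestPoolFixed:
    def test_single_study_passthrough(self):
        m = pool_fixed([pe(0.3, 0.1)])
        assert m.effect == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1)
        assert m.k_studies == 1 and m.df == 0

    def test_two_identical_studies(self):
        m = pool_fixed([pe(0.3, 0.1), pe(0.3, 0.1)])
        assert m.effect == pytest.approx(0.3)
        assert m.se == pytest.approx(0.1 / math.sqrt(2))
        assert m.Q_within == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_weighted_mean(self):
        m = pool_fixed([pe(0.2, 0.1), pe(0.5, 0.2)])
        assert m.effect == pytest.approx(0.26, abs=1e-12)
        assert m.se == pytest.approx(1 / math.sqrt(125), abs=1e-12)
        assert m.se == pytest.approx(0.0894, abs=5e-5)

    def test_order_invariance_and_bounds(self, rng):
        ests = [pe(e, s) for e, s in zip(rng.normal(0, 1, 8), rng.uniform(0.05, 0.4, 8))]
        a = pool_fixed(ests)
        b = pool_fixed(ests[::-1])
        assert a.effect == pytest.approx(b.effect, abs=1e-14)
        effects = [e.effect for e in ests]
        assert min(effects) <= a.effect <= max(effects)

    def test_mixed_scales_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            pool_fixed([pe(0.2, 0.1, scale="logOR"), pe(5.0, 1.0, scale="MD%")])


class TestPoolRandom:
    def test_homogeneous_equals_fixed(self):
        ests = [pe(0.3, 0.1), pe(0.31, 0.1), pe(0.29, 0.1)]
        fe, re = pool_fixed(ests), pool_random(ests)
        assert re.tau2 == 0.0
        assert re.effect == pytest.approx(fe.effect)
        assert re.se == pytest.approx(fe.se)

    def test_dersimonian_laird_oracle(self):
        # independent recomputation of tau2 and the re-weighted pool
        ests = [pe(0.1, 0.1), pe(0.9, 0.15), pe(-0.4, 0.2), pe(0.5, 0.1)]
        e = np.array([x.effect for x in ests])
        w = np.array([1 / x.se**2 for x in ests])
        mu = np.sum(w * e) / np.sum(w)
        q = np.sum(w * (e - mu) ** 2)
        tau2 = max(0.0, (q - 3) / (np.sum(w) - np.sum(w**2) / np.sum(w)))
        w2 = 1 / (np.array([x.se**2 for x in ests]) + tau2)
        m = pool_random(ests)
        assert m.tau2 == pytest.approx(tau2, abs=1e-12)
        assert m.effect == pytest.approx(np.sum(w2 * e) / np.sum(w2), abs=1e-12)
        assert m.se == pytest.approx(1 / math.sqrt(np.sum(w2)), abs=1e-12)

    def test_random_se_never_below_fixed(self, rng):
        for _ in range(30):
            ests = [pe(e, s) for e, s in zip(rng.normal(0, 1, 6), rng.uniform(0.05, 0.4, 6))]
            assert pool_random(ests).se >= pool_fixed(ests).se - 1e-12
            assert pool_random(ests).tau2 >= 0

    def test_single_study_warns(self):
        with pytest.warns(UserWarning):
            m = pool_random([pe(0.3, 0.1)])
        assert m.tau2 == 0.0 and m.effect == pytest.approx(0.3)

    def test_deterministic(self):
        ests = [pe(0.1, 0.1), pe(0.5, 0.2)]
        assert pool_random(ests) == pool_random(ests)


class TestBetweenCompoundQ:
    def _me(self, effect, se, compound):
        return MetaEstimate(compound, "ACM", effect, se, 0, 0, 1, 0, 0, 0.0, 2, "fixed", "logOR")

    def test_identical_estimates_give_zero(self):
        q, df, p = between_compound_q([self._me(0.3, 0.1, "a"), self._me(0.3, 0.1, "b")])
        assert q == pytest.approx(0.0, abs=1e-15)
        assert df == 1 and p == pytest.approx(1.0)

    def test_two_compound_hand_formula(self):
        # log-ORs back-transformed from printed CIs of two discordant compounds
        e1, s1 = 0.4447, 0.1583
        e2, s2 = -0.1744, 0.0874
        w1, w2 = 1 / s1**2, 1 / s2**2
        mu = (w1 * e1 + w2 * e2) / (w1 + w2)
        expected = w1 * (e1 - mu) ** 2 + w2 * (e2 - mu) ** 2
        q, df, p = between_compound_q([self._me(e1, s1, "a"), self._me(e2, s2, "b")])
        assert q == pytest.approx(expected, abs=1e-12)
        assert df == 1
        assert p < 0.05  # the two compounds clearly disagree

    def test_four_compound_brute_force(self, rng):
        effects = rng.normal(0, 0.5, 4)
        ses = rng.uniform(0.05, 0.3, 4)
        mes = [self._me(e, s, f"c{i}") for i, (e, s) in enumerate(zip(effects, ses))]
        q, df, p = between_compound_q(mes)
        w = 1 / ses**2
        mu = np.sum(w * effects) / np.sum(w)
        assert q == pytest.approx(float(np.sum(w * (effects - mu) ** 2)), abs=1e-12)
        assert df == 3

    def test_fewer_than_two_compounds_errors(self):
        with pytest.raises(ValueError):
            between_compound_q([self._me(0.3, 0.1, "a")])


class TestMetaRegression:
    def test_exact_linear_fit_recovers_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ests = [pe(0.1 + 0.5 * xi, 0.1) for xi in x]
        res = meta_regress(ests, x)
        assert res["slope"] == pytest.approx(0.5, abs=1e-10)
        assert res["tau2"] == pytest.approx(0.0, abs=1e-10)

    def test_wls_oracle_k3(self):
        ests = [pe(0.2, 0.1), pe(0.6, 0.2), pe(0.9, 0.15)]
        x = np.array([0.0, 1.0, 2.0])
        res = meta_regress(ests, x)
        # independent weighted normal equations at the fitted tau2
        v = np.array([0.01, 0.04, 0.0225])
        w = 1 / (v + res["tau2"])
        X = np.column_stack([np.ones(3), x])
        y = np.array([0.2, 0.6, 0.9])
        beta = np.linalg.solve(X.T @ (X * w[:, None]), X.T @ (w * y))
        assert res["slope"] == pytest.approx(beta[1], abs=1e-10)

    def test_slope_invariant_under_centering(self):
        ests = [pe(0.2, 0.1), pe(0.6, 0.2), pe(0.9, 0.15), pe(0.3, 0.12)]
        x = np.array([10.0, 20.0, 30.0, 40.0])
        a = meta_regress(ests, x)
        b = meta_regress(ests, x - x.mean())
        assert a["slope"] == pytest.approx(b["slope"], abs=1e-10)

    def test_constant_covariate_errors(self):
        ests = [pe(0.2, 0.1), pe(0.6, 0.2), pe(0.9, 0.15)]
        with pytest.raises(ValueError, match="constant"):
            meta_regress(ests, np.ones(3))


class TestFunnel:
    def test_one_point_per_study_and_boundary(self):
        ests = [pe(0.2, 0.1, study="s1"), pe(0.5, 0.2, study="s2")]
        pooled = pool_fixed(ests)
        f = funnel_coords(ests, pooled)
        assert len(f["points"]) == 2
        b = f["boundary"]
        assert b.iloc[0]["low"] == pytest.approx(pooled.effect)
        assert b.iloc[0]["high"] == pytest.approx(pooled.effect)
        row = b.iloc[(b["se"] - 0.2).abs().idxmin()]
        assert row["high"] - pooled.effect == pytest.approx(1.959964 * row["se"], abs=1e-12)
        assert b["se"].max() == pytest.approx(0.2)


def test_compound_meta_groups_and_excludes(rng):
    import pandas as pd

    rows = [
        dict(study_id="a1", compound="A", outcome="CVD", type="binary",
             t_events=10, t_total=100, c_events=20, c_total=100),
        dict(study_id="a2", compound="A", outcome="CVD", type="binary",
             t_events=12, t_total=100, c_events=18, c_total=100),
        dict(study_id="b1", compound="B", outcome="CVD", type="binary",
             t_events=0, t_total=50, c_events=0, c_total=50),
        dict(study_id="b2", compound="B", outcome="CVD", type="binary",
             t_events=30, t_total=100, c_events=15, c_total=100),
    ]
    trials = trials_from_frame(pd.DataFrame(rows))
    pooled, excl = compound_meta(trials, "CVD")
    assert set(pooled) == {"A", "B"}
    assert pooled["A"].k_studies == 2
    assert pooled["B"].k_studies == 1
    assert [e.reason for e in excl] == ["double-zero-events"]
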