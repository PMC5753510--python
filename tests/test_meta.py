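"""Meta-analysis engine: effect sizes, pooling, heterogeneity, decisions."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from miriad.meta import (GroupSummary, StudyRecord, effects_from_studies,
                         forest_table, hedges_g, leave_one_out,
                         pool_random_effects, significance_rule,
                         subgroup_compare)
from miriad.meta import EffectEstimate, PooledResult
from miriad.synthetic import MetaSimConfig, simulate_meta_studies


def make_effect(g, v, study_id="s"):
    half = 1.959964 * math.sqrt(v)
    return EffectEstimate(study_id=study_id, g=g, variance=v,
                          ci_low=g - half, ci_high=g + half)


class TestHedgesG:
    def test_hand_evaluated_closed_form(self):
        # n1=n2=10, means 0/1, sds 1/1: d=1, J=1-3/71, var=(20/100)+g^2/40
        e = hedges_g(GroupSummary(10, 0.0, 1.0), GroupSummary(10, 1.0, 1.0))
        j = 1 - 3 / 71
        assert e.g == pytest.approx(j, abs=1e-6)
        assert e.g == pytest.approx(0.957746, abs=1e-6)
        assert e.variance == pytest.approx(20 / 100 + j**2 / 40, abs=1e-9)
        assert e.variance == pytest.approx(0.2229320, abs=1e-6)
        assert e.ci_low == pytest.approx(e.g - 1.959964 * math.sqrt(e.variance))

    def test_identical_means_give_zero(self):
        e = hedges_g(GroupSummary(8, 2.5, 1.2), GroupSummary(12, 2.5, 0.8))
        assert e.g == 0.0

    def test_positive_when_control_above_case(self):
        # down-regulation in disease -> positive SMD
        e = hedges_g(GroupSummary(20, 1.0, 1.0), GroupSummary(20, 2.0, 1.0))
        assert e.g > 0

    @given(
        n1=st.integers(3, 50), n2=st.integers(3, 50),
        m1=st.floats(-3, 3), m2=st.floats(-3, 3),
        s1=st.floats(0.2, 3), s2=st.floats(0.2, 3),
    )
    def test_antisymmetry_under_group_swap(self, n1, n2, m1, m2, s1, s2):
        a, b = GroupSummary(n1, m1, s1), GroupSummary(n2, m2, s2)
        assert hedges_g(a, b).g == pytest.approx(-hedges_g(b, a).g, abs=1e-12)

    def test_degenerate_zero_sd_unequal_means(self):
        with pytest.raises(ValueError, match="degenerate"):
            hedges_g(GroupSummary(5, 0.0, 0.0), GroupSummary(5, 1.0, 0.0))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            GroupSummary(1, 0.0, 1.0)


class TestPooling:
    def test_single_study_identity(self):
        e = make_effect(0.4, 0.05)
        pooled = pool_random_effects([e])
        assert pooled.smd == pytest.approx(e.g)
        assert pooled.ci_low == pytest.approx(e.ci_low)
        assert pooled.ci_high == pytest.approx(e.ci_high)
        assert pooled.df == 0 and pooled.Q == 0.0 and pooled.p_het == 1.0

    def test_two_equal_effects_hand_values(self):
        # g=0.5 with v=0.1 and v=0.2: Q=0, tau2=0, pooled=0.5, se=sqrt(1/15)
        pooled = pool_random_effects([make_effect(0.5, 0.1, "a"),
                                      make_effect(0.5, 0.2, "b")])
        assert pooled.Q == pytest.approx(0.0, abs=1e-12)
        assert pooled.tau2 == 0.0
        assert pooled.smd == pytest.approx(0.5)
        assert pooled.se == pytest.approx(math.sqrt(1 / 15), abs=1e-9)
        assert pooled.se == pytest.approx(0.258199, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_random_effects([])

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1)),
                    min_size=2, max_size=10))
    def test_random_ci_never_narrower_than_fixed(self, gv):
        effects = [make_effect(g, v, str(i)) for i, (g, v) in enumerate(gv)]
        re = pool_random_effects(effects, model="random")
        fe = pool_random_effects(effects, model="fixed")
        assert re.ci_high - re.ci_low >= fe.ci_high - fe.ci_low - 1e-12
        assert 0.0 <= re.i2 <= 100.0 and re.tau2 >= 0.0

    @given(g=st.floats(-2, 2), v=st.floats(0.01, 1), k=st.integers(2, 8))
    def test_identical_studies_pool_to_common_effect(self, g, v, k):
        effects = [make_effect(g, v, str(i)) for i in range(k)]
        pooled = pool_random_effects(effects)
        assert pooled.Q == pytest.approx(0.0, abs=1e-9)
        assert pooled.smd == pytest.approx(g, abs=1e-9)

    @given(st.lists(st.tuples(st.floats(-2, 2), st.floats(0.01, 1)),
                    min_size=2, max_size=10))
    def test_antisymmetry_of_pooled_smd(self, gv):
        effects = [make_effect(g, v, str(i)) for i, (g, v) in enumerate(gv)]
        mirrored = [make_effect(-g, v, str(i)) for i, (g, v) in enumerate(gv)]
        a, b = pool_random_effects(effects), pool_random_effects(mirrored)
        assert a.smd == pytest.approx(-b.smd, abs=1e-10)
        assert a.ci_low == pytest.approx(-b.ci_high, abs=1e-10)

    def test_heterogeneity_flag_on_divergent_studies(self):
        effects = [make_effect(0.0, 0.01, "a"), make_effect(2.0, 0.01, "b"),
                   make_effect(-2.0, 0.01, "c")]
        pooled = pool_random_effects(effects)
        assert pooled.heterogeneity_flag
        assert pooled.i2 > 50.0 and pooled.tau2 > 0.0


class TestDecisionRules:
    @pytest.mark.parametrize(
        "ci_low, ci_high, expected",
        [
            (0.38, 0.88, True),    # pooled tissue comparison
            (-2.71, -0.16, False), # vascular invasion: CI contains -1
            (-1.0, 0.5, False),    # boundary touch counts as overlap
            (1.01, 2.0, True),
        ],
    )
    def test_unit_interval_rule(self, ci_low, ci_high, expected):
        r = PooledResult(smd=(ci_low + ci_high) / 2, se=0.1, ci_low=ci_low,
                         ci_high=ci_high, z=0, p=0, Q=0, df=0, p_het=1, i2=0,
                         tau2=0, model="random", heterogeneity_flag=False,
                         significance_flag=False, n_studies=1)
        assert significance_rule(r) is expected

    def test_null_effect_not_flagged_significant(self):
        effects = [make_effect(0.01 * (i - 2), 0.05, str(i)) for i in range(5)]
        pooled = pool_random_effects(effects)
        assert not pooled.significance_flag  # CI straddles 0


class TestLeaveOneOut:
    def test_identical_studies_give_identical_results(self):
        effects = [make_effect(0.3, 0.1, s) for s in "abc"]
        out = leave_one_out(effects)
        assert len(out) == 3
        assert len({(r.smd, r.ci_low, r.ci_high) for r in out}) == 1
        assert [r.omitted for r in out] == ["a", "b", "c"]

    def test_omitting_outlier_minimizes_i2(self):
        effects = [make_effect(0.5, 0.02, s) for s in "abcd"]
        effects.append(make_effect(3.0, 0.02, "outlier"))
        out = leave_one_out(effects)
        best = min(out, key=lambda r: r.i2)
        assert best.omitted == "outlier"
        assert best.i2 == pytest.approx(0.0, abs=1e-9)

    def test_requires_two_studies(self):
        with pytest.raises(ValueError):
            leave_one_out([make_effect(0.5, 0.1)])


class TestSubgroups:
    def test_single_study_stratum_identity(self):
        studies = [
            StudyRecord("s1", GroupSummary(10, 0, 1), GroupSummary(10, 1, 1),
                        stratum="tissue"),
            StudyRecord("s2", GroupSummary(10, 0, 1), GroupSummary(10, 0.5, 1),
                        stratum="cirrhosis"),
        ]
        pooled = subgroup_compare(studies, "cirrhosis")
        expected = hedges_g(studies[1].case, studies[1].control)
        assert pooled.smd == pytest.approx(expected.g)

    def test_unknown_stratum_rejected(self):
        studies = [StudyRecord("s1", GroupSummary(10, 0, 1), GroupSummary(10, 1, 1))]
        with pytest.raises(ValueError):
            subgroup_compare(studies, "grade")

    def test_null_subgroup_rarely_flagged(self):
        # delta=0 simulation: the significance flag stays false at the
        # nominal rate of the 95% CI (a zero-crossing call has ~5% type I
        # error by construction, so the false rate sits near 0.95)
        flags = 0
        for rep in range(200):
            cfg = MetaSimConfig(n_studies=5, delta=0.0, tau=0.1, seed=10_000 + rep)
            pooled = subgroup_compare(simulate_meta_studies(cfg), "tissue")
            flags += pooled.significance_flag
            assert abs(pooled.smd) < 1.0
        assert flags / 200 < 0.10


class TestForestTable:
    def test_weights_sum_to_100(self):
        effects = [make_effect(0.2, 0.1, "a"), make_effect(0.6, 0.05, "b"),
                   make_effect(0.4, 0.2, "c")]
        pooled = pool_random_effects(effects)
        rows = forest_table(effects, pooled)
        assert len(rows) == 3
        assert sum(r["weight_percent"] for r in rows) == pytest.approx(100.0)
        # smaller variance -> larger weight
        assert rows[1]["weight_percent"] == max(r["weight_percent"] for r in rows)


class TestParameterRecovery:
    def test_coverage_and_bias_at_study_conditions(self):
        # 200 simulated meta-analyses at the default conditions (K=11,
        # delta=0.63, tau calibrated so mean I2 ~ 40%)
        delta = 0.63
        cov, ests, i2s = 0, [], []
        for rep in range(200):
            cfg = MetaSimConfig(seed=rep)
            pooled = pool_random_effects(
                effects_from_studies(simulate_meta_studies(cfg)))
            cov += pooled.ci_low <= delta <= pooled.ci_high
            ests.append(pooled.smd)
            i2s.append(pooled.i2)
        assert 0.92 <= cov / 200 <= 0.98
        assert abs(np.mean(ests) - delta) < 0.03
        assert 30 < np.mean(i2s) < 50
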