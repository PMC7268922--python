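"""Fixed/random-effects pooling, heterogeneity, model selection, partial
mega-analysis and the significance filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from statsmodels.stats.meta_analysis import combine_effects

from megalfc import (EffectRecord, MetaAnalysis, fixed_effect, mega,
                     partial_mega, partial_select, random_effect,
                     significance_filter)


def records(ys, ses, gene="G", study_ids=None):
    ids = study_ids or [f"S{i + 1}" for i in range(len(ys))]
    return [EffectRecord(gene=gene, study_id=s, y=float(y), se=float(se),
                         z=float(y / se), n_case=10, n_control=10)
            for s, y, se in zip(ids, ys, ses)]


class TestFixedEffect:
    def test_single_study_identity(self):
        res = fixed_effect(records([0.7], [0.2]))
        assert res.pooled_lfc == pytest.approx(0.7)
        assert res.se_pooled == pytest.approx(0.2)
        assert res.Q == 0.0 and res.df == 0
        assert res.isq == 0.0 and res.p_q == 1.0

    def test_two_equal_studies(self):
        res = fixed_effect(records([1, 1], [1, 1]))
        assert res.pooled_lfc == pytest.approx(1.0)
        assert res.se_pooled == pytest.approx(np.sqrt(0.5))
        assert res.Q == pytest.approx(0.0)
        assert res.isq == 0.0

    def test_heterogeneous_pair_closed_form(self):
        """y=(0,2), se=(1,1): pooled 1, Q=2 at df=1, ISq=50, p_Q=chi2 tail."""
        res = fixed_effect(records([0, 2], [1, 1]))
        assert res.pooled_lfc == pytest.approx(1.0)
        assert res.Q == pytest.approx(2.0)
        assert res.df == 1
        assert res.isq == pytest.approx(50.0)
        assert res.p_q == pytest.approx(stats.chi2.sf(2.0, 1))

    def test_empty_error(self):
        with pytest.raises(ValueError):
            fixed_effect([])

    def test_oracle_weighted_mean_1000_instances(self):
        """Pooled estimate equals the brute-force inverse-variance weighted
        mean to 1e-12 relative error on 1000 random instances."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            k = rng.integers(2, 12)
            y = rng.normal(0, 2, k)
            se = rng.uniform(0.05, 3, k)
            res = fixed_effect(records(y, se))
            w = 1 / se**2
            expect = np.sum(w * y) / np.sum(w)
            assert res.pooled_lfc == pytest.approx(expect, rel=1e-12)
            assert res.se_pooled == pytest.approx(np.sum(w) ** -0.5,
                                                  rel=1e-12)

    def test_matches_statsmodels(self):
        """Independent cross-check against statsmodels combine_effects."""
        rng = np.random.default_rng(99)
        for _ in range(50):
            k = rng.integers(2, 10)
            y = rng.normal(0, 1, k)
            se = rng.uniform(0.1, 2, k)
            mine = fixed_effect(records(y, se))
            sm = combine_effects(y, se**2, method_re="dl")
            assert mine.pooled_lfc == pytest.approx(sm.mean_effect_fe,
                                                    rel=1e-10)
            assert mine.se_pooled == pytest.approx(sm.sd_eff_w_fe, rel=1e-10)
            assert mine.Q == pytest.approx(sm.q, rel=1e-10)

    def test_weights_sum_to_one(self):
        res = fixed_effect(records([0.1, 0.4, -0.2], [0.2, 0.5, 1.0]))
        assert sum(res.weights) == pytest.approx(1.0, abs=1e-10)


class TestRandomEffect:
    def test_truncation_reduces_to_fixed(self):
        fe = fixed_effect(records([1, 1], [1, 1]))
        re = random_effect(records([1, 1], [1, 1]))
        assert re.tau2 == 0.0
        assert re.pooled_lfc == pytest.approx(fe.pooled_lfc)
        assert re.se_pooled == pytest.approx(fe.se_pooled)

    def test_hand_computed_dl_pair(self):
        """y=(0,2), se=(1,1): Q=2, C=1, tau2=1, star weights equal,
        pooled=1, se_pooled=1."""
        res = random_effect(records([0, 2], [1, 1]))
        assert res.tau2 == pytest.approx(1.0)
        assert res.pooled_lfc == pytest.approx(1.0)
        assert res.se_pooled == pytest.approx(1.0)
        np.testing.assert_allclose(res.weights, [0.5, 0.5])
        # heterogeneity stays the fixed-weights quantity
        assert res.Q == pytest.approx(2.0)
        assert res.isq == pytest.approx(50.0)

    def test_matches_statsmodels_dl(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            k = rng.integers(3, 10)
            y = rng.normal(0, 1.5, k)
            se = rng.uniform(0.1, 1.5, k)
            mine = random_effect(records(y, se))
            sm = combine_effects(y, se**2, method_re="dl")
            # statsmodels reports the untruncated moment estimate
            assert mine.tau2 == pytest.approx(max(0.0, sm.tau2), abs=1e-10)
            if sm.tau2 > 0:
                assert mine.pooled_lfc == pytest.approx(sm.mean_effect_re,
                                                        rel=1e-10)
                assert mine.se_pooled == pytest.approx(sm.sd_eff_w_re,
                                                       rel=1e-10)

    def test_tau2_recovery_simulation(self):
        """Planted tau2=0.25, k=50, se=0.1: mean DL estimate over 200
        replicates within [0.15, 0.35]."""
        rng = np.random.default_rng(2024)
        se = np.full(50, 0.1)
        estimates = []
        for _ in range(200):
            theta_i = rng.normal(0.0, np.sqrt(0.25), 50)
            y = rng.normal(theta_i, se)
            estimates.append(random_effect(records(y, se)).tau2)
        assert 0.15 < np.mean(estimates) < 0.35

    def test_single_study_rejected(self):
        with pytest.raises(ValueError):
            random_effect(records([1.0], [0.5]))


class TestModelSelection:
    def test_homogeneous_selects_fixed(self):
        res = mega(records([0.5, 0.5, 0.5], [1, 1, 1]), mode="auto")
        assert res.model == "fixed"
        assert res.isq == 0.0

    def test_heterogeneous_selects_random(self):
        res = mega(records([0, 2], [1, 1]), mode="auto")
        assert res.model == "random"
        assert res.isq == pytest.approx(50.0)

    def test_forced_fixed_overrides(self):
        res = mega(records([0, 2], [1, 1]), mode="fixed")
        assert res.model == "fixed"

    def test_auto_invariant_model_iff_isq_zero(self):
        rng = np.random.default_rng(31)
        for _ in range(200):
            k = rng.integers(2, 9)
            res = mega(records(rng.normal(0, 1, k),
                               rng.uniform(0.1, 1, k)), mode="auto")
            assert (res.model == "fixed") == (res.isq == 0.0)

    def test_k1_auto_is_fixed(self):
        assert mega(records([0.3], [0.1]), mode="auto").model == "fixed"


class TestPartialSelect:
    def test_nine_studies_keep_four(self):
        assert len(partial_select(records(np.arange(9) / 10,
                                          np.ones(9)))) == 4

    def test_eight_studies_keep_four(self):
        assert len(partial_select(records(np.arange(8) / 10,
                                          np.ones(8)))) == 4

    def test_largest_absolute_effect_wins(self):
        recs = records([0.1, -0.5, 0.2], [1, 1, 1])
        chosen = partial_select(recs)
        assert len(chosen) == 1
        assert chosen[0].y == -0.5

    def test_tie_break_se_then_study_id(self):
        recs = records([0.5, -0.5, 0.5], [0.3, 0.2, 0.2],
                       study_ids=["SB", "SC", "SA"])
        chosen = partial_select(recs)
        assert len(chosen) == 1
        assert chosen[0].study_id == "SA"  # same |y|, same se, lexicographic

    def test_selection_permutation_invariant(self):
        recs = records([0.1, 0.9, -0.4, 0.6, 0.2], [1, 1, 1, 1, 1])
        base = {r.study_id for r in partial_select(recs)}
        for perm in ([4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            shuffled = [recs[i] for i in perm]
            assert {r.study_id for r in partial_select(shuffled)} == base

    def test_single_study_kept(self):
        assert len(partial_select(records([0.2], [1]))) == 1


class TestPartialMega:
    def test_identical_effects_match_full(self):
        recs = records([0.4] * 6, [0.5] * 6)
        full = mega(recs)
        part = partial_mega(recs)
        assert part.k == 3
        assert part.pooled_lfc == pytest.approx(full.pooled_lfc)
        assert part.analysis == "partial-MA"

    def test_signal_in_minority_of_studies_amplified(self):
        """Signal planted in 4 of 9 studies: the top-50% selection pools
        exactly the signal studies, so |partial| >= |full|."""
        ys = [1.0, 1.1, 0.9, 1.05, 0.01, -0.02, 0.03, 0.0, -0.01]
        recs = records(ys, [0.1] * 9)
        full = mega(recs)
        part = partial_mega(recs)
        assert part.k == 4
        assert {r for r in part.study_ids} == {"S1", "S2", "S3", "S4"}
        assert abs(part.pooled_lfc) > abs(full.pooled_lfc)

    def test_k1_partial_equals_full(self):
        recs = records([0.7], [0.2])
        assert partial_mega(recs).pooled_lfc == mega(recs).pooled_lfc


class TestSignificanceFilter:
    def test_strong_up_regulation_passes(self):
        res = fixed_effect(records([0.51], [0.51 / 6.05]))  # p ~ 1.5e-9
        assert res.p < 1e-7 and res.pooled_lfc > 0.49
        assert significance_filter(res)

    def test_weak_p_fails_despite_lfc(self):
        res = fixed_effect(records([-0.49], [0.214]))  # p ~ 2.2e-2
        assert not significance_filter(res)

    def test_boundary_is_strict(self):
        res = fixed_effect(records([0.49], [0.49 / 8]))
        assert res.p < 1e-12
        assert not significance_filter(res)  # LFC not strictly > 0.49

    def test_down_regulation_threshold_asymmetric(self):
        res = fixed_effect(records([-0.6], [0.05]))
        assert res.p < 1e-7
        assert not significance_filter(res)  # -0.74 < -0.6: fails
        res2 = fixed_effect(records([-0.8], [0.05]))
        assert significance_filter(res2)

    def test_invalid_thresholds(self):
        res = fixed_effect(records([1.0], [0.1]))
        with pytest.raises(ValueError):
            significance_filter(res, up=-1.0, down=-2.0)


class TestInvariants:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        y = rng.normal(0, 1, k)
        se = rng.uniform(0.1, 2, k)
        perm = rng.permutation(k)
        a = mega(records(y, se))
        b = mega(records(y[perm], se[perm],
                         study_ids=[f"S{i + 1}" for i in perm]))
        assert a.pooled_lfc == pytest.approx(b.pooled_lfc, abs=1e-12)
        assert a.Q == pytest.approx(b.Q, abs=1e-10)
        assert a.isq == pytest.approx(b.isq, abs=1e-10)
        assert a.model == b.model

    def test_homogeneous_limit_random_equals_fixed(self):
        """Equal SEs and no excess dispersion: DL collapses onto fixed."""
        recs = records([0.3, 0.3, 0.3, 0.3], [0.4] * 4)
        fe, re = fixed_effect(recs), random_effect(recs)
        assert re.pooled_lfc == pytest.approx(fe.pooled_lfc, abs=1e-10)
        assert re.se_pooled == pytest.approx(fe.se_pooled, abs=1e-10)

    def test_adding_consistent_study_never_inflates_se(self):
        recs = records([0.2, 0.6, 0.4], [0.3, 0.5, 0.2])
        base = fixed_effect(recs)
        grown = fixed_effect(recs + records([base.pooled_lfc], [0.7],
                                            study_ids=["S9"]))
        assert grown.se_pooled <= base.se_pooled

    def test_ci_always_brackets_estimate(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(1, 8))
            res = mega(records(rng.normal(0, 1, k), rng.uniform(0.1, 2, k)))
            assert res.ci_low <= res.pooled_lfc <= res.ci_high
            assert 0.0 <= res.isq < 100.0
            assert res.df == res.k - 1
            assert sum(res.weights) == pytest.approx(1.0, abs=1e-10)

    def test_mixed_gene_records_rejected(self):
        recs = records([0.1], [1], gene="A") + records([0.2], [1], gene="B")
        with pytest.raises(ValueError, match="mix"):
            MetaAnalysis.from_records(recs)
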