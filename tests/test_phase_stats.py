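"""Moments, normality gate, phase ANOVA, Holm pairwise tests and merging."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lactoref import (
    DegenerateSampleError,
    InsufficientDataError,
    ValidationError,
    analyze_analyte,
    anova_phase,
    holm_adjust,
    merge_phases,
    needs_log,
    pairwise_holm,
    sample_moments,
)
from lactoref.phase_stats import PHASE_PAIRS, ln_transform, significance_code
from lactoref.registry import PHASE_ORDER


class TestSampleMoments:
    def test_symmetric_vector_has_zero_skew(self):
        sk, _ = sample_moments([-2, -1, 0, 1, 2])
        assert sk == pytest.approx(0, abs=1e-12)

    def test_bernoulli_like_vector(self):
        sk, ku = sample_moments([0, 0, 0, 1])
        assert sk == pytest.approx(2 / np.sqrt(3), abs=1e-9)   # ≈ 1.1547
        assert ku == pytest.approx(-2 / 3, abs=1e-9)

    def test_large_gaussian_sample_moments_near_zero(self):
        x = np.random.default_rng(7).standard_normal(100_000)
        sk, ku = sample_moments(x)
        # asymptotic SEs sqrt(6/n), sqrt(24/n)
        assert abs(sk) < 0.03 and abs(ku) < 0.06

    def test_degenerate_and_short_samples_rejected(self):
        with pytest.raises(DegenerateSampleError):
            sample_moments([3, 3, 3, 3])
        with pytest.raises(InsufficientDataError):
            sample_moments([1, 2, 3])


class TestNormalityGate:
    @pytest.mark.parametrize("sk, ku, expected", [
        (0.2, -0.3, False),
        (1.6, 0.0, True),
        (0.0, -1.6, True),
        (1.5, 1.5, False),       # the ±1.5 gate is strict
        (-1.51, 0.0, True),
    ])
    def test_gate(self, sk, ku, expected):
        assert needs_log(sk, ku) is expected

    def test_ln_transform_requires_positive(self):
        with pytest.raises(ValidationError):
            ln_transform([1.0, 0.0, 2.0])


def _anova_oracle(groups):
    """Brute-force sums-of-squares ANOVA for the test's own bookkeeping."""
    allv = [v for g in groups for v in g]
    grand = sum(allv) / len(allv)
    ss_t = sum((v - grand) ** 2 for v in allv)
    ss_b = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_w = ss_t - ss_b
    k, n = len(groups), len(allv)
    f = (ss_b / (k - 1)) / (ss_w / (n - k))
    return ss_b / ss_t, f


class TestAnova:
    def _run(self, groups):
        vals = np.concatenate([np.asarray(g, float) for g in groups])
        labels = np.concatenate([[PHASE_ORDER[i]] * len(g)
                                 for i, g in enumerate(groups)])
        return anova_phase(vals, labels)

    def test_identical_groups_have_zero_effect(self):
        res = self._run([[1, 2, 3], [1, 2, 3]])
        assert res.r_squared == pytest.approx(0)
        assert res.f_stat == pytest.approx(0)
        assert res.p_overall == pytest.approx(1)

    def test_pure_between_group_variance(self):
        res = self._run([[0, 0], [1, 1]])
        assert res.r_squared == pytest.approx(1)

    def test_matches_sums_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4], [5, 6, 7]]
        r2, f = _anova_oracle(groups)
        res = self._run(groups)
        assert res.r_squared == pytest.approx(r2, rel=1e-12)
        assert res.f_stat == pytest.approx(f, rel=1e-12)
        from scipy.stats import f_oneway
        assert res.p_overall == pytest.approx(f_oneway(*groups).pvalue, rel=1e-9)

    def test_constant_data_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            self._run([[1, 1], [1, 1]])

    @given(scale=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_r_squared_affine_invariant(self, scale, shift):
        groups = [[1.0, 2.0, 3.5], [2.0, 3.0, 4.0], [5.0, 6.5, 7.0]]
        base = self._run(groups).r_squared
        scaled = self._run([[scale * v + shift for v in g] for g in groups])
        assert scaled.r_squared == pytest.approx(base, rel=1e-6)


class TestHolm:
    def test_step_down_arithmetic(self):
        adj = holm_adjust([0.01, 0.02, 0.03])
        assert adj == pytest.approx([0.03, 0.04, 0.04])

    @given(ps=st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=6))
    def test_adjusted_dominates_raw_and_caps_at_one(self, ps):
        adj = holm_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_groups_pair_is_nonsignificant(self):
        rng = np.random.default_rng(0)
        g = rng.normal(0, 1, 20)
        vals = np.concatenate([g, g, rng.normal(5, 1, 20), rng.normal(9, 1, 20)])
        labels = np.concatenate([[p] * 20 for p in PHASE_ORDER])
        adj = pairwise_holm(vals, labels)
        assert adj[("dry", "postpartum")] == pytest.approx(1.0)

    def test_pooling_options_differ_but_agree_on_strong_effects(self):
        rng = np.random.default_rng(1)
        vals = np.concatenate([rng.normal(m, 1, 30) for m in (0, 4, 8, 12)])
        labels = np.concatenate([[p] * 30 for p in PHASE_ORDER])
        for pooling in ("pair", "all"):
            adj = pairwise_holm(vals, labels, sd_pooling=pooling)
            assert all(p < 0.01 for p in adj.values())


class TestMergePhases:
    def _pmap(self, nonsig_pairs):
        return {pair: (0.5 if pair in nonsig_pairs else 0.01)
                for pair in PHASE_PAIRS}

    def test_all_significant_gives_singletons(self):
        part = merge_phases(self._pmap(set()))
        assert sorted(len(b) for b in part.blocks) == [1, 1, 1, 1]

    def test_fructosamine_pattern_two_blocks(self):
        nonsig = {("dry", "late_lactation"), ("postpartum", "early_lactation")}
        part = merge_phases(self._pmap(nonsig))
        assert set(part.blocks) == {
            frozenset({"dry", "late_lactation"}),
            frozenset({"postpartum", "early_lactation"})}

    def test_transitive_closure(self):
        nonsig = {("dry", "postpartum"), ("postpartum", "early_lactation")}
        part = merge_phases(self._pmap(nonsig))
        assert frozenset({"dry", "postpartum", "early_lactation"}) in part.blocks

    def test_boundary_p_equal_alpha_does_not_merge(self):
        pmap = {pair: 0.01 for pair in PHASE_PAIRS}
        pmap[("dry", "late_lactation")] = 0.05   # p > 0.05 merges; 0.05 does not
        part = merge_phases(pmap)
        assert sorted(len(b) for b in part.blocks) == [1, 1, 1, 1]

    def test_all_64_patterns_yield_valid_partitions(self):
        for bits in itertools.product([True, False], repeat=6):
            nonsig = {p for p, b in zip(PHASE_PAIRS, bits) if b}
            part = merge_phases(self._pmap(nonsig))
            union = set().union(*part.blocks)
            assert union == set(PHASE_ORDER)
            assert sum(len(b) for b in part.blocks) == 4
            # merged pairs end up in one block
            for a, b in nonsig:
                assert part.block_of(a) == part.block_of(b)


class TestSignificanceCodes:
    @pytest.mark.parametrize("p, code", [(0.005, "***"), (0.05, "*"),
                                         (0.099, "*"), (0.2, "ns")])
    def test_display_convention(self, p, code):
        assert significance_code(p) == code


class TestAnalyzeAnalyte:
    def test_log_gate_applied_prospectively(self):
        rng = np.random.default_rng(3)
        # heavily right-skewed data in every phase trips the moment gate
        vals = np.concatenate([rng.lognormal(0, 1.2, 40) for _ in PHASE_ORDER])
        labels = np.concatenate([[p] * 40 for p in PHASE_ORDER])
        res = analyze_analyte(vals, labels, "X")
        assert res.log_used

    def test_explicit_flag_respected(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(10, 1, 30) for _ in PHASE_ORDER])
        labels = np.concatenate([[p] * 30 for p in PHASE_ORDER])
        assert not analyze_analyte(vals, labels, "X", log_transform=False).log_used
        assert analyze_analyte(vals, labels, "X", log_transform=True).log_used
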