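import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import beta as beta_fn, comb
from scipy.stats import betabinom as scipy_betabinom, binom

from hotspotkit.betabinom import (
    BetaBinomialFit,
    FixedEffects,
    HotspotCall,
    PositionHistogram,
    benjamini_hochberg,
    betabin_pmf,
    betabin_sf,
    build_histogram,
    call_hotspots,
    fdr_correct,
    filter_hotspots,
    fit_betabinomial,
    kl_divergence,
    model_table,
    stepwise_fixed_effects,
)
from hotspotkit.mutation_io import PositionCounts


def make_hist(h, n_patients=500, gene="G"):
    h = np.asarray(h, dtype=np.int64)
    return PositionHistogram(gene=gene, h=h, n_sites=int(h.sum()), n_patients=n_patients)


class TestBuildHistogram:
    def test_direct_tally(self):
        pc = PositionCounts("G", counts={10: 3, 20: 3, 30: 1}, protein_length=100)
        hist = build_histogram(pc, n_patients=50)
        assert hist.h.tolist() == [97, 1, 0, 2]
        assert hist.k == 3

    def test_empty_counts(self):
        pc = PositionCounts("G", counts={}, protein_length=50)
        hist = build_histogram(pc, n_patients=10)
        assert hist.h.tolist() == [50]

    def test_against_bincount_oracle(self, rng):
        counts = {int(p): int(c) for p, c in
                  zip(rng.choice(500, 80, replace=False) + 1, rng.integers(1, 12, 80))}
        pc = PositionCounts("G", counts=counts, protein_length=500)
        hist = build_histogram(pc, n_patients=100)
        oracle = np.bincount(list(counts.values()), minlength=hist.k + 1)
        oracle[0] = 500 - len(counts)
        assert hist.h.tolist() == oracle.tolist()
        assert hist.h.sum() == 500

    def test_inconsistent_length_errors(self):
        pc = PositionCounts("G", counts={1: 1, 2: 1, 3: 1}, protein_length=None)
        pc.counts = {1: 1, 2: 1, 3: 1}
        pc.protein_length = 2
        with pytest.raises(ValueError):
            build_histogram(pc, n_patients=10)

    def test_recurrence_above_cohort_errors(self):
        pc = PositionCounts("G", counts={5: 20}, protein_length=10)
        with pytest.raises(ValueError):
            build_histogram(pc, n_patients=10)


class TestBetabinPmf:
    def test_uniform_mixing(self):
        for i in range(3):
            assert betabin_pmf(i, 2, 1.0, 1.0) == pytest.approx(1 / 3, abs=1e-12)

    def test_large_ab_binomial_limit(self):
        i = np.arange(11)
        assert np.allclose(betabin_pmf(i, 10, 1e6, 1e6), binom.pmf(i, 10, 0.5), atol=1e-4)

    def test_closed_form_n1(self):
        # P(X=0 | n=1, a=2, b=3) = b/(a+b)
        assert betabin_pmf(0, 1, 2.0, 3.0) == pytest.approx(0.6, abs=1e-12)

    def test_sums_to_one(self):
        for n, a, b in [(10, 0.3, 7.0), (100, 2.0, 2.0), (500, 0.05, 400.0)]:
            total = betabin_pmf(np.arange(n + 1), n, a, b).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [1, 5, 20, 50])
    def test_beta_ratio_oracle(self, n):
        a, b = 0.7, 5.3
        i = np.arange(n + 1)
        oracle = comb(n, i) * beta_fn(i + a, n - i + b) / beta_fn(a, b)
        assert np.allclose(betabin_pmf(i, n, a, b), oracle, atol=1e-10)

    def test_matches_scipy(self):
        i = np.arange(51)
        assert np.allclose(
            betabin_pmf(i, 50, 0.4, 9.0), scipy_betabinom.pmf(i, 50, 0.4, 9.0), atol=1e-12
        )

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            betabin_pmf(5, 2, 1.0, 1.0)
        with pytest.raises(ValueError):
            betabin_pmf(0, 2, -1.0, 1.0)

    def test_sf_by_summation(self):
        n, a, b = 40, 1.2, 8.0
        for i in [0, 1, 17, 40]:
            oracle = scipy_betabinom.pmf(np.arange(i, n + 1), n, a, b).sum()
            assert betabin_sf(i, n, a, b) == pytest.approx(oracle, abs=1e-12)


class TestKlDivergence:
    def test_identical_is_zero(self):
        v = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(v, v) == 0.0

    def test_log2_closed_form(self):
        assert kl_divergence(np.array([1.0, 0.0]), np.array([0.5, 0.5])) == pytest.approx(
            np.log(2)
        )

    def test_elementwise_sum_oracle(self, rng):
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            q = rng.dirichlet(np.ones(6))
            oracle = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
            assert kl_divergence(p, q) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            kl_divergence(np.ones(2) / 2, np.ones(3) / 3)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None)
    def test_non_negative(self, seed):
        r = np.random.default_rng(seed)
        p = r.dirichlet(np.ones(5))
        q = r.dirichlet(np.ones(5))
        assert kl_divergence(p, q) >= 0.0


class TestFitBetabinomial:
    def test_self_fit_kl_near_zero(self):
        a, b, n = 0.5, 50.0, 200
        pmf = betabin_pmf(np.arange(7), n, a, b)
        h = pmf / pmf.sum() * 10000.0
        hist = PositionHistogram("G", h, 10000, n)
        fit = fit_betabinomial(hist)
        assert fit.kl < 1e-6

    def test_mean_recovery_single_seed(self):
        rng = np.random.default_rng(77)
        counts = scipy_betabinom.rvs(500, 0.05, 400.0, size=10000, random_state=rng)
        hist = make_hist(np.bincount(counts))
        fit = fit_betabinomial(hist)
        true_mean = 0.05 / 400.05
        assert abs(fit.mean_rate - true_mean) / true_mean < 0.2
        assert fit.converged

    def test_single_bin_degenerate(self):
        hist = make_hist([100])
        fit = fit_betabinomial(hist)
        assert not fit.converged

    def test_deterministic_given_init(self):
        hist = make_hist([900, 80, 15, 5])
        f1 = fit_betabinomial(hist, init=(0.5, 100.0))
        f2 = fit_betabinomial(hist, init=(0.5, 100.0))
        assert (f1.a, f1.b, f1.kl) == (f2.a, f2.b, f2.kl)

    def test_ml_objective_runs(self):
        hist = make_hist([900, 80, 15, 5])
        fit = fit_betabinomial(hist, objective="ml")
        assert fit.a > 0 and fit.b > 0


class TestStepwiseFixedEffects:
    def test_good_fit_stops_immediately(self):
        # histogram drawn from (in fact equal to) a beta-binomial: kl < 1 at step 0
        a, b, n = 0.5, 50.0, 200
        pmf = betabin_pmf(np.arange(6), n, a, b)
        h = np.round(pmf / pmf.sum() * 2000).astype(np.int64)
        hist = make_hist(h, n_patients=n)
        fit, F = stepwise_fixed_effects(hist)
        assert fit.kl < 1.0
        assert fit.n_steps == 0
        assert np.all(F.F == 0)

    def test_spike_absorption(self):
        rng = np.random.default_rng(2024)
        counts = scipy_betabinom.rvs(500, 0.05, 400.0, size=5000, random_state=rng)
        counts[:5] = 25
        hist = make_hist(np.bincount(counts, minlength=26))
        fit, F = stepwise_fixed_effects(hist)
        assert F.F[25] >= 4

    def test_conservation_and_monotone_trace(self):
        rng = np.random.default_rng(5)
        counts = scipy_betabinom.rvs(300, 0.3, 60.0, size=2000, random_state=rng)
        counts[:4] = 30
        hist = make_hist(np.bincount(counts), n_patients=300)
        fit, F, trace = stepwise_fixed_effects(hist, return_trace=True)
        # conservation: reduced + F == original for every bin
        reduced = hist.h - F.F
        assert np.all(reduced >= 0)
        assert np.all(reduced + F.F == hist.h)
        assert all(t2 <= t1 + 1e-9 for t1, t2 in zip(trace, trace[1:]))

    def test_k2_greedy_step_is_grid_optimum(self):
        hist = make_hist([60, 10, 25], n_patients=50)
        fit0 = fit_betabinomial(hist)
        # exhaustive brute force over the 2 x 10 candidate grid
        best = None
        for i in (1, 2):
            for f in np.arange(0.1, 1.01, 0.1):
                r = max(1, int(round(f * hist.h[i])))
                r = min(r, int(hist.h[i]))
                cand = hist.h.copy()
                cand[i] -= r
                cand_fit = fit_betabinomial(
                    PositionHistogram("G", cand, int(cand.sum()), 50),
                    init=(fit0.a, fit0.b),
                )
                if best is None or cand_fit.kl < best[0]:
                    best = (cand_fit.kl, i, r)
        _, F = stepwise_fixed_effects(
            hist, kl_stop=0.0, max_steps=1, min_improvement=-np.inf
        )
        committed_bin = int(np.flatnonzero(F.F)[0])
        assert committed_bin == best[1]
        assert F.F[committed_bin] == best[2]

    def test_all_zero_histogram(self):
        hist = PositionHistogram("G", np.zeros(1, dtype=np.int64), 0, 10)
        fit, F = stepwise_fixed_effects(hist)
        assert np.all(F.F == 0)

    def test_max_steps_cap(self):
        rng = np.random.default_rng(8)
        counts = scipy_betabinom.rvs(300, 0.3, 60.0, size=2000, random_state=rng)
        hist = make_hist(np.bincount(counts), n_patients=300)
        fit, F = stepwise_fixed_effects(hist, kl_stop=0.0, min_improvement=0.0, max_steps=3)
        assert fit.n_steps <= 3


class TestCallHotspots:
    def make_inputs(self):
        pc = PositionCounts("G", counts={5: 9, 11: 5, 40: 2}, protein_length=500)
        fit = BetaBinomialFit(a=1.0, b=999.0, n=500, kl=0.0, converged=True)
        F = np.zeros(10, dtype=np.int64)
        return pc, fit, F

    def test_no_fixed_effect_no_flags(self):
        pc, fit, F = self.make_inputs()
        calls = call_hotspots(pc, fit, FixedEffects(F))
        assert not any(c.flagged for c in calls)
        assert len(calls) == 3

    def test_pvalue_summation_oracle(self):
        pc, fit, F = self.make_inputs()
        F[9] = 1
        calls = call_hotspots(pc, fit, FixedEffects(F))
        call9 = next(c for c in calls if c.recurrence == 9)
        oracle = scipy_betabinom.pmf(np.arange(9, 501), 500, 1.0, 999.0).sum()
        assert call9.p_value == pytest.approx(oracle, rel=1e-9)
        assert call9.flagged

    def test_tail_monotonicity(self):
        pc, fit, F = self.make_inputs()
        calls = {c.recurrence: c for c in call_hotspots(pc, fit, FixedEffects(F))}
        assert calls[9].p_value <= calls[5].p_value <= calls[2].p_value


class TestFdrAndFilter:
    def _call(self, rec, p):
        return HotspotCall("G", 1, rec, p)

    def test_bh_single(self):
        out = fdr_correct([self._call(5, 0.01)])
        assert out[0].q_value == pytest.approx(0.01)

    def test_bh_hand_computation(self):
        calls = [self._call(5, 0.01), self._call(6, 0.02), self._call(7, 0.03)]
        out = fdr_correct(calls)
        assert [c.q_value for c in out] == pytest.approx([0.03, 0.03, 0.03])

    def test_below_warm_min_gets_no_q(self):
        out = fdr_correct([self._call(3, 0.001), self._call(5, 0.5)])
        assert out[0].q_value is None
        assert not out[0].is_warm
        assert out[1].q_value is not None

    @given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_bh_matches_statsmodels(self, pvals):
        from statsmodels.stats.multitest import multipletests

        ours = benjamini_hochberg(np.array(pvals))
        theirs = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_filter_recurrence_seven_passes(self):
        c = self._call(7, 0.9)
        c.q_value, c.is_warm = 0.5, True
        assert filter_hotspots([c])[0].passes_filter

    def test_filter_low_q_passes(self):
        c = self._call(4, 0.001)
        c.q_value, c.is_warm = 0.009, True
        assert filter_hotspots([c])[0].passes_filter

    def test_filter_neither_branch_fails(self):
        c = self._call(6, 0.2)
        c.q_value, c.is_warm = 0.5, True
        assert not filter_hotspots([c])[0].passes_filter


class TestModelTable:
    def test_columns_and_conservation(self):
        hist = make_hist([90, 6, 4], n_patients=100)
        fit, F = stepwise_fixed_effects(hist)
        table = model_table(hist, fit, F)
        assert list(table.columns) == ["i", "h", "model_expected", "F", "p_tail"]
        assert (table["h"] - table["F"] >= 0).all()
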