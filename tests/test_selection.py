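import numpy as np
import pytest

from blink import (candidate_filter, information_criterion, ld_prune,
                   pearson_r, scan_markers, select_pseudo_qtns)
from blink.fem import fit_fem
from blink.selection import ConstantVectorError, criterion_penalty
from blink.simulate import simulate_genotypes


class TestCandidateFilter:
    def _scan(self, pvals, geno):
        s = scan_markers(geno, np.random.default_rng(0).normal(
            size=geno.n_individuals))
        s.p_value[:] = pvals
        return s

    def test_threshold_arithmetic(self):
        g = simulate_genotypes(30, 2, seed=0)
        s = self._scan([1e-6, 2e-5], g)
        # cutoff = 0.01 / 1000 = 1e-5 when M=1000
        out = candidate_filter(s, alpha=0.01, M=1000)
        assert list(out) == [0]

    def test_all_null_gives_empty(self):
        g = simulate_genotypes(30, 5, seed=1)
        s = self._scan([0.5] * 5, g)
        assert candidate_filter(s, 0.01).size == 0

    def test_matches_bruteforce_filter_sort(self):
        g = simulate_genotypes(80, 500, seed=2)
        rng = np.random.default_rng(3)
        y = g.codes[37] * 1.2 + g.codes[301] * 0.9 + rng.normal(size=80)
        scan = scan_markers(g, y)
        out = candidate_filter(scan, 0.01)
        cutoff = 0.01 / 500
        expected = [j for j in range(500)
                    if np.isfinite(scan.p_value[j])
                    and scan.p_value[j] <= cutoff]
        expected.sort(key=lambda j: (scan.p_value[j],
                                     str(scan.chromosome[j]),
                                     scan.position[j],
                                     str(scan.marker_id[j])))
        assert list(out) == expected
        assert np.all(np.diff(scan.p_value[out]) >= 0)


class TestPearsonR:
    def test_identity_and_reflection(self):
        x = np.array([0, 1, 2, 0, 1], dtype=float)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, 2 - x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # cov/sd*sd computed by hand: r = 2.25 / 2.75 = 9/11
        assert pearson_r([0, 1, 2, 0], [0, 2, 2, 1]) == \
            pytest.approx(9 / 11, abs=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ConstantVectorError):
            pearson_r([1, 1, 1], [0, 1, 2])


def brute_force_prune(candidates, G, beta):
    """Independent greedy re-implementation: explicit removal list,
    quadratic loops, pairwise numpy corrcoef."""
    remaining = list(candidates)
    kept = []
    while remaining:
        head = remaining.pop(0)
        kept.append(head)
        survivors = []
        for c in remaining:
            gh, gc = G[head], G[c]
            if np.std(gh) == 0 or np.std(gc) == 0:
                r = 0.0
            else:
                r = np.corrcoef(gh, gc)[0, 1]
            if abs(r) <= beta:
                survivors.append(c)
        remaining = survivors
    return kept


class TestLdPrune:
    def _correlated_geno(self, seed=4, n=80, m=60):
        """Markers with deliberate LD blocks: later markers copy earlier
        ones with a few flipped genotypes."""
        rng = np.random.default_rng(seed)
        g = simulate_genotypes(n, m, seed=seed)
        codes = g.codes.copy()
        for j in range(1, m, 3):
            src = codes[j - 1].copy()
            flip = rng.random(n) < 0.05
            src[flip] = rng.integers(0, 3, size=int(flip.sum()))
            codes[j] = src
        g.codes = codes
        return g

    def test_single_removal_example(self):
        g = self._correlated_geno()
        dos = g.codes.astype(float)
        # find an (A,B) pair with |r|>0.9 and a C weakly correlated to A
        a, b = 0, 1
        assert abs(np.corrcoef(dos[a], dos[b])[0, 1]) > 0.7
        c = next(j for j in range(2, g.n_markers)
                 if abs(np.corrcoef(dos[a], dos[j])[0, 1]) < 0.3)
        out = ld_prune(np.array([a, b, c]), g, beta=0.7)
        assert list(out) == [a, c]

    def test_beta_one_is_noop_without_perfect_pairs(self):
        g = simulate_genotypes(50, 20, seed=5)
        cand = np.arange(20)
        assert list(ld_prune(cand, g, beta=1.0)) == list(cand)

    def test_matches_bruteforce_on_40_candidates(self):
        g = self._correlated_geno(seed=6)
        cand = np.arange(40)
        dos = g.codes.astype(float)
        for beta in (0.3, 0.5, 0.7, 0.9):
            ours = list(ld_prune(cand, g, beta=beta))
            theirs = brute_force_prune(list(cand), dos, beta)
            assert ours == theirs
            # no surviving pair in high LD
            for i, a in enumerate(ours):
                for b in ours[i + 1:]:
                    assert abs(np.corrcoef(dos[a], dos[b])[0, 1]) <= beta + 1e-12

    def test_invariant_to_appending_removed(self):
        g = self._correlated_geno(seed=7)
        cand = np.arange(30)
        kept = ld_prune(cand, g, beta=0.5)
        removed = [c for c in cand if c not in set(kept)]
        again = ld_prune(np.concatenate([kept, removed]), g, beta=0.5)
        assert list(again) == list(kept)


class TestInformationCriterion:
    def _fit(self, n2ll, k, n):
        f = fit_fem(np.random.default_rng(0).normal(size=n),
                    np.ones((n, 1)), n_pseudo_qtns=k)
        f.neg2_log_likelihood = n2ll
        return f

    def test_k_zero_bic_is_deviance(self):
        assert information_criterion(self._fit(42.0, 0, 50)) == 42.0

    def test_published_penalty_form(self):
        # -2LL + 2 k ln(n) = 100 + 6 ln(100)
        f = self._fit(100.0, 3, 100)
        assert information_criterion(f, "bic") == \
            pytest.approx(100 + 6 * np.log(100), rel=1e-12)
        assert information_criterion(f, "bic") == pytest.approx(127.631, abs=5e-4)

    def test_textbook_switch_and_aic(self):
        f = self._fit(100.0, 3, 100)
        assert information_criterion(f, "bic", bic_penalty_factor=1.0) == \
            pytest.approx(100 + 3 * np.log(100), rel=1e-12)
        assert information_criterion(f, "aic") == pytest.approx(106.0)

    def test_ebic_reduces_to_bic_at_gamma_zero(self):
        f = self._fit(80.0, 2, 40)
        assert information_criterion(f, "ebic", M=500, gamma=0.0) == \
            pytest.approx(information_criterion(f, "bic"), rel=1e-12)

    def test_ebic_contract(self):
        f = self._fit(80.0, 10, 40)
        with pytest.raises(ValueError):
            information_criterion(f, "ebic", M=5)


class TestSelect:
    def test_zero_candidates(self):
        g = simulate_genotypes(30, 10, seed=8)
        y = np.random.default_rng(9).normal(size=30)
        out = select_pseudo_qtns(np.array([], dtype=int), y, None, g)
        assert out.chosen_k == 0
        assert len(out.criterion_trace) == 1

    def test_strong_single_candidate_chosen(self):
        """y = 2 * top candidate + noise, others pure noise: BIC picks
        k = 1 in nearly every seeded replicate."""
        wins = 0
        for seed in range(100):
            g = simulate_genotypes(120, 8, seed=seed)
            rng = np.random.default_rng(1000 + seed)
            y = 2.0 * g.codes[0] + rng.normal(size=120)
            cand = np.arange(8)
            out = select_pseudo_qtns(cand, y, None, g)
            wins += out.chosen_k == 1
        assert wins >= 95

    def test_trace_deviance_nonincreasing_and_penalty_closed_form(self):
        g = simulate_genotypes(100, 200, seed=10)
        rng = np.random.default_rng(11)
        y = g.codes[3] + 0.7 * g.codes[90] + rng.normal(size=100)
        out = select_pseudo_qtns(np.array([3, 90, 7, 150, 42]), y, None, g)
        trace = out.criterion_trace
        n2ll = [r[1] for r in trace]
        assert all(b <= a + 1e-9 for a, b in zip(n2ll, n2ll[1:]))
        for k, d, crit in trace:
            assert crit - d == pytest.approx(
                criterion_penalty(k, 100, "bic"), rel=1e-12)

    def test_chosen_k_minimises_criterion(self):
        g = simulate_genotypes(90, 50, seed=12)
        rng = np.random.default_rng(13)
        y = 1.5 * g.codes[10] + rng.normal(size=90)
        out = select_pseudo_qtns(np.array([10, 20, 30]), y, None, g)
        crit = [r[2] for r in out.criterion_trace]
        ks = [r[0] for r in out.criterion_trace]
        assert out.chosen_k == ks[int(np.argmin(crit))]

    def test_candidate_cap_preserves_residual_df(self):
        g = simulate_genotypes(12, 40, seed=14)
        y = np.random.default_rng(15).normal(size=12)
        out = select_pseudo_qtns(np.arange(40), y, None, g)
        # t capped at n - c - 2 = 10
        assert max(r[0] for r in out.criterion_trace) <= 10
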