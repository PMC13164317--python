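"""Over-representation statistics against exact and hand oracles."""
import itertools
import math
import random
from fractions import Fraction

import pytest
from scipy import stats

from nbhub import (
    GeneSetLibrary,
    ProteinSet,
    SyntheticSpec,
    bh_adjust,
    combined_score,
    enrich,
    hypergeom_tail,
    odds_ratio,
)
from nbhub.synthetic import gen_geneset_library


def exact_tail(k, n, K, N):
    """Exact P(X >= k) by rational summation over the support."""
    total = Fraction(0)
    for j in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, j) * math.comb(N - K, n - j), math.comb(N, n))
    return total


class TestHypergeomTail:
    def test_k_zero_is_certain(self):
        assert hypergeom_tail(0, 4, 5, 10) == 1.0

    def test_closed_form_example(self):
        # C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeom_tail(4, 4, 5, 10) == pytest.approx(5 / 210, rel=1e-12)

    def test_matches_draw_enumeration_small(self):
        # literal enumeration over all C(N, n) draws
        N, K, n = 8, 3, 4
        population = list(range(N))
        marked = set(range(K))
        for k in range(0, min(n, K) + 1):
            hits = sum(
                1
                for draw in itertools.combinations(population, n)
                if len(marked & set(draw)) >= k
            )
            expected = hits / math.comb(N, n)
            assert hypergeom_tail(k, n, K, N) == pytest.approx(expected, rel=1e-12)

    def test_matches_exact_oracle_exhaustively(self):
        # every configuration with N <= 30, relative error <= 1e-12
        for N in range(1, 31):
            for K in range(0, N + 1):
                for n in range(0, N + 1):
                    for k in range(0, min(n, K) + 1):
                        expected = float(exact_tail(k, n, K, N))
                        got = hypergeom_tail(k, n, K, N)
                        assert got == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_agrees_with_scipy_survival_function(self):
        for N, K, n, k in [(1000, 50, 100, 12), (500, 400, 50, 45), (50, 10, 20, 5)]:
            assert hypergeom_tail(k, n, K, N) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, K, n), rel=1e-9
            )

    def test_bound_violations_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_tail(5, 4, 5, 10)  # k > n


def hand_bh(p_values):
    """Textbook step-up: sort, scale by m/rank, enforce monotonicity, cap at 1."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(1.0, p_values[i] * m / rank_from_top)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


class TestBHAdjust:
    def test_single_p_identity(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_hand_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_matches_hand_oracle_on_random_vectors(self):
        rng = random.Random(99)
        for _ in range(500):
            m = rng.randint(1, 40)
            p = [rng.random() * 0.999 + 0.001 for _ in range(m)]
            assert bh_adjust(p) == pytest.approx(hand_bh(p), rel=1e-12)

    def test_outputs_dominate_inputs(self):
        rng = random.Random(5)
        p = [rng.random() for _ in range(30)]
        adjusted = bh_adjust(p)
        assert all(a >= x for a, x in zip(adjusted, p))
        assert all(a <= 1.0 for a in adjusted)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestOddsRatio:
    def test_no_association_table(self):
        # a=2,b=2,c=2,d=2 -> OR 1; translate back to (k,n,K,N)
        assert odds_ratio(2, 4, 4, 8) == pytest.approx(1.0)

    def test_haldane_correction_on_zero_cell(self):
        # a=4, b=0, c=1, d=5 -> corrected (4.5*5.5)/(0.5*1.5) = 33.0
        assert odds_ratio(4, 4, 5, 10) == pytest.approx(33.0)

    def test_query_equals_term_large_finite(self):
        value = odds_ratio(3, 3, 3, 10)
        assert math.isfinite(value) and value > 10


class TestCombinedScore:
    def test_zero_when_overlap_at_mean(self):
        # N=10, K=5, n=4 -> mu = 2
        assert combined_score(0.5, 2, 4, 5, 10) == 0.0

    def test_vanishes_as_p_approaches_one(self):
        assert combined_score(1.0, 4, 4, 5, 10) == 0.0

    def test_plug_in_formula(self):
        N, K, n, k = 10, 5, 4, 4
        p = hypergeom_tail(k, n, K, N)
        mu = n * K / N
        sigma = math.sqrt(n * (K / N) * (1 - K / N) * (N - n) / (N - 1))
        assert combined_score(p, k, n, K, N) == pytest.approx(
            -math.log(p) * (k - mu) / sigma
        )


class TestEnrich:
    def library(self):
        return GeneSetLibrary(
            "lib",
            terms={"T1": {"A", "B", "C"}, "T2": {"D", "E"}, "T3": {"A", "F", "G", "H"}},
        )

    def test_disjoint_query_errors(self):
        with pytest.raises(ValueError, match="no testable genes"):
            enrich(ProteinSet("q", {"ZZZ"}), self.library())

    def test_query_overlapping_no_term_gives_p_one(self):
        lib = GeneSetLibrary("lib", terms={"T1": {"A", "B"}, "T2": {"C", "D"}},
                             universe={"A", "B", "C", "D", "E"})
        results = enrich(ProteinSet("q", {"E"}), lib, top=None)
        assert all(r.k == 0 and r.p_value == 1.0 for r in results)

    def test_planted_term_ranks_first(self):
        lib, query, label = gen_geneset_library(SyntheticSpec(seed=0))
        assert enrich(query, lib, top=1)[0].term == label

    def test_invariant_to_term_order_and_query_duplication(self):
        lib = self.library()
        reversed_lib = GeneSetLibrary(
            "lib", terms=dict(reversed(list(lib.terms.items())))
        )
        q = ProteinSet("q", {"A", "B", "D"})
        r1 = {r.term: r.p_value for r in enrich(q, lib, top=None)}
        r2 = {r.term: r.p_value for r in enrich(q, reversed_lib, top=None)}
        assert r1 == r2
        # symbols normalize, so case duplicates collapse
        q_dup = ProteinSet("q", {"A", "a", "B", "D"})
        r3 = {r.term: r.p_value for r in enrich(q_dup, lib, top=None)}
        assert r1 == r3

    def test_results_share_one_universe_and_bh_dominates(self):
        lib, query, _ = gen_geneset_library(SyntheticSpec(seed=2))
        results = enrich(query, lib, top=None)
        assert len({r.N for r in results}) == 1
        assert all(r.adjusted_p >= r.p_value for r in results)
        assert [r.p_value for r in results] == sorted(r.p_value for r in results)


class TestCalibration:
    def test_planted_term_top_ranked_in_at_least_95_of_100_runs(self):
        spec = SyntheticSpec()
        wins = 0
        for s in range(100):
            lib, query, label = gen_geneset_library(spec, planted=True, seed=1000 + s)
            if enrich(query, lib, top=1)[0].term == label:
                wins += 1
        assert wins >= 95

    def test_null_type_one_error_controlled(self):
        # Under 200 planted-free runs the chance of any BH discovery at 0.05 is
        # at most 5% (discrete hypergeometric p-values make it conservative, so
        # only the upper side of the binomial band is informative: the
        # one-sided 95% bound for Binomial(200, 0.05) is 17).
        spec = SyntheticSpec()
        hits = 0
        for s in range(200):
            lib, query, _ = gen_geneset_library(spec, planted=False, seed=5000 + s)
            results = enrich(query, lib, top=None)
            if min(r.adjusted_p for r in results) < 0.05:
                hits += 1
        assert hits <= 17
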