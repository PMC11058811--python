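"""Composition probabilities, region scores, null models and tests."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import epimosaic as em
from epimosaic.errors import (
    CompositionMismatchError,
    DegenerateTraceError,
    ValidationError,
)

from conftest import trace_from_string


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def enumerate_arrangements(n_pos: int, n_neg: int):
    """Yield every distinct binary arrangement of a fixed composition."""
    n = n_pos + n_neg
    for pos_idx in itertools.combinations(range(n), n_pos):
        arr = np.zeros(n, dtype=bool)
        arr[list(pos_idx)] = True
        yield arr


def num_runs_of(labels: np.ndarray) -> int:
    return 1 + int((np.diff(labels) != 0).sum())


def max_run_of(labels: np.ndarray) -> int:
    return max(r.length for r in em.run_length_encode(em.BasalTrace(labels)))


def exact_p_value(labels: np.ndarray, statistic: str) -> float:
    """Exhaustive-enumeration p-value toward contiguity (no estimator)."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if statistic == "num_runs":
        obs = num_runs_of(labels)
        hits = sum(num_runs_of(a) <= obs
                   for a in enumerate_arrangements(n_pos, n_neg))
    else:  # max_run
        obs = max_run_of(labels)
        hits = sum(max_run_of(a) >= obs
                   for a in enumerate_arrangements(n_pos, n_neg))
    return hits / math.comb(n_pos + n_neg, n_pos)


# ---------------------------------------------------------------------------
# composition and region scores
# ---------------------------------------------------------------------------

class TestComposition:
    def test_all_pos(self):
        probs = em.composition_probs(trace_from_string("PPPPP"))
        assert (probs.p_positive, probs.p_negative) == (1.0, 0.0)

    def test_balanced(self):
        probs = em.composition_probs(trace_from_string("PPNNNP"))
        assert (probs.p_positive, probs.p_negative) == (0.5, 0.5)

    def test_bernoulli_sampling(self):
        trace = em.gen_bernoulli_trace(
            em.SyntheticConfig(family="bernoulli", length=10_000, seed=2,
                               p_pos=0.3))
        se = math.sqrt(0.3 * 0.7 / 10_000)
        assert abs(em.composition_probs(trace).p_positive - 0.3) < 3 * se


class TestRegionProbability:
    def test_half_cubed(self):
        probs = em.CompositionProbs(0.5, 0.5)
        score = em.region_probability(em.RunSegment("POS", 3, 0), probs)
        assert score.probability == pytest.approx(0.125)
        assert score.log_score == pytest.approx(3 * math.log(0.5))

    def test_certainty(self):
        probs = em.CompositionProbs(0.0, 1.0)
        score = em.region_probability(em.RunSegment("NEG", 1, 0), probs)
        assert score.probability == 1.0 and score.log_score == 0.0

    def test_zero_probability_label_inconsistent(self):
        probs = em.CompositionProbs(1.0, 0.0)
        with pytest.raises(CompositionMismatchError):
            em.region_probability(em.RunSegment("NEG", 2, 0), probs)


class TestRegionLogScores:
    def test_direct_arithmetic(self):
        scores = em.region_log_scores(trace_from_string("PPN"))
        assert scores[0].log_score == pytest.approx(2 * math.log(2 / 3))
        assert scores[1].log_score == pytest.approx(math.log(1 / 3))

    def test_single_label_trace(self):
        scores = em.region_log_scores(trace_from_string("PPPP"))
        assert len(scores) == 1 and scores[0].probability == 1.0

    def test_alternating_all_half(self):
        scores = em.region_log_scores(trace_from_string("PN" * 50))
        assert all(s.log_score == pytest.approx(math.log(0.5)) for s in scores)

    @settings(max_examples=150, derandomize=True)
    @given(st.lists(st.booleans(), min_size=1, max_size=200))
    def test_arrangement_invariance_identity(self, bits):
        """Sum of per-region log scores depends only on composition."""
        trace = em.BasalTrace(np.array(bits, bool))
        total = sum(s.log_score for s in em.region_log_scores(trace))
        p = trace.n_pos / len(trace)
        expected = 0.0
        if trace.n_pos:
            expected += trace.n_pos * math.log(p)
        if trace.n_neg:
            expected += trace.n_neg * math.log(1 - p)
        assert abs(total - expected) < 1e-9


# ---------------------------------------------------------------------------
# analytic null moments
# ---------------------------------------------------------------------------

class TestRunsNullMoments:
    def test_balanced_five_against_enumeration(self):
        runs = [num_runs_of(a) for a in enumerate_arrangements(5, 5)]
        assert len(runs) == 252
        mean, var = em.runs_null_moments(5, 5)
        assert mean == pytest.approx(np.mean(runs), abs=1e-12)
        assert var == pytest.approx(np.var(runs), rel=1e-12)

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 9), (1, 5), (7, 2)])
    def test_unbalanced_against_enumeration(self, n_pos, n_neg):
        runs = [num_runs_of(a) for a in enumerate_arrangements(n_pos, n_neg)]
        mean, var = em.runs_null_moments(n_pos, n_neg)
        assert mean == pytest.approx(np.mean(runs), abs=1e-12)
        assert var == pytest.approx(np.var(runs), abs=1e-12)

    def test_single_label(self):
        assert em.runs_null_moments(7, 0) == (1.0, 0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            em.runs_null_moments(-1, 5)

    def test_monte_carlo_agreement(self, rng):
        """Permutation mean of the run count matches the analytic mean."""
        labels = np.repeat([True, False], 50)
        counts = []
        for _ in range(10_000):
            rng.shuffle(labels)
            counts.append(num_runs_of(labels))
        mean, var = em.runs_null_moments(50, 50)
        se = math.sqrt(var / 10_000)
        assert abs(np.mean(counts) - mean) < 3 * se


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------

class TestPermutationTest:
    def test_two_blocks_highly_significant(self, balanced_trace):
        # exact null P(R <= 2) = 2 / C(20,10) ~ 1.1e-5
        res = em.permutation_test(balanced_trace, "num_runs",
                                  n_perm=10_000, seed=7)
        assert res.n_runs == 2
        assert res.perm_p_value <= 0.01

    def test_alternating_p_is_one(self, alternating_trace):
        res = em.permutation_test(alternating_trace, "num_runs",
                                  n_perm=500, seed=7)
        assert res.n_runs == 20
        assert res.perm_p_value == 1.0

    def test_single_label_not_testable(self):
        with pytest.raises(DegenerateTraceError, match="not testable"):
            em.permutation_test(trace_from_string("PPPP"), seed=1)

    def test_small_n_perm_rejected(self, balanced_trace):
        with pytest.raises(ValidationError):
            em.permutation_test(balanced_trace, n_perm=50, seed=1)

    def test_seed_required_and_reproducible(self, balanced_trace):
        with pytest.raises(ValidationError):
            em.permutation_test(balanced_trace, n_perm=100)
        a = em.permutation_test(balanced_trace, n_perm=500, seed=42)
        b = em.permutation_test(balanced_trace, n_perm=500, seed=42)
        assert a.perm_p_value == b.perm_p_value

    @pytest.mark.parametrize("statistic",
                             ["num_runs", "max_run", "mean_region_log_score"])
    def test_label_symmetry(self, statistic):
        """Swapping POS and NEG leaves run count and p-value unchanged."""
        trace = trace_from_string("PPPNNPNNNNPPPP", "s")
        swapped = em.BasalTrace(~trace.labels, "s")
        a = em.permutation_test(trace, statistic, n_perm=2000, seed=9)
        b = em.permutation_test(swapped, statistic, n_perm=2000, seed=9)
        assert a.n_runs == b.n_runs
        assert a.perm_p_value == b.perm_p_value
        np.testing.assert_allclose(np.sort(np.abs(a.log_scores())),
                                   np.sort(np.abs(b.log_scores())))

    @pytest.mark.parametrize("statistic", ["num_runs", "max_run"])
    def test_matches_exhaustive_enumeration_small(self, statistic):
        """Permutation p agrees with the exhaustive oracle on short traces."""
        n_perm = 5000
        tol = 2 / math.sqrt(n_perm)
        rng = np.random.default_rng(5)
        for length in (5, 8, 10):
            for _ in range(3):
                labels = rng.random(length) < 0.5
                if labels.all() or not labels.any():
                    continue
                trace = em.BasalTrace(labels)
                res = em.permutation_test(trace, statistic,
                                          n_perm=n_perm, seed=int(rng.integers(1 << 30)))
                assert abs(res.perm_p_value - exact_p_value(labels, statistic)) < tol

    def test_mean_log_score_matches_run_count_direction(self, balanced_trace):
        """Fewer runs means a more negative mean per-region log score, so the
        two statistics give identical permutation p-values."""
        a = em.permutation_test(balanced_trace, "num_runs", n_perm=2000, seed=3)
        b = em.permutation_test(balanced_trace, "mean_region_log_score",
                                n_perm=2000, seed=3)
        assert a.perm_p_value == b.perm_p_value


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestContiguityReport:
    def test_per_trace_independent_results(self):
        traces = [trace_from_string("PPPNNN", "a"),
                  trace_from_string("PNPNPN", "b")]
        results = em.contiguity_report(traces, "per_trace", n_perm=500, seed=1)
        assert [r.source_id for r in results] == ["a", "b"]
        assert results[0].perm_p_value < results[1].perm_p_value

    def test_pooled_run_count_sums(self):
        traces = [trace_from_string("PPPNNN", "emb1"),
                  trace_from_string("PPNN", "emb1")]
        pooled = em.contiguity_report(traces, "pooled", n_perm=500, seed=1)
        assert len(pooled) == 1
        assert pooled[0].n_runs == 2 + 2
        per = em.contiguity_report(traces, "per_trace", n_perm=500, seed=1)
        assert pooled[0].n_runs == sum(r.n_runs for r in per)

    def test_pooled_groups_by_animal(self):
        traces = [trace_from_string("PPNN", "emb1"),
                  trace_from_string("PN", "emb1"),
                  trace_from_string("PPPN", "emb2")]
        pooled = em.contiguity_report(traces, "pooled", n_perm=500, seed=1)
        assert [r.source_id for r in pooled] == ["emb1", "emb2"]

    def test_single_label_trace_reported_untestable(self):
        results = em.contiguity_report(
            [trace_from_string("PPPP", "mono")], "per_trace",
            n_perm=500, seed=1)
        assert results[0].testable is False
        assert math.isnan(results[0].perm_p_value)

    def test_markov_scores_more_negative_than_bernoulli(self):
        """Clustered traces carry longer, lower-probability regions."""
        medians = {}
        for family, theta in (("markov", 0.95), ("bernoulli", None)):
            scores = []
            for seed in range(10):
                cfg = em.SyntheticConfig(family=family, length=2000,
                                         seed=100 + seed, p_pos=0.5,
                                         theta=theta)
                trace = (em.gen_markov_trace(cfg) if family == "markov"
                         else em.gen_bernoulli_trace(cfg))
                scores.extend(s.log_score for s in em.region_log_scores(trace))
            medians[family] = np.median(scores)
        assert medians["markov"] < medians["bernoulli"]


# ---------------------------------------------------------------------------
# persistence estimate
# ---------------------------------------------------------------------------

class TestEstimatePersistence:
    def test_alternating_stay_freq_zero(self, alternating_trace):
        est = em.estimate_persistence(alternating_trace)
        assert est.stay_freq == 0.0
        assert est.theta_hat == -1.0  # more alternating than random

    def test_single_run_trace(self):
        est = em.estimate_persistence(trace_from_string("P" * 10))
        assert est.stay_freq == 1.0 and est.theta_hat == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            em.estimate_persistence(trace_from_string("P"))

    def test_iid_trace_has_near_zero_theta(self):
        """theta_hat corrects for composition: i.i.d. traces read ~0 even
        when unbalanced (where the raw stay frequency reads high)."""
        cfg = em.SyntheticConfig(family="bernoulli", length=20_000, seed=3,
                                 p_pos=0.8)
        est = em.estimate_persistence(em.gen_bernoulli_trace(cfg))
        assert est.stay_freq > 0.5  # raw frequency inflated by composition
        assert abs(est.theta_hat) < 4 * est.se

    def test_recovers_markov_theta(self):
        cfg = em.SyntheticConfig(family="markov", length=10_000, seed=8,
                                 p_pos=0.5, theta=0.9)
        est = em.estimate_persistence(em.gen_markov_trace(cfg))
        assert est.theta_hat == pytest.approx(0.9, abs=0.02)
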