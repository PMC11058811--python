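"""Contiguity statistics for binary basal-layer traces.

The mosaic arrangement of donor (EGFP+) and host (EGFP-) cells along the
basal layer is quantified in three layers:

1. **Composition probabilities** — the per-pixel frequency of each label,
   ``p_pos = n_pos / n`` and ``p_neg = n_neg / n``.
2. **Per-region scores** — each maximal same-label region of length ``L``
   is assigned the probability ``p_label ** L`` it would have as a block of
   i.i.d. draws at the observed composition; scores are reported as natural
   logs, ``L * ln(p_label)``.
3. **Null models and tests** — a key algebraic fact is that the *sum* of the
   per-region log scores equals ``n_pos*ln(p_pos) + n_neg*ln(p_neg)`` for
   every arrangement of a fixed composition, so the total log product alone
   cannot distinguish clustering from random intermixing.  The package
   therefore keeps the per-region score distribution and, for the formal
   "more contiguous than random" question, tests run-based statistics
   against the composition-conditional null of a uniformly shuffled trace:
   analytic Wald-Wolfowitz moments of the run count, and seeded permutation
   tests on run count, longest run, or mean per-region log score.

All p-values are one-sided toward contiguity and use the add-one estimator
``(b + 1) / (n_perm + 1)`` so that zero is never reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    CompositionMismatchError,
    DegenerateTraceError,
    ValidationError,
)
from .io import NEG, POS, BasalTrace, RunSegment, run_length_encode

Statistic = Literal["num_runs", "max_run", "mean_region_log_score"]

STATISTICS = ("num_runs", "max_run", "mean_region_log_score")

DEFAULT_N_PERM = 10_000


# ---------------------------------------------------------------------------
# composition and per-region scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionProbs:
    """Per-pixel label frequencies of a trace (the random-arrangement null)."""

    p_positive: float
    p_negative: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_positive <= 1.0 and 0.0 <= self.p_negative <= 1.0):
            raise ValidationError("composition probabilities must lie in [0, 1]")
        if abs(self.p_positive + self.p_negative - 1.0) > 1e-12:
            raise ValidationError("composition probabilities must sum to 1")

    def prob_of(self, label: str) -> float:
        return self.p_positive if label == POS else self.p_negative


@dataclass(frozen=True)
class RegionScore:
    """Block probability and log score of one maximal region."""

    run: RunSegment
    probability: float
    log_score: float


@dataclass
class ContiguityResult:
    """Full contiguity analysis of one trace (or one pooled animal)."""

    source_id: str
    composition: CompositionProbs
    region_scores: list[RegionScore]
    total_log_prob: float
    n_runs: int
    max_run_pos: int
    max_run_neg: int
    n_pos: int
    n_neg: int
    null_mean_runs: float
    null_var_runs: float
    perm_p_value: float
    perm_statistic: str
    n_perm: int
    seed: int
    testable: bool = True

    def log_scores(self, label: str | None = None) -> np.ndarray:
        """Per-region log scores, optionally restricted to one label."""
        return np.array(
            [s.log_score for s in self.region_scores
             if label is None or s.run.label == label]
        )


def composition_probs(trace: BasalTrace) -> CompositionProbs:
    """Per-pixel label frequencies: ``p_pos = n_pos / n``."""
    n = len(trace)
    return CompositionProbs(
        p_positive=trace.n_pos / n, p_negative=trace.n_neg / n
    )


def region_probability(run: RunSegment, probs: CompositionProbs) -> RegionScore:
    """Block probability ``p_label ** L`` of one region, computed in log space."""
    p = probs.prob_of(run.label)
    if p == 0.0:
        raise CompositionMismatchError(
            f"run of label {run.label} is impossible under a composition "
            f"with p_{run.label.lower()} = 0; composition must come from "
            "the same trace"
        )
    log_score = run.length * math.log(p)
    return RegionScore(run=run, probability=math.exp(log_score),
                       log_score=log_score)


def region_log_scores(trace: BasalTrace) -> list[RegionScore]:
    """Score every maximal region of a trace against its own composition."""
    probs = composition_probs(trace)
    return [region_probability(run, probs) for run in run_length_encode(trace)]


# ---------------------------------------------------------------------------
# analytic null: Wald-Wolfowitz run-count moments
# ---------------------------------------------------------------------------

def runs_null_moments(n_pos: int, n_neg: int) -> tuple[float, float]:
    """Mean and variance of the run count under uniform random arrangement.

    For a sequence holding ``n_pos`` and ``n_neg`` labels in uniformly
    random order (``n = n_pos + n_neg``):

    * mean ``= 1 + 2 n_pos n_neg / n``
    * variance ``= 2 n_pos n_neg (2 n_pos n_neg - n) / (n^2 (n - 1))``

    the classical Wald-Wolfowitz moments; variance is defined as 0 when
    ``n == 1``.
    """
    if n_pos < 0 or n_neg < 0:
        raise ValidationError("label counts must be non-negative")
    n = n_pos + n_neg
    if n < 1:
        raise ValidationError("need at least one pixel")
    mean = 1.0 + 2.0 * n_pos * n_neg / n
    if n == 1:
        return mean, 0.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1))
    return mean, max(var, 0.0)


# ---------------------------------------------------------------------------
# permutation machinery
# ---------------------------------------------------------------------------

def _num_runs_rows(mat: np.ndarray) -> np.ndarray:
    """Run count of every row of a 2D boolean matrix."""
    return 1 + (np.diff(mat, axis=1) != 0).sum(axis=1)


def _max_run_rows(mat: np.ndarray) -> np.ndarray:
    """Longest run (either label) of every row, vectorized via reduceat."""
    m, n = mat.shape
    flat = mat.ravel()
    is_start = np.empty(m * n, dtype=bool)
    is_start[0] = True
    is_start[1:] = flat[1:] != flat[:-1]
    is_start[::n] = True  # force run breaks at row boundaries
    starts = np.flatnonzero(is_start)
    lengths = np.diff(np.append(starts, m * n))
    first_per_row = np.searchsorted(starts, np.arange(m) * n)
    return np.maximum.reduceat(lengths, first_per_row)


def _max_run_of(labels: np.ndarray, which: bool) -> int:
    """Longest run of one label value in a 1D boolean array (0 if absent)."""
    x = labels == which
    if not x.any():
        return 0
    runs = np.diff(np.flatnonzero(np.diff(np.concatenate(([0], x.view(np.int8), [0])))))
    return int(runs[::2].max()) if runs.size else 0


def _perm_statistic_values(
    mat: np.ndarray, statistic: str, total_log_prob: float
) -> np.ndarray:
    if statistic == "num_runs":
        return _num_runs_rows(mat)
    if statistic == "max_run":
        return _max_run_rows(mat)
    if statistic == "mean_region_log_score":
        # the summed log score is arrangement-invariant, so only the run
        # count varies across permutations
        return total_log_prob / _num_runs_rows(mat)
    raise ValidationError(
        f"unknown statistic {statistic!r}; choose from {STATISTICS}"
    )


def _observed_statistic(trace: BasalTrace, statistic: str,
                        total_log_prob: float) -> float:
    row = trace.labels[None, :]
    return float(_perm_statistic_values(row, statistic, total_log_prob)[0])


def _one_sided_exceedance(statistic: str, null_values: np.ndarray,
                          observed: float) -> np.ndarray:
    """Boolean mask of null draws at least as contiguous as observed.

    Contiguity means few runs, long maximal runs, low (very negative) mean
    per-region log scores.
    """
    if statistic == "num_runs":
        return null_values <= observed
    if statistic == "max_run":
        return null_values >= observed
    return null_values <= observed  # mean_region_log_score


def permutation_test(
    trace: BasalTrace,
    statistic: Statistic = "num_runs",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ContiguityResult:
    """One-sided permutation test of contiguity against random intermixing.

    The null shuffles the trace's labels uniformly, holding composition
    fixed.  The p-value is the add-one fraction of permutations at least as
    contiguous as the observed trace.

    Raises
    ------
    DegenerateTraceError
        If the trace holds a single label: its composition admits exactly
        one arrangement, so the hypothesis is not testable.
    """
    if seed is None:
        raise ValidationError("permutation_test requires an explicit seed")
    if n_perm < 100:
        raise ValidationError(f"n_perm must be >= 100, got {n_perm}")
    if trace.n_pos == 0 or trace.n_neg == 0:
        raise DegenerateTraceError(
            f"trace {trace.source_id!r} holds a single label; the "
            "composition-conditional null has one arrangement — report "
            "as 'not testable'"
        )
    if statistic not in STATISTICS:
        raise ValidationError(
            f"unknown statistic {statistic!r}; choose from {STATISTICS}"
        )

    scores = region_log_scores(trace)
    total_log_prob = float(sum(s.log_score for s in scores))
    observed = _observed_statistic(trace, statistic, total_log_prob)

    rng = np.random.default_rng(seed)
    mat = np.tile(trace.labels, (n_perm, 1))
    rng.permuted(mat, axis=1, out=mat)
    null_values = _perm_statistic_values(mat, statistic, total_log_prob)
    b = int(_one_sided_exceedance(statistic, null_values, observed).sum())
    p_value = (b + 1) / (n_perm + 1)

    mean, var = runs_null_moments(trace.n_pos, trace.n_neg)
    return ContiguityResult(
        source_id=trace.source_id,
        composition=composition_probs(trace),
        region_scores=scores,
        total_log_prob=total_log_prob,
        n_runs=int(_num_runs_rows(trace.labels[None, :])[0]),
        max_run_pos=_max_run_of(trace.labels, True),
        max_run_neg=_max_run_of(trace.labels, False),
        n_pos=trace.n_pos,
        n_neg=trace.n_neg,
        null_mean_runs=mean,
        null_var_runs=var,
        perm_p_value=p_value,
        perm_statistic=statistic,
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# aggregation across sections / animals
# ---------------------------------------------------------------------------

def _pooled_result(
    traces: Sequence[BasalTrace],
    source_id: str,
    statistic: str,
    n_perm: int,
    seed: int,
) -> ContiguityResult:
    """Pool sections of one animal: runs are computed per section, then the
    run lists concatenated, so no artificial junction region is created.

    The permutation null shuffles each section's labels independently
    (composition held fixed within each section).
    """
    n_pos = sum(t.n_pos for t in traces)
    n_neg = sum(t.n_neg for t in traces)
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0:
        raise DegenerateTraceError(
            f"pooled traces for {source_id!r} hold a single label; not testable"
        )
    composition = CompositionProbs(p_positive=n_pos / n, p_negative=n_neg / n)

    # per-region scores against the pooled composition
    scores: list[RegionScore] = []
    for t in traces:
        for run in run_length_encode(t):
            scores.append(region_probability(run, composition))
    total_log_prob = float(sum(s.log_score for s in scores))
    obs_runs = sum(int(_num_runs_rows(t.labels[None, :])[0]) for t in traces)
    obs_max = max(
        _max_run_rows(t.labels[None, :])[0] for t in traces
    )
    observed = {
        "num_runs": float(obs_runs),
        "max_run": float(obs_max),
        "mean_region_log_score": total_log_prob / obs_runs,
    }[statistic]

    rng = np.random.default_rng(seed)
    null_runs = np.zeros(n_perm, dtype=np.int64)
    null_max = np.zeros(n_perm, dtype=np.int64)
    for t in traces:
        mat = np.tile(t.labels, (n_perm, 1))
        rng.permuted(mat, axis=1, out=mat)
        null_runs += _num_runs_rows(mat)
        if statistic == "max_run":
            null_max = np.maximum(null_max, _max_run_rows(mat))
    if statistic == "num_runs":
        null_values: np.ndarray = null_runs
    elif statistic == "max_run":
        null_values = null_max
    else:
        null_values = total_log_prob / null_runs
    b = int(_one_sided_exceedance(statistic, null_values, observed).sum())

    moments = [runs_null_moments(t.n_pos, t.n_neg) for t in traces]
    return ContiguityResult(
        source_id=source_id,
        composition=composition,
        region_scores=scores,
        total_log_prob=total_log_prob,
        n_runs=obs_runs,
        max_run_pos=max(_max_run_of(t.labels, True) for t in traces),
        max_run_neg=max(_max_run_of(t.labels, False) for t in traces),
        n_pos=n_pos,
        n_neg=n_neg,
        null_mean_runs=float(sum(m for m, _ in moments)),
        null_var_runs=float(sum(v for _, v in moments)),
        perm_p_value=(b + 1) / (n_perm + 1),
        perm_statistic=statistic,
        n_perm=n_perm,
        seed=seed,
    )


def contiguity_report(
    traces: Sequence[BasalTrace],
    aggregation: Literal["per_trace", "pooled"] = "per_trace",
    statistic: Statistic = "num_runs",
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> list[ContiguityResult]:
    """Run the contiguity analysis over many traces.

    ``per_trace`` tests each section independently; ``pooled`` groups
    sections by ``source_id`` (one result per animal), concatenating run
    lists rather than pixel sequences.  Single-label inputs yield a result
    flagged ``testable=False`` with ``perm_p_value = nan`` instead of a
    p-value.
    """
    if not traces:
        raise ValidationError("need at least one trace")
    if seed is None:
        raise ValidationError("contiguity_report requires an explicit seed")
    seeds = np.random.SeedSequence(seed).generate_state(len(traces) + 1)

    if aggregation == "per_trace":
        results = []
        for sub_seed, trace in zip(seeds, traces):
            try:
                results.append(
                    permutation_test(trace, statistic=statistic,
                                     n_perm=n_perm, seed=int(sub_seed >> 1))
                )
            except DegenerateTraceError:
                results.append(_untestable_result(trace, statistic, n_perm, seed))
        return results
    if aggregation == "pooled":
        groups: dict[str, list[BasalTrace]] = {}
        for t in traces:
            groups.setdefault(t.source_id, []).append(t)
        results = []
        for sub_seed, (source_id, group) in zip(seeds, groups.items()):
            try:
                results.append(
                    _pooled_result(group, source_id, statistic, n_perm,
                                   int(sub_seed >> 1))
                )
            except DegenerateTraceError:
                results.append(
                    _untestable_pooled(group, source_id, statistic, n_perm, seed)
                )
        return results
    raise ValidationError(
        f"aggregation must be 'per_trace' or 'pooled', got {aggregation!r}"
    )


def _untestable_result(trace: BasalTrace, statistic: str, n_perm: int,
                       seed: int) -> ContiguityResult:
    scores = region_log_scores(trace)
    mean, var = runs_null_moments(trace.n_pos, trace.n_neg)
    return ContiguityResult(
        source_id=trace.source_id,
        composition=composition_probs(trace),
        region_scores=scores,
        total_log_prob=float(sum(s.log_score for s in scores)),
        n_runs=1,
        max_run_pos=_max_run_of(trace.labels, True),
        max_run_neg=_max_run_of(trace.labels, False),
        n_pos=trace.n_pos,
        n_neg=trace.n_neg,
        null_mean_runs=mean,
        null_var_runs=var,
        perm_p_value=float("nan"),
        perm_statistic=statistic,
        n_perm=n_perm,
        seed=seed,
        testable=False,
    )


def _untestable_pooled(traces: Sequence[BasalTrace], source_id: str,
                       statistic: str, n_perm: int, seed: int) -> ContiguityResult:
    n_pos = sum(t.n_pos for t in traces)
    n_neg = sum(t.n_neg for t in traces)
    n = n_pos + n_neg
    composition = CompositionProbs(p_positive=n_pos / n, p_negative=n_neg / n)
    scores = [
        region_probability(run, composition)
        for t in traces for run in run_length_encode(t)
    ]
    moments = [runs_null_moments(t.n_pos, t.n_neg) for t in traces]
    return ContiguityResult(
        source_id=source_id,
        composition=composition,
        region_scores=scores,
        total_log_prob=float(sum(s.log_score for s in scores)),
        n_runs=len(scores),
        max_run_pos=max(_max_run_of(t.labels, True) for t in traces),
        max_run_neg=max(_max_run_of(t.labels, False) for t in traces),
        n_pos=n_pos,
        n_neg=n_neg,
        null_mean_runs=float(sum(m for m, _ in moments)),
        null_var_runs=float(sum(v for _, v in moments)),
        perm_p_value=float("nan"),
        perm_statistic=statistic,
        n_perm=n_perm,
        seed=seed,
        testable=False,
    )


# ---------------------------------------------------------------------------
# persistence (effect size)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersistenceEstimate:
    """Clustering strength of a trace on two scales.

    ``stay_freq`` is the raw same-label transition frequency,
    ``1 - changes / (length - 1)``.  ``theta_hat`` converts it to the
    persistence parameter of the redraw-parameterised two-state chain
    (stay probability ``theta + (1 - theta) * pi_s``): under that chain the
    marginal stay frequency is ``theta + (1 - theta) * q`` with
    ``q = p^2 + (1 - p)^2``, so ``theta_hat = (stay_freq - q) / (1 - q)``
    with the trace's own composition plugged in for ``p``.  ``theta_hat``
    is 0 for i.i.d. traces of any composition, where ``stay_freq`` alone
    would read high for unbalanced compositions.
    """

    theta_hat: float
    se: float
    stay_freq: float
    se_stay: float
    n_transitions: int


def estimate_persistence(trace: BasalTrace) -> PersistenceEstimate:
    """Estimate clustering strength from the label-change count.

    The change count is treated as binomial over ``length - 1``
    transitions for the standard error; the generator-scale estimate and
    its delta-method SE divide by ``1 - q`` (``q`` from the observed
    composition).  ``theta_hat`` is clipped to [-1, 1]; values below 0
    indicate arrangements more alternating than random.
    """
    n = len(trace)
    if n < 2:
        raise ValidationError("persistence needs a trace of length >= 2")
    changes = int((np.diff(trace.labels) != 0).sum())
    m = n - 1
    stay = 1.0 - changes / m
    se_stay = math.sqrt(max(stay * (1.0 - stay), 0.0) / m)
    p = trace.n_pos / n
    q = p * p + (1.0 - p) * (1.0 - p)
    if q >= 1.0:  # single-label trace: persistence unidentified, report 1
        return PersistenceEstimate(theta_hat=1.0, se=0.0, stay_freq=stay,
                                   se_stay=se_stay, n_transitions=m)
    theta_hat = (stay - q) / (1.0 - q)
    theta_hat = min(max(theta_hat, -1.0), 1.0)
    return PersistenceEstimate(
        theta_hat=theta_hat, se=se_stay / (1.0 - q), stay_freq=stay,
        se_stay=se_stay, n_transitions=m,
    )
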