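"""Generalized pairwise comparisons (GPC) and net treatment benefit.

Every verum observation unit is compared with every placebo unit (unmatched)
or only with the same subject's other period (matched).  Each pair gets a
score in {-1, 0, +1} (or, for the non-prioritized multivariate variant, a
fraction in [-1, 1]); the net treatment benefit Delta is the mean score over
all pairs — the probability that a random subject does better on verum minus
the probability of the reverse, range [-1, +1].

Comparison variants:

* ``univariate`` — each period block is collapsed to one summary measure
  (default: change from baseline at the post-treatment visit) and the
  summaries are compared;
* ``prioritized`` — time points are compared in a clinical priority order
  (default t3, t4, t2, t1); the first non-tied comparison decides the pair;
* ``nonprioritized`` — the four per-time scores are averaged.

Since the raw outcomes here are harms (blister counts, pain/pruritus VAS),
the default orientation is ``lower_is_better``, so Delta > 0 reads as a
verum benefit.  ``higher_is_better`` recovers the raw "+1 if V1 > V2"
scoring convention.

Inference: unmatched variants use a within-subject treatment-label-swap
permutation test of H0 "the two treatment arms share one outcome
distribution"; matched variants use the exact conditional sign test, which
conditions on the non-tied pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .trial_data import TrialDataset, PeriodBlock, summarize_block

__all__ = [
    "GPCConfig", "GPCResult",
    "score_pair", "score_pair_prioritized", "score_pair_nonprioritized",
    "net_benefit_unmatched", "net_benefit_matched",
    "permutation_test_unmatched", "conditional_sign_test",
]

PAIRINGS = ("unmatched", "matched")
COMPARISONS = ("univariate", "prioritized", "nonprioritized")
DIRECTIONS = ("lower_is_better", "higher_is_better")

#: matched GPC needs at least this many pairs for a meaningful sign test
MIN_MATCHED_SUBJECTS = 15


@dataclass
class GPCConfig:
    pairing: str = "unmatched"
    comparison: str = "prioritized"
    priority_order: tuple[int, ...] = (3, 4, 2, 1)
    direction: str = "lower_is_better"
    summary: str = "change_from_baseline_t3"   # univariate only
    outcome: str = "count"
    n_perm: int = 1000
    exact: bool = False   # enumerate all 2^n label swaps instead of sampling

    def validate(self) -> None:
        if self.pairing not in PAIRINGS:
            raise ValueError(f"pairing must be one of {PAIRINGS}")
        if self.comparison not in COMPARISONS:
            raise ValueError(f"comparison must be one of {COMPARISONS}")
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if sorted(self.priority_order) != [1, 2, 3, 4]:
            raise ValueError("priority_order must be a permutation of 1..4")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class GPCResult:
    """Win/loss/tie accounting, net benefit and (optionally) a p-value.

    ``delta`` is the mean pairwise score; for integer-scored variants it
    equals ``(wins - losses) / n_pairs`` exactly.  ``small_sample_warning``
    flags matched analyses with fewer pairs than the sign test needs.
    """

    delta: float
    wins: int
    losses: int
    ties: int
    n_pairs: int
    p_value: float | None = None
    small_sample_warning: bool = False
    config: GPCConfig | None = field(default=None, repr=False)


# -- pair-level scoring ----------------------------------------------------

def score_pair(v1: float, v2: float, direction: str = "lower_is_better") -> int:
    """Score one (verum value, placebo value) pair as -1, 0 or +1.

    ``lower_is_better``: +1 iff v1 < v2 (verum did better on a harm scale).
    ``higher_is_better``: +1 iff v1 > v2 (the raw scoring convention).
    Ties score 0 — they are first-class, never broken.
    """
    s = np.sign(v2 - v1) if direction == "lower_is_better" else np.sign(v1 - v2)
    return int(s)


def score_pair_prioritized(block1, block2, priority_order=(3, 4, 2, 1),
                           direction: str = "lower_is_better") -> int:
    """Resolve a pair of 4-vectors down the time-priority ladder.

    The highest-priority time decides; on a tie the next time point is
    consulted, and an all-tie pair scores 0.
    """
    v1 = block1.values if isinstance(block1, PeriodBlock) else np.asarray(block1)
    v2 = block2.values if isinstance(block2, PeriodBlock) else np.asarray(block2)
    for t in priority_order:
        s = score_pair(v1[t - 1], v2[t - 1], direction)
        if s != 0:
            return s
    return 0


def score_pair_nonprioritized(block1, block2,
                              direction: str = "lower_is_better") -> float:
    """Average of the four per-time scores; a rational number in [-1, 1]."""
    v1 = block1.values if isinstance(block1, PeriodBlock) else np.asarray(block1)
    v2 = block2.values if isinstance(block2, PeriodBlock) else np.asarray(block2)
    return float(np.mean([score_pair(a, b, direction) for a, b in zip(v1, v2)]))


# -- vectorized scoring over all block pairs -------------------------------

def _pairwise_sign(values: np.ndarray, direction: str) -> np.ndarray:
    """values (m,) -> (m, m) score of value_i as verum vs value_j as placebo."""
    diff = values[None, :] - values[:, None]  # v_j - v_i
    return np.sign(diff) if direction == "lower_is_better" else np.sign(-diff)


def _score_matrix(dataset: TrialDataset, config: GPCConfig) -> np.ndarray:
    """(2n, 2n) matrix: U[i, j] = score of block i (verum) vs block j (placebo).

    Precomputing scores between *all* blocks lets every label permutation be
    evaluated by pure indexing, which is what makes the permutation test and
    the simulation benchmarks cheap.
    """
    blocks = dataset.block_matrix(config.outcome)
    if config.comparison == "univariate":
        summaries = np.array([
            summarize_block(PeriodBlock("x", 1, "verum", row), config.summary)
            for row in blocks
        ])
        return _pairwise_sign(summaries, config.direction)
    per_time = np.stack([_pairwise_sign(blocks[:, t], config.direction)
                         for t in range(4)])  # (4, m, m)
    if config.comparison == "nonprioritized":
        return per_time.mean(axis=0)
    # prioritized: first non-zero down the ladder
    U = np.zeros_like(per_time[0])
    for t in config.priority_order:
        U = np.where(U == 0, per_time[t - 1], U)
    return U


def _arm_indices(dataset: TrialDataset) -> tuple[np.ndarray, np.ndarray]:
    """Canonical-block indices of each subject's (verum, placebo) block."""
    treatments = dataset.block_treatments()
    n = len(treatments) // 2
    verum = np.empty(n, dtype=int)
    placebo = np.empty(n, dtype=int)
    for k in range(n):
        i, j = 2 * k, 2 * k + 1  # subject k's period-1 and period-2 blocks
        if treatments[i] == "verum":
            verum[k], placebo[k] = i, j
        else:
            verum[k], placebo[k] = j, i
    return verum, placebo


def _accounting(scores: np.ndarray) -> tuple[int, int, int]:
    wins = int((scores > 0).sum())
    losses = int((scores < 0).sum())
    ties = int(scores.size) - wins - losses
    return wins, losses, ties


# -- net benefit -----------------------------------------------------------

def net_benefit_unmatched(dataset: TrialDataset,
                          config: GPCConfig | None = None) -> GPCResult:
    """Net treatment benefit over all n^2 verum-placebo block pairs.

    Periods are treated as independent, so a subject's own two blocks are
    paired together as well; this ignores the cross-over structure but uses
    every pair.
    """
    config = config or GPCConfig()
    config.validate()
    U = _score_matrix(dataset, config)
    verum, placebo = _arm_indices(dataset)
    if len(verum) == 0:
        raise ValueError("empty treatment arm")
    scores = U[np.ix_(verum, placebo)]
    wins, losses, ties = _accounting(scores)
    return GPCResult(delta=float(scores.mean()), wins=wins, losses=losses,
                     ties=ties, n_pairs=scores.size, config=config)


def net_benefit_matched(dataset: TrialDataset,
                        config: GPCConfig | None = None) -> GPCResult:
    """Net treatment benefit over the n within-subject pairs only."""
    config = config or GPCConfig(pairing="matched")
    config = replace(config, pairing="matched")
    config.validate()
    U = _score_matrix(dataset, config)
    verum, placebo = _arm_indices(dataset)
    scores = U[verum, placebo]
    wins, losses, ties = _accounting(scores)
    return GPCResult(delta=float(scores.mean()), wins=wins, losses=losses,
                     ties=ties, n_pairs=scores.size,
                     small_sample_warning=len(verum) < MIN_MATCHED_SUBJECTS,
                     config=config)


# -- inference -------------------------------------------------------------

def _swap_deltas(U: np.ndarray, verum: np.ndarray, placebo: np.ndarray,
                 swaps: np.ndarray) -> np.ndarray:
    """Delta for each label-swap vector; swaps has shape (B, n) in {0, 1}."""
    v = np.where(swaps == 1, placebo[None, :], verum[None, :])   # (B, n)
    p = np.where(swaps == 1, verum[None, :], placebo[None, :])
    return U[v[:, :, None], p[:, None, :]].mean(axis=(1, 2))


def permutation_test_unmatched(dataset: TrialDataset,
                               config: GPCConfig | None = None,
                               seed: int | np.random.Generator = 0) -> GPCResult:
    """Two-sided permutation test of the unmatched net benefit.

    The reference distribution swaps, independently per subject with
    probability 1/2, which of the subject's two period blocks is labelled
    verum.  This preserves the within-subject dependence while making the
    arms exchangeable under H0.  With ``config.exact`` all 2^n swap vectors
    are enumerated and p = #(|Delta*| >= |Delta_obs|) / 2^n; otherwise
    ``n_perm`` random swaps give the add-one randomization-test estimate
    p = (1 + #(|Delta*| >= |Delta_obs|)) / (n_perm + 1), avoiding p = 0.
    """
    config = config or GPCConfig()
    config.validate()
    result = net_benefit_unmatched(dataset, config)
    U = _score_matrix(dataset, config)
    verum, placebo = _arm_indices(dataset)
    n = len(verum)
    obs = abs(result.delta)

    if config.exact:
        if n > 20:
            raise ValueError("exact enumeration limited to n <= 20 subjects")
        swaps = np.array(list(itertools.product((0, 1), repeat=n)), dtype=int)
        deltas = _swap_deltas(U, verum, placebo, swaps)
        p = float((np.abs(deltas) >= obs - 1e-12).mean())
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        swaps = rng.integers(0, 2, size=(config.n_perm, n))
        deltas = _swap_deltas(U, verum, placebo, swaps)
        exceed = int((np.abs(deltas) >= obs - 1e-12).sum())
        p = (1.0 + exceed) / (config.n_perm + 1.0)
    result.p_value = min(1.0, p)
    return result


def conditional_sign_test(dataset: TrialDataset,
                          config: GPCConfig | None = None) -> GPCResult:
    """Exact sign test of the matched GPC scores, conditioning on non-ties.

    With m non-tied within-subject scores and b of them favourable,
    p = min(1, 2 * min(P(B <= b), P(B >= b))) for B ~ Binomial(m, 1/2);
    all-tie data give p = 1.  The result carries a warning flag below
    ``MIN_MATCHED_SUBJECTS`` subjects, where the number of pairs is too small
    for the test to be meaningful.
    """
    config = config or GPCConfig(pairing="matched")
    result = net_benefit_matched(dataset, config)
    m = result.wins + result.losses
    if m == 0:
        result.p_value = 1.0
        return result
    b = result.wins
    p = 2.0 * min(stats.binom.cdf(b, m, 0.5), stats.binom.sf(b - 1, m, 0.5))
    result.p_value = min(1.0, float(p))
    return result
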