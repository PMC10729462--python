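"""Nonparametric marginal model: relative effects and the ANOVA-type statistic.

For one treatment period the data form a 2 (treatment group, whole-plot) x 4
(time, sub-plot) factorial with independent subjects between groups and
repeated measures within subject.  Effects are measured on the rank scale:
the relative effect p = P(X1 < X2) + 0.5 * P(X1 = X2) of one distribution
with respect to another, estimated by midranks so that ties (inevitable for
counts and gridded VAS scores) are handled exactly.

The treatment-by-time interaction — "do the longitudinal profiles differ
between treatments?" — is tested with the ANOVA-type statistic (ATS), a
quadratic form in the contrasted cell mean ranks whose null distribution is
approximated by an F distribution with box-type estimated numerator degrees
of freedom (denominator infinite by default; a finite-denominator variant is
available).  Because periods of a cross-over cannot be pooled on the rank
scale without mixing dependence structures, the test is applied to each
period separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TrialDataset, TREATMENTS

__all__ = ["RelativeEffectTable", "ATSResult", "relative_effect",
           "ats_interaction_test", "nmm_crossover"]


def relative_effect(sample1, sample2) -> float:
    """Estimate p = P(X1 < X2) + 0.5 * P(X1 = X2) by midranks.

    Equals the pair-counting estimate (#{x1 < x2} + 0.5 #{x1 = x2}) / (n1 n2);
    0.5 means no tendency, 1.0 means sample2 stochastically above sample1.
    """
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size == 0 or x2.size == 0:
        raise ValueError("samples must be non-empty")
    ranks = stats.rankdata(np.concatenate([x1, x2]))
    mean_rank_2 = ranks[x1.size:].mean()
    return float((mean_rank_2 - (x2.size + 1) / 2.0) / x1.size)


@dataclass
class RelativeEffectTable:
    """Estimated relative effect of each (group, time) cell vs the pooled data."""

    effects: pd.DataFrame = field(repr=False)  # index=group, columns=time
    group_sizes: dict[str, int] = field(default_factory=dict)

    def __getitem__(self, key: tuple[str, int]) -> float:
        group, time = key
        return float(self.effects.loc[group, time])


@dataclass
class ATSResult:
    statistic: float
    df: float              # box-type numerator degrees of freedom
    p_value: float
    period: int
    contrast: str = "interaction"
    relative_effects: RelativeEffectTable | None = field(default=None,
                                                         repr=False)


def _period_matrices(dataset: TrialDataset, period: int,
                     outcome: str) -> dict[str, np.ndarray]:
    if period not in (1, 2):
        raise ValueError("period must be 1 or 2")
    mat = dataset.block_matrix(outcome)
    periods = dataset.df["period"].to_numpy()[::4]
    treatments = dataset.block_treatments()
    out = {}
    for g in TREATMENTS:
        out[g] = mat[(periods == period) & (treatments == g)]
    return out


def ats_interaction_test(dataset: TrialDataset, period: int,
                         outcome: str = "count",
                         denominator: str = "infinite") -> ATSResult:
    """ANOVA-type test of the treatment-by-time interaction in one period.

    Midranks are taken over all observations of the period; the 2x4 cell
    mean-rank vector is contrasted by the interaction projection
    T = (I2 - J2/2) (x) (I4 - J4/4); the statistic is the quadratic form
    normalized by trace(T V) with V the estimated covariance of the cell
    means, and the numerator df is the box approximation
    trace(T V)^2 / trace(T V T V).  ``denominator='finite'`` uses the
    matching finite denominator df instead of infinity.
    """
    groups = _period_matrices(dataset, period, outcome)
    sizes = {g: m.shape[0] for g, m in groups.items()}
    if min(sizes.values()) < 2:
        raise ValueError("each treatment group needs at least 2 subjects "
                         f"in period {period} (got {sizes})")

    stacked = np.vstack([groups[g] for g in TREATMENTS])
    N = stacked.size
    ranks = stats.rankdata(stacked.ravel()).reshape(stacked.shape) / N

    # per-group normalized rank matrices, cell means and covariances
    offset = 0
    means, covs, ns = [], [], []
    effects = {}
    for g in TREATMENTS:
        n_g = sizes[g]
        R = ranks[offset:offset + n_g]
        offset += n_g
        means.append(R.mean(axis=0))
        covs.append(np.cov(R, rowvar=False, ddof=1) / n_g)
        ns.append(n_g)
        effects[g] = R.mean(axis=0) * N  # mean midranks
    p_hat = np.concatenate(means)                      # (8,)
    V = np.zeros((8, 8))
    V[:4, :4], V[4:, 4:] = covs[0], covs[1]

    eff = pd.DataFrame(
        {t + 1: [(effects[g][t] - 0.5) / N for g in TREATMENTS]
         for t in range(4)},
        index=list(TREATMENTS))
    table = RelativeEffectTable(effects=eff,
                                group_sizes={g: sizes[g] for g in TREATMENTS})

    P2 = np.eye(2) - np.full((2, 2), 0.5)
    P4 = np.eye(4) - np.full((4, 4), 0.25)
    T = np.kron(P2, P4)

    TV = T @ V
    tr_TV = float(np.trace(TV))
    if tr_TV <= 1e-14:
        return ATSResult(statistic=0.0, df=1.0, p_value=1.0, period=period,
                         relative_effects=table)
    statistic = float(p_hat @ T @ p_hat) / tr_TV
    f_num = tr_TV ** 2 / float(np.trace(TV @ TV))

    if denominator == "infinite":
        p_value = float(stats.chi2.sf(f_num * statistic, f_num))
    elif denominator == "finite":
        # box-type denominator df from the group-wise diagonal blocks of T V
        denom = 0.0
        for a, (S, n_g) in enumerate(zip(covs, ns)):
            T_aa = T[4 * a:4 * a + 4, 4 * a:4 * a + 4]
            denom += float(np.trace(T_aa @ S)) ** 2 / (n_g - 1)
        f_den = tr_TV ** 2 / denom if denom > 0 else np.inf
        p_value = float(stats.f.sf(statistic, f_num, f_den))
    else:
        raise ValueError("denominator must be 'infinite' or 'finite'")
    return ATSResult(statistic=statistic, df=f_num, p_value=p_value,
                     period=period, relative_effects=table)


RULES = ("per_period", "bonferroni", "min_p")


def nmm_crossover(dataset: TrialDataset, outcome: str = "count",
                  rule: str = "per_period", alpha: float = 0.05,
                  denominator: str = "infinite"):
    """Interaction test in both periods plus a combined decision.

    ``per_period`` reports both tests without combining; ``bonferroni``
    rejects if min p < alpha/2; ``min_p`` rejects if min p < alpha (a liberal
    union rule, included because separate per-period testing is itself
    liberal when read as one procedure).

    Returns ``(result_period1, result_period2, reject)`` with ``reject``
    None under ``per_period``.
    """
    if rule not in RULES:
        raise ValueError(f"rule must be one of {RULES}")
    r1 = ats_interaction_test(dataset, 1, outcome, denominator)
    r2 = ats_interaction_test(dataset, 2, outcome, denominator)
    p_min = min(r1.p_value, r2.p_value)
    if rule == "per_period":
        reject = None
    elif rule == "bonferroni":
        reject = p_min < alpha / 2.0
    else:
        reject = p_min < alpha
    return r1, r2, reject
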