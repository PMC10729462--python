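"""AIC-weighted model averaging of treatment effects over a candidate pool.

With 15 subjects there is little information to pick a single parametric
model, so a predefined pool of plausible mean models is fitted by maximum
likelihood and their treatment-effect estimates are combined with Akaike
weights

    w_q = exp(-AIC_q / 2) / sum_q' exp(-AIC_q' / 2),

computed after subtracting the minimum AIC (the weights are invariant to a
common shift).  The averaged effect is a difference-in-differences of
response proportions (the "delta-delta" measure, post-treatment vs baseline)
for the binary outcome, or a weighted-geometric-mean rate ratio at the
post-treatment visit for counts.

Inference is by a within-subject treatment-label-swap permutation test of
the averaged effect.  A permutation construction is used deliberately: it is
exact under period exchangeability within subject regardless of how well any
candidate model fits, whereas analytic post-averaging variances are known to
be fragile in this sample-size regime (see docs/methods.md).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .trial_data import TrialDataset

__all__ = ["CandidateModel", "CandidatePool", "MAResult", "akaike_weights",
           "fit_pool", "averaged_effect", "ma_permutation_test",
           "default_pool"]

FAMILIES = ("poisson", "negbin", "binomial")
COUNT_FAMILIES = ("poisson", "negbin")


@dataclass(frozen=True)
class CandidateModel:
    """One candidate mean model.

    ``time``: categorical (three dummies) or linear trend; flags control the
    period main effect and the group-time / group-period interactions.  The
    treatment group main effect is always included (it is what the averaged
    effect measures).
    """

    name: str
    family: str
    time: str = "categorical"
    period: bool = True
    group_time: bool = True
    group_period: bool = False

    def validate(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.time not in ("categorical", "linear"):
            raise ValueError("time must be 'categorical' or 'linear'")


@dataclass
class CandidatePool:
    models: list[CandidateModel]

    def validate(self) -> None:
        if len(self.models) < 2:
            raise ValueError("a candidate pool needs at least 2 models")
        fams = {m.family in COUNT_FAMILIES for m in self.models}
        if len(fams) > 1:
            raise ValueError("all candidates must target the same outcome "
                             "(count families and binomial cannot be mixed)")
        for m in self.models:
            m.validate()

    @property
    def outcome(self) -> str:
        return "count" if self.models[0].family in COUNT_FAMILIES else "binary"


def default_pool(outcome: str = "count") -> CandidatePool:
    """The default candidate pool (Q=6 for counts, Q=3 for binary).

    Counts: {Poisson, negative binomial} x {categorical time with
    group-time interaction, linear time with group-time interaction,
    categorical time main effects only}, all with a period main effect.
    Binary: the binomial versions of the three structures.
    """
    structures = [("catGT", "categorical", True),
                  ("linGT", "linear", True),
                  ("catMain", "categorical", False)]
    if outcome == "count":
        models = [CandidateModel(f"{fam}_{tag}", fam, time=tm, group_time=gt)
                  for fam in ("poisson", "negbin")
                  for tag, tm, gt in structures]
    elif outcome == "binary":
        models = [CandidateModel(f"binom_{tag}", "binomial", time=tm,
                                 group_time=gt)
                  for tag, tm, gt in structures]
    else:
        raise ValueError("outcome must be 'count' or 'binary'")
    return CandidatePool(models)


def akaike_weights(aics) -> np.ndarray:
    """Akaike weights, shift-invariant and robust to failed fits.

    Non-finite AIC entries (failed fits) get weight exactly 0 with a
    warning; if every entry is non-finite there is nothing to average and
    an error is raised.
    """
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AIC values")
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("all candidate fits failed (no finite AIC)")
    if not finite.all():
        warnings.warn(f"{int((~finite).sum())} candidate fit(s) failed; "
                      "their weight is set to 0", stacklevel=2)
    w = np.zeros_like(a)
    shifted = a[finite] - a[finite].min()
    e = np.exp(-0.5 * shifted)
    w[finite] = e / e.sum()
    return w


@dataclass
class CandidateFit:
    model: CandidateModel
    aic: float
    converged: bool
    predictions: np.ndarray | None = field(default=None, repr=False)
    params: np.ndarray | None = field(default=None, repr=False)


@dataclass
class MAResult:
    weights: np.ndarray
    aics: np.ndarray
    effect: float
    effect_name: str
    p_value: float | None = None
    n_failed: int = 0
    flagged: bool = False
    pool: CandidatePool | None = field(default=None, repr=False)


def _design(model: CandidateModel, G: np.ndarray, P: np.ndarray,
            time: np.ndarray) -> np.ndarray:
    # time dummies for all observed visits beyond the first (the reference)
    observed = np.unique(time)
    cols = [np.ones_like(G), G]
    if model.period:
        cols.append(P)
    if model.time == "categorical":
        T = [(time == t).astype(float) for t in observed[1:]]
        cols.extend(T)
        if model.group_time:
            cols.extend(G * t for t in T)
    else:
        tl = (time - observed[0]).astype(float)
        cols.append(tl)
        if model.group_time:
            cols.append(G * tl)
    if model.group_period:
        cols.append(G * P)
    return np.column_stack(cols)


def _fit_one(model: CandidateModel, y: np.ndarray,
             X: np.ndarray) -> CandidateFit:
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if model.family == "poisson":
                res = sm.Poisson(y, X).fit(disp=0, maxiter=200)
            elif model.family == "negbin":
                res = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
            else:
                res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        aic = float(res.aic)
        if not np.isfinite(aic) or not converged:
            return CandidateFit(model, np.inf, False)
        return CandidateFit(model, aic, True,
                            predictions=np.asarray(res.predict(X)),
                            params=np.asarray(res.params))
    except Exception:
        return CandidateFit(model, np.inf, False)


def _dataset_vectors(dataset: TrialDataset, outcome: str):
    df = dataset.df
    y = dataset.outcome_values(outcome)
    G = (df["treatment"] == "verum").to_numpy(float)
    P = (df["period"] == 2).to_numpy(float)
    time = df["time"].to_numpy()
    if outcome == "binary":
        # the derived responder indicator is structurally 0 at baseline;
        # binomial candidates are fit over the post-baseline visits
        keep = time >= 2
        y, G, P, time = y[keep], G[keep], P[keep], time[keep]
    return y, G, P, time


def fit_pool(dataset: TrialDataset, pool: CandidatePool | None = None,
             outcome: str | None = None) -> list[CandidateFit]:
    """Fit every candidate by maximum likelihood; failures get AIC = inf."""
    pool = pool or default_pool(outcome or "count")
    pool.validate()
    outcome = outcome or pool.outcome
    y, G, P, time = _dataset_vectors(dataset, outcome)
    fits = [_fit_one(m, y, _design(m, G, P, time)) for m in pool.models]
    if not any(np.isfinite(f.aic) for f in fits):
        raise RuntimeError("every candidate fit failed")
    return fits


def averaged_effect(fits: list[CandidateFit], weights: np.ndarray,
                    effect: str, G: np.ndarray, time: np.ndarray) -> float:
    """Weighted treatment effect from model-predicted cell means.

    ``delta_delta``: weighted mean of per-model differences-in-differences of
    predicted response proportions, (verum - placebo) at t3 minus the same at
    t1 (baseline); when baseline is not modelled (the derived responder
    indicator, structurally 0 at t1) the baseline difference is exactly 0.
    ``rate_ratio``: exp of the weighted mean per-model log ratio of predicted
    means, verum vs placebo, at t3.  Predictions are averaged over the
    observed rows of each (treatment, time) cell, so every model is
    evaluated on the same standard population.
    """
    if effect not in ("delta_delta", "rate_ratio"):
        raise ValueError("effect must be 'delta_delta' or 'rate_ratio'")
    has_baseline = bool(np.any(time == 1))

    def cell(pred, g, t):
        mask = (G == g) & (time == t)
        return float(pred[mask].mean())

    total, wsum = 0.0, 0.0
    for f, w in zip(fits, weights):
        if w == 0 or f.predictions is None:
            continue
        pred = f.predictions
        if effect == "delta_delta":
            base = (cell(pred, 1, 1) - cell(pred, 0, 1)) if has_baseline \
                else 0.0
            val = (cell(pred, 1, 3) - cell(pred, 0, 3)) - base
        else:
            v3, p3 = cell(pred, 1, 3), cell(pred, 0, 3)
            if v3 <= 0 or p3 <= 0:
                continue
            val = np.log(v3 / p3)
        total += w * val
        wsum += w
    if wsum == 0:
        raise RuntimeError("no usable candidate fit for the requested effect")
    avg = total / wsum
    return float(np.exp(avg)) if effect == "rate_ratio" else float(avg)


def _effect_statistic(effect_name: str, value: float) -> float:
    # distance from the null value on a symmetric scale
    return abs(np.log(value)) if effect_name == "rate_ratio" else abs(value)


def _ma_effect_for_G(pool, y, G, P, time, effect_name) -> tuple[float, int]:
    fits = [_fit_one(m, y, _design(m, G, P, time)) for m in pool.models]
    n_failed = sum(not f.converged for f in fits)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = akaike_weights([f.aic for f in fits])
    return averaged_effect(fits, w, effect_name, G, time), n_failed


def ma_permutation_test(dataset: TrialDataset,
                        pool: CandidatePool | None = None,
                        outcome: str | None = None,
                        effect: str | None = None,
                        n_perm: int = 200,
                        seed: int | np.random.Generator = 0,
                        exact: bool = False) -> MAResult:
    """Permutation test of the model-averaged treatment effect.

    The reference distribution flips, independently per subject (with
    probability 1/2, or exhaustively when ``exact``), which of the subject's
    two period blocks carries the verum label, refitting the whole pool each
    time.  Two-sided add-one p-value on the |log rate-ratio| or
    |delta-delta| scale.  The result is flagged when more than 10% of
    permutation refits fail.
    """
    pool = pool or default_pool(outcome or "count")
    pool.validate()
    outcome = outcome or pool.outcome
    effect = effect or ("rate_ratio" if outcome == "count" else "delta_delta")
    y, G, P, time = _dataset_vectors(dataset, outcome)

    fits = fit_pool(dataset, pool, outcome)
    aics = np.array([f.aic for f in fits])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        weights = akaike_weights(aics)
    e_obs = averaged_effect(fits, weights, effect, G, time)
    t_obs = _effect_statistic(effect, e_obs)

    n = dataset.n_subjects
    # flipping a subject's labels toggles G on all 8 of its rows
    subj_rows = np.arange(len(y)) // 8

    if exact:
        if n > 16:
            raise ValueError("exact enumeration limited to n <= 16 subjects")
        swap_vectors = np.array(list(itertools.product((0, 1), repeat=n)))
    else:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        swap_vectors = rng.integers(0, 2, size=(n_perm, n))

    exceed, failures = 0, 0
    for swap in swap_vectors:
        G_perm = np.where(swap[subj_rows] == 1, 1.0 - G, G)
        try:
            e_perm, nf = _ma_effect_for_G(pool, y, G_perm, P, time, effect)
            failures += int(nf > 0)
        except (RuntimeError, ValueError):
            failures += 1
            continue
        if _effect_statistic(effect, e_perm) >= t_obs - 1e-12:
            exceed += 1
    n_done = len(swap_vectors)
    if exact:
        p = exceed / n_done
    else:
        p = (1.0 + exceed) / (n_done + 1.0)
    return MAResult(weights=weights, aics=aics, effect=e_obs,
                    effect_name=effect, p_value=min(1.0, p),
                    n_failed=sum(not f.converged for f in fits),
                    flagged=failures > 0.1 * n_done, pool=pool)
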