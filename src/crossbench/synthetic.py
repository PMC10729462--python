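"""Seeded generator of cross-over trial datasets with realistic dependence.

The generator emulates the structure of a small blistering-disease cross-over
trial: 15 subjects split ~8/7 between the two sequences, two treatment
periods, four visits per period, overdispersed serially correlated blister
counts and a gridded 0-10 VAS score.  It is a *null* generator — no
treatment, period, or carry-over effect is built in — so that rejection rates
measured on its output (after block permutation) estimate type-I error.

Mechanism per subject-period block:

* a subject-level log-normal frailty ``u`` (mean 1, log-scale SD ``subject_sd``)
  shared by both periods creates between-subject heterogeneity and
  within-subject, between-period dependence;
* a latent standard-normal AR(1) path ``z_1..z_4`` with lag-1 correlation
  ``serial_corr`` drives serial dependence within the block;
* counts arise through a Gaussian copula: the negative-binomial quantile
  (mean ``baseline_mean * u``, size ``dispersion``) evaluated at ``Phi(z_t)``;
  ``dispersion=None`` selects the Poisson limit;
* VAS scores use an independent AR(1) path mapped affinely
  (``vas_mean + vas_sd * z``) then rounded to the half-point grid and clamped
  to [0, 10] — ties are expected and intentional.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .trial_data import TrialDataset, expected_treatment

__all__ = ["GeneratorConfig", "generate_trial", "lag1_block_correlation"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic trial generator.

    Defaults mirror the motivating study's shape (15 subjects, 8/7 sequence
    split) with moderate overdispersion and serial correlation.
    """

    n_subjects: int = 15
    sequence_split: tuple[int, int] = (8, 7)  # (PV, VP)
    baseline_mean: float = 7.0        # lambda_0, expected blister count
    subject_sd: float = 0.5           # sigma_u, log-scale frailty SD
    serial_corr: float = 0.6          # rho, lag-1 latent correlation
    dispersion: float | None = 4.0    # NB size; None => Poisson marginal
    vas_mean: float = 5.0
    vas_sd: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if sum(self.sequence_split) != self.n_subjects:
            raise ValueError("sequence_split must sum to n_subjects")
        if min(self.sequence_split) < 0:
            raise ValueError("sequence_split entries must be >= 0")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.subject_sd < 0 or self.vas_sd < 0:
            raise ValueError("SD parameters must be >= 0")
        if not (0.0 <= self.serial_corr < 1.0):
            raise ValueError("serial_corr must lie in [0, 1)")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be > 0 (or None for Poisson)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sequence_split"] = list(self.sequence_split)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "sequence_split" in d:
            d["sequence_split"] = tuple(d["sequence_split"])
        return cls(**d)


def _ar1_paths(rng: np.random.Generator, n_paths: int, rho: float) -> np.ndarray:
    """Standard-normal AR(1) paths of length 4, shape (n_paths, 4)."""
    eps = rng.standard_normal((n_paths, 4))
    z = np.empty_like(eps)
    z[:, 0] = eps[:, 0]
    scale = np.sqrt(1.0 - rho ** 2)
    for t in range(1, 4):
        z[:, t] = rho * z[:, t - 1] + scale * eps[:, t]
    return z


def _count_quantile(p: np.ndarray, mean: np.ndarray,
                    dispersion: float | None) -> np.ndarray:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    if dispersion is None:
        return stats.poisson.ppf(p, mean)
    r = dispersion
    return stats.nbinom.ppf(p, r, r / (r + mean))


def generate_trial(config: GeneratorConfig,
                   rng: np.random.Generator | None = None) -> TrialDataset:
    """Generate one null cross-over dataset; same seed gives identical data."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    n = config.n_subjects
    n_pv, _ = config.sequence_split
    width = max(2, len(str(n)))
    subjects = [f"S{i + 1:0{width}d}" for i in range(n)]
    sequences = ["PV"] * n_pv + ["VP"] * (n - n_pv)

    # subject frailty: log-normal, mean exactly 1
    frailty = np.exp(config.subject_sd * rng.standard_normal(n)
                     - 0.5 * config.subject_sd ** 2)

    z_count = _ar1_paths(rng, 2 * n, config.serial_corr)
    z_vas = _ar1_paths(rng, 2 * n, config.serial_corr)

    mean = config.baseline_mean * np.repeat(frailty, 2)[:, None]
    counts = _count_quantile(stats.norm.cdf(z_count), mean,
                             config.dispersion).astype(int)

    vas = config.vas_mean + config.vas_sd * z_vas
    vas = np.clip(np.round(2.0 * vas) / 2.0, 0.0, 10.0)

    rows = []
    b = 0
    for subj, seq in zip(subjects, sequences):
        for period in (1, 2):
            treat = expected_treatment(seq, period)
            for t in range(4):
                rows.append((subj, seq, period, treat, t + 1,
                             counts[b, t], vas[b, t]))
            b += 1
    df = pd.DataFrame(rows, columns=["subject_id", "sequence", "period",
                                     "treatment", "time", "count", "vas"])
    return TrialDataset(df)


def lag1_block_correlation(dataset: TrialDataset, outcome: str) -> float:
    """Pooled Pearson correlation of within-block lag-1 pairs.

    Diagnostic for the serial dependence the generator is supposed to
    produce.  Raises on constant data, where the correlation is undefined.
    """
    mat = dataset.block_matrix(outcome)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 blocks")
    x = mat[:, :3].ravel()
    y = mat[:, 1:].ravel()
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("outcome is constant; lag-1 correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
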