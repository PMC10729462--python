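"""Block permutation null and effect injection for power scenarios.

The simulation machinery works on whole subject-period blocks of four
repeated measurements.  Randomly reassigning the 2n blocks to the 2n
(subject, period) slots destroys treatment, period and subject effects while
preserving the within-block serial dependence — on average this creates a
situation of no difference between treatments, so rejection rates estimate
type-I error.  Power scenarios then add random effects to the *placebo* arm
(larger counts / VAS scores are worse outcomes) at specific visits:

* Scenario ``S1``: effect with mean ``delta`` at the post-treatment visit
  (t3) only;
* Scenario ``S2``: additionally about half the effect (mean ``delta / 2``)
  at the follow-up visit (t4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .trial_data import TrialDataset

__all__ = ["ScenarioSpec", "block_permute", "inject_effect", "null_replicates"]

_VALUE_COLUMNS = ("count", "vas", "binary")

SCENARIOS = ("NULL", "S1", "S2")
DISTRIBUTIONS = ("point_mass", "poisson", "rounded_gaussian")


@dataclass
class ScenarioSpec:
    """One power-simulation condition.

    ``outcome='binary_source'`` means: inject on the counts, then re-derive
    the binary responder indicator downstream — mirroring how the binary
    endpoint is defined in the first place.
    """

    scenario: str = "S1"
    effect_distribution: str = "poisson"
    delta: float = 0.0
    outcome: str = "count"

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        if self.effect_distribution not in DISTRIBUTIONS:
            raise ValueError(f"effect_distribution must be one of {DISTRIBUTIONS}")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.scenario == "NULL" and self.delta != 0:
            raise ValueError("NULL scenario requires delta = 0")
        if self.outcome not in ("count", "ordinal", "binary_source"):
            raise ValueError("outcome must be count, ordinal or binary_source")
        counts = self.outcome in ("count", "binary_source")
        if counts and self.effect_distribution == "rounded_gaussian":
            raise ValueError("rounded_gaussian injection is for the ordinal "
                             "outcome; counts use point_mass or poisson")
        if not counts and self.effect_distribution == "poisson":
            raise ValueError("poisson injection is for count outcomes")


def block_permute(dataset: TrialDataset,
                  rng: np.random.Generator) -> TrialDataset:
    """Reassign the 2n period blocks uniformly at random to the 2n slots.

    All outcome columns travel together (a block keeps its count, VAS and any
    binary values), within-block time order is preserved, and the design
    columns (sequence, period, treatment) are untouched.  The multiset of
    block value-vectors — hence every per-outcome total — is invariant.
    """
    df = dataset.df.copy()
    n_blocks = len(df) // 4
    perm = rng.permutation(n_blocks)
    for col in _VALUE_COLUMNS:
        if col in df.columns:
            vals = df[col].to_numpy().reshape(n_blocks, 4)
            df[col] = vals[perm].reshape(-1)
    return TrialDataset(df)


def _draws(rng: np.random.Generator, dist: str, mean: float, size: int,
           count_outcome: bool) -> np.ndarray:
    if dist == "point_mass":
        add = np.full(size, float(mean))
        return np.round(add) if count_outcome else add
    if dist == "poisson":
        return rng.poisson(mean, size).astype(float)
    # rounded_gaussian (ordinal): SD = mean / 2, rounded to the grid later
    sd = mean / 2.0
    return rng.normal(mean, sd, size)


def inject_effect(dataset: TrialDataset, spec: ScenarioSpec,
                  rng: np.random.Generator) -> TrialDataset:
    """Add the scenario's random effects to the placebo arm.

    Placebo records at t3 receive a draw with mean ``delta``; under S2,
    placebo records at t4 additionally receive a draw with mean ``delta/2``.
    Counts stay non-negative integers; ordinal values are rounded back to the
    half-point grid and clamped to [0, 10].  Verum records are untouched.
    """
    spec.validate()
    if spec.scenario == "NULL":
        raise ValueError("NULL scenario injects nothing; use block_permute")
    count_outcome = spec.outcome in ("count", "binary_source")
    col = "count" if count_outcome else "vas"

    df = dataset.df.copy()
    placebo = (df["treatment"] == "placebo").to_numpy()
    values = df[col].to_numpy(dtype=float)

    targets = [(3, spec.delta)]
    if spec.scenario == "S2":
        targets.append((4, spec.delta / 2.0))
    for t, mean in targets:
        mask = placebo & (df["time"].to_numpy() == t)
        add = _draws(rng, spec.effect_distribution, mean, int(mask.sum()),
                     count_outcome)
        values[mask] = values[mask] + add

    if count_outcome:
        df[col] = np.maximum(np.round(values), 0).astype(int)
    else:
        df[col] = np.clip(np.round(2.0 * values) / 2.0, 0.0, 10.0)
    return TrialDataset(df)


def null_replicates(dataset: TrialDataset, B: int,
                    seed: int | np.random.SeedSequence) -> Iterator[TrialDataset]:
    """Yield ``B`` independent block-permuted datasets, reproducibly."""
    if B < 1:
        raise ValueError("B must be >= 1")
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    for child in ss.spawn(B):
        yield block_permute(dataset, np.random.default_rng(child))
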