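"""Shared fixtures and builders for the crossbench test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from crossbench import GeneratorConfig, TrialDataset, generate_trial


def dataset_from_blocks(placebo_blocks, verum_blocks,
                        vas_placebo=None, vas_verum=None) -> TrialDataset:
    """Build a dataset from per-subject (placebo, verum) count 4-vectors.

    Sequences alternate PV, VP, PV, ... so treatment is not confounded with
    period.  VAS defaults to a constant 5.0 unless per-block values are
    given.
    """
    placebo_blocks = [np.asarray(b, dtype=float) for b in placebo_blocks]
    verum_blocks = [np.asarray(b, dtype=float) for b in verum_blocks]
    assert len(placebo_blocks) == len(verum_blocks)
    n = len(placebo_blocks)
    rows = []
    for k in range(n):
        subj = f"S{k + 1:02d}"
        seq = "PV" if k % 2 == 0 else "VP"
        arm_of_period = {1: "placebo", 2: "verum"} if seq == "PV" \
            else {1: "verum", 2: "placebo"}
        for period in (1, 2):
            treat = arm_of_period[period]
            if treat == "placebo":
                counts = placebo_blocks[k]
                vass = None if vas_placebo is None else vas_placebo[k]
            else:
                counts = verum_blocks[k]
                vass = None if vas_verum is None else vas_verum[k]
            for t in range(4):
                vas = 5.0 if vass is None else float(vass[t])
                rows.append((subj, seq, period, treat, t + 1,
                             int(counts[t]), vas))
    df = pd.DataFrame(rows, columns=["subject_id", "sequence", "period",
                                     "treatment", "time", "count", "vas"])
    return TrialDataset(df)


@pytest.fixture(scope="session")
def null_dataset() -> TrialDataset:
    """One default-configuration synthetic dataset (15 subjects, seeded)."""
    return generate_trial(GeneratorConfig(seed=20240917))


@pytest.fixture()
def tiny_dataset() -> TrialDataset:
    """Three subjects with hand-chosen count blocks."""
    return dataset_from_blocks(
        placebo_blocks=[(5, 4, 3, 2), (6, 6, 6, 6), (2, 3, 1, 0)],
        verum_blocks=[(3, 2, 2, 1), (5, 5, 4, 4), (7, 6, 5, 4)],
    )
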