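"""Data model for 2x2 cross-over trials with four repeated measures per period.

The canonical layout is long format: one row per (subject, period, time), with
a treatment label determined by the subject's sequence, a blister ``count``
outcome, an ordinal ``vas`` outcome on a half-point 0-10 grid, and an optional
derived ``binary`` responder indicator.  Everything downstream (permutation
engine, pairwise comparisons, rank statistics, marginal regressions) consumes
this container, so validation is strict: complete cases only, both periods per
subject, exactly the four time points per period.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

SEQUENCES = ("PV", "VP")  # placebo-first / verum-first
TREATMENTS = ("placebo", "verum")
TIMES = (1, 2, 3, 4)  # baseline, on-treatment, post-treatment, follow-up

#: canonical CSV columns (``binary`` is optional until :func:`dichotomize`)
CANONICAL_COLUMNS = ("subject_id", "sequence", "period", "treatment", "time",
                     "count", "vas", "binary")
REQUIRED_COLUMNS = CANONICAL_COLUMNS[:-1]

#: outcome label -> column name
OUTCOME_COLUMNS = {"count": "count", "ordinal": "vas", "binary": "binary"}

SUMMARIES = ("change_from_baseline_t3", "mean_post", "total")


class SchemaError(ValueError):
    """A required column is missing or mis-declared."""


class IntegrityError(ValueError):
    """The rows do not form a complete 2x2x4 cross-over layout."""


class DomainError(ValueError):
    """An outcome value is outside its admissible domain."""


def expected_treatment(sequence: str, period: int) -> str:
    """Treatment implied by the randomized sequence and the period."""
    if sequence == "PV":
        return "placebo" if period == 1 else "verum"
    return "verum" if period == 1 else "placebo"


@dataclass(frozen=True)
class PeriodBlock:
    """One subject-period's ordered 4-vector of measurements.

    This is the unit that the block-permutation null shuffles: permuting whole
    blocks preserves the serial dependence among the four visits.
    """

    subject_id: str
    period: int
    treatment: str
    values: np.ndarray  # shape (4,), ordered by time 1..4

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.shape != (4,):
            raise IntegrityError("a period block must hold exactly 4 values")
        object.__setattr__(self, "values", v)


def summarize_block(block: PeriodBlock, summary: str) -> float:
    """Collapse a block to the univariate summary used by univariate GPC.

    ``change_from_baseline_t3`` = value(t3) - value(t1); ``mean_post`` = mean
    over t2..t4; ``total`` = sum of all four visits.
    """
    v = block.values
    if summary == "change_from_baseline_t3":
        return float(v[2] - v[0])
    if summary == "mean_post":
        return float(np.mean(v[1:]))
    if summary == "total":
        return float(np.sum(v))
    raise ValueError(f"unknown summary {summary!r}; choose from {SUMMARIES}")


@dataclass
class TrialDataset:
    """Validated long-format 2x2 cross-over dataset.

    Rows are kept in canonical (subject, period, time) order.  Construction
    validates structure (completeness, uniqueness, sequence/treatment
    consistency) and outcome domains (non-negative integer counts, VAS on the
    half-point grid, binary in {0, 1}).
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.df = _validate(self.df)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_subjects(self) -> int:
        return self.df["subject_id"].nunique()

    @property
    def subjects(self) -> list[str]:
        return list(pd.unique(self.df["subject_id"]))

    @property
    def has_binary(self) -> bool:
        return "binary" in self.df.columns

    def outcome_values(self, outcome: str) -> np.ndarray:
        col = _outcome_column(self, outcome)
        return self.df[col].to_numpy(dtype=float)

    def blocks(self, outcome: str) -> list[PeriodBlock]:
        """Partition the dataset into 2n period blocks in canonical order."""
        col = _outcome_column(self, outcome)
        vals = self.df[col].to_numpy(dtype=float).reshape(-1, 4)
        meta = self.df.iloc[::4][["subject_id", "period", "treatment"]]
        return [
            PeriodBlock(str(s), int(p), str(t), vals[i])
            for i, (s, p, t) in enumerate(meta.itertuples(index=False, name=None))
        ]

    def block_matrix(self, outcome: str) -> np.ndarray:
        """(2n, 4) array of block values in canonical block order."""
        col = _outcome_column(self, outcome)
        return self.df[col].to_numpy(dtype=float).reshape(-1, 4)

    def block_treatments(self) -> np.ndarray:
        """Treatment label of each canonical block, shape (2n,)."""
        return self.df["treatment"].to_numpy()[::4]

    def copy(self) -> "TrialDataset":
        return TrialDataset(self.df.copy())

    def equals(self, other: "TrialDataset") -> bool:
        a, b = self.df, other.df
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            av, bv = a[c].to_numpy(), b[c].to_numpy()
            if a[c].dtype.kind in "fc":
                if not np.allclose(av.astype(float), bv.astype(float)):
                    return False
            elif not (av == bv).all():
                return False
        return True


def _outcome_column(dataset: TrialDataset, outcome: str) -> str:
    try:
        col = OUTCOME_COLUMNS[outcome]
    except KeyError:
        raise ValueError(
            f"unknown outcome {outcome!r}; choose from {sorted(OUTCOME_COLUMNS)}"
        ) from None
    if col not in dataset.df.columns:
        raise SchemaError(
            f"outcome column {col!r} not present; run dichotomize() first"
            if outcome == "binary" else f"outcome column {col!r} missing"
        )
    return col


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")

    keep = [c for c in CANONICAL_COLUMNS if c in df.columns]
    df = df[keep].copy()

    if len(df) == 0:
        df["period"] = df["period"].astype(int)
        df["time"] = df["time"].astype(int)
        return df.reset_index(drop=True)

    for col in keep:
        if df[col].isna().any():
            raise IntegrityError(f"missing values in column {col!r} "
                                 "(complete cases are required)")

    df["subject_id"] = df["subject_id"].astype(str)
    df["sequence"] = df["sequence"].astype(str)
    df["treatment"] = df["treatment"].astype(str)
    period = df["period"].to_numpy()
    time = df["time"].to_numpy()
    if not np.isin(period, (1, 2)).all():
        raise DomainError("period must be 1 or 2")
    if not np.isin(time, TIMES).all():
        raise DomainError("time must be one of 1, 2, 3, 4")
    df["period"] = df["period"].astype(int)
    df["time"] = df["time"].astype(int)
    if not df["sequence"].isin(SEQUENCES).all():
        raise DomainError(f"sequence must be one of {SEQUENCES}")
    if not df["treatment"].isin(TREATMENTS).all():
        raise DomainError(f"treatment must be one of {TREATMENTS}")

    counts = df["count"].to_numpy(dtype=float)
    if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
        raise DomainError("count outcome must be a non-negative integer")
    df["count"] = np.round(counts).astype(int)

    vas2 = 2.0 * df["vas"].to_numpy(dtype=float)
    if (not np.allclose(vas2, np.round(vas2), atol=1e-9)) or \
            (vas2 < -1e-9).any() or (vas2 > 20 + 1e-9).any():
        raise DomainError("vas must lie on the half-point grid {0, 0.5, ..., 10}")
    df["vas"] = np.round(vas2) / 2.0

    if "binary" in df.columns:
        b = df["binary"].to_numpy(dtype=float)
        if not np.isin(b, (0.0, 1.0)).all():
            raise DomainError("binary outcome must be 0 or 1")
        df["binary"] = b.astype(int)

    df = df.sort_values(["subject_id", "period", "time"],
                        kind="mergesort").reset_index(drop=True)

    if df.duplicated(["subject_id", "period", "time"]).any():
        dup = df[df.duplicated(["subject_id", "period", "time"])].iloc[0]
        raise IntegrityError(
            f"duplicated record for subject {dup['subject_id']!r} "
            f"period {dup['period']} time {dup['time']}")

    if len(df) % 8 != 0:
        raise IntegrityError("row count is not a multiple of 8 "
                             "(2 periods x 4 time points per subject)")
    t = df["time"].to_numpy().reshape(-1, 4)
    if not (t == np.array(TIMES)).all():
        raise IntegrityError("each (subject, period) must contain exactly "
                             "times 1, 2, 3, 4")
    per_subject = df.groupby("subject_id", sort=False)
    if not (per_subject.size() == 8).all():
        raise IntegrityError("each subject must contribute exactly 2 periods")
    if not (per_subject["period"].nunique() == 2).all():
        raise IntegrityError("each subject must appear in both periods")
    if not (per_subject["sequence"].nunique() == 1).all():
        raise IntegrityError("sequence must be constant within subject")

    expected = np.where(
        (df["sequence"].to_numpy() == "PV") == (df["period"].to_numpy() == 2),
        "verum", "placebo")
    if not (df["treatment"].to_numpy() == expected).all():
        raise IntegrityError("treatment labels inconsistent with "
                             "(sequence, period): PV means placebo in period 1")
    return df


# -- I/O -------------------------------------------------------------------

def read_trial_csv(path, schema: Mapping[str, str] | None = None) -> TrialDataset:
    """Read a long-format trial CSV into a validated :class:`TrialDataset`.

    Parameters
    ----------
    path : str or path-like
        CSV file with one header row.
    schema : mapping, optional
        Maps canonical column names (``subject_id`` ... ``binary``) to the
        names actually used in the file, for renamed columns.
    """
    raw = pd.read_csv(path)
    if schema:
        rename = {}
        for canonical, actual in schema.items():
            if canonical not in CANONICAL_COLUMNS:
                raise SchemaError(f"unknown canonical column {canonical!r}")
            if actual not in raw.columns:
                raise SchemaError(f"column {actual!r} (for {canonical!r}) "
                                  "not found in file")
            rename[actual] = canonical
        raw = raw.rename(columns=rename)
    return TrialDataset(raw)


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write the canonical CSV; ``read_trial_csv`` round-trips it exactly."""
    dataset.df.to_csv(path, index=False)


# -- outcome derivation ----------------------------------------------------

def dichotomize(dataset: TrialDataset, threshold: float = 0.4,
                baseline_time: int = 1) -> TrialDataset:
    """Derive the binary responder outcome from the count outcome.

    A record at time > ``baseline_time`` is a response (1) iff its count shows
    a *strictly* more-than-``threshold`` reduction from the same period's
    baseline count, i.e. count < (1 - threshold) * baseline.  Baseline records
    get 0, and a zero baseline yields 0 at every time (no reduction is
    definable).  Count and ordinal columns are untouched; the operation is
    idempotent.
    """
    if baseline_time not in TIMES:
        raise ValueError("baseline_time must be one of 1..4")
    df = dataset.df.copy()
    counts = df["count"].to_numpy(dtype=float).reshape(-1, 4)
    base = counts[:, baseline_time - 1][:, None]
    binary = (counts < (1.0 - threshold) * base) & (base > 0)
    binary[:, baseline_time - 1] = False
    df["binary"] = binary.reshape(-1).astype(int)
    return TrialDataset(df)
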