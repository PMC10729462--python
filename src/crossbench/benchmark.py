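"""Simulation benchmark: type-I error and power across methods and outcomes.

For each replicate a null dataset is produced (synthetic generation followed
by block permutation) and, for power, scenario effects are injected into the
placebo arm.  Every method sees the same simulated dataset within a
replicate (common random numbers), so paired comparisons of rejection rates
between methods are valid.  Results are tidy tables with one row per
(method, outcome, scenario, delta): rejection count, rate, Monte-Carlo
standard error, and failure count.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gee, gpc, model_averaging, nmm
from .permutation import ScenarioSpec, block_permute, inject_effect
from .synthetic import GeneratorConfig, generate_trial
from .trial_data import TrialDataset, dichotomize

__all__ = ["BenchmarkConfig", "estimate_type1", "estimate_power",
           "run_benchmark", "METHODS", "smoke_config"]

#: direction of benefit per outcome: counts and VAS are harms, response is good
_DIRECTION = {"count": "lower_is_better", "ordinal": "lower_is_better",
              "binary": "higher_is_better"}

#: outcomes each method supports (GEE and MA are excluded from ordinal)
_METHOD_OUTCOMES = {
    "gpc_unmatched_prioritized": ("count", "ordinal", "binary"),
    "gpc_unmatched_nonprioritized": ("count", "ordinal", "binary"),
    "gpc_unmatched_univariate": ("count", "ordinal", "binary"),
    "gpc_matched_prioritized": ("count", "ordinal", "binary"),
    "gpc_matched_univariate": ("count", "ordinal", "binary"),
    "nmm_period1": ("count", "ordinal", "binary"),
    "nmm_period2": ("count", "ordinal", "binary"),
    "gee": ("count", "binary"),
    "ma": ("count", "binary"),
}
METHODS = tuple(_METHOD_OUTCOMES)

DEFAULT_METHODS = ("gpc_unmatched_prioritized", "gpc_unmatched_nonprioritized",
                   "gpc_unmatched_univariate", "gpc_matched_prioritized",
                   "nmm_period1", "nmm_period2", "gee")


@dataclass
class BenchmarkConfig:
    methods: tuple[str, ...] = DEFAULT_METHODS
    outcomes: tuple[str, ...] = ("count", "binary", "ordinal")
    #: scenario -> outcome -> list of effect sizes delta
    deltas: dict = field(default_factory=lambda: {
        "S1": {"count": [1, 2, 4], "binary": [1, 2, 4], "ordinal": [1, 2]},
        "S2": {"count": [1, 2, 4], "binary": [1, 2, 4], "ordinal": [1, 2]},
    })
    n_sim: int = 1000
    n_perm: int = 1000
    ma_n_perm: int = 200
    alpha: float = 0.05
    seed: int = 0
    count_distribution: str = "poisson"
    ordinal_distribution: str = "rounded_gaussian"
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def validate(self) -> None:
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; "
                             f"valid names: {sorted(METHODS)}")
        bad = [o for o in self.outcomes
               if o not in ("count", "binary", "ordinal")]
        if bad:
            raise ValueError(f"unknown outcome(s) {bad}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_sim < 1 or self.n_perm < 1:
            raise ValueError("n_sim and n_perm must be >= 1")
        for sc in self.deltas:
            if sc not in ("S1", "S2"):
                raise ValueError(f"unknown scenario {sc!r}")
        self.generator.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        d["outcomes"] = list(self.outcomes)
        d["generator"] = self.generator.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkConfig":
        d = dict(d)
        if "generator" in d:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("methods", "outcomes"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("benchmark config must be a YAML mapping")
        try:
            cfg = cls.from_dict(data)
        except TypeError as exc:
            raise ValueError(f"invalid benchmark config: {exc}") from exc
        cfg.validate()
        return cfg


def smoke_config(seed: int = 0) -> BenchmarkConfig:
    """A small configuration that exercises every stage quickly."""
    return BenchmarkConfig(
        methods=("gpc_unmatched_prioritized", "gpc_matched_prioritized",
                 "nmm_period1", "gee"),
        outcomes=("count", "binary"),
        deltas={"S1": {"count": [4], "binary": [4]}},
        n_sim=50, n_perm=200, ma_n_perm=50, seed=seed)


# -- per-replicate method runners ------------------------------------------

def _run_method(name: str, dataset: TrialDataset, outcome: str,
                config: BenchmarkConfig, rng: np.random.Generator):
    """Return (p_value, failed) for one method on one replicate dataset."""
    direction = _DIRECTION[outcome]
    if name.startswith("gpc_"):
        _, pairing, comparison = name.split("_")
        gcfg = gpc.GPCConfig(pairing=pairing, comparison=comparison,
                             direction=direction, outcome=outcome,
                             n_perm=config.n_perm)
        if pairing == "unmatched":
            res = gpc.permutation_test_unmatched(dataset, gcfg, seed=rng)
        else:
            res = gpc.conditional_sign_test(dataset, gcfg)
        return res.p_value, False
    if name.startswith("nmm_"):
        period = int(name[-1])
        res = nmm.ats_interaction_test(dataset, period, outcome)
        return res.p_value, False
    if name == "gee":
        family = "poisson_log" if outcome == "count" else "binomial_logit"
        correction = "bias_corrected" if outcome == "count" else "none"
        try:
            fit = gee.fit_gee(dataset, gee.GEEModelSpec(
                family=family, correction=correction))
            if not fit.converged:
                return None, True
            # F reference with subject-based denominator df: the chi-square
            # reference is markedly liberal with this few independent units
            _, _, p = gee.wald_test(
                fit, denominator_df=dataset.n_subjects - 1)
            return p, False
        except (ValueError, np.linalg.LinAlgError):
            return None, True
    if name == "ma":
        try:
            res = model_averaging.ma_permutation_test(
                dataset, outcome=outcome, n_perm=config.ma_n_perm, seed=rng)
            return (None, True) if res.flagged else (res.p_value, False)
        except RuntimeError:
            return None, True
    raise ValueError(f"unknown method {name!r}")


def _outcome_datasets(base: TrialDataset, outcomes) -> dict[str, TrialDataset]:
    out = {}
    for oc in outcomes:
        out[oc] = dichotomize(base) if oc == "binary" else base
    return out


@dataclass
class _Tally:
    rejections: int = 0
    failures: int = 0
    n: int = 0


def _rows(tallies: dict, config: BenchmarkConfig, scenario: str) -> list[dict]:
    # wall-clock time is deliberately not a report column: re-runs with the
    # same seed must produce byte-identical CSVs (timings go to run.log)
    rows = []
    for (method, outcome, delta), t in tallies.items():
        n_ok = t.n - t.failures
        rate = t.rejections / n_ok if n_ok else np.nan
        rows.append({
            "method": method, "outcome": outcome, "scenario": scenario,
            "delta": delta, "n_sim": t.n, "rejections": t.rejections,
            "failures": t.failures, "rate": rate,
            "mc_se": float(np.sqrt(rate * (1 - rate) / n_ok)) if n_ok else np.nan,
            "alpha": config.alpha, "seed": config.seed,
        })
    return rows


def _replicate_streams(rep_ss: np.random.SeedSequence, k: int):
    return [np.random.default_rng(c) for c in rep_ss.spawn(k)]


def estimate_type1(config: BenchmarkConfig) -> pd.DataFrame:
    """Empirical type-I error of each method under the block-permutation null."""
    config.validate()
    tallies: dict = {}
    ss = np.random.SeedSequence(config.seed)
    n_method_streams = len(config.methods) * len(config.outcomes)
    for rep_ss in ss.spawn(config.n_sim):
        streams = _replicate_streams(rep_ss, 2 + n_method_streams)
        base = generate_trial(config.generator, rng=streams[0])
        nulld = block_permute(base, streams[1])
        datasets = _outcome_datasets(nulld, config.outcomes)
        s = 2
        for method in config.methods:
            for outcome in config.outcomes:
                rng = streams[s]
                s += 1
                if outcome not in _METHOD_OUTCOMES[method]:
                    continue
                key = (method, outcome, 0.0)
                t = tallies.setdefault(key, _Tally())
                t.n += 1
                p, failed = _run_method(method, datasets[outcome], outcome,
                                        config, rng)
                if failed or p is None:
                    t.failures += 1
                elif p < config.alpha:
                    t.rejections += 1
    return pd.DataFrame(_rows(tallies, config, "NULL"))


def estimate_power(config: BenchmarkConfig) -> pd.DataFrame:
    """Empirical power under the injection scenarios, paired across methods."""
    config.validate()
    frames = []
    for scenario, per_outcome in config.deltas.items():
        conditions = [(oc, float(d)) for oc in config.outcomes
                      for d in per_outcome.get(oc, [])]
        if not conditions:
            continue
        tallies: dict = {}
        ss = np.random.SeedSequence(config.seed)
        n_streams = 2 + len(conditions) * (1 + len(config.methods))
        for rep_ss in ss.spawn(config.n_sim):
            streams = _replicate_streams(rep_ss, n_streams)
            base = generate_trial(config.generator, rng=streams[0])
            nulld = block_permute(base, streams[1])
            s = 2
            for outcome, delta in conditions:
                inj_rng = streams[s]
                s += 1
                if outcome == "ordinal":
                    spec = ScenarioSpec(scenario,
                                        config.ordinal_distribution,
                                        delta, "ordinal")
                else:
                    spec = ScenarioSpec(
                        scenario, config.count_distribution, delta,
                        "binary_source" if outcome == "binary" else "count")
                injected = inject_effect(nulld, spec, inj_rng)
                dataset = dichotomize(injected) if outcome == "binary" \
                    else injected
                for method in config.methods:
                    rng = streams[s]
                    s += 1
                    if outcome not in _METHOD_OUTCOMES[method]:
                        continue
                    key = (method, outcome, delta)
                    t = tallies.setdefault(key, _Tally())
                    t.n += 1
                    p, failed = _run_method(method, dataset, outcome,
                                            config, rng)
                    if failed or p is None:
                        t.failures += 1
                    elif p < config.alpha:
                        t.rejections += 1
        frames.append(pd.DataFrame(_rows(tallies, config, scenario)))
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def run_benchmark(config_path, out_dir) -> Path:
    """Run the full benchmark from a YAML config and write report files.

    Writes ``results.csv`` (type-I error + power rows), ``config_echo.yaml``
    and ``run.log`` into ``out_dir``; returns the results path.
    """
    config = BenchmarkConfig.from_yaml(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    start = _time.time()
    type1 = estimate_type1(config)
    power = estimate_power(config)
    results = pd.concat([type1, power], ignore_index=True)
    results_path = out / "results.csv"
    results.to_csv(results_path, index=False)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    import crossbench
    with open(out / "run.log", "w") as fh:
        fh.write(f"crossbench {crossbench.__version__}\n"
                 f"numpy {np.__version__}, pandas {pd.__version__}\n"
                 f"seed {config.seed}, n_sim {config.n_sim}, "
                 f"n_perm {config.n_perm}\n"
                 f"total runtime {(_time.time() - start):.1f} s\n"
                 f"rows written: {len(results)}\n")
    return results_path
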