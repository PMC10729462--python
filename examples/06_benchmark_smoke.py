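"""A miniature run of the full method comparison.

Estimates type-I error (block-permutation null) and power (Scenario S1,
4 added blisters at the post-treatment visit) for a few methods at a small
replication count. The real benchmark uses the same machinery with
n_sim = 1000 via `crossbench run --config bench.yaml --out results/`.
"""
from crossbench.benchmark import BenchmarkConfig, estimate_power, estimate_type1

config = BenchmarkConfig(
    methods=("gpc_unmatched_prioritized", "gpc_matched_prioritized",
             "nmm_period1", "gee"),
    outcomes=("count",),
    deltas={"S1": {"count": [4]}},
    n_sim=100, n_perm=500, seed=0)

print("type-I error under the block-permutation null (target 0.05):")
print(estimate_type1(config)[["method", "rate", "mc_se", "failures"]]
      .to_string(index=False))
print("\npower, scenario S1, delta = 4 added blisters:")
print(estimate_power(config)[["method", "rate", "mc_se", "failures"]]
      .to_string(index=False))
print("\nRates are rejection fractions at the two-sided 0.05 level; "
      "mc_se is the binomial Monte-Carlo standard error.")
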