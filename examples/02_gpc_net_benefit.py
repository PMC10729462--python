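"""Generalized pairwise comparisons on a synthetic trial.

Compares every verum period block with every placebo block in a clinical
priority order (post-treatment visit first) and tests the net treatment
benefit Delta with a within-subject label-swap permutation test.
"""
from crossbench import GPCConfig, GeneratorConfig, generate_trial, \
    permutation_test_unmatched, conditional_sign_test

trial = generate_trial(GeneratorConfig(seed=7))

config = GPCConfig(pairing="unmatched", comparison="prioritized",
                   priority_order=(3, 4, 2, 1), direction="lower_is_better",
                   outcome="count", n_perm=2000)
res = permutation_test_unmatched(trial, config, seed=1)
print("unmatched prioritized GPC on blister counts")
print(f"  wins {res.wins}, losses {res.losses}, ties {res.ties} "
      f"over {res.n_pairs} pairs")
print(f"  net treatment benefit Delta = {res.delta:+.3f} "
      "(P(better on verum) - P(better on placebo))")
print(f"  two-sided permutation p = {res.p_value:.3f}")

matched = conditional_sign_test(trial, GPCConfig(pairing="matched",
                                                 comparison="prioritized"))
print("\nmatched GPC (within-subject pairs, conditional sign test)")
print(f"  Delta = {matched.delta:+.3f}, p = {matched.p_value:.3f}"
      + ("  [warning: fewer than 15 pairs]" if matched.small_sample_warning else ""))
print("\nOn null data Delta should be near 0 with a non-small p-value.")
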