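"""AIC model averaging of the treatment effect over a candidate pool.

Six count models (Poisson / negative binomial x three time structures) are
fit by maximum likelihood, weighted by exp(-AIC/2), and the averaged rate
ratio is tested by a within-subject label-swap permutation test.
"""
from crossbench import GeneratorConfig, generate_trial, ma_permutation_test

trial = generate_trial(GeneratorConfig(seed=11))
res = ma_permutation_test(trial, outcome="count", n_perm=200, seed=1)
print("Akaike weights:")
for model, w in zip(res.pool.models, res.weights):
    print(f"  {model.name:<15} {w:.3f}")
print(f"\naveraged rate ratio at the post-treatment visit: {res.effect:.3f}")
print(f"two-sided permutation p = {res.p_value:.3f}")
print("Negative-binomial candidates should dominate (the generator is "
      "overdispersed); on null data the rate ratio is near 1.")
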