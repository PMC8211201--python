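"""Miniature subsampling experiment: how estimates degrade with less data.

Draws random subsets of individuals and of observations per individual
from a balanced reference network, recomputes all global measures on
each subsample, and summarizes per regime how often community structure
was detected, R_com was acceptable, and the community count was right.
"""

from netsubsample import (
    GeneratorConfig,
    build_observed,
    generate_population,
    run_experiment,
    summarize_grid,
)

cfg = GeneratorConfig(seed=21)
data, _ = generate_population(cfg)
ref = build_observed(data, min_days=40, obs_cap=40, seed=22,
                     n_rand=200, n_boot=200, n_repeat=2)
print(f"reference: {ref.n_individuals} individuals, density {ref.metrics.density:.3f}, "
      f"Q {ref.metrics.q:.3f}, {ref.metrics.n_communities} communities, "
      f"R_com {ref.r_com_obs:.3f}")

results = run_experiment(
    ref, individuals_grid=(15, 50), obs_grid=(5, 20), n_reps=10,
    n_rand=200, n_boot=200, seed=23,
)
summary = summarize_grid(results, ref)
print(summary.to_string(index=False))
print("counts are out of 10 replicates; 'evidence' = permutation p < 0.05, "
      "'acceptable' = 0.5 <= R_com <= reference")
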