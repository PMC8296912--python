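"""Generate a synthetic DHS-like child survey with known inequality truth.

Draws 5,000 children in 200 clusters: log-normal household wealth with a
PSU random intercept, wealth-linked covariates, v005-scale survey weights,
and three binary outcomes from linear probability models.  The companion
truth record holds the exact coefficients, so any estimator run on the
file can be checked against them.
"""

from healthineq import GeneratorConfig, generate_dataset, population_truth, write_dataset

config = GeneratorConfig(n_children=5000, n_psu=200)
dataset, truth = generate_dataset(config, seed=7)
truth["population_truth"] = population_truth(config, oracle_n=100_000, seed=7)

write_dataset(dataset, "synthetic_microdata.csv", truth, "synthetic_truth.json")

print(f"children: {dataset.n}, clusters: {dataset.psu_count}")
print(f"mean v005 weight: {dataset.df['raw_weight'].mean():,.0f}")
for name, res in truth["population_truth"].items():
    print(f"{name:14s} population ENCI {res['enci']:+.4f}  prevalence {res['mean']:.1%}")
# A positive population ENCI means the outcome is concentrated among richer
# children (pro-rich); negative means among poorer children (pro-poor).
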