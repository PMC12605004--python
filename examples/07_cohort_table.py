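"""Cohort characteristics table with exact group-comparison tests.

Continuous variables get Kruskal-Wallis p-values; categorical variables get
Fisher exact p-values (Freeman-Halton enumeration beyond 2x2). On a matched
synthetic cohort every test should be unremarkable.
"""

from omicnet import cohort_table, fisher_exact, generate_cohort
from omicnet.simulate import SyntheticConfig

cfg = SyntheticConfig(seed=4)
_, _, meta, _ = generate_cohort(cfg)
table = cohort_table(meta)
print(table[["variable", "p", "test"]].to_string(index=False))
print("\nGroups are generated from identical covariate distributions, so the")
print("p-values hover well above any significance threshold.")

# the exact test itself, on a published-style 2x2 (RF status by subgroup)
p = fisher_exact([[14, 26], [28, 12]])
print(f"\nFisher exact on a 14/26 vs 28/12 split: p = {p:.4f} "
      "(a real subgroup difference)")
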