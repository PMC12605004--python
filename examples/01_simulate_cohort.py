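"""Generate a synthetic plasma multi-omic cohort and inspect its structure.

Builds a 40/40/40 cohort (ACPA- RA, ACPA+ RA, controls) with 20 planted
subgroup effects of Cohen's d = 1.0, writes it to TSV, and prints what was
planted versus what a naive per-feature effect-size scan sees.
"""

import numpy as np

from omicnet import (
    cohens_d,
    generate_cohort,
    log_transform,
    write_cohort,
)
from omicnet.simulate import SyntheticConfig, evenly_planted

cfg = SyntheticConfig(planted=evenly_planted(20, 1.0, 260, 40), seed=7)
prot, met, meta, truth = generate_cohort(cfg)
write_cohort(prot, met, meta, truth, "example_cohort")

print(f"proteins:    {prot.values.shape[0]} samples x {prot.values.shape[1]} features")
print(f"metabolites: {met.values.shape[1]} features, "
      f"{met.n_missing} censored cells (lowest 10% per metabolite)")

g = meta.frame["group"]
logp = log_transform(prot)
planted_neg = [e.feature_id for e in truth.planted if e.groups == ("ACPA_NEG",)
               and e.feature_id in prot.feature_ids]
ds = [cohens_d(logp.values.loc[(g == "ACPA_NEG").values, f],
               logp.values.loc[(g == "CONTROL").values, f])
      for f in planted_neg]
print(f"\nplanted ACPA- protein effects (target d = 1.0), observed at n=40/group:")
print("  " + ", ".join(f"{d:.2f}" for d in ds))
print("Sampling noise at this cohort size moves observed d by roughly +/- 0.25,")
print("which is why the analysis gates calls on both p-value and effect size.")
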