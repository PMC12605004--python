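"""Set enrichment of differential hits against pathway-style annotations.

Annotations here are synthetic pathway blocks (the generator's latent
communities double as 'pathways'), tested with the one-tailed Fisher exact
tail and its conservative EASE variant.
"""

from omicnet import (
    AnnotationCollection,
    differential_features,
    fisher_enrichment,
    generate_cohort,
    merge_omics,
    preprocess_metabolites,
    preprocess_proteins,
)
from omicnet.simulate import SyntheticConfig, evenly_planted

cfg = SyntheticConfig(planted=evenly_planted(20, 1.2, 260, 40), seed=2)
prot, met, meta, truth = generate_cohort(cfg)
merged = merge_omics(preprocess_proteins(prot), preprocess_metabolites(met)[0])

# pathway annotation = the latent community each feature loads on
universe = merged.feature_ids
ann = AnnotationCollection.from_pairs(
    (f"pathway_{i % 30:02d}", fid) for i, fid in enumerate(universe)
)

res = differential_features(merged, meta, "ACPA_NEG_vs_CTRL")
hits = set(res.loc[res["passes_relaxed"], "feature_id"])  # relaxed: p<0.05
print(f"{len(hits)} relaxed hits in a universe of {len(universe)} features\n")

enr = fisher_enrichment(hits, universe, ann, mode="standard")
top = enr.head(5)[["term_id", "k", "K", "p_standard", "p_ease", "enriched"]]
print(top.to_string(index=False))
print("\nPlanted effects sit in the low-index pathways (features are planted")
print("in ID order), so those terms surface; p_ease >= p_standard always —")
print("the EASE tail discounts terms supported by a single overlapping hit.")
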