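"""Elastic-net network inference and phenotype-seeded random walk.

Infers the multi-omic association graph by per-feature neighborhood selection,
runs random walk with restart (r = 0.5) from the three one-hot phenotype
nodes, and extracts the top-50 phenotype-centric subnetwork. Takes a few
minutes: one cross-validated elastic net per feature.
"""

from omicnet import (
    encode_design,
    generate_cohort,
    infer_network,
    merge_omics,
    preprocess_metabolites,
    preprocess_proteins,
    rwr,
    top_n_features,
)
from omicnet.io import SmokingMode
from omicnet.simulate import SyntheticConfig, evenly_planted

cfg = SyntheticConfig(planted=evenly_planted(20, 1.0, 260, 40), seed=1)
prot, met, meta, truth = generate_cohort(cfg)
merged = merge_omics(preprocess_proteins(prot), preprocess_metabolites(met)[0])
design = encode_design(
    meta, include={"sex", "age", "bmi", "smoking", "meds", "phenotype"},
    smoking_mode=SmokingMode.UNKNOWN_LEVEL,
)
design = design.loc[:, design.nunique() > 1]

net = infer_network(merged, design, seed=1)
print(f"network: {net.graph.number_of_nodes()} nodes, {net.n_edges} edges "
      f"({len(net.nodes_of_kind('phenotype'))} phenotype, "
      f"{len(net.nodes_of_kind('covariate'))} covariate nodes)")

ranking = rwr(net, [n for n in net.nodes if n.startswith("group_")])
print(f"RWR converged in {ranking.iterations} iterations "
      f"(L1 residual {ranking.residual:.2e})")

sub = top_n_features(net, ranking, 50)
planted = set(truth.planted_ids)
recovered = len(set(sub.nodes) & planted)
print(f"top-50 phenotype-centric subnetwork: {len(sub.edges)} induced edges; "
      f"{recovered}/20 planted features recovered")
print("Relevance scores measure steady-state visit probability of a walker")
print("restarting at the phenotype nodes — features wired close to the")
print("phenotype rank highest, even when their marginal effect is modest.")
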