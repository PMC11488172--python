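#!/usr/bin/env python
"""Map the absorbed compounds to putative protein targets by fingerprint
similarity (Tanimoto > 0.60 against annotated reference ligands) and union
the two disease-target source lists.

Reads the stage-01/02 outputs; writes target_associations.tsv,
drug_targets.txt and disease_targets.txt under results/analysis.
"""

import argparse
from pathlib import Path

import pandas as pd

from netpharm.simulate import SimConfig, simulate_fingerprint_library
from netpharm.targets import (map_targets, read_id_list, union_disease_targets,
                              write_fingerprints)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=0)
args = ap.parse_args()

OUT = Path("results/analysis")
matches = pd.read_csv(OUT / "matches.tsv", sep="\t")
absorbed = sorted(set(matches.component_id))
origins = pd.read_csv(OUT / "node_origins.tsv", sep="\t")
drug_pool = sorted(origins.loc[origins.origin.isin(["drug", "both"]), "node"])

cfg = SimConfig(seed=args.seed)
queries, refs, ann, truth = simulate_fingerprint_library(cfg, absorbed, drug_pool)
write_fingerprints(queries, OUT / "compound_fingerprints.tsv")
write_fingerprints(refs, OUT / "reference_fingerprints.tsv")

assoc = map_targets(queries, refs, ann)
pd.DataFrame([{
    "compound": a.compound_id, "target": a.target_id,
    "similarity": round(a.similarity, 4), "via": a.via_compound_id,
} for a in assoc]).to_csv(OUT / "target_associations.tsv", sep="\t", index=False)

drug_targets = sorted({a.target_id for a in assoc})
(OUT / "drug_targets.txt").write_text("\n".join(drug_targets) + "\n")

ds = union_disease_targets(read_id_list(OUT / "disease_source_a.txt"),
                           read_id_list(OUT / "disease_source_b.txt"))
(OUT / "disease_targets.txt").write_text(
    "\n".join(sorted(ds.unioned_ids)) + "\n")

planted = set(truth.planted_associations)
got = {(a.compound_id, a.target_id) for a in assoc}
print(f"compounds mapped: {len(absorbed)}; associations: {len(assoc)} "
      f"over {len(drug_targets)} targets")
print(f"planted compound–target pairs recovered: "
      f"{len(planted & got)}/{len(planted)}; spurious: {len(got - planted)}")
print(f"disease targets after union/dedup: {len(ds.unioned_ids)}")
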