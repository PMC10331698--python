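"""Two-pass SOM clustering of response profiles.

Pass 1 clusters every profile row on a 7x7 map; pass 2 removes rows with
more than two positive cytotoxicity endpoints and re-clusters on a 6x6 map,
since broad cytotoxic suppression otherwise dominates the layout.  Reports
which clusters carry the cytotoxic profiles and where the duplicate samples
of bioactive chemicals land.
"""

import sys
from pathlib import Path

import pandas as pd

import phenoscreen as ps

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

vocab = ps.Vocabulary.from_csv(DATA / "endpoints.csv")
cfg = ps.PipelineConfig(seed=SEED)
profiles = ps.ProfileMatrix.from_tsv(ROOT / "profiles.tsv")
hits = ps.read_level5_table(ROOT / "hitcalls.csv")

counts = ps.cytotox_counts(hits, vocab, profiles.values.index)
res = ps.two_pass_clustering(profiles, counts, cfg)

res.assignments_full.to_csv(ROOT / "clusters_full.csv")
res.assignments_filtered.to_csv(ROOT / "clusters_filtered.csv")
res.cluster_summary.to_csv(ROOT / "cluster_summary.csv", index=False)
res.som_filtered.codebook_frame().to_csv(ROOT / "codebook_filtered.tsv",
                                         sep="\t")

n_removed = len(res.assignments_full) - len(res.assignments_filtered)
print(f"pass 1: {len(res.assignments_full)} profiles on a 7x7 map; "
      f"pass 2: {n_removed} cytotoxic rows removed, "
      f"{len(res.assignments_filtered)} re-clustered on a 6x6 map")

full = pd.DataFrame({"cluster": res.assignments_full, "n_cytotox": counts})
cyto_clusters = (full.groupby("cluster")["n_cytotox"].mean()
                 .sort_values(ascending=False))
print("pass-1 clusters most influenced by cytotoxicity "
      "(cluster: mean positive cytotox endpoints):")
for cl, m in cyto_clusters.head(5).items():
    print(f"  {cl}: {m:.1f}")

occ = res.cluster_summary.sort_values("n_profiles", ascending=False)
print("largest pass-2 clusters:")
for _, row in occ.head(3).iterrows():
    chems = row["chemicals"].split(";")
    label = ", ".join(chems[:4]) + ("..." if len(chems) > 4 else "")
    print(f"  cluster {row['cluster']}: {row['n_profiles']} profiles "
          f"({label})")
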