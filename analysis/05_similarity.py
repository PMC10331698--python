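"""Profile-similarity search of screen profiles against the reference database.

Matches every profile row by Pearson correlation over the shared endpoint
panel (top 10 with r > 0.6, cytotoxic reference profiles excluded) and
reports the best match per screened chemical.
"""

import sys
from pathlib import Path

import phenoscreen as ps

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

cfg = ps.PipelineConfig(seed=SEED)
profiles = ps.ProfileMatrix.from_tsv(ROOT / "profiles.tsv")
refdb = ps.ReferenceDB.from_tsv(DATA / "reference_db.tsv")

matches = ps.search_all(profiles, refdb, cfg.similarity_r_min,
                        cfg.similarity_top_k, True,
                        cfg.max_cytotox_endpoints_for_profiling)
matches.to_csv(ROOT / "similarity_matches.csv", index=False)

print(f"{len(matches)} matches with r > {cfg.similarity_r_min} "
      f"over {profiles.values.shape[0]} query profiles")
if len(matches):
    best = (matches[matches["rank"] == 1]
            .assign(chemical=lambda d: d["query_sample"].map(
                profiles.chemical_of))
            .sort_values("r", ascending=False)
            .drop_duplicates("chemical"))
    print("top rank-1 matches (chemical -> reference, r):")
    for _, row in best.head(10).iterrows():
        print(f"  {row['chemical']} @ {row['query_concentration']:g} uM -> "
              f"{row['reference_label']} (r={row['r']:.3f})")
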