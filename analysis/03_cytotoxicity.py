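"""Cytotoxicity screening: overt flags, positive-endpoint counts, nonspecifics.

Counts hit-called cytotoxicity-role endpoints (SRB total protein, PBMC
viability) per sample-concentration, averages the counts over blinded
duplicates, and reports chemicals active on two or more cytotoxicity
endpoints as nonspecifically cytotoxic.
"""

import sys
from pathlib import Path

import phenoscreen as ps

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

vocab = ps.Vocabulary.from_csv(DATA / "endpoints.csv")
profiles = ps.ProfileMatrix.from_tsv(ROOT / "profiles.tsv")
hits = ps.read_level5_table(ROOT / "hitcalls.csv")

summary = ps.cytotox_summary_table(hits, vocab, profiles)
summary.to_csv(ROOT / "cytotox_summary.csv", index=False)

nonspec = summary[summary["nonspecific"]]
chems = sorted(nonspec["chemical_id"].unique())
print(f"{len(chems)} nonspecifically cytotoxic chemicals "
      f"(>=2 positive cytotoxicity endpoints)")
for chem in chems:
    sub = nonspec[nonspec["chemical_id"] == chem]
    cells = "; ".join(f"{c:g} ({m:g})" for c, m in
                      zip(sub["concentration"], sub["mean_count"]))
    print(f"  {chem}: {cells}")
print(f"overtly cytotoxic sample-concentrations: "
      f"{int(summary['overt'].sum())} of {len(summary)}")
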