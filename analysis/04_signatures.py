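"""Toxicity-signature analysis: per-concentration calls and the summary table.

Builds the 95% historical-control envelope, runs the stepwise nine-rule
engine on every un-inverted profile row, and summarizes each chemical with
the minimum-concentration listing convention (nd / NA / conc / >=conc).
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
hist = pd.read_csv(DATA / "historical_controls.tsv", sep="\t")

envelope = ps.build_envelope(hist, cfg.envelope_coverage, cfg.envelope_method)
envelope.to_tsv(ROOT / "envelope.tsv")

calls = ps.evaluate_all(profiles, envelope, vocab, cfg)
calls.to_csv(ROOT / "signature_calls.csv", index=False)

summaries = ps.summarize_all(calls, profiles.replicate_of)
table = ps.signature_table(summaries)
table.to_csv(ROOT / "signature_table.csv")

listed = summaries[summaries["status"].isin(["listed_ge", "listed_at_top"])]
print(f"signature calls for {table.shape[0]} chemicals "
      f"x {table.shape[1]} signatures")
per_sig = listed.groupby("signature").size()
for sig in ps.SIGNATURES:
    print(f"  {sig}: {per_sig.get(sig, 0)} chemicals listed")
flagged_chems = sorted(listed["chemical_id"].unique())
print(f"chemicals with at least one signature: {len(flagged_chems)}")
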