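"""Generate the synthetic screen used by the downstream analysis steps.

Writes a default-condition screen — 100 chemicals (≈1 in 5 bioactive), two
blinded duplicate samples each, 4-point dilution series, lognormal
measurement noise of 0.05 log10 units — together with the historical
vehicle-control collection and a labeled reference profile database, under
results/data/.
"""

import sys
from pathlib import Path

import phenoscreen as ps

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

vocab = ps.default_vocabulary()
cfg = ps.PipelineConfig(seed=SEED)

wells, truth = ps.generate_screen(cfg, n_chemicals=100, seed=SEED)
ps.write_well_table(wells, OUT / "wells.csv")
vocab.to_csv(OUT / "endpoints.csv")

hist = ps.generate_historical_controls(vocab, seed=SEED + 1)
hist.to_csv(OUT / "historical_controls.tsv", sep="\t", index=False)

archetypes = {
    name: ps.make_archetype(name, vocab, n_cytotox_endpoints=6)
    for name in ("cyclosporine_like", "glucocorticoid_like",
                 "antimetabolite_like", "nonspecific_cytotoxic")
}
refdb = ps.generate_reference_db(archetypes, n_per_archetype=2, seed=SEED + 2)
refdb.to_tsv(OUT / "reference_db.tsv")

n_active = sum(1 for a in truth.archetype.values() if a != "inactive")
print(f"screen: {len(truth.archetype)} chemicals "
      f"({n_active} bioactive by design), {len(wells):,} wells")
print(f"historical controls: {hist['run'].nunique()} runs x "
      f"{len(hist) // (hist['run'].nunique() * len(vocab))} wells per endpoint")
print(f"reference db: {len(refdb.values)} labeled profiles")
print(f"outputs in {OUT}")
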