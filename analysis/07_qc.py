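"""Assay acceptance: vehicle-well %CV and the positive-control Pearson test.

Computes the per-plate %CV of vehicle wells from the screen, then simulates
a positive-control reference set (a strong multi-system suppressor, as a
cytotoxic reference compound produces) to establish the 1% false-negative
Pearson cutoff and measure the pass rate of new same-distribution controls.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import phenoscreen as ps

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = ROOT / "data"

vocab = ps.Vocabulary.from_csv(DATA / "endpoints.csv")
wells = ps.read_well_table(DATA / "wells.csv", vocab)

cvs = ps.plate_cv_table(wells)
cvs.rename("cv_percent").to_csv(ROOT / "plate_cv.csv")
pct_ok = 100.0 * (cvs < 20.0).mean()
print(f"plate %CV: median {cvs.median():.1f}%, "
      f"{pct_ok:.1f}% of {len(cvs)} plates below 20% "
      f"({'pass' if pct_ok >= 95.0 else 'FAIL'} at the >=95% rule)")

# positive-control reference set: strong suppressive profile + assay noise
rng = np.random.default_rng(SEED + 10)
arch = ps.make_archetype("nonspecific_cytotoxic", vocab, n_cytotox_endpoints=8)
eps = vocab.endpoint_ids
base = (np.array([arch.effect_at(e, -1) for e in eps])
        + rng.normal(0, 0.15, len(eps)))
reference = pd.DataFrame(base + rng.normal(0, 0.05, (100, len(eps))),
                         columns=eps)
cutoff = ps.pearson_fn_cutoff(reference)

new_control = pd.Series(base + rng.normal(0, 0.05, len(eps)), index=eps)
res = ps.qc_accept(new_control, reference, cvs)
print(f"positive-control Pearson test: r={res.pearson_r:.4f} vs "
      f"1%-false-negative cutoff {res.cutoff_r:.4f} -> "
      f"{'pass' if res.pearson_pass else 'fail'}")
print(f"assay accepted: {res.accepted}")

draws = 2000
mean_ref = reference.to_numpy().mean(axis=0)
passed = sum(
    ps.pearson_profile(base + rng.normal(0, 0.05, len(eps)), mean_ref) > cutoff
    for _ in range(draws))
print(f"simulated same-distribution controls: {100.0 * passed / draws:.2f}% "
      f"pass over {draws} draws (nominal ~99%)")
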