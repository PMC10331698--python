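"""Cytotoxicity flagging, counting and profile filtering.

Two distinct notions are kept and never conflated:

* **overt cytotoxicity** — a threshold rule on the un-inverted Log10Ratio:
  any cytotoxicity-role endpoint (SRB total protein, PBMC viability) below
  −0.3 at a sample-concentration;
* **positive cytotoxicity endpoints** — hit-call based: the number of
  cytotoxicity-role endpoints with ``hitc = 1`` and LOEC at or below the
  concentration of interest.  Samples active on two or more such endpoints
  are *nonspecifically cytotoxic*; profiles with more than two are removed
  before clustering and similarity search.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProfileMatrix
from .vocab import Vocabulary


@dataclass
class CytotoxFlags:
    """Cytotoxicity status of one sample-concentration."""

    sample_id: str
    concentration: float
    cytotox_endpoints_below_threshold: list[str] = field(default_factory=list)
    n_active_cytotox_hits: int = 0
    overt: bool = False
    nonspecific: bool = False


def flag_overt(profiles: ProfileMatrix, vocabulary: Vocabulary,
               threshold: float = -0.3, strict: bool = True) -> pd.DataFrame:
    """Overt-cytotoxicity flags per sample-concentration row.

    ``strict`` compares with ``<`` (boundary values not overt); the
    non-strict variant uses ``<=``.  Operates on un-inverted Log10Ratios.
    """
    cols = [c for c in profiles.values.columns if c in set(vocabulary.cytotox_endpoints)]
    sub = profiles.values[cols]
    below = sub.lt(threshold) if strict else sub.le(threshold)
    out = pd.DataFrame(index=profiles.values.index)
    out["overt"] = below.any(axis=1)
    out["endpoints_below"] = [
        ";".join(sub.columns[row]) for row in below.to_numpy()
    ]
    return out


def count_active_cytotox(hits: pd.DataFrame, vocabulary: Vocabulary,
                         sample_id: str, concentration: float) -> int:
    """Number of cytotoxicity-role endpoints active (hitc=1, LOEC ≤ conc) for a sample."""
    cyto = set(vocabulary.cytotox_endpoints)
    sub = hits[(hits["sample_id"] == sample_id) & (hits["hitc"] == 1)]
    sub = sub[sub["endpoint_id"].isin(cyto)]
    return int((sub["loec_uM"] <= concentration).sum())


def cytotox_counts(hits: pd.DataFrame, vocabulary: Vocabulary,
                   rows: pd.MultiIndex) -> pd.Series:
    """Vectorized active-cytotoxicity-endpoint counts for every (sample, conc) row."""
    cyto = set(vocabulary.cytotox_endpoints)
    active = hits[(hits["hitc"] == 1) & hits["endpoint_id"].isin(cyto)]
    loecs = {
        s: g["loec_uM"].to_numpy(float)
        for s, g in active.groupby("sample_id", sort=False)
    }
    counts = [
        int((loecs[s] <= c).sum()) if s in loecs else 0
        for s, c in zip(rows.get_level_values("sample_id"),
                        rows.get_level_values("concentration"))
    ]
    return pd.Series(counts, index=rows, name="n_cytotox")


def flag_nonspecific(sample_hits: pd.DataFrame, vocabulary: Vocabulary,
                     tested_concs, min_endpoints: int = 2
                     ) -> tuple[bool, list[float]]:
    """Nonspecific cytotoxicity for one blinded sample.

    True when the sample is active on ``min_endpoints`` or more
    cytotoxicity-role endpoints; also returns the tested concentrations at
    which that many endpoints are active (LOEC ≤ concentration).
    """
    cyto = set(vocabulary.cytotox_endpoints)
    active = sample_hits[(sample_hits["hitc"] == 1)
                         & sample_hits["endpoint_id"].isin(cyto)]
    loecs = active["loec_uM"].to_numpy(float)
    concs = [float(c) for c in sorted(tested_concs)
             if (loecs <= c).sum() >= min_endpoints]
    return len(concs) > 0, concs


def cytotox_summary_table(hits: pd.DataFrame, vocabulary: Vocabulary,
                          profiles: ProfileMatrix,
                          threshold: float = -0.3, strict: bool = True,
                          min_endpoints: int = 2) -> pd.DataFrame:
    """Chemical-level cytotoxicity summary.

    One row per chemical × tested concentration with the count of positive
    cytotoxicity endpoints averaged over the duplicate samples (fractional
    counts are therefore possible), overt status (any sample overt), and the
    nonspecific flag (replicate-mean count ≥ ``min_endpoints``).
    """
    counts = cytotox_counts(hits, vocabulary, profiles.values.index)
    overt = flag_overt(profiles, vocabulary, threshold, strict)["overt"]
    df = pd.DataFrame({"n_cytotox": counts, "overt": overt}).reset_index()
    df["chemical_id"] = df["sample_id"].map(profiles.chemical_of)
    out = (
        df.groupby(["chemical_id", "concentration"], sort=True)
        .agg(mean_count=("n_cytotox", "mean"), overt=("overt", "any"))
        .reset_index()
    )
    out["nonspecific"] = out["mean_count"] >= min_endpoints
    return out


def filter_for_profiling(profiles: ProfileMatrix, counts: pd.Series,
                         max_allowed: int = 2) -> ProfileMatrix:
    """Remove rows with more than ``max_allowed`` positive cytotoxicity endpoints."""
    counts = counts.reindex(profiles.values.index)
    if counts.isna().any():
        raise ValueError("cytotoxicity counts missing for some profile rows")
    keep = (counts <= max_allowed).to_numpy()
    return profiles.subset_rows(keep)
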