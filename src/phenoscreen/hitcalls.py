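"""Hit calls and lowest-effective-concentration (LOEC) determination.

Per endpoint, baseline variability (``bmad``) is the scaled median absolute
deviation of responses pooled from each sample's two lowest tested
concentrations.  The response cutoff is ``coff = max(3·bmad, log10 1.2)``.
A sample is called active on an endpoint (``hitc = 1``) when its
direction-corrected response at any concentration strictly exceeds ``coff``;
the LOEC is the lowest such concentration.  Each blinded duplicate sample is
hit-called independently; concordance between duplicates is reported
separately.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ProfileMatrix, LEVEL5_COLUMNS


def _two_lowest_mask(values: pd.DataFrame) -> np.ndarray:
    """Boolean row mask selecting each sample's two lowest tested concentrations.

    Samples with a single tested concentration contribute that one row.
    """
    samples = values.index.get_level_values("sample_id")
    concs = values.index.get_level_values("concentration").to_numpy(float)
    rank = (
        pd.Series(concs)
        .groupby(pd.Series(samples.to_numpy()), sort=False)
        .rank(method="dense")
        .to_numpy()
    )
    return rank <= 2


def mad(x: np.ndarray, scale: float = 1.4826) -> float:
    """Median absolute deviation with a consistency scale (1.4826 → normal sd)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty pool for MAD")
    return float(scale * np.median(np.abs(x - np.median(x))))


def compute_bmad(profiles: ProfileMatrix, endpoint_id: str,
                 mad_scale: float = 1.4826) -> float:
    """Baseline MAD for one endpoint from the pooled two-lowest-concentration responses."""
    mask = _two_lowest_mask(profiles.values)
    pool = profiles.values.loc[mask, endpoint_id].to_numpy(float)
    return mad(pool, mad_scale)


def compute_bmad_all(profiles: ProfileMatrix,
                     mad_scale: float = 1.4826) -> pd.Series:
    """Baseline MAD for every endpoint (vectorized :func:`compute_bmad`)."""
    mask = _two_lowest_mask(profiles.values)
    baseline = profiles.values.loc[mask]
    if baseline.empty:
        raise ValueError("empty baseline pool")
    med = baseline.median(axis=0)
    return mad_scale * (baseline - med).abs().median(axis=0)


def compute_cutoff(bmad: float, floor_fold: float = 1.2) -> float:
    """Response cutoff: the maximum of 3·bmad and log10(floor_fold)."""
    if floor_fold <= 1.0:
        raise ValueError("floor_fold must exceed 1")
    if bmad < 0:
        raise ValueError("bmad must be non-negative")
    return max(3.0 * bmad, math.log10(floor_fold))


def call_hits(responses: pd.Series, coff: float) -> tuple[int, float | None]:
    """Hit-call one sample on one endpoint.

    Parameters
    ----------
    responses
        Direction-corrected Log10Ratio per tested concentration
        (index = concentration in µM).
    coff
        Response cutoff; exceedance is strict (ties are inactive).

    Returns
    -------
    (hitc, loec)
        ``hitc`` ∈ {0, 1}; ``loec`` is the lowest exceeding concentration in
        µM, or None when inactive.
    """
    exceed = responses[responses > coff]
    if exceed.empty:
        return 0, None
    return 1, float(min(exceed.index))


def hitcall_table(profiles: ProfileMatrix,
                  config: PipelineConfig | None = None) -> pd.DataFrame:
    """Hit-call every sample × endpoint of a direction-corrected profile matrix.

    Returns the level-5-style table with columns
    ``sample_id, chemical_id, endpoint_id, bmad, coff, hitc, loec_uM``.
    """
    config = config or PipelineConfig()
    values = profiles.values
    bmads = compute_bmad_all(profiles, config.mad_scale)
    coffs = np.maximum(3.0 * bmads, config.coff_floor)

    exceed = values.gt(coffs, axis=1)
    concs = values.index.get_level_values("concentration").to_numpy(float)
    masked = np.where(exceed.to_numpy(), concs[:, None], np.inf)
    loec = (
        pd.DataFrame(masked, index=values.index, columns=values.columns)
        .groupby(level="sample_id", sort=False)
        .min()
    )

    long = loec.stack().rename("loec_uM").reset_index()
    long.columns = ["sample_id", "endpoint_id", "loec_uM"]
    long["hitc"] = (long["loec_uM"] < np.inf).astype(int)
    long["loec_uM"] = long["loec_uM"].replace(np.inf, np.nan)
    long["chemical_id"] = long["sample_id"].map(profiles.chemical_of)
    long["bmad"] = long["endpoint_id"].map(bmads)
    long["coff"] = long["endpoint_id"].map(coffs)
    return long[LEVEL5_COLUMNS]


def replicate_concordance(hits_a: pd.Series, hits_b: pd.Series) -> float:
    """Percent of endpoints on which two duplicate samples agree in hitc."""
    if set(hits_a.index) != set(hits_b.index):
        raise ValueError("duplicate samples measured different endpoint sets")
    hits_b = hits_b.reindex(hits_a.index)
    return float(100.0 * (hits_a == hits_b).mean())


def concordance_table(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-chemical replicate concordance of hit calls.

    Chemicals with a single blinded sample are skipped.  Returns one row per
    chemical with ``concordance_pct``; the screen-level summary is the mean
    ± sd of this column.
    """
    rows = []
    for chemical, sub in hits.groupby("chemical_id", sort=False):
        pivot = sub.pivot(index="endpoint_id", columns="sample_id", values="hitc")
        samples = list(pivot.columns)
        if len(samples) < 2:
            continue
        pct = replicate_concordance(pivot[samples[0]], pivot[samples[1]])
        rows.append({"chemical_id": chemical, "concordance_pct": pct})
    return pd.DataFrame(rows, columns=["chemical_id", "concordance_pct"])
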