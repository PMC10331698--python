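"""Plate- and assay-level acceptance criteria.

Plate performance is the percent coefficient of variation (%CV) of the
vehicle-control wells' raw values.  Positive-control performance uses the
leave-one-out (LOO) Pearson test: for each profile in the positive-control
reference set, the Pearson correlation with the mean of the remaining
profiles is computed; the 1st percentile of those correlations is the 1%
false-negative cutoff.  A new positive-control profile passes when its
correlation with the mean reference profile exceeds that cutoff.  An assay
is accepted when the positive control passes the Pearson test and at least
95% of plates have %CV below 20%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .similarity import pearson_profile


@dataclass
class QCResult:
    assay_id: str
    pearson_r: float
    cutoff_r: float
    pearson_pass: bool
    pct_plates_cv_ok: float
    plates_pass: bool

    @property
    def accepted(self) -> bool:
        return self.pearson_pass and self.plates_pass


def plate_cv(vehicle_values) -> float:
    """%CV (100·sd/mean, sample sd) of a plate's vehicle-control raw values."""
    x = np.asarray(vehicle_values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 vehicle wells for a %CV")
    return float(100.0 * x.std(ddof=1) / x.mean())


def plate_cv_table(wells: pd.DataFrame, aggregate: str = "max") -> pd.Series:
    """Per-plate %CV of vehicle wells.

    %CV is computed per (plate, endpoint) and aggregated to the plate with
    ``aggregate`` ("max" by default — a plate is only as good as its worst
    endpoint — or "mean").
    """
    veh = wells[wells["well_role"] == "vehicle_control"]
    per_ep = veh.groupby(["plate_id", "endpoint_id"])["raw_value"].apply(plate_cv)
    return getattr(per_ep.groupby("plate_id"), aggregate)()


def loo_pearson_values(reference: pd.DataFrame) -> np.ndarray:
    """Leave-one-out Pearson values of a positive-control reference set.

    For each of the n reference profiles (rows), the correlation between the
    profile and the mean of the other n−1 profiles; returns n values.
    """
    if reference.shape[0] < 3:
        raise ValueError("need at least 3 reference profiles")
    X = reference.to_numpy(float)
    n = X.shape[0]
    total = X.sum(axis=0)
    out = np.empty(n)
    for i in range(n):
        rest_mean = (total - X[i]) / (n - 1)
        out[i] = pearson_profile(X[i], rest_mean)
    return out


def pearson_fn_cutoff(reference: pd.DataFrame) -> float:
    """The 1% false-negative Pearson cutoff: 1st percentile of the LOO values.

    Percentiles use linear interpolation between order statistics.
    """
    return float(np.percentile(loo_pearson_values(reference), 1.0))


def qc_accept(new_profile: pd.Series | np.ndarray, reference: pd.DataFrame,
              plate_cvs: pd.Series | np.ndarray,
              cv_limit: float = 20.0, min_pct_plates: float = 95.0,
              assay_id: str = "assay") -> QCResult:
    """Assay-level acceptance from the Pearson test and the plate %CV rule."""
    cutoff = pearson_fn_cutoff(reference)
    if isinstance(new_profile, pd.Series):
        new_profile = new_profile.reindex(reference.columns).to_numpy(float)
    r = pearson_profile(new_profile, reference.to_numpy(float).mean(axis=0))
    cvs = np.asarray(plate_cvs, dtype=float)
    pct_ok = float(100.0 * (cvs < cv_limit).mean()) if cvs.size else 100.0
    return QCResult(
        assay_id=assay_id,
        pearson_r=r,
        cutoff_r=cutoff,
        pearson_pass=r > cutoff,
        pct_plates_cv_ok=pct_ok,
        plates_pass=pct_ok >= min_pct_plates,
    )
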