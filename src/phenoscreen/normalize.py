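"""Normalization to Log10Ratio profiles and the historical-control envelope.

A well's Log10Ratio is ``log10(raw / mean of the 8 same-plate vehicle wells)``
for the same endpoint.  Loss-of-signal endpoints are sign-inverted *only* for
hit calling; the signature engine and all profile-level analyses consume the
un-inverted matrix (both orientations are retained by the pipeline).

The significance envelope is the per-endpoint interval covering the configured
fraction (default 95%) of historical vehicle-control Log10Ratios; values
strictly outside it count as significant responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProfileMatrix, ValidationError, N_VEHICLE_WELLS
from .vocab import Vocabulary


def compute_log10_ratios(wells: pd.DataFrame, vocabulary: Vocabulary | None = None
                         ) -> ProfileMatrix:
    """Convert a well table to a (sample, concentration) × endpoint Log10Ratio matrix.

    Each treatment well is divided by the mean raw value of the 8
    vehicle-control wells on the same plate for the same endpoint, then
    log10-transformed.  Vehicle wells are excluded from the output rows.
    """
    veh = wells[wells["well_role"] == "vehicle_control"]
    vmeans = veh.groupby(["plate_id", "endpoint_id"])["raw_value"].agg(["mean", "size"])
    short = vmeans[vmeans["size"] != N_VEHICLE_WELLS]
    if len(short):
        raise ValidationError(
            f"plate/endpoint pairs without {N_VEHICLE_WELLS} vehicle wells: "
            f"{list(short.index[:5])}"
        )

    trt = wells[wells["well_role"] == "treatment"].copy()
    key = pd.MultiIndex.from_frame(trt[["plate_id", "endpoint_id"]])
    try:
        trt["vehicle_mean"] = vmeans["mean"].reindex(key).to_numpy()
    except KeyError as exc:  # pragma: no cover - reindex fills NaN instead
        raise ValidationError(str(exc))
    if trt["vehicle_mean"].isna().any():
        bad = trt.loc[trt["vehicle_mean"].isna(), ["plate_id", "endpoint_id"]]
        raise ValidationError(
            f"missing vehicle wells for plate/endpoint: "
            f"{list(bad.itertuples(index=False, name=None))[:5]}"
        )
    trt["log10_ratio"] = np.log10(trt["raw_value"] / trt["vehicle_mean"])

    values = trt.pivot_table(
        index=["sample_id", "concentration_uM"],
        columns="endpoint_id",
        values="log10_ratio",
    )
    values.index = values.index.set_names(["sample_id", "concentration"])
    values.columns.name = None
    if values.isna().any().any():
        raise ValidationError("incomplete profiles: some sample/concentration rows "
                              "lack measurements for some endpoints")
    if vocabulary is not None:
        # keep vocabulary column order for endpoints present
        order = [e for e in vocabulary.endpoint_ids if e in values.columns]
        values = values[order]
    replicate_of = dict(
        trt.drop_duplicates("sample_id")[["sample_id", "chemical_id"]].to_numpy()
    )
    return ProfileMatrix(values, replicate_of)


def invert_down_endpoints(profile: ProfileMatrix, vocabulary: Vocabulary
                          ) -> ProfileMatrix:
    """Negate loss-of-signal endpoints so every response points positive."""
    values = profile.values.copy()
    down = [c for c in values.columns if vocabulary[c].is_down_readout]
    values[down] = -values[down]
    return ProfileMatrix(values, dict(profile.replicate_of))


# --------------------------------------------------------------------------
# Historical-control envelope


@dataclass
class HistoricalEnvelope:
    """Per-endpoint (lower, upper) Log10Ratio bounds at the configured coverage."""

    bounds: pd.DataFrame  # index endpoint_id, columns ["lower", "upper"]
    coverage: float = 0.95

    def __post_init__(self) -> None:
        if not ((self.bounds["lower"] <= 0) & (self.bounds["upper"] >= 0)).all():
            raise ValidationError(
                "envelope must contain 0 for every endpoint (vehicle-centered)"
            )

    def __contains__(self, endpoint_id: str) -> bool:
        return endpoint_id in self.bounds.index

    def lower(self, endpoint_id: str) -> float:
        return float(self.bounds.at[endpoint_id, "lower"])

    def upper(self, endpoint_id: str) -> float:
        return float(self.bounds.at[endpoint_id, "upper"])

    def to_tsv(self, path) -> None:
        self.bounds.to_csv(path, sep="\t", index_label="endpoint_id")

    @classmethod
    def from_tsv(cls, path, coverage: float = 0.95) -> "HistoricalEnvelope":
        return cls(pd.read_csv(path, sep="\t", index_col="endpoint_id"), coverage)


def build_envelope(historical: pd.DataFrame, coverage: float = 0.95,
                   method: str = "quantile") -> HistoricalEnvelope:
    """Build the significance envelope from historical vehicle Log10Ratios.

    Parameters
    ----------
    historical
        Long table with columns ``endpoint_id`` and ``log10_ratio``; at least
        two values per endpoint.
    coverage
        Central coverage fraction (default 0.95).
    method
        ``"quantile"`` — empirical quantiles at (1−coverage)/2 and
        1−(1−coverage)/2 (distribution-free default); ``"normal"`` —
        mean ± z·sd normal-theory interval.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    counts = historical.groupby("endpoint_id")["log10_ratio"].size()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"endpoints with <2 historical values: {list(thin.index[:5])}"
        )
    alpha = (1.0 - coverage) / 2.0
    grouped = historical.groupby("endpoint_id")["log10_ratio"]
    if method == "quantile":
        lower = grouped.quantile(alpha)
        upper = grouped.quantile(1.0 - alpha)
    elif method == "normal":
        from scipy.stats import norm
        z = norm.ppf(1.0 - alpha)
        mean, sd = grouped.mean(), grouped.std(ddof=1)
        lower, upper = mean - z * sd, mean + z * sd
    else:
        raise ValueError(f"unknown envelope method {method!r}")
    # vehicle-centered by construction up to sampling noise; clip to contain 0
    bounds = pd.DataFrame({
        "lower": np.minimum(lower, 0.0),
        "upper": np.maximum(upper, 0.0),
    })
    bounds.index.name = "endpoint_id"
    return HistoricalEnvelope(bounds, coverage)


def outside_envelope(value: float, endpoint_id: str,
                     envelope: HistoricalEnvelope) -> bool:
    """True iff ``value`` falls strictly outside the endpoint's envelope.

    Boundary values count as inside (conservative call).
    """
    if endpoint_id not in envelope:
        raise KeyError(f"endpoint {endpoint_id!r} not in envelope")
    return value < envelope.lower(endpoint_id) or value > envelope.upper(endpoint_id)


def outside_envelope_frame(values: pd.DataFrame,
                           envelope: HistoricalEnvelope) -> pd.DataFrame:
    """Vectorized :func:`outside_envelope` over a profile matrix."""
    missing = set(values.columns) - set(envelope.bounds.index)
    if missing:
        raise KeyError(f"endpoints not in envelope: {sorted(missing)[:5]}")
    lo = envelope.bounds["lower"].reindex(values.columns)
    hi = envelope.bounds["upper"].reindex(values.columns)
    return values.lt(lo, axis=1) | values.gt(hi, axis=1)
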