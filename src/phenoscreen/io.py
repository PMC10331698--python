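"""Tables and file formats.

The canonical in-memory containers are pandas objects:

* a **well table** is a long-format ``DataFrame`` with one row per well and
  columns ``plate_id, well_id, sample_id, chemical_id, concentration_uM,
  endpoint_id, raw_value, well_role``;
* a :class:`ProfileMatrix` wraps a wide ``DataFrame`` of Log10Ratio values
  with ``(sample_id, concentration)`` rows and endpoint columns, plus the
  blinded-sample → chemical mapping.

All formats round-trip: ``read(write(x)) == x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .vocab import Vocabulary

WELL_ROLES = ("treatment", "vehicle_control", "positive_control", "non_stim_control")
N_VEHICLE_WELLS = 8

WELL_COLUMNS = [
    "plate_id", "well_id", "sample_id", "chemical_id",
    "concentration_uM", "endpoint_id", "raw_value", "well_role",
]


class FormatError(ValueError):
    """A file does not conform to the expected layout."""


class ValidationError(ValueError):
    """A table violates a domain invariant."""


@dataclass(frozen=True)
class WellRecord:
    """One well: a single biomarker measured under one treatment."""

    plate_id: str
    well_id: str
    sample_id: str
    chemical_id: str
    concentration_uM: float
    endpoint_id: str
    raw_value: float
    well_role: str


# --------------------------------------------------------------------------
# Well tables


def validate_well_table(wells: pd.DataFrame, vocabulary: Vocabulary) -> pd.DataFrame:
    """Validate a well table against the domain invariants.

    Checks raw values are positive, endpoints resolve in the vocabulary,
    roles are known, treatment concentrations are positive, and every
    (plate, endpoint) carries exactly 8 vehicle-control wells.
    """
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise FormatError(f"well table missing column(s): {missing}")

    bad = wells.index[~(wells["raw_value"] > 0)]
    if len(bad):
        raise ValidationError(f"raw_value must be > 0 (rows {list(bad[:5])})")

    unknown = set(wells["endpoint_id"]) - set(vocabulary.endpoint_ids)
    if unknown:
        raise ValidationError(f"unknown endpoint_id(s): {sorted(unknown)[:5]}")

    bad_roles = set(wells["well_role"]) - set(WELL_ROLES)
    if bad_roles:
        raise ValidationError(f"unknown well_role(s): {sorted(bad_roles)}")

    trt = wells[wells["well_role"] == "treatment"]
    if len(trt) and not (trt["concentration_uM"] > 0).all():
        raise ValidationError("treatment wells must have concentration_uM > 0")

    veh = wells[wells["well_role"] == "vehicle_control"]
    counts = veh.groupby(["plate_id", "endpoint_id"], sort=False).size()
    # every plate/endpoint that has any wells must carry its 8 vehicle wells
    plates = wells.groupby(["plate_id", "endpoint_id"], sort=False).size()
    bad_pairs = [
        pair for pair in plates.index
        if counts.get(pair, 0) != N_VEHICLE_WELLS
    ]
    if bad_pairs:
        raise ValidationError(
            f"plate/endpoint pairs without exactly {N_VEHICLE_WELLS} "
            f"vehicle_control wells: {bad_pairs[:5]}"
        )
    return wells


def read_well_table(path: str | Path, vocabulary: Vocabulary) -> pd.DataFrame:
    """Read and validate a long-format well CSV."""
    wells = pd.read_csv(
        path,
        dtype={
            "plate_id": str, "well_id": str, "sample_id": str,
            "chemical_id": str, "endpoint_id": str, "well_role": str,
        },
    )
    return validate_well_table(wells, vocabulary)


def write_well_table(wells: pd.DataFrame, path: str | Path) -> None:
    wells.to_csv(path, index=False, columns=WELL_COLUMNS)


# --------------------------------------------------------------------------
# Profile matrices


@dataclass
class ProfileMatrix:
    """Log10Ratio profiles: (sample_id, concentration) rows × endpoint columns."""

    values: pd.DataFrame
    replicate_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.nlevels != 2:
            raise ValidationError(
                "ProfileMatrix rows must be a (sample_id, concentration) MultiIndex"
            )
        self.values.index = self.values.index.set_names(
            ["sample_id", "concentration"]
        )
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("ProfileMatrix values must all be finite")

    @property
    def endpoints(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index.get_level_values("sample_id").unique())

    def chemical_of(self, sample_id: str) -> str:
        return self.replicate_of.get(sample_id, sample_id)

    def row(self, sample_id: str, concentration: float) -> pd.Series:
        return self.values.loc[(sample_id, concentration)]

    def subset_rows(self, mask) -> "ProfileMatrix":
        return ProfileMatrix(self.values.loc[mask].copy(), dict(self.replicate_of))

    def validate_endpoints(self, vocabulary: Vocabulary) -> None:
        unknown = set(self.values.columns) - set(vocabulary.endpoint_ids)
        if unknown:
            raise ValidationError(f"unknown endpoint column(s): {sorted(unknown)[:5]}")

    # -- TSV interchange: rows "sample_id:conc", chemical_id column, endpoints

    def to_tsv(self, path: str | Path) -> None:
        out = self.values.copy()
        out.insert(
            0, "chemical_id",
            [self.chemical_of(s) for s in out.index.get_level_values("sample_id")],
        )
        out.index = [
            f"{s}:{c:g}" for s, c in
            zip(self.values.index.get_level_values("sample_id"),
                self.values.index.get_level_values("concentration"))
        ]
        out.to_csv(path, sep="\t", index_label="row_id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileMatrix":
        df = pd.read_csv(path, sep="\t", index_col="row_id")
        if "chemical_id" not in df.columns:
            raise FormatError("profile TSV missing 'chemical_id' column")
        parts = [rid.rsplit(":", 1) for rid in df.index]
        samples = [p[0] for p in parts]
        concs = [float(p[1]) for p in parts]
        replicate_of = dict(zip(samples, df["chemical_id"].astype(str)))
        values = df.drop(columns="chemical_id")
        values.index = pd.MultiIndex.from_arrays(
            [samples, concs], names=["sample_id", "concentration"]
        )
        return cls(values, replicate_of)


# --------------------------------------------------------------------------
# Hit-call ("level 5") tables

LEVEL5_COLUMNS = [
    "sample_id", "chemical_id", "endpoint_id", "bmad", "coff", "hitc", "loec_uM",
]


def write_level5_table(hits: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample × endpoint hit-call table (``loec_uM`` empty for hitc=0)."""
    missing = [c for c in LEVEL5_COLUMNS if c not in hits.columns]
    if missing:
        raise FormatError(f"hit table missing column(s): {missing}")
    hits.to_csv(path, index=False, columns=LEVEL5_COLUMNS)


def read_level5_table(path: str | Path) -> pd.DataFrame:
    hits = pd.read_csv(
        path, dtype={"sample_id": str, "chemical_id": str, "endpoint_id": str}
    )
    missing = [c for c in LEVEL5_COLUMNS if c not in hits.columns]
    if missing:
        raise FormatError(f"hit table missing column(s): {missing}")
    hits["hitc"] = hits["hitc"].astype(int)
    return hits
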