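"""Profile-similarity search against a labeled reference database.

Queries are matched to reference profiles by Pearson correlation over the
shared endpoint panel.  Same-mechanism profile pairs typically correlate at
r > 0.7; the search reports the top 10 matches with r > 0.6 to cast a wider
mechanistic net.  Overtly cytotoxic reference profiles (more than two
positive cytotoxicity endpoints) are excluded because broad suppression
confounds mechanistic similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ProfileMatrix


class ConstantProfileError(ValueError):
    """Pearson correlation is undefined for a constant profile."""


def pearson_profile(a: pd.Series | np.ndarray, b: pd.Series | np.ndarray) -> float:
    """Sample Pearson correlation of two profiles over shared endpoints.

    When both inputs are Series the intersection of their endpoint sets is
    used; at least 3 shared endpoints are required and neither profile may be
    constant.
    """
    if isinstance(a, pd.Series) and isinstance(b, pd.Series):
        shared = a.index.intersection(b.index)
        a, b = a[shared].to_numpy(float), b[shared].to_numpy(float)
    else:
        a, b = np.asarray(a, float), np.asarray(b, float)
    if a.size < 3:
        raise ValueError("need at least 3 shared endpoints for a correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ConstantProfileError("correlation undefined for a constant profile")
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@dataclass(frozen=True)
class SimilarityMatch:
    query_sample: str
    query_concentration: float
    reference_label: str
    reference_concentration: float
    r: float
    rank: int


@dataclass
class ReferenceDB:
    """Labeled reference profiles at specific concentrations.

    ``values`` has a (label, concentration) MultiIndex over endpoint columns;
    ``n_cytotox`` carries each profile's positive-cytotoxicity-endpoint count
    for the cytotoxic-profile exclusion.
    """

    values: pd.DataFrame
    n_cytotox: pd.Series = field(default=None)  # type: ignore[assignment]
    mechanism: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_cytotox is None:
            self.n_cytotox = pd.Series(0, index=self.values.index)
        self.values.index = self.values.index.set_names(["label", "concentration"])

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "n_cytotox", self.n_cytotox.reindex(out.index))
        if self.mechanism is not None:
            out.insert(0, "mechanism", self.mechanism.reindex(self.values.index))
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "ReferenceDB":
        df = pd.read_csv(path, sep="\t", index_col=["label", "concentration"])
        n_cyto = df.pop("n_cytotox")
        mech = df.pop("mechanism") if "mechanism" in df.columns else None
        return cls(df, n_cyto, mech)


def search_reference(query: pd.Series, reference_db: ReferenceDB,
                     r_min: float = 0.6, top_k: int = 10,
                     exclude_cytotoxic: bool = True,
                     max_cytotox: int = 2,
                     query_sample: str = "query",
                     query_concentration: float = float("nan"),
                     ) -> list[SimilarityMatch]:
    """Rank reference profiles by Pearson correlation with the query.

    Returns at most ``top_k`` matches with r strictly above ``r_min``, sorted
    by descending r (ties broken by reference label, then concentration, for
    determinism).  With ``exclude_cytotoxic``, reference profiles with more
    than ``max_cytotox`` positive cytotoxicity endpoints are skipped.  An
    empty result is not an error.
    """
    refs = reference_db.values
    if exclude_cytotoxic:
        keep = (reference_db.n_cytotox.reindex(refs.index) <= max_cytotox).to_numpy()
        refs = refs.loc[keep]

    shared = query.index.intersection(refs.columns)
    if len(refs.columns) and len(shared) < 0.5 * len(refs.columns):
        warnings.warn(
            f"query overlaps only {len(shared)}/{len(refs.columns)} reference "
            "endpoints; rejecting query", stacklevel=2)
        return []

    scored = []
    for (label, conc), ref_row in refs.iterrows():
        try:
            r = pearson_profile(query, ref_row)
        except ConstantProfileError:
            continue
        if r > r_min:
            scored.append((r, str(label), float(conc)))
    scored.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [
        SimilarityMatch(query_sample, query_concentration, label, conc, r, i + 1)
        for i, (r, label, conc) in enumerate(scored[:top_k])
    ]


def search_all(profiles: ProfileMatrix, reference_db: ReferenceDB,
               r_min: float = 0.6, top_k: int = 10,
               exclude_cytotoxic: bool = True, max_cytotox: int = 2
               ) -> pd.DataFrame:
    """Run the reference search for every profile row; returns a match table."""
    rows = []
    for (sample, conc), row in profiles.values.iterrows():
        for m in search_reference(
            row, reference_db, r_min, top_k, exclude_cytotoxic, max_cytotox,
            query_sample=sample, query_concentration=float(conc),
        ):
            rows.append(m.__dict__)
    return pd.DataFrame(rows, columns=[
        "query_sample", "query_concentration", "reference_label",
        "reference_concentration", "r", "rank",
    ])
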