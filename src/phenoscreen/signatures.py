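"""The stepwise nine-signature toxicity-alert engine.

Signatures are small rule sets over named endpoints of the un-inverted
Log10Ratio profile of one sample-concentration, combining an absolute effect
size (|Log10Ratio| > 0.1, i.e. a 20% change, or a −0.3 cytotoxicity level)
with significance against the historical-control envelope.

Evaluation is stepwise:

1. **acute_toxicity** — three or more SRB endpoints at or below −0.3 with at
   least one in an endothelial-cell-containing system (3C, 4H, LPS, Mphg).
   Concentrations flagged acute are not evaluated for any other signature
   (those signatures are *not assessable* there).
2. **liver_toxicity** — 3C:SRB at or below −0.3; flagged profiles continue
   through the remaining rules.
3. **organ_toxicity** — 3C:Proliferation significantly decreased
   (outside envelope, < −0.1) without 3C cytotoxicity (3C:SRB > −0.3).
4. **immunosuppression** — T-cell proliferation loss (SAg:Proliferation
   outside envelope, < −0.1), or combined IgG and B-cell proliferation loss
   (BT:sIgG and BT:Proliferation both outside envelope, < −0.1), or PBMC
   cytotoxicity (SAg or BT PBMC Cytotoxicity < −0.3).
5. **thrombosis** — tissue factor induction (3C:TF outside envelope, > 0.1)
   without 3C cytotoxicity.
6. **skin_irritation** — LPS:PGE2 induction (outside envelope, > 0.1) with
   TNFα increased or unchanged (LPS:sTNFα not significantly decreased).
7. **skin_sensitization** — HDF3CGF:Collagen III loss (outside envelope, < −0.1).
8. **skin_rash** — HDF3CGF:VCAM-1 induction (outside envelope, > 0.1).
9. **vascular_toxicity** — CASM3C:SAA induction (outside envelope, > 0.1).

A chemical-level flag at a concentration requires both blinded duplicate
samples flagged there.  The chemical summary lists the minimum flagged
concentration when the signature was detected at two or more concentrations
(rendered ``>=conc``) or at the top tested concentration (rendered without a
symbol); otherwise "nd" (not detected) or "NA" (not assessable at any
concentration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .io import ProfileMatrix
from .normalize import HistoricalEnvelope, outside_envelope
from .vocab import Vocabulary

#: The nine signatures in stepwise evaluation order.
SIGNATURES: tuple[str, ...] = (
    "acute_toxicity",
    "liver_toxicity",
    "organ_toxicity",
    "immunosuppression",
    "thrombosis",
    "skin_irritation",
    "skin_sensitization",
    "skin_rash",
    "vascular_toxicity",
)

#: Named endpoints the rules read (plus every SRB endpoint for rule 1).
REQUIRED_ENDPOINTS: tuple[str, ...] = (
    "3C:SRB", "3C:Proliferation", "3C:TF",
    "SAg:Proliferation", "SAg:PBMC Cytotoxicity",
    "BT:sIgG", "BT:Proliferation", "BT:PBMC Cytotoxicity",
    "LPS:PGE2", "LPS:sTNFα",
    "HDF3CGF:Collagen III", "HDF3CGF:VCAM-1",
    "CASM3C:SAA",
)


@dataclass(frozen=True)
class SignatureCall:
    """One signature's outcome at one sample-concentration."""

    sample_id: str
    concentration: float
    signature: str
    flagged: bool
    evaluable: bool


def _value(row: pd.Series, endpoint_id: str, signature: str) -> float:
    if endpoint_id not in row.index:
        raise KeyError(
            f"endpoint {endpoint_id!r} required by signature {signature!r} "
            f"is missing from the profile"
        )
    return float(row[endpoint_id])


def evaluate_signatures(row: pd.Series, envelope: HistoricalEnvelope,
                        vocabulary: Vocabulary,
                        config: PipelineConfig | None = None
                        ) -> dict[str, tuple[bool, bool]]:
    """Evaluate all nine signatures on one un-inverted profile row.

    Returns ``{signature: (flagged, evaluable)}``.  When acute toxicity is
    flagged, every other signature is returned unflagged with
    ``evaluable=False``.
    """
    config = config or PipelineConfig()
    cyto_thr = config.cytotox_log10ratio          # −0.3
    eff = config.effect_size                      # 0.1

    def cyto_low(v: float) -> bool:
        # the −0.3 rule inside signatures: "≤" by default, "<" when strict
        return v < cyto_thr if config.signature_cytotox_strict else v <= cyto_thr

    def sig_out(endpoint: str, v: float) -> bool:
        return outside_envelope(v, endpoint, envelope)

    def get(endpoint: str, sig: str) -> float:
        return _value(row, endpoint, sig)

    # Rule 1 — acute toxicity over all SRB endpoints
    srb_vals = {e: get(e, "acute_toxicity") for e in vocabulary.srb_endpoints}
    low_srb = [e for e, v in srb_vals.items() if cyto_low(v)]
    acute = (len(low_srb) >= 3
             and any(vocabulary[e].is_endothelial_system for e in low_srb))

    out: dict[str, tuple[bool, bool]] = {"acute_toxicity": (acute, True)}
    if acute:
        for sig in SIGNATURES[1:]:
            out[sig] = (False, False)
        return out

    srb_3c = get("3C:SRB", "liver_toxicity")
    not_cytotoxic_3c = srb_3c > cyto_thr

    # Rule 2 — liver toxicity (flags and continues)
    out["liver_toxicity"] = (cyto_low(srb_3c), True)

    # Rule 3 — organ toxicity
    prolif_3c = get("3C:Proliferation", "organ_toxicity")
    out["organ_toxicity"] = (
        sig_out("3C:Proliferation", prolif_3c) and prolif_3c < -eff
        and not_cytotoxic_3c,
        True,
    )

    # Rule 4 — immunosuppression (three OR arms)
    sag_prolif = get("SAg:Proliferation", "immunosuppression")
    igg = get("BT:sIgG", "immunosuppression")
    bt_prolif = get("BT:Proliferation", "immunosuppression")
    sag_pbmc = get("SAg:PBMC Cytotoxicity", "immunosuppression")
    bt_pbmc = get("BT:PBMC Cytotoxicity", "immunosuppression")
    arm_t = sig_out("SAg:Proliferation", sag_prolif) and sag_prolif < -eff
    arm_b = (sig_out("BT:sIgG", igg) and igg < -eff
             and sig_out("BT:Proliferation", bt_prolif) and bt_prolif < -eff)
    arm_pbmc = sag_pbmc < cyto_thr or bt_pbmc < cyto_thr
    out["immunosuppression"] = (arm_t or arm_b or arm_pbmc, True)

    # Rule 5 — thrombosis
    tf = get("3C:TF", "thrombosis")
    out["thrombosis"] = (
        sig_out("3C:TF", tf) and tf > eff and not_cytotoxic_3c, True,
    )

    # Rule 6 — skin irritation (TNFα increased or unchanged)
    pge2 = get("LPS:PGE2", "skin_irritation")
    tnfa = get("LPS:sTNFα", "skin_irritation")
    tnfa_decreased = sig_out("LPS:sTNFα", tnfa) and tnfa < 0
    out["skin_irritation"] = (
        sig_out("LPS:PGE2", pge2) and pge2 > eff and not tnfa_decreased, True,
    )

    # Rule 7 — skin sensitization
    col3 = get("HDF3CGF:Collagen III", "skin_sensitization")
    out["skin_sensitization"] = (
        sig_out("HDF3CGF:Collagen III", col3) and col3 < -eff, True,
    )

    # Rule 8 — skin rash
    vcam = get("HDF3CGF:VCAM-1", "skin_rash")
    out["skin_rash"] = (sig_out("HDF3CGF:VCAM-1", vcam) and vcam > eff, True)

    # Rule 9 — vascular toxicity
    saa = get("CASM3C:SAA", "vascular_toxicity")
    out["vascular_toxicity"] = (sig_out("CASM3C:SAA", saa) and saa > eff, True)

    return out


def evaluate_all(profiles: ProfileMatrix, envelope: HistoricalEnvelope,
                 vocabulary: Vocabulary,
                 config: PipelineConfig | None = None) -> pd.DataFrame:
    """Per-concentration signature calls for every profile row.

    Returns a long table with columns
    ``sample_id, concentration, signature, flagged, evaluable``.
    """
    records = []
    for (sample, conc), row in profiles.values.iterrows():
        calls = evaluate_signatures(row, envelope, vocabulary, config)
        for sig, (flagged, evaluable) in calls.items():
            records.append((sample, float(conc), sig, flagged, evaluable))
    return pd.DataFrame(
        records,
        columns=["sample_id", "concentration", "signature", "flagged", "evaluable"],
    )


# --------------------------------------------------------------------------
# Chemical-level summarization


@dataclass(frozen=True)
class SignatureSummary:
    chemical_id: str
    signature: str
    status: str            # "nd" | "NA" | "listed_at_top" | "listed_ge"
    min_conc: float | None = None


def summarize_signature(flagged_concs: set[float], evaluable_concs: set[float],
                        tested_concs) -> tuple[str, float | None]:
    """Apply the listing convention to one chemical × signature.

    ``flagged_concs`` are the concentrations flagged in *both* duplicate
    samples; ``evaluable_concs`` those assessable in both.  Detected at two
    or more concentrations → ``listed_ge`` at the minimum; detected at the
    top tested concentration only → ``listed_at_top``; no assessable
    concentration → ``NA``; otherwise ``nd`` (a single non-top detection
    summarizes to nd).
    """
    tested = sorted(float(c) for c in tested_concs)
    if not tested:
        raise ValueError("no tested concentrations")
    top = tested[-1]
    if len(flagged_concs) >= 2:
        return "listed_ge", min(flagged_concs)
    if top in flagged_concs:
        return "listed_at_top", top
    if not evaluable_concs:
        return "NA", None
    return "nd", None


def summarize_all(calls: pd.DataFrame, replicate_of: dict[str, str]
                  ) -> pd.DataFrame:
    """Chemical-level signature summaries from per-concentration calls.

    A concentration counts as flagged (or evaluable) for a chemical only when
    every blinded sample of that chemical is flagged (evaluable) there.
    """
    df = calls.copy()
    df["chemical_id"] = df["sample_id"].map(lambda s: replicate_of.get(s, s))
    rows = []
    for (chem, sig), sub in df.groupby(["chemical_id", "signature"], sort=False):
        by_conc = sub.groupby("concentration")
        flagged = set(by_conc["flagged"].all().loc[lambda s: s].index)
        evaluable = set(by_conc["evaluable"].all().loc[lambda s: s].index)
        tested = sub["concentration"].unique()
        status, min_conc = summarize_signature(flagged, evaluable, tested)
        rows.append({"chemical_id": chem, "signature": sig,
                     "status": status, "min_conc": min_conc})
    out = pd.DataFrame(rows, columns=["chemical_id", "signature", "status", "min_conc"])
    order = {s: i for i, s in enumerate(SIGNATURES)}
    return out.sort_values(
        ["chemical_id", "signature"], key=lambda s: s.map(order) if s.name == "signature" else s
    ).reset_index(drop=True)


def _render_cell(status: str, min_conc: float | None) -> str:
    if status == "listed_ge":
        return f">={min_conc:g}"
    if status == "listed_at_top":
        return f"{min_conc:g}"
    return status  # "nd" or "NA"


def _parse_cell(cell: str) -> tuple[str, float | None]:
    if cell in ("nd", "NA"):
        return cell, None
    if cell.startswith(">="):
        return "listed_ge", float(cell[2:])
    return "listed_at_top", float(cell)


def signature_table(summaries: pd.DataFrame) -> pd.DataFrame:
    """Render summaries as one row per chemical, one rendered cell per signature."""
    if summaries.empty:
        return pd.DataFrame(columns=list(SIGNATURES)).rename_axis("chemical_id")
    cells = summaries.assign(
        cell=[_render_cell(s, c) for s, c in
              zip(summaries["status"], summaries["min_conc"])]
    )
    wide = cells.pivot(index="chemical_id", columns="signature", values="cell")
    return wide.reindex(columns=list(SIGNATURES))


def parse_signature_table(table: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`signature_table` (round-trips statuses and concentrations)."""
    rows = []
    for chem, row in table.iterrows():
        for sig in table.columns:
            status, conc = _parse_cell(str(row[sig]))
            rows.append({"chemical_id": chem, "signature": sig,
                         "status": status, "min_conc": conc})
    return pd.DataFrame(rows, columns=["chemical_id", "signature", "status", "min_conc"])
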