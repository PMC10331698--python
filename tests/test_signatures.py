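"""The nine-rule signature engine versus a direct-transcription oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps
from phenoscreen.signatures import SIGNATURES

# ---------------------------------------------------------------------------
# Independent oracle: a literal transcription of the nine rules, written
# without reference to the engine's implementation.

ENV_LO, ENV_HI = -0.05, 0.05
ENDOTHELIAL_SRB = ("3C:SRB", "4H:SRB", "LPS:SRB", "Mphg:SRB")


def oracle(vals: dict, srb_ids) -> dict:
    def v(e):
        return vals.get(e, 0.0)

    def outside(e):
        return v(e) < ENV_LO or v(e) > ENV_HI

    low_srb = [e for e in srb_ids if v(e) <= -0.3]
    acute = len(low_srb) >= 3 and any(e in ENDOTHELIAL_SRB for e in low_srb)
    out = {"acute_toxicity": (acute, True)}
    if acute:
        for sig in SIGNATURES[1:]:
            out[sig] = (False, False)
        return out

    out["liver_toxicity"] = (v("3C:SRB") <= -0.3, True)
    out["organ_toxicity"] = (
        outside("3C:Proliferation") and v("3C:Proliferation") < -0.1
        and v("3C:SRB") > -0.3, True)
    out["immunosuppression"] = (
        (outside("SAg:Proliferation") and v("SAg:Proliferation") < -0.1)
        or (outside("BT:sIgG") and v("BT:sIgG") < -0.1
            and outside("BT:Proliferation") and v("BT:Proliferation") < -0.1)
        or v("SAg:PBMC Cytotoxicity") < -0.3
        or v("BT:PBMC Cytotoxicity") < -0.3, True)
    out["thrombosis"] = (
        outside("3C:TF") and v("3C:TF") > 0.1 and v("3C:SRB") > -0.3, True)
    out["skin_irritation"] = (
        outside("LPS:PGE2") and v("LPS:PGE2") > 0.1
        and not (outside("LPS:sTNFα") and v("LPS:sTNFα") < 0), True)
    out["skin_sensitization"] = (
        outside("HDF3CGF:Collagen III") and v("HDF3CGF:Collagen III") < -0.1,
        True)
    out["skin_rash"] = (
        outside("HDF3CGF:VCAM-1") and v("HDF3CGF:VCAM-1") > 0.1, True)
    out["vascular_toxicity"] = (
        outside("CASM3C:SAA") and v("CASM3C:SAA") > 0.1, True)
    return out


@pytest.fixture(scope="module")
def envelope(vocab):
    bounds = pd.DataFrame({"lower": ENV_LO, "upper": ENV_HI},
                          index=pd.Index(vocab.endpoint_ids,
                                         name="endpoint_id"))
    return ps.HistoricalEnvelope(bounds)


def make_row(vocab, vals: dict) -> pd.Series:
    row = pd.Series(0.0, index=vocab.endpoint_ids)
    for k, v in vals.items():
        row[k] = v
    return row


# value classes: cytotoxic, moderate decrease, significant-but-small,
# boundary, null, and increase counterparts
CLASSES = [-0.4, -0.3, -0.2, -0.1, -0.08, 0.0, 0.08, 0.1, 0.2]
SMALL = [-0.4, -0.2, -0.08, 0.0, 0.08, 0.2]

GRIDS = {
    "acute_toxicity": (
        ["3C:SRB", "4H:SRB", "BE3C:SRB", "KF3CT:SRB", "MyoF:SRB"],
        [[-0.4, -0.3, 0.0]] * 5),
    "liver_toxicity": (["3C:SRB"], [CLASSES]),
    "organ_toxicity": (["3C:Proliferation", "3C:SRB"], [CLASSES, SMALL]),
    "immunosuppression": (
        ["SAg:Proliferation", "BT:sIgG", "BT:Proliferation",
         "SAg:PBMC Cytotoxicity", "BT:PBMC Cytotoxicity"],
        [SMALL[:4], SMALL[:4], SMALL[:4], [-0.4, -0.3, 0.0], [-0.4, 0.0]]),
    "thrombosis": (["3C:TF", "3C:SRB"], [CLASSES, [-0.4, -0.3, 0.0]]),
    "skin_irritation": (
        ["LPS:PGE2", "LPS:sTNFα"], [CLASSES, [-0.2, -0.08, -0.02, 0.0, 0.2]]),
    "skin_sensitization": (["HDF3CGF:Collagen III"], [CLASSES]),
    "skin_rash": (["HDF3CGF:VCAM-1"], [CLASSES]),
    "vascular_toxicity": (["CASM3C:SAA"], [CLASSES]),
}


class TestTruthTables:
    @pytest.mark.parametrize("signature", SIGNATURES)
    def test_exhaustive_grid_matches_oracle(self, signature, vocab, envelope):
        endpoints, classes = GRIDS[signature]
        mismatches = 0
        for combo in itertools.product(*classes):
            vals = dict(zip(endpoints, combo))
            row = make_row(vocab, vals)
            got = ps.evaluate_signatures(row, envelope, vocab)
            want = oracle(vals, vocab.srb_endpoints)
            if got != want:
                mismatches += 1
        assert mismatches == 0


class TestRuleExamples:
    def test_acute_masks_all_others(self, vocab, envelope):
        row = make_row(vocab, {"3C:SRB": -0.4, "4H:SRB": -0.4,
                               "BE3C:SRB": -0.4})
        calls = ps.evaluate_signatures(row, envelope, vocab)
        assert calls["acute_toxicity"] == (True, True)
        for sig in SIGNATURES[1:]:
            assert calls[sig] == (False, False)

    def test_three_srb_without_endothelial_not_acute(self, vocab, envelope):
        row = make_row(vocab, {"BE3C:SRB": -0.4, "KF3CT:SRB": -0.4,
                               "MyoF:SRB": -0.4})
        calls = ps.evaluate_signatures(row, envelope, vocab)
        assert calls["acute_toxicity"] == (False, True)

    def test_liver_flags_and_continues_organ_guard(self, vocab, envelope):
        row = make_row(vocab, {"3C:SRB": -0.35})
        calls = ps.evaluate_signatures(row, envelope, vocab)
        assert calls["acute_toxicity"][0] is False   # only one SRB endpoint
        assert calls["liver_toxicity"] == (True, True)
        # 3C cytotoxicity voids the organ-toxicity guard (3C:SRB > -0.3 fails)
        assert calls["organ_toxicity"] == (False, True)

    def test_saa_increase_flags_only_vascular(self, vocab, envelope):
        row = make_row(vocab, {"CASM3C:SAA": 0.2})
        calls = ps.evaluate_signatures(row, envelope, vocab)
        flagged = {s for s, (f, _) in calls.items() if f}
        assert flagged == {"vascular_toxicity"}

    def test_missing_endpoint_error_names_endpoint_and_signature(
            self, vocab, envelope):
        row = make_row(vocab, {}).drop("CASM3C:SAA")
        with pytest.raises(KeyError, match="CASM3C:SAA.*vascular_toxicity"):
            ps.evaluate_signatures(row, envelope, vocab)

    def test_strictness_switch_moves_boundary(self, vocab, envelope):
        row = make_row(vocab, {"3C:SRB": -0.3})
        default = ps.evaluate_signatures(row, envelope, vocab)
        strict = ps.evaluate_signatures(
            row, envelope, vocab,
            ps.PipelineConfig(signature_cytotox_strict=True))
        assert default["liver_toxicity"][0] is True    # "<=" reading
        assert strict["liver_toxicity"][0] is False    # "<" reading


class TestSummarization:
    CONCS = (2.2, 6.7, 20.0, 60.0)

    @pytest.mark.parametrize("flagged,expected", [
        ({20.0, 60.0}, ("listed_ge", 20.0)),
        ({60.0}, ("listed_at_top", 60.0)),
        ({6.7, 20.0, 60.0}, ("listed_ge", 6.7)),
        (set(), ("nd", None)),
        ({6.7}, ("nd", None)),  # single non-top detection is not listed
    ])
    def test_listing_convention(self, flagged, expected):
        status, conc = ps.summarize_signature(flagged, set(self.CONCS),
                                              self.CONCS)
        assert (status, conc) == expected

    def test_all_masked_is_na(self):
        assert ps.summarize_signature(set(), set(), self.CONCS) == ("NA", None)

    def test_chemical_flag_requires_both_replicates(self):
        calls = pd.DataFrame([
            {"sample_id": s, "concentration": c, "signature": "vascular_toxicity",
             "flagged": flag, "evaluable": True}
            for c in self.CONCS
            for s, flag in (("C1-r1", True), ("C1-r2", c >= 20.0))
        ])
        out = ps.summarize_all(calls, {"C1-r1": "C1", "C1-r2": "C1"})
        row = out.set_index("signature").loc["vascular_toxicity"]
        assert row["status"] == "listed_ge" and row["min_conc"] == 20.0

    def test_acute_masking_monotone(self, vocab, envelope):
        """Flagging acute at one more concentration never adds listings."""
        def calls_for(acute_concs):
            rows = []
            for c in self.CONCS:
                vals = {"CASM3C:SAA": 0.3}
                if c in acute_concs:
                    vals.update({"3C:SRB": -0.5, "4H:SRB": -0.5,
                                 "LPS:SRB": -0.5})
                for s in ("C1-r1", "C1-r2"):
                    got = ps.evaluate_signatures(
                        make_row(vocab, vals), envelope, vocab)
                    for sig, (f, ev) in got.items():
                        rows.append({"sample_id": s, "concentration": c,
                                     "signature": sig, "flagged": f,
                                     "evaluable": ev})
            return ps.summarize_all(pd.DataFrame(rows),
                                    {"C1-r1": "C1", "C1-r2": "C1"})

        base = calls_for({60.0}).set_index("signature")
        more = calls_for({20.0, 60.0}).set_index("signature")
        allm = calls_for(set(self.CONCS)).set_index("signature")
        assert base.loc["vascular_toxicity", "status"] == "listed_ge"
        assert more.loc["vascular_toxicity", "status"] == "listed_ge"
        assert more.loc["vascular_toxicity", "min_conc"] >= \
            base.loc["vascular_toxicity", "min_conc"]
        # fully masked -> every non-acute signature NA
        for sig in SIGNATURES[1:]:
            assert allm.loc[sig, "status"] == "NA"
        assert allm.loc["acute_toxicity", "status"] == "listed_ge"


class TestSignatureTable:
    def test_empty_set_header_only(self):
        table = ps.signature_table(pd.DataFrame(
            columns=["chemical_id", "signature", "status", "min_conc"]))
        assert list(table.columns) == list(SIGNATURES)
        assert len(table) == 0

    def test_rendering_and_round_trip(self):
        summaries = pd.DataFrame([
            {"chemical_id": "C1", "signature": s, "status": "nd",
             "min_conc": None} for s in SIGNATURES])
        summaries.loc[summaries.signature == "vascular_toxicity",
                      ["status", "min_conc"]] = ["listed_ge", 1.5]
        summaries.loc[summaries.signature == "liver_toxicity",
                      ["status", "min_conc"]] = ["listed_at_top", 60.0]
        summaries.loc[summaries.signature == "skin_rash", "status"] = "NA"
        table = ps.signature_table(summaries)
        assert table.loc["C1", "vascular_toxicity"] == ">=1.5"
        assert table.loc["C1", "liver_toxicity"] == "60"
        assert table.loc["C1", "skin_rash"] == "NA"
        back = ps.parse_signature_table(table)
        merged = back.merge(summaries, on=["chemical_id", "signature"],
                            suffixes=("_back", ""))
        assert (merged["status_back"] == merged["status"]).all()
        for a, b in zip(merged["min_conc_back"], merged["min_conc"]):
            assert (pd.isna(a) and pd.isna(b)) or a == b

    def test_noiseless_summaries_match_planted(self, noiseless_screen):
        _, _, truth, result = noiseless_screen
        got = result.signature_summaries.set_index(["chemical_id", "signature"])
        for (chem, sig), (status, conc) in truth.signature_summary.items():
            row = got.loc[(chem, sig)]
            assert row["status"] == status
            if conc is None:
                assert pd.isna(row["min_conc"])
            else:
                assert row["min_conc"] == conc
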