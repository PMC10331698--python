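"""Log10Ratio normalization, direction correction and the significance envelope."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phenoscreen as ps
from phenoscreen.io import WELL_COLUMNS


def wells_from_raws(endpoint, vehicle_raws, treatment_raws, concs=None):
    rows = []
    for w, v in enumerate(vehicle_raws):
        rows.append(["P1", f"V{w}", "VEHICLE", "DMSO", 0.0, endpoint, v,
                     "vehicle_control"])
    concs = concs or [10.0] * len(treatment_raws)
    for i, (r, c) in enumerate(zip(treatment_raws, concs)):
        rows.append(["P1", f"T{i}", f"S{i}", f"C{i}", c, endpoint, r,
                     "treatment"])
    return pd.DataFrame(rows, columns=WELL_COLUMNS)


class TestLog10Ratios:
    def test_identity_and_doubling(self, vocab):
        wells = wells_from_raws("3C:TF", [100.0] * 8, [100.0, 200.0])
        pm = ps.compute_log10_ratios(wells, vocab)
        vals = pm.values["3C:TF"].to_numpy()
        assert vals[0] == pytest.approx(0.0, abs=1e-12)
        assert vals[1] == pytest.approx(math.log10(2.0), abs=1e-9)

    def test_hand_computed_vehicle_mean(self, vocab):
        vehicle = [80, 90, 95, 100, 100, 105, 110, 120]  # mean 100
        wells = wells_from_raws("3C:TF", vehicle, [50.0])
        pm = ps.compute_log10_ratios(wells, vocab)
        assert pm.values["3C:TF"].iloc[0] == pytest.approx(-0.30103, abs=1e-5)

    def test_vehicle_wells_excluded_from_rows(self, vocab):
        wells = wells_from_raws("3C:TF", [100.0] * 8, [100.0])
        pm = ps.compute_log10_ratios(wells, vocab)
        assert "VEHICLE" not in pm.values.index.get_level_values("sample_id")

    def test_missing_vehicle_wells_error_names_plate(self, vocab):
        wells = wells_from_raws("3C:TF", [100.0] * 7, [100.0])
        with pytest.raises(ps.ValidationError, match="P1"):
            ps.compute_log10_ratios(wells, vocab)

    def test_all_equal_to_vehicle_mean_gives_zero_matrix(self, vocab):
        wells = wells_from_raws("3C:TF", [100.0] * 8, [100.0] * 5)
        pm = ps.compute_log10_ratios(wells, vocab)
        assert np.allclose(pm.values.to_numpy(), 0.0)

    @settings(deadline=None, max_examples=25)
    @given(vehicle=st.lists(st.floats(1.0, 1e4), min_size=8, max_size=8),
           treats=st.lists(st.floats(1.0, 1e4), min_size=1, max_size=6))
    def test_matches_bruteforce_recomputation(self, vocab, vehicle, treats):
        wells = wells_from_raws("3C:TF", vehicle, treats)
        pm = ps.compute_log10_ratios(wells, vocab)
        vmean = sum(vehicle) / 8.0
        for i, r in enumerate(treats):
            got = float(pm.values.loc[(f"S{i}", 10.0), "3C:TF"])
            assert got == pytest.approx(math.log10(r / vmean), rel=1e-12)


class TestInversion:
    def test_down_endpoint_negated_others_unchanged(self, vocab):
        idx = pd.MultiIndex.from_tuples([("S1", 10.0)])
        pm = ps.ProfileMatrix(pd.DataFrame(
            [[0.2, -0.3]], index=idx, columns=["3C:SRB", "3C:TF"]))
        out = ps.invert_down_endpoints(pm, vocab)
        assert out.values.loc[("S1", 10.0), "3C:SRB"] == -0.2  # down readout
        assert out.values.loc[("S1", 10.0), "3C:TF"] == -0.3   # unchanged

    def test_mixed_row_matches_bruteforce_loop(self, vocab):
        rng = np.random.default_rng(5)
        cols = vocab.endpoint_ids
        idx = pd.MultiIndex.from_tuples([("S1", 10.0), ("S2", 20.0)])
        pm = ps.ProfileMatrix(pd.DataFrame(
            rng.normal(0, 0.3, (2, len(cols))), index=idx, columns=cols))
        out = ps.invert_down_endpoints(pm, vocab)
        for col in cols:
            sign = -1.0 if vocab[col].is_down_readout else 1.0
            assert np.allclose(out.values[col], sign * pm.values[col])

    def test_involution(self, vocab):
        rng = np.random.default_rng(6)
        idx = pd.MultiIndex.from_tuples([("S1", 10.0)])
        pm = ps.ProfileMatrix(pd.DataFrame(
            rng.normal(size=(1, len(vocab))), index=idx,
            columns=vocab.endpoint_ids))
        twice = ps.invert_down_endpoints(
            ps.invert_down_endpoints(pm, vocab), vocab)
        pd.testing.assert_frame_equal(twice.values, pm.values)


def historical(endpoint, values):
    return pd.DataFrame({"endpoint_id": endpoint, "log10_ratio": values})


class TestEnvelope:
    def test_degenerate_all_zero(self):
        env = ps.build_envelope(historical("3C:TF", [0.0] * 10))
        assert env.lower("3C:TF") == 0.0 == env.upper("3C:TF")

    def test_evenly_spaced_quantiles(self):
        vals = np.linspace(-0.1, 0.1, 1000)
        env = ps.build_envelope(historical("3C:TF", vals), coverage=0.95)
        assert env.lower("3C:TF") == pytest.approx(-0.095, abs=0.001)
        assert env.upper("3C:TF") == pytest.approx(0.095, abs=0.001)

    def test_normal_monte_carlo(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 0.05, 10_000)
        env = ps.build_envelope(historical("3C:TF", vals), coverage=0.95)
        # 2.5/97.5 percentiles of Normal(0, 0.05) are ±0.098
        assert env.lower("3C:TF") == pytest.approx(-0.098, abs=0.004)
        assert env.upper("3C:TF") == pytest.approx(0.098, abs=0.004)

    def test_monotone_in_coverage(self):
        rng = np.random.default_rng(8)
        hist = pd.concat([
            historical("3C:TF", rng.normal(0, 0.05, 500)),
            historical("3C:SRB", rng.normal(0, 0.02, 500)),
        ])
        e95 = ps.build_envelope(hist, 0.95)
        e99 = ps.build_envelope(hist, 0.99)
        assert (e99.bounds["lower"] <= e95.bounds["lower"]).all()
        assert (e99.bounds["upper"] >= e95.bounds["upper"]).all()

    def test_normal_theory_method(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 0.05, 10_000)
        env = ps.build_envelope(historical("3C:TF", vals), 0.95, "normal")
        assert env.upper("3C:TF") == pytest.approx(1.96 * 0.05, rel=0.05)

    def test_too_few_values_error(self):
        with pytest.raises(ps.ValidationError, match="historical"):
            ps.build_envelope(historical("3C:TF", [0.0]))

    def test_round_trip_tsv(self, tmp_path):
        env = ps.build_envelope(historical("3C:TF", np.linspace(-1, 1, 100)))
        env.to_tsv(tmp_path / "env.tsv")
        back = ps.HistoricalEnvelope.from_tsv(tmp_path / "env.tsv")
        pd.testing.assert_frame_equal(back.bounds, env.bounds)


class TestOutsideEnvelope:
    @pytest.fixture()
    def env(self):
        bounds = pd.DataFrame({"lower": [-0.1], "upper": [0.1]},
                              index=pd.Index(["3C:TF"], name="endpoint_id"))
        return ps.HistoricalEnvelope(bounds)

    @pytest.mark.parametrize("value,expected", [
        (0.0, False),
        (-0.12, True),
        (0.12, True),
        (-0.1, False),   # boundary is inside (strict comparison)
        (0.1, False),
    ])
    def test_strict_boundary_convention(self, env, value, expected):
        assert ps.outside_envelope(value, "3C:TF", env) is expected

    def test_unknown_endpoint_error(self, env):
        with pytest.raises(KeyError, match="BT:sIgG"):
            ps.outside_envelope(0.0, "BT:sIgG", env)

    def test_frame_version_matches_scalar(self, env):
        vals = pd.DataFrame(
            [[-0.2], [0.05], [0.1]],
            index=pd.MultiIndex.from_tuples(
                [("S1", 1.0), ("S1", 2.0), ("S1", 3.0)]),
            columns=["3C:TF"])
        out = ps.outside_envelope_frame(vals, env)
        expected = [ps.outside_envelope(v, "3C:TF", env)
                    for v in vals["3C:TF"]]
        assert out["3C:TF"].tolist() == expected
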