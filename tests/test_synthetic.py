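"""Synthetic-screen generator: determinism, planted effects, noise calibration."""

import math

import numpy as np
import pandas as pd
import pytest

import phenoscreen as ps


class TestArchetypes:
    def test_effects_zero_below_onset(self, vocab):
        arch = ps.make_archetype("cyclosporine_like", vocab, onset=2)
        for series in arch.effects.values():
            assert series[0] == series[1] == 0.0
            assert series[2] != 0.0 and series[3] == series[2]

    def test_signs_follow_readout_direction(self, vocab):
        arch = ps.make_archetype("glucocorticoid_like", vocab)
        assert arch.effects["Mphg:sIL-10"][-1] < 0       # suppressed cytokine
        assert arch.effects["CASM3C:SAA"][-1] > 0        # induced acute-phase

    def test_cytotoxic_archetype_counts(self, vocab):
        arch = ps.make_archetype("nonspecific_cytotoxic", vocab,
                                 n_cytotox_endpoints=5)
        assert arch.n_cytotox_endpoints == 5
        assert all(vocab[e].is_cytotox_role for e in arch.effects)

    def test_too_many_cytotox_endpoints_error(self, vocab):
        with pytest.raises(ValueError, match="cytotox"):
            ps.make_archetype("nonspecific_cytotoxic", vocab,
                              n_cytotox_endpoints=99)

    def test_unknown_requirements_error(self, vocab):
        with pytest.raises(ValueError, match="unknown archetype"):
            ps.make_archetype("not_a_thing", vocab)
        with pytest.raises(ValueError, match="unknown signature"):
            ps.make_archetype("single_signature", vocab, sig_name="nope")


class TestGenerateScreen:
    def test_same_seed_identical_tables(self):
        w1, _ = ps.generate_screen(n_chemicals=6, noise_sd=0.05, seed=9)
        w2, _ = ps.generate_screen(n_chemicals=6, noise_sd=0.05, seed=9)
        pd.testing.assert_frame_equal(w1, w2)
        w3, _ = ps.generate_screen(n_chemicals=6, noise_sd=0.05, seed=10)
        assert not w1["raw_value"].equals(w3["raw_value"])

    def test_design_shape(self, vocab):
        wells, truth = ps.generate_screen(n_chemicals=6, noise_sd=0.0, seed=0)
        ps.validate_well_table(wells, vocab)
        trt = wells[wells.well_role == "treatment"]
        # 2 blinded samples x 4 concentrations x 148 endpoints per chemical
        per_chem = trt.groupby("chemical_id").size()
        assert (per_chem == 2 * 4 * 148).all()
        assert sorted(trt["concentration_uM"].unique()) == [2.2, 6.7, 20.0, 60.0]

    def test_noiseless_inactive_profiles_are_exactly_zero(self, vocab):
        wells, _ = ps.generate_screen(
            n_chemicals=3, archetype_mix={"inactive": 1.0}, noise_sd=0.0,
            seed=0)
        pm = ps.compute_log10_ratios(wells, vocab)
        assert np.allclose(pm.values.to_numpy(), 0.0)

    def test_noiseless_cytotoxic_counts_recovered_end_to_end(self, vocab):
        cfg = ps.PipelineConfig()
        wells, truth = ps.generate_screen(
            cfg, n_chemicals=1,
            archetype_mix={"nonspecific_cytotoxic": 1.0},
            noise_sd=0.0, seed=0, n_cytotox_endpoints=3)
        pm = ps.compute_log10_ratios(wells, vocab)
        inv = ps.invert_down_endpoints(pm, vocab)
        hits = ps.hitcall_table(inv, cfg)
        chem = next(iter(truth.samples))
        sample = truth.samples[chem][0]
        assert ps.count_active_cytotox(hits, vocab, sample, 60.0) == 3
        assert ps.count_active_cytotox(hits, vocab, sample, 6.7) == 0

    def test_planted_truth_active_set_respects_cutoff_floor(self):
        _, truth = ps.generate_screen(n_chemicals=30, noise_sd=0.0, seed=1)
        floor = math.log10(1.2)
        for chem, loecs in truth.active_endpoints.items():
            arch = truth.archetype[chem]
            if arch == "inactive":
                assert loecs == {}
            else:
                assert loecs  # every non-inactive archetype plants hits
                assert all(l in (2.2, 6.7, 20.0, 60.0) for l in loecs.values())


class TestHistoricalControls:
    def test_noiseless_envelope_collapses_to_zero(self, vocab):
        hist = ps.generate_historical_controls(vocab, noise_sd=0.0, seed=0)
        env = ps.build_envelope(hist)
        assert (env.bounds["lower"] == 0.0).all()
        assert (env.bounds["upper"] == 0.0).all()

    def test_envelope_matches_normal_percentiles(self, vocab):
        hist = ps.generate_historical_controls(
            vocab, n_runs=1250, wells_per_run=8, noise_sd=0.05, seed=1)
        env = ps.build_envelope(hist)
        # 10,000 draws per endpoint; 95% envelope of Normal(0, 0.05) ~ ±0.098
        assert env.bounds["lower"].mean() == pytest.approx(-0.098, abs=0.003)
        assert env.bounds["upper"].mean() == pytest.approx(0.098, abs=0.003)

    def test_seed_reproducibility(self, vocab):
        h1 = ps.generate_historical_controls(vocab, noise_sd=0.05, seed=2)
        h2 = ps.generate_historical_controls(vocab, noise_sd=0.05, seed=2)
        pd.testing.assert_frame_equal(h1, h2)

    def test_default_run_count(self, vocab):
        hist = ps.generate_historical_controls(vocab, noise_sd=0.05, seed=3)
        assert hist["run"].nunique() == 23


class TestReferenceDB:
    def test_noiseless_profiles_equal_archetype_means(self, vocab):
        arch = {"cyc": ps.make_archetype("cyclosporine_like", vocab)}
        db = ps.generate_reference_db(arch, n_per_archetype=2, noise_sd=0.0,
                                      seed=0)
        mean = [arch["cyc"].effect_at(e, -1) for e in vocab.endpoint_ids]
        assert np.allclose(db.values.to_numpy(), np.tile(mean, (2, 1)))

    def test_same_archetype_profiles_correlate(self, vocab):
        arch = {"cyc": ps.make_archetype("cyclosporine_like", vocab)}
        db = ps.generate_reference_db(arch, n_per_archetype=2, noise_sd=0.03,
                                      seed=1)
        r = ps.pearson_profile(db.values.iloc[0], db.values.iloc[1])
        assert r > 0.7

    def test_orthogonal_archetypes_weakly_correlated(self, vocab):
        arch = {
            "thromb": ps.make_archetype("single_signature", vocab,
                                        sig_name="thrombosis"),
            "rash": ps.make_archetype("single_signature", vocab,
                                      sig_name="skin_rash"),
        }
        db = ps.generate_reference_db(arch, n_per_archetype=1, noise_sd=0.05,
                                      seed=2)
        r = ps.pearson_profile(db.values.iloc[0], db.values.iloc[1])
        assert abs(r) < 0.3

    def test_cytotox_metadata_planted(self, vocab):
        arch = {"cyto": ps.make_archetype("nonspecific_cytotoxic", vocab,
                                          n_cytotox_endpoints=4, onset=0)}
        db = ps.generate_reference_db(arch, noise_sd=0.0, seed=0)
        assert int(db.n_cytotox.iloc[0]) == 4


class TestStochasticRecovery:
    def test_sensitivity_specificity_and_concordance(self, vocab):
        """Planted effects of 0.3 at noise 0.05 are recovered almost always."""
        cfg = ps.PipelineConfig(seed=7)
        wells, truth = ps.generate_screen(
            cfg, n_chemicals=50, noise_sd=0.05, seed=7, effect_magnitude=0.3)
        pm = ps.compute_log10_ratios(wells, vocab)
        inv = ps.invert_down_endpoints(pm, vocab)
        hits = ps.hitcall_table(inv, cfg)
        sens, spec = ps.score_hitcalls(hits, truth)
        assert sens >= 0.95
        assert spec >= 0.95
        conc = ps.concordance_table(hits)
        assert 93.0 <= conc["concordance_pct"].mean() <= 100.0
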