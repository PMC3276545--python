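"""The synthetic-screen generator: event models, Poisson load, truth recovery."""

import numpy as np
import pandas as pd
import pytest

from reporterscreen.simulate import (EffectModel, SimulationConfig,
                                     simulate_control_population,
                                     simulate_diploid_cross,
                                     simulate_pyro_assay, simulate_screen,
                                     simulate_transgene_mutation,
                                     simulate_treated_population)


class TestConfig:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_weights={"coding": 0.5, "cnv": 0.2,
                                           "cis": 0.2, "trans": 0.2})

    def test_dominance_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(dominance={"coding": 1.0, "cnv": 1.0,
                                        "cis": 1.0, "trans": 1.5})

    def test_negative_load_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mean_load=-0.1)


class TestControlPopulation:
    def test_noise_free_line(self):
        cfg = SimulationConfig(yfp_resid_sd=1e-300, yfp_slope=1.0,
                               yfp_intercept=0.0)
        ev = simulate_control_population(cfg, 100)
        np.testing.assert_allclose(ev["yfp"], ev["fsc"], atol=1e-12)

    def test_fsc_yfp_correlation_exceeds_0_9(self):
        # generating model: corr = slope*sd_fsc / sqrt(slope^2 sd_fsc^2 + resid^2)
        # = 0.1/sqrt(0.01+0.0016) = 0.928 at the defaults
        cfg = SimulationConfig(seed=4)
        ev = simulate_control_population(cfg, 50_000)
        r = np.corrcoef(ev["fsc"], ev["yfp"])[0, 1]
        assert r > 0.9

    def test_seeded_determinism(self):
        cfg = SimulationConfig(seed=9)
        ev1 = simulate_control_population(cfg, 1000)
        ev2 = simulate_control_population(cfg, 1000)
        pd.testing.assert_frame_equal(ev1, ev2)

    def test_different_seeds_differ(self):
        ev1 = simulate_control_population(SimulationConfig(seed=1), 100)
        ev2 = simulate_control_population(SimulationConfig(seed=2), 100)
        assert not ev1["yfp"].equals(ev2["yfp"])

    def test_nonpositive_n(self):
        with pytest.raises(ValueError):
            simulate_control_population(SimulationConfig(), 0)


class TestTreatedPopulation:
    def test_zero_load_identical_in_law_to_control(self):
        cfg = SimulationConfig(seed=5, mean_load=0.0)
        rng1 = np.random.default_rng(5)
        ctl = simulate_control_population(cfg, 5000, rng1)
        trt, truth = simulate_treated_population(cfg, 5000)
        assert truth == []
        # same per-event model: compare moments
        assert trt["yfp"].mean() == pytest.approx(ctl["yfp"].mean(), abs=0.01)
        assert trt["yfp"].std() == pytest.approx(ctl["yfp"].std(), rel=0.05)

    def test_mutant_fraction_matches_poisson_zero_class(self):
        lam = 0.0303
        n = 1_000_000
        cfg = SimulationConfig(seed=6, mean_load=lam)
        _, truth = simulate_treated_population(cfg, n)
        expected = 1 - np.exp(-lam)  # 0.02985
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(len(truth) / n - expected) < 3 * se

    def test_coding_only_always_decreases(self):
        cfg = SimulationConfig(
            seed=8, mean_load=0.5,
            class_weights={"coding": 1.0, "cnv": 0.0, "cis": 0.0, "trans": 0.0})
        _, truth = simulate_treated_population(cfg, 2000)
        assert len(truth) > 0
        assert all(rec.effect < 1.0 for rec in truth)

    def test_invalid_weights_rejected_at_config(self):
        with pytest.raises(ValueError):
            SimulationConfig(class_weights={"coding": 1.0})


class TestDiploidCross:
    def _record(self, label, effect, dominance, copies=1):
        from reporterscreen.simulate import TruthRecord
        return TruthRecord(genotype_id="g", n_mutations=1,
                           class_labels=(label,), effect=effect,
                           dominance=dominance, copies_yfp=copies)

    def _median_shifts(self, rec, cfg, n_rep=40):
        """Mean YFP/CFP offsets over replicate crosses vs reference crosses."""
        rng = np.random.default_rng(77)
        ref = self._record("trans", 1.0, 0.0)
        d_yfp, d_cfp = [], []
        for _ in range(n_rep):
            mut = simulate_diploid_cross(rec, cfg, rng, n=4000)
            ctl = simulate_diploid_cross(ref, cfg, rng, n=4000)
            d_yfp.append(mut["yfp"].median() - ctl["yfp"].median())
            d_cfp.append(mut["cfp"].median() - ctl["cfp"].median())
        return np.mean(d_yfp), np.mean(d_cfp)

    def test_fully_recessive_trans_matches_control_in_law(self, small_config):
        rec = self._record("trans", 2.0, 0.0)
        dy, dc = self._median_shifts(rec, small_config)
        tol = 3 * small_config.diploid_culture_noise_sd * small_config.fsc_mean / np.sqrt(40)
        assert abs(dy) < tol and abs(dc) < tol

    def test_cis_shifts_yfp_only(self, small_config):
        rec = self._record("cis", 2.0, 1.0)
        dy, dc = self._median_shifts(rec, small_config)
        tol = 3 * small_config.diploid_culture_noise_sd * small_config.fsc_mean / np.sqrt(40)
        assert dy == pytest.approx(np.log10(2.0), abs=3 * tol)
        assert abs(dc) < tol

    def test_cnv_raises_yfp_and_lowers_cfp(self, small_config):
        rec = self._record("cnv", 2.0, 1.0, copies=2)
        dy, dc = self._median_shifts(rec, small_config)
        assert dy > 0.2
        assert dc < -0.05
        assert dc == pytest.approx(np.log10(small_config.cnv_cfp_effect),
                                   abs=0.03)

    def test_dominant_trans_shifts_both_channels(self, small_config):
        rec = self._record("trans", 2.0, 1.0)
        dy, dc = self._median_shifts(rec, small_config)
        assert dy == pytest.approx(np.log10(2.0), abs=0.03)
        assert dc == pytest.approx(np.log10(2.0), abs=0.03)


class TestPyroAssay:
    def test_single_copy_fraction_half(self):
        cfg = SimulationConfig(seed=3, pyro_reads=200_000)
        y, c = simulate_pyro_assay(1, cfg)
        assert y + c == 200_000
        assert y / (y + c) == pytest.approx(0.5, abs=0.005)

    def test_duplication_fraction_two_thirds(self):
        cfg = SimulationConfig(seed=3, pyro_reads=200_000)
        y, c = simulate_pyro_assay(2, cfg)
        assert y / (y + c) == pytest.approx(2 / 3, abs=0.005)

    def test_zero_reads_rejected(self):
        cfg = SimulationConfig(pyro_reads=0)
        with pytest.raises(ValueError):
            simulate_pyro_assay(1, cfg)

    def test_invalid_copies(self):
        with pytest.raises(ValueError):
            simulate_pyro_assay(0, SimulationConfig())


class TestTransgeneMutation:
    def test_trans_and_cnv_leave_no_record(self, annotation, rng):
        assert simulate_transgene_mutation("trans", annotation, rng) is None
        assert simulate_transgene_mutation("cnv", annotation, rng) is None

    def test_coding_record_is_protein_changing_transition(self, annotation, rng):
        from reporterscreen.classify import coding_effect, locate_mutation
        for _ in range(20):
            m = simulate_transgene_mutation("coding", annotation, rng)
            assert locate_mutation(m.position, annotation) == "cds"
            assert (m.ref, m.alt) in {("G", "A"), ("C", "T")}
            assert coding_effect(m.position, m.ref, m.alt, annotation) in (
                "nonsynonymous", "nonsense")

    def test_cis_record_in_promoter(self, annotation, rng):
        for _ in range(20):
            m = simulate_transgene_mutation("cis", annotation, rng)
            assert annotation.promoter_span[0] <= m.position <= annotation.promoter_span[1]
            assert m.position < 0
            assert (m.ref, m.alt) in {("G", "A"), ("C", "T")}


class TestScreenDataset:
    def test_deterministic_and_seed_sensitive(self, small_config):
        ds1 = simulate_screen(small_config)
        ds2 = simulate_screen(small_config)
        pd.testing.assert_frame_equal(ds1.haploid_cultures, ds2.haploid_cultures)
        pd.testing.assert_frame_equal(ds1.treated_events, ds2.treated_events)
        other = SimulationConfig(**{**small_config.__dict__, "seed": 8})
        ds3 = simulate_screen(other)
        assert not ds1.haploid_cultures["yfp"].equals(ds3.haploid_cultures["yfp"])

    def test_every_culture_genotype_in_truth(self, small_config):
        ds = simulate_screen(small_config)
        truth_ids = {rec.genotype_id for rec in ds.truth}
        assert set(ds.haploid_cultures["genotype_id"]) == truth_ids
        assert set(ds.diploid_cultures["genotype_id"]) == truth_ids
        assert set(ds.pyro_assays["genotype_id"]) == truth_ids

    def test_minimum_event_counts(self, small_config):
        ds = simulate_screen(small_config)
        hap_counts = ds.haploid_cultures.groupby("genotype_id").size()
        dip_counts = ds.diploid_cultures.groupby("genotype_id").size()
        assert (hap_counts >= 5000).all()
        assert (dip_counts >= 9000).all()

    def test_truth_labels_recovered_by_classification(self, small_config):
        from reporterscreen.pipeline import classify_screen
        ds = simulate_screen(small_config)
        table = classify_screen(ds)
        assert (table["class"] == table["true_class"]).all()

    def test_recessive_trans_mostly_uncalled_in_diploids(self):
        # with trans dominance 0 and the screen's class weights, the large
        # majority of mutants should show no significant diploid YFP effect
        from reporterscreen.pipeline import compute_z_table
        cfg = SimulationConfig(seed=13, n_mutant_genotypes=120,
                               n_cells_control=1000, n_cells_treated=1000,
                               n_control_replicates=12)
        ds = simulate_screen(cfg)
        dz = compute_z_table(ds.diploid_cultures, ds.diploid_controls, "yfp")
        merged = dz.merge(
            pd.DataFrame([{"genotype_id": r.genotype_id,
                           "true_class": r.class_label} for r in ds.truth]),
            on="genotype_id")
        trans = merged[merged["true_class"] == "trans"]
        assert (np.abs(trans["z"]) < 2.58).mean() >= 0.8
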