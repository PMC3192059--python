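import numpy as np
import pandas as pd
import pytest

from isoscreen import ValidationError
from isoscreen.diffscreen import compute_fold_changes, consensus_screen
from isoscreen.normalize import preprocess
from isoscreen.qpcr import ddct
from isoscreen.simulate import (CHROMOSOME_GENE_WEIGHTS, SimulationConfig,
                                simulate_experiment, truth_recovery_report)


class TestConfig:
    def test_invalid_fields_named(self):
        with pytest.raises(ValidationError, match="background_rate"):
            SimulationConfig(seed=1, background_rate=1.5).validate()
        with pytest.raises(ValidationError, match="imprint_gene_fold"):
            SimulationConfig(seed=1, imprint_gene_fold=0.9).validate()

    def test_disabled_imprint_effect(self):
        sim = simulate_experiment(SimulationConfig(seed=3, imprint_gene_fold=None))
        assert sim.truth.imprint_gene is None
        assert sim.truth.imprint_effects == {}


class TestDeterminismAndLayout:
    def test_same_seed_bitwise_identical(self):
        a = simulate_experiment(SimulationConfig(seed=11))
        b = simulate_experiment(SimulationConfig(seed=11))
        pd.testing.assert_frame_equal(a.expression.values, b.expression.values)
        pd.testing.assert_frame_equal(a.ct.data, b.ct.data)
        pd.testing.assert_frame_equal(a.methylation.data, b.methylation.data)
        assert a.truth.to_dict() == b.truth.to_dict()
        c = simulate_experiment(SimulationConfig(seed=12))
        assert not a.expression.values.equals(c.expression.values)

    def test_dimensions_and_chromosome_allocation_exact(self):
        cfg = SimulationConfig(seed=5, n_genes=500, n_clones=4, n_somatic=1)
        sim = simulate_experiment(cfg)
        assert sim.expression.shape == (500, 1 + 4 + 1 + 1)
        counts = sim.annotation["chromosome"].value_counts()
        weights = pd.Series(CHROMOSOME_GENE_WEIGHTS, dtype=float)
        expected = 500 * weights / weights.sum()
        assert counts.sum() == 500
        assert (abs(counts.reindex(weights.index) - expected) <= 1).all()

    def test_marginal_sd_matches_configuration(self):
        """Reference-sample SD ~ sqrt(baseline_sd^2 + noise_sd^2)."""
        target = np.hypot(2.0, 0.15)
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, n_genes=500)
            sim = simulate_experiment(cfg)
            log2 = np.log2(sim.expression.values["H9"])
            assert abs(log2.std() - target) / target < 0.10

    def test_escape_genes_never_reactivated(self, default_sim):
        truth = default_sim.truth
        planted = set().union(*truth.reactivated_by_clone.values())
        assert planted.isdisjoint(truth.escape_genes)
        assert truth.imprint_gene not in planted

    def test_imprint_gene_silenced_beyond_fold_in_every_clone(self, default_sim):
        truth = default_sim.truth
        for clone, eff in truth.imprint_effects.items():
            assert eff <= -np.log2(truth.config.imprint_gene_fold)


class TestCtRoundTrip:
    def test_ddct_recovers_planted_fold(self, default_sim):
        """ddCt on the synthesized Ct tables recovers the planted imprint
        silencing within 15% (clone-averaged)."""
        sim = default_sim
        res = ddct(sim.ct, sim.truth.imprint_gene)
        clones = sim.manifest.clones
        recovered = np.exp(np.mean(np.log(res.loc[clones, "re"])))
        planted = np.exp(np.mean([eff * np.log(2)
                                  for eff in sim.truth.imprint_effects.values()]))
        assert recovered == pytest.approx(planted, rel=0.15)

    def test_reactivated_target_recovered_about_twofold_up(self, default_sim):
        sim = default_sim
        target = sorted(sim.truth.core_reactivated)[0]
        res = ddct(sim.ct, target)
        mean_re = res.loc[sim.manifest.clones, "re"].mean()
        assert mean_re == pytest.approx(2.0, rel=0.25)


class TestRecoveryReport:
    def run_recovery(self, sim):
        collapsed, _ = preprocess(sim.expression)
        fct = compute_fold_changes(collapsed, sim.manifest)
        return fct, truth_recovery_report(fct, sim.annotation, sim.manifest,
                                          sim.truth)

    def test_defaults_recover_all_headlines(self, default_sim):
        _, rec = self.run_recovery(default_sim)
        assert rec["imprint"]["precision"] == 1.0
        assert rec["imprint"]["recall"] == 1.0
        assert rec["headline"]["imprint_gene_uniquely_found"]
        assert rec["headline"]["x_enrichment_detected"]
        assert rec["headline"]["x_upregulation_dominant"]
        assert rec["reactivation"]["recall"] is not None

    def test_null_truth_gives_null_ratios_not_one(self):
        sim = simulate_experiment(SimulationConfig(
            seed=21, imprint_gene_fold=None, reactivated_fraction=0.0))
        _, rec = self.run_recovery(sim)
        assert rec["imprint"]["recall"] is None         # empty truth
        assert rec["reactivation"]["n_true"] == 0

    def test_recall_non_increasing_in_noise(self):
        """Background recall degrades (weakly) as technical noise grows."""
        means = []
        for noise in (0.1, 0.3, 0.6):
            recalls = []
            for seed in range(8):
                sim = simulate_experiment(SimulationConfig(
                    seed=seed, noise_sd=noise, n_genes=800))
                _, rec = self.run_recovery(sim)
                recalls.append(rec["background"]["recall"])
            means.append(np.mean(recalls))
        assert means[0] >= means[1] >= means[2]


class TestUnrelatedLineMultiplier:
    def test_count_ratio_reflects_background_multiplier(self):
        """With planted imprint and X effects disabled, the unrelated iPS
        line shows ~4x the 2-fold deviation count of a clone."""
        clone_total = unrelated_total = 0
        for seed in range(30):
            sim = simulate_experiment(SimulationConfig(
                seed=seed, imprint_gene_fold=None, reactivated_fraction=0.0))
            collapsed, _ = preprocess(sim.expression)
            fct = compute_fold_changes(collapsed, sim.manifest)
            from isoscreen.diffscreen import flag_signs
            signs = flag_signs(fct, 2.0)
            clone_total += int((signs[sim.manifest.clones[0]] != 0).sum())
            unrelated_total += int((signs[sim.manifest.unrelated[0]] != 0).sum())
        ratio = unrelated_total / clone_total
        assert ratio == pytest.approx(4.0, rel=0.25)
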