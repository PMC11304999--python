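import dataclasses

import numpy as np
import pandas as pd
import pytest

import engraftment as eg
from engraftment.synthetic import (
    EngraftmentParams,
    load_scenario_params,
    retention_probabilities,
    simulate_donor,
    simulate_engraftment,
    simulate_study,
    write_study,
)


@pytest.fixture(scope="module")
def base_params():
    return load_scenario_params("human_to_mouse")


class TestDonor:
    def test_proportions_sum_to_one(self, base_params):
        donor = simulate_donor(base_params, seed=1)
        assert donor.proportions.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(donor.asv_ids) == base_params.s_asvs

    def test_sigma_zero_gives_uniform(self, base_params):
        params = dataclasses.replace(base_params, donor_sigma=0.0)
        donor = simulate_donor(params, seed=1)
        np.testing.assert_allclose(donor.proportions, 1 / params.s_asvs, atol=1e-15)

    def test_replicates_tightly_correlated(self, base_params):
        """Technical PCR replicates differ only by multinomial noise, so their
        normalized profiles correlate near-perfectly."""
        from engraftment.io_tables import CountTable
        from engraftment.normalization import normalize_counts

        params = dataclasses.replace(base_params, s_asvs=300, depth_mean=1e5)
        rs = []
        for seed in range(1, 6):
            donor = simulate_donor(params, seed=seed)
            norm = normalize_counts(CountTable(donor.replicate_counts))
            cols = norm.values.columns
            rs.append(eg.pairwise_r(norm.values[cols[0]], norm.values[cols[1]]))
        assert min(rs) > 0.95

    def test_too_few_asvs_rejected(self, base_params):
        with pytest.raises(ValueError, match="at least 10"):
            simulate_donor(dataclasses.replace(base_params, s_asvs=5), seed=1)


class TestRetentionModel:
    def test_logistic_monotone_in_abundance(self, base_params):
        donor = simulate_donor(base_params, seed=1)
        pi = retention_probabilities(
            donor.proportions, donor.taxonomy, list(donor.asv_ids), base_params
        )
        order = np.argsort(donor.proportions)
        assert (np.diff(pi[order]) >= 0).all()

    def test_override_and_phylum_overrides(self, base_params):
        donor = simulate_donor(base_params, seed=1)
        params = dataclasses.replace(base_params, retention_override=0.42,
                                     phylum_retention={"Proteobacteria": 0.9})
        pi = retention_probabilities(
            donor.proportions, donor.taxonomy, list(donor.asv_ids), params
        )
        phyla = donor.taxonomy.rank_labels("phylum").to_numpy()
        assert set(pi[phyla == "Proteobacteria"]) == {0.9}
        assert set(pi[phyla != "Proteobacteria"]) == {0.42}


class TestEngraftment:
    def test_no_bottleneck_limit(self, base_params):
        """Full retention, no reweighting, no influx, deep sequencing:
        recipients reproduce the donor, transfer efficiency near 1."""
        params = dataclasses.replace(
            base_params, retention_override=1.0, fitness_sigma=0.0,
            host_sigma=0.0, influx_rate=0.0, depth_mean=1e6, input_depth_mean=1e6,
        )
        study = simulate_study("human_to_mouse", 3, params)
        res = eg.between_group_efficiency(study.bundle, "HM_input", "HM->WT")
        assert res.mean_r > 0.98

    def test_uniform_retention_binomial_losses(self, base_params):
        """pi = 0.5 over 400 ASVs: non-retained count per recipient follows
        Binomial(400, 0.5); the pooled mean over 20 seeds sits within 3 SE."""
        params = dataclasses.replace(base_params, retention_override=0.5,
                                     retention_correlation=0.0, n_recipients=2)
        lost = []
        for seed in range(1, 21):
            study = simulate_study("human_to_mouse", seed, params)
            masks = study.truth["retention_masks"]
            lost.extend((~masks).sum(axis=0).tolist())
        se = np.sqrt(400 * 0.25 / len(lost))
        assert np.mean(lost) == pytest.approx(200, abs=3 * se)

    def test_ground_truth_dimensions(self, base_params):
        study = simulate_study("human_to_mouse", 1, base_params)
        masks = study.truth["retention_masks"]
        recipients = [
            s for s in study.bundle.counts.sample_ids
            if study.bundle.metadata.table.loc[s, "role"] == "recipient"
        ]
        assert sorted(masks.columns) == sorted(recipients)
        assert list(masks.index) == [f"asv{i:04d}" for i in range(base_params.s_asvs)]

    def test_reads_only_from_positive_truth(self, base_params):
        study = simulate_study("human_to_mouse", 2, base_params)
        counts = study.bundle.counts.counts
        truth = study.truth["true_proportions"]
        recipients = truth.columns
        observed = counts.loc[counts.index.intersection(truth.index), recipients]
        assert ((observed > 0) <= (truth > 0)).all().all()


class TestPassage:
    def test_lossless_passage_reproduces_pool(self, base_params):
        """rho = 1 with no noise or influx: generation-2 communities equal the
        pooled generation-1 slurry up to multinomial sampling."""
        params = dataclasses.replace(
            base_params, passage_retention=1.0, passage_fitness_sigma=0.0,
            passage_host_sigma=0.0, passage_influx_rate=0.0,
            depth_mean=1e6, input_depth_mean=1e6,
        )
        study = simulate_study("mouse_adapted", 4, params)
        res = eg.between_group_efficiency(study.bundle, "NIMM_input", "NIMM-g2->WT")
        assert res.mean_r > 0.99

    def test_no_influx_masks_nested(self, base_params):
        params = dataclasses.replace(base_params, influx_rate=0.0,
                                     passage_influx_rate=0.0)
        study = simulate_study("mouse_adapted", 4, params)
        pooled = study.truth["pooled_slurry"]
        gen2 = study.truth["true_proportions"]
        absent = pooled[pooled == 0].index
        assert (gen2.loc[gen2.index.intersection(absent)] == 0).all().all()

    def test_passage_beats_human_transfer(self, base_params):
        """Mouse-adapted passage transfers far more faithfully than the
        human -> mouse bottleneck on matched seeds."""
        for seed in (1, 2, 3):
            human = simulate_study("human_to_mouse", seed)
            ma = simulate_study("mouse_adapted", seed)
            r_h = eg.between_group_efficiency(human.bundle, "HM_input", "HM->WT").mean_r
            r_m = eg.between_group_efficiency(ma.bundle, "NIMM_input", "NIMM-g2->WT").mean_r
            assert r_m > r_h


class TestScenarios:
    def test_unknown_scenario_lists_valid_names(self):
        with pytest.raises(ValueError, match="human_to_mouse"):
            simulate_study("nope", 1)

    def test_same_seed_bit_identical(self):
        s1 = simulate_study("human_to_mouse", 9)
        s2 = simulate_study("human_to_mouse", 9)
        pd.testing.assert_frame_equal(s1.bundle.counts.counts, s2.bundle.counts.counts)
        pd.testing.assert_frame_equal(s1.truth["retention_masks"],
                                      s2.truth["retention_masks"])

    def test_different_seeds_differ(self):
        s1 = simulate_study("human_to_mouse", 9)
        s2 = simulate_study("human_to_mouse", 10)
        assert not s1.bundle.counts.counts.equals(s2.bundle.counts.counts)

    def test_all_scenarios_pass_io_validation(self):
        for scenario in ("human_to_mouse", "mouse_adapted", "two_event", "null"):
            study = simulate_study(scenario, 1)
            # construction re-validates: depths >= 1, integer counts, no dups
            assert study.bundle.counts.depths().min() >= 1
            assert study.bundle.metadata.table.shape[0] == len(
                study.bundle.counts.sample_ids
            )

    def test_write_study_round_trips(self, tmp_path):
        study = simulate_study("human_to_mouse", 1)
        paths = write_study(study, tmp_path)
        counts = eg.read_count_table(paths["counts"])
        pd.testing.assert_frame_equal(counts.counts, study.bundle.counts.counts,
                                      check_names=False)
        meta = eg.read_metadata(paths["metadata"])
        assert set(meta.sample_ids) == set(study.bundle.counts.sample_ids)


class TestParameterDirections:
    def test_efficiency_increases_with_retention_alpha(self, base_params):
        """Weakening the bottleneck (larger logistic intercept) must raise
        measured transfer efficiency."""
        means = []
        for alpha in (-1.0, 0.0, 1.0, 2.5, 4.0):
            params = dataclasses.replace(base_params, retention_alpha=alpha)
            rs = [
                eg.between_group_efficiency(
                    simulate_study("human_to_mouse", seed, params).bundle,
                    "HM_input", "HM->WT",
                ).mean_r
                for seed in (1, 2, 3)
            ]
            means.append(np.mean(rs))
        assert all(np.diff(means) > 0)

    def test_host_noise_decreases_consistency(self, base_params):
        """More per-recipient reassembly noise must lower within-group r
        (three-point sweep, averaged over seeds)."""
        means = []
        for sigma in (0.3, 0.9, 1.8):
            params = dataclasses.replace(base_params, host_sigma=sigma)
            rs = [
                eg.within_group_consistency(
                    simulate_study("human_to_mouse", seed, params).bundle, "HM->WT"
                ).mean_r
                for seed in range(1, 9)
            ]
            means.append(np.mean(rs))
        assert means[0] > means[1] > means[2]
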