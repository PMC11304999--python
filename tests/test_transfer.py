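import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import engraftment as eg
from engraftment.io_tables import CountTable
from engraftment.transfer import (
    UndefinedCorrelationError,
    abundance_histogram,
    aggregate_to_rank,
    pairwise_r,
)
from conftest import make_metadata


def brute_force_pearson(x, y):
    """Covariance/variance definition, written independently of the library."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    mx, my = x.mean(), y.mean()
    cov = ((x - mx) * (y - my)).sum()
    return cov / np.sqrt(((x - mx) ** 2).sum() * ((y - my) ** 2).sum())


class TestPairwiseR:
    def test_identity_gives_one(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        assert pairwise_r(x, x) == pytest.approx(1.0)

    def test_perfect_anti_order(self):
        assert pairwise_r([0, 1, 2, 3], [3, 2, 1, 0], "keep_all") == pytest.approx(-1.0)

    def test_matches_formula_oracle(self, rng):
        x = rng.random(20)
        y = rng.random(20)
        assert pairwise_r(x, y, "keep_all") == pytest.approx(
            brute_force_pearson(x, y), abs=1e-12
        )

    def test_permutation_invariance(self, rng):
        x = rng.random(30)
        y = rng.random(30)
        perm = rng.permutation(30)
        assert pairwise_r(x[perm], y[perm], "keep_all") == pytest.approx(
            pairwise_r(x, y, "keep_all"), abs=1e-12
        )

    def test_joint_zero_inflation_under_keep_all(self, rng):
        """Padding both profiles with shared absences drags r toward +1 —
        the inflation that motivates the drop_joint_zeros default."""
        x = np.concatenate([rng.random(15) + 0.5, [0.0]])
        y = np.concatenate([rng.random(15) + 0.5, [0.0]])
        base = pairwise_r(x, y, "keep_all")
        padded_x = np.concatenate([x, np.zeros(50)])
        padded_y = np.concatenate([y, np.zeros(50)])
        inflated = pairwise_r(padded_x, padded_y, "keep_all")
        assert inflated > base
        # and the default policy is immune to the padding
        assert pairwise_r(padded_x, padded_y) == pytest.approx(
            pairwise_r(x, y), abs=1e-12
        )

    def test_too_few_features_raises(self):
        with pytest.raises(UndefinedCorrelationError, match="retained"):
            pairwise_r([0.0, 1.0, 0.0], [0.0, 2.0, 0.0])

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedCorrelationError, match="variance"):
            pairwise_r([1.0, 1.0, 1.0, 1.0], [0.5, 1.0, 2.0, 3.0], "keep_all")


class TestAggregateToRank:
    def test_same_genus_counts_add(self, toy_counts, toy_taxonomy):
        genus = aggregate_to_rank(toy_counts, toy_taxonomy, "genus")
        # asvA + asvB share Blautia: 5+3, 0+4, 10+5, 1+2
        assert genus.counts.loc["Blautia"].tolist() == [8, 4, 15, 3]

    def test_depth_conserved(self, toy_counts, toy_taxonomy):
        for rank in ("genus", "phylum"):
            agg = aggregate_to_rank(toy_counts, toy_taxonomy, rank)
            assert agg.depths().tolist() == toy_counts.depths().tolist()

    def test_unclassified_pooled(self, toy_counts, toy_taxonomy):
        partial = eg.TaxonomyTable(toy_taxonomy.lineages.drop(index="asvC"))
        meta = make_metadata(["s1", "s2", "s3", "s4"], list("gggg"))
        bundle = eg.align(toy_counts, partial, meta)
        agg = aggregate_to_rank(bundle.counts, bundle.taxonomy, "phylum")
        assert "Unclassified" in agg.asv_ids

    def test_phylum_fixture_matches_hand_sum(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 9, size=(6, 2)), index=[f"a{i}" for i in range(6)],
            columns=["s1", "s2"],
        )
        from engraftment.io_tables import RANKS, TaxonomyTable

        phyla = ["P1", "P1", "P2", "P2", "P3", "P3"]
        rows = {
            f"a{i}": dict.fromkeys(RANKS, "unclassified") | {"phylum": phyla[i]}
            for i in range(6)
        }
        tax = TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index",
                                                   columns=list(RANKS)))
        agg = aggregate_to_rank(CountTable(counts), tax, "phylum")
        for p, (i, j) in {"P1": (0, 1), "P2": (2, 3), "P3": (4, 5)}.items():
            np.testing.assert_array_equal(
                agg.counts.loc[p].to_numpy(),
                counts.iloc[i].to_numpy() + counts.iloc[j].to_numpy(),
            )

    def test_unknown_rank_rejected(self, toy_counts, toy_taxonomy):
        with pytest.raises(KeyError, match="kingdom"):
            aggregate_to_rank(toy_counts, toy_taxonomy, "kingdom")


def _identical_pair_bundle():
    """Input group and recipient group carry identical compositions."""
    mat = np.array([[50, 50, 50], [30, 30, 30], [20, 20, 20], [5, 5, 5]])
    counts = CountTable(
        pd.DataFrame(mat, index=[f"a{i}" for i in range(4)],
                     columns=["in1", "r1", "r2"])
    )
    meta = make_metadata(
        ["in1", "r1", "r2"],
        ["inp", "rec", "rec"],
        roles=["input", "recipient", "recipient"],
        kinds=["technical", "biological", "biological"],
    )
    return eg.align(counts, None, meta)


class TestGroupEfficiency:
    def test_perfect_transfer_gives_r_one(self):
        bundle = _identical_pair_bundle()
        res = eg.between_group_efficiency(bundle, "inp", "rec")
        assert res.n_pairs == 2
        assert res.pairs["r"].tolist() == pytest.approx([1.0, 1.0])
        assert res.sd_r == pytest.approx(0.0)

    def test_within_group_pair_count(self):
        mat = np.column_stack([[10, 5, 3, 1]] * 4) + np.arange(4)
        counts = CountTable(
            pd.DataFrame(mat, index=list("abcd"), columns=[f"m{i}" for i in range(4)])
        )
        bundle = eg.align(counts, None, make_metadata(list(counts.sample_ids), ["g"] * 4))
        res = eg.within_group_consistency(bundle, "g")
        assert res.n_pairs == 6  # k(k-1)/2 with k=4

    def test_identical_pair_within_group(self):
        mat = np.array([[7, 7], [3, 3], [1, 1]])
        counts = CountTable(pd.DataFrame(mat, index=list("abc"), columns=["m1", "m2"]))
        bundle = eg.align(counts, None, make_metadata(["m1", "m2"], ["g", "g"]))
        res = eg.within_group_consistency(bundle, "g")
        assert res.n_pairs == 1
        assert res.pairs["r"].iloc[0] == pytest.approx(1.0)

    def test_singleton_group_rejected(self):
        bundle = _identical_pair_bundle()
        with pytest.raises(ValueError, match="single sample"):
            eg.within_group_consistency(bundle, "inp")

    def test_input_modes_both_available(self):
        bundle = _identical_pair_bundle()
        per = eg.between_group_efficiency(bundle, "inp", "rec",
                                          input_mode="per_replicate")
        avg = eg.between_group_efficiency(bundle, "inp", "rec")
        assert per.input_mode == "per_replicate"
        assert avg.input_mode == "average_replicates"
        assert per.n_pairs == avg.n_pairs == 2  # single input replicate here


class TestClassification:
    def test_forced_by_definitions(self):
        mat = np.array([[1, 1], [0, 3], [2, 0]])
        counts = CountTable(pd.DataFrame(mat, index=list("abc"), columns=["in1", "r1"]))
        meta = make_metadata(["in1", "r1"], ["inp", "rec"],
                             roles=["input", "recipient"],
                             kinds=["technical", "biological"])
        bundle = eg.align(counts, None, meta)
        cls = eg.classify_asvs(bundle, "inp", "r1")
        assert cls.table.loc["a", "label"] == "transferred"
        assert cls.table.loc["b", "label"] == "newly_detected"
        assert cls.table.loc["c", "label"] == "non_transferring"

    def test_identical_profiles_have_no_failures(self):
        bundle = _identical_pair_bundle()
        cls = eg.classify_asvs(bundle, "inp", "r1")
        counts = cls.counts_per_label()
        assert counts["non_transferring"] == 0
        assert counts["newly_detected"] == 0

    def test_labels_partition_universe(self):
        bundle = _identical_pair_bundle()
        cls = eg.classify_asvs(bundle, "inp", "r1")
        assert cls.counts_per_label()["transferred"] + cls.counts_per_label()[
            "non_transferring"
        ] + cls.counts_per_label()["newly_detected"] + cls.counts_per_label()[
            "absent_both"
        ] == len(bundle.counts.asv_ids)

    def test_simulator_ground_truth_at_high_depth(self):
        """At deep sequencing, transfer-fate labels recover the simulator's
        retention mask for every ASV detected in the input."""
        params = dataclasses.replace(
            eg.load_scenario_params("human_to_mouse"),
            s_asvs=100, depth_mean=1e6, input_depth_mean=1e6, influx_rate=0.0,
        )
        study = eg.simulate_study("human_to_mouse", 5, params)
        b = study.bundle
        masks = study.truth["retention_masks"]
        input_present = (
            b.counts.counts[b.samples_in_group("HM_input")].sum(axis=1) >= 1
        )
        rec = b.samples_in_group("HM->WT")[0]
        cls = eg.classify_asvs(b, "HM_input", rec)
        donor_ids = masks.index
        expected_depth = study.truth["true_proportions"][rec].reindex(donor_ids)
        confident = input_present[donor_ids] & (
            ~masks[rec] | (expected_depth * 1e6 >= 20)
        )
        pred = cls.table.loc[donor_ids, "label"] == "transferred"
        agreement = (pred == masks[rec])[confident].mean()
        assert agreement == pytest.approx(1.0, abs=0.01)


class TestHistogram:
    def test_hand_binning(self):
        table = pd.DataFrame(
            {
                "input_abundance": [0.2, 0.3, 1.7],
                "recipient_abundance": [0.0, 0.0, 0.0],
                "label": ["non_transferring"] * 3,
            },
            index=list("abc"),
        )
        cls = eg.AsvTransferClassification(table, "inp", "r1", "per_sample")
        hist = abundance_histogram(cls, "non_transferring", bin_width=1.0)
        assert hist["count"].tolist() == [2, 1]
        assert hist["bin_left"].tolist() == [0.0, 1.0]

    def test_empty_class_gives_empty_histogram(self):
        bundle = _identical_pair_bundle()
        cls = eg.classify_asvs(bundle, "inp", "r1")
        hist = abundance_histogram(cls, "newly_detected")
        assert hist.empty

    def test_mass_conservation(self):
        study = eg.simulate_study("human_to_mouse", 3)
        b = study.bundle
        rec = b.samples_in_group("HM->WT")[0]
        cls = eg.classify_asvs(b, "HM_input", rec)
        for which in ("non_transferring", "newly_detected"):
            hist = abundance_histogram(cls, which)
            assert hist["count"].sum() == cls.counts_per_label()[which]


class TestStratifiedEfficiency:
    def test_single_asv_stratum_flagged(self):
        mat = np.array([[50, 40], [30, 35], [20, 25], [5, 4]])
        counts = CountTable(pd.DataFrame(mat, index=[f"a{i}" for i in range(4)],
                                         columns=["in1", "r1"]))
        from engraftment.io_tables import RANKS, TaxonomyTable

        rows = {
            f"a{i}": dict.fromkeys(RANKS, "unclassified")
            | {"phylum": "Lonely" if i == 3 else "Common"}
            for i in range(4)
        }
        tax = TaxonomyTable(pd.DataFrame.from_dict(rows, orient="index",
                                                   columns=list(RANKS)))
        meta = make_metadata(["in1", "r1"], ["inp", "rec"],
                             roles=["input", "recipient"],
                             kinds=["technical", "biological"])
        bundle = eg.align(counts, tax, meta)
        res = eg.stratified_efficiency(bundle, "inp", "rec")
        assert res["Lonely"] is None
        assert res["Common"] is not None

    def test_retention_contrast_orders_strata(self):
        """A phylum engrafting at 0.95 should show higher transfer efficiency
        than one engrafting at 0.3 (averaged over recipients)."""
        params = dataclasses.replace(
            eg.load_scenario_params("human_to_mouse"),
            phylum_retention={"Firmicutes": 0.95, "Bacteroidota": 0.3},
            n_recipients=20,
        )
        study = eg.simulate_study("human_to_mouse", 11, params)
        res = eg.stratified_efficiency(study.bundle, "HM_input", "HM->WT")
        assert res["Firmicutes"].mean_r > res["Bacteroidota"].mean_r

    def test_perfect_stratum_near_one(self):
        params = dataclasses.replace(
            eg.load_scenario_params("human_to_mouse"),
            phylum_retention={"Firmicutes": 1.0},
            fitness_sigma=0.0, host_sigma=0.05, influx_rate=0.0,
            depth_mean=1e5, input_depth_mean=1e6,
        )
        study = eg.simulate_study("human_to_mouse", 2, params)
        res = eg.stratified_efficiency(study.bundle, "HM_input", "HM->WT")
        assert res["Firmicutes"].mean_r > 0.95


@given(data=st.data())
@settings(max_examples=30, deadline=None)
def test_pairwise_r_oracle_property(data):
    n = data.draw(st.integers(5, 40))
    x = np.array(data.draw(st.lists(
        st.floats(0, 10, allow_nan=False), min_size=n, max_size=n)))
    y = np.array(data.draw(st.lists(
        st.floats(0, 10, allow_nan=False), min_size=n, max_size=n)))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return
    assert pairwise_r(x, y, "keep_all") == pytest.approx(
        brute_force_pearson(x, y), abs=1e-9
    )
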