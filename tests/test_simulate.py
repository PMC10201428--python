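"""Simulator statistical structure and determinism."""
import numpy as np
import pytest
import scipy.stats

from castlib import donor_quant as dq
from castlib import end_model, simulate as sim, target_quant as tq


def uniform_truth(manifest, seed=0, **kw):
    eff = {v.variant_id: 1.0 for v in manifest.variants}
    return sim.make_truth(manifest, seed=seed, efficiencies=eff, **kw)


class TestDonorSim:
    def test_null_model_output_matches_input(self, small_manifest):
        """With no noise and uniform efficiencies, output barcode frequencies
        are chi-square consistent with the planted abundances."""
        truth = uniform_truth(small_manifest, seed=2)
        ds = sim.simulate_donor_reads(small_manifest, truth, 40_000, 40_000)
        p19 = end_model.primer19("left")
        cout = dq.count_barcodes(ds.output_reads, small_manifest, p19)
        ids = [v.variant_id for v in small_manifest.variants]
        a = np.array([truth.abundances[i] for i in ids])
        expected = a / a.sum() * cout.n_barcode_matched
        obs = np.array([cout.counts[i] for i in ids])
        stat = scipy.stats.chisquare(obs, expected)
        assert stat.pvalue > 1e-3

    def test_zero_efficiency_yields_zero_output(self, small_manifest):
        eff = {v.variant_id: 1.0 for v in small_manifest.variants}
        dead = small_manifest.variants[0].variant_id
        eff[dead] = 0.0
        truth = sim.make_truth(small_manifest, seed=3, efficiencies=eff)
        ds = sim.simulate_donor_reads(small_manifest, truth, 5_000, 5_000)
        cout = dq.count_barcodes(ds.output_reads, small_manifest, end_model.primer19("left"))
        assert cout.counts[dead] == 0

    def test_determinism(self, small_manifest):
        truth = uniform_truth(small_manifest, seed=4, uncoupling_rate=0.2, error_rate=0.01)
        a = sim.simulate_donor_reads(small_manifest, truth, 2_000, 2_000)
        b = sim.simulate_donor_reads(small_manifest, truth, 2_000, 2_000)
        assert a.input_reads == b.input_reads and a.output_reads == b.output_reads

    def test_empty_manifest_rejected(self, small_manifest):
        import castlib.library_design as ld

        empty = ld.VariantManifest([], "left")
        truth = uniform_truth(small_manifest)
        with pytest.raises(ValueError, match="empty manifest"):
            sim.simulate_donor_reads(empty, truth, 10, 10)

    def test_truth_roundtrip(self, small_manifest, tmp_path):
        truth = sim.make_truth(small_manifest, seed=8, uncoupling_rate=0.35, error_rate=1e-3)
        p = tmp_path / "truth.tsv"
        truth.to_tsv(p)
        back = sim.SimTruth.from_tsv(p)
        assert back.efficiencies == truth.efficiencies
        assert back.abundances == truth.abundances
        assert back.uncoupling_rate == truth.uncoupling_rate
        assert back.wt_ids == truth.wt_ids


class TestCouplingSim:
    def test_zero_uncoupling_fully_coupled(self, small_manifest):
        truth = uniform_truth(small_manifest, seed=5)
        r1, r2 = sim.simulate_coupling_pairs(small_manifest, truth, 2_000)
        rep = dq.coupling_qc(zip(r1, r2), small_manifest, end_model.primer19("left"))
        assert rep.overall_fraction_correct == 1.0
        observed = rep.per_variant[rep.per_variant["n_pairs"] > 0]
        assert (observed["fraction_correct"] == 1.0).all()

    def test_zero_pairs_rejected(self, small_manifest):
        truth = uniform_truth(small_manifest)
        with pytest.raises(ValueError):
            sim.simulate_coupling_pairs(small_manifest, truth, 0)


class TestTargetSim:
    def test_uniform_model_uniform_distances(self):
        uni = tq.InsertionPreferenceModel(
            sim.default_preference_model().weights * 0 + 0.25
        )
        sims = sim.simulate_target_reads(uni, 1_000, 30_000, targets=("A",), seed=6)
        s = sims["A"]
        counts = np.bincount(s.true_distances - 43, minlength=14)
        stat = scipy.stats.chisquare(counts)
        assert stat.pvalue > 1e-3

    def test_single_motif_model_unimodal(self):
        """Reads carrying the planted motif once show one dominant distance
        (the placement-aligned one)."""
        sims = sim.simulate_target_reads(sim.cwg_model(), 1_000, 30_000, targets=("A",), seed=7)
        s = sims["A"]
        calls, _ = tq.call_integrations(s.output_pairs, s.context)
        groups = tq.motif_distance_distribution(calls, "CWG")
        checked = 0
        for key, dist in groups.items():
            if len(key) != 1 or dist.sum() < 300:
                continue
            expected_mode = 46 + key[0]
            assert dist.idxmax() == expected_mode
            runner_up = dist.drop(index=expected_mode).max()
            assert dist[expected_mode] >= 3 * runner_up
            checked += 1
        assert checked >= 3

    def test_reads_carry_planted_end_at_planted_distance(self):
        sims = sim.simulate_target_reads(None, 100, 500, targets=("B",), seed=8)
        s = sims["B"]
        prefixes = tq.default_end_prefixes()
        for k in range(50):
            i5, _ = s.output_pairs[k]
            alen = tq.filter_target_read(i5, s.context.i5_anchors)
            d = int(s.true_distances[k])
            j = alen + (d - tq.DEG_START)
            expected = prefixes["right" if s.true_orientations[k] == "T-RL" else "left"]
            assert i5[j : j + 20] == expected

    def test_determinism(self):
        a = sim.simulate_target_reads(None, 500, 500, targets=("A",), seed=11)["A"]
        b = sim.simulate_target_reads(None, 500, 500, targets=("A",), seed=11)["A"]
        assert a.output_pairs == b.output_pairs and a.input_pairs == b.input_pairs


class TestTn7Sim:
    def test_all_unintegrated(self):
        reads = sim.simulate_tn7_reads(500, {"unintegrated": 1.0}, seed=1)
        from castlib.aux_quant import classify_tn7

        table = classify_tn7(reads)
        assert table.counts["unintegrated"] == 500
        assert table.integrated_fraction == 0.0

    def test_dominant_class_recovered_as_mode(self):
        probs = {"unintegrated": 0.2, (0, "T-RL"): 0.6, (5, "T-LR"): 0.2}
        reads = sim.simulate_tn7_reads(3_000, probs, seed=2)
        from castlib.aux_quant import classify_tn7

        table = classify_tn7(reads)
        assert table.unclassified == 0
        assert max(table.counts, key=table.counts.get) == (0, "T-RL")

    def test_invalid_offset_rejected_at_construction(self):
        with pytest.raises(ValueError, match="invalid Tn7 class"):
            sim.simulate_tn7_reads(10, {(31, "T-RL"): 1.0})

    def test_probabilities_must_normalize(self):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.simulate_tn7_reads(10, {"unintegrated": 0.5})

    def test_read_counts_conserve(self):
        probs = {"unintegrated": 0.5, (3, "T-RL"): 0.5}
        reads = sim.simulate_tn7_reads(777, probs, seed=3)
        assert len(reads) == 777
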