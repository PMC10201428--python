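"""Barcode extraction, counting, enrichment and coupling QC."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from castlib import donor_quant as dq
from castlib import end_model, simulate as sim
from castlib.donor_quant import CountTable

P19 = "ACGTACGTACGTACGTACG"  # 19 nt


class TestExtractBarcode:
    def test_downstream_ten(self):
        read = "TTTT" + P19 + "ACGTACGTAC" + "GGGG"
        assert dq.extract_barcode(read, P19) == "ACGTACGTAC"

    def test_single_mismatch_rejected(self):
        mutated = "G" + P19[1:]
        read = "TTTT" + mutated + "ACGTACGTAC"
        assert dq.extract_barcode(read, P19) is None

    def test_too_short_tail_rejected(self):
        read = "TTTT" + P19 + "ACGTACGTA"  # 9 nt after primer
        assert dq.extract_barcode(read, P19) is None

    def test_first_occurrence_rule(self):
        read = P19 + "AAAAAAAAAA" + P19 + "CCCCCCCCCC"
        assert dq.extract_barcode(read, P19) == "AAAAAAAAAA"

    def test_wrong_primer_length(self):
        with pytest.raises(ValueError):
            dq.extract_barcode("ACGT", "ACGT")


class TestCounting:
    def test_exact_match_counting(self, small_manifest):
        v = small_manifest.variants[0]
        p19 = end_model.primer19("left")
        reads = ["XX".replace("X", "A") + p19 + v.barcode + "TTTT"] * 3
        reads.append("A" * 10 + p19 + "ACGTACGTAC" + "TT")  # unmatched barcode
        t = dq.count_barcodes(reads, small_manifest, p19)
        assert t.counts[v.variant_id] == 3
        assert t.n_barcode_matched == 3
        assert t.n_pass_filter == 4
        assert t.n_total_reads == 4

    def test_empty_read_set(self, small_manifest):
        t = dq.count_barcodes([], small_manifest, end_model.primer19("left"))
        assert sum(t.counts.values()) == 0
        assert t.n_total_reads == 0

    def test_oracle_equivalence_on_simulated_reads(self, small_manifest):
        """Brute-force per-read scan agrees on 1000 simulated reads."""
        truth = sim.make_truth(small_manifest, seed=5, uncoupling_rate=0.3, error_rate=0.01)
        ds = sim.simulate_donor_reads(small_manifest, truth, 1000, 1000)
        p19 = end_model.primer19("left")
        table = dq.count_barcodes(ds.input_reads, small_manifest, p19)
        # oracle: independent scan, no shared helpers
        brute = {v.variant_id: 0 for v in small_manifest.variants}
        bc2id = {v.barcode: v.variant_id for v in small_manifest.variants}
        matched = 0
        for read in ds.input_reads:
            for i in range(len(read) - 19 + 1):
                if read[i : i + 19] == p19:
                    bc = read[i + 19 : i + 29]
                    if len(bc) == 10 and bc in bc2id:
                        brute[bc2id[bc]] += 1
                        matched += 1
                    break
        assert table.counts == brute
        assert table.n_barcode_matched == matched

    def test_merge_examples(self):
        t1 = CountTable("a", {"v": 2, "w": 0}, 3, 3, 2)
        t2 = CountTable("b", {"v": 3, "w": 1}, 5, 4, 4)
        m = dq.merge_counts(t1, t2)
        assert m.counts == {"v": 5, "w": 1}
        assert m.n_total_reads == 8 and m.n_pass_filter == 7 and m.n_barcode_matched == 6

    def test_merge_with_empty_is_identity(self):
        t = CountTable("a", {"v": 2}, 4, 3, 2)
        z = CountTable("z", {"v": 0}, 0, 0, 0)
        assert dq.merge_counts(t, z).counts == t.counts

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 50)), min_size=1, max_size=8))
    def test_merge_commutative(self, pairs):
        ids = [f"v{i}" for i in range(len(pairs))]
        c1 = {i: a for i, (a, _) in zip(ids, pairs)}
        c2 = {i: b for i, (_, b) in zip(ids, pairs)}
        t1 = CountTable("a", c1, sum(c1.values()) + 2, sum(c1.values()) + 1, sum(c1.values()))
        t2 = CountTable("b", c2, sum(c2.values()) + 2, sum(c2.values()) + 1, sum(c2.values()))
        assert dq.merge_counts(t1, t2).counts == dq.merge_counts(t2, t1).counts


def tiny_tables(in_counts, out_counts):
    ti = CountTable("in", in_counts, sum(in_counts.values()), sum(in_counts.values()), sum(in_counts.values()))
    to = CountTable("out", out_counts, sum(out_counts.values()), sum(out_counts.values()), sum(out_counts.values()))
    return ti, to


class TestEnrichment:
    def test_fold_change_and_normalization(self):
        # v doubles in relative abundance (fc 2.0) while the WT members have
        # mean fold-change 2.0 -> normalized score exactly 1, log2 = 0
        ti, to = tiny_tables(
            {"v": 20, "w1": 5, "w2": 5, "other": 70},
            {"v": 40, "w1": 15, "w2": 5, "other": 40},
        )
        et = dq.enrichment(ti, to, ["w1", "w2"])
        row = et.table.set_index("variant_id")
        assert row.loc["v", "fold_change"] == pytest.approx(2.0)
        assert row.loc[["w1", "w2"], "fold_change"].mean() == pytest.approx(2.0)
        assert row.loc["v", "normalized_score"] == pytest.approx(1.0)
        assert row.loc["v", "log2_normalized"] == pytest.approx(0.0)

    def test_wt_mean_is_one_by_construction(self, small_manifest):
        truth = sim.make_truth(small_manifest, seed=6, uncoupling_rate=0.1)
        ds = sim.simulate_donor_reads(small_manifest, truth, 20_000, 20_000)
        p19 = end_model.primer19("left")
        et = dq.enrichment(
            dq.count_barcodes(ds.input_reads, small_manifest, p19),
            dq.count_barcodes(ds.output_reads, small_manifest, p19),
            small_manifest.wt_ids,
        )
        wt = et.table.set_index("variant_id").loc[small_manifest.wt_ids, "normalized_score"]
        assert wt.mean() == pytest.approx(1.0, abs=1e-12)

    def test_noise_free_recovery_rank_correlation(self, small_manifest):
        """Without uncoupling/errors, scores track planted efficiencies."""
        import scipy.stats

        truth = sim.make_truth(small_manifest, seed=7)
        ds = sim.simulate_donor_reads(small_manifest, truth, 150_000, 150_000)
        p19 = end_model.primer19("left")
        et = dq.enrichment(
            dq.count_barcodes(ds.input_reads, small_manifest, p19),
            dq.count_barcodes(ds.output_reads, small_manifest, p19),
            small_manifest.wt_ids,
        )
        s = et.scores()
        ids = [v.variant_id for v in small_manifest.variants]
        rho = scipy.stats.spearmanr(
            [truth.efficiencies[i] for i in ids], [s[i] for i in ids]
        ).statistic
        assert rho >= 0.95

    def test_missing_wt_in_input_rejected(self):
        ti, to = tiny_tables({"v": 10, "w1": 0}, {"v": 5, "w1": 5})
        with pytest.raises(ValueError, match="absent from input"):
            dq.enrichment(ti, to, ["w1"])

    def test_zero_input_variant_flagged_undefined(self):
        ti, to = tiny_tables({"v": 0, "w1": 10}, {"v": 5, "w1": 5})
        et = dq.enrichment(ti, to, ["w1"])
        row = et.table.set_index("variant_id").loc["v"]
        assert row["undefined"] and np.isnan(row["normalized_score"])

    def test_normalization_idempotent(self):
        ti, to = tiny_tables({"v": 10, "w1": 20, "w2": 10}, {"v": 30, "w1": 20, "w2": 10})
        et = dq.enrichment(ti, to, ["w1", "w2"])
        s = et.table.set_index("variant_id")["normalized_score"]
        wt_mean = s[["w1", "w2"]].mean()
        assert np.allclose(s / wt_mean, s)

    def test_scale_invariance(self):
        ti, to = tiny_tables({"v": 10, "w1": 20, "w2": 10}, {"v": 30, "w1": 20, "w2": 10})
        scaled = CountTable("out10", {k: 10 * v for k, v in to.counts.items()}, 600, 600, 600)
        a = dq.enrichment(ti, to, ["w1", "w2"]).table["normalized_score"]
        b = dq.enrichment(ti, scaled, ["w1", "w2"]).table["normalized_score"]
        assert np.allclose(a, b)


class TestCouplingQC:
    def test_fraction_correct(self, small_manifest):
        p19 = end_model.primer19("left")
        v = small_manifest.variants[0]
        other = small_manifest.variants[1]
        r1 = [p19 + v.barcode + "AAAA"] * 3
        r2 = [v.end_sequence, v.end_sequence, other.end_sequence]
        rep = dq.coupling_qc(zip(r1, r2), small_manifest, p19)
        row = rep.per_variant.set_index("variant_id").loc[v.variant_id]
        assert row["n_pairs"] == 3
        assert row["fraction_correct"] == pytest.approx(2 / 3)
        assert row["most_abundant_incorrect_fraction"] == pytest.approx(1 / 3)

    def test_unmatched_barcode_excluded_and_counted(self, small_manifest):
        p19 = end_model.primer19("left")
        rep = dq.coupling_qc([(p19 + "ACGTACGTAC", "ACGT")], small_manifest, p19)
        assert rep.n_pairs == 0 and rep.n_excluded == 1
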