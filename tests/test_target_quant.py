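"""Integration-distance calling, 8-mer enrichment, logo pooling, prediction."""
import math
from collections import Counter

import numpy as np
import pytest

from castlib import simulate as sim
from castlib import target_quant as tq
from castlib.target_quant import (
    DEG_START,
    REL_LABELS,
    IntegrationCall,
    degenerate_enrichment,
)


@pytest.fixture(scope="module")
def ctx():
    return tq.make_target_context("A")


@pytest.fixture(scope="module")
def small_sim():
    return sim.simulate_target_reads(None, 2_000, 4_000, targets=("A",), seed=13)["A"]


class TestFiltering:
    def test_exact_anchor_passes(self, ctx):
        read = ctx.i5_anchors[34] + "ACGTACGT" + "A" * 40
        assert tq.filter_target_read(read, ctx.i5_anchors) == 34

    def test_one_mismatch_rejected(self, ctx):
        a = ctx.i5_anchors[34]
        bad = ("A" if a[0] != "A" else "C") + a[1:]
        assert tq.filter_target_read(bad + "A" * 40, ctx.i5_anchors) is None

    def test_diversity_anchor_passes(self, ctx):
        read = ctx.i5_anchors[35] + "ACGTACGT" + "A" * 40
        assert tq.filter_target_read(read, ctx.i5_anchors) == 35


class TestCalling:
    def test_planted_call_recovered(self, small_sim):
        """A simulated read with planted d=49 T-RL is called (49, T-RL, right)."""
        s = small_sim
        idx = next(
            k for k in range(len(s.output_pairs))
            if s.true_distances[k] == 49 and s.true_orientations[k] == "T-RL"
        )
        call, status = tq.call_integration(*s.output_pairs[idx], s.context)
        assert status == "ok"
        assert (call.distance, call.orientation, call.end_detected) == (49, "T-RL", "right")
        assert call.degenerate_8mer == s.true_8mers[idx]

    def test_read_without_end_match_is_nocall(self, small_sim):
        i5, i7 = small_sim.input_pairs[0]  # unintegrated read
        call, status = tq.call_integration(i5, i7, small_sim.context)
        assert call is None and status == "no_match"

    def test_unanchored_read_rejected(self, ctx):
        call, status = tq.call_integration("A" * 90, "C" * 90, ctx)
        assert call is None and status == "filter_i5"

    def test_call_validation(self):
        with pytest.raises(ValueError, match="outside"):
            IntegrationCall(60, "T-RL", "right", "ACGTACGT", "A")
        with pytest.raises(ValueError, match="orientation"):
            IntegrationCall(49, "RL", "right", "ACGTACGT", "A")


class TestEnrichment:
    def test_textbook_fold_change(self):
        input_counts = Counter({"AAAAAAAA": 1})
        for i in range(399):
            input_counts[f"F{i:07d}"] += 1  # distinct filler 8-mers
        calls = [IntegrationCall(49, "T-RL", "right", "AAAAAAAA", "A")] * 4
        calls += [IntegrationCall(50, "T-RL", "right", "CCCCCCCC", "A")] * 396
        # only real DNA keys participate; replace filler with valid 8-mers
        input_counts = Counter({"AAAAAAAA": 1, "CCCCCCCC": 399})
        enr = degenerate_enrichment(input_counts, calls)
        row = enr.table.set_index(["eight_mer", "distance"]).loc[("AAAAAAAA", 49)]
        assert row["log2_fold_change"] == pytest.approx(2.0)

    def test_missing_input_censored(self):
        input_counts = Counter({"CCCCCCCC": 10})
        calls = [IntegrationCall(49, "T-RL", "right", "AAAAAAAA", "A")]
        enr = degenerate_enrichment(input_counts, calls)
        row = enr.table.iloc[0]
        assert row["no_input"] and math.isnan(row["fold_change"])

    def test_totals_conserved_against_brute_force(self, small_sim):
        """Aggregated output counts re-sum to the call list (oracle recount)."""
        calls, _ = tq.call_integrations(small_sim.output_pairs[:2000], small_sim.context)
        enr = degenerate_enrichment(Counter({"A" * 8: 1}), calls)
        brute = Counter((c.degenerate_8mer, c.distance) for c in calls)
        table = enr.table.set_index(["eight_mer", "distance"])["output_count"]
        assert table.to_dict() == dict(brute)
        assert enr.n_output_total == len(calls)


class TestLogoPooling:
    def test_single_sequence_full_information(self):
        calls = [IntegrationCall(50, "T-RL", "right", "ACGTACGT", "A")] * 5
        enr = degenerate_enrichment(Counter({"ACGTACGT": 1, "GGGGGGGG": 99}), calls)
        pfm = tq.build_logo(enr, threshold=4.0, top_k=5000)
        covered = pfm.n_observations[pfm.n_observations > 0]
        ics = pfm.information_content[covered.index]
        assert np.allclose(ics, 2.0)
        assert 1 in pfm.shortfall or 0 in pfm.shortfall  # fewer than top_k survivors

    def test_count_conservation(self, small_sim):
        """Column sums equal the number of selected records covering each
        position (independent recount)."""
        calls, _ = tq.call_integrations(small_sim.output_pairs, small_sim.context)
        pfm = tq.pfm_from_calls(calls)
        expected = {lab: 0 for lab in REL_LABELS}
        for c in calls:
            for k in range(8):
                rel = DEG_START + k - (c.distance - 8)
                if 0 <= rel < 11:
                    expected[REL_LABELS[rel]] += 1
        assert pfm.n_observations.to_dict() == expected


class TestMotifDistance:
    def test_no_occurrence_excluded(self):
        calls = [IntegrationCall(49, "T-RL", "right", "AAAAAAAA", "A")]
        assert tq.motif_distance_distribution(calls, "CWG") == {}

    def test_classes_partition_by_offsets(self):
        calls = [
            IntegrationCall(46, "T-RL", "right", "CAGAAAAA", "A"),
            IntegrationCall(47, "T-RL", "right", "ACAGAAAA", "A"),
            IntegrationCall(46, "T-RL", "right", "CAGCTGAA", "A"),
        ]
        groups = tq.motif_distance_distribution(calls, "CWG")
        assert set(groups) == {(0,), (1,), (0, 3)}

    def test_two_occurrence_class_bimodal(self):
        """Under a strong central CWG model, 8-mers carrying the motif twice
        show two preferred distances."""
        res = sim.simulate_target_reads(sim.cwg_model(), 1_000, 60_000, targets=("A",), seed=17)
        calls, _ = tq.call_integrations(res["A"].output_pairs, res["A"].context)
        groups = tq.motif_distance_distribution(calls, "CWG")
        two = {k: v for k, v in groups.items() if len(k) == 2 and k[1] - k[0] >= 3 and v.sum() >= 80}
        assert two, "no populated two-occurrence class"
        k, dist = next(iter(two.items()))
        d1, d2 = 46 + k[0], 46 + k[1]
        between = [d for d in range(d1 + 1, d2)]
        assert dist.get(d1, 0) > max(dist.get(d, 0) for d in between)
        assert dist.get(d2, 0) > max(dist.get(d, 0) for d in between)


class TestPreferenceModel:
    def test_uniform_model_ties_broken_by_ascending_distance(self, ctx):
        uni = tq.InsertionPreferenceModel(sim.default_preference_model().weights * 0 + 0.25)
        seq = "A" * 70
        df = tq.predict_sites(uni, seq)
        scored = df[~df["skipped"]]
        assert (scored.sort_values("distance")["rank"].to_numpy() == np.arange(1, len(scored) + 1)).all()

    def test_planted_optimum_ranked_first(self):
        model = sim.default_preference_model()
        argmax = model.weights.idxmax(axis=1)
        rng = np.random.default_rng(5)
        seq = list("".join(rng.choice(list("ACGT"), 70)))
        d_star = 49
        for r, lab in enumerate(REL_LABELS):
            seq[d_star - 8 + r] = argmax[lab]
        df = tq.predict_sites(model, "".join(seq)).set_index("distance")
        assert df.loc[d_star, "rank"] == 1

    def test_disfavored_minus3_drops_rank(self):
        """Placing a disfavored base at the -3 position of one distance drops
        that distance below its (unchanged) neighbor."""
        model = sim.default_preference_model()
        seq = list("A" * 70)
        # indices 41..52 chosen so the windows of both d=49 and d=50 are
        # simultaneously optimal under the model (both scores maximal; the
        # tie then breaks to the smaller distance)
        seq[41:53] = list("AAAACTAGCAAA")
        base = tq.predict_sites(model, "".join(seq)).set_index("distance")
        s49, s50 = base.loc[49, "score"], base.loc[50, "score"]
        assert s49 == pytest.approx(s50)
        assert base.loc[49, "rank"] == 1 and base.loc[50, "rank"] == 2
        # poison -3 of d=49 (idx 41, outside d=50's window)
        seq[41] = "C"
        poisoned = tq.predict_sites(model, "".join(seq)).set_index("distance")
        drop = s49 - poisoned.loc[49, "score"]
        assert drop == pytest.approx(math.log(0.33 / 0.01))
        assert poisoned.loc[50, "score"] == pytest.approx(s50)
        assert poisoned.loc[49, "rank"] > poisoned.loc[50, "rank"]

    def test_short_sequence_skips_distances(self):
        model = sim.default_preference_model()
        df = tq.predict_sites(model, "A" * 50)
        assert df[df["distance"] > 47]["skipped"].all()

    def test_fit_weights_sum_to_one(self, small_sim):
        calls, _ = tq.call_integrations(small_sim.output_pairs[:1500], small_sim.context)
        model = tq.fit_preference_model(calls)
        assert np.allclose(model.weights.sum(axis=1), 1.0)

    def test_iupac_summary_reports_central_motif(self):
        model = sim.default_preference_model()
        summary = model.iupac_summary(min_frac=0.15)
        central = summary[4:7]  # TSD2..TSD4
        assert central == "YWR"
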