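"""Canned in-silico experiments at the screen's study conditions.

Each function wires the simulators to the quantification stages at fixed,
documented problem sizes and returns the measured quantities.  They are used
by the test-bench and by ``scripts/acceptance.py``; all are deterministic
given their seed.
"""
from __future__ import annotations

import numpy as np
import scipy.stats

from . import donor_quant as dq
from . import end_model
from . import library_design as ld
from . import simulate as sim
from . import target_quant as tq
from .aux_quant import classify_tn7


def standard_manifest(seed: int, side: str = "left", n_designed: int = 196) -> ld.VariantManifest:
    """A representative barcoded manifest (truncations + substitutions + TBS
    swaps) with the four WT spike-ins appended (``n_designed + 4`` members)."""
    fixture = end_model.wt_fixture()
    end = fixture.left_end if side == "left" else fixture.right_end
    pool = (
        ld.design_truncations(end, 2)
        + ld.design_substitutions(end, widths=(4,))
        + ld.design_tbs_variants(end, "identity")
    )
    if n_designed > len(pool):
        raise ValueError(f"only {len(pool)} designed variants available")
    return ld.assign_barcodes(pool[:n_designed], seed, wt_end=end.sequence)


def donor_recovery(
    seed: int,
    n_variants: int = 200,
    depth: int = 100_000,
    uncoupling: float = 0.35,
    error_rate: float = 1e-3,
) -> dict:
    """Parameter recovery for the donor screen.

    Simulates a barcoded library with planted log-uniform efficiencies at the
    given depth/noise and returns the Spearman correlation between planted
    efficiency and normalized enrichment score, plus the mean normalized
    score of the four WT members.
    """
    man = standard_manifest(seed, n_designed=n_variants - 4)
    truth = sim.make_truth(man, seed=seed, uncoupling_rate=uncoupling, error_rate=error_rate)
    ds = sim.simulate_donor_reads(man, truth, depth, depth)
    p19 = end_model.primer19(man.side)
    cin = dq.count_barcodes(ds.input_reads, man, p19, "input")
    cout = dq.count_barcodes(ds.output_reads, man, p19, "output")
    et = dq.enrichment(cin, cout, man.wt_ids)
    scores = et.scores()
    ids = [v.variant_id for v in man.variants]
    truth_eff = np.array([truth.efficiencies[i] for i in ids])
    est = np.array([scores[i] for i in ids])
    ok = ~np.isnan(est)
    rho = float(scipy.stats.spearmanr(truth_eff[ok], est[ok]).statistic)
    wt_mean = float(np.mean([scores[w] for w in man.wt_ids]))
    return {
        "spearman_rho": rho,
        "wt_mean_normalized": wt_mean,
        "n_variants": len(man),
        "manifest": man,
        "truth": truth,
        "enrichment": et,
    }


def coupling_estimate(
    seed: int,
    uncoupling: float = 0.35,
    n_pairs: int = 50_000,
) -> dict:
    """Recover a planted uncoupling rate from paired barcode/end reads."""
    man = standard_manifest(seed)
    truth = sim.make_truth(man, seed=seed, uncoupling_rate=uncoupling, error_rate=0.0)
    r1, r2 = sim.simulate_coupling_pairs(man, truth, n_pairs)
    report = dq.coupling_qc(zip(r1, r2), man, end_model.primer19(man.side))
    return {
        "overall_fraction_correct": report.overall_fraction_correct,
        "planted_coupled_fraction": 1.0 - uncoupling,
        "mean_most_abundant_incorrect": report.mean_most_abundant_incorrect,
        "report": report,
    }


def target_screen(
    seed: int,
    n_input: int = 1_000_000,
    n_output: int = 250_000,
    model: tq.InsertionPreferenceModel | None = None,
    targets=("A", "B"),
) -> dict:
    """Run the full degenerate-target screen for both libraries.

    Returns per-library enrichment tables, the pooled top-5000 logo, the
    number of four-fold-enriched records per library, and call QC.
    """
    if model is None:
        model = sim.default_preference_model()
    sims = sim.simulate_target_reads(model, n_input, n_output, targets=targets, seed=seed)
    prefixes = tq.default_end_prefixes()
    enrichments = []
    qc = {}
    calls_by_target = {}
    for name in targets:
        s = sims[name]
        calls, call_qc = tq.call_integrations(s.output_pairs, s.context, prefixes)
        in_counts, in_qc = tq.count_input_8mers([p[0] for p in s.input_pairs], s.context)
        enr = tq.degenerate_enrichment(in_counts, calls)
        t = enr.table
        qc[name] = {
            "calls": dict(call_qc),
            "input": dict(in_qc),
            "n_fourfold": int(((~t["no_input"]) & (t["fold_change"] >= 4.0)).sum()),
        }
        enrichments.append(enr)
        calls_by_target[name] = calls
    logo = tq.build_logo(enrichments, threshold=4.0, top_k=5000)
    return {
        "sims": sims,
        "enrichments": enrichments,
        "calls": calls_by_target,
        "logo": logo,
        "qc": qc,
        "model": model,
    }


def distance_call_accuracy(seed: int, n_reads: int = 10_000, target: str = "A") -> dict:
    """Fraction of error-free reads whose (distance, orientation) call equals
    the simulator's planted truth."""
    sims = sim.simulate_target_reads(
        sim.default_preference_model(), n_input=1000, n_output=n_reads,
        targets=(target,), seed=seed, error_rate=0.0,
    )
    s = sims[target]
    prefixes = tq.default_end_prefixes()
    n_ok = 0
    n_called = 0
    for k, (i5, i7) in enumerate(s.output_pairs):
        call, status = tq.call_integration(i5, i7, s.context, prefixes)
        if call is None:
            continue
        n_called += 1
        if (
            call.distance == int(s.true_distances[k])
            and call.orientation == s.true_orientations[k]
            and call.degenerate_8mer == s.true_8mers[k]
        ):
            n_ok += 1
    return {"n_reads": n_reads, "n_called": n_called, "n_correct": n_ok,
            "accuracy": n_ok / n_reads if n_reads else float("nan")}


def motif_shift(seed: int, n_reads: int = 100_000, target: str = "A", motif: str = "CWG") -> dict:
    """Modal called distance per single-occurrence motif placement.

    Under a model preferring the motif at the central TSD triplet, placing
    the motif ``k`` bases further into the degenerate block shifts the
    preferred integration distance by exactly ``k``.
    """
    model = sim.cwg_model()
    sims = sim.simulate_target_reads(model, n_input=1000, n_output=n_reads,
                                     targets=(target,), seed=seed)
    s = sims[target]
    calls, _ = tq.call_integrations(s.output_pairs, s.context)
    dists = tq.motif_distance_distribution(calls, motif)
    modal = {
        k[0]: int(v.idxmax()) for k, v in dists.items() if len(k) == 1 and v.sum() >= 50
    }
    return {"modal_distance_by_offset": modal, "distributions": dists, "calls": calls}


def refit_consistency(seed: int, n_reads: int = 100_000, target: str = "A") -> dict:
    """Simulate from a model and re-fit it from its own reads.

    The refit uses the unbiased all-calls estimator; reported is the maximum
    per-position total variation between planted and re-fitted weights.
    """
    model = sim.default_preference_model()
    sims = sim.simulate_target_reads(model, n_input=1000, n_output=n_reads,
                                     targets=(target,), seed=seed)
    s = sims[target]
    calls, _ = tq.call_integrations(s.output_pairs, s.context)
    refit = tq.fit_preference_model(calls, pseudocount=0.5)
    tv = 0.5 * (refit.weights - model.weights).abs().sum(axis=1)
    return {"max_tv": float(tv.max()), "tv": tv, "refit": refit}


def tn7_mixture(seed: int, n_reads: int = 20_000) -> dict:
    """Classify a simulated glmS amplicon mixture and recover its composition."""
    probs = {"unintegrated": 0.40, (0, "T-RL"): 0.35, (0, "T-LR"): 0.05}
    rest = 1.0 - sum(probs.values())
    for d in range(1, 31):
        probs[(d, "T-RL")] = rest / 30
    reads = sim.simulate_tn7_reads(n_reads, probs, seed=seed)
    table = classify_tn7(reads)
    modal = max(table.counts, key=table.counts.get)
    return {"table": table, "planted": probs, "modal_class": modal,
            "integrated_fraction": table.integrated_fraction,
            "unclassified": table.unclassified}
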