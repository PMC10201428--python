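"""Synthetic-read simulators with recorded ground truth.

Every analysis stage in the package can be exercised on reads produced here:

* donor junction amplicons — [end-proximal 15 nt][19-nt primer][10-nt
  barcode][cargo stub], with per-variant log-normal input abundances,
  multiplicative integration efficiencies in the output, barcode uncoupling
  (PCR recombination) and uniform per-base substitution errors;
* long paired reads linking barcode (read 1) and full end sequence (read 2)
  for coupling QC;
* degenerate target-library amplicons (i5/i7 pairs) in which the
  integration distance and the degenerate bases are drawn jointly from a
  TSD-relative nucleotide-preference model, so that the per-position base
  frequencies among output reads are exactly the model weights at covered
  positions;
* Tn7 glmS amplicons (unintegrated, or integrated 0-30 bp downstream in
  either orientation).

All simulators are deterministic given their seed.  Primer-derived bases
(anchors, the 19-nt donor primer) are written verbatim into reads, as PCR
primers overwrite the template in real amplicons.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import add_errors, decode_rows, encode, revcomp
from . import aux_quant, end_model, target_quant
from .library_design import VariantManifest
from .target_quant import (
    DEG_END,
    DEG_LEN,
    DEG_START,
    DISTANCE_WINDOW,
    I7_FIXED_START,
    READ_LEN,
    REL_LABELS,
    InsertionPreferenceModel,
    TargetContext,
    make_target_context,
    window_indices,
)

DONOR_PREFIX_LEN = 15
CARGO_STUB_LEN = 20


# -- ground truth ------------------------------------------------------------


@dataclass
class SimTruth:
    """Planted parameters for donor-library simulations.

    ``efficiencies`` are relative integration efficiencies (wild-type = 1);
    ``abundances`` are the (unnormalized) input plasmid abundances drawn
    log-normally with ``abundance_sigma``.
    """

    efficiencies: dict
    abundances: dict
    wt_ids: list
    uncoupling_rate: float = 0.0
    error_rate: float = 0.0
    abundance_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rate in (("uncoupling_rate", self.uncoupling_rate), ("error_rate", self.error_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        for w in self.wt_ids:
            if self.efficiencies.get(w) != 1.0:
                raise ValueError("wild-type members must have efficiency exactly 1")
        if any(e < 0 for e in self.efficiencies.values()):
            raise ValueError("efficiencies must be non-negative")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# uncoupling_rate={self.uncoupling_rate!r} error_rate={self.error_rate!r} "
                f"abundance_sigma={self.abundance_sigma!r} seed={self.seed}\n"
            )
            fh.write(f"# wt_ids={','.join(self.wt_ids)}\n")
            fh.write("variant_id\tabundance\tefficiency\n")
            for vid in self.efficiencies:
                fh.write(f"{vid}\t{self.abundances[vid]!r}\t{self.efficiencies[vid]!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "SimTruth":
        params: dict = {}
        wt_ids: list[str] = []
        eff: dict = {}
        ab: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# wt_ids="):
                    wt_ids = line.split("=", 1)[1].split(",")
                elif line.startswith("# "):
                    for tok in line[2:].split():
                        k, v = tok.split("=")
                        params[k] = float(v) if k != "seed" else int(v)
                elif line and not line.startswith("variant_id"):
                    vid, a, e = line.split("\t")
                    ab[vid] = float(a)
                    eff[vid] = float(e)
        return cls(eff, ab, wt_ids, params["uncoupling_rate"], params["error_rate"],
                   params["abundance_sigma"], params["seed"])


def make_truth(
    manifest: VariantManifest,
    seed: int = 0,
    uncoupling_rate: float = 0.0,
    error_rate: float = 0.0,
    abundance_sigma: float = 1.0,
    efficiency_range: tuple[float, float] = (0.01, 10.0),
    efficiencies: dict | None = None,
) -> SimTruth:
    """Draw a ground-truth record for a manifest.

    Non-wild-type efficiencies are log-uniform over ``efficiency_range``
    unless given explicitly; the four wild-type members are fixed at 1.
    """
    rng = np.random.default_rng(seed)
    wt = set(manifest.wt_ids)
    ids = [v.variant_id for v in manifest.variants]
    ab = {vid: float(a) for vid, a in zip(ids, np.exp(rng.normal(0.0, abundance_sigma, len(ids))))}
    if efficiencies is None:
        lo, hi = (math.log10(x) for x in efficiency_range)
        eff = {vid: (1.0 if vid in wt else float(10 ** rng.uniform(lo, hi))) for vid in ids}
    else:
        eff = {vid: (1.0 if vid in wt else float(efficiencies[vid])) for vid in ids}
    return SimTruth(eff, ab, sorted(wt), uncoupling_rate, error_rate, abundance_sigma, seed)


# -- donor junction amplicons ------------------------------------------------


def _donor_template(end_sequence: str, side: str) -> str:
    """Constant part of a junction read up to the barcode slot.

    The last 19 nt are the primer-derived anchor (written verbatim); the 15
    bases before it come from the variant's own end sequence (filler-padded
    for very short ends).
    """
    p19 = end_model.primer19(side)
    padded = (end_model._filler(40) + end_sequence)[-(DONOR_PREFIX_LEN + 19):]
    return padded[:DONOR_PREFIX_LEN] + p19


@dataclass
class DonorSim:
    input_reads: list
    output_reads: list
    truth: SimTruth
    manifest: VariantManifest


def _uncoupled_barcodes(
    idx: np.ndarray, probs: np.ndarray, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Barcode indices after PCR recombination: with probability ``rate`` a
    read's barcode is re-drawn from *another* variant, proportional to input
    abundance."""
    bidx = idx.copy()
    if rate <= 0 or len(idx) == 0:
        return bidx
    mask = rng.random(len(idx)) < rate
    k = int(mask.sum())
    if k == 0:
        return bidx
    draw = rng.choice(len(probs), size=k, p=probs)
    own = idx[mask]
    coll = draw == own
    while coll.any():
        draw[coll] = rng.choice(len(probs), size=int(coll.sum()), p=probs)
        coll = draw == own
    bidx[mask] = draw
    return bidx


def _assemble_donor(
    manifest: VariantManifest,
    var_idx: np.ndarray,
    bc_idx: np.ndarray,
    error_rate: float,
    rng: np.random.Generator,
) -> list[str]:
    cargo = end_model.wt_fixture().cargo[:CARGO_STUB_LEN]
    tmpl = np.stack([encode(_donor_template(v.end_sequence, v.side)) for v in manifest.variants])
    bc = np.stack([encode(v.barcode) for v in manifest.variants])
    stub = encode(cargo)
    n = len(var_idx)
    reads = np.empty((n, tmpl.shape[1] + 10 + CARGO_STUB_LEN), dtype=np.uint8)
    reads[:, : tmpl.shape[1]] = tmpl[var_idx]
    reads[:, tmpl.shape[1] : tmpl.shape[1] + 10] = bc[bc_idx]
    reads[:, tmpl.shape[1] + 10 :] = stub
    reads = add_errors(reads, error_rate, rng)
    return decode_rows(reads)


def simulate_donor_reads(
    manifest: VariantManifest,
    truth: SimTruth,
    n_input: int,
    n_output: int,
    seed: int | None = None,
) -> DonorSim:
    """Simulate input and output junction libraries.

    Input reads are multinomial over the planted abundances; output reads
    over abundance x efficiency.  Uncoupling and per-base errors apply to
    both samples.
    """
    if not manifest.variants:
        raise ValueError("empty manifest")
    if n_input <= 0 or n_output <= 0:
        raise ValueError("read counts must be positive")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    ids = [v.variant_id for v in manifest.variants]
    a = np.array([truth.abundances[i] for i in ids])
    e = np.array([truth.efficiencies[i] for i in ids])
    p_in = a / a.sum()
    w = a * e
    if w.sum() <= 0:
        raise ValueError("all variants have zero output weight")
    p_out = w / w.sum()
    reads = {}
    for tag, n, p in (("input", n_input, p_in), ("output", n_output, p_out)):
        idx = rng.choice(len(ids), size=n, p=p)
        bidx = _uncoupled_barcodes(idx, p_in, truth.uncoupling_rate, rng)
        reads[tag] = _assemble_donor(manifest, idx, bidx, truth.error_rate, rng)
    return DonorSim(reads["input"], reads["output"], truth, manifest)


def simulate_coupling_pairs(
    manifest: VariantManifest,
    truth: SimTruth,
    n: int,
    seed: int | None = None,
) -> tuple[list[str], list[str]]:
    """Paired long reads: read 1 carries primer+barcode, read 2 the full end.

    A fraction ``1 - uncoupling_rate`` of pairs is concordant; uncoupled
    pairs carry the barcode of another variant drawn by abundance.
    """
    if n <= 0:
        raise ValueError("number of pairs must be positive")
    if not manifest.variants:
        raise ValueError("empty manifest")
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    ids = [v.variant_id for v in manifest.variants]
    a = np.array([truth.abundances[i] for i in ids])
    p_in = a / a.sum()
    idx = rng.choice(len(ids), size=n, p=p_in)
    bidx = _uncoupled_barcodes(idx, p_in, truth.uncoupling_rate, rng)
    side = manifest.side
    p19 = end_model.primer19(side)
    stub = end_model.wt_fixture().cargo[:CARGO_STUB_LEN]
    r1_mat = np.empty((n, 19 + 10 + CARGO_STUB_LEN), dtype=np.uint8)
    r1_mat[:, :19] = encode(p19)
    bc = np.stack([encode(v.barcode) for v in manifest.variants])
    r1_mat[:, 19:29] = bc[bidx]
    r1_mat[:, 29:] = encode(stub)
    r1_mat = add_errors(r1_mat, truth.error_rate, rng)
    read1 = decode_rows(r1_mat)
    ends = [v.end_sequence for v in manifest.variants]
    if truth.error_rate > 0:
        from ._seq import mutate_string

        read2 = [mutate_string(ends[i], truth.error_rate, rng) for i in idx]
    else:
        read2 = [ends[i] for i in idx]
    return read1, read2


# -- degenerate target libraries ---------------------------------------------


def default_preference_model() -> InsertionPreferenceModel:
    """The planted TSD-relative preference model.

    Encodes the documented integration-site biases: a central YWR motif
    within the 5-nt TSD (pyrimidine / weak / purine at TSD2-TSD4), plus D
    (not C) at the -3 and H (not G) at the +3 flanking positions.  Weight
    sharpness was fixed by exact enumeration of the induced output
    distribution over all 8-mers x distances so that simulated libraries at
    the default depths operate in the screen's regime (>= 5000 four-fold
    enriched records per library).
    """
    w = {
        "-3": (0.33, 0.01, 0.33, 0.33),
        "-2": (0.25, 0.25, 0.25, 0.25),
        "-1": (0.25, 0.25, 0.25, 0.25),
        "TSD1": (0.32, 0.32, 0.32, 0.04),
        "TSD2": (0.01, 0.49, 0.01, 0.49),
        "TSD3": (0.49, 0.01, 0.01, 0.49),
        "TSD4": (0.49, 0.01, 0.49, 0.01),
        "TSD5": (0.04, 0.32, 0.32, 0.32),
        "+1": (0.25, 0.25, 0.25, 0.25),
        "+2": (0.25, 0.25, 0.25, 0.25),
        "+3": (0.33, 0.33, 0.01, 0.33),
    }
    df = pd.DataFrame(w, index=["A", "C", "G", "T"]).T
    return InsertionPreferenceModel(df)


def cwg_model(strength: float = 0.85) -> InsertionPreferenceModel:
    """A sharp model preferring 5'-CWG-3' at the central TSD triplet."""
    rest = (1.0 - strength) / 3.0
    half = (1.0 - 2 * rest) / 2.0
    uni = (0.25,) * 4
    w = {lab: uni for lab in REL_LABELS}
    w["TSD2"] = (rest, strength, rest, rest)
    w["TSD3"] = (half, rest, rest, half)
    w["TSD4"] = (rest, rest, strength, rest)
    df = pd.DataFrame(w, index=["A", "C", "G", "T"]).T
    return InsertionPreferenceModel(df)


def distance_distribution(
    model: InsertionPreferenceModel,
    context: TargetContext,
    prior: np.ndarray | None = None,
) -> pd.Series:
    """Marginal integration-distance distribution induced by the model.

    ``P(d)`` is proportional to the product, over window positions occupied
    by *fixed* plasmid bases, of the model weight relative to the uniform
    background (``w / 0.25``), times an optional prior.  Degenerate
    positions integrate out, so a uniform model yields a uniform distance
    distribution, and given ``d`` the window-covered degenerate bases are
    drawn exactly from the per-position weights.
    """
    lo, hi = DISTANCE_WINDOW
    ds = np.arange(lo, hi + 1)
    if prior is None:
        prior = np.ones(len(ds))
    probs = np.asarray(prior, dtype=float).copy()
    for i, d in enumerate(ds):
        for r, idx in enumerate(window_indices(d)):
            if DEG_START <= idx < DEG_END:
                continue
            probs[i] *= model.weights.at[REL_LABELS[r], context.downstream[idx]] / 0.25
    if probs.sum() <= 0:
        raise ValueError("degenerate distance distribution")
    return pd.Series(probs / probs.sum(), index=ds, name="p")


@dataclass
class TargetSim:
    context: TargetContext
    input_pairs: list
    output_pairs: list
    true_distances: np.ndarray
    true_orientations: list
    true_8mers: list
    model: InsertionPreferenceModel


def _sample_deg_bases(
    d_arr: np.ndarray, model: InsertionPreferenceModel, rng: np.random.Generator
) -> np.ndarray:
    """Degenerate 8-mer codes per read: window-covered positions follow the
    model weights given the read's distance, the rest are uniform."""
    n = len(d_arr)
    codes = rng.integers(0, 4, (n, DEG_LEN), dtype=np.uint8)
    wmat = model.weights.to_numpy()  # (11, 4), row order REL_LABELS
    for d in np.unique(d_arr):
        sel = np.where(d_arr == d)[0]
        w0 = d - 8
        for k in range(DEG_LEN):
            rel = DEG_START + k - w0
            if 0 <= rel < len(REL_LABELS):
                codes[sel, k] = rng.choice(4, size=len(sel), p=wmat[rel])
    return codes


def simulate_target_reads(
    model: InsertionPreferenceModel | None = None,
    n_input: int = 100_000,
    n_output: int = 100_000,
    targets=("A", "B"),
    p_trl: float = 0.9,
    error_rate: float = 0.0,
    seed: int = 0,
    fixture=None,
) -> dict[str, TargetSim]:
    """Simulate degenerate target libraries for each target.

    Input plasmids carry uniform random 8-mers.  Output reads draw the pair
    (distance, 8-mer) jointly from the preference model over the 11-nt
    TSD-relative window (flanking fixed plasmid bases weigh the distance
    marginal), the orientation from a Bernoulli(p_trl) for T-RL, and both i5
    and i7 reads are emitted with 34/35- and 45/46-nt anchors in equal
    proportion.
    """
    if model is None:
        model = default_preference_model()
    if n_input <= 0 or n_output <= 0:
        raise ValueError("read counts must be positive")
    if fixture is None:
        fixture = end_model.wt_fixture()
    prox = {
        "T-RL": fixture.right_end.sequence + fixture.cargo,
        "T-LR": fixture.left_end.sequence + fixture.cargo,
    }
    dist = {"T-RL": prox["T-LR"], "T-LR": prox["T-RL"]}
    out: dict[str, TargetSim] = {}
    for ti, name in enumerate(targets):
        rng = np.random.default_rng([seed, ti])
        ctx = make_target_context(name)
        down = ctx.downstream
        seg59_fixed = down[50:I7_FIXED_START]  # indices 50..58

        def fill59(eight: str, j0: int) -> str:
            return down[j0:DEG_START] + eight + seg59_fixed

        # input libraries: uniform 8-mers
        in_codes = rng.integers(0, 4, (n_input, DEG_LEN), dtype=np.uint8)
        in_8 = decode_rows(in_codes)
        a5 = rng.integers(34, 36, n_input)
        a7 = rng.integers(45, 47, n_input)
        input_pairs = []
        for k in range(n_input):
            al5, al7 = int(a5[k]), int(a7[k])
            i5 = ctx.i5_anchors[al5] + in_8[k] + down[DEG_END : DEG_END + READ_LEN - al5 - DEG_LEN]
            j0 = I7_FIXED_START - (READ_LEN - al7)
            i7 = ctx.i7_anchors[al7] + revcomp(fill59(in_8[k], j0))
            input_pairs.append((i5, i7))
        # output libraries: joint (distance, 8-mer) from the model
        pd_ = distance_distribution(model, ctx)
        d_arr = rng.choice(pd_.index.to_numpy(), size=n_output, p=pd_.to_numpy())
        codes = _sample_deg_bases(d_arr, model, rng)
        out_8 = decode_rows(codes)
        orient = np.where(rng.random(n_output) < p_trl, "T-RL", "T-LR")
        a5 = rng.integers(34, 36, n_output)
        a7 = rng.integers(45, 47, n_output)
        output_pairs = []
        for k in range(n_output):
            d = int(d_arr[k])
            o = orient[k]
            al5, al7 = int(a5[k]), int(a7[k])
            eight = out_8[k]
            seg = eight[: max(0, min(d, DEG_END) - DEG_START)] + down[DEG_END : max(DEG_END, d)]
            i5 = ctx.i5_anchors[al5] + seg + prox[o][: READ_LEN - al5 - len(seg)]
            body = revcomp((down[37:DEG_START] + eight + seg59_fixed)[d - 5 - 37 :])
            i7 = ctx.i7_anchors[al7] + body + dist[o][: READ_LEN - al7 - len(body)]
            output_pairs.append((i5, i7))
        if error_rate > 0:
            for pairs in (input_pairs, output_pairs):
                mat = np.stack([encode(r) for pair in pairs for r in pair])
                mat = add_errors(mat, error_rate, rng)
                dec = decode_rows(mat)
                pairs[:] = [(dec[2 * i], dec[2 * i + 1]) for i in range(len(pairs))]
        out[name] = TargetSim(ctx, input_pairs, output_pairs, d_arr, list(orient), out_8, model)
    return out


# -- Tn7 glmS amplicons ------------------------------------------------------


def simulate_tn7_reads(
    n: int,
    class_probs: dict,
    error_rate: float = 0.0,
    seed: int = 0,
    read_len: int = 80,
) -> list[str]:
    """Simulate glmS amplicons from a distribution over product classes.

    ``class_probs`` maps ``"unintegrated"`` or ``(distance, orientation)``
    (distance 0-30, orientation T-RL/T-LR) to probabilities summing to 1.
    Each read carries the expected 65-nt class prefix; construction rejects
    invalid classes or non-normalized probabilities.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    prefixes = aux_quant.tn7_expected_prefixes()
    lo, hi = aux_quant.TN7_OFFSET_RANGE
    for key, p in class_probs.items():
        if key != "unintegrated":
            if (
                not isinstance(key, tuple)
                or len(key) != 2
                or not lo <= key[0] <= hi
                or key[1] not in aux_quant.TN7_ORIENTATIONS
            ):
                raise ValueError(f"invalid Tn7 class {key!r}")
        if p < 0:
            raise ValueError("class probabilities must be non-negative")
    if abs(sum(class_probs.values()) - 1.0) > 1e-9:
        raise ValueError("class probabilities must sum to 1")
    rng = np.random.default_rng(seed)
    genome = aux_quant.tn7_reference_genome()
    fixture = end_model.wt_fixture()
    ends = {"T-RL": fixture.right_end.sequence, "T-LR": fixture.left_end.sequence}
    keys = list(class_probs)
    counts = rng.multinomial(n, [class_probs[k] for k in keys])
    reads: list[str] = []
    for key, c in zip(keys, counts):
        if c == 0:
            continue
        if key == "unintegrated":
            full = genome
        else:
            d, o = key
            g = aux_quant._TN7_INSERTION_BASE + d
            full = genome[:g] + ends[o] + fixture.cargo
        assert full[: aux_quant.TN7_PREFIX_LEN] == prefixes[key]
        reads.extend([full[:read_len]] * int(c))
    perm = rng.permutation(len(reads))
    reads = [reads[i] for i in perm]
    if error_rate > 0:
        mat = add_errors(np.stack([encode(r) for r in reads]), error_rate, rng)
        reads = decode_rows(mat)
    return reads
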