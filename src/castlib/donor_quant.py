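"""Donor-library quantification: barcode counting, enrichment and coupling QC.

Reads are filtered for a perfect match to the 19-bp primer-binding sequence
at the 3' terminus of the transposon end; the 10-nt barcode immediately
downstream identifies the library member.  Enrichment divides each member's
relative output abundance by its relative input abundance, and scores are
normalized by the mean fold-change of the four wild-type spike-in members so
a score of 1 means wild-type-like integration efficiency.

Coupling QC consumes long paired reads (barcode on read 1, full end sequence
on read 2) and quantifies PCR-recombination uncoupling: the fraction of
pairs whose end sequence exactly matches the manifest entry for their
barcode.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library_design import VariantManifest

BARCODE_LENGTH = 10
PRIMER_LENGTH = 19


def extract_barcode(read: str, primer19: str) -> str | None:
    """The 10 nt directly downstream of the first exact primer match.

    Returns ``None`` (reject) when the primer is absent or fewer than 10 nt
    remain; rejects are QC events, not errors.
    """
    if len(primer19) != PRIMER_LENGTH:
        raise ValueError(f"primer must be {PRIMER_LENGTH} nt")
    i = read.find(primer19)
    if i < 0:
        return None
    start = i + PRIMER_LENGTH
    bc = read[start : start + BARCODE_LENGTH]
    return bc if len(bc) == BARCODE_LENGTH else None


@dataclass
class CountTable:
    sample_id: str
    counts: dict
    n_total_reads: int
    n_pass_filter: int
    n_barcode_matched: int

    def __post_init__(self) -> None:
        total = sum(self.counts.values())
        if not total == self.n_barcode_matched <= self.n_pass_filter <= self.n_total_reads:
            raise ValueError("count-table QC invariant violated")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variant_id": list(self.counts), "count": list(self.counts.values())}
        )

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            fh.write(
                f"# sample={self.sample_id} n_total={self.n_total_reads} "
                f"n_pass_filter={self.n_pass_filter} n_matched={self.n_barcode_matched}\n"
            )
            self.to_frame().to_csv(fh, sep="\t", index=False)


def count_barcodes(
    reads,
    manifest: VariantManifest,
    primer19: str,
    sample_id: str = "sample",
) -> CountTable:
    """Exact-match barcode counting with QC tallies.

    Reads without a perfect primer match (or with <10 nt after it) fail the
    filter; reads whose extracted barcode is not in the manifest are
    discarded but counted.
    """
    bc_map = manifest.barcode_map()
    counts = {v.variant_id: 0 for v in manifest.variants}
    n_total = n_pass = n_match = 0
    for read in reads:
        n_total += 1
        bc = extract_barcode(read, primer19)
        if bc is None:
            continue
        n_pass += 1
        vid = bc_map.get(bc)
        if vid is None:
            continue
        n_match += 1
        counts[vid] += 1
    return CountTable(sample_id, counts, n_total, n_pass, n_match)


def merge_counts(t1: CountTable, t2: CountTable) -> CountTable:
    """Element-wise sum of two count tables (e.g. two NGS runs); QC summed."""
    keys = set(t1.counts) | set(t2.counts)
    counts = {k: t1.counts.get(k, 0) + t2.counts.get(k, 0) for k in sorted(keys)}
    return CountTable(
        f"{t1.sample_id}+{t2.sample_id}",
        counts,
        t1.n_total_reads + t2.n_total_reads,
        t1.n_pass_filter + t2.n_pass_filter,
        t1.n_barcode_matched + t2.n_barcode_matched,
    )


@dataclass
class EnrichmentTable:
    """Per-variant enrichment with wild-type normalization.

    ``table`` columns: input/output counts and fractions, fold_change,
    normalized_score (fold-change over the mean wild-type fold-change) and
    log2_normalized; variants unseen in the input are flagged ``undefined``.
    """

    table: pd.DataFrame
    wt_ids: list

    def scores(self) -> pd.Series:
        return self.table.set_index("variant_id")["normalized_score"]

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table.to_csv(fh, sep="\t", index=False)


def enrichment(
    input_table: CountTable,
    output_table: CountTable,
    wt_ids,
    pseudocount: float = 0.0,
) -> EnrichmentTable:
    """Fold-change of relative abundances, normalized to the WT spike-ins.

    No smoothing by default: variants with zero input counts get NaN scores
    and an ``undefined`` flag rather than a pseudocounted value
    (``pseudocount`` is available but off).  Raises ``ValueError`` if any WT
    member is absent from the input.
    """
    wt_ids = list(wt_ids)
    ids = sorted(set(input_table.counts) | set(output_table.counts))
    cin = np.array([input_table.counts.get(i, 0) for i in ids], dtype=float) + pseudocount
    cout = np.array([output_table.counts.get(i, 0) for i in ids], dtype=float) + pseudocount
    for w in wt_ids:
        if w not in input_table.counts or input_table.counts[w] <= 0:
            raise ValueError(f"WT member {w!r} absent from input library")
    if cin.sum() == 0 or cout.sum() == 0:
        raise ValueError("empty count table")
    in_frac = cin / cin.sum()
    out_frac = cout / cout.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(in_frac > 0, out_frac / in_frac, np.nan)
    pos = {v: i for i, v in enumerate(ids)}
    wt_fc = np.array([fc[pos[w]] for w in wt_ids])
    wt_mean = float(np.mean(wt_fc))
    if not wt_mean > 0:
        raise ValueError("mean WT fold-change is not positive; cannot normalize")
    norm = fc / wt_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        log2n = np.log2(norm)
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "input_count": cin,
            "output_count": cout,
            "input_fraction": in_frac,
            "output_fraction": out_frac,
            "fold_change": fc,
            "normalized_score": norm,
            "log2_normalized": log2n,
            "undefined": in_frac == 0,
        }
    )
    return EnrichmentTable(table, wt_ids)


@dataclass
class CouplingReport:
    per_variant: pd.DataFrame
    overall_fraction_correct: float
    mean_most_abundant_incorrect: float
    n_pairs: int
    n_excluded: int


def coupling_qc(pairs, manifest: VariantManifest, primer19: str) -> CouplingReport:
    """Barcode-to-end coupling QC from paired long reads.

    A pair is *correct* iff read 2 exactly matches the manifest end sequence
    of the variant identified by read 1's barcode.  Incorrect pairs are
    tallied by the end sequence they carry, and the most abundant incorrect
    sequence per variant is reported as a fraction of that variant's pairs.
    Pairs with unmatched barcodes are excluded and counted.
    """
    bc_map = manifest.barcode_map()
    end_by_id = manifest.end_by_id()
    n_pairs_v: Counter = Counter()
    n_correct_v: Counter = Counter()
    wrong_v: dict[str, Counter] = {}
    n_excluded = 0
    n_pairs = 0
    for r1, r2 in pairs:
        bc = extract_barcode(r1, primer19)
        vid = bc_map.get(bc) if bc is not None else None
        if vid is None:
            n_excluded += 1
            continue
        n_pairs += 1
        n_pairs_v[vid] += 1
        if r2 == end_by_id[vid]:
            n_correct_v[vid] += 1
        else:
            wrong_v.setdefault(vid, Counter())[r2] += 1
    rows = []
    for v in manifest.variants:
        vid = v.variant_id
        n = n_pairs_v[vid]
        frac = n_correct_v[vid] / n if n else math.nan
        mai = max(wrong_v[vid].values()) / n if n and vid in wrong_v else (0.0 if n else math.nan)
        rows.append((vid, n, frac, mai))
    df = pd.DataFrame(
        rows, columns=["variant_id", "n_pairs", "fraction_correct", "most_abundant_incorrect_fraction"]
    )
    overall = sum(n_correct_v.values()) / n_pairs if n_pairs else math.nan
    observed = df[df["n_pairs"] > 0]
    mean_mai = float(observed["most_abundant_incorrect_fraction"].mean()) if len(observed) else math.nan
    return CouplingReport(df, overall, mean_mai, n_pairs, n_excluded)
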