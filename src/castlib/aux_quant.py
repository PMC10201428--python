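"""Auxiliary quantification: qPCR efficiency, normalized fluorescence, and
Tn7 glmS amplicon classification.

qPCR transposition efficiency is ``2^dCq`` with ``dCq = Cq(reference) -
Cq(target)`` (reference gene *rssA*), so rarer integration products give
efficiencies below 1; replicates are averaged on the efficiency scale.

Tn7 amplicons are classified by an exact match of the first 65 bp of read
sequence against the expected products: the unintegrated genomic locus, or
integrations 0-30 bp downstream of the glmS attachment point in either
orientation (T-RL: right end proximal to the target side; T-LR: left end
proximal).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import random_dna
from . import end_model

# -- qPCR --------------------------------------------------------------------


@dataclass(frozen=True)
class QPCRRecord:
    orientation: str
    cq_target: float
    cq_reference: float

    def __post_init__(self) -> None:
        if self.cq_reference is None or (isinstance(self.cq_reference, float) and math.isnan(self.cq_reference)):
            raise ValueError("missing reference Cq")
        if self.cq_target is None or (isinstance(self.cq_target, float) and math.isnan(self.cq_target)):
            raise ValueError("missing target Cq")

    @property
    def delta_cq(self) -> float:
        return self.cq_reference - self.cq_target

    @property
    def efficiency(self) -> float:
        return 2.0 ** self.delta_cq


def qpcr_efficiency(records) -> dict[str, float]:
    """Mean transposition efficiency (2^dCq) per orientation across replicates.

    Replicates are averaged after exponentiation (efficiency scale), the
    default aggregation; average-then-exponentiate is available by
    aggregating ``delta_cq`` externally.
    """
    records = list(records)
    if not records:
        raise ValueError("no qPCR records")
    out: dict[str, list[float]] = {}
    for r in records:
        out.setdefault(r.orientation, []).append(r.efficiency)
    return {k: float(np.mean(v)) for k, v in out.items()}


def nfi(fluorescence, od600) -> np.ndarray:
    """Normalized fluorescence intensity: element-wise fluorescence / OD600."""
    f = np.asarray(fluorescence, dtype=float)
    od = np.asarray(od600, dtype=float)
    if f.shape != od.shape:
        raise ValueError("fluorescence and OD600 series differ in length")
    if (od <= 0).any():
        raise ValueError("OD600 values must be positive")
    return f / od


# -- Tn7 glmS classification -------------------------------------------------

TN7_PREFIX_LEN = 65
TN7_OFFSET_RANGE = (0, 30)
TN7_ORIENTATIONS = ("T-RL", "T-LR")
_TN7_GENOME_SEED = 70017
_TN7_INSERTION_BASE = 20  # genomic bases before the d=0 insertion point
TN7_GENOME_LEN = 160


def tn7_reference_genome() -> str:
    """Deterministic synthetic glmS-adjacent genomic context."""
    return random_dna(np.random.default_rng(_TN7_GENOME_SEED), TN7_GENOME_LEN)


def tn7_expected_prefixes(fixture: "end_model.MiniTransposon | None" = None) -> dict:
    """Expected 65-bp read prefixes per product class.

    Keys: ``"unintegrated"`` and ``(d, orientation)`` for d in 0..30.
    """
    if fixture is None:
        fixture = end_model.wt_fixture()
    genome = tn7_reference_genome()
    ends = {"T-RL": fixture.right_end.sequence, "T-LR": fixture.left_end.sequence}
    prefixes: dict = {"unintegrated": genome[:TN7_PREFIX_LEN]}
    lo, hi = TN7_OFFSET_RANGE
    for d in range(lo, hi + 1):
        g = _TN7_INSERTION_BASE + d
        for o, end_seq in ends.items():
            prefixes[(d, o)] = (genome[:g] + end_seq)[:TN7_PREFIX_LEN]
    if len(set(prefixes.values())) != len(prefixes):
        raise RuntimeError("expected Tn7 prefixes are not unique")
    return prefixes


@dataclass
class Tn7ClassTable:
    counts: dict
    n_reads: int
    unclassified: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) + self.unclassified != self.n_reads:
            raise ValueError("class counts plus unclassified must equal read total")

    @property
    def integrated_fraction(self) -> float:
        classified = sum(self.counts.values())
        if classified == 0:
            return math.nan
        integrated = sum(v for k, v in self.counts.items() if k != "unintegrated")
        return integrated / classified

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, v in self.counts.items():
            if k == "unintegrated":
                rows.append(("unintegrated", "", "", v))
            else:
                d, o = k
                rows.append(("integrated", d, o, v))
        df = pd.DataFrame(rows, columns=["class", "distance", "orientation", "count"])
        return df.sort_values(["class", "distance", "orientation"]).reset_index(drop=True)


def classify_tn7(reads, expected_prefixes: dict | None = None) -> Tn7ClassTable:
    """Partition reads by exact 65-bp prefix match; non-matching reads are
    counted as unclassified.  Each read contributes to exactly one tally."""
    if expected_prefixes is None:
        expected_prefixes = tn7_expected_prefixes()
    lookup = {v: k for k, v in expected_prefixes.items()}
    counts = {k: 0 for k in expected_prefixes}
    n = 0
    unclassified = 0
    for read in reads:
        n += 1
        cls = lookup.get(read[:TN7_PREFIX_LEN])
        if cls is None:
            unclassified += 1
        else:
            counts[cls] += 1
    return Tn7ClassTable(counts, n, unclassified)
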