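"""Degenerate target-library analysis.

A target plasmid carries a 32-bp crRNA-matched target followed by a
downstream region with an 8-bp fully degenerate block at distances 43-50
(1-based bp downstream of the target's 3' end).  After transposition, paired
amplicon reads are filtered by exact upstream anchors (34/35 nt on the i5
side, 45/46 nt on the i7 side), and the integration distance is called by
scanning the i5 read for a 20-nt transposon end prefix at distances 43-56;
the end identity fixes the orientation (right end at the upstream junction ->
T-RL, left end -> T-LR).  The degenerate 8-mer is reassembled from the i5
and/or i7 read depending on where the junction falls.

Coordinate conventions (fixed across the simulator and the caller):

* distance ``x`` (1-based) <-> 0-based downstream index ``x - 1``;
* the degenerate block occupies indices 42..49 (distances 43-50);
* integration at distance ``d`` places the transposon junction after index
  ``d - 1``; the 5-nt target-site duplication (TSD) spans distances
  ``d-4 .. d`` and the scored window adds 3-bp flanks on both sides
  (distances ``d-7 .. d+3``).

Enrichment per 8-mer follows the screen's estimator: relative abundance in
the output divided by relative abundance in the input, log2-transformed.
Logos pool only degenerate-derived bases from four-fold-enriched records,
top-``k`` per library ranked by enrichment.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import complement, random_dna, revcomp
from . import end_model
from .motif_tools import PositionFrequencyMatrix, iupac_scan

# -- coordinate system -------------------------------------------------------

DEG_START = 42          # 0-based downstream index of the degenerate block
DEG_LEN = 8
DEG_END = DEG_START + DEG_LEN
DISTANCE_WINDOW = (43, 56)
TSD_LENGTH = 5
FLANK = 3
END_MATCH_LEN = 20

#: TSD-relative position labels, tip of window to end: -3..-1 flank,
#: TSD1..TSD5, +1..+3 flank.
REL_LABELS = tuple(
    [f"-{FLANK - i}" for i in range(FLANK)]
    + [f"TSD{i + 1}" for i in range(TSD_LENGTH)]
    + [f"+{i + 1}" for i in range(FLANK)]
)
CENTRAL_TSD_LABELS = ("TSD2", "TSD3", "TSD4")

DOWNSTREAM_LEN = 110
I7_FIXED_START = 59     # i7 anchors cover indices 59..103 (45 nt) or 59..104
READ_LEN = 90

ORIENTATIONS = ("T-RL", "T-LR")


def window_indices(d: int) -> list[int]:
    """Downstream 0-based indices of the 11-nt scored window at distance ``d``."""
    return [d - 8 + r for r in range(len(REL_LABELS))]


# -- context -----------------------------------------------------------------


@dataclass(frozen=True)
class TargetContext:
    """Fixed plasmid context for one target library (A or B)."""

    name: str
    target32: str
    downstream: str  # DOWNSTREAM_LEN nt; 'N' placeholders at the degenerate block
    i5_anchors: dict
    i7_anchors: dict

    def plasmid_base(self, index: int) -> str:
        b = self.downstream[index]
        if b == "N":
            raise ValueError(f"index {index} lies in the degenerate block")
        return b

    def filled_downstream(self, eight_mer: str) -> str:
        if len(eight_mer) != DEG_LEN:
            raise ValueError("degenerate block must be 8 nt")
        return self.downstream[:DEG_START] + eight_mer + self.downstream[DEG_END:]


_CONTEXT_SEEDS = {"A": 230401, "B": 230402}

#: Fixed flank bases adjacent to the degenerate block.  Real targets show
#: one or two dominant integration distances set by the bases flanking the
#: insertion window; these fixtures emulate that by giving distances 48-49
#: favorable -3 (D = not C) and +3 (H = not G) flanks while competing
#: distances carry disfavored bases at informative window positions.
_FLANK_OVERRIDES = {
    "A": {35: "C", 36: "C", 37: "C", 38: "C", 39: "C", 40: "G", 41: "G",
          50: "A", 51: "A", 52: "G", 53: "G", 54: "G", 55: "G", 56: "G"},
    "B": {35: "C", 36: "C", 37: "C", 38: "C", 39: "C", 40: "G", 41: "G",
          50: "A", 51: "A", 52: "G", 53: "G", 54: "G", 55: "G", 56: "G"},
}


def make_target_context(name: str) -> TargetContext:
    """Deterministic synthetic plasmid context for target ``name``."""
    if name not in _CONTEXT_SEEDS:
        raise ValueError(f"unknown target {name!r}; expected one of {sorted(_CONTEXT_SEEDS)}")
    rng = np.random.default_rng(_CONTEXT_SEEDS[name])
    target32 = random_dna(rng, 32)
    down = list(random_dna(rng, DOWNSTREAM_LEN))
    down[DEG_START:DEG_END] = "N" * DEG_LEN
    for i, b in _FLANK_OVERRIDES[name].items():
        down[i] = b
    downstream = "".join(down)
    i5 = {34: downstream[8:DEG_START], 35: downstream[7:DEG_START]}
    i7 = {
        45: revcomp(downstream[I7_FIXED_START : I7_FIXED_START + 45]),
        46: revcomp(downstream[I7_FIXED_START : I7_FIXED_START + 46]),
    }
    return TargetContext(name, target32, downstream, i5, i7)


# -- filtering and calling ---------------------------------------------------


def filter_target_read(read: str, anchors: dict) -> int | None:
    """Return the matched anchor length if the read begins with an exact
    anchor of an accepted length, else ``None`` (reject)."""
    for length in sorted(anchors, reverse=True):
        if read.startswith(anchors[length]):
            return length
    return None


@dataclass(frozen=True)
class IntegrationCall:
    distance: int
    orientation: str
    end_detected: str  # 'left' | 'right'
    degenerate_8mer: str
    target: str

    def __post_init__(self) -> None:
        lo, hi = DISTANCE_WINDOW
        if not lo <= self.distance <= hi:
            raise ValueError(f"distance {self.distance} outside [{lo},{hi}]")
        if self.orientation not in ORIENTATIONS:
            raise ValueError(f"bad orientation {self.orientation!r}")
        if set(self.degenerate_8mer) - set("ACGT"):
            raise ValueError("degenerate 8-mer must be ACGT")


def _i5_offset(alen: int, index: int) -> int:
    return alen + (index - DEG_START)


def _i7_offset(alen: int, index: int) -> int:
    return alen + (I7_FIXED_START - 1 - index)


def call_integration(
    i5_read: str,
    i7_read: str,
    context: TargetContext,
    end_prefixes: dict | None = None,
) -> tuple[IntegrationCall | None, str]:
    """Call (distance, orientation, 8-mer) from one read pair.

    Returns ``(call, status)`` where status is one of ``ok``, ``filter_i5``,
    ``filter_i7``, ``no_match``, ``ambiguous``, ``truncated``.  Candidate
    distances are scanned in ascending order; the first exact 20-nt end match
    wins, and a simultaneous left+right match at that distance is discarded
    as ambiguous.
    """
    if end_prefixes is None:
        end_prefixes = default_end_prefixes()
    alen5 = filter_target_read(i5_read, context.i5_anchors)
    if alen5 is None:
        return None, "filter_i5"
    alen7 = filter_target_read(i7_read, context.i7_anchors)
    if alen7 is None:
        return None, "filter_i7"
    right20 = end_prefixes["right"]
    left20 = end_prefixes["left"]
    lo, hi = DISTANCE_WINDOW
    call_d = None
    orientation = end_det = None
    for d in range(lo, hi + 1):
        j = alen5 + (d - DEG_START)
        window = i5_read[j : j + END_MATCH_LEN]
        if len(window) < END_MATCH_LEN:
            break
        is_r = window == right20
        is_l = window == left20
        if is_r and is_l:
            return None, "ambiguous"
        if is_r or is_l:
            call_d = d
            orientation = "T-RL" if is_r else "T-LR"
            end_det = "right" if is_r else "left"
            break
    if call_d is None:
        return None, "no_match"
    bases = []
    for idx in range(DEG_START, DEG_END):
        if idx <= call_d - 1:
            off = _i5_offset(alen5, idx)
            if off >= len(i5_read):
                return None, "truncated"
            bases.append(i5_read[off])
        else:
            off = _i7_offset(alen7, idx)
            if off >= len(i7_read):
                return None, "truncated"
            bases.append(complement(i7_read[off]))
    eight = "".join(bases)
    if set(eight) - set("ACGT"):
        return None, "truncated"
    return IntegrationCall(call_d, orientation, end_det, eight, context.name), "ok"


def default_end_prefixes(fixture=None) -> dict:
    return {
        "left": end_model.end_prefix("left", END_MATCH_LEN, fixture),
        "right": end_model.end_prefix("right", END_MATCH_LEN, fixture),
    }


def call_integrations(
    read_pairs,
    context: TargetContext,
    end_prefixes: dict | None = None,
) -> tuple[list[IntegrationCall], Counter]:
    """Batch caller: returns the successful calls and a status tally."""
    if end_prefixes is None:
        end_prefixes = default_end_prefixes()
    calls: list[IntegrationCall] = []
    qc: Counter = Counter()
    for i5, i7 in read_pairs:
        call, status = call_integration(i5, i7, context, end_prefixes)
        qc[status] += 1
        if call is not None:
            calls.append(call)
    return calls, qc


def count_input_8mers(i5_reads, context: TargetContext) -> tuple[Counter, Counter]:
    """Count degenerate 8-mers in input-library i5 reads (anchor-filtered)."""
    counts: Counter = Counter()
    qc: Counter = Counter()
    for read in i5_reads:
        alen = filter_target_read(read, context.i5_anchors)
        if alen is None:
            qc["filter_i5"] += 1
            continue
        eight = read[alen : alen + DEG_LEN]
        if len(eight) < DEG_LEN or set(eight) - set("ACGT"):
            qc["truncated"] += 1
            continue
        counts[eight] += 1
        qc["ok"] += 1
    return counts, qc


# -- enrichment --------------------------------------------------------------


@dataclass
class DegenerateEnrichment:
    """Per-(8-mer, distance[, orientation]) enrichment against input abundance.

    ``table`` holds one row per observed output class with input/output
    counts, relative abundances and (log2) fold-change.  Records whose 8-mer
    was never seen in the input are flagged ``no_input`` and carry NaN
    fold-changes; 8-mers absent from the output are not materialised (their
    log2 fold-change is -inf, i.e. censored).
    """

    table: pd.DataFrame
    n_input_total: int
    n_output_total: int
    by_orientation: bool = False
    input_counts: Counter = field(default_factory=Counter)


def degenerate_enrichment(
    input_counts: Counter,
    calls,
    by_orientation: bool = False,
) -> DegenerateEnrichment:
    """Aggregate integration calls into per-(8-mer, distance) enrichment.

    The input abundance of an 8-mer is position-agnostic (the input library
    has no integration), so every output record of one 8-mer shares an input
    denominator.
    """
    n_in = sum(input_counts.values())
    if n_in == 0:
        raise ValueError("input library is empty")
    key = (lambda c: (c.degenerate_8mer, c.distance, c.orientation)) if by_orientation \
        else (lambda c: (c.degenerate_8mer, c.distance))
    out_counts = Counter(key(c) for c in calls)
    n_out = sum(out_counts.values())
    if n_out == 0:
        raise ValueError("no integration calls to aggregate")
    rows = []
    for k, c_out in out_counts.items():
        eight, dist = k[0], k[1]
        c_in = input_counts.get(eight, 0)
        out_frac = c_out / n_out
        in_frac = c_in / n_in
        fc = out_frac / in_frac if c_in > 0 else math.nan
        row = {
            "eight_mer": eight,
            "distance": dist,
            "output_count": c_out,
            "input_count": c_in,
            "output_fraction": out_frac,
            "input_fraction": in_frac,
            "fold_change": fc,
            "log2_fold_change": math.log2(fc) if fc and not math.isnan(fc) else math.nan,
            "no_input": c_in == 0,
        }
        if by_orientation:
            row["orientation"] = k[2]
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["fold_change", "eight_mer", "distance"], ascending=[False, True, True]
    ).reset_index(drop=True)
    return DegenerateEnrichment(table, n_in, n_out, by_orientation, Counter(input_counts))


# -- logo pooling ------------------------------------------------------------


def build_logo(
    enrichments,
    threshold: float = 4.0,
    top_k: int = 5000,
) -> PositionFrequencyMatrix:
    """Pool TSD-relative logos from one or more libraries.

    Per library: keep records with fold-change >= ``threshold``, rank by
    enrichment (ties broken lexicographically for determinism), take the top
    ``top_k`` across all integration positions, and map each record's
    degenerate bases into TSD-relative coordinates given its called distance.
    Only degenerate-derived bases contribute.  A shortfall (fewer than
    ``top_k`` survivors) is recorded on the returned PFM.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if isinstance(enrichments, DegenerateEnrichment):
        enrichments = [enrichments]
    acc = np.zeros((len(REL_LABELS), 4))
    shortfall = {}
    for li, enr in enumerate(enrichments):
        t = enr.table
        keep = t[(~t["no_input"]) & (t["fold_change"] >= threshold)]
        keep = keep.sort_values(
            ["fold_change", "eight_mer", "distance"], ascending=[False, True, True]
        ).head(top_k)
        if len(keep) < top_k:
            shortfall[li] = len(keep)
        _accumulate_rel_counts(acc, keep["eight_mer"].tolist(), keep["distance"].to_numpy())
    pfm = PositionFrequencyMatrix(
        pd.DataFrame(acc, index=list(REL_LABELS), columns=["A", "C", "G", "T"])
    )
    pfm.shortfall = shortfall
    return pfm


def _accumulate_rel_counts(acc: np.ndarray, eight_mers: list, distances: np.ndarray) -> None:
    """Accumulate degenerate-base counts into TSD-relative coordinates.

    For a record at distance ``d``, degenerate index ``DEG_START + k`` maps to
    relative slot ``DEG_START + k - (d - 8)`` when inside the 11-nt window.
    """
    from ._seq import encode

    if not eight_mers:
        return
    n = len(eight_mers)
    codes = encode("".join(eight_mers)).reshape(n, DEG_LEN)
    d = np.asarray(distances)[:, None]
    idx = np.arange(DEG_START, DEG_END)[None, :]
    rel = idx - (d - 8)
    ok = (rel >= 0) & (rel < len(REL_LABELS))
    np.add.at(acc, (rel[ok], codes[ok]), 1.0)


def pfm_from_calls(calls) -> PositionFrequencyMatrix:
    """TSD-relative PFM over *all* calls (no enrichment selection).

    This is the unbiased per-position base-frequency estimator used for
    model-consistency checks; ``build_logo`` applies the screen's four-fold /
    top-k selection instead.
    """
    acc = np.zeros((len(REL_LABELS), 4))
    calls = list(calls)
    _accumulate_rel_counts(
        acc, [c.degenerate_8mer for c in calls], np.array([c.distance for c in calls], dtype=int)
    )
    return PositionFrequencyMatrix(
        pd.DataFrame(acc, index=list(REL_LABELS), columns=["A", "C", "G", "T"])
    )


# -- motif-distance analysis -------------------------------------------------


def motif_distance_distribution(calls, motif: str = "CWG") -> dict:
    """Empirical integration-distance distribution per motif placement.

    Output calls are partitioned by the tuple of offsets at which ``motif``
    occurs within the 8-mer; single-occurrence classes are keyed ``(k,)`` and
    multi-occurrence classes by their full offset tuple.  8-mers without the
    motif are excluded.
    """
    groups: dict[tuple, Counter] = {}
    for c in calls:
        hits = iupac_scan(c.degenerate_8mer, motif)
        if not hits:
            continue
        key = tuple(h.start for h in hits)
        groups.setdefault(key, Counter())[c.distance] += 1
    return {
        k: pd.Series(v).sort_index().rename("n_reads") for k, v in sorted(groups.items())
    }


# -- preference model --------------------------------------------------------


@dataclass
class InsertionPreferenceModel:
    """TSD-relative nucleotide weights used to score candidate insertion sites.

    ``weights`` rows (one per REL_LABELS position) sum to 1.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        self.weights = self.weights.reindex(index=list(REL_LABELS), columns=["A", "C", "G", "T"])
        if self.weights.isna().any().any():
            raise ValueError("model must define weights for every position/base")
        sums = self.weights.sum(axis=1)
        if not np.allclose(sums, 1.0):
            raise ValueError("weights per position must sum to 1")

    @property
    def log_weights(self) -> pd.DataFrame:
        with np.errstate(divide="ignore"):
            return np.log(self.weights)

    def score_window(self, bases: str) -> float:
        if len(bases) != len(REL_LABELS):
            raise ValueError(f"window must be {len(REL_LABELS)} nt")
        lw = self.log_weights
        return float(sum(lw.at[lab, b] for lab, b in zip(REL_LABELS, bases)))

    def iupac_summary(self, min_frac: float = 0.15) -> str:
        """Minimal IUPAC code per position covering bases above ``min_frac``."""
        from .motif_tools import IUPAC_CODES

        inv = {v: k for k, v in IUPAC_CODES.items()}
        out = []
        for _, row in self.weights.iterrows():
            allowed = frozenset(b for b, w in row.items() if w >= min_frac) or frozenset("ACGT")
            out.append(inv[allowed])
        return "".join(out)


def fit_preference_model(
    source,
    threshold: float = 4.0,
    top_k: int = 5000,
    pseudocount: float = 0.5,
) -> InsertionPreferenceModel:
    """Fit TSD-relative weights from pooled logo frequencies.

    ``source`` may be a :class:`PositionFrequencyMatrix`, a
    :class:`DegenerateEnrichment` (or list of them; the screen's logo
    selection is applied first), or a list of calls.
    """
    if isinstance(source, PositionFrequencyMatrix):
        pfm = source
    elif isinstance(source, DegenerateEnrichment) or (
        isinstance(source, (list, tuple)) and source and isinstance(source[0], DegenerateEnrichment)
    ):
        pfm = build_logo(source, threshold=threshold, top_k=top_k)
    else:
        pfm = pfm_from_calls(source)
    counts = pfm.counts + pseudocount
    weights = counts.div(counts.sum(axis=1), axis=0)
    return InsertionPreferenceModel(weights)


def predict_sites(
    model: InsertionPreferenceModel,
    downstream_seq: str,
    window: tuple[int, int] = DISTANCE_WINDOW,
) -> pd.DataFrame:
    """Rank candidate integration distances along a concrete downstream sequence.

    ``downstream_seq`` is indexed so that 0-based index ``x - 1`` is distance
    ``x``; distances whose 11-nt window falls outside the sequence are
    skipped and reported with NaN scores.  Ties rank by ascending distance.
    """
    lo, hi = window
    rows = []
    for d in range(lo, hi + 1):
        idxs = window_indices(d)
        if idxs[0] < 0 or idxs[-1] >= len(downstream_seq):
            rows.append({"distance": d, "score": math.nan, "skipped": True})
            continue
        bases = "".join(downstream_seq[i] for i in idxs)
        rows.append({"distance": d, "score": model.score_window(bases), "skipped": False})
    df = pd.DataFrame(rows)
    scored = df[~df["skipped"]].sort_values(["score", "distance"], ascending=[False, True])
    df["rank"] = math.nan
    df.loc[scored.index, "rank"] = range(1, len(scored) + 1)
    return df.sort_values("distance").reset_index(drop=True)
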