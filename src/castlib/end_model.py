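"""Transposon-end architecture: domain types and the packaged WT fixture.

The model follows the canonical Tn7-family CAST end layout: each transposon
end starts with an 8-bp terminal end whose first two bases are the highly
conserved TG dinucleotide, followed by repeated 14-nt TnsB binding sites
(TBSs; L1-L3 on the left end, R1-R3 on the right).  The left end additionally
carries an integration host factor (IHF) consensus site
(``5'-WATCARNNNNTTR-3'``) between L1 and L2.

Coordinates are 0-based, half-open and transposon-centric: position 0 is the
first base of the terminal end, and both ends are stored tip-inward (5'->3'
from the transposon tip toward the cargo), so "TG" always sits at positions
0-1.

The native end sequences are not part of this package; ``make_wt_fixture``
builds a synthetic mini-transposon that satisfies every documented
architectural constraint (lengths, TBS count and conservation pattern, IHF
consensus placement, terminal TG) and is used throughout the test-bench.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from Bio.Data import CodonTable as _CodonTable

from ._seq import random_dna, revcomp
from .motif_tools import IUPACPattern, iupac_scan

# -- architectural constants -------------------------------------------------

LEFT_END_LENGTH = 147
RIGHT_END_LENGTH = 75
MINIMAL_RIGHT_LENGTH = 57
MINI_TN_LENGTH = 775
TERMINAL_END_LENGTH = 8
TBS_LENGTH = 14
FLANK_LENGTH = 5

#: 0-based TBS positions that are identical across all six binding sites
#: (positions 1, 6-8 and 12-14 in 1-based coordinates).
TBS_CONSERVED_POSITIONS = (0, 5, 6, 7, 11, 12, 13)

#: IUPAC consensus used to locate TBSs: conserved bases fixed, the rest N.
TBS_CONSENSUS = "CNNNNTGTNNNGCA"

IHF_CONSENSUS = "WATCARNNNNTTR"

#: The six fixture TBS sequences.  Conserved positions carry the consensus
#: base; every non-conserved position varies across the set so that the
#: TBS logo's fully conserved columns are exactly TBS_CONSERVED_POSITIONS.
TBS_SEQS: dict[str, str] = {
    "L1": "CATCATGTCACGCA",
    "L2": "CCGATTGTACGGCA",
    "L3": "CGCTGTGTGGTGCA",
    "R1": "CTGACTGTTAAGCA",
    "R2": "CACGATGTATCGCA",
    "R3": "CGATCTGTCCGGCA",
}

_LEFT_TERMINAL = "TGACGCAT"
#: Right terminal end; harbours a frame-3 TAA so that the minimal right end
#: encodes stop codons in all three reading frames (see linker_design).
_RIGHT_TERMINAL = "TGTAAAGT"

#: Embedded left-end IHF site: a perfect match to the 13-nt consensus.
IHF_SITE_SEQ = "TATCAGACGTTTA"

_FILLER_UNIT = "CACAACCA"

DEFAULT_FIXTURE_SEED = 6677


class Interval(NamedTuple):
    """Half-open [start, end) interval with a label, end-local coordinates."""

    start: int
    end: int
    label: str


class EndAnnotationError(ValueError):
    """Raised when a sequence cannot be annotated as a transposon end."""


# -- domain types ------------------------------------------------------------


@dataclass
class TransposonEndModel:
    side: str  # 'left' | 'right'
    sequence: str
    tbs_list: list[Interval]
    ihf_site: Interval | None = None

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.sequence[:2] != "TG":
            raise EndAnnotationError("no terminal TG")
        prev_end = 0
        for iv in self.tbs_list:
            if iv.start < prev_end:
                raise ValueError("TBS intervals overlap or are out of tip->interior order")
            if iv.end - iv.start != TBS_LENGTH:
                raise ValueError(f"TBS interval {iv} does not have length {TBS_LENGTH}")
            prev_end = iv.end
        if self.ihf_site is not None:
            if len(self.tbs_list) < 2:
                raise ValueError("IHF site requires at least two TBSs")
            if not (self.tbs_list[0].end <= self.ihf_site.start and self.ihf_site.end <= self.tbs_list[1].start):
                raise ValueError("IHF site must lie strictly between the first two TBSs")

    @property
    def terminal_end(self) -> str:
        return self.sequence[:TERMINAL_END_LENGTH]

    def tbs_sequences(self) -> dict[str, str]:
        return {iv.label: self.sequence[iv.start : iv.end] for iv in self.tbs_list}

    def annotation_table(self):
        import pandas as pd

        rows = [("terminal_end", 0, TERMINAL_END_LENGTH)]
        rows += [(iv.label, iv.start, iv.end) for iv in self.tbs_list]
        if self.ihf_site is not None:
            rows.append((self.ihf_site.label, self.ihf_site.start, self.ihf_site.end))
        return pd.DataFrame(rows, columns=["label", "start", "end"])


@dataclass
class MiniTransposon:
    """A mini transposon: left end + cargo + right end, plus 5-nt donor flanks.

    The top-strand element sequence reads the left end tip-inward, the cargo,
    then the reverse complement of the (tip-inward) right end.
    """

    left_end: TransposonEndModel
    cargo: str
    right_end: TransposonEndModel
    flank_5: str = ""
    flank_3: str = ""

    @property
    def total_length(self) -> int:
        return len(self.left_end.sequence) + len(self.cargo) + len(self.right_end.sequence)

    @property
    def sequence(self) -> str:
        return self.left_end.sequence + self.cargo + revcomp(self.right_end.sequence)

    @property
    def donor_context(self) -> str:
        return self.flank_5 + self.sequence + self.flank_3


STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: Average residue masses (Da) for the 20 standard amino acids and the mass
#: of one water molecule, used for expected protein sizes.
RESIDUE_AVG_MASS: dict[str, float] = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01524


def _standard_codon_map() -> dict[str, str]:
    table = _CodonTable.unambiguous_dna_by_id[1]
    mapping = dict(table.forward_table)
    for codon in table.stop_codons:
        mapping[codon] = "*"
    return mapping


@dataclass(frozen=True)
class GeneticCodeTable:
    codon_to_aa: dict[str, str] = field(default_factory=_standard_codon_map)
    stop_codons: frozenset[str] = STOP_CODONS
    residue_masses: dict[str, float] = field(default_factory=lambda: dict(RESIDUE_AVG_MASS))
    water_mass: float = WATER_MASS

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError("genetic code table must map all 64 codons")
        if len(self.stop_codons) != 3:
            raise ValueError("standard code has exactly 3 stop codons")

    def translate(self, dna: str, frame: int = 1) -> str:
        """Translate ``dna`` in reading frame 1, 2 or 3 (trailing bases dropped)."""
        if frame not in (1, 2, 3):
            raise ValueError("frame must be 1, 2 or 3")
        s = dna[frame - 1 :]
        return "".join(self.codon_to_aa[s[i : i + 3]] for i in range(0, len(s) - len(s) % 3, 3))


STANDARD_CODE = GeneticCodeTable()


# -- fixture construction ----------------------------------------------------


def _filler(n: int, phase: int = 0) -> str:
    unit = _FILLER_UNIT
    s = unit * (n // len(unit) + 2)
    return s[phase : phase + n]


def _clean_random(rng: np.random.Generator, n: int, context_before: str, context_after: str, patterns) -> str:
    """Draw a random segment whose insertion creates no new consensus matches."""
    for _ in range(200):
        seg = random_dna(rng, n)
        joined = context_before + seg + context_after
        if not any(iupac_scan(joined, p) for p in patterns if len(joined) >= len(p.pattern)):
            return seg
    raise RuntimeError("could not draw a consensus-free random segment")


def _assemble_left(rng: np.random.Generator) -> TransposonEndModel:
    tbs = TBS_SEQS
    parts = [
        _LEFT_TERMINAL,          # [0, 8)
        tbs["L1"],               # [8, 22)
        _filler(8),              # [22, 30)
        IHF_SITE_SEQ,            # [30, 43)
        _filler(7, phase=3),     # [43, 50)
        tbs["L2"],               # [50, 64)
        _filler(36, phase=1),    # [64, 100)
        tbs["L3"],               # [100, 114)
    ]
    head = "".join(parts)
    assert len(head) == 114
    patterns = [IUPACPattern(TBS_CONSENSUS), IUPACPattern(IHF_CONSENSUS)]
    tail = _clean_random(rng, LEFT_END_LENGTH - 114, head[-(TBS_LENGTH - 1) :], "", patterns)
    seq = head + tail
    intervals = [Interval(8, 22, "L1"), Interval(50, 64, "L2"), Interval(100, 114, "L3")]
    return TransposonEndModel("left", seq, intervals, ihf_site=Interval(30, 43, "IHF"))


def _assemble_right(rng: np.random.Generator) -> TransposonEndModel:
    tbs = TBS_SEQS
    parts = [
        _RIGHT_TERMINAL,         # [0, 8)
        tbs["R1"],               # [8, 22)
        _filler(8, phase=2),     # [22, 30)
        tbs["R2"],               # [30, 44)
        _filler(14, phase=5),    # [44, 58)
        tbs["R3"],               # [58, 72)
    ]
    head = "".join(parts)
    assert len(head) == 72
    patterns = [IUPACPattern(TBS_CONSENSUS), IUPACPattern(IHF_CONSENSUS)]
    tail = _clean_random(rng, RIGHT_END_LENGTH - 72, head[-(TBS_LENGTH - 1) :], "", patterns)
    seq = head + tail
    intervals = [Interval(8, 22, "R1"), Interval(30, 44, "R2"), Interval(58, 72, "R3")]
    return TransposonEndModel("right", seq, intervals)


def make_wt_fixture(seed: int = DEFAULT_FIXTURE_SEED) -> MiniTransposon:
    """Build the deterministic 775-bp WT mini-transposon fixture.

    Architecture: 147-nt left end (terminal TG end, L1-L3 TBSs, perfect IHF
    consensus match between L1 and L2), 553-nt cargo, 75-nt right end
    (terminal TG end, R1-R3 TBSs).  Identical seeds yield identical sequences.
    """
    rng = np.random.default_rng(seed)
    left = _assemble_left(rng)
    right = _assemble_right(rng)
    cargo_len = MINI_TN_LENGTH - LEFT_END_LENGTH - RIGHT_END_LENGTH
    cargo = random_dna(rng, cargo_len)
    flank_5 = random_dna(rng, FLANK_LENGTH)
    flank_3 = random_dna(rng, FLANK_LENGTH)
    mt = MiniTransposon(left, cargo, right, flank_5, flank_3)
    # construction-time invariants: the annotator must recover exactly the
    # planted architecture from sequence alone
    for end, n in ((left, 3), (right, 3)):
        found = annotate_end(end.sequence, end.side)
        assert [tuple(iv) for iv in found.tbs_list] == [tuple(iv) for iv in end.tbs_list]
        assert len(found.tbs_list) == n
    assert mt.total_length == MINI_TN_LENGTH
    return mt


def minimal_right_end(fixture: MiniTransposon | None = None) -> TransposonEndModel:
    """The minimal 57-nt right end: the WT right end truncated after R2."""
    if fixture is None:
        fixture = wt_fixture()
    seq = fixture.right_end.sequence[:MINIMAL_RIGHT_LENGTH]
    return annotate_end(seq, "right")


_WT_CACHE: dict[int, MiniTransposon] = {}


def wt_fixture(seed: int = DEFAULT_FIXTURE_SEED) -> MiniTransposon:
    """Cached accessor for the default WT fixture."""
    if seed not in _WT_CACHE:
        _WT_CACHE[seed] = make_wt_fixture(seed)
    return _WT_CACHE[seed]


# -- annotation --------------------------------------------------------------


def annotate_end(
    sequence: str,
    side: str,
    tbs_motif: str = TBS_CONSENSUS,
    min_sites: int | None = None,
) -> TransposonEndModel:
    """Annotate a transposon end by consensus scanning tip -> interior.

    TBS intervals are located as non-overlapping matches to ``tbs_motif``
    taken greedily from the tip; the left end additionally records the first
    IHF consensus match between the first two TBSs.  Raises
    :class:`EndAnnotationError` when the terminal TG is missing or fewer than
    the required number of TBSs are found (3 for the left end, 2 for the
    right end, overridable via ``min_sites``).
    """
    if len(sequence) < TERMINAL_END_LENGTH + len(tbs_motif):
        raise EndAnnotationError("sequence too short to be a transposon end")
    if sequence[:2] != "TG":
        raise EndAnnotationError("no terminal TG")
    if min_sites is None:
        min_sites = 3 if side == "left" else 2
    hits = iupac_scan(sequence, tbs_motif)
    intervals: list[Interval] = []
    cursor = TERMINAL_END_LENGTH
    prefix = "L" if side == "left" else "R"
    for h in hits:
        if h.start >= cursor:
            intervals.append(Interval(h.start, h.start + len(tbs_motif), f"{prefix}{len(intervals) + 1}"))
            cursor = h.start + len(tbs_motif)
    if len(intervals) < min_sites:
        raise EndAnnotationError(
            f"insufficient TBS matches: found {len(intervals)}, need {min_sites}"
        )
    ihf = None
    if side == "left" and len(intervals) >= 2:
        lo, hi = intervals[0].end, intervals[1].start
        inner = sequence[lo:hi]
        if len(inner) >= len(IHF_CONSENSUS):
            m = iupac_scan(inner, IHF_CONSENSUS)
            if m:
                s = lo + m[0].start
                ihf = Interval(s, s + len(IHF_CONSENSUS), "IHF")
    return TransposonEndModel(side, sequence, intervals, ihf_site=ihf)


def primer19(side: str, fixture: MiniTransposon | None = None) -> str:
    """The 19-bp primer-binding sequence at the 3' (interior) terminus of an end."""
    if fixture is None:
        fixture = wt_fixture()
    end = fixture.left_end if side == "left" else fixture.right_end
    return end.sequence[-19:]


def end_prefix(side: str, n: int = 20, fixture: MiniTransposon | None = None) -> str:
    """The first ``n`` tip-inward bases of an end (junction-detection probe)."""
    if fixture is None:
        fixture = wt_fixture()
    end = fixture.left_end if side == "left" else fixture.right_end
    return end.sequence[:n]
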