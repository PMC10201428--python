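"""IUPAC consensus scanning and position-frequency-matrix (sequence logo) tools.

These primitives back the transposase-binding-site annotation, the integration
host factor (IHF) consensus search (``5'-WATCARNNNNTTR-3'``), and the
target-site-duplication logos built by :mod:`castlib.target_quant`.

Information content follows the WebLogo convention for DNA: per column,
``IC = 2 - H`` bits where ``H`` is the Shannon entropy of the observed base
frequencies.  No small-sample correction is applied.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._seq import revcomp

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate-nucleotide pattern over the IUPAC alphabet."""

    pattern: str

    def __post_init__(self) -> None:
        bad = [c for c in self.pattern if c not in IUPAC_CODES]
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s) {bad!r} in pattern {self.pattern!r}")

    def __len__(self) -> int:
        return len(self.pattern)

    def matches(self, window: str) -> bool:
        return self.count_mismatches(window) == 0

    def count_mismatches(self, window: str) -> int:
        if len(window) != len(self.pattern):
            raise ValueError("window length differs from pattern length")
        return sum(b not in IUPAC_CODES[p] for b, p in zip(window, self.pattern))


@dataclass(frozen=True)
class MotifHit:
    start: int
    strand: str  # '+' or '-'
    n_mismatch: int


def iupac_scan(
    seq: str,
    pattern: str | IUPACPattern,
    both_strands: bool = False,
    max_mismatch: int = 0,
) -> list[MotifHit]:
    """Scan ``seq`` for windows compatible with an IUPAC ``pattern``.

    A sequence base matches a pattern symbol when it belongs to the symbol's
    IUPAC set.  Returns hits with 0-based start coordinates on the forward
    sequence; ``'-'``-strand hits report the start of the window on the
    forward strand whose reverse complement matches the pattern.
    """
    pat = pattern if isinstance(pattern, IUPACPattern) else IUPACPattern(pattern)
    k = len(pat)
    if len(seq) < k:
        raise ValueError("sequence shorter than pattern")
    hits = [
        MotifHit(i, "+", nm)
        for i in range(len(seq) - k + 1)
        if (nm := pat.count_mismatches(seq[i : i + k])) <= max_mismatch
    ]
    if both_strands:
        rc = revcomp(seq)
        hits += [
            MotifHit(len(seq) - i - k, "-", nm)
            for i in range(len(rc) - k + 1)
            if (nm := pat.count_mismatches(rc[i : i + k])) <= max_mismatch
        ]
    return sorted(hits, key=lambda h: (h.start, h.strand))


BASES = ("A", "C", "G", "T")


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts with WebLogo-style information content.

    ``counts`` is indexed by position label (a string or int; e.g. TSD-relative
    coordinates ``-3 .. +3``) with columns A, C, G, T.
    """

    counts: pd.DataFrame
    shortfall: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = self.counts.reindex(columns=list(BASES)).fillna(0.0)

    @classmethod
    def from_sequences(cls, seqs: Sequence[str], positions: Sequence | None = None) -> "PositionFrequencyMatrix":
        seqs = list(seqs)
        if not seqs:
            raise ValueError("at least one sequence required")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("sequences must have equal lengths")
        if positions is None:
            positions = list(range(L))
        elif len(positions) != L:
            raise ValueError("positions length differs from sequence length")
        counts = pd.DataFrame(0.0, index=list(positions), columns=list(BASES))
        arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(seqs), L)
        for j, pos in enumerate(positions):
            col, n = np.unique(arr[:, j], return_counts=True)
            for b, c in zip(col, n):
                counts.loc[pos, b.decode()] = float(c)
        return cls(counts)

    @property
    def n_observations(self) -> pd.Series:
        """Total observations per position (column sums of the count table)."""
        return self.counts.sum(axis=1)

    @property
    def probabilities(self) -> pd.DataFrame:
        tot = self.counts.sum(axis=1)
        return self.counts.div(tot.where(tot > 0), axis=0)

    @property
    def information_content(self) -> pd.Series:
        """Bits per position: 2 - Shannon entropy of the base frequencies."""
        p = self.probabilities.to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        h = -np.nansum(plogp, axis=1)
        ic = 2.0 - h
        ic[np.isnan(p).all(axis=1)] = np.nan
        return pd.Series(ic, index=self.counts.index, name="ic_bits")

    def supported_positions(self, min_frac: float = 0.05) -> list:
        """Positions whose observation count is at least ``min_frac`` of the
        best-covered position.  Information content at sparsely covered
        columns is dominated by small-sample noise and is not comparable."""
        n = self.n_observations
        if n.max() <= 0:
            return []
        return n[n >= min_frac * n.max()].index.tolist()

    def conserved_positions(self) -> list:
        """Positions where a single base accounts for every observation."""
        out = []
        for pos, row in self.counts.iterrows():
            tot = row.sum()
            if tot > 0 and (row == tot).any():
                out.append(pos)
        return out

    def to_tsv(self, path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            df = self.counts.copy()
            df.insert(0, "position", df.index)
            df["ic_bits"] = self.information_content.to_numpy()
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "PositionFrequencyMatrix":
        df = pd.read_csv(path, sep="\t", comment="#")
        df = df.set_index("position")
        return cls(df[list(BASES)].astype(float))

    def plot(self, ax=None):
        """Render a simple information-content logo (stacked letters by IC share)."""
        import matplotlib.pyplot as plt  # lazy; plotting is optional

        if ax is None:
            _, ax = plt.subplots(figsize=(0.6 * len(self.counts) + 1, 2.5))
        probs = self.probabilities
        ic = self.information_content
        colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
        for x, pos in enumerate(self.counts.index):
            y = 0.0
            order = probs.loc[pos].sort_values().items()
            for base, p in order:
                if p and p > 0:
                    h = p * ic[pos]
                    ax.bar(x, h, bottom=y, width=0.8, color=colors[base])
                    if h > 0.12:
                        ax.text(x, y + h / 2, base, ha="center", va="center", fontsize=8, color="white")
                    y += h
        ax.set_xticks(range(len(self.counts)))
        ax.set_xticklabels([str(p) for p in self.counts.index], rotation=0, fontsize=8)
        ax.set_ylabel("bits")
        ax.set_ylim(0, 2)
        return ax


def logo_from_sites(seqs: Sequence[str], positions: Sequence | None = None) -> PositionFrequencyMatrix:
    """Build a PFM from equal-length binding-site sequences.

    Raises ``ValueError`` on unequal lengths or an empty input.
    """
    return PositionFrequencyMatrix.from_sequences(seqs, positions=positions)
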