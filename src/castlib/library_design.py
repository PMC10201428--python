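"""Programmatic design of barcoded transposon-end variant libraries.

Reproduces the design *categories* of a pooled end-mutagenesis screen:
truncations (innermost bases replaced by neutral filler so the overall
mini-transposon size is unchanged), tiled substitutions (1/2/4-bp windows,
complemented), TnsB-binding-site identity swaps / spacing changes /
inversions / additions, and 10-nt barcode assignment with four wild-type
spike-in members per manifest.

The substitution rule (base-wise complement) and the truncation filler are
package design choices: complementing is a maximal, unambiguous perturbation,
and the filler is a fixed low-complexity A/C sequence that cannot create a
TBS or IHF consensus match (both consensi require T/G bases).
"""
from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import complement, revcomp
from .end_model import Interval, TransposonEndModel, _filler

BARCODE_LENGTH = 10
MIN_BARCODE_DISTANCE = 3
N_WT_MEMBERS = 4

CATEGORIES = (
    "wildtype", "truncation", "substitution", "tbs_identity", "tbs_spacing",
    "tbs_inversion", "tbs_addition", "terminal_end", "flank", "palindrome", "linker",
)


class BarcodeSpaceError(RuntimeError):
    """Raised when no further barcode at the required distance can be drawn."""


@dataclass
class EndVariant:
    variant_id: str
    side: str
    category: str
    end_sequence: str
    barcode: str | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if set(self.end_sequence) - set("ACGT"):
            raise ValueError("end_sequence must be over ACGT")
        if self.barcode is not None and len(self.barcode) != BARCODE_LENGTH:
            raise ValueError(f"barcode must be {BARCODE_LENGTH} nt")


MANIFEST_COLUMNS = ["variant_id", "side", "category", "end_sequence", "barcode", "description"]


@dataclass
class VariantManifest:
    variants: list[EndVariant]
    side: str

    @property
    def wt_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants if v.category == "wildtype"]

    def __len__(self) -> int:
        return len(self.variants)

    def barcode_map(self) -> dict[str, str]:
        return {v.barcode: v.variant_id for v in self.variants}

    def end_by_id(self) -> dict[str, str]:
        return {v.variant_id: v.end_sequence for v in self.variants}

    def validate(self) -> None:
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("variant_id values are not unique")
        bcs = [v.barcode for v in self.variants]
        if any(b is None for b in bcs):
            raise ValueError("manifest contains unassigned barcodes")
        mat = np.frombuffer("".join(bcs).encode(), dtype="S1").reshape(len(bcs), BARCODE_LENGTH)
        for i in range(len(bcs)):
            d = (mat[i + 1 :] != mat[i]).sum(axis=1)
            if (d < MIN_BARCODE_DISTANCE).any():
                raise ValueError("barcodes closer than the minimum Hamming distance")
        wt = [v for v in self.variants if v.category == "wildtype"]
        if len(wt) != N_WT_MEMBERS:
            raise ValueError(f"manifest must contain exactly {N_WT_MEMBERS} wildtype members")
        if len({v.end_sequence for v in wt}) != 1:
            raise ValueError("wildtype members must share an identical end sequence")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[v.variant_id, v.side, v.category, v.end_sequence, v.barcode, v.description] for v in self.variants],
            columns=MANIFEST_COLUMNS,
        )

    def to_tsv(self, path, header_lines=()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "VariantManifest":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
        missing = set(MANIFEST_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"manifest file missing columns: {sorted(missing)}")
        variants = []
        for i, row in df.iterrows():
            try:
                variants.append(
                    EndVariant(row.variant_id, row.side, row.category, row.end_sequence,
                               row.barcode, row.description)
                )
            except ValueError as exc:
                raise ValueError(f"manifest row {i + 2}: {exc}") from exc
        sides = {v.side for v in variants}
        if len(sides) != 1:
            raise ValueError("manifest mixes sides")
        man = cls(variants, sides.pop())
        man.validate()
        return man


# -- designers ---------------------------------------------------------------


def design_truncations(end: TransposonEndModel, step: int) -> list[EndVariant]:
    """Serial inward truncations emulated by filler replacement.

    Variant ``k`` replaces the innermost ``k*step`` bases with the neutral
    filler, preserving overall length; the final variant replaces the whole
    end.
    """
    L = len(end.sequence)
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > L:
        raise ValueError("step larger than end length")
    out = []
    n = -(-L // step)
    for k in range(1, n + 1):
        m = min(k * step, L)
        seq = end.sequence[: L - m] + _filler(m)
        out.append(
            EndVariant(
                f"{end.side}_trunc_{k:04d}", end.side, "truncation", seq,
                description=f"innermost {m} nt replaced with filler",
            )
        )
    return out


def design_substitutions(end: TransposonEndModel, widths=(1, 2, 4)) -> list[EndVariant]:
    """Tiled complement substitutions at every start offset for each width.

    Windows overlap, so each base away from the edges is covered by ``w``
    variants of width ``w`` (the basis for per-base averaging of effects).
    """
    if not set(widths) <= {1, 2, 4}:
        raise ValueError("widths must be a subset of {1, 2, 4}")
    seq = end.sequence
    out = []
    for w in sorted(widths):
        for start in range(len(seq) - w + 1):
            var = seq[:start] + complement(seq[start : start + w]) + seq[start + w :]
            out.append(
                EndVariant(
                    f"{end.side}_sub_w{w}_{start:04d}", end.side, "substitution", var,
                    description=f"complemented window [{start},{start + w})",
                )
            )
    return out


def _replace_intervals(seq: str, replacements: dict[Interval, str]) -> str:
    out = seq
    for iv, new in sorted(replacements.items(), key=lambda kv: -kv[0].start):
        out = out[: iv.start] + new + out[iv.end :]
    return out


def design_tbs_variants(
    end: TransposonEndModel,
    mode: str,
    tbs_pool: list[str] | None = None,
    params: dict | None = None,
) -> list[EndVariant]:
    """TBS architecture variants: identity swaps, spacing, inversions, additions.

    identity   all assignments of the choice pool (default: the end's own
               three TBS sequences) to the end's TBS slots -> 3^3 = 27.
    spacing    change each inter-TBS gap by each delta in ``params['deltas']``
               (negative: delete bases adjacent to the downstream TBS;
               positive: insert filler there).
    inversion  reverse-complement each TBS individually.
    addition   insert a fourth TBS between sites 2 and 3 (left end) or distal
               to site 3 (right end); sequence from ``params['tbs']`` or the
               end's first TBS.
    """
    params = params or {}
    tbs = end.tbs_list
    if not tbs:
        raise ValueError("end has no annotated TBS intervals")
    seqs = [end.sequence[iv.start : iv.end] for iv in tbs]
    out: list[EndVariant] = []
    side = end.side
    if mode == "identity":
        pool = tbs_pool if tbs_pool is not None else seqs
        for i, combo in enumerate(itertools.product(pool, repeat=len(tbs))):
            var = _replace_intervals(end.sequence, dict(zip(tbs, combo)))
            out.append(
                EndVariant(
                    f"{side}_tbsid_{i:04d}", side, "tbs_identity", var,
                    description="TBS assignment " + "|".join(combo),
                )
            )
    elif mode == "spacing":
        deltas = params.get("deltas", (-2, -1, 1, 2))
        for gi in range(len(tbs) - 1):
            gap = tbs[gi + 1].start - tbs[gi].end
            for d in deltas:
                if d == 0:
                    continue
                if d < 0:
                    if -d > gap:
                        raise ValueError(
                            f"spacing deletion of {-d} exceeds gap of {gap} between "
                            f"{tbs[gi].label} and {tbs[gi + 1].label}"
                        )
                    var = end.sequence[: tbs[gi + 1].start + d] + end.sequence[tbs[gi + 1].start :]
                else:
                    var = end.sequence[: tbs[gi + 1].start] + _filler(d) + end.sequence[tbs[gi + 1].start :]
                out.append(
                    EndVariant(
                        f"{side}_tbssp_g{gi + 1}_{d:+d}", side, "tbs_spacing", var,
                        description=f"gap {tbs[gi].label}-{tbs[gi + 1].label} changed by {d:+d}",
                    )
                )
    elif mode == "inversion":
        sites = params.get("sites", range(len(tbs)))
        for si in sites:
            iv = tbs[si]
            var = _replace_intervals(end.sequence, {iv: revcomp(seqs[si])})
            out.append(
                EndVariant(
                    f"{side}_tbsinv_{iv.label}", side, "tbs_inversion", var,
                    description=f"{iv.label} reverse-complemented",
                )
            )
    elif mode == "addition":
        extra = params.get("tbs", seqs[0])
        if side == "left":
            if len(tbs) < 3:
                raise ValueError("left-end addition requires three TBSs")
            pos = (tbs[1].end + tbs[2].start) // 2
            desc = "fourth TBS inserted between L2 and L3"
        else:
            pos = tbs[-1].end
            desc = "fourth TBS inserted distal to R3"
        var = end.sequence[:pos] + extra + end.sequence[pos:]
        out.append(EndVariant(f"{side}_tbsadd", side, "tbs_addition", var, description=desc))
    else:
        raise ValueError(f"unknown TBS variant mode {mode!r}")
    return out


# -- barcode assignment ------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def assign_barcodes(
    variants: list[EndVariant],
    seed: int,
    *,
    wt_end: str,
    max_candidates: int = 200_000,
    max_tries_per_barcode: int = 10_000,
) -> VariantManifest:
    """Assign unique 10-nt barcodes (pairwise Hamming >= 3) and append 4 WT members.

    Deterministic given ``seed``.  ``wt_end`` is the wild-type end sequence
    shared by the four spike-in members.  Raises :class:`BarcodeSpaceError`
    when the requested number of barcodes exceeds ``max_candidates`` or the
    sampler cannot place another barcode at the required distance.
    """
    if not variants:
        raise ValueError("no variants to barcode")
    sides = {v.side for v in variants}
    if len(sides) != 1:
        raise ValueError("variants mix sides")
    side = sides.pop()
    n_total = len(variants) + N_WT_MEMBERS
    if n_total > max_candidates:
        raise BarcodeSpaceError(
            f"requested {n_total} barcodes but the configured space holds {max_candidates}"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((n_total, BARCODE_LENGTH), dtype=np.uint8)
    k = 0
    while k < n_total:
        for _ in range(max_tries_per_barcode):
            cand = rng.integers(0, 4, BARCODE_LENGTH, dtype=np.uint8)
            if k == 0 or ((accepted[:k] != cand).sum(axis=1) >= MIN_BARCODE_DISTANCE).all():
                accepted[k] = cand
                k += 1
                break
        else:
            raise BarcodeSpaceError("barcode space exhausted at the required Hamming distance")
    codes = ["".join("ACGT"[c] for c in row) for row in accepted]
    assigned = [dataclasses.replace(v, barcode=codes[i]) for i, v in enumerate(variants)]
    for j in range(N_WT_MEMBERS):
        assigned.append(
            EndVariant(
                f"{side}_wt_{j + 1}", side, "wildtype", wt_end,
                barcode=codes[len(variants) + j], description="wildtype spike-in",
            )
        )
    manifest = VariantManifest(assigned, side)
    manifest.validate()
    return manifest
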