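"""Transposon-end ORF analysis and constrained recoding for in-frame tagging.

Transposition leaves the transposon ends as sequence 'scars' at the
insertion site.  The short right end can be recoded into a benign peptide
linker: stop codons and codons for bulky/charged residues are replaced by
minimal-edit codons for allowed residues, while never touching bases the
mutability register marks as intolerant (the conserved TBS positions).  An
accepted linker variant translates cleanly in its frame, enabling fusions of
an interrupted endogenous gene to a promoter- and start-codon-less cargo ORF
(e.g. GFP).
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

from .end_model import (
    STANDARD_CODE,
    TBS_CONSERVED_POSITIONS,
    GeneticCodeTable,
    TransposonEndModel,
)

#: Default disallowed residues for linker design: bulky and/or charged
#: (aromatics, charged side chains, proline).  Configurable per call.
DEFAULT_DISALLOWED = frozenset("WFYRKDEHP")

#: Packaged superfolder GFP (sfGFP) protein sequence, 238 aa: the
#: folding-reporter GFP scaffold carrying S30R, Y39N, N105T, Y145F, I171V
#: and A206V.  Used as the reference cargo for fusion sizing.
SFGFP_PROTEIN = (
    "MSKGEELFTGVVPILVELDGDVNGHKFSVRGEGEGDATNGKLTLKFICTTGKLPVPWPTLVTTLTYGVQCFSRY"
    "PDHMKRHDFFKSAMPEGYVQERTISFKDDGTYKTRAEVKFEGDTLVNRIELKGIDFKEDGNILGHKLEYNFNSH"
    "NVYITADKQKNGIKANFKIRHNVEDGSVQLADHYQQNTPIGDGPVLLPDNHYLSTQSVLSKDPNEKRDHMVLLE"
    "FVTAAGITHGMDELYK"
)


class UnresolvableCodonError(ValueError):
    """Raised when no allowed replacement codon avoids the immutable mask."""


def find_stops(end_dna: str, code: GeneticCodeTable = STANDARD_CODE) -> dict[int, list[int]]:
    """Stop-codon positions (codon indices) per reading frame 1-3.

    Only complete codons are scanned; trailing partial codons are ignored.
    """
    out: dict[int, list[int]] = {}
    for frame in (1, 2, 3):
        protein = code.translate(end_dna, frame)
        out[frame] = [i for i, aa in enumerate(protein) if aa == "*"]
    return out


def conserved_tbs_mask(end: TransposonEndModel) -> set[int]:
    """Absolute base positions inside TBSs that the substitution register
    reports as intolerant (conserved TBS positions)."""
    mask: set[int] = set()
    for iv in end.tbs_list:
        mask.update(iv.start + off for off in TBS_CONSERVED_POSITIONS)
    return mask


@dataclass
class LinkerVariant:
    name: str
    frame: int
    dna: str
    protein: str
    edits: list = field(default_factory=list)  # (codon_index, old_codon, new_codon)
    violations: list = field(default_factory=list)

    @property
    def n_edited_bases(self) -> int:
        return sum(
            sum(a != b for a, b in zip(old, new)) for _, old, new in self.edits
        )


def _codon_span(frame: int, codon_index: int) -> range:
    start = frame - 1 + 3 * codon_index
    return range(start, start + 3)


def design_linkers(
    end_dna: str | TransposonEndModel,
    frame: int,
    disallowed_residues=DEFAULT_DISALLOWED,
    immutable_mask: set[int] | None = None,
    code: GeneticCodeTable = STANDARD_CODE,
    max_variants: int = 64,
) -> list[LinkerVariant]:
    """Minimal-edit recoding of one reading frame into an allowed linker.

    For each offending codon (stop or disallowed residue) every replacement
    codon encoding an allowed residue is scored by the number of base
    changes, excluding any replacement that would edit a masked base; all
    co-optimal replacements are kept and combined across codons, so the
    result enumerates every minimal-edit solution (capped at
    ``max_variants``, deterministic order).

    When ``end_dna`` is an annotated end model, the immutable mask defaults
    to its conserved TBS positions.
    """
    if isinstance(end_dna, TransposonEndModel):
        if immutable_mask is None:
            immutable_mask = conserved_tbs_mask(end_dna)
        dna = end_dna.sequence
    else:
        dna = end_dna
    mask = immutable_mask or set()
    disallowed = frozenset(disallowed_residues)
    protein = code.translate(dna, frame)
    offending = [
        i for i, aa in enumerate(protein) if aa == "*" or aa in disallowed
    ]
    options: list[list[tuple[int, str, str]]] = []
    for ci in offending:
        span = _codon_span(frame, ci)
        old = dna[span.start : span.stop]
        cands = []
        for codon, aa in code.codon_to_aa.items():
            if aa == "*" or aa in disallowed:
                continue
            changed = [p for p, (a, b) in zip(span, zip(old, codon)) if a != b]
            if any(p in mask for p in changed):
                continue
            cands.append((len(changed), codon))
        if not cands:
            raise UnresolvableCodonError(
                f"unresolvable codon {old} at codon index {ci} (frame {frame}): "
                "every allowed replacement touches a masked base"
            )
        best = min(c for c, _ in cands)
        options.append([(ci, old, codon) for c, codon in sorted(cands) if c == best])
    variants = []
    for li, combo in enumerate(itertools.islice(itertools.product(*options), max_variants)):
        new = list(dna)
        for ci, _, codon in combo:
            span = _codon_span(frame, ci)
            new[span.start : span.stop] = codon
        new_dna = "".join(new)
        new_protein = code.translate(new_dna, frame)
        violations = [
            i for i, aa in enumerate(new_protein) if aa == "*" or aa in disallowed
        ]
        name = f"ORF{frame}{chr(ord('a') + li)}" if li < 26 else f"ORF{frame}_{li}"
        variants.append(
            LinkerVariant(name, frame, new_dna, new_protein, list(combo), violations)
        )
    ok = [v for v in variants if not v.violations]
    return ok


@dataclass
class FusionResult:
    dna: str
    protein: str
    in_frame: bool
    failures: list


def build_fusion(
    gene_dna: str,
    insertion_offset: int,
    end_variant_dna: str,
    cargo_orf: str,
    code: GeneticCodeTable = STANDARD_CODE,
) -> FusionResult:
    """Concatenate gene[0:offset] + linker end + cargo and check the frame.

    The cargo ORF is assumed promoter- and start-codon-less (it is expressed
    only via the fusion).  Returns a structured report: a frame shift or an
    internal stop is recorded as a failure rather than raised, mirroring how
    a wild-type (stop-containing) end yields no functional tag.
    """
    if not 0 <= insertion_offset <= len(gene_dna):
        raise ValueError("insertion offset outside gene")
    dna = gene_dna[:insertion_offset] + end_variant_dna + cargo_orf
    failures = []
    if len(dna) % 3 != 0:
        failures.append(f"frame shift: fusion length {len(dna)} not divisible by 3")
    protein = code.translate(dna, frame=1)
    body = protein[:-1] if protein.endswith("*") else protein
    for i, aa in enumerate(body):
        if aa == "*":
            failures.append(f"internal stop at codon {i}")
    return FusionResult(dna, protein, not failures, failures)


def protein_mw(protein: str, code: GeneticCodeTable = STANDARD_CODE) -> float:
    """Expected protein mass in kDa (average residue masses + one water)."""
    seq = protein[:-1] if protein.endswith("*") else protein
    if not seq:
        warnings.warn("empty protein: mass is one water molecule", stacklevel=2)
    try:
        total = sum(code.residue_masses[a] for a in seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    return (total + code.water_mass) / 1000.0
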