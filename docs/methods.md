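# Methods

This note documents the models, estimators, simulators and numerical
choices in `castlib`, in the spirit of a statistical-software methods
appendix: what each stage assumes, which defaults matter, and what passing
the test-bench does and does not demonstrate about real sequencing data.

## Transposon-end model and the packaged fixture

Ends are modelled tip-inward (position 0 = first base of the 8-bp terminal
end, which must begin with the conserved TG dinucleotide), with 14-nt TnsB
binding sites (TBSs) located by an IUPAC consensus scan
(`CNNNNTGTNNNGCA`): the fixed consensus positions are the TBS positions
conserved across all six sites (1, 6–8, 12–14 in 1-based coordinates), the
rest are free.  Greedy non-overlapping matching from the tip reproduces the
canonical L1–L3 / R1–R3 arrangement; a left end must yield ≥ 3 sites, a
right end ≥ 2 (the minimal 57-bp right end exposes exactly two).

Native CAST end sequences are not distributed with the package.  The WT
fixture (`make_wt_fixture`) is a **synthetic** 775-bp mini-transposon —
147-bp left end, 553-bp cargo, 75-bp right end, 5-nt donor flanks — that
satisfies every architectural constraint the model encodes: terminal TG,
three TBSs per end sharing exactly the conserved position set, a perfect
integration host factor (IHF) consensus match (`WATCARNNNNTTR`) strictly
between L1 and L2, and stop codons in all three reading frames of the
minimal right end.  Construction is deterministic given its seed, and the
builder asserts that annotation from sequence alone recovers the planted
architecture with no spurious consensus matches.  Two deliberate choices:

* the conserved TBS tail is `GCA` so that the immutable codon it forms when
  frame-aligned encodes alanine — a conserved tail encoding a stop or a
  disallowed residue would make linker design of that frame infeasible by
  construction rather than by biology;
* inter-feature gaps use a low-complexity A/C filler, which cannot create
  TBS or IHF consensus matches (both require T/G bases); interior tails are
  consensus-free random sequence so the 19-bp primer anchor is unique.

The 14-nt fixture IHF site embeds a perfect 13-nt consensus match; note
that natural left-end IHF sites need not match the consensus at every
offset, so consensus scanning is a detection heuristic, not a definition.

## Library design

Designers are pure functions of the end model and their parameters, so
category counts follow closed forms (length/step truncations, L−w+1
substitution windows per width, 3³ = 27 identity swaps).  Unstated rules
were fixed as: substitutions complement each window base (a maximal,
unambiguous perturbation); truncations replace the innermost k·step bases
with the neutral filler, preserving overall element size.  Barcodes are
10-nt, drawn by seeded rejection sampling under a pairwise Hamming-distance
≥ 3 constraint, so no single sequencing error can convert one valid barcode
into another (the counters use exact matching); four wild-type members with
identical end sequence and unique barcodes are appended to every manifest.

## Donor quantification

Filtering and counting follow the screen's rules exactly: perfect 19-bp
primer match (first occurrence if repeated), 10-nt barcode directly
downstream, exact barcode matching, discards counted.  Enrichment uses
relative abundances over matched reads; normalization divides by the mean
wild-type fold-change, making the WT mean score 1 identically and the score
scale-invariant in sequencing depth.  Variants absent from the input are
reported as undefined (NaN) rather than pseudocounted; a pseudocount
parameter exists but defaults to 0 because the estimator is a plain ratio.
Orientation-specific samples (T-RL/T-LR amplicons) are independent runs of
the same pipeline; no cross-orientation normalization is attempted.

Coupling QC declares a pair correct iff read 2 equals the manifest end
sequence for read 1's barcode, with incorrect pairs tallied by the end
sequence they carry.  Exact matching means sequencing errors depress the
estimate; the coupling experiments are therefore simulated error-free, and
the estimator should be read as "exact-concordance fraction" on real data.

## Read simulators

All simulators are deterministic given their seed and write primer-derived
bases verbatim (PCR primers overwrite template), so anchor filters behave
as they do on real amplicons.  Quality strings are constant because no
stage consumes qualities.  What is modelled: multinomial sampling over
log-normal input abundances (σ = 1); multiplicative efficiency on the
output; barcode uncoupling at a tunable rate, with replacement barcodes
drawn from *other* members proportional to abundance (reproducing the
observation that uncoupled reads map to a diverse pool); uniform per-base
substitution error.  What is not modelled: amplification bias beyond
uncoupling, indels, chimeras within the end sequence itself, quality-value
structure.  Passing recovery tests therefore shows estimator correctness
under these noise sources, not robustness to artifacts outside them.

### Target-library sampling scheme

The insertion-preference model is a position weight matrix over the 11-nt
TSD-relative window (−3…−1, TSD1…TSD5, +1…+3; TSD length 5, the Tn7-family
standard).  Output reads draw the pair (distance, 8-mer) jointly:

* P(d) ∝ Π over *fixed plasmid* window positions of w(base)/0.25 — the
  likelihood ratio of the flanking bases against a uniform background, so a
  uniform model yields uniform distances;
* degenerate bases inside the window are drawn from the per-position
  weights; degenerate bases outside it are uniform.

This scheme has the property that, given d, the base frequencies at covered
positions equal the model weights exactly, so re-fitting a model from all
calls of its own simulation is unbiased (the refit-consistency check uses
the unselected estimator `pfm_from_calls`; the screen's four-fold/top-5000
logo selection is deliberately a *biased, sharpened* summary and is tested
for its arithmetic, not for unbiasedness).

### Default planted preferences and target contexts

The default model encodes the documented integration-site biases — a
central YWR (pyrimidine/weak/purine) preference at TSD2–TSD4, D (not C) at
−3 and H (not G) at +3 — with three-base preferences at TSD1/TSD5 and
uniform weights elsewhere.  The two packaged target contexts (A, B) fix the
bases flanking the degenerate block so that two central distances (48, 49)
carry favorable flanks while every competing distance has at least one
strongly disfavored base at an informative window position, emulating real
targets with one or two dominant insertion distances.  Sharpness of the
weights and the default depths (10⁶ input / 2.5 × 10⁵ output reads per
library) were chosen together, by exact enumeration of the induced
distribution over all 65 536 8-mers × 14 distances, so that each simulated
library operates in the screen's published regime: comfortably more than
5000 (8-mer, distance) records exceed four-fold enrichment, the top-5000
selections of the two libraries pool to 10 000 nucleotides per fully
covered logo position, and sampling noise cannot push enriched records to
distances that would break full coverage.  The deep input (~15 reads per
8-mer) mirrors the practice of sequencing input libraries to saturation and
makes single-count noise fold-changes impossible.

Logo information content is the WebLogo DNA convention, IC = 2 − H bits,
with no small-sample correction.  IC values are only compared across
columns with adequate support: `supported_positions` masks columns with
fewer than 5% of the best column's observations, whose IC is dominated by
small-sample noise (a column with one observation always shows 2 bits).

Orientation is sampled independently of the motif (default 90% T-RL, the
dominant orientation); the preference model is applied on the top strand
for both orientations — a simplification, since orientation-specific motif
asymmetries are not modelled.

## Integration-distance calling

Candidate distances 43–56 are scanned in ascending order on the anchored i5
read; the first exact 20-nt end-prefix match wins, a simultaneous left and
right match is discarded as ambiguous, and the degenerate 8-mer is
reassembled from the i5 read (positions upstream of the junction) and the
complemented i7 read (positions downstream), which is exact because the
5-nt TSD duplication makes the downstream read contiguous through the
junction in plasmid coordinates.  On error-free reads the caller is exact
(the test-bench checks 10⁴/10⁴ correct calls including the 8-mer); a
sequencing error inside the matched 20-mer causes a no-call rather than a
miscall.

Per-8-mer enrichment uses the position-agnostic input abundance (the input
library has no insertion, so there is no distance to stratify by);
output-absent 8-mers are censored (−∞ log2 fold-change) rather than
pseudocounted, and records whose 8-mer was never seen in the input are
flagged and excluded from ranking.  Site prediction scores candidate
distances by summed log-weights over the full 11-nt window (fixed plasmid
bases included — they are real sequence for prediction even though logos
pool only degenerate-derived bases); ties rank by ascending distance.

## Linker design

Disallowed residues default to {W, F, Y, R, K, D, E, H, P} — aromatic,
charged, or conformationally disruptive — and are configurable.  The
immutable mask defaults to the conserved TBS positions when an annotated
end is supplied, wiring the screen's mutability register into the designer.
Replacement codons are chosen per offending codon by minimal base edits
among allowed residues, all co-optimal choices are enumerated and combined
(deterministic order, capped at 64 variants), and acceptance requires a
clean re-scan; because codons are disjoint, per-codon minimality implies
global minimality, which the test-bench confirms by exhaustive search over
all smaller edit sets on short ends.  Fusion checking reports frame shifts
and internal stops as structured failures (a wild-type, stop-containing end
fails exactly as it does in a tagging experiment).  Protein masses use
average residue masses + one water; the packaged sfGFP (238 aa) computes to
26.8 kDa at one decimal, cross-checked against Biopython's calculator.

## Auxiliary quantification

qPCR efficiency is 2^ΔCq with ΔCq = Cq(reference) − Cq(target), so rarer
integration products give efficiencies below 1; replicates are averaged on
the efficiency scale (average-then-exponentiate is available by aggregating
ΔCq externally — the two differ by Jensen's inequality and the choice is
documented rather than hidden).  Tn7 classification is an exact 65-bp
prefix partition over {unintegrated} ∪ {0–30 bp} × {T-RL, T-LR}; prefix
uniqueness is asserted at construction, so each read lands in exactly one
tally and, at error rate 0, classification is exact.

## Problem sizes in the test-bench

Donor recovery: 200 members, 10⁵ reads per sample, uncoupling 0.35, error
10⁻³ (Spearman ρ ≥ 0.9 across seeds, typically 0.91–0.96).  Coupling: 5 ×
10⁴ pairs (binomial standard error ≈ 0.002, acceptance band ± 0.02).
Caller exactness: 10⁴ error-free reads.  Motif displacement and refit
consistency: 10⁵ output reads.  Target screen: 10⁶ input / 2.5 × 10⁵
output reads per library.  The whole acceptance run completes in well under
a minute on one CPU.

## Known limitations

* All fixtures are synthetic; nothing here validates against native VchCAST
  sequence content, only against the documented architecture and pipeline
  arithmetic.
* The preference model is positionally independent (a PWM); cooperative or
  spacing-dependent effects at the integration site are not representable.
* The coupling estimator conflates sequencing error with uncoupling when
  applied to error-containing reads (see above).
* Orientation-specific sequence preferences and donor-flank effects are out
  of scope of the simulator's noise model.
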