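# castlib

Analysis toolkit for pooled-library screens of CRISPR-associated transposon
(CAST) end sequences and integration sites, of the kind used to dissect the
Type I-F *Vibrio cholerae* CAST (VchCAST) system: thousands of barcoded
transposon-end variants are cloned into a donor plasmid, transposition is
performed in *E. coli*, and junction amplicon sequencing of the input and
output libraries measures each variant's relative integration efficiency.
A companion target-plasmid screen with an 8-bp degenerate insertion window
maps the transposase's nucleotide preferences at the integration site with
single-bp resolution.

The package is aimed at people building or analysing such screens: it
implements the full computational workflow (variant design, barcode
counting, enrichment scoring, integration-distance calling, sequence-logo
and preference-model construction, linker/ORF engineering, small
quantification utilities) together with read-level simulators that generate
every input with planted ground truth, so each stage is testable end to end.

## The quantities computed

**Donor screen.** For library member *i* with barcode counts
*c*<sub>i</sub> in the input and output libraries, the relative abundance is
*f*<sub>i</sub> = *c*<sub>i</sub>/Σ*c*, the fold-change is
FC<sub>i</sub> = *f*<sub>i</sub><sup>out</sup>/*f*<sub>i</sub><sup>in</sup>,
and the reported score normalizes by the four wild-type spike-ins:

> score<sub>i</sub> = FC<sub>i</sub> / mean(FC<sub>WT1..4</sub>),

log2-transformed last.  Reads must contain a perfect match to the 19-bp
primer-binding sequence at the 3' terminus of the transposon end; the 10-nt
barcode immediately downstream identifies the member.  Barcode–end
uncoupling (PCR recombination) is quantified from long paired reads as the
fraction of pairs whose end sequence exactly matches the manifest entry for
their barcode.

**Target screen.** Paired amplicon reads over the degenerate window are
anchor-filtered (34/35-nt i5, 45/46-nt i7 exact prefixes), and the
integration distance *d* ∈ [43, 56] bp downstream of the 32-bp target is
called by the first exact 20-nt transposon-end match scanning the i5 read;
the end identity (right/left) fixes the orientation (T-RL/T-LR).  Per-8-mer
log2 fold-changes against the input feed a position-frequency matrix in
TSD-relative coordinates (5-nt target-site duplication ± 3-bp flanks),
built from the top 5000 four-fold-enriched sequences of each library
(2 × 5000 → 10 000 observations per fully covered logo position).  The
normalized logo doubles as an insertion-site preference model: candidate
distances along any downstream sequence are ranked by
Σ<sub>p</sub> log *w*<sub>p</sub>(base at *p*) over the 11-nt window.

**Engineering and utilities.** The linker designer recodes transposon-end
reading frames by minimal-edit codon replacement (stops and bulky/charged
residues out, conserved TnsB-binding-site bases untouched), checks in-frame
fusions, and sizes products by average residue mass.  qPCR transposition
efficiency is 2^ΔCq against a reference gene; Tn7 glmS amplicons are
classified by exact 65-bp expected prefixes (unintegrated, or integrated
0–30 bp downstream in either orientation).

## Worked example

Simulate a 200-member donor library (log-uniform planted efficiencies,
35% barcode uncoupling, 0.1% sequencing error, 10⁵ reads per sample) and
recover the planted efficiencies:

```python
from castlib import experiments

res = experiments.donor_recovery(seed=1)
print(f"Spearman rho (truth vs score): {res['spearman_rho']:.3f}")
print(f"WT mean normalized score:      {res['wt_mean_normalized']:.3f}")
```

```
Spearman rho (truth vs score): 0.928
WT mean normalized score:      1.000
```

The rank correlation of 0.93 shows that barcode uncoupling at the measured
real-data scale does not prevent accurate relative-efficiency estimation,
and the wild-type spike-ins average to a score of exactly 1 by construction.
Ranking insertion sites along a concrete target with the default preference
model:

```python
from castlib import simulate, target_quant

model = simulate.default_preference_model()
ctx = target_quant.make_target_context("A")
df = target_quant.predict_sites(model, ctx.filled_downstream("CCTAGCAA"))
print(df[df["rank"] <= 3][["distance", "score", "rank"]])
```

```
 distance      score  rank
       43 -19.569749   3.0
       47 -15.677928   2.0
       48 -12.181421   1.0
```

Distance 48 ranks first: this 8-mer places the preferred YWR triplet and
favorable flanks in the TSD window of a 48-bp insertion.

A command-line interface mirrors the library (`castlib design`,
`simulate`, `quant-donor`, `coupling`, `quant-target`, `logo`,
`predict-site`, `scan`, `linker`, `qpcr`, `tn7`, `run-demo`); every output
table carries a provenance header with the package version, seed and
configuration hash.

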