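# Methods

## Problem setting

A genome that reassigns a stop codon to a sense codon (TAG→Gln, table 15;
TGA→Trp, table 4) cannot be annotated correctly under the standard
bacterial code (table 11): every in-frame occurrence of the repurposed
codon truncates a gene call.  The observable signature is a drop in coding
density from the ~90% typical of phage genomes to roughly 70% or below,
together with markedly shorter genes.  `codoncall` turns that signature
into a decision procedure: annotate under every candidate code with an
identical, self-contained gene caller and ask whether an alternative code
repairs the annotation decisively.

## Translation tables

Tables 11, 4 and 15 are defined in-package from the standard codon→amino
acid assignment; tables 4 and 15 differ from table 11 only at their single
reassigned codon.  Custom codes are registered as table 11 plus
single-codon reassignments, which covers lineages whose repurposed stop
encodes an amino acid that is not yet known (register it as `X`).  Input
is normalised to uppercase DNA (U→T); ambiguity codes other than N are
treated as N, and any codon containing N translates to X.  RNA codes,
context-dependent recoding (selenocysteine, pyrrolysine) and programmed
frameshifting are out of scope.

## Gene caller

The caller is deliberately simple — composition scoring plus exact
dynamic-programming selection — because its purpose is the *contrast
between codes*, not call-level agreement with any production gene finder.

**Enumeration.**  Six frames; stop set from the active code; permitted
start codons ATG/GTG/TTG; minimum ORF length 90 nt (stop included in the
span, coordinates 0-based half-open on the forward strand).  Every start
variant of a stop-anchored ORF family is a separate candidate.  ORFs
truncated by a contig edge are emitted with `has_start`/`has_stop` flags
and participate in gene calling by default, since virome contigs are
frequently fragments.

**Composition model.**  For each genome (contig), the maximal ORF of every
family with length ≥ 300 nt forms the training set.  The score of hexamer
*h* is `log((c_cod(h)+ψ)/Σ(c_cod+ψ) ÷ (c_bg(h)+ψ)/Σ(c_bg+ψ))` where
`c_cod` counts in-frame dicodons (6-mer windows every 3 nt, stop excluded)
in training ORFs, `c_bg` counts all 6-mers on both strands of the genome,
and ψ = 1.0 is the pseudocount (ψ = 0 is refused whenever any count is
zero).  If no ORF reaches 300 nt the model falls back to all-zero
log-odds with a warning, leaving selection to start bonuses and ORF
structure.  Start bonuses default to ATG 1.0, GTG 0.5, TTG 0.25 (log-odds
units), reflecting standard prokaryotic start usage.  No
ribosome-binding-site model is included; this is a stated fidelity limit,
acceptable because both codes being compared are scored by the same model.

**Selection.**  One candidate per family (best score, then earlier start,
then longer), then maximum-total-score selection under pairwise overlap
≤ 30 nt on any strand, solved exactly as weighted interval scheduling over
candidates sorted by end.  For end-sorted intervals the
consecutive-overlap constraint implies the pairwise constraint, so the DP
is exact whenever every candidate is longer than the overlap allowance —
guaranteed here by min_len 90 > max_overlap 30, and enforced with an
explicit error otherwise.  Ties break toward earlier start, then longer
ORF, making the whole pipeline deterministic.  Genomes are treated as
linear; `--circular` appends a 3 kb junction window and deduplicates
wrap-around calls, clipping junction-spanning features at the origin in
GFF3 output.

## Code selection rule

With per-table statistics in hand, an alternative table *t* is chosen over
table 11 iff

* coding density(t) − coding density(11) ≥ 10 percentage points, **and**
* median gene length(t) / median gene length(11) ≥ 1.2.

Several qualifying alternatives resolve by highest coding density; exact
ties keep table 11.  The margins are set an order of magnitude below the
gaps that genuine reassignment produces (tens of points of density,
2–3× length on synthetic genomes) yet far above the ~0-point gains seen
when a standard-code genome is annotated under an alternative code, where
the only change is occasional read-through of a TAG- or TGA-terminated
gene into its intergenic spacer.  The rule is this package's own; it is
not a reimplementation of any published tool's internal criterion, and
reports label the decision accordingly (`decision_reason`).

The decision is per genome: a multi-record FASTA is treated as one genome
using one code.  Host-code information (e.g. *Mycoplasma*/*Spiroplasma*
hosts natively using table 4) is carried as a metadata flag only.

## Suppressor tRNAs

A suppressor tRNA's anticodon is the reverse complement of a stop codon:
CTA (amber, reads TAG), TCA (opal, reads TGA), TTA (ochre, reads TAA).
Classification is exact; detection is a recall-oriented cloverleaf
heuristic: a 5-bp anticodon stem whose halves are reverse complements
flanking a 7-nt loop (anticodon at loop positions 3–5), embedded in a
60–100 nt window whose terminal 7-mers pair with ≥ 6/7 complementarity
(acceptor stem).  Among qualifying windows the detector keeps the most
complementary, tie-broken toward canonical tRNA geometry (anticodon arm
26 nt from the 5′ end of a 76-nt body).  This is not a covariance-model
search: it has an appreciable false-positive rate on random sequence and
both orientations of a true tRNA can report (the mirror hit classifies as
`none`).  Externally produced tRNA annotations (GFF3 with an
`anticodon=` attribute, or resolvable from sequence) therefore take
precedence when supplied.  tRNA evidence is reported (`trna_support`) but
never required for a code switch: many genuinely reassigned genomes carry
no detectable suppressor.  Ochre suppressors are classified but unused,
as no table reassigning TAA is in scope.

## Synthetic genomes

The generator emulates the coding statistics of phage genomes and nothing
else (no promoters, terminators, repeats, or realistic gene content).
Defaults, chosen to match the regime the method targets:

| parameter | default | rationale |
|---|---|---|
| n_genes | 45 | ~30 kb genome at the lengths below |
| gene length | log-normal, median 600 bp, σ = 0.5, clipped [90, 6000] | phage-like length distribution |
| intergenic length | geometric, mean 50 bp | yields truth coding density ≈ 90% |
| GC (intergenic) | 0.45 | gut-phage-like |
| minus-strand fraction | 0.3 | phage genes cluster on one strand |
| reassigned-codon rate | 0.03 per internal codon (tables 4/15) | ≈ 6 planted TAG/TGA per median gene: fragmentation under the wrong code saturates without being unrealistic |

Codon usage is genome-specific: per-amino-acid Dirichlet(0.5) preferences
over the synonymous codons of the generating code, so the composition
model has genuine signal.  Under table 15, each internal codon position is
TAG with probability 0.03 and otherwise an amino acid drawn from a fixed
phage-like composition, with Gln encoded only by CAA/CAG so planted TAGs
are the only in-gene TAGs; table 4 is analogous with TGA/TGG for Trp.
Table 11 genomes plant nothing and their genes contain no internal stop of
any table.  Terminal stops are drawn 0.6/0.2/0.2 for TAA/TAG/TGA
(restricted and renormalised to the generating code's stop set).

Intergenic spacers are GC-matched random sequence overlaid with a 12-nt
cassette (`TTAATTAATTAA`) roughly every 66 nt and in every spacer ≥ 13 nt.
The cassette contains the universal stop TAA in all three frames of both
strands, so spurious ORFs are interrupted under *every* candidate table
and the density contrast between codes reflects the genes, not intergenic
noise.  When a suppressor tRNA is to be planted, one mid-genome spacer is
forced to ≥ 150 nt so the 76-nt tRNA always has a host gap; the insertion
shifts downstream truth coordinates by exactly +76.

All randomness flows from a single `numpy` Generator seeded per genome
(cohorts use seed + index), making sequences byte-identical across runs.

What passing on this generator does and does not show: recovery and
contrast results demonstrate that the decision rule responds correctly to
the fragmentation signature at realistic densities and rates; they do not
demonstrate call-level accuracy on real genomes, where gene starts, RBS
signals, overlapping genes, HGT islands and compositional heterogeneity
are harder than anything the generator produces.

## Statistics

Cohort comparisons use two-sided Welch t-tests by default ("simple t-test"
is underspecified; a paired mode is provided since the natural design —
the same genomes under two codes — is paired, but unpaired is the default
to match grouped presentation).  All p-values in a report are adjusted
jointly with Benjamini–Hochberg (via `statsmodels`); the display
significance tier defaults to 1e-10.  Degenerate zero-variance
comparisons return p = 1 by convention.  Gene lengths include the stop
codon throughout (the common annotation convention); proteins exclude it.
Coding density is the union of gene intervals across both strands, per
contig, as a percentage of total genome length.

## Problem sizes used in validation

The test suite and the acceptance script run 50 genomes (~30 kb) per
generating table for recovery and contrast measurements, 80 planted-tRNA
fixtures (10-gene genomes), 200 random instances against the exhaustive
selection oracle, and 100 random 5-kb sequences for the stop-set
monotonicity property; a full run completes in well under a minute on a
single CPU, scaling linearly in total genome length.

## Known limitations

* The gene caller has no RBS/start-site model; start calls are
  composition-driven and recovery is therefore measured by stop
  coordinate.
* The tRNA detector trades precision for recall by design; its hits are
  evidence, not annotations.
* Only single-codon reassignments of table-11 stops are representable;
  TAA reassignment is classified (ochre) but never selected for.
* Circular-genome handling clips junction-spanning features in GFF3
  rather than splitting them into two parts.
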