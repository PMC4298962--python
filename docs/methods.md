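# Methods

This note documents the models, parameters and design decisions behind
`armsurvey`, and what its simulation-based validation does and does not
demonstrate.

## The survey model

A chromosome-arm shotgun survey samples an arm of size *S* bp with *N* reads
of mean length *L*, a (1 − purity) fraction of which derive from other
chromosomes because flow sorting is imperfect.  Treating read starts as
uniform and independent, the probability that a given base is covered by at
least one on-target read is

P = [1 − (1 − L/S)^N] · purity.

`surveystats.representation_probability` evaluates the inner power in log
space (`N·log1p(−L/S)`), which is exact to double precision for
megabase-scale arms where L/S ≈ 1e-6.  Coverage fold is total read length /
S.  Report rounding follows the survey's printed precision: probabilities to
3 decimals, coverage to 2, percentages to 2, arm lengths to 0.1 Mb.

## Repeat identification

Two complementary detectors, combined by `nonrepetitive_summary`:

* **Deep contigs.**  A greedy exact suffix/prefix overlap layout (minimum
  overlap and contig length both 40 nt) assembles the reads; byte-identical
  reads and contained reads attach to their container's contig.  Contig
  depth is defined as total aligned member bases divided by contig length —
  the conventional direction, which is what a "depth ≥ 5" threshold
  presupposes.  At ~1.5× arm coverage, depth ≥ 5 contigs are collapsed
  repeats; their member reads are flagged.  Tie-breaks (longest overlap,
  then lexicographic read id) make the layout deterministic and independent
  of input order.
* **Library masking.**  Reads are compared with repeat-library elements by
  k-mer seeding (k = 13), diagonal chaining and edit-distance verification;
  intervals of ≥ 50 nt at ≥ 80% identity are masked.  These two thresholds
  are this package's choices (the original workflow delegated them to a
  masking tool's defaults); they mask TE copies with up to ~10% point
  divergence essentially completely while leaving genic sequence untouched
  in simulation.

Reads in deep contigs, or masked over more than half their length, are
removed; partially masked survivors keep their mask and the masked
intervals are excluded from downstream similarity searches (they are
replaced by `N`, which the seed index skips).  Whole-read removal is also
supported; interval exclusion is the default because it preserves genic
fragments that merely abut a TE.

The assembly report estimates arm length as bases-in-contigs plus bases of
unassembled singleton reads: assembly collapses redundant coverage, so the
sum approximates unique sequence content.

## Similarity searches and e-values

`align.internal_search` is a deterministic seed-and-extend local aligner
used for desk-scale runs: a sorted-array k-mer index over the subjects
(k = 13 nt / 4 aa), per-query seed lookup with high-copy k-mers (> 200 index
hits) ignored, diagonal-band chaining, and extension by edlib infix
alignment (nucleotide) or Smith–Waterman with BLOSUM62 (translated mode, all
six reading frames).  Terminal non-matching cigar runs are trimmed so a read
overhanging its homologous region is not penalised in identity.  Problems
small enough (query × database ≤ 1e5 cells) go straight to exact
Smith–Waterman.  Percent similarity is the BLOSUM62 positives fraction —
the default matrix of the standard search tools, since "75% amino-acid
similarity" does not by itself name one.

E-values have the Karlin–Altschul shape E = K·m·n·exp(−λ·raw score) with
fixed constants (nt: λ = 0.60, K = 0.33 on a +2/−3 scoring; protein:
λ = 0.267, K = 0.041).  They calibrate the cascade's thresholds at desk
scale and keep externally produced 12/13-column BLAST tables drop-in
replaceable; they are not a faithful reimplementation of BLAST statistics,
which is out of scope.  Externally produced tables enter through
`seqio.read_hits_tabular` (an optional 13th column supplies percent
positives; without it the protein filter requires internal recomputation).

In the pipeline driver the reverse search of the reciprocal-best-hit step is
the transpose of the forward search, because the internal aligner scores
symmetrically; `homology.reciprocal_best` itself is general and is tested on
asymmetric direction-specific score matrices.  A reciprocal pair is kept
when the gene is the read's best hit in both search directions — both
argmaxes are per read, so one gene may retain several supporting reads, as
the downstream two-read rule requires.

## Catalogue rules

After deduplication of identical-coordinate identical-sequence reads
(amplification artifacts; the lexicographically smallest read id survives),
genes supported by a single read are dropped: at survey impurity levels the
contaminating fraction covers the rest of the genome at ~0.001×, so a real
contaminant gene essentially never attracts two distinct reads.  UniGene/
UniProt subjects hit by more than 50 reads are dropped as probable repeats.
Catalogue entries are grouped into loci by shared supporting reads
(connected components across genomes); a locus's conservation profile — the
set of model genomes retaining it — populates the 7-region Venn, and
two-tailed Fisher tests contrast class proportions between arms.

## Genome zipper

Deletion bins give macro order; reference co-linearity gives micro order.
Marker anchoring follows the EST-mapping rule (≥ 95% identity over ≥ 30 nt
against a gene's supporting reads); conflicting bins for one gene resolve by
majority.  The syntenic gene set (backbone genes inside called blocks —
windows of 500 kb stepped at 50 kb holding ≥ 50 genes/Mb in ≥ 2 species'
tracks, merged maximally) is segmented where the marker-bin sequence breaks
co-linearity (a bin jump of more than one, or a direction reversal);
segments are ordered by mean anchored bin, and oriented by the sign of the
Kendall correlation between reference position and bin rank — segments
confined to a single bin cannot be oriented and default to `+`.  Genes
without markers inherit the segment they fall in by reference adjacency.
Non-syntenic conserved genes with a marker-supported bin are appended with
bin-only placement.

`detect_rearrangements` densely re-ranks the recovered genes and decomposes
the zipper/reference permutation into maximal runs of consecutive ranks;
runs of ≥ 5 genes are segments (the spec's "large regions"), shorter runs
small-scale translocations — the 5-gene threshold is this package's
explicit choice where the source analysis distinguished the two informally.
Applying the reported runs in order reproduces the zipper's syntenic order
exactly (an invariant under test).

## Non-syntenic genes and wheat-specific calls

Candidates are genes conserved in all three model genomes, with ≥ 2
supporting reads, whose backbone position lies outside every syntenic
block.  The evenness rule divides the gene into k = min(n_reads, 4) equal
segments and requires every segment to be overlapped by at least one read.
For 2–3 reads this is exactly the published rule; for ≥ 4 reads the
original assessment was visual, and the k = 4 cap is the automated,
reproducible generalisation (flagged as such here).  Note the verdict is
not monotone in reads while k still grows with n (adding a read can raise k
and expose an uncovered segment); once k is capped at 4 it is monotone.

Mutual synteny among the three references is computed by the same
block-calling machinery applied pairwise to shared-ortholog positions at
the same thresholds; a genuine candidate whose triplet is mutually syntenic
in the references is called a putative wheat-specific rearrangement.

## Gene models

Reads are assembled (same 40/40 parameters) against the coding sequence of
their assigned reference — one reference per read, precedence genome A >
B > C > UniGene.  Contigs are placed back on the reference by alignment;
ordered contigs merge with reference-gap `n` runs (floor one `n`);
overlapping contigs merge when the overlap agrees at ≥ 95% identity,
keeping the earlier contig's bases (the original tool's consensus behaviour
is unspecified), otherwise both are kept and the model flagged ambiguous.
Transcript screening at ≥ 95% identity sets coverage over non-`n` bases;
classes: high ≥ 60%, low ≥ 20%, else eliminated — the printed class ranges
overlap at their boundaries, resolved upward here (60% is high).  Because
read-to-reference precedence is per read, a locus can yield one principal
model plus short secondary fragments on another genome's reference; the
transcript screen eliminates such fragments, which is the designed
behaviour, and class-recovery validation therefore scores each locus's
principal (longest) model.

Cross-dataset matching is best-reciprocal at ≥ 95% identity and e ≤ 1e-20,
e-value primary and identity secondary; equal-e-value ties break toward the
subject whose location label matches the query's arm (the homoeolog rule).
Identity histograms use 1% bins, bin b covering [b, b+1).

## The synthetic-data generator

`simgen` emulates the study conditions: three reference genomes share an
ancestral gene order on a colinear chromosome (per-lineage losses at 8%,
moves to a sparse scatter chromosome at 2%, sequence divergence 3% per
lineage; conservation-class proportions can be planted exactly); the wheat
arm copies the order with 2% divergence and applies configured
rearrangements; a colinear non-syntenic pool chromosome supplies insertions
targeted at base-pair positions of the final arm (distal 10% with the
configured bias — a planted subset of the pool has one ortholog scattered,
breaking mutual synteny); TE families (10 families, 0.8–3 kb) are tiled to
the target repeat fraction, half of all copies exact and the rest mutated
up to 8%, matching the age structure that makes young elements assemble
into deep contigs while older ones are caught by masking; a fraction of
copies of half the families carry a fixed 75 bp tRNA-like inset (no RNA
folding is simulated — prediction is delegated to external tables, and the
in-repo "predictor" that scans for the token is a labelled synthetic
stand-in).  Reads have truncated-normal lengths (minimum 50 bp; the source
reports only means, so a two-parameter family suffices), uniform starts,
forward strand only; impurity reads come from a simulated second arm
carrying its own gene set plus an organellar genome; duplicates are exact.
Divergence is substitution-only, which keeps planted coordinates alignable
and matches the identical-coordinate definition of MDA duplicates; MDA
chimeras and coverage waviness are not modelled.

Desk-scale validation sizes were chosen once per scenario: ~2000 genes on
an 8 Mb arm for order recovery, a 0.6 Mb arm at 75% repeat load for repeat
detection, a 0.5 Mb arm at 6× coverage for model-class recovery, and a
0.3 Mb arm for the shared unit fixtures.  Consequences for interpretation:
passing tests show the algorithms recover planted structure under the
modelled error processes (divergence, impurity, duplication, repeat load);
they do not certify performance under 454 homopolymer errors, chimeric
reads, or repeat landscapes richer than the simulated family model.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open internally; BLAST tabular stays 1-based
inclusive with minus-strand subject coordinates swapped on read; BED is
0-based half-open; `NA` is the single missing token in TSVs.  The Fisher
utility wraps the standard two-tailed hypergeometric summation and returns
p = 1 with a warning for tables with an all-zero margin; the test suite
checks it against an independent exhaustive enumeration.  Empty FASTA files
parse to empty collections with a warning; structural violations raise
errors naming the line.  Degenerate cases (zero reads, empty chromosomes,
fewer than two syntenic genes) return empty results rather than raising,
except where the operation's contract requires an error (evenness with a
single read, assembly of an empty read set).
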