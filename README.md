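# armsurvey

Analysis toolkit for **chromosome-arm shotgun surveys**: low-coverage 454-style
sequencing of a flow-sorted chromosome arm, used to catalogue a wheat arm's
genes and structure without a genome assembly.

Such surveys (for example of the arms of bread-wheat chromosome 5D) face four
linked problems, and this package implements the full analysis chain for them:

1. **Repeat identification** — Triticeae arms are ~75% transposable elements.
   Repetitive reads are found two ways: similarity to a repeat library
   (masking), and membership in *deep contigs* of a greedy overlap assembly —
   contigs whose read depth (aligned member bases / contig length) is ≥ 5,
   the signature of a collapsed repeat at ~1.5× coverage.
2. **Conserved-gene discovery** — non-repetitive reads are compared with the
   gene sets of three sequenced grass genomes and EST/protein databases
   through a filter cascade: organellar removal (≥95% identity over ≥75% of
   the read), per-database quality thresholds (protein: e ≤ 1e-6, ≥75%
   similarity, ≥30 aa; nucleotide: e ≤ 1e-30, ≥75% identity — 95% within
   species — over ≥90 nt), reciprocal-best-hit retention, collapse of
   identical-coordinate amplification (MDA) duplicates, elimination of
   single-read genes as probable contaminants, and exclusion of subjects hit
   by >50 reads as probable repeats.
3. **Virtual gene order ("genome zipper")** — deletion-bin-mapped EST/SSR
   markers give coarse order along the arm; co-linearity with a reference
   genome orders genes within blocks.  Comparing the zipper with the
   reference order exposes rearrangements as breaks in co-linearity
   (e.g. three segments in the order 1-2-3 in the reference but 3-2-1 on the
   arm, with internal inversions), and read-coverage evenness separates
   genuine non-syntenic genes (candidate wheat-specific translocations) from
   pseudogene fragments.
4. **Gene modelling** — reads are assembled against the coding sequence of
   their assigned reference gene, contigs condensed into one model with `n`
   gap fill, and models classed by transcript coverage: high confidence
   (60–100%), low (20–60%), eliminated (<20%).

The survey's headline statistic is the **representation probability** — the
chance that a given base of an arm of size *S* is sampled by at least one of
*N* reads of mean length *L* from a sort of purity *p*:

    P = [1 − (1 − L/S)^N] · p

A first-class **synthetic-data generator** (`armsurvey.simgen`) emulates the
whole study design — three model genomes with an ancestral gene order, a
flow-sorted arm with planted rearrangements and TE families, impure reads
with exact-duplicate artifacts, bin markers, transcripts — and records every
planted feature in a `TruthSet`, so each stage is scored by parameter
recovery.

## Worked example

```python
from armsurvey import SimConfig, pipeline, representation_probability

p = representation_probability(S=490e6, N=2_271_366, L=347.25, purity=0.855)
print(f"P(base represented) = {p:.3f}")

cfg = SimConfig(seed=1, arm_size=300_000, n_genes=60, repeat_fraction=0.5,
                coverage_fold=2.0, purity=0.92, artifact_rate=0.02,
                n_nonsyntenic_pool=30, n_nonsyntenic_insertions=6,
                n_contaminant_genes=10, marker_fraction=0.5, n_bins=6)
sim = pipeline.simulate_all(cfg)
filtered = pipeline.run_repeat_filter(sim["reads"],
                                      sorted(sim["arm"].te_families.items()))
rep = filtered["report"]
print(f"reads: {rep['total_reads']}, aligned into contigs: "
      f"{rep['aligned_reads']} ({rep['aligned_reads_pct']}%)")
print(f"deep-contig reads: {rep['deep_contig_reads']} "
      f"({rep['deep_contig_reads_pct']}%)")
print(f"non-repetitive reads kept: {rep['nonrepetitive_reads']}")
print(f"estimated arm length: {rep['estimated_arm_length']:,} bp")

hom = pipeline.run_homology(filtered["reads"], sim["panel"],
                            organelle_genome=sim["arm"].organelle_genome)
print(f"conserved loci: {hom['n_loci']}, venn: {hom['venn']}")
zp = pipeline.run_zipper(hom, sim["panel"], sim["markers"], sim["bin_order"])
print(f"zipper rows: {len(zp['rows'])}, syntenic blocks: {len(zp['blocks'])}, "
      f"co-linear segments: {len(zp['segment_model']['segments'])}")
```

prints

```
P(base represented) = 0.684
reads: 1748, aligned into contigs: 1632 (93.36%)
deep-contig reads: 145 (8.3%)
non-repetitive reads kept: 946
estimated arm length: 261,782 bp
conserved loci: 67, venn: {'A': 1, 'B': 0, 'C': 0, 'AB': 3, 'AC': 7, 'BC': 4, 'ABC': 52}
zipper rows: 55, syntenic blocks: 1, co-linear segments: 1
```

Reading the numbers: a 490 Mbp arm surveyed with 2.27 M reads of 347 bp at
85.5% purity has a 68.4% chance of any given base being sampled.  On the
simulated 300 kb arm, the assembly plus masking removes the repeat load
(half the arm by construction), 67 conserved gene loci are recovered and
classed by which of the three model genomes retain them (the 7-region Venn),
and the zipper orders the syntenic genes into a single co-linear segment —
this arm was simulated without rearrangements, so one segment is the correct
answer.  Configs with planted inversions and segment reversals (see
`tests/test_acceptance.py`) recover the planted segment model instead.

A thin CLI mirrors the library (`armsurvey simulate / mask / stats /
fisher`); the library functions are the primary interface.

## Layout

```
src/armsurvey/
  simgen.py       synthetic arms, reads, markers, transcripts + TruthSet
  seqio.py        FASTA / BLAST-tabular / BED / TSV records and IO
  align.py        internal seed-and-extend search (nt + translated)
  repeatscan.py   greedy overlap assembly, deep contigs, library masking
  homology.py     filter cascade, RBH, dedup, gene catalogue + Venn
  zipper.py       density windows, blocks, zipper, rearrangement detection
  nonsyntenic.py  evenness test, wheat-specific rearrangement calls
  genemodels.py   reference-guided models, confidence classes, cross-match
  surveystats.py  representation probability, Fisher utility, reports
  pipeline.py     stage composition at desk scale
docs/methods.md   model assumptions, parameters, design decisions
```
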