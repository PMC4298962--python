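"""The conserved-gene filter cascade and catalogue construction.

Reads surviving repeat removal pass through, in order: an organellar
contamination filter (>=95% identity over >=75% of the read), per-database
alignment-quality filters (protein: e <= 1e-6, >=75% similarity, >=30 aa;
nucleotide: e <= 1e-30, >=75% identity — 95% for same-species databases —
over >=90 nt, best hit per read), a reciprocal-best-hit requirement against
the reference gene sets, amplification-artifact deduplication (identical
reads aligned to the same subject at the same start/end collapse to one),
and finally the catalogue rules: genes supported by a single read are
discarded as probable contaminants, and UniGene/UniProt subjects matched by
more than 50 reads are discarded as probable repeats.  The surviving
evidence is grouped into loci via shared supporting reads, giving each
locus a conservation profile over the three model genomes (the 7-region
Venn of the survey).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .align import internal_search  # noqa: F401  (re-exported search entry point)
from .seqio import AlignmentHit, SurveyRead
from .surveystats import fisher_two_tailed

GENOME_TAGS = ("genomeA", "genomeB", "genomeC")
GENOME_OF_TAG = {"genomeA": "A", "genomeB": "B", "genomeC": "C"}
VENN_CLASSES = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass
class GeneEvidence:
    """One reference gene (or UniGene/UniProt entry) with its wheat support."""

    gene_id: str
    genome: str                    # A | B | C | unigene | uniprot
    chromosome: str | None
    position: int | None
    supporting_reads: set = field(default_factory=set)
    conservation_profile: set = field(default_factory=set)
    unig_uniprot_support: bool = False
    locus: int | None = None


def _hit_rank(h: AlignmentHit):
    """Best-hit ordering: lowest e-value, longest alignment, lexicographic id."""
    return (h.evalue, -h.aln_len, h.subject_id)


def filter_organellar(reads: list[SurveyRead], organelle_hits: list[AlignmentHit],
                      min_identity: float = 95.0,
                      min_read_fraction: float = 0.75) -> dict:
    """Drop reads matching an organellar genome at >=95% identity over
    >=75% of the read length."""
    lengths = {r.read_id: len(r) for r in reads}
    removed = set()
    for h in organelle_hits:
        L = lengths.get(h.query_id)
        if L is None:
            continue
        if (h.pct_identity is not None and h.pct_identity >= min_identity
                and (h.q_end - h.q_start) >= min_read_fraction * L):
            removed.add(h.query_id)
    return {"reads": [r for r in reads if r.read_id not in removed],
            "removed_ids": sorted(removed)}


def filter_protein_hits(hits: list[AlignmentHit], max_evalue: float = 1e-6,
                        min_similarity: float = 75.0, min_len_aa: int = 30
                        ) -> list[AlignmentHit]:
    """Protein-mode quality filter (similarity = positives fraction)."""
    out = []
    for h in hits:
        if h.pct_similarity is None:
            raise ValueError(
                f"hit {h.query_id}->{h.subject_id} lacks percent similarity; "
                "recompute with the internal aligner or supply a 13-column table")
        if h.evalue <= max_evalue and h.pct_similarity >= min_similarity \
                and h.aln_len >= min_len_aa:
            out.append(h)
    return out


def filter_nucleotide_hits(hits: list[AlignmentHit], same_species: bool = False,
                           max_evalue: float = 1e-30, min_len_nt: int = 90,
                           best_per_read: bool = True) -> list[AlignmentHit]:
    """Nucleotide-mode quality filter; identity floor rises to 95% for
    same-species databases.  Keeps only the best hit per read."""
    min_identity = 95.0 if same_species else 75.0
    passing = [h for h in hits
               if h.evalue <= max_evalue and h.aln_len >= min_len_nt
               and h.pct_identity is not None and h.pct_identity >= min_identity]
    if not best_per_read:
        return passing
    best: dict[str, AlignmentHit] = {}
    for h in passing:
        cur = best.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


def reciprocal_best(hits_fwd: list[AlignmentHit],
                    hits_rev: list[AlignmentHit]) -> list[AlignmentHit]:
    """Keep (read, gene) pairs where the gene is the read's best hit in both
    search directions.

    ``hits_fwd`` has reads as queries; ``hits_rev`` has genes as queries and
    reads as subjects (the reverse search).  For each read, the best forward
    subject and the best reverse-search gene matching that read must agree.
    Ties break by lowest e-value, then longest alignment, then id.
    """
    best_fwd: dict[str, AlignmentHit] = {}
    for h in hits_fwd:
        cur = best_fwd.get(h.query_id)
        if cur is None or _hit_rank(h) < _hit_rank(cur):
            best_fwd[h.query_id] = h
    best_rev: dict[str, tuple] = {}
    for h in hits_rev:
        read = h.subject_id
        rank = (h.evalue, -h.aln_len, h.query_id)
        if read not in best_rev or rank < best_rev[read]:
            best_rev[read] = rank
    out = []
    for read in sorted(best_fwd):
        fwd = best_fwd[read]
        rev = best_rev.get(read)
        if rev is not None and rev[2] == fwd.subject_id:
            out.append(fwd)
    return out


def dedup_artifacts(assignments: list[AlignmentHit],
                    read_sequences: dict[str, str]) -> dict:
    """Collapse amplification artifacts: identical-sequence reads aligned to
    the same subject with the same start and end keep only the
    lexicographically smallest read id."""
    groups: dict[tuple, list[AlignmentHit]] = defaultdict(list)
    for h in assignments:
        key = (h.subject_id, h.s_start, h.s_end, read_sequences[h.query_id])
        groups[key].append(h)
    kept, dropped = [], []
    for key in sorted(groups, key=lambda k: (k[0], k[1], k[2])):
        hs = sorted(groups[key], key=lambda h: h.query_id)
        kept.append(hs[0])
        dropped.extend(h.query_id for h in hs[1:])
    kept.sort(key=lambda h: (h.query_id, h.subject_id))
    return {"assignments": kept, "dropped_read_ids": dropped}


def build_gene_catalogue(assignments_by_db: dict[str, list[AlignmentHit]],
                         gene_table: dict | None = None,
                         min_reads: int = 2, max_reads_unigene: int = 50) -> dict:
    """Apply the read-support rules and build the conserved-gene catalogue.

    ``assignments_by_db`` maps each database tag (genomeA/genomeB/genomeC/
    unigene/uniprot) to its deduplicated read->subject assignments.
    ``gene_table`` maps subject ids to (genome, chromosome, position, ...)
    annotation when available.  Returns the catalogue, the 7-region Venn of
    conservation profiles over loci (groups of per-genome genes linked by
    shared supporting reads), and the per-class UniGene/UniProt support
    fractions.
    """
    support: dict[tuple, set] = defaultdict(set)       # (db, subject) -> read ids
    for db, hits in assignments_by_db.items():
        for h in hits:
            support[(db, h.subject_id)].add(h.query_id)

    # single-read elimination, >50-read exclusion for UniGene/UniProt
    retained: dict[tuple, set] = {}
    for (db, subj), rids in support.items():
        if len(rids) < min_reads:
            continue
        if db in ("unigene", "uniprot") and len(rids) > max_reads_unigene:
            continue
        retained[(db, subj)] = rids

    read_dbs: dict[str, set] = defaultdict(set)
    read_subjects: dict[str, list] = defaultdict(list)
    for (db, subj), rids in retained.items():
        for rid in rids:
            read_dbs[rid].add(db)
            read_subjects[rid].append((db, subj))

    evidence: dict[tuple, GeneEvidence] = {}
    for (db, subj), rids in sorted(retained.items()):
        if db in GENOME_TAGS:
            genome = GENOME_OF_TAG[db]
        else:
            genome = db
        chrom = pos = None
        if gene_table and subj in gene_table:
            info = gene_table[subj]
            chrom, pos = info[1], info[2]
        profile = set()
        unig = False
        for rid in rids:
            for g in read_dbs[rid] & set(GENOME_TAGS):
                profile.add(GENOME_OF_TAG[g])
            if read_dbs[rid] & {"unigene", "uniprot"}:
                unig = True
        evidence[(db, subj)] = GeneEvidence(
            gene_id=subj, genome=genome, chromosome=chrom, position=pos,
            supporting_reads=set(rids), conservation_profile=profile,
            unig_uniprot_support=unig)

    # loci: connected components of genome-gene evidence linked by shared reads
    genome_keys = sorted(k for k in evidence if k[0] in GENOME_TAGS)
    parent = {k: k for k in genome_keys}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for rid in sorted(read_subjects):
        keys = sorted((db, s) for db, s in read_subjects[rid] if db in GENOME_TAGS)
        for a, b in zip(keys, keys[1:]):
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb

    loci: dict[tuple, list] = defaultdict(list)
    for k in genome_keys:
        loci[find(k)].append(k)
    venn = {c: 0 for c in VENN_CLASSES}
    venn_support = {c: 0 for c in VENN_CLASSES}
    for idx, (root, keys) in enumerate(sorted(loci.items())):
        genomes = sorted({GENOME_OF_TAG[db] for db, _ in keys})
        cls = "".join(genomes)
        unig = any(evidence[k].unig_uniprot_support for k in keys)
        for k in keys:
            evidence[k].locus = idx
        if cls in venn:
            venn[cls] += 1
            if unig:
                venn_support[cls] += 1
    support_fraction = {c: (venn_support[c] / venn[c] if venn[c] else None)
                        for c in VENN_CLASSES}
    return {"catalogue": evidence, "venn": venn,
            "venn_unig_uniprot_fraction": support_fraction,
            "n_loci": sum(venn.values())}


def contrast_arms(venn1: dict, venn2: dict) -> dict:
    """Two-tailed Fisher p per Venn class: class count vs rest, arm 1 vs arm 2."""
    n1, n2 = sum(venn1.values()), sum(venn2.values())
    out = {}
    for cls in VENN_CLASSES:
        a, c = venn1.get(cls, 0), venn2.get(cls, 0)
        out[cls] = fisher_two_tailed(a, n1 - a, c, n2 - c)
    return out
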