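"""End-to-end composition of the survey stages at desk scale.

The driver wires the stages together in the order the analysis prescribes:
repeat removal (library masking + deep-contig flagging), the organellar
filter, per-database similarity searches with the quality cascade,
reciprocal-best-hit retention, artifact deduplication, catalogue
construction, and zipper building.  Desk-scale searches run the internal
nucleotide-mode aligner against reference coding sequences; externally
produced BLAST tables can be substituted for any search through
``seqio.read_hits_tabular``.

The reverse search needed for reciprocal-best-hit filtering is the
transpose of the forward search here: the internal aligner scores
symmetrically, so each forward hit is re-labelled with query and subject
exchanged rather than recomputed.
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict

from . import homology, repeatscan, simgen, zipper as zipmod
from .align import internal_search
from .seqio import AlignmentHit, SurveyRead

GENOME_DB = {"A": "genomeA", "B": "genomeB", "C": "genomeC"}


def masked_query_sequence(read: SurveyRead) -> str:
    """Read sequence with masked intervals replaced by N (excluded from
    seeding and never counted as identity)."""
    if not read.masked:
        return read.sequence
    seq = read.sequence
    out = []
    pos = 0
    for s, e in read.masked:
        out.append(seq[pos:s])
        out.append("N" * (e - s))
        pos = e
    out.append(seq[pos:])
    return "".join(out)


def transpose_hit(h: AlignmentHit) -> AlignmentHit:
    return dataclasses.replace(
        h, query_id=h.subject_id, subject_id=h.query_id,
        q_start=h.s_start, q_end=h.s_end, s_start=h.q_start, s_end=h.q_end)


def run_repeat_filter(reads: list[SurveyRead], repeat_library,
                      depth_threshold: float = 5.0) -> dict:
    """Library masking + greedy assembly + deep-contig flagging."""
    mask = repeatscan.library_mask(reads, repeat_library)
    assembly = repeatscan.overlap_assemble(reads)
    deep = repeatscan.flag_deep_contig_reads(assembly.contigs, depth_threshold,
                                             total_reads=len(reads))
    summary = repeatscan.nonrepetitive_summary(reads, assembly, deep["read_ids"])
    return {"assembly": assembly, "deep": deep, "mask": mask, **summary}


def run_homology(reads: list[SurveyRead], panel: simgen.ReferencePanel,
                 organelle_genome: str | None = None,
                 unigene_db: list | None = None) -> dict:
    """Organellar filter, per-genome searches, cascade, RBH, dedup, catalogue."""
    queries = [(r.read_id, masked_query_sequence(r)) for r in reads]
    seq_of = dict(queries)

    removed_organellar: list[str] = []
    if organelle_genome:
        org_hits = internal_search(queries, [("organelle", organelle_genome)],
                                   mode="nt", db_tag="organelle", min_seeds=2)
        res = homology.filter_organellar(reads, org_hits)
        removed_organellar = res["removed_ids"]
        reads = res["reads"]
        queries = [(r.read_id, seq_of[r.read_id]) for r in reads]

    assignments_by_db: dict[str, list[AlignmentHit]] = {}
    dropped_artifacts: dict[str, list[str]] = {}
    read_seq = {r.read_id: r.sequence for r in reads}
    # one combined search over the three genomes (one index build / seed
    # pass per read), split into per-database hit sets afterwards
    combined = []
    db_of_gene: dict[str, str] = {}
    for g, genome in sorted(panel.genomes.items()):
        for rec in genome.cds_records():
            combined.append(rec)
            db_of_gene[rec[0]] = GENOME_DB[g]
    all_hits = internal_search(queries, combined, mode="nt", db_tag="genomeA",
                               max_candidates=12)
    per_db: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in all_hits:
        db = db_of_gene[h.subject_id]
        per_db[db].append(dataclasses.replace(h, db_tag=db))
    for g in sorted(panel.genomes):
        db = GENOME_DB[g]
        fwd = homology.filter_nucleotide_hits(per_db.get(db, []), same_species=False,
                                              best_per_read=False)
        rev = [transpose_hit(h) for h in fwd]
        rbh = homology.reciprocal_best(fwd, rev)
        dd = homology.dedup_artifacts(rbh, read_seq)
        assignments_by_db[db] = dd["assignments"]
        dropped_artifacts[db] = dd["dropped_read_ids"]
    if unigene_db:
        hits = internal_search(queries, unigene_db, mode="nt", db_tag="unigene")
        fwd = homology.filter_nucleotide_hits(hits, same_species=False)
        dd = homology.dedup_artifacts(fwd, read_seq)
        assignments_by_db["unigene"] = dd["assignments"]
        dropped_artifacts["unigene"] = dd["dropped_read_ids"]

    cat = homology.build_gene_catalogue(assignments_by_db, panel.gene_table())
    return {"reads": reads, "assignments_by_db": assignments_by_db,
            "catalogue": cat["catalogue"], "venn": cat["venn"],
            "venn_unig_uniprot_fraction": cat["venn_unig_uniprot_fraction"],
            "n_loci": cat["n_loci"],
            "removed_organellar": removed_organellar,
            "dropped_artifacts": dropped_artifacts}


def run_zipper(hom: dict, panel: simgen.ReferencePanel, markers, bin_order,
               backbone: str = "A") -> dict:
    """Blocks, marker anchoring, zipper rows and the segment model."""
    catalogue = hom["catalogue"]
    read_seqs = {r.read_id: r.sequence for r in hom["reads"]}
    genome = panel.genomes[backbone]
    reference_order = [g.gene_id for g in genome.genes
                       if g.chromosome == simgen.CHROM_MAIN]
    tracks = zipmod.catalogue_tracks(catalogue, backbone)
    gp = defaultdict(list)
    for (db, _), ev in catalogue.items():
        if ev.genome == backbone and ev.chromosome is not None:
            gp[ev.chromosome].append(ev.position)
    blocks = zipmod.call_syntenic_blocks(tracks, gene_positions=dict(gp))
    rows = zipmod.build_zipper(catalogue, reference_order, markers, bin_order,
                               read_seqs=read_seqs, blocks=blocks,
                               backbone=backbone)
    model = zipmod.detect_rearrangements(rows, reference_order)
    return {"rows": rows, "blocks": blocks, "segment_model": model,
            "reference_order": reference_order}


def simulate_all(config: simgen.SimConfig) -> dict:
    """Full simulation bundle for one arm under one config."""
    panel = simgen.simulate_reference_genomes(config)
    arm = simgen.simulate_wheat_arm(config, panel)
    contaminant = (simgen.simulate_contaminant_arm(config, panel)
                   if config.purity < 1.0 else None)
    reads = simgen.simulate_reads(arm, contaminant, config)
    markers, transcripts = simgen.simulate_markers_and_transcripts(arm, config)
    return {"panel": panel, "arm": arm, "reads": reads,
            "markers": markers, "transcripts": transcripts,
            "bin_order": [b for b, _, _ in arm.truth.bin_boundaries]}
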