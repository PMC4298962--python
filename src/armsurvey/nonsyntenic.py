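"""Validation of non-syntenic conserved genes and wheat-specific calls.

Genes conserved with all three model genomes but lying outside the arm's
syntenic blocks may be genuine lineage-specific translocations — or
pseudogene fragments and spurious matches.  Genuine genes attract reads
spread along their length; artefacts cluster.  The evenness test divides a
gene into k = min(n_reads, 4) equal segments and calls it genuine only if
every segment is overlapped by at least one read.  Genuine non-syntenic
genes whose three reference orthologs are mutually syntenic among the
references themselves are then called putative wheat-specific
rearrangements.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from .seqio import AlignmentHit, normalize_intervals
from .zipper import SyntenicBlock, call_syntenic_blocks, window_density


@dataclass
class CoverageProfile:
    """Read placements along one reference gene."""

    gene_id: str
    gene_len: int
    read_intervals: list = field(default_factory=list)   # half-open, on the gene

    def __post_init__(self):
        for s, e in self.read_intervals:
            if not (0 <= s < e <= self.gene_len):
                raise ValueError(f"read interval ({s}, {e}) outside gene of "
                                 f"length {self.gene_len}")

    @property
    def n_reads(self) -> int:
        return len(self.read_intervals)


def evenness_test(profile: CoverageProfile, n_segments_cap: int = 4) -> str:
    """``genuine`` iff each of k = min(n_reads, cap) equal-length segments
    is overlapped by at least one read; otherwise ``artefactual``."""
    n = profile.n_reads
    if n < 2:
        raise ValueError("evenness test requires >= 2 reads "
                         "(single-read genes are eliminated upstream)")
    k = min(n, n_segments_cap)
    L = profile.gene_len
    for i in range(k):
        seg_start = i * L / k
        seg_end = (i + 1) * L / k
        if not any(s < seg_end and e > seg_start for s, e in profile.read_intervals):
            return "artefactual"
    return "genuine"


def coverage_profiles(catalogue: dict, assignments_by_db: dict,
                      gene_lengths: dict, backbone_db: str = "genomeA") -> dict:
    """Build per-gene coverage profiles from retained backbone assignments."""
    by_gene: dict[str, list] = defaultdict(list)
    for h in assignments_by_db.get(backbone_db, []):
        by_gene[h.subject_id].append((h.s_start, h.s_end))
    out = {}
    for gid, ivs in by_gene.items():
        L = gene_lengths.get(gid)
        if L is None:
            continue
        ivs = [(max(0, s), min(L, e)) for s, e in ivs if min(L, e) > max(0, s)]
        out[gid] = CoverageProfile(gid, L, ivs)
    return out


def find_nonsyntenic_conserved(catalogue: dict, blocks: list[SyntenicBlock],
                               backbone: str = "A", min_reads: int = 2) -> list:
    """Genes conserved in all three genomes, with >= 2 supporting reads,
    whose backbone position lies outside every syntenic block."""
    out = []
    for (db, _), ev in sorted(catalogue.items()):
        if ev.genome != backbone or ev.chromosome is None:
            continue
        if ev.conservation_profile != {"A", "B", "C"}:
            continue
        if len(ev.supporting_reads) < min_reads:
            continue
        if any(b.contains(ev.chromosome, ev.position) for b in blocks):
            continue
        out.append(ev)
    return out


def build_cross_genome_synteny(position_tables: dict, orthologs: list[dict],
                               min_genes_per_mb: float = 50.0,
                               window: int = 500_000, step: int = 50_000) -> dict:
    """Mutual-synteny table among the reference genomes.

    ``position_tables``: genome -> {gene_id: (chromosome, position)}.
    ``orthologs``: one dict per ortholog group mapping genome -> gene_id
    (missing genomes omitted).  A pair of genomes is syntenic for a group
    when both members lie inside a dense block of shared-ortholog positions
    (the same block-calling machinery, applied pairwise); a group is
    mutually syntenic when all three pairs are.  Returns backbone gene_id ->
    bool for groups with all three members.
    """
    genomes = sorted(position_tables)
    pair_blocks: dict[tuple, dict] = {}
    for i, gx in enumerate(genomes):
        for gy in genomes[i + 1:]:
            shared = [o for o in orthologs if gx in o and gy in o]
            for qa, qb in ((gx, gy), (gy, gx)):
                positions: dict[str, list[int]] = defaultdict(list)
                for o in shared:
                    chrom, pos = position_tables[qa][o[qa]]
                    positions[chrom].append(pos)
                tracks = {"pair": window_density(dict(positions), window, step)}
                pair_blocks[(qa, qb)] = call_syntenic_blocks(
                    tracks, min_genes_per_mb=min_genes_per_mb, min_species=1,
                    window=window, step=step,
                    gene_positions=dict(positions))
    table = {}
    backbone = genomes[0]
    for o in orthologs:
        if len(o) < 3:
            continue
        ok = True
        for i, gx in enumerate(genomes):
            for gy in genomes[i + 1:]:
                cx, px = position_tables[gx][o[gx]]
                cy, py = position_tables[gy][o[gy]]
                in_x = any(b.contains(cx, px) for b in pair_blocks[(gx, gy)])
                in_y = any(b.contains(cy, py) for b in pair_blocks[(gy, gx)])
                if not (in_x and in_y):
                    ok = False
        table[o[backbone]] = ok
    return table


def classify_wheat_specific(candidates: list, verdicts: dict,
                            synteny_table: dict,
                            triplet_ids: dict | None = None) -> list[dict]:
    """Call putative wheat-specific rearrangements.

    ``candidates``: non-syntenic conserved gene evidence (backbone keyed);
    ``verdicts``: gene_id -> genuine/artefactual from the evenness test;
    ``synteny_table``: backbone gene_id -> mutually syntenic among the three
    references; ``triplet_ids``: backbone gene_id -> (idA, idB, idC) for
    reporting.  Genes missing from the synteny table are skipped with a
    warning entry.
    """
    import warnings

    calls = []
    for ev in candidates:
        gid = ev.gene_id
        if verdicts.get(gid) != "genuine":
            continue
        if gid not in synteny_table:
            warnings.warn(f"no cross-genome synteny row for {gid}; skipped",
                          stacklevel=2)
            continue
        if not synteny_table[gid]:
            continue
        calls.append({
            "gene_id": gid,
            "triplet": (triplet_ids or {}).get(gid),
            "n_reads": len(ev.supporting_reads),
            "call": "wheat_specific",
        })
    return calls
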