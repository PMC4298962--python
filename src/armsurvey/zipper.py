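"""Virtual gene order ("genome zipper"), syntenic blocks and rearrangements.

A survey without an assembly cannot order its genes directly.  The zipper
orders them indirectly: deletion-bin-mapped markers give coarse order along
the arm (macro order), and colinearity with a sequenced reference genome
gives order within each co-linear block (micro order).  Bin order wins
between blocks; reference order wins within blocks.  Comparing the
resulting order with the reference's own order exposes rearrangements as
breaks in co-linearity: the permutation is decomposed greedily into maximal
co-linear runs with orientation, long runs being "segments" and short ones
small-scale translocations.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import internal_search
from .seqio import MarkerRecord
from .surveystats import fisher_two_tailed

WINDOW = 500_000
STEP = 50_000
MIN_GENES_PER_MB = 50
MIN_SPECIES = 2
MIN_SEGMENT_GENES = 5


@dataclass
class ZipperRow:
    index: int
    ref_gene: str
    ref_chrom: str
    ref_pos: int
    wheat_reads: set
    bin: str | None
    map_position: float | None
    syntenic: bool


@dataclass
class SyntenicBlock:
    ref_chrom: str
    start: int
    end: int
    arm: str = ""
    gene_count: int = 0
    species_support: set = field(default_factory=set)
    orientation: str = "unknown"

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.ref_chrom and self.start <= pos < self.end


# ---------------------------------------------------------------------------
# density and blocks

def window_density(gene_positions: dict[str, list[int]], window: int = WINDOW,
                   step: int = STEP) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Sliding-window conserved-gene counts per chromosome.

    Genes are assigned to every window covering their (midpoint) position;
    returns ``{chrom: (window_starts, counts)}``.
    """
    if step > window:
        raise ValueError("step must not exceed window")
    out = {}
    for chrom, positions in gene_positions.items():
        pos = np.sort(np.asarray(list(positions), dtype=np.int64))
        if len(pos) == 0:
            out[chrom] = (np.zeros(1, dtype=np.int64), np.zeros(1, dtype=np.int64))
            continue
        last = int(pos[-1])
        starts = np.arange(0, last + 1, step, dtype=np.int64)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, starts + window, side="left")
        out[chrom] = (starts, hi - lo)
    return out


def call_syntenic_blocks(tracks: dict[str, dict], min_genes_per_mb: float = MIN_GENES_PER_MB,
                         min_species: int = MIN_SPECIES, window: int = WINDOW,
                         step: int = STEP, arm: str = "",
                         gene_positions: dict[str, list[int]] | None = None
                         ) -> list[SyntenicBlock]:
    """Merge windows dense in >= ``min_species`` species' tracks into blocks.

    ``tracks`` maps species -> window_density output on a shared reference
    coordinate grid.  The per-window threshold is ``min_genes_per_mb``
    scaled to the window size.
    """
    threshold = min_genes_per_mb * window / 1e6
    chroms = sorted({c for t in tracks.values() for c in t})
    blocks: list[SyntenicBlock] = []
    for chrom in chroms:
        series = []
        length = 0
        for sp, t in tracks.items():
            if chrom in t:
                length = max(length, len(t[chrom][0]))
        support_sets: list[set] = [set() for _ in range(length)]
        for sp, t in tracks.items():
            if chrom not in t:
                continue
            starts, counts = t[chrom]
            for i, c in enumerate(counts):
                if c >= threshold:
                    support_sets[i].add(sp)
        current = None
        for i in range(length + 1):
            qualified = i < length and len(support_sets[i]) >= min_species
            if qualified:
                w_start, w_end = i * step, i * step + window
                if current is None:
                    current = SyntenicBlock(chrom, w_start, w_end, arm=arm)
                else:
                    current.end = w_end
                current.species_support |= support_sets[i]
            elif current is not None:
                blocks.append(current)
                current = None
        # merged maximal runs
    if gene_positions:
        for b in blocks:
            pos = np.sort(np.asarray(gene_positions.get(b.ref_chrom, []), dtype=np.int64))
            b.gene_count = int(np.searchsorted(pos, b.end) - np.searchsorted(pos, b.start))
    return blocks


def catalogue_tracks(catalogue: dict, backbone: str = "A") -> dict:
    """Per-species density tracks on the backbone genome's coordinates.

    For species X the track counts backbone genes (with their chromosome
    and position) whose locus is also conserved in X.
    """
    per_species: dict[str, dict[str, list[int]]] = {s: defaultdict(list)
                                                    for s in ("A", "B", "C")}
    for (db, _), ev in catalogue.items():
        if ev.genome != backbone or ev.chromosome is None:
            continue
        for sp in ("A", "B", "C"):
            if sp in ev.conservation_profile or sp == backbone:
                per_species[sp][ev.chromosome].append(ev.position)
    return {sp: window_density(dict(chroms)) for sp, chroms in per_species.items()}


# ---------------------------------------------------------------------------
# marker anchoring

def anchor_markers(markers: list[MarkerRecord], catalogue: dict,
                   read_seqs: dict[str, str], backbone: str = "A",
                   min_identity: float = 95.0, min_len: int = 30) -> dict:
    """Assign deletion bins to backbone genes via marker-read matches.

    A marker anchors the gene whose supporting read it matches at
    >= ``min_identity`` % identity over >= ``min_len`` nt; conflicting bins
    for one gene resolve by majority (ties to the bin seen first in marker
    order).  Returns gene_id -> (bin, map_position).
    """
    gene_of_read: dict[str, list[str]] = defaultdict(list)
    backbone_genes = {ev.gene_id: ev for (db, _), ev in catalogue.items()
                      if ev.genome == backbone}
    involved: dict[str, str] = {}
    for gid, ev in backbone_genes.items():
        for rid in ev.supporting_reads:
            gene_of_read[rid].append(gid)
            if rid in read_seqs:
                involved[rid] = read_seqs[rid]
    if not involved or not markers:
        return {}
    hits = internal_search([(m.marker_id, m.sequence) for m in markers],
                           sorted(involved.items()), mode="nt",
                           db_tag="dataset_ext", min_seeds=1)
    by_marker = {m.marker_id: m for m in markers}
    votes: dict[str, list] = defaultdict(list)
    for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
        if h.pct_identity < min_identity or h.aln_len < min_len:
            continue
        m = by_marker[h.query_id]
        for gid in gene_of_read[h.subject_id]:
            votes[gid].append((m.bin, m.map_position))
    anchored = {}
    for gid, vs in votes.items():
        counts = Counter(b for b, _ in vs)
        top = max(counts.values())
        bin_ = next(b for b, _ in vs if counts[b] == top)
        mp = next((p for b, p in vs if b == bin_ and p is not None), None)
        anchored[gid] = (bin_, mp)
    return anchored


# ---------------------------------------------------------------------------
# zipper construction

def build_zipper(catalogue: dict, reference_order: list[str],
                 markers: list[MarkerRecord], bin_order: list[str],
                 read_seqs: dict[str, str] | None = None,
                 blocks: list[SyntenicBlock] | None = None,
                 backbone: str = "A",
                 anchors: dict | None = None) -> list[ZipperRow]:
    """Order the arm's conserved genes into a virtual gene map.

    Syntenic genes (inside called blocks) are segmented where the marker
    bins break co-linearity; segments are ordered by their anchoring bins,
    genes within a segment by reference position respecting the segment's
    orientation (sign of the bin/position rank correlation).  Non-syntenic
    conserved genes with a marker-supported bin are appended with bin-only
    placement.
    """
    bin_rank = {b: i for i, b in enumerate(bin_order)}
    backbone_genes = {ev.gene_id: ev for (db, _), ev in catalogue.items()
                      if ev.genome == backbone and ev.chromosome is not None}
    if blocks is None:
        tracks = catalogue_tracks(catalogue, backbone)
        gp: dict[str, list[int]] = defaultdict(list)
        for ev in backbone_genes.values():
            gp[ev.chromosome].append(ev.position)
        blocks = call_syntenic_blocks(tracks, gene_positions=dict(gp))
    if anchors is None:
        anchors = anchor_markers(markers, catalogue, read_seqs or {}, backbone)
    for gid, (b, _) in anchors.items():
        if b not in bin_rank:
            raise ValueError(f"marker bin {b!r} absent from declared bin order")

    ref_rank = {g: i for i, g in enumerate(reference_order)}
    syntenic, nonsyntenic = [], []
    for gid, ev in backbone_genes.items():
        (syntenic if any(bl.contains(ev.chromosome, ev.position) for bl in blocks)
         else nonsyntenic).append(ev)
    syntenic.sort(key=lambda e: (ref_rank.get(e.gene_id, 1 << 30),
                                 e.chromosome, e.position))

    # segment the reference order where marker bins break co-linearity
    segments: list[list] = []
    seg_marked: list[list] = []
    prev_bin = None
    direction = 0
    current: list = []
    marked_in_current: list = []
    prev_chrom = None
    for ev in syntenic:
        b = anchors.get(ev.gene_id, (None, None))[0]
        br = bin_rank.get(b) if b is not None else None
        new_seg = False
        if prev_chrom is not None and ev.chromosome != prev_chrom:
            new_seg = True
        elif br is not None and prev_bin is not None:
            d = br - prev_bin
            if abs(d) > 1:
                new_seg = True
            elif d != 0 and direction != 0 and np.sign(d) != direction:
                new_seg = True
        if new_seg and current:
            segments.append(current)
            seg_marked.append(marked_in_current)
            current, marked_in_current = [], []
            direction = 0
            prev_bin = br
        current.append(ev)
        if br is not None:
            if prev_bin is not None and not new_seg and br != prev_bin:
                direction = int(np.sign(br - prev_bin))
            prev_bin = br
            marked_in_current.append((ev, br))
        prev_chrom = ev.chromosome
    if current:
        segments.append(current)
        seg_marked.append(marked_in_current)

    # reassign boundary genes that sit closer to the neighbouring segment's
    # first marker than to their own segment's last marker: not needed at
    # desk scale; unmarked genes inherit the segment they fall in by
    # reference adjacency (construction above).

    def seg_key(i: int):
        marked = seg_marked[i]
        if marked:
            return (0, float(np.mean([br for _, br in marked])), i)
        # marker-less segments placed by reference adjacency: keep next to
        # their reference neighbours via their order of appearance
        return (0, _nearest_marked_rank(seg_marked, i), i)

    order = sorted(range(len(segments)), key=seg_key)

    rows: list[ZipperRow] = []
    idx = 0
    for i in order:
        seg = segments[i]
        marked = seg_marked[i]
        orientation = "+"
        if len({br for _, br in marked}) >= 2:
            ranks = [ref_rank.get(ev.gene_id, 0) for ev, _ in marked]
            tau, _ = sps.kendalltau(ranks, [br for _, br in marked])
            if tau is not None and not np.isnan(tau) and tau < 0:
                orientation = "-"
        ordered = sorted(seg, key=lambda e: (e.chromosome, e.position))
        if orientation == "-":
            ordered = ordered[::-1]
        for ev in ordered:
            b, mp = anchors.get(ev.gene_id, (None, None))
            rows.append(ZipperRow(idx, ev.gene_id, ev.chromosome, ev.position,
                                  set(ev.supporting_reads), b, mp, True))
            idx += 1
    appended = [ev for ev in nonsyntenic if ev.gene_id in anchors]
    appended.sort(key=lambda e: (bin_rank[anchors[e.gene_id][0]], e.chromosome, e.position))
    for ev in appended:
        b, mp = anchors[ev.gene_id]
        rows.append(ZipperRow(idx, ev.gene_id, ev.chromosome, ev.position,
                              set(ev.supporting_reads), b, mp, False))
        idx += 1
    return rows


def _nearest_marked_rank(seg_marked: list, i: int) -> float:
    for off in range(1, len(seg_marked)):
        for j in (i - off, i + off):
            if 0 <= j < len(seg_marked) and seg_marked[j]:
                return float(np.mean([br for _, br in seg_marked[j]]))
    return 0.0


# ---------------------------------------------------------------------------
# rearrangement detection

def detect_rearrangements(zipper: list[ZipperRow], reference_order: list[str],
                          min_segment_genes: int = MIN_SEGMENT_GENES) -> dict:
    """Greedy maximal co-linear run decomposition of the zipper/reference
    permutation.

    Runs of >= ``min_segment_genes`` genes are reported as segments with
    orientation; shorter runs as small-scale translocations.  Breakpoint
    intervals are the gene pairs flanking adjacent segment joins.
    """
    ref_rank_all = {g: i for i, g in enumerate(reference_order)}
    genes = [r for r in zipper if r.syntenic and r.ref_gene in ref_rank_all]
    if len(genes) < 2:
        return {"segments": [], "translocations": [], "breakpoints": [],
                "runs": []}
    # dense re-ranking over the recovered subset
    present = sorted((ref_rank_all[r.ref_gene] for r in genes))
    dense = {rank: i for i, rank in enumerate(present)}
    seq = [dense[ref_rank_all[r.ref_gene]] for r in genes]

    runs: list[tuple[int, int, str]] = []   # (start_idx, end_idx) into seq + orientation
    i = 0
    while i < len(seq):
        j = i + 1
        if j < len(seq) and abs(seq[j] - seq[i]) == 1:
            step = seq[j] - seq[i]
            while j < len(seq) and seq[j] - seq[j - 1] == step:
                j += 1
            runs.append((i, j, "+" if step == 1 else "-"))
        else:
            runs.append((i, j, "+"))
        i = j

    all_runs, segments, translocations = [], [], []
    for si, (a, b, orient) in enumerate(runs):
        entry = {
            "genes": [genes[k].ref_gene for k in range(a, b)],
            "orientation": orient,
            "ref_start_gene": genes[a if orient == "+" else b - 1].ref_gene,
            "ref_end_gene": genes[b - 1 if orient == "+" else a].ref_gene,
            "zipper_start": genes[a].index,
            "zipper_end": genes[b - 1].index,
            "n_genes": b - a,
        }
        all_runs.append(entry)
        (segments if b - a >= min_segment_genes else translocations).append(entry)
    breakpoints = []
    for s1, s2 in zip(segments, segments[1:]):
        breakpoints.append((s1["genes"][-1], s2["genes"][0]))
    return {"segments": segments, "translocations": translocations,
            "breakpoints": breakpoints, "runs": all_runs}


def apply_segment_model(segments: list[dict]) -> list[str]:
    """Reconstruct the zipper's syntenic gene order from a segment model."""
    out: list[str] = []
    for seg in segments:
        out.extend(seg["genes"])
    return out


# ---------------------------------------------------------------------------
# per-bin statistics and three-way comparison

def bin_synteny_stats(zipper: list[ZipperRow], min_genes: int = 5) -> pd.DataFrame:
    """Per-bin syntenic/non-syntenic counts with Fisher p (bin vs rest)."""
    binned = [r for r in zipper if r.bin is not None]
    per_bin: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for r in binned:
        per_bin[r.bin][0 if r.syntenic else 1] += 1
    tot_syn = sum(v[0] for v in per_bin.values())
    tot_non = sum(v[1] for v in per_bin.values())
    rows = []
    for b in sorted(per_bin):
        syn, non = per_bin[b]
        p = fisher_two_tailed(syn, non, tot_syn - syn, tot_non - non)
        n = syn + non
        rows.append(dict(bin=b, syntenic=syn, non_syntenic=non,
                         prop_syntenic=round(syn / n, 4) if n else np.nan,
                         fisher_p=p, low_power=n < min_genes))
    return pd.DataFrame(rows)


def compare_zippers(zip1: list[ZipperRow], zip2: list[ZipperRow],
                    zip3: list[ZipperRow], names=("z1", "z2", "z3")) -> dict:
    """Three-way shared/unique syntenic-gene Venn and pairwise link table."""
    sets = [ {r.ref_gene for r in z if r.syntenic} for z in (zip1, zip2, zip3)]
    venn = {}
    for mask in range(1, 8):
        inc = [s for i, s in enumerate(sets) if mask >> i & 1]
        exc = [s for i, s in enumerate(sets) if not mask >> i & 1]
        region = set.intersection(*inc) - (set.union(*exc) if exc else set())
        key = "".join(n for i, n in enumerate(names) if mask >> i & 1)
        venn[key] = len(region)
    pos = [ {r.ref_gene: r.index for r in z if r.syntenic} for z in (zip1, zip2, zip3)]
    links = []
    for g in sorted(set.union(*sets)):
        links.append({"gene": g, **{f"pos_{n}": pos[i].get(g)
                                    for i, n in enumerate(names)}})
    return {"venn": venn, "links": pd.DataFrame(links)}
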