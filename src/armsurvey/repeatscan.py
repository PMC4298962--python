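"""Repeat identification by assembly depth and repeat-library masking.

Collapsed repeats betray themselves in a greedy overlap assembly: reads from
many near-identical TE copies stack into contigs whose read depth far
exceeds the survey's nominal coverage, so members of deep contigs (depth >=
5 by default) are flagged repetitive.  Known families are masked directly
against a repeat library.  The two prongs are combined by
:func:`nonrepetitive_summary`, which also produces the survey's
assembly/filter report (aligned read counts, bases in contigs, estimated
arm length as assembled + unassembled bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import KmerIndex, SEED_K_NT, infix_align
from .seqio import SurveyRead, normalize_intervals


@dataclass
class Contig:
    contig_id: str
    length: int
    member_reads: list = field(default_factory=list)   # (read_id, aligned_len)
    sequence: str = ""

    @property
    def depth(self) -> float:
        """Total aligned member bases over contig length."""
        return sum(l for _, l in self.member_reads) / self.length if self.length else 0.0


@dataclass
class AssemblyResult:
    contigs: list                 # Contig
    singleton_ids: list           # read ids in no contig

    def member_ids(self) -> set:
        return {rid for c in self.contigs for rid, _ in c.member_reads}


def overlap_assemble(reads: list[SurveyRead], min_overlap: int = 40,
                     min_contig: int = 40) -> AssemblyResult:
    """Greedy exact suffix/prefix overlap layout.

    Ties are broken by longest overlap first, then lexicographic read id;
    byte-identical reads and reads contained in another read are attached to
    their container's contig rather than opening a layout node.  The result
    is deterministic for a given read set regardless of input order.
    """
    if not reads:
        raise ValueError("no reads to assemble")
    reads = sorted(reads, key=lambda r: r.read_id)
    seq_of = {r.read_id: r.sequence for r in reads}

    # collapse byte-identical reads onto a lexicographically-smallest holder
    holder: dict[str, str] = {}
    attached: dict[str, list[str]] = {}
    for r in reads:
        h = holder.get(r.sequence)
        if h is None:
            holder[r.sequence] = r.read_id
            attached[r.read_id] = []
        else:
            attached[h].append(r.read_id)
    nodes = sorted(attached)   # distinct-sequence representatives

    prefix_index: dict[str, list[str]] = {}
    for rid in nodes:
        s = seq_of[rid]
        if len(s) >= min_overlap:
            prefix_index.setdefault(s[:min_overlap], []).append(rid)

    overlap_edges: list[tuple[int, str, str]] = []
    containments: list[tuple[str, str]] = []   # (container, contained)
    for a in nodes:
        sa = seq_of[a]
        for p in range(0, len(sa) - min_overlap + 1):
            key = sa[p:p + min_overlap]
            for b in prefix_index.get(key, ()):
                if b == a:
                    continue
                sb = seq_of[b]
                o = len(sa) - p
                if len(sb) <= o:
                    if sa[p:p + len(sb)] == sb:
                        containments.append((a, b))
                elif sa[p:] == sb[:o]:
                    overlap_edges.append((o, a, b))

    contained = {b for _, b in containments}
    container_of: dict[str, str] = {}
    for a, b in sorted(containments):
        container_of.setdefault(b, a)

    # greedy path building among non-contained nodes
    succ: dict[str, tuple[str, int]] = {}
    pred: dict[str, str] = {}
    parent: dict[str, str] = {rid: rid for rid in nodes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for o, a, b in sorted(overlap_edges, key=lambda e: (-e[0], e[1], e[2])):
        if a in contained or b in contained:
            continue
        if a in succ or b in pred or find(a) == find(b):
            continue
        succ[a] = (b, o)
        pred[b] = a
        parent[find(a)] = find(b)

    contigs: list[Contig] = []
    singles: list[str] = []
    path_heads = sorted(rid for rid in nodes if rid not in contained and rid not in pred)
    contig_of: dict[str, Contig] = {}
    serial = 0
    for head in path_heads:
        members = [head]
        seq_parts = [seq_of[head]]
        cur = head
        while cur in succ:
            nxt, o = succ[cur]
            seq_parts.append(seq_of[nxt][o:])
            members.append(nxt)
            cur = nxt
        sequence = "".join(seq_parts)
        if len(members) == 1 and not attached[head]:
            singles.append(head)
            continue
        contig = Contig(f"ctg{serial:06d}", len(sequence), [], sequence)
        serial += 1
        for rid in members:
            contig.member_reads.append((rid, len(seq_of[rid])))
            for dup in attached[rid]:
                contig.member_reads.append((dup, len(seq_of[dup])))
            contig_of[rid] = contig
        contigs.append(contig)

    # attach contained reads (and their duplicates) to the container's contig
    for b in sorted(contained):
        a = container_of[b]
        while a in contained:
            a = container_of[a]
        target = contig_of.get(a)
        if target is None:
            # container was a singleton; promote it to a contig
            target = Contig(f"ctg{serial:06d}", len(seq_of[a]), [(a, len(seq_of[a]))],
                            seq_of[a])
            serial += 1
            for dup in attached[a]:
                target.member_reads.append((dup, len(seq_of[dup])))
            contigs.append(target)
            contig_of[a] = target
            if a in singles:
                singles.remove(a)
        target.member_reads.append((b, len(seq_of[b])))
        for dup in attached[b]:
            target.member_reads.append((dup, len(seq_of[dup])))
        contig_of[b] = target

    contigs = [c for c in contigs if c.length >= min_contig]
    kept = {rid for c in contigs for rid, _ in c.member_reads}
    singles = sorted(set(seq_of) - kept)
    return AssemblyResult(contigs, singles)


def flag_deep_contig_reads(contigs: list[Contig], depth_threshold: float = 5.0,
                           total_reads: int | None = None) -> dict:
    """Reads belonging to contigs of depth >= threshold (collapsed repeats)."""
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    deep = [c for c in contigs if c.depth >= depth_threshold]
    ids = {rid for c in deep for rid, _ in c.member_reads}
    report = {
        "deep_contigs": len(deep),
        "deep_contig_reads": len(ids),
        "deep_contig_reads_pct": (round(100.0 * len(ids) / total_reads, 2)
                                  if total_reads else None),
    }
    return {"read_ids": ids, "report": report}


def library_mask(reads: list[SurveyRead], repeat_library: list[tuple[str, str]],
                 min_identity: float = 80.0, min_len: int = 50) -> dict:
    """Mask read intervals similar to repeat-library elements.

    Seed matching against a k-mer index of the library, diagonal chaining,
    and edit-distance verification of each chained interval; intervals of
    >= ``min_len`` nt at >= ``min_identity`` % identity are added to the
    read's mask.  Returns per-family masked-length percentages alongside the
    (mutated in place) reads.
    """
    if not repeat_library:
        raise ValueError("empty repeat library")
    index = KmerIndex(repeat_library, k=SEED_K_NT)
    fam_masked: dict[str, int] = {name: 0 for name, _ in repeat_library}
    total_len = sum(len(r) for r in reads)
    for read in reads:
        seeded = index.seeds(read.sequence)
        new_intervals: list[tuple[int, int]] = []
        for subj_idx, seeds in seeded.items():
            fam, element = repeat_library[subj_idx]
            for qlo, qhi, slo, shi in _chain_intervals(seeds, SEED_K_NT,
                                                       len(read.sequence), len(element)):
                if qhi - qlo < min_len:
                    continue
                aln = infix_align(read.sequence[qlo:qhi], element[slo:shi])
                if aln is None:
                    continue
                q_lead, q_span, _, _, cols, matches, _ = aln
                if q_span >= min_len and cols \
                        and 100.0 * matches / cols >= min_identity:
                    new_intervals.append((qlo + q_lead, qlo + q_lead + q_span))
                    fam_masked[fam] += q_span
        if new_intervals:
            read.masked = normalize_intervals(read.masked + new_intervals,
                                              len(read.sequence))
    table = {fam: round(100.0 * masked / total_len, 3) if total_len else 0.0
             for fam, masked in sorted(fam_masked.items())}
    return {"reads": reads, "family_pct": table,
            "total_masked_pct": round(
                100.0 * sum(r.masked_length for r in reads) / total_len, 3)
                if total_len else 0.0}


def _chain_intervals(seeds, k, qlen, slen, band: int = 40, margin: int = 30,
                     max_gap: int = 120):
    """Group diagonal-consistent seeds into candidate (q, s) intervals."""
    by_diag = sorted(seeds, key=lambda t: (t[1] - t[0], t[0]))
    chains: list[list[tuple[int, int]]] = []
    for qp, sp in by_diag:
        d = sp - qp
        placed = False
        for chain in chains:
            cq, cs = chain[-1]
            if abs((cs - cq) - d) <= band and abs(qp - cq) <= max_gap + k:
                chain.append((qp, sp))
                placed = True
                break
        if not placed:
            chains.append([(qp, sp)])
    out = []
    for chain in chains:
        if len(chain) < 2:
            continue
        qlo = max(0, min(q for q, _ in chain) - margin)
        qhi = min(qlen, max(q for q, _ in chain) + k + margin)
        slo = max(0, min(s for _, s in chain) - 2 * margin)
        shi = min(slen, max(s for _, s in chain) + k + 2 * margin)
        out.append((qlo, qhi, slo, shi))
    return out


def nonrepetitive_summary(reads: list[SurveyRead], assembly: AssemblyResult,
                          deep_read_ids: set,
                          majority_masked_cutoff: float = 0.5) -> dict:
    """Combine the two repeat prongs and produce the Table-2-style report.

    Deep-contig reads and majority-masked reads are removed; partially
    masked survivors keep their mask so downstream alignment can exclude the
    masked intervals.  Estimated arm length = bases in contigs + bases of
    unassembled (singleton) reads.
    """
    total_reads = len(reads)
    total_bases = sum(len(r) for r in reads)
    by_id = {r.read_id: r for r in reads}
    aligned_ids = assembly.member_ids()
    bases_in_contigs = sum(c.length for c in assembly.contigs)
    non_aligned = sum(len(by_id[rid]) for rid in assembly.singleton_ids)
    report = {
        "total_reads": total_reads,
        "total_bases": total_bases,
        "aligned_reads": len(aligned_ids),
        "aligned_reads_pct": round(100.0 * len(aligned_ids) / total_reads, 2)
                             if total_reads else 0.0,
        "aligned_bases": sum(l for c in assembly.contigs for _, l in c.member_reads),
        "singleton_reads": len(assembly.singleton_ids),
        "n_contigs": len(assembly.contigs),
        "n_contigs_gt100": sum(1 for c in assembly.contigs if c.length > 100),
        "bases_in_contigs": bases_in_contigs,
        "non_aligned_bases": non_aligned,
        "estimated_arm_length": bases_in_contigs + non_aligned,
        "deep_contig_reads": len(deep_read_ids),
        "deep_contig_reads_pct": round(100.0 * len(deep_read_ids) / total_reads, 2)
                                 if total_reads else 0.0,
    }
    filtered, removed = [], []
    for r in reads:
        if r.read_id in deep_read_ids or r.masked_fraction > majority_masked_cutoff:
            removed.append(r.read_id)
        else:
            filtered.append(r)
    report["repetitive_reads_removed"] = len(removed)
    report["nonrepetitive_reads"] = len(filtered)
    report["nonrepetitive_bases"] = sum(len(r) - r.masked_length for r in filtered)
    return {"reads": filtered, "removed_ids": removed, "report": report}
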