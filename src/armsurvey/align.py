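"""Seed-and-extend local alignment for desk-scale similarity searches.

This is the package's internal stand-in for an external BLAST-style search:
a k-mer seed index over the subject set, diagonal-filtered seed chaining,
and edit-distance extension (edlib) in nucleotide mode or Smith-Waterman
with BLOSUM62 (Biopython) in translated mode.  Problems below a size cutoff
skip the heuristics and go straight to exact Smith-Waterman.  E-values are
Karlin-Altschul shaped, E = K * m * n * exp(-lambda * S), with fixed
calibration constants; they make the pipeline's e-value thresholds
meaningful at desk scale and keep externally produced BLAST tables drop-in
compatible, but are not a faithful reimplementation of BLAST statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .seqio import AlignmentHit

# scoring / calibration constants
NT_MATCH, NT_MISMATCH = 2, -3
NT_LAMBDA, NT_K = 0.60, 0.33
AA_LAMBDA, AA_K = 0.267, 0.041
SW_CUTOFF = 100_000          # m*n below this -> exact Smith-Waterman
SEED_K_NT = 13
SEED_K_AA = 4
DIAG_BAND = 40
SEED_MARGIN = 25

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _nt_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.match_score = NT_MATCH
    a.mismatch_score = NT_MISMATCH
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _aa_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(mode="local")
    a.substitution_matrix = BLOSUM62
    a.open_gap_score = -11
    a.extend_gap_score = -1
    return a


def nt_evalue(raw_score: float, m: int, n: int) -> float:
    return NT_K * m * n * float(np.exp(-NT_LAMBDA * raw_score))


def aa_evalue(raw_score: float, m: int, n: int) -> float:
    return AA_K * m * n * float(np.exp(-AA_LAMBDA * raw_score))


# ---------------------------------------------------------------------------
# k-mer index

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Integer codes of all ACGT-only k-mers of ``seq`` and their positions."""
    s = seq.upper()
    n = len(s)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    codes = np.frombuffer(s.encode(), dtype=np.uint8)
    lut = np.full(256, -1, dtype=np.int64)
    for b, v in _BASE_CODE.items():
        lut[ord(b)] = v
    vals = lut[codes]
    ok = vals >= 0
    # rolling polynomial over a window of k
    kmers = np.zeros(n - k + 1, dtype=np.int64)
    valid = np.ones(n - k + 1, dtype=bool)
    for i in range(k):
        kmers = kmers * 4 + np.where(ok[i:n - k + 1 + i], vals[i:n - k + 1 + i], 0)
        valid &= ok[i:n - k + 1 + i]
    pos = np.nonzero(valid)[0]
    return kmers[pos], pos


class KmerIndex:
    """Sorted-array k-mer index over a subject sequence collection."""

    def __init__(self, subjects: list[tuple[str, str]], k: int = SEED_K_NT):
        self.k = k
        self.subjects = subjects
        codes_all, subj_all, pos_all = [], [], []
        for idx, (_, seq) in enumerate(subjects):
            codes, pos = _encode_kmers(seq, k)
            codes_all.append(codes)
            pos_all.append(pos)
            subj_all.append(np.full(len(pos), idx, dtype=np.int64))
        if codes_all:
            codes = np.concatenate(codes_all)
            order = np.argsort(codes, kind="stable")
            self.codes = codes[order]
            self.subj = np.concatenate(subj_all)[order]
            self.pos = np.concatenate(pos_all)[order]
        else:
            self.codes = np.empty(0, dtype=np.int64)
            self.subj = np.empty(0, dtype=np.int64)
            self.pos = np.empty(0, dtype=np.int64)
        self.total_len = sum(len(s) for _, s in subjects)

    def seeds(self, query: str, max_kmer_hits: int = 200
              ) -> dict[int, list[tuple[int, int]]]:
        """Map subject index -> [(q_pos, s_pos), ...] shared k-mer seeds.

        Query k-mers hitting more than ``max_kmer_hits`` index positions are
        ignored as uninformative (high-copy) seeds.
        """
        qcodes, qpos = _encode_kmers(query, self.k)
        if len(qcodes) == 0 or len(self.codes) == 0:
            return {}
        lo = np.searchsorted(self.codes, qcodes, side="left")
        hi = np.searchsorted(self.codes, qcodes, side="right")
        counts = hi - lo
        keep = (counts > 0) & (counts <= max_kmer_hits)
        if not keep.any():
            return {}
        lo, counts, qpos = lo[keep], counts[keep], qpos[keep]
        total = int(counts.sum())
        starts = np.cumsum(counts) - counts
        j = np.arange(total) - np.repeat(starts, counts) + np.repeat(lo, counts)
        qp_all = np.repeat(qpos, counts)
        subj_all = self.subj[j]
        spos_all = self.pos[j]
        order = np.argsort(subj_all, kind="stable")
        subj_all, qp_all, spos_all = subj_all[order], qp_all[order], spos_all[order]
        uniq, first = np.unique(subj_all, return_index=True)
        bounds = list(first) + [len(subj_all)]
        out: dict[int, list[tuple[int, int]]] = {}
        for u, a, b in zip(uniq, bounds[:-1], bounds[1:]):
            out[int(u)] = list(zip(qp_all[a:b].tolist(), spos_all[a:b].tolist()))
        return out


# ---------------------------------------------------------------------------
# extension

def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """(columns, matches, gap_columns) from an extended edlib cigar."""
    cols = matches = gaps = 0
    for num, op in _CIGAR_RE.findall(cigar):
        n = int(num)
        cols += n
        if op == "=":
            matches += n
        elif op in "ID":
            gaps += n
    return cols, matches, gaps


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def infix_align(query_seg: str, target_window: str
                ) -> tuple[int, int, int, int, int, int, int] | None:
    """Align a query segment inside a (larger) target window with edlib HW
    and trim terminal non-matching cigar runs.

    Returns (q_offset, q_span, t_offset, t_span, columns, matches, gaps)
    relative to the segment/window starts, or None for no alignment.
    """
    res = edlib.align(query_seg, target_window, task="path", mode="HW")
    if res["editDistance"] < 0 or not res.get("cigar"):
        return None
    t_start = res["locations"][0][0] or 0
    ops = _parse_cigar(res["cigar"])
    q_lead = t_lead = 0
    while ops and ops[0][1] != "=":
        n, op = ops.pop(0)
        if op in "=XI":
            q_lead += n
        if op in "=XD":
            t_lead += n
    while ops and ops[-1][1] != "=":
        ops.pop()
    if not ops:
        return None
    cols = matches = gaps = 0
    q_span = t_span = 0
    for n, op in ops:
        cols += n
        if op == "=":
            matches += n
        if op in "ID":
            gaps += n
        if op in "=XI":
            q_span += n
        if op in "=XD":
            t_span += n
    return q_lead, q_span, t_start + t_lead, t_span, cols, matches, gaps


def _extend_nt(query: str, subject: str, seeds: list[tuple[int, int]],
               k: int) -> tuple[int, int, int, int, int, int, int] | None:
    """Extend a diagonal-consistent seed chain with an infix edlib alignment.

    The query segment (seed span + margin) is aligned inside a subject
    window; terminal non-matching cigar runs are trimmed so read overhangs
    beyond the homologous region do not count against identity.  Returns
    (q_start, q_end, s_start, s_end, columns, matches, gaps) or None.
    """
    if not seeds:
        return None
    diags = np.array([sp - qp for qp, sp in seeds])
    centre = int(np.median(diags))
    kept = [(qp, sp) for (qp, sp), d in zip(seeds, diags) if abs(d - centre) <= DIAG_BAND]
    if not kept:
        return None
    qlo = max(0, min(qp for qp, _ in kept) - SEED_MARGIN)
    qhi = min(len(query), max(qp for qp, _ in kept) + k + SEED_MARGIN)
    slo = max(0, min(sp for _, sp in kept) - 2 * SEED_MARGIN)
    shi = min(len(subject), max(sp for _, sp in kept) + k + 2 * SEED_MARGIN)
    aln = infix_align(query[qlo:qhi], subject[slo:shi])
    if aln is None:
        return None
    q_lead, q_span, t_off, t_span, cols, matches, gaps = aln
    q_start = qlo + q_lead
    s_start = slo + t_off
    return q_start, q_start + q_span, s_start, s_start + t_span, cols, matches, gaps


def _sw_nt(query: str, subject: str):
    """Exact local alignment; same return shape as :func:`_extend_nt`."""
    aligner = _nt_aligner()
    alns = aligner.align(query, subject)
    if len(alns) == 0:
        return None
    aln = alns[0]
    if aln.score <= 0 or len(aln.aligned[0]) == 0:
        return None
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.internal_gaps
    (qs, qe) = aln.aligned[0][0][0], aln.aligned[0][-1][1]
    (ss, se) = aln.aligned[1][0][0], aln.aligned[1][-1][1]
    return int(qs), int(qe), int(ss), int(se), int(cols), int(counts.identities), int(counts.internal_gaps)


def _translate_frames(seq: str) -> list[tuple[int, str]]:
    """All 6 reading frames as (frame, peptide); frames 1..3 fwd, -1..-3 rev."""
    frames = []
    rc = revcomp(seq)
    for i in range(3):
        for sign, s in ((1, seq), (-1, rc)):
            sub = s[i:]
            sub = sub[:len(sub) - len(sub) % 3]
            frames.append((sign * (i + 1), str(Seq(sub).translate())))
    return frames


# ---------------------------------------------------------------------------
# public search

def internal_search(
    queries: list[tuple[str, str]],
    subjects: list[tuple[str, str]],
    mode: str = "nt",
    db_tag: str = "dataset_ext",
    max_candidates: int = 8,
    min_seeds: int = 2,
    max_evalue: float = 10.0,
    sw_cutoff: int = SW_CUTOFF,
) -> list[AlignmentHit]:
    """Local similarity search of ``queries`` against ``subjects``.

    ``mode='nt'`` searches both strands of each nucleotide query;
    ``mode='translated'`` searches all six reading frames of each nucleotide
    query against protein subjects, reporting percent similarity (BLOSUM62
    positives) alongside identity.  At most one hit (the best-scoring) is
    reported per (query, subject) pair.
    """
    if mode not in ("nt", "translated"):
        raise ValueError(f"unknown mode {mode!r}")
    for name, seq in list(queries) + list(subjects):
        if not seq or not set(seq.upper()) <= set("ACGTUNRYSWKMBDHVEFILPQZJOX*"):
            raise ValueError(f"invalid alphabet in sequence {name!r}")

    if mode == "nt":
        return _search_nt(queries, subjects, db_tag, max_candidates,
                          min_seeds, max_evalue, sw_cutoff)
    return _search_translated(queries, subjects, db_tag, max_candidates,
                              min_seeds, max_evalue)


def _search_nt(queries, subjects, db_tag, max_candidates, min_seeds,
               max_evalue, sw_cutoff) -> list[AlignmentHit]:
    index = KmerIndex(subjects, k=SEED_K_NT)
    n_db = max(index.total_len, 1)
    hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        best: dict[int, tuple] = {}  # subject idx -> (score, hit fields)
        exhaustive = len(qseq) * n_db <= sw_cutoff
        for strand, oriented in (("+", qseq), ("-", revcomp(qseq))):
            small = range(len(subjects)) if exhaustive else ()
            seeded = index.seeds(oriented)
            cand = sorted(seeded, key=lambda i: -len(seeded[i]))
            cand = [i for i in cand if len(seeded[i]) >= min_seeds][:max_candidates]
            for i in set(cand) | set(small):
                sseq = subjects[i][1]
                if len(oriented) * len(sseq) <= sw_cutoff:
                    ext = _sw_nt(oriented, sseq)
                else:
                    ext = _extend_nt(oriented, sseq, seeded.get(i, []), SEED_K_NT)
                if ext is None:
                    continue
                qs, qe, ss, se, cols, matches, gaps = ext
                if cols == 0:
                    continue
                mism = cols - matches - gaps
                raw = NT_MATCH * matches + NT_MISMATCH * (mism + gaps)
                if raw <= 0:
                    continue
                ev = nt_evalue(raw, len(qseq), n_db)
                if ev > max_evalue:
                    continue
                if strand == "-":  # map back onto the original read
                    qs, qe = len(qseq) - qe, len(qseq) - qs
                score_key = (raw, -ev)
                if i not in best or score_key > best[i][0]:
                    pid = 100.0 * matches / cols
                    best[i] = (score_key, AlignmentHit(
                        query_id=qid, subject_id=subjects[i][0],
                        pct_identity=round(pid, 2), aln_len=cols, evalue=ev,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        db_tag=db_tag, strand=strand, bitscore=float(raw)))
        hits.extend(best[i][1] for i in sorted(best))
    return hits


def _search_translated(queries, subjects, db_tag, max_candidates, min_seeds,
                       max_evalue) -> list[AlignmentHit]:
    aligner = _aa_aligner()
    # protein subject index: plain dict of k-mers (protein sets are small)
    k = SEED_K_AA
    pindex: dict[str, list[int]] = {}
    for i, (_, pseq) in enumerate(subjects):
        for j in range(len(pseq) - k + 1):
            pindex.setdefault(pseq[j:j + k], []).append(i)
    n_db = max(sum(len(s) for _, s in subjects), 1)
    hits: list[AlignmentHit] = []
    for qid, qseq in queries:
        best: dict[int, tuple] = {}
        for frame, pep in _translate_frames(qseq):
            counts: dict[int, int] = {}
            for j in range(len(pep) - k + 1):
                for i in pindex.get(pep[j:j + k], ()):
                    counts[i] = counts.get(i, 0) + 1
            cand = sorted(counts, key=lambda i: -counts[i])
            cand = [i for i in cand if counts[i] >= max(1, min_seeds - 1)][:max_candidates]
            for i in cand:
                sseq = subjects[i][1]
                alns = aligner.align(pep, sseq)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                if aln.score <= 0:
                    continue
                c = aln.counts(BLOSUM62)
                cols = c.identities + c.mismatches + c.internal_gaps
                if cols == 0:
                    continue
                ev = aa_evalue(aln.score, len(pep), n_db)
                if ev > max_evalue:
                    continue
                qs_aa, qe_aa = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
                ss, se = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
                qs, qe, strand = _frame_to_nt(frame, qs_aa, qe_aa, len(qseq))
                key = (aln.score, -ev)
                if i not in best or key > best[i][0]:
                    best[i] = (key, AlignmentHit(
                        query_id=qid, subject_id=subjects[i][0],
                        pct_identity=round(100.0 * c.identities / cols, 2),
                        pct_similarity=round(100.0 * c.positives / cols, 2),
                        aln_len=cols, evalue=ev,
                        q_start=qs, q_end=qe, s_start=ss, s_end=se,
                        db_tag=db_tag, strand=strand, bitscore=float(aln.score)))
        hits.extend(best[i][1] for i in sorted(best))
    return hits


def _frame_to_nt(frame: int, qs_aa: int, qe_aa: int, qlen: int) -> tuple[int, int, str]:
    """Map amino-acid coordinates in a reading frame back to the read."""
    off = abs(frame) - 1
    s = off + 3 * qs_aa
    e = off + 3 * qe_aa
    if frame > 0:
        return s, min(e, qlen), "+"
    return max(qlen - e, 0), qlen - s, "-"
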