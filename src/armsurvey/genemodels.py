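"""Reference-guided gene models and transcript-coverage confidence classes.

Non-repetitive reads are assembled against the coding sequence of the
reference gene they were assigned to (one reference per read, chosen by
database precedence genome A > genome B > genome C > UniGene).  Contigs
mapping to different parts of the same reference are condensed into a
single model, reference-coordinate gaps filled with runs of ``n``.  Models
are then screened with assembled transcriptome sequences at >= 95%
identity; the fraction of non-``n`` model bases covered by transcripts sets
the confidence class: high for 60-100% coverage, low for 20-60%, the rest
eliminated as probable fragments or pseudogenes (the 60% and 20% boundaries
belong to the upper class).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .align import internal_search, _cigar_stats
from .repeatscan import overlap_assemble
from .seqio import AlignmentHit, SurveyRead, normalize_intervals

DB_PRECEDENCE = ("genomeA", "genomeB", "genomeC", "unigene")
HIGH_MIN, LOW_MIN = 60.0, 20.0


@dataclass
class GeneModel:
    model_id: str
    reference_id: str
    sequence: str              # may contain runs of 'n' between merged contigs
    source_class: str = "conserved"      # conserved | non_conserved
    transcript_coverage: float | None = None
    confidence: str = "unclassified"     # high | low | eliminated
    ambiguous: bool = False

    @property
    def non_n_length(self) -> int:
        return len(self.sequence) - self.sequence.count("n")


@dataclass
class PlacedContig:
    s_start: int
    s_end: int
    sequence: str


def assign_reads_by_precedence(assignments_by_db: dict) -> dict[str, str]:
    """read_id -> reference id, honouring database precedence per read."""
    choice: dict[str, tuple[int, str]] = {}
    for db, hits in assignments_by_db.items():
        if db not in DB_PRECEDENCE:
            continue
        rank = DB_PRECEDENCE.index(db)
        for h in hits:
            cur = choice.get(h.query_id)
            if cur is None or rank < cur[0]:
                choice[h.query_id] = (rank, h.subject_id)
    return {rid: ref for rid, (_, ref) in choice.items()}


def map_reads_to_reference(reads: list[SurveyRead], reference_cds: dict[str, str],
                           read_to_ref: dict[str, str],
                           min_overlap: int = 40, min_contig: int = 40
                           ) -> dict[str, list[PlacedContig]]:
    """Assemble each reference's assigned reads and place the contigs on it.

    Placement aligns each contig back to the reference CDS and records the
    subject interval; contigs that fail to place are dropped.
    """
    by_id = {r.read_id: r for r in reads}
    per_ref: dict[str, list[SurveyRead]] = defaultdict(list)
    for rid, ref in read_to_ref.items():
        if rid in by_id and ref in reference_cds:
            per_ref[ref].append(by_id[rid])
    placed: dict[str, list[PlacedContig]] = {}
    for ref, group in sorted(per_ref.items()):
        asm = overlap_assemble(group, min_overlap=min_overlap, min_contig=min_contig)
        pieces = [(c.contig_id, c.sequence) for c in asm.contigs]
        pieces += [(rid, by_id[rid].sequence) for rid in asm.singleton_ids]
        hits = internal_search(pieces, [(ref, reference_cds[ref])], mode="nt",
                               min_seeds=1)
        best: dict[str, AlignmentHit] = {}
        for h in hits:
            cur = best.get(h.query_id)
            if cur is None or h.bitscore > cur.bitscore:
                best[h.query_id] = h
        out = []
        for pid, seq in pieces:
            h = best.get(pid)
            if h is None:
                continue
            sub = seq[h.q_start:h.q_end]
            if h.strand == "-":
                from .align import revcomp
                sub = revcomp(sub)
            out.append(PlacedContig(h.s_start, h.s_end, sub))
        if out:
            placed[ref] = sorted(out, key=lambda c: (c.s_start, c.s_end))
    return placed


def merge_contigs(contigs: list[PlacedContig], reference_id: str,
                  model_id: str | None = None, source_class: str = "conserved",
                  min_overlap_identity: float = 95.0) -> GeneModel:
    """Condense placed contigs into one model, gaps filled with 'n'.

    Overlapping contigs (in reference coordinates) merge when the
    overlapping sequence agrees at >= 95% identity, keeping the earlier
    contig's bases in the overlap; disagreeing overlaps keep both sequences
    (separated by a single 'n') and flag the model ambiguous.  A reference
    gap of g bases becomes max(g, 1) 'n' characters.
    """
    if not contigs:
        raise ValueError("no contigs to merge")
    contigs = sorted(contigs, key=lambda c: (c.s_start, c.s_end))
    parts = [contigs[0].sequence]
    cur_end = contigs[0].s_end
    ambiguous = False
    for c in contigs[1:]:
        gap = c.s_start - cur_end
        if gap >= 0:
            parts.append("n" * max(gap, 1))
            parts.append(c.sequence)
        else:
            o = min(-gap, len(c.sequence), len(parts[-1]))
            prev_tail = parts[-1][-o:]
            next_head = c.sequence[:o]
            res = edlib.align(prev_tail, next_head, task="path", mode="NW")
            cols, matches, _ = _cigar_stats(res["cigar"]) if res["editDistance"] >= 0 \
                else (0, 0, 0)
            if cols and 100.0 * matches / cols >= min_overlap_identity:
                parts.append(c.sequence[o:])
            else:
                ambiguous = True
                parts.append("n")
                parts.append(c.sequence)
        cur_end = max(cur_end, c.s_end)
    return GeneModel(model_id or f"model_{reference_id}", reference_id,
                     "".join(parts), source_class=source_class, ambiguous=ambiguous)


def classify_confidence(model: GeneModel, transcript_hits: list[AlignmentHit],
                        min_identity: float = 95.0) -> GeneModel:
    """Set transcript coverage (% of non-'n' bases covered at >= 95%
    identity) and the confidence class; mutates and returns the model."""
    ivs = [(h.s_start, h.s_end) for h in transcript_hits
           if h.subject_id == model.model_id
           and h.pct_identity is not None and h.pct_identity >= min_identity]
    ivs = normalize_intervals(
        [(max(0, s), min(len(model.sequence), e)) for s, e in ivs],
        len(model.sequence))
    is_n = np.frombuffer(model.sequence.encode(), dtype=np.uint8) == ord("n")
    covered = np.zeros(len(model.sequence), dtype=bool)
    for s, e in ivs:
        covered[s:e] = True
    non_n = int((~is_n).sum())
    cov = 100.0 * int((covered & ~is_n).sum()) / non_n if non_n else 0.0
    model.transcript_coverage = round(cov, 2)
    if cov >= HIGH_MIN:
        model.confidence = "high"
    elif cov >= LOW_MIN:
        model.confidence = "low"
    else:
        model.confidence = "eliminated"
    return model


def classify_all(models: list[GeneModel], transcripts: list[tuple[str, str]],
                 min_identity: float = 95.0) -> list[GeneModel]:
    """Screen all models with the transcript set and classify each."""
    hits = internal_search(transcripts, [(m.model_id, m.sequence) for m in models],
                           mode="nt", min_seeds=1)
    by_model: dict[str, list[AlignmentHit]] = defaultdict(list)
    for h in hits:
        by_model[h.subject_id].append(h)
    for m in models:
        classify_confidence(m, by_model.get(m.model_id, []), min_identity)
    return models


def cross_dataset_match(models_q: list[GeneModel], models_s: list[GeneModel],
                        locations_s: dict[str, str] | None = None,
                        arms_q: dict[str, str] | None = None,
                        min_identity: float = 95.0, max_evalue: float = 1e-20) -> dict:
    """Best-reciprocal matching of two gene-model sets.

    Matches require >= 95% identity and e <= 1e-20 in both directions; a
    query's equal-e-value ties break in favour of the subject whose location
    label matches the query's arm.  Returns the match list, the 1%-bin
    identity histogram (bin b counts identities in [b, b+1)), and the
    query-arm x subject-location concordance table.
    """
    locations_s = locations_s or {}
    arms_q = arms_q or {}
    q_seqs = [(m.model_id, m.sequence) for m in models_q]
    s_seqs = [(m.model_id, m.sequence) for m in models_s]
    fwd = [h for h in internal_search(q_seqs, s_seqs, mode="nt", min_seeds=1)
           if h.pct_identity >= min_identity and h.evalue <= max_evalue]
    rev = [h for h in internal_search(s_seqs, q_seqs, mode="nt", min_seeds=1)
           if h.pct_identity >= min_identity and h.evalue <= max_evalue]

    def best_of(hits, tie_location_for: dict | None):
        best: dict[str, AlignmentHit] = {}
        for h in sorted(hits, key=lambda h: (h.query_id, h.subject_id)):
            cur = best.get(h.query_id)
            if cur is None:
                best[h.query_id] = h
                continue
            if h.evalue < cur.evalue:
                best[h.query_id] = h
            elif h.evalue == cur.evalue and tie_location_for is not None:
                want = tie_location_for.get(h.query_id)
                if want is not None and locations_s.get(h.subject_id) == want \
                        and locations_s.get(cur.subject_id) != want:
                    best[h.query_id] = h
        return best

    best_fwd = best_of(fwd, arms_q)
    best_rev = best_of(rev, None)
    matches = []
    for qid in sorted(best_fwd):
        h = best_fwd[qid]
        back = best_rev.get(h.subject_id)
        if back is not None and back.subject_id == qid:
            matches.append(h)

    bins = [int(np.floor(h.pct_identity)) for h in matches]
    histogram = pd.Series(bins).value_counts().sort_index().to_dict() if bins else {}
    rows = [{"query": h.query_id, "subject": h.subject_id,
             "identity": h.pct_identity,
             "query_arm": arms_q.get(h.query_id),
             "subject_location": locations_s.get(h.subject_id)} for h in matches]
    concordance = (pd.crosstab(pd.Series([r["query_arm"] for r in rows], name="arm"),
                               pd.Series([r["subject_location"] for r in rows],
                                         name="location"))
                   if rows else pd.DataFrame())
    return {"matches": matches, "identity_histogram": histogram,
            "concordance": concordance, "table": pd.DataFrame(rows)}
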