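"""Readers, writers and shared record types for the survey pipeline.

All internal coordinates are 0-based half-open.  External tabular formats
keep their native conventions: BLAST tabular (outfmt-6 dialect) is 1-based
inclusive with minus-strand subject hits encoded as s_start > s_end, and BED
is 0-based half-open.  ``NA`` is the single missing-value token in every TSV
this package writes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

NA = "NA"

VALID_DB_TAGS = {
    "genomeA", "genomeB", "genomeC",
    "unigene", "uniprot", "organelle", "transcript", "dataset_ext",
}


class ParseError(ValueError):
    """Raised when an input file violates its format; carries the line number."""

    def __init__(self, path, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


@dataclass
class SurveyRead:
    """One shotgun read from a flow-sorted chromosome arm."""

    read_id: str
    arm: str
    sequence: str
    masked: list[tuple[int, int]] = field(default_factory=list)
    source: str = "unknown"  # target | contaminant | unknown

    def __post_init__(self):
        self.masked = normalize_intervals(self.masked, len(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def masked_length(self) -> int:
        return sum(e - s for s, e in self.masked)

    @property
    def masked_fraction(self) -> float:
        return self.masked_length / len(self.sequence) if self.sequence else 0.0

    def unmasked_intervals(self) -> list[tuple[int, int]]:
        """Complement of the masked intervals on [0, len)."""
        out, pos = [], 0
        for s, e in self.masked:
            if s > pos:
                out.append((pos, s))
            pos = e
        if pos < len(self.sequence):
            out.append((pos, len(self.sequence)))
        return out


def normalize_intervals(
    intervals: Iterable[tuple[int, int]], length: int | None = None
) -> list[tuple[int, int]]:
    """Sort, bounds-check and merge overlapping/adjacent half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if s < 0 or e < s:
            raise ValueError(f"invalid interval ({s}, {e})")
        if length is not None and e > length:
            raise ValueError(f"interval ({s}, {e}) exceeds length {length}")
        if s == e:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


@dataclass
class AlignmentHit:
    """One pairwise local-alignment record (BLAST tabular dialect).

    ``pct_identity`` is meaningful in nucleotide mode, ``pct_similarity``
    (positives fraction) in protein mode; either may be ``None`` when the
    producing search does not report it.  Coordinates are 0-based half-open
    on the plus strand of each sequence; ``strand`` records subject
    orientation relative to the query.
    """

    query_id: str
    subject_id: str
    pct_identity: float | None
    aln_len: int
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    db_tag: str
    pct_similarity: float | None = None
    strand: str = "+"
    bitscore: float = 0.0

    def __post_init__(self):
        if self.db_tag not in VALID_DB_TAGS:
            raise ValueError(f"unknown db_tag {self.db_tag!r}")
        for pct in (self.pct_identity, self.pct_similarity):
            if pct is not None and not (0.0 <= pct <= 100.0):
                raise ValueError(f"percentage out of range: {pct}")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class MarkerRecord:
    """A deletion-bin-mapped EST or SSR marker."""

    marker_id: str
    kind: str  # EST | SSR
    bin: str
    sequence: str
    map_position: float | None = None


# ---------------------------------------------------------------------------
# FASTA

import string

_SEQ_CHARS = frozenset(string.ascii_letters + "*-.")  # nucleotide + amino-acid alphabets


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into ``[(id, sequence), ...]``.

    Empty files yield an empty list with a warning; structural problems
    raise :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    n_nonblank = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_nonblank += 1
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] if line[1:].split() else None
                if header is None:
                    raise ParseError(path, lineno, "empty FASTA header")
                chunks = []
            else:
                if header is None:
                    raise ParseError(path, lineno, "sequence before first '>' header")
                if not set(line) <= _SEQ_CHARS:
                    bad = sorted(set(line) - _SEQ_CHARS)
                    raise ParseError(path, lineno, f"invalid sequence characters {bad}")
                chunks.append(line)
    if header is not None:
        records.append((header, "".join(chunks)))
    if n_nonblank == 0:
        logger.warning("empty FASTA file: %s", path)
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    records = list(records)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt-6 dialect, optional 13th "positives %" column)

def read_hits_tabular(path, db_tag: str) -> list[AlignmentHit]:
    """Read a 12(+1)-column tab-separated hit table.

    Subject coordinates given in descending order denote a minus-strand hit
    and are normalized (swapped) with ``strand='-'``.
    """
    path = Path(path)
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(path, lineno, f"expected >= 12 columns, got {len(fields)}")
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                aln_len = int(fields[3])
                qs, qe = int(fields[6]), int(fields[7])
                ss, se = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bits = float(fields[11])
                positives = float(fields[12]) if len(fields) > 12 and fields[12] != NA else None
            except ValueError as exc:
                raise ParseError(path, lineno, f"non-numeric field: {exc}") from None
            strand = "+"
            if ss > se:
                ss, se = se, ss
                strand = "-"
            if qs > qe:
                qs, qe = qe, qs
            hits.append(AlignmentHit(
                query_id=qid, subject_id=sid, pct_identity=pident,
                aln_len=aln_len, evalue=evalue,
                q_start=qs - 1, q_end=qe, s_start=ss - 1, s_end=se,
                db_tag=db_tag, pct_similarity=positives, strand=strand,
                bitscore=bits,
            ))
    return hits


def write_hits_tabular(hits: Iterable[AlignmentHit], path) -> None:
    """Inverse of :func:`read_hits_tabular` (1-based inclusive, strand re-encoded)."""
    with open(path, "w") as fh:
        for h in hits:
            ss, se = h.s_start + 1, h.s_end
            if h.strand == "-":
                ss, se = se, ss
            sim = f"{h.pct_similarity:.2f}" if h.pct_similarity is not None else NA
            pid = f"{h.pct_identity:.2f}" if h.pct_identity is not None else "0.00"
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, pid, h.aln_len, 0, 0,
                h.q_start + 1, h.q_end, ss, se,
                f"{h.evalue:.3g}", f"{h.bitscore:.1f}", sim,
            ])) + "\n")


# ---------------------------------------------------------------------------
# BED

def read_bed(path) -> list[tuple[str, int, int]]:
    path = Path(path)
    out: list[tuple[str, int, int]] = []
    prev: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, lineno, "BED requires >= 3 columns")
            try:
                chrom, s, e = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(path, lineno, str(exc)) from None
            if s < 0 or e < s:
                raise ParseError(path, lineno, f"invalid interval [{s}, {e})")
            if chrom in prev and s < prev[chrom]:
                raise ParseError(path, lineno, "unsorted BED intervals")
            prev[chrom] = s
            out.append((chrom, s, e))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path) -> None:
    intervals = list(intervals)
    order: dict[str, int] = {}
    for chrom, s, e in intervals:
        if e < s:
            raise ValueError(f"invalid interval [{s}, {e})")
        if chrom in order and s < order[chrom]:
            raise ValueError("intervals must be sorted within chromosome")
        order[chrom] = s
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


# ---------------------------------------------------------------------------
# Zipper / marker tables

ZIPPER_COLUMNS = ["index", "ref_gene", "ref_chrom", "ref_pos",
                  "reads", "bin", "map_position", "syntenic_flag"]


def write_zipper(rows: Sequence, path) -> None:
    """Write virtual-gene-order rows as TSV (see :class:`armsurvey.zipper.ZipperRow`)."""
    with open(path, "w") as fh:
        fh.write("\t".join(ZIPPER_COLUMNS) + "\n")
        last = -1
        for r in rows:
            if r.index <= last:
                raise ValueError("zipper rows must have strictly increasing indices")
            last = r.index
            mp = NA if r.map_position is None else f"{r.map_position:g}"
            fh.write("\t".join(map(str, [
                r.index, r.ref_gene, r.ref_chrom, r.ref_pos,
                ",".join(sorted(r.wheat_reads)) if r.wheat_reads else NA,
                r.bin if r.bin is not None else NA,
                mp, int(r.syntenic),
            ])) + "\n")


def write_markers(markers: Iterable[MarkerRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker_id\tkind\tbin\tmap_position\tsequence\n")
        for m in markers:
            mp = NA if m.map_position is None else f"{m.map_position:g}"
            fh.write(f"{m.marker_id}\t{m.kind}\t{m.bin}\t{mp}\t{m.sequence}\n")


def read_markers(path) -> list[MarkerRecord]:
    path = Path(path)
    out: list[MarkerRecord] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("marker_id"):
            raise ParseError(path, 1, "missing marker table header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(path, lineno, "expected 5 columns")
            mid, kind, bin_, mp, seq = fields
            try:
                map_position = None if mp == NA else float(mp)
            except ValueError:
                raise ParseError(path, lineno, f"bad map position {mp!r}") from None
            out.append(MarkerRecord(mid, kind, bin_, seq, map_position))
    return out


def read_position_table(path) -> list[dict]:
    """Read a per-gene position table (gene_id, chromosome, start, end, strand)."""
    path = Path(path)
    out: list[dict] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(path, lineno, "column count mismatch")
            rec = dict(zip(header, fields))
            try:
                rec["start"] = int(rec["start"])
                rec["end"] = int(rec["end"])
            except (KeyError, ValueError) as exc:
                raise ParseError(path, lineno, str(exc)) from None
            out.append(rec)
    return out


def write_position_table(rows: Iterable[dict], path) -> None:
    cols = ["gene_id", "chromosome", "start", "end", "strand"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(str(r[c]) for c in cols) + "\n")
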