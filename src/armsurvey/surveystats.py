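"""Closed-form survey statistics and the shared Fisher exact-test utility.

The representation probability of a chromosome-arm shotgun survey is the
chance that any given base of the arm is sampled by at least one read,

    P = [1 - (1 - L/S)^N] * purity

with arm size ``S`` (bp), read count ``N``, mean read length ``L`` (bp) and
flow-sort purity.  Coverage fold is total read length / S.  Both follow the
standard Clarke-Carbon style sampling argument; purity scales the result by
the fraction of reads actually originating from the target arm.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass
class ArmSurveyStats:
    """Summary statistics of one arm survey (Table-1 style)."""

    S: float          # arm size, bp
    N: int            # read count
    L: float          # mean read length, bp
    purity: float     # fraction in (0, 1]
    total_read_len: float  # bp

    @property
    def coverage_fold(self) -> float:
        return coverage_fold(self.total_read_len, self.S)

    @property
    def representation_P(self) -> float:
        return representation_probability(self.S, self.N, self.L, self.purity)

    def as_row(self) -> dict:
        d = asdict(self)
        d["coverage_fold"] = round(self.coverage_fold, 2)
        d["representation_P"] = round(self.representation_P, 3)
        return d


def representation_probability(S: float, N: int, L: float, purity: float) -> float:
    """P(base sampled by >= 1 read) = [1 - (1 - L/S)^N] * purity.

    Computed in log space: (1-L/S)^N = exp(N*log1p(-L/S)) stays accurate for
    the tiny per-read sampling probabilities of megabase-scale arms.
    """
    if not (S > L >= 1):
        raise ValueError(f"require S > L >= 1, got S={S}, L={L}")
    if N < 0:
        raise ValueError("N must be >= 0")
    if not (0.0 <= purity <= 1.0):
        raise ValueError("purity must be in [0, 1]")
    if N == 0:
        return 0.0
    log_miss = N * math.log1p(-L / S)
    return -math.expm1(log_miss) * purity


def coverage_fold(total_read_len: float, S: float) -> float:
    """Fold coverage = total read length / arm size."""
    if S <= 0:
        raise ValueError("arm size must be positive")
    return total_read_len / S


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric point probabilities no larger than the observed
    table's.  A table with an all-zero margin carries no information and
    returns p = 1.0 with a warning.
    """
    cells = (a, b, c, d)
    if any((not isinstance(x, (int, np.integer))) or x < 0 for x in cells):
        raise ValueError(f"cells must be non-negative integers, got {cells}")
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        warnings.warn("Fisher table has an all-zero margin; p = 1.0", stacklevel=2)
        return 1.0
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def trna_density(prediction_table: pd.DataFrame, surveyed_Mb: float,
                 by: str = "isotype") -> pd.DataFrame:
    """Per-isotype tRNA-gene counts and densities (genes/Mb).

    ``prediction_table`` holds one externally produced prediction per row
    with columns (read_id, isotype, anticodon, score); this package never
    predicts tRNA genes itself.  Unknown isotype tokens are pooled under
    ``Other``.
    """
    if surveyed_Mb <= 0:
        raise ValueError("surveyed_Mb must be positive")
    if prediction_table.empty:
        return pd.DataFrame({by: ["Total"], "count": [0], "density_per_Mb": [0.0]})
    tab = prediction_table.copy()
    known = set(_AMINO_ACIDS)
    tab[by] = [t if t in known else "Other" for t in tab[by].astype(str)]
    counts = tab.groupby(by, sort=True).size().rename("count").reset_index()
    total = pd.DataFrame({by: ["Total"], "count": [int(counts["count"].sum())]})
    out = pd.concat([counts, total], ignore_index=True)
    out["density_per_Mb"] = out["count"] / surveyed_Mb
    return out


def trna_arm_comparison(tables: dict[str, pd.DataFrame],
                        surveyed_Mb: dict[str, float]) -> pd.DataFrame:
    """Side-by-side per-isotype density comparison across arms/datasets."""
    frames = []
    for arm, tab in tables.items():
        d = trna_density(tab, surveyed_Mb[arm])
        d = d.rename(columns={"count": f"count_{arm}",
                              "density_per_Mb": f"density_{arm}"})
        frames.append(d.set_index("isotype"))
    return pd.concat(frames, axis=1).fillna(0).reset_index()


_AMINO_ACIDS = [
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "SeC", "Thr", "Trp", "Tyr",
    "Val", "iMet", "Sup", "Undet",
]


def survey_report(stats: ArmSurveyStats, assembly_report: dict,
                  filter_counts: dict | None = None) -> dict:
    """Collate Table-1/2-style numbers into one JSON-ready report.

    ``assembly_report`` is the dict produced by
    :func:`armsurvey.repeatscan.nonrepetitive_summary`; percentages are
    recomputed here from their stated denominators so the report is
    self-consistent by construction.
    """
    n_reads = assembly_report["total_reads"]
    total_bases = assembly_report["total_bases"]
    aligned_reads = assembly_report["aligned_reads"]
    aligned_bases = assembly_report["aligned_bases"]
    report = {
        "arm_size_bp": stats.S,
        "n_reads": stats.N,
        "mean_read_length_bp": round(stats.L, 2),
        "total_read_length_bp": stats.total_read_len,
        "coverage_fold": round(stats.coverage_fold, 2),
        "purity": stats.purity,
        "representation_probability": round(stats.representation_P, 3),
        "aligned_reads_no": aligned_reads,
        "aligned_reads_pct": round(100.0 * aligned_reads / n_reads, 2) if n_reads else 0.0,
        "aligned_bases_no": aligned_bases,
        "aligned_bases_pct": round(100.0 * aligned_bases / total_bases, 2) if total_bases else 0.0,
        "singleton_reads": assembly_report["singleton_reads"],
        "contigs": assembly_report["n_contigs"],
        "bases_in_contigs": assembly_report["bases_in_contigs"],
        "non_aligned_bases": assembly_report["non_aligned_bases"],
        "estimated_arm_length_bp": estimated_arm_length(
            assembly_report["bases_in_contigs"], assembly_report["non_aligned_bases"]),
        "deep_contig_reads_no": assembly_report["deep_contig_reads"],
        "deep_contig_reads_pct": round(
            100.0 * assembly_report["deep_contig_reads"] / n_reads, 2) if n_reads else 0.0,
        "denominators": {
            "reads_pct": "total reads", "bases_pct": "total read bases",
        },
    }
    if filter_counts:
        report["filter_counts"] = dict(filter_counts)
    return report


def estimated_arm_length(bases_in_contigs: int, non_aligned_bases: int) -> int:
    """Arm-length estimate: assembled (collapsed) bases + unassembled bases."""
    return int(bases_in_contigs) + int(non_aligned_bases)


def format_mb(bp: float, ndigits: int = 1) -> float:
    """Base pairs -> megabases at the report precision."""
    return round(bp / 1e6, ndigits)
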