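"""Synthetic chromosome-arm survey data with planted ground truth.

The generator emulates the statistical structure a chromosome-arm shotgun
survey analysis assumes: three reference ("model") genomes sharing an
ancestral gene order with per-lineage losses and moves; a flow-sorted wheat
arm whose gene complement copies one reference's colinear order with planted
rearrangements (inversion, three-segment order reversal, telomere-biased
non-syntenic insertions); transposable-element families tiled to a target
repeat fraction, some copies carrying a captured tRNA-like inset; shotgun
reads with configurable coverage, flow-sort purity (contaminant reads from a
second arm and an organellar genome) and exact-duplicate amplification
artifacts; deletion-bin markers; and transcripts at planted coverage
classes.  Every planted feature is recorded in a :class:`TruthSet` so each
downstream stage can be scored against it.

All randomness flows from ``SimConfig.seed`` through a single
``numpy.random.Generator``; identical configs produce byte-identical
outputs.  Sequence divergence is simulated as substitutions only, which
keeps planted coordinates alignable and matches the exact-duplicate
definition the artifact-removal rule relies on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import MarkerRecord, SurveyRead, write_fasta, write_markers, write_position_table


class ConfigError(ValueError):
    """Invalid simulation configuration."""


class InputError(ValueError):
    """Invalid runtime input to a simulation operation."""


@dataclass
class Rearrangement:
    """One planted rearrangement over a half-open gene-index range."""

    type: str                 # inversion | segment_reversal | translocation_in | translocation_out
    start: int
    end: int
    n_segments: int = 3

    _TYPES = ("inversion", "segment_reversal", "translocation_in", "translocation_out")

    def __post_init__(self):
        if self.type not in self._TYPES:
            raise ConfigError(f"unknown rearrangement type {self.type!r}")
        if self.start < 0 or self.end <= self.start:
            raise ConfigError(f"bad rearrangement range [{self.start}, {self.end})")

    @classmethod
    def coerce(cls, item) -> "Rearrangement":
        if isinstance(item, cls):
            return item
        if isinstance(item, dict):
            return cls(**item)
        return cls(*item)


@dataclass
class SimConfig:
    """Study conditions for one simulated arm survey.

    Defaults are a desk-scale rendition of a flow-sorted Triticeae arm
    survey: ~350 bp mean reads at ~1.5-fold coverage, ~90% sort purity,
    exact-duplicate amplification artifacts, and three quarters of the arm
    occupied by TE families.
    """

    seed: int = 0
    arm_size: int = 1_000_000
    arm_label: str = "5DS"
    n_genes: int = 200
    repeat_fraction: float = 0.75
    n_repeat_families: int = 10
    trna_capture_rate: float = 0.10
    mean_read_len: float = 350.0
    read_len_sd: float = 60.0
    min_read_len: int = 50
    coverage_fold: float = 1.5
    purity: float = 0.90
    artifact_rate: float = 0.02
    organelle_fraction: float = 0.2     # fraction of impurity reads that are organellar
    rearrangement_spec: list = field(default_factory=list)
    nonsyntenic_telomere_bias: float = 0.8
    transcript_fraction_high: float = 0.60
    transcript_fraction_low: float = 0.25
    # gene/sequence geometry
    mean_gene_len: int = 900
    gene_len_sd: int = 250
    min_gene_len: int = 300
    # reference-panel structure
    lineage_loss_rate: float = 0.08
    lineage_move_rate: float = 0.02
    lineage_divergence: float = 0.03
    wheat_divergence: float = 0.02
    conservation_classes: dict | None = None   # e.g. {"ABC": .6, "AB": .1, ...}
    n_nonsyntenic_pool: int = 60
    n_nonsyntenic_insertions: int = 12
    nonsyntenic_mutual_fraction: float = 0.6
    n_contaminant_genes: int = 20
    # markers / bins
    n_bins: int = 9
    marker_fraction: float = 0.25
    marker_len: int = 150
    # TE families
    te_len_range: tuple = (800, 3000)
    te_exact_copy_fraction: float = 0.5
    te_max_divergence: float = 0.08
    trna_token_len: int = 75

    def __post_init__(self):
        self.rearrangement_spec = [Rearrangement.coerce(r) for r in self.rearrangement_spec]
        self.validate()

    def validate(self) -> None:
        fracs = dict(
            repeat_fraction=self.repeat_fraction, purity=self.purity,
            artifact_rate=self.artifact_rate, trna_capture_rate=self.trna_capture_rate,
            nonsyntenic_telomere_bias=self.nonsyntenic_telomere_bias,
            transcript_fraction_high=self.transcript_fraction_high,
            transcript_fraction_low=self.transcript_fraction_low,
            lineage_loss_rate=self.lineage_loss_rate,
            lineage_move_rate=self.lineage_move_rate,
            marker_fraction=self.marker_fraction,
            organelle_fraction=self.organelle_fraction,
        )
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.transcript_fraction_high + self.transcript_fraction_low > 1.0:
            raise ConfigError("transcript class fractions exceed 1")
        if self.coverage_fold <= 0:
            raise ConfigError("coverage_fold must be > 0")
        if not (self.mean_read_len < self.arm_size):
            raise ConfigError("mean_read_len must be smaller than arm_size")
        genic = (self.n_genes + self.n_nonsyntenic_insertions) * self.mean_gene_len
        if self.repeat_fraction + genic / self.arm_size > 1.0:
            raise ConfigError(
                "repeat_fraction plus implied genic fraction exceeds 1; "
                "enlarge arm_size or reduce n_genes/repeat_fraction")
        if self.conservation_classes is not None:
            total = sum(self.conservation_classes.values())
            if total > 1.0 + 1e-9:
                raise ConfigError("conservation_classes fractions sum to > 1")


# ---------------------------------------------------------------------------
# truth containers

@dataclass
class GeneTruth:
    anc: int                      # ancestral gene index
    origins: list                 # genomes carrying an ortholog, subset of [A, B, C]
    arm_start: int | None         # position on the simulated arm (None if absent)
    arm_end: int | None
    syntenic: bool
    planted_duplicate: bool = False
    mutually_syntenic: bool | None = None   # among the three references (non-syntenic genes)
    transcript_class: str = "none"          # high | low | none


@dataclass
class TruthSet:
    """Planted ground truth for one simulated arm."""

    arm_size: int
    repeat_intervals: list = field(default_factory=list)   # (start, end, family)
    trna_inset_intervals: list = field(default_factory=list)
    gene_records: list = field(default_factory=list)       # GeneTruth
    segment_structure: list = field(default_factory=list)  # (segment_id, orientation)
    wheat_order: list = field(default_factory=list)        # ancestral indices in arm order
    artifact_pairs: list = field(default_factory=list)     # (kept_id, dup_id)
    contaminant_read_ids: set = field(default_factory=set)
    organelle_read_ids: set = field(default_factory=set)
    bin_boundaries: list = field(default_factory=list)     # (bin_id, start, end)
    read_positions: dict = field(default_factory=dict)     # read_id -> (start, end) on its source

    def validate(self) -> None:
        for s, e, _ in self.repeat_intervals:
            if not (0 <= s < e <= self.arm_size):
                raise ValueError(f"repeat interval ({s}, {e}) out of bounds")
        if self.organelle_read_ids & (self.contaminant_read_ids - self.organelle_read_ids):
            raise ValueError("read classified in two truth categories")

    def read_category(self, read_id: str) -> str:
        if read_id in self.organelle_read_ids:
            return "organelle"
        if read_id in self.contaminant_read_ids:
            return "contaminant"
        return "target"

    def repeat_read_ids(self, min_overlap_fraction: float = 0.5) -> set:
        """Reads whose span lies mostly inside planted repeat intervals."""
        if not self.repeat_intervals:
            return set()
        starts = np.array([s for s, _, _ in self.repeat_intervals])
        ends = np.array([e for _, e, _ in self.repeat_intervals])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        out = set()
        for rid, (rs, re_) in self.read_positions.items():
            if self.read_category(rid) != "target":
                continue
            i = np.searchsorted(starts, re_)
            ov = 0
            for s, e in zip(starts[:i], ends[:i]):
                if e > rs:
                    ov += min(e, re_) - max(s, rs)
            if ov > min_overlap_fraction * (re_ - rs):
                out.add(rid)
        return out

    def read_repeat_overlap(self) -> dict:
        """Per target read: bases overlapping planted repeat intervals."""
        if not self.repeat_intervals:
            return {}
        starts = np.array(sorted(s for s, _, _ in self.repeat_intervals))
        ends = np.array([e for _, e, _ in sorted(self.repeat_intervals)])
        out = {}
        for rid, (rs, re_) in self.read_positions.items():
            if self.read_category(rid) != "target":
                continue
            i = np.searchsorted(starts, re_)
            ov = 0
            for s, e in zip(starts[:i], ends[:i]):
                if e > rs:
                    ov += min(e, re_) - max(s, rs)
            out[rid] = ov
        return out

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["contaminant_read_ids"] = sorted(self.contaminant_read_ids)
        d["organelle_read_ids"] = sorted(self.organelle_read_ids)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, default=str)


# ---------------------------------------------------------------------------
# sequence primitives

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
           if a + b + c not in ("TAA", "TAG", "TGA")]


def random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_CODONS), n_codons)
    return "".join(_CODONS[i] for i in idx)


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitution-only mutation at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    idx = np.nonzero(hit)[0]
    if len(idx) == 0:
        return seq
    # replace with a strictly different base
    shifts = rng.integers(1, 4, len(idx))
    code = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    cur = code[arr[idx]]
    cur = np.where(cur < 0, 0, cur)
    arr[idx] = _BASES[(cur + shifts) % 4]
    return arr.tobytes().decode()


def translate_cds(cds: str) -> str:
    from Bio.Seq import Seq
    return str(Seq(cds).translate()).rstrip("*")


# ---------------------------------------------------------------------------
# reference genomes

GENOMES = ("A", "B", "C")
GENOME_LABELS = {"A": "bd", "B": "os", "C": "sb"}

CHROM_MAIN = "1"          # colinear syntenic backbone
CHROM_NONSYN = "2"        # colinear pool outside the arm's syntenic region
CHROM_SCATTER = "3"       # destination of per-lineage moved genes (sparse)
CHROM_CONTAM = "4"        # genes carried by the contaminant arm


@dataclass
class RefGene:
    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    cds: str
    anc: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass
class ReferenceGenome:
    name: str
    label: str
    genes: list            # RefGene, ordered by (chromosome, start)

    def by_id(self) -> dict:
        return {g.gene_id: g for g in self.genes}

    def chromosome_genes(self, chrom: str) -> list:
        return [g for g in self.genes if g.chromosome == chrom]

    def cds_records(self) -> list:
        return [(g.gene_id, g.cds) for g in self.genes]

    def protein_records(self) -> list:
        return [(g.gene_id, translate_cds(g.cds)) for g in self.genes]

    def position_rows(self) -> list:
        return [dict(gene_id=g.gene_id, chromosome=g.chromosome,
                     start=g.start, end=g.end, strand=g.strand)
                for g in self.genes]


@dataclass
class ReferencePanel:
    genomes: dict                       # name -> ReferenceGenome
    ancestral_cds: dict                 # anc index -> sequence
    ancestral_category: dict            # anc index -> main | nonsyntenic | contaminant
    ortholog: dict                      # anc index -> {genome name -> gene_id or None}
    config: SimConfig

    def gene_table(self) -> dict:
        """gene_id -> (genome name, chromosome, midpoint, anc)."""
        out = {}
        for name, genome in self.genomes.items():
            for g in genome.genes:
                out[g.gene_id] = (name, g.chromosome, g.midpoint, g.anc)
        return out

    def anc_of_gene(self) -> dict:
        return {gid: v[3] for gid, v in self.gene_table().items()}


def _conservation_profiles(cfg: SimConfig, rng: np.random.Generator) -> list[set]:
    """Which reference genomes retain each main ancestral gene."""
    n = cfg.n_genes
    if cfg.conservation_classes is not None:
        profiles: list[set] = []
        classes = list(cfg.conservation_classes.items())
        counts = [int(round(f * n)) for _, f in classes]
        while sum(counts) > n:
            counts[int(np.argmax(counts))] -= 1
        for (label, _), k in zip(classes, counts):
            profiles.extend(set(label) for _ in range(k))
        while len(profiles) < n:
            profiles.append(set(GENOMES))
        perm = rng.permutation(n)
        return [profiles[i] for i in perm]
    keep = rng.random((n, 3)) >= cfg.lineage_loss_rate
    return [{g for g, k in zip(GENOMES, row) if k} for row in keep]


def simulate_reference_genomes(config: SimConfig) -> ReferencePanel:
    """Three annotated model genomes sharing an ancestral gene order.

    Genome ``A`` is the zipper backbone (cf. *B. distachyon*); ``B`` and
    ``C`` play the rice/sorghum roles.  Chromosome 1 of each genome carries
    the colinear main gene set (minus per-lineage losses, with a small
    fraction of genes moved to a sparse chromosome 3), chromosome 2 a
    colinear non-syntenic gene pool, and chromosome 4 the genes sampled by
    contaminant reads.
    """
    if config.n_genes < 20:
        raise ConfigError("n_genes must be >= 20")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_main = config.n_genes
    n_total = n_main + config.n_nonsyntenic_pool + config.n_contaminant_genes

    lens = rng.normal(config.mean_gene_len, config.gene_len_sd, n_total)
    lens = np.clip(lens, config.min_gene_len, None).astype(int)
    lens -= lens % 3
    ancestral = {i: random_cds(rng, lens[i] // 3) for i in range(n_total)}
    category = {}
    for i in range(n_total):
        if i < n_main:
            category[i] = "main"
        elif i < n_main + config.n_nonsyntenic_pool:
            category[i] = "nonsyntenic"
        else:
            category[i] = "contaminant"

    profiles = _conservation_profiles(config, rng)
    moved = {g: set() for g in GENOMES}      # anc indices moved to CHROM_SCATTER
    for g in GENOMES:
        for i in range(n_main):
            if g in profiles[i] and rng.random() < config.lineage_move_rate:
                moved[g].add(i)

    # non-syntenic pool: mutually syntenic among references except for a
    # planted subset broken by moving one genome's ortholog to chromosome 3
    ns_indices = list(range(n_main, n_main + config.n_nonsyntenic_pool))
    broken: dict[int, str] = {}
    n_broken = int(round((1.0 - config.nonsyntenic_mutual_fraction) * len(ns_indices)))
    for i in rng.choice(ns_indices, size=n_broken, replace=False):
        broken[int(i)] = GENOMES[int(rng.integers(0, 3))]

    ortholog: dict[int, dict] = {i: {g: None for g in GENOMES} for i in range(n_total)}
    genomes: dict[str, ReferenceGenome] = {}
    for g in GENOMES:
        label = GENOME_LABELS[g]
        genes: list[RefGene] = []
        by_chrom: dict[str, list[int]] = {CHROM_MAIN: [], CHROM_NONSYN: [],
                                          CHROM_SCATTER: [], CHROM_CONTAM: []}
        for i in range(n_main):
            if g not in profiles[i]:
                continue
            by_chrom[CHROM_SCATTER if i in moved[g] else CHROM_MAIN].append(i)
        for i in ns_indices:
            by_chrom[CHROM_SCATTER if broken.get(i) == g else CHROM_NONSYN].append(i)
        for i in range(n_main + config.n_nonsyntenic_pool, n_total):
            by_chrom[CHROM_CONTAM].append(i)
        for chrom, members in by_chrom.items():
            if chrom == CHROM_SCATTER:
                members = [members[j] for j in rng.permutation(len(members))]
            pos = 0
            gap_hi = 60_000 if chrom == CHROM_SCATTER else 2_000
            for rank, i in enumerate(members):
                pos += int(rng.integers(500, gap_hi))
                cds = mutate(ancestral[i], config.lineage_divergence, rng)
                gid = f"{label}{chrom}g{rank:05d}"
                genes.append(RefGene(gid, chrom, pos, pos + len(cds), "+", cds, i))
                ortholog[i][g] = gid
                pos += len(cds)
        genes.sort(key=lambda x: (x.chromosome, x.start))
        genomes[g] = ReferenceGenome(g, label, genes)
    return ReferencePanel(genomes, ancestral, category, ortholog, config)


# ---------------------------------------------------------------------------
# wheat arm

@dataclass
class SimulatedArm:
    label: str
    sequence: str
    truth: TruthSet
    wheat_gene_seqs: dict          # anc index -> wheat copy sequence
    organelle_genome: str
    config: SimConfig
    te_families: dict = field(default_factory=dict)   # family name -> master element
    trna_token: str = ""


def _apply_rearrangements(order: list[int], spec: list[Rearrangement]) -> list[int]:
    order = list(order)
    for r in spec:
        if r.end > len(order):
            raise ConfigError(
                f"rearrangement range [{r.start}, {r.end}) out of bounds for {len(order)} genes")
        if r.type == "inversion":
            order[r.start:r.end] = order[r.start:r.end][::-1]
        elif r.type == "segment_reversal":
            span = order[r.start:r.end]
            k = r.n_segments
            bounds = np.linspace(0, len(span), k + 1).astype(int)
            segments = [span[bounds[j]:bounds[j + 1]] for j in range(k)]
            order[r.start:r.end] = [x for seg in reversed(segments) for x in seg]
        elif r.type == "translocation_out":
            chunk = order[r.start:r.end]
            del order[r.start:r.end]
            dest = (r.start + len(order) // 2) % (len(order) + 1)
            order[dest:dest] = chunk
        elif r.type == "translocation_in":
            # duplicate the range elsewhere; copies are flagged planted duplicates
            chunk = order[r.start:r.end]
            dest = (r.end + len(order) // 3) % (len(order) + 1)
            order[dest:dest] = chunk
    return order


def _segment_runs(order: list[int]) -> list[tuple[int, str]]:
    """Maximal runs of consecutive ancestral indices (truth segment model)."""
    runs = []
    i = 0
    seg = 0
    while i < len(order):
        j = i + 1
        if j < len(order) and abs(order[j] - order[i]) == 1:
            step = order[j] - order[i]
            while j < len(order) and order[j] - order[j - 1] == step:
                j += 1
            runs.append((seg, "+" if step == 1 else "-"))
        else:
            runs.append((seg, "+"))
        seg += 1
        i = j
    return runs


def simulate_wheat_arm(config: SimConfig, panel: ReferencePanel) -> SimulatedArm:
    """Assemble the arm: rearranged syntenic gene runs, telomere-biased
    non-syntenic insertions, and TE copies tiled to the target repeat
    fraction (a fraction carrying a tRNA-like inset)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n_main = config.n_genes

    syntenic_order = _apply_rearrangements(list(range(n_main)), config.rearrangement_spec)
    seen: set[int] = set()
    duplicates: set[int] = set()
    for i in syntenic_order:
        if i in seen:
            duplicates.add(i)
        seen.add(i)

    # choose non-syntenic genes from the chromosome-2 pool
    pool = [i for i, c in panel.ancestral_category.items() if c == "nonsyntenic"]
    ns_genes = [int(i) for i in rng.choice(pool, size=config.n_nonsyntenic_insertions,
                                           replace=False)]

    wheat_seqs = {}
    for i in list(syntenic_order) + ns_genes:
        if i not in wheat_seqs:
            wheat_seqs[i] = mutate(panel.ancestral_cds[i], config.wheat_divergence, rng)

    # TE families
    te_lo, te_hi = config.te_len_range
    families = {f"TEfam{k:02d}": random_dna(rng, int(rng.integers(te_lo, te_hi)))
                for k in range(config.n_repeat_families)}
    trna_token = random_dna(rng, config.trna_token_len)

    spacer = 100   # filler separating stacked insertions from their neighbours
    genic_total = sum(len(wheat_seqs[i]) for i in syntenic_order) \
        + sum(len(wheat_seqs[g]) + spacer for g in ns_genes)
    repeat_budget = int(config.repeat_fraction * config.arm_size)
    filler_budget = config.arm_size - genic_total - repeat_budget
    if filler_budget < 0:
        raise ConfigError("arm_size too small for requested gene and repeat content")

    # backbone layout: one intergenic gap per syntenic slot; non-syntenic
    # insertions are then targeted at base-pair fractions of the final arm
    # (distal 10% with probability nonsyntenic_telomere_bias), so insertion
    # clusters stack inside existing gaps instead of stretching the arm
    n_gaps = len(syntenic_order) + 1
    w = rng.random(n_gaps) + 0.2
    w /= w.sum()
    rep_share = (w * repeat_budget).astype(int)
    fil_share = (w * filler_budget).astype(int)
    gap_len = rep_share + fil_share

    gene_starts = []     # backbone coordinate at which syntenic gene j starts
    bp = 0
    for j, anc in enumerate(syntenic_order):
        bp += int(gap_len[j])
        gene_starts.append(bp)
        bp += len(wheat_seqs[anc])
    backbone_len = bp + int(gap_len[-1])
    final_len = backbone_len + sum(len(wheat_seqs[g]) + spacer for g in ns_genes)

    targets = []
    for g in ns_genes:
        if rng.random() < config.nonsyntenic_telomere_bias:
            frac = float(rng.uniform(0.905, 0.99))
        else:
            frac = float(rng.uniform(0.005, 0.895))
        targets.append((frac * final_len, g))
    targets.sort()
    inserted_at: dict[int, list[int]] = {k: [] for k in range(n_gaps)}
    added = 0
    slot = 0
    for t, g in targets:
        while slot < len(gene_starts) and gene_starts[slot] + added < t:
            slot += 1
        inserted_at[slot].append(g)
        added += len(wheat_seqs[g]) + spacer

    truth = TruthSet(arm_size=config.arm_size)
    pieces: list[str] = []
    pos = 0
    fam_names = sorted(families)
    inset_families = set(fam_names[:max(1, len(fam_names) // 2)])

    def emit_gap(k: int):
        nonlocal pos
        f = fil_share[k]
        pieces.append(random_dna(rng, f // 2))
        pos += f // 2
        remaining = rep_share[k]
        while remaining >= 60:
            fam = fam_names[int(rng.integers(0, len(fam_names)))]
            element = families[fam]
            copy = element if len(element) <= remaining else element[:remaining]
            if rng.random() >= config.te_exact_copy_fraction:
                copy = mutate(copy, float(rng.uniform(0.005, config.te_max_divergence)), rng)
            if fam in inset_families and rng.random() < config.trna_capture_rate:
                mid = len(copy) // 2
                copy = copy[:mid] + trna_token + copy[mid:]
                truth.trna_inset_intervals.append((pos + mid, pos + mid + len(trna_token)))
            pieces.append(copy)
            truth.repeat_intervals.append((pos, pos + len(copy), fam))
            pos += len(copy)
            remaining -= len(copy)
        pieces.append(random_dna(rng, f - f // 2 + max(remaining, 0)))
        pos += f - f // 2 + max(remaining, 0)

    emitted_dup: set[int] = set()
    wheat_order: list[int] = []

    def emit_gene(anc: int, syntenic: bool):
        nonlocal pos
        seq = wheat_seqs[anc]
        is_dup = anc in duplicates and anc in emitted_dup
        truth.gene_records.append(GeneTruth(
            anc=anc,
            origins=[g for g in GENOMES if panel.ortholog[anc][g] is not None],
            arm_start=pos, arm_end=pos + len(seq),
            syntenic=syntenic, planted_duplicate=is_dup,
            mutually_syntenic=(None if syntenic else _is_mutually_syntenic(panel, anc)),
        ))
        if anc in duplicates:
            emitted_dup.add(anc)
        wheat_order.append(anc)
        pieces.append(seq)
        pos += len(seq)

    for k in range(n_gaps):
        emit_gap(k)
        for g in inserted_at[k]:
            emit_gene(g, syntenic=False)
            pieces.append(random_dna(rng, spacer))
            pos += spacer
        if k < len(syntenic_order):
            emit_gene(syntenic_order[k], syntenic=True)

    truth.wheat_order = wheat_order
    truth.segment_structure = _segment_runs(syntenic_order)
    arm_len = pos
    truth.arm_size = arm_len
    width = int(np.ceil(arm_len / config.n_bins))
    truth.bin_boundaries = [(f"bin{b + 1}", b * width, min((b + 1) * width, arm_len))
                            for b in range(config.n_bins)]
    truth.validate()

    organelle = random_dna(np.random.default_rng(np.random.SeedSequence([config.seed, 9])),
                           20_000)
    return SimulatedArm(config.arm_label, "".join(pieces), truth, wheat_seqs,
                        organelle, config, te_families=families, trna_token=trna_token)


def _is_mutually_syntenic(panel: ReferencePanel, anc: int) -> bool:
    """Truth label: the three orthologs all sit on the colinear pool chromosome."""
    genome_of = {}
    for g in GENOMES:
        gid = panel.ortholog[anc][g]
        if gid is None:
            return False
        genome_of[g] = panel.genomes[g].by_id()[gid].chromosome
    return all(c == CHROM_NONSYN for c in genome_of.values())


def simulate_contaminant_arm(config: SimConfig, panel: ReferencePanel) -> str:
    """A second arm supplying impurity reads: contaminant-pool genes spread
    thinly through random and TE sequence."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    genes = [i for i, c in panel.ancestral_category.items() if c == "contaminant"]
    pieces = []
    for i in genes:
        pieces.append(random_dna(rng, int(rng.integers(3_000, 8_000))))
        pieces.append(mutate(panel.ancestral_cds[i], config.wheat_divergence, rng))
    pieces.append(random_dna(rng, 5_000))
    return "".join(pieces)


# ---------------------------------------------------------------------------
# reads

def simulate_reads(arm: SimulatedArm, contaminant_source: str | None,
                   config: SimConfig) -> list[SurveyRead]:
    """Shotgun reads with truncated-normal lengths, impurity reads from the
    contaminant arm and organellar genome, and byte-identical duplicate
    artifacts; all labels recorded in the arm's TruthSet."""
    if not arm.sequence:
        raise InputError("empty arm sequence")
    if not (0.0 < config.purity <= 1.0):
        raise ConfigError("purity must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    S = len(arm.sequence)
    N = int(round(config.coverage_fold * S / config.mean_read_len))
    truth = arm.truth

    n_impure = int(round((1.0 - config.purity) * N))
    if n_impure and contaminant_source is None and config.organelle_fraction < 1.0:
        raise InputError("purity < 1 requires a contaminant source")
    n_org = int(round(config.organelle_fraction * n_impure))
    n_cont = n_impure - n_org

    sources = [("target", arm.sequence)] * (N - n_impure)
    sources += [("contaminant", contaminant_source)] * n_cont
    sources += [("organelle", arm.organelle_genome)] * n_org
    perm = rng.permutation(len(sources))

    reads: list[SurveyRead] = []
    for k, idx in enumerate(perm):
        cat, template = sources[idx]
        L = int(np.clip(rng.normal(config.mean_read_len, config.read_len_sd),
                        config.min_read_len, min(len(template), 4 * config.mean_read_len)))
        start = int(rng.integers(0, len(template) - L + 1))
        rid = f"{arm.label}_r{k:07d}"
        reads.append(SurveyRead(rid, arm.label, template[start:start + L], source=(
            "target" if cat == "target" else "contaminant")))
        truth.read_positions[rid] = (start, start + L)
        if cat == "contaminant":
            truth.contaminant_read_ids.add(rid)
        elif cat == "organelle":
            truth.contaminant_read_ids.add(rid)
            truth.organelle_read_ids.add(rid)

    n_dup = int(round(config.artifact_rate * N))
    if n_dup:
        picks = rng.choice(len(reads), size=n_dup, replace=False)
        for j in sorted(int(p) for p in picks):
            src = reads[j]
            rid = f"{src.read_id}d"
            reads.append(SurveyRead(rid, src.arm, src.sequence, source=src.source))
            truth.read_positions[rid] = truth.read_positions[src.read_id]
            truth.artifact_pairs.append((src.read_id, rid))
            if src.read_id in truth.contaminant_read_ids:
                truth.contaminant_read_ids.add(rid)
            if src.read_id in truth.organelle_read_ids:
                truth.organelle_read_ids.add(rid)
    return reads


# ---------------------------------------------------------------------------
# markers and transcripts

def simulate_markers_and_transcripts(
        arm: SimulatedArm, config: SimConfig
) -> tuple[list[MarkerRecord], list[tuple[str, str]]]:
    """Deletion-bin markers (gene subsequences tagged with the bin containing
    the gene) and transcripts covering each gene to its planted coverage
    class (high ~75%, low ~40%, none)."""
    truth = arm.truth
    if not truth.bin_boundaries:
        raise InputError("truth has no bin boundaries")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))

    def bin_of(p: int) -> str:
        for bid, s, e in truth.bin_boundaries:
            if s <= p < e:
                return bid
        return truth.bin_boundaries[-1][0]

    markers: list[MarkerRecord] = []
    transcripts: list[tuple[str, str]] = []
    arm_len = truth.arm_size
    for rec in truth.gene_records:
        seq = arm.wheat_gene_seqs[rec.anc]
        mid = (rec.arm_start + rec.arm_end) // 2
        if rng.random() < config.marker_fraction and not rec.planted_duplicate:
            mlen = min(config.marker_len, len(seq))
            off = int(rng.integers(0, len(seq) - mlen + 1))
            markers.append(MarkerRecord(
                marker_id=f"mk{rec.anc:05d}",
                kind="EST" if rng.random() < 0.7 else "SSR",
                bin=bin_of(mid),
                sequence=seq[off:off + mlen],
                map_position=round(100.0 * mid / arm_len, 2),
            ))
        u = rng.random()
        if u < config.transcript_fraction_high:
            rec.transcript_class = "high"
            frac = float(rng.uniform(0.70, 0.85))
        elif u < config.transcript_fraction_high + config.transcript_fraction_low:
            rec.transcript_class = "low"
            frac = float(rng.uniform(0.30, 0.50))
        else:
            rec.transcript_class = "none"
            continue
        tlen = max(60, int(frac * len(seq)))
        off = int(rng.integers(0, len(seq) - tlen + 1))
        transcripts.append((f"tx{rec.anc:05d}", seq[off:off + tlen]))
    return markers, transcripts


def score_repeat_detection(truth: TruthSet, detected_ids: set,
                           min_false_overlap: int = 50) -> dict:
    """Sensitivity and false-discovery rate of repeat-read detection.

    A target read is truly repeat-derived when more than half its bases lie
    in planted repeat intervals; a detection is counted false only when the
    read overlaps planted repeats by fewer than ``min_false_overlap`` bases
    (reads in between are partial repeat carriers and count neither way).
    """
    ov = truth.read_repeat_overlap()
    majority = {rid for rid, o in ov.items()
                if o > 0.5 * (truth.read_positions[rid][1] - truth.read_positions[rid][0])}
    clean = {rid for rid, o in ov.items() if o < min_false_overlap}
    detected_targets = {rid for rid in detected_ids if rid in ov}
    tp = len(detected_targets & majority)
    fp = len(detected_targets & clean)
    return {
        "sensitivity": tp / len(majority) if majority else float("nan"),
        "fdr": fp / len(detected_targets) if detected_targets else 0.0,
        "n_true_repeat_reads": len(majority),
        "n_detected": len(detected_targets),
    }


def trna_prediction_table(reads, token: str, min_match: int = 60):
    """Synthetic stand-in for an external tRNA prediction run: flags reads
    whose unmasked sequence contains (most of) the planted tRNA-like token.
    Real analyses consume genuine predictor output through the same table
    shape (read_id, isotype, anticodon, score)."""
    import pandas as pd
    rows = []
    probe = token[:min_match]
    for r in reads:
        seq = r.sequence
        for s, e in r.masked:
            seq = seq[:s] + "#" * (e - s) + seq[e:]
        start = 0
        while True:
            i = seq.find(probe, start)
            if i < 0:
                break
            rows.append(dict(read_id=r.read_id, isotype="Lys", anticodon="TTT",
                             score=80.0))
            start = i + 1
    return pd.DataFrame(rows, columns=["read_id", "isotype", "anticodon", "score"])


# ---------------------------------------------------------------------------
# output bundle

def write_simulation(outdir, panel: ReferencePanel, arm: SimulatedArm,
                     reads, markers, transcripts) -> None:
    """Write the full simulation bundle in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta([(r.read_id, r.sequence) for r in reads], outdir / "reads.fasta")
    refdir = outdir / "references"
    refdir.mkdir(exist_ok=True)
    for g, genome in panel.genomes.items():
        write_fasta(genome.cds_records(), refdir / f"{genome.label}.cds.fasta")
        write_position_table(genome.position_rows(), refdir / f"{genome.label}.pos.tsv")
    write_fasta(sorted(arm.te_families.items()), outdir / "repeats.fasta")
    write_markers(markers, outdir / "markers.tsv")
    write_fasta(transcripts, outdir / "transcripts.fasta")
    arm.truth.to_json(outdir / "truth.json")
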