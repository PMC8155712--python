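"""Synthetic genomes with planted regulatory elements and simulated libraries.

The generator writes a toy bacterial genome in which every regulatory
element the pipeline must recover is planted explicitly and recorded in a
:class:`TruthSet`:

* each gene gets a primary TSS upstream of its start codon at a 5'-UTR
  distance drawn around a median of 42 nt (a configurable fraction is
  leaderless, UTR < 9 nt), with a -10 box (TANAAT) and a -35 box (TTGCCAA)
  written into the sequence at offsets -10 and -35 from the TSS, a purine
  at the TSS and a pyrimidine at -1;
* 5'-UTRs longer than 15 nt carry an AGGAG ribosome binding site 5-10 nt
  upstream of the start codon;
* each transcription unit ends in an intrinsic terminator: an 8-bp GC stem
  with a 4-nt loop followed by a >= 4-nt U-tract (L-shaped) or by non-U
  bases (I-shaped), with the transcript 3'-end position (TEP) planted at
  the end of the U-tract / just past the stem;
* a fraction of genes get secondary/internal/antisense TSSs and processed
  5'-end sites.

Library simulation places negative-binomially dispersed counts at planted
sites (with +/-1 nt positional jitter), leaks planted TSS signal into the
TAP- library at a configured ratio, shows processed sites at equal or
higher depth in TAP-, piles Term-seq ends at TEPs with small satellite
signals nearby, covers each unit uniformly with RNA-seq and drops coverage
>= 5-fold past the TEP, and scatters Poisson background genome-wide.
Everything is reproducible bit-for-bit from (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_io import (
    AnnotationSet,
    EndCountTrack,
    Gene,
    GenomeRecord,
    GenomeSet,
    revcomp,
)

_BASES = np.array(list("ACGT"))
_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

# relative depth of planted TSS classes vs the primary TSS
_CLASS_LEVEL = {"P": 1.0, "S": 0.3, "I": 0.25, "A": 0.2}


@dataclass
class SimConfig:
    """Study conditions for the simulator; defaults mirror the real design
    (duplicate dRNA-seq, triplicate Term-seq/RNA-seq, ~42 nt median 5'-UTR)."""

    n_genes: int = 60
    gene_length_range: Tuple[int, int] = (120, 300)
    intergenic_range: Tuple[int, int] = (100, 250)
    gc_content: float = 0.47
    utr5_median: float = 42.0
    utr5_sigma: float = 0.35
    frac_leaderless: float = 0.10
    frac_secondary: float = 0.20
    frac_internal: float = 0.15
    frac_antisense: float = 0.15
    frac_processed: float = 0.25
    frac_L_terminators: float = 0.70
    utr3_range: Tuple[int, int] = (25, 60)
    tap_plus_depth_mean: float = 100.0
    tap_minus_leak_ratio: float = 0.2
    term_depth_mean: float = 100.0
    rna_depth_mean: float = 2.0
    replicates_tss: int = 2
    replicates_term: int = 3
    replicates_rna: int = 3
    nb_dispersion: float = 0.1
    jitter_prob: float = 0.1
    background_rate: float = 5e-4
    seed: int = 0

    def __post_init__(self):
        for name in (
            "frac_leaderless", "frac_secondary", "frac_internal",
            "frac_antisense", "frac_processed", "frac_L_terminators",
            "gc_content",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gene_length_range", "intergenic_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive (min, max) range")
        if self.replicates_tss < 2:
            raise ValueError("replicates_tss must be >= 2 (duplicate design)")
        if self.replicates_term < 3:
            raise ValueError("replicates_term must be >= 3 (triplicate design)")


@dataclass(frozen=True)
class PlantedSite:
    position: int
    strand: str
    gene_id: str
    klass: str = ""  # TSS class P/S/I/A; TEP shape L/I; motif kind


@dataclass
class GenePlan:
    """One gene cassette in coding orientation (local coordinates)."""

    gene_id: str
    strand: str
    cassette: List[str]  # mutable char list, coding orientation
    tss_local: int
    utr5: int
    gene_start_local: int
    gene_end_local: int  # half-open
    tep_local: int
    shape: str  # 'L' or 'I'
    promoter_region: Tuple[int, int]  # [tss-50, tss) clipped, local
    terminator_region: Tuple[int, int]  # [tep-40, tep+20] -> half-open local
    rbs_local: Optional[int] = None  # start of AGGAG, local
    rbs_distance: Optional[int] = None
    extra_tss: List[Tuple[int, str, str]] = field(default_factory=list)  # (local, klass, strand_rel)
    processed_local: Optional[int] = None
    level: float = 1.0
    offset: int = 0  # global offset of cassette start (set at assembly)

    def to_global(self, local: int) -> int:
        if self.strand == "+":
            return self.offset + local
        return self.offset + len(self.cassette) - 1 - local

    def global_strand(self, relative: str) -> str:
        same = self.strand
        opp = "-" if same == "+" else "+"
        return same if relative == "sense" else opp


@dataclass
class TruthSet:
    """Planted ground truth; the universal oracle for pipeline tests."""

    seq_id: str
    genome_length: int
    tss: List[PlantedSite] = field(default_factory=list)
    teps: List[PlantedSite] = field(default_factory=list)
    motifs: List[PlantedSite] = field(default_factory=list)
    processed: List[PlantedSite] = field(default_factory=list)
    units: Dict[str, Tuple[int, int, str]] = field(default_factory=dict)
    gene_levels: Dict[str, float] = field(default_factory=dict)
    plans: Dict[str, GenePlan] = field(default_factory=dict)

    def primary_tss(self) -> List[PlantedSite]:
        return [t for t in self.tss if t.klass == "P"]

    def tss_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.tss])

    def tep_table(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(t) for t in self.teps])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> List[str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return list(rng.choice(_BASES, size=n, p=p))


def _build_gene_plan(idx: int, config: SimConfig, rng: np.random.Generator) -> GenePlan:
    gene_id = f"gene{idx:04d}"
    strand = "+" if idx % 2 == 0 else "-"
    gc = config.gc_content

    if rng.random() < config.frac_leaderless:
        utr5 = int(rng.integers(0, 9))
    else:
        utr5 = int(round(rng.lognormal(math.log(config.utr5_median), config.utr5_sigma)))
        utr5 = min(max(utr5, 10), 150)

    lo, hi = config.gene_length_range
    ncod = int(rng.integers(max(2, lo // 3), hi // 3 + 1))
    body = "ATG" + "".join(rng.choice(_NONSTOP_CODONS) for _ in range(ncod - 2)) + "TAA"

    utr3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
    stem = "".join(rng.choice(["G", "C"], size=8))
    loop = "".join(rng.choice(_BASES, size=4))
    hairpin = stem + loop + revcomp(stem)
    shape = "L" if rng.random() < config.frac_L_terminators else "I"
    if shape == "L":
        utract = "T" * int(rng.integers(4, 8))
        term = hairpin + utract
        tep_off_in_term = len(term) - 1  # last U
    else:
        spacer = "".join(rng.choice(["A", "G", "C"], size=3))
        term = hairpin + spacer
        tep_off_in_term = len(term) - 1

    pre = 45
    tss_local = pre
    gene_start = tss_local + utr5
    gene_end = gene_start + len(body)
    term_start = gene_end + utr3
    tep_local = term_start + tep_off_in_term
    # tail: first two bases non-T so the I-shape U-count window stays clean
    tail = list(rng.choice(["A", "G", "C"], size=2)) + _random_seq(rng, 28, gc)

    cassette = (
        _random_seq(rng, pre, gc)
        + _random_seq(rng, utr5, gc)
        + list(body)
        + _random_seq(rng, utr3, gc)
        + list(term)
        + tail
    )

    # promoter motifs relative to the TSS
    minus10 = "TA" + str(rng.choice(_BASES)) + "AAT"
    cassette[tss_local - 10 : tss_local - 4] = list(minus10)
    cassette[tss_local - 35 : tss_local - 28] = list("TTGCCAA")
    cassette[tss_local] = str(rng.choice(["A", "G"]))  # purine at +1
    cassette[tss_local - 1] = str(rng.choice(["C", "T"]))  # pyrimidine at -1

    rbs_local = None
    rbs_dist = None
    if utr5 > 15:
        d = int(rng.integers(5, min(10, utr5 - 6) + 1))
        rbs_local = gene_start - d - 5
        rbs_dist = d
        cassette[rbs_local : rbs_local + 5] = list("AGGAG")

    extra: List[Tuple[int, str, str]] = []
    if rng.random() < config.frac_secondary and utr5 >= 25:
        extra.append((tss_local + int(rng.integers(5, utr5 - 10)), "S", "sense"))
    if rng.random() < config.frac_internal:
        extra.append((gene_start + int(rng.integers(30, len(body) - 10)), "I", "sense"))
    if rng.random() < config.frac_antisense:
        extra.append((gene_start + int(rng.integers(30, len(body) - 10)), "A", "anti"))

    processed_local = None
    if rng.random() < config.frac_processed:
        processed_local = gene_start + int(rng.integers(10, max(11, len(body) // 2)))

    return GenePlan(
        gene_id=gene_id,
        strand=strand,
        cassette=cassette,
        tss_local=tss_local,
        utr5=utr5,
        gene_start_local=gene_start,
        gene_end_local=gene_end,
        tep_local=tep_local,
        shape=shape,
        promoter_region=(tss_local - 50, tss_local),
        terminator_region=(tep_local - 40, tep_local + 21),
        rbs_local=rbs_local,
        rbs_distance=rbs_dist,
        extra_tss=extra,
        processed_local=processed_local,
        level=float(rng.lognormal(0.0, 0.4)),
    )


def _assemble(plans: Sequence[GenePlan], config: SimConfig,
              rng: np.random.Generator, seq_id: str
              ) -> Tuple[GenomeSet, AnnotationSet, TruthSet]:
    pieces: List[str] = ["".join(_random_seq(rng, 60, config.gc_content))]
    cursor = 60
    genes: List[Gene] = []
    truth = TruthSet(seq_id=seq_id, genome_length=0)

    for plan in plans:
        plan.offset = cursor
        cas = "".join(plan.cassette)
        if plan.strand == "-":
            cas = revcomp(cas)
        pieces.append(cas)
        clen = len(plan.cassette)

        if plan.strand == "+":
            gstart = plan.offset + plan.gene_start_local
            gend = plan.offset + plan.gene_end_local
        else:
            gstart = plan.offset + clen - plan.gene_end_local
            gend = plan.offset + clen - plan.gene_start_local
        genes.append(Gene(plan.gene_id, seq_id, gstart, gend, plan.strand))

        tss_g = plan.to_global(plan.tss_local)
        truth.tss.append(PlantedSite(tss_g, plan.strand, plan.gene_id, "P"))
        for local, klass, rel in plan.extra_tss:
            truth.tss.append(
                PlantedSite(plan.to_global(local), plan.global_strand(rel), plan.gene_id, klass)
            )
        tep_g = plan.to_global(plan.tep_local)
        truth.teps.append(PlantedSite(tep_g, plan.strand, plan.gene_id, plan.shape))
        if plan.processed_local is not None:
            truth.processed.append(
                PlantedSite(plan.to_global(plan.processed_local), plan.strand, plan.gene_id)
            )
        for kind, local in (("minus10", plan.tss_local - 10), ("minus35", plan.tss_local - 35)):
            truth.motifs.append(
                PlantedSite(plan.to_global(local), plan.strand, plan.gene_id, kind)
            )
        if plan.rbs_local is not None:
            truth.motifs.append(
                PlantedSite(plan.to_global(plan.rbs_local), plan.strand, plan.gene_id, "rbs")
            )
        lo, hi = sorted((tss_g, tep_g))
        truth.units[plan.gene_id] = (lo, hi + 1, plan.strand)
        truth.gene_levels[plan.gene_id] = plan.level
        truth.plans[plan.gene_id] = plan

        cursor += clen
        spacer = int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1))
        pieces.append("".join(_random_seq(rng, spacer, config.gc_content)))
        cursor += spacer

    pieces.append("".join(_random_seq(rng, 60, config.gc_content)))
    sequence = "".join(pieces)
    truth.genome_length = len(sequence)
    genome = GenomeSet([GenomeRecord(seq_id, sequence, circular=True)])
    annotation = AnnotationSet(genes)
    return genome, annotation, truth


def generate_genome(config: SimConfig, seq_id: str = "chr"
                    ) -> Tuple[GenomeSet, AnnotationSet, TruthSet]:
    """Generate a toy genome with planted regulatory elements.

    Deterministic given ``config.seed``; genes alternate strands.
    """
    rng = np.random.default_rng(config.seed)
    plans = [_build_gene_plan(i, config, rng) for i in range(config.n_genes)]
    return _assemble(plans, config, rng, seq_id)


# ---------------------------------------------------------------------------
# Library simulation


def _nb(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 0:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def _place_with_jitter(track: EndCountTrack, pos: int, strand: str, count: int,
                       jitter_prob: float, rng: np.random.Generator) -> None:
    if count <= 0:
        return
    half = jitter_prob / 2.0
    lo, c0, hi = rng.multinomial(count, [half, 1.0 - jitter_prob, half])
    for p, c in ((pos - 1, lo), (pos, c0), (pos + 1, hi)):
        if c > 0 and p >= 0:
            track.add(p, strand, float(c))


def _background(track: EndCountTrack, glen: int, rate: float,
                rng: np.random.Generator) -> None:
    for strand in "+-":
        n = int(rng.poisson(rate * glen))
        for pos in rng.integers(0, glen, size=n):
            track.add(int(pos), strand, 1.0)


def _finalize(track: EndCountTrack) -> EndCountTrack:
    track.total_reads = track.total()
    return track


def simulate_tss_libraries(truth: TruthSet, config: SimConfig
                           ) -> List[EndCountTrack]:
    """Simulate TAP+ and TAP- dRNA-seq tracks for each replicate.

    TAP+ places dispersed counts at planted TSSs; the TAP- expectation at a
    TSS is ``tap_minus_leak_ratio`` times the TAP+ expectation.  Processed
    sites appear in both libraries, boosted in TAP- so that the two library
    totals match in expectation (degradation products dominate untreated
    libraries, keeping size factors comparable).
    """
    if config.replicates_tss < 2:
        raise ValueError("at least 2 dRNA-seq replicates are required")
    rng = np.random.default_rng([config.seed, 1])
    glen = truth.genome_length

    tss_lams = [
        (t, config.tap_plus_depth_mean * truth.gene_levels[t.gene_id] * _CLASS_LEVEL[t.klass])
        for t in truth.tss
    ]
    proc_lam = {
        s: 0.8 * config.tap_plus_depth_mean * truth.gene_levels[s.gene_id]
        for s in truth.processed
    }
    e_plus = sum(l for _, l in tss_lams) + sum(proc_lam.values())
    e_minus = config.tap_minus_leak_ratio * sum(l for _, l in tss_lams) + sum(proc_lam.values())
    boost = (e_plus - e_minus) / len(proc_lam) if proc_lam else 0.0

    tracks: List[EndCountTrack] = []
    for r in range(1, config.replicates_tss + 1):
        plus = EndCountTrack(truth.seq_id, "TAP_PLUS", f"rep{r}")
        minus = EndCountTrack(truth.seq_id, "TAP_MINUS", f"rep{r}")
        for site, lam in tss_lams:
            _place_with_jitter(plus, site.position, site.strand,
                               _nb(rng, lam, config.nb_dispersion),
                               config.jitter_prob, rng)
            _place_with_jitter(minus, site.position, site.strand,
                               _nb(rng, lam * config.tap_minus_leak_ratio, config.nb_dispersion),
                               config.jitter_prob, rng)
        for site, lam in proc_lam.items():
            _place_with_jitter(plus, site.position, site.strand,
                               _nb(rng, lam, config.nb_dispersion),
                               config.jitter_prob, rng)
            _place_with_jitter(minus, site.position, site.strand,
                               _nb(rng, lam + boost, config.nb_dispersion),
                               config.jitter_prob, rng)
        _background(plus, glen, config.background_rate, rng)
        _background(minus, glen, config.background_rate, rng)
        tracks += [_finalize(plus), _finalize(minus)]
    return tracks


def simulate_term_libraries(truth: TruthSet, config: SimConfig
                            ) -> Tuple[List[EndCountTrack], List[EndCountTrack]]:
    """Simulate Term-seq (strand already reversed) and RNA-seq tracks.

    Term-seq ends pile at planted TEPs with small satellite signals within
    +/-10 nt (stochastic termination); RNA coverage is uniform over each
    transcription unit and drops 10-fold for 100 nt past the TEP.
    """
    if config.replicates_term < 3:
        raise ValueError("at least 3 Term-seq replicates are required (triplicate consensus)")
    rng = np.random.default_rng([config.seed, 2])
    glen = truth.genome_length

    term_tracks: List[EndCountTrack] = []
    for r in range(1, config.replicates_term + 1):
        track = EndCountTrack(truth.seq_id, "TERM", f"rep{r}")
        for site in truth.teps:
            lam = config.term_depth_mean * truth.gene_levels[site.gene_id]
            _place_with_jitter(track, site.position, site.strand,
                               _nb(rng, lam, config.nb_dispersion),
                               config.jitter_prob, rng)
            offsets = rng.choice(
                np.concatenate([np.arange(-9, -2), np.arange(3, 10)]),
                size=3, replace=False,
            )
            for off in offsets:
                track.add(int(site.position + off), site.strand,
                          float(rng.poisson(0.05 * lam) + 1))
        _background(track, glen, config.background_rate, rng)
        term_tracks.append(_finalize(track))

    rna_tracks: List[EndCountTrack] = []
    for r in range(1, config.replicates_rna + 1):
        track = EndCountTrack(truth.seq_id, "RNA", f"rep{r}")
        for gene_id, (lo, hi, strand) in truth.units.items():
            lam = config.rna_depth_mean * truth.gene_levels[gene_id]
            counts = rng.poisson(lam, size=hi - lo)
            for i, c in enumerate(counts):
                if c > 0:
                    track.add(lo + i, strand, float(c))
            # read-through tail past the TEP at a tenth of the unit density
            if strand == "+":
                tail = range(hi, min(glen, hi + 100))
            else:
                tail = range(max(0, lo - 100), lo)
            tail_counts = rng.poisson(lam / 10.0, size=len(tail))
            for p, c in zip(tail, tail_counts):
                if c > 0:
                    track.add(p, strand, float(c))
        _background(track, glen, config.background_rate / 5, rng)
        rna_tracks.append(_finalize(track))

    return term_tracks, rna_tracks


# ---------------------------------------------------------------------------
# Ortholog genome


@dataclass
class DivergenceConfig:
    """Scenario fractions (conserved, mismatched, orphan, specific) applied
    per gene, plus a CDS point-mutation rate."""

    fractions: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    cds_mutation_rate: float = 0.02
    seed: int = 1

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("scenario fractions must sum to 1")


@dataclass(frozen=True)
class OrthologTruth:
    gene_a: str
    gene_b: Optional[str]
    promoter_class: str
    terminator_class: str


def _class_counts(fractions: Sequence[float], n: int) -> List[int]:
    # largest-remainder apportionment: exact deterministic class counts
    raw = [f * n for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _mutate(seq: List[str], start: int, end: int, rate: float,
            rng: np.random.Generator) -> None:
    for i in range(start, end):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != seq[i]]
            seq[i] = choices[int(rng.integers(0, 3))]


def generate_ortholog_pair(truth: TruthSet, config: SimConfig,
                           div: DivergenceConfig, seq_id: str = "chrB"
                           ) -> Tuple[GenomeSet, AnnotationSet, TruthSet, List[OrthologTruth]]:
    """Build a diverged ortholog genome and per-gene conservation truth.

    Per gene one of four scenarios is applied (deterministic class counts,
    seeded assignment order): *conserved* copies the promoter/terminator
    region with the matching TSS/TEP offset; *mismatched* copies the region
    but removes the site; *orphan* randomizes the region; *specific*
    deletes the ortholog.  The same scenario governs a gene's promoter and
    terminator region.  Coding sequences receive point mutations at
    ``cds_mutation_rate`` (start and stop codons preserved).
    """
    rng = np.random.default_rng([config.seed, div.seed])
    gene_ids = sorted(truth.plans)
    counts = _class_counts(div.fractions, len(gene_ids))
    classes = (["conserved"] * counts[0] + ["mismatched"] * counts[1]
               + ["orphan"] * counts[2] + ["specific"] * counts[3])
    order = rng.permutation(len(gene_ids))
    assignment = {gene_ids[order[i]]: classes[i] for i in range(len(gene_ids))}

    plans_b: List[GenePlan] = []
    ortho: List[OrthologTruth] = []
    for gene_id in gene_ids:
        plan = truth.plans[gene_id]
        klass = assignment[gene_id]
        if klass == "specific":
            ortho.append(OrthologTruth(gene_id, None, "specific", "specific"))
            continue
        cas = list(plan.cassette)
        _mutate(cas, plan.gene_start_local + 3, plan.gene_end_local - 3,
                div.cds_mutation_rate, rng)
        if klass == "orphan":
            lo, hi = plan.promoter_region
            cas[max(0, lo):hi] = _random_seq(rng, hi - max(0, lo), config.gc_content)
            lo, hi = plan.terminator_region
            cas[max(0, lo):min(len(cas), hi)] = _random_seq(
                rng, min(len(cas), hi) - max(0, lo), config.gc_content)
        plan_b = GenePlan(
            gene_id=gene_id,
            strand=plan.strand,
            cassette=cas,
            tss_local=plan.tss_local,
            utr5=plan.utr5,
            gene_start_local=plan.gene_start_local,
            gene_end_local=plan.gene_end_local,
            tep_local=plan.tep_local,
            shape=plan.shape,
            promoter_region=plan.promoter_region,
            terminator_region=plan.terminator_region,
            rbs_local=plan.rbs_local,
            rbs_distance=plan.rbs_distance,
            level=plan.level,
        )
        if klass != "conserved":
            # site absent in strain B: suppress the planted TSS/TEP
            plan_b.tss_local = -1
        plans_b.append(plan_b)
        ortho.append(OrthologTruth(gene_id, gene_id, klass, klass))

    genome_b, annotation_b, truth_b = _assemble_b(plans_b, config, rng, seq_id)
    return genome_b, annotation_b, truth_b, ortho


def _assemble_b(plans: List[GenePlan], config: SimConfig,
                rng: np.random.Generator, seq_id: str
                ) -> Tuple[GenomeSet, AnnotationSet, TruthSet]:
    pieces: List[str] = ["".join(_random_seq(rng, 60, config.gc_content))]
    cursor = 60
    genes: List[Gene] = []
    truth = TruthSet(seq_id=seq_id, genome_length=0)
    for plan in plans:
        suppressed = plan.tss_local < 0
        if suppressed:
            # restore geometry for coordinate mapping; only truth sites differ
            plan.tss_local = plan.gene_start_local - plan.utr5
        plan.offset = cursor
        cas = "".join(plan.cassette)
        if plan.strand == "-":
            cas = revcomp(cas)
        pieces.append(cas)
        clen = len(plan.cassette)
        if plan.strand == "+":
            gstart = plan.offset + plan.gene_start_local
            gend = plan.offset + plan.gene_end_local
        else:
            gstart = plan.offset + clen - plan.gene_end_local
            gend = plan.offset + clen - plan.gene_start_local
        genes.append(Gene(plan.gene_id, seq_id, gstart, gend, plan.strand))
        if not suppressed:
            truth.tss.append(
                PlantedSite(plan.to_global(plan.tss_local), plan.strand, plan.gene_id, "P"))
            truth.teps.append(
                PlantedSite(plan.to_global(plan.tep_local), plan.strand, plan.gene_id, plan.shape))
        truth.gene_levels[plan.gene_id] = plan.level
        truth.plans[plan.gene_id] = plan
        cursor += clen
        spacer = int(rng.integers(config.intergenic_range[0], config.intergenic_range[1] + 1))
        pieces.append("".join(_random_seq(rng, spacer, config.gc_content)))
        cursor += spacer
    pieces.append("".join(_random_seq(rng, 60, config.gc_content)))
    sequence = "".join(pieces)
    truth.genome_length = len(sequence)
    return (GenomeSet([GenomeRecord(seq_id, sequence, circular=True)]),
            AnnotationSet(genes), truth)


# ---------------------------------------------------------------------------
# Expression counts


@dataclass
class ExpressionSimConfig:
    n_genes: int = 2000
    n_deg: int = 100
    true_lfc: float = 2.0
    replicates: int = 3
    dispersion: float = 0.1
    base_mean_range: Tuple[float, float] = (50.0, 1000.0)
    libsize_range: Tuple[float, float] = (0.7, 1.4)
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("at least 2 replicates per group are required")
        if self.n_deg > self.n_genes:
            raise ValueError("n_deg cannot exceed n_genes")


def simulate_expression(config: ExpressionSimConfig
                        ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an ortholog count matrix with planted fold changes.

    Returns ``(counts, truth)``: counts is genes x samples (columns
    ``A_rep*``/``B_rep*``) with library sizes varying across samples;
    truth holds each gene's true log2 fold change (A over B).
    """
    rng = np.random.default_rng(config.seed)
    genes = [f"pair{i:05d}" for i in range(config.n_genes)]
    lo, hi = config.base_mean_range
    base = 10 ** rng.uniform(math.log10(lo), math.log10(hi), size=config.n_genes)
    lfc = np.zeros(config.n_genes)
    deg_idx = rng.choice(config.n_genes, size=config.n_deg, replace=False)
    signs = np.where(np.arange(config.n_deg) % 2 == 0, 1.0, -1.0)
    lfc[deg_idx] = signs * config.true_lfc

    samples = [f"A_rep{r + 1}" for r in range(config.replicates)] + \
              [f"B_rep{r + 1}" for r in range(config.replicates)]
    libsize = rng.uniform(*config.libsize_range, size=len(samples))
    mat = np.zeros((config.n_genes, len(samples)), dtype=np.int64)
    mean_a = base * np.power(2.0, lfc / 2.0)
    mean_b = base * np.power(2.0, -lfc / 2.0)
    for j, sample in enumerate(samples):
        mu = (mean_a if sample.startswith("A") else mean_b) * libsize[j]
        if config.dispersion > 0:
            n = 1.0 / config.dispersion
            mat[:, j] = rng.negative_binomial(n, n / (n + mu))
        else:
            mat[:, j] = rng.poisson(mu)
    counts = pd.DataFrame(mat, index=genes, columns=samples)
    truth = pd.DataFrame({"gene": genes, "true_lfc": lfc}).set_index("gene")
    return counts, truth


# ---------------------------------------------------------------------------
# Truth emission


def write_truth(truth: TruthSet, prefix) -> None:
    """Emit truth tables as TSV (positions 0-based, as planted)."""
    truth.tss_table().to_csv(f"{prefix}.tss_truth.tsv", sep="\t", index=False)
    truth.tep_table().to_csv(f"{prefix}.tep_truth.tsv", sep="\t", index=False)
    pd.DataFrame([asdict(m) for m in truth.motifs]).to_csv(
        f"{prefix}.motif_truth.tsv", sep="\t", index=False)
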