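"""Ortholog mapping and conservation classification of regulatory regions.

Orthologs are defined operationally: best protein-level local alignment
(BLOSUM62, gap open 11 / extend 1) with an approximate Karlin-Altschul
E-value below 1e-6 covering more than 80% of the query CDS.  Promoter
regions (50 nt upstream of a TSS) are searched within the 550 nt upstream
of the ortholog's start codon, terminator regions (40 nt upstream to 20 nt
downstream of a TEP) within the 520 nt downstream of the ortholog's stop
codon; a region is *conserved* when it matches reciprocally and the
partner strain has a TSS/TEP at the corresponding offset (+/-5 nt),
*mismatched* when it matches without a corresponding site, *orphan* when
it does not match, and *specific* when the gene has no ortholog.

5'-UTR length conservation uses the published thresholds: a length
difference below 2 nt is conserved, above 10 nt degenerated; the gap in
between is reported as intermediate.  Sequence divergence is the
p-distance (proportion of differing sites, gap columns excluded under
pairwise deletion) on a global pairwise alignment.
"""
from __future__ import annotations

import logging
import math
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .genome_io import AnnotationSet, Gene, GenomeSet, extract
from .tep_caller import TEPRecord
from .tss_caller import TSSRecord

logger = logging.getLogger(__name__)

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    identity: float
    coverage_a: float
    evalue_like: float


@dataclass
class RegionComparisonRecord:
    gene_a: str
    region_kind: str  # promoter | terminator
    klass: str  # conserved | mismatched | orphan | specific
    site_position: int
    match_offset: Optional[int] = None
    site_offset_delta: Optional[int] = None


@dataclass
class UTRConservationRecord:
    gene_a: str
    kind: str
    delta_len: int
    klass: str  # conserved | intermediate | degenerated
    p_distance: Optional[float]


# ---------------------------------------------------------------------------
# Proteomes and ortholog mapping


def extract_proteome(genome: GenomeSet, annotation: AnnotationSet) -> Dict[str, str]:
    """Translate every CDS (bacterial table) into a protein dictionary;
    the trailing stop is removed, internal stops are kept as '*'."""
    proteome: Dict[str, str] = {}
    for gene in annotation:
        if gene.feature_type != "CDS":
            continue
        cds = extract(genome, gene.seq_id, gene.start, gene.end, gene.strand)
        trimmed = cds[: len(cds) - len(cds) % 3]
        prot = str(Seq(trimmed).translate(table=11))
        proteome[gene.gene_id] = prot.rstrip("*")
    return proteome


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_stats(alignment) -> Tuple[int, int, int, int, int, int]:
    """(aligned columns, identities, q_start, q_end, s_start, s_end)."""
    cols = ident = 0
    q_start = s_start = None
    q_end = s_end = 0
    qseq, sseq = alignment.sequences
    for (qs, qe), (ss, se) in zip(*alignment.aligned):
        if q_start is None:
            q_start, s_start = qs, ss
        q_end, s_end = qe, se
        cols += qe - qs
        ident += sum(1 for a, b in zip(qseq[qs:qe], sseq[ss:se]) if a == b)
    return cols, ident, q_start or 0, q_end, s_start or 0, s_end


def _evalue(score: float, m: int, n: int) -> float:
    bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
    return m * n * 2.0 ** (-bits)


def map_orthologs(
    proteome_a: Dict[str, str],
    proteome_b: Dict[str, str],
    aligner: str = "builtin",
    evalue_max: float = 1e-6,
    min_coverage: float = 0.8,
) -> List[OrthologPair]:
    """Best-hit ortholog pairs between two proteomes.

    ``builtin`` uses Smith-Waterman with BLOSUM62 and an approximate
    E-value; ``blastp`` shells out to NCBI BLAST+ when available.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    if aligner == "blastp":
        return _map_orthologs_blastp(proteome_a, proteome_b, evalue_max, min_coverage)
    if aligner != "builtin":
        raise ValueError(f"unknown aligner {aligner!r}; use 'builtin' or 'blastp'")
    pa = _protein_aligner()
    db_size = sum(len(s) for s in proteome_b.values())
    pairs: List[OrthologPair] = []
    targets = list(proteome_b.items())
    for gene_a, seq_a in proteome_a.items():
        if not seq_a:
            continue
        best_id, best_score = None, -math.inf
        for gene_b, seq_b in targets:
            if not seq_b:
                continue
            score = pa.score(seq_a, seq_b)
            if score > best_score:
                best_id, best_score = gene_b, score
        if best_id is None:
            continue
        aln = pa.align(seq_a, proteome_b[best_id])[0]
        cols, ident, qs, qe, _, _ = _alignment_stats(aln)
        if cols == 0:
            continue
        coverage = (qe - qs) / len(seq_a)
        ev = _evalue(best_score, len(seq_a), db_size)
        if ev < evalue_max and coverage > min_coverage:
            pairs.append(OrthologPair(gene_a, best_id, ident / cols, coverage, ev))
    return pairs


def _map_orthologs_blastp(proteome_a, proteome_b, evalue_max, min_coverage):
    for exe in ("makeblastdb", "blastp"):
        if shutil.which(exe) is None:
            raise RuntimeError(f"external aligner component {exe!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        qpath, dbpath = tmp / "a.faa", tmp / "b.faa"
        for path, prot in ((qpath, proteome_a), (dbpath, proteome_b)):
            with open(path, "w") as fh:
                for gid, seq in prot.items():
                    fh.write(f">{gid}\n{seq}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(dbpath), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        out = subprocess.run(
            ["blastp", "-query", str(qpath), "-db", str(dbpath),
             "-outfmt", "6 qseqid sseqid pident length qlen evalue bitscore",
             "-evalue", str(evalue_max), "-max_target_seqs", "5"],
            check=True, capture_output=True, text=True,
        ).stdout
    best: Dict[str, OrthologPair] = {}
    best_score: Dict[str, float] = {}
    for line in out.splitlines():
        q, s, pident, length, qlen, ev, bits = line.split("\t")
        cov = int(length) / int(qlen)
        if float(ev) < evalue_max and cov > min_coverage:
            if float(bits) > best_score.get(q, -1.0):
                best_score[q] = float(bits)
                best[q] = OrthologPair(q, s, float(pident) / 100.0, cov, float(ev))
    return [best[q] for q in sorted(best)]


# ---------------------------------------------------------------------------
# Distances and alignments


def p_distance(seq_a: str, seq_b: str) -> Optional[float]:
    """Proportion of differing sites, gap columns excluded (pairwise
    deletion); None when no comparable columns remain."""
    if len(seq_a) != len(seq_b):
        raise ValueError("p_distance requires equal aligned lengths")
    comparable = diffs = 0
    for a, b in zip(seq_a, seq_b):
        if a == "-" or b == "-":
            continue
        comparable += 1
        if a != b:
            diffs += 1
    if comparable == 0:
        logger.warning("p_distance undefined: no comparable columns")
        return None
    return diffs / comparable


def _dna_aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -2.0
    return aligner


def align_global(seq_a: str, seq_b: str) -> Tuple[str, str]:
    """Needleman-Wunsch (match 1 / mismatch -1 / gap -2) aligned strings."""
    aln = _dna_aligner("global").align(seq_a, seq_b)[0]
    return str(aln[0]), str(aln[1])


@dataclass(frozen=True)
class RegionMatch:
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    identity: float
    aligned_len: int


def _shares_word(query: str, subject: str, word_size: int) -> bool:
    if word_size <= 0:
        return True
    if len(query) < word_size or len(subject) < word_size:
        return False
    words = {query[i : i + word_size] for i in range(len(query) - word_size + 1)}
    return any(subject[i : i + word_size] in words
               for i in range(len(subject) - word_size + 1))


def local_match(
    query: str, subject: str, min_len: int = 25, min_identity: float = 0.7,
    word_size: int = 11,
) -> Optional[RegionMatch]:
    """Local alignment accepted at ``min_len`` aligned columns and
    ``min_identity``; the builtin stand-in for a BLASTN search.

    Like BLASTN, a hit requires an exact shared word of ``word_size`` nt to
    seed it; chance 70%-identity alignments between unrelated sequences
    rarely contain one.
    """
    if not query or not subject:
        return None
    if not _shares_word(query, subject, word_size):
        return None
    aligner = _dna_aligner("local")
    aln = aligner.align(query, subject)
    if len(aln) == 0 or aln.score <= 0:
        return None
    cols, ident, qs, qe, ss, se = _alignment_stats(aln[0])
    if cols >= min_len and ident / cols >= min_identity:
        return RegionMatch(qs, qe, ss, se, ident / cols, cols)
    return None


# ---------------------------------------------------------------------------
# UTR conservation


def classify_utr_conservation(
    pairs: Sequence[OrthologPair],
    utrs_a: Dict[str, "UTRRecord"],
    utrs_b: Dict[str, "UTRRecord"],
    kind: str = "five_prime",
    conserved_max: int = 2,
    degenerated_min: int = 10,
) -> List[UTRConservationRecord]:
    """Length-difference classes for UTRs present in both strains.

    Differences under ``conserved_max`` nt are conserved, over
    ``degenerated_min`` nt degenerated, the remainder intermediate.
    """
    out: List[UTRConservationRecord] = []
    for pair in pairs:
        ua = utrs_a.get(pair.gene_a)
        ub = utrs_b.get(pair.gene_b)
        if ua is None or ub is None or ua.kind != kind or ub.kind != kind:
            continue
        delta = abs(ua.length - ub.length)
        if delta < conserved_max:
            klass = "conserved"
        elif delta > degenerated_min:
            klass = "degenerated"
        else:
            klass = "intermediate"
        pdist = None
        if ua.sequence and ub.sequence:
            a, b = align_global(ua.sequence, ub.sequence)
            pdist = p_distance(a, b)
        out.append(UTRConservationRecord(pair.gene_a, kind, delta, klass, pdist))
    return out


# ---------------------------------------------------------------------------
# Promoter / terminator region conservation


def _upstream_window(gene: Gene, genome: GenomeSet, length: int) -> str:
    """Coding-orientation sequence of ``length`` nt ending at the start codon."""
    if gene.strand == "+":
        return extract(genome, gene.seq_id, gene.start - length, gene.start, "+")
    return extract(genome, gene.seq_id, gene.end, gene.end + length, "-")


def _downstream_window(gene: Gene, genome: GenomeSet, length: int) -> str:
    """Coding-orientation sequence of ``length`` nt starting after the stop."""
    if gene.strand == "+":
        return extract(genome, gene.seq_id, gene.end, gene.end + length, "+")
    return extract(genome, gene.seq_id, gene.start - length, gene.start, "-")


def _promoter_region(position: int, strand: str, genome: GenomeSet,
                     seq_id: str, length: int) -> str:
    """The ``length`` nt immediately upstream of a TSS, coding orientation."""
    if strand == "+":
        return extract(genome, seq_id, position - length, position, "+")
    return extract(genome, seq_id, position + 1, position + 1 + length, "-")


def _terminator_region(position: int, strand: str, genome: GenomeSet,
                       seq_id: str, up: int = 40, down: int = 20) -> str:
    """TEP-40 .. TEP+20 in coding orientation (site at offset ``up``)."""
    if strand == "+":
        return extract(genome, seq_id, position - up, position + down + 1, "+")
    return extract(genome, seq_id, position - down, position + up + 1, "-")


def _site_utr_offset(gene: Gene, position: int) -> int:
    """Distance from a site to the gene's start codon (upstream positive)."""
    if gene.strand == "+":
        return gene.start - position
    return position - (gene.end - 1)


def _site_stop_offset(gene: Gene, position: int) -> int:
    if gene.strand == "+":
        return position - (gene.end - 1)
    return gene.start - position


def classify_promoter_regions(
    tss_a: Sequence[TSSRecord],
    tss_b: Sequence[TSSRecord],
    annotation_a: AnnotationSet,
    annotation_b: AnnotationSet,
    genome_a: GenomeSet,
    genome_b: GenomeSet,
    pairs: Sequence[OrthologPair],
    region_len: int = 50,
    search_len: int = 550,
    site_tolerance: int = 5,
    min_len: int = 25,
    min_identity: float = 0.7,
) -> List[RegionComparisonRecord]:
    """Four-class conservation of promoter regions for CDS-associated TSSs.

    Every P/S TSS of strain A is classified independently: its 50-nt
    upstream region is searched within the 550 nt upstream of the ortholog
    start codon (and reciprocally for strain B's promoter); *conserved*
    additionally requires a strain-B TSS at the matching offset.
    """
    pair_by_a = {p.gene_a: p for p in pairs}
    b_tss_by_gene: Dict[str, List[TSSRecord]] = {}
    for rec in tss_b:
        if rec.category in ("P", "S") and rec.associated_gene:
            b_tss_by_gene.setdefault(rec.associated_gene, []).append(rec)

    out: List[RegionComparisonRecord] = []
    for rec in tss_a:
        if rec.category not in ("P", "S") or not rec.associated_gene:
            continue
        gene_a = annotation_a.get(rec.associated_gene)
        pair = pair_by_a.get(gene_a.gene_id)
        if pair is None:
            out.append(RegionComparisonRecord(
                gene_a.gene_id, "promoter", "specific", rec.position))
            continue
        gene_b = annotation_b.get(pair.gene_b)
        region = _promoter_region(rec.position, rec.strand, genome_a,
                                  rec.seq_id, region_len)
        if len(region) < region_len:
            logger.debug("promoter region truncated for %s", gene_a.gene_id)
        window_b = _upstream_window(gene_b, genome_b, search_len)
        fwd = local_match(region, window_b, min_len, min_identity)

        b_sites = b_tss_by_gene.get(gene_b.gene_id, [])
        rev = None
        for b_rec in b_sites:
            region_b = _promoter_region(b_rec.position, b_rec.strand, genome_b,
                                        b_rec.seq_id, region_len)
            window_a = _upstream_window(gene_a, genome_a, search_len)
            rev = local_match(region_b, window_a, min_len, min_identity)
            if rev is not None:
                break

        site_ok = False
        delta = None
        if fwd is not None and b_sites:
            # the A TSS sits at the 3' end of its promoter region; project it
            # through the match into strain B's upstream-window coordinates
            predicted = fwd.s_end + (len(region) - fwd.q_end)
            for b_rec in b_sites:
                u_b = _site_utr_offset(gene_b, b_rec.position)
                actual = len(window_b) - u_b
                d = abs(predicted - actual)
                if delta is None or d < delta:
                    delta = d
                if d <= site_tolerance:
                    site_ok = True
        if fwd is not None and rev is not None and site_ok:
            klass = "conserved"
        elif fwd is not None or rev is not None:
            klass = "mismatched"
        else:
            klass = "orphan"
        out.append(RegionComparisonRecord(
            gene_a.gene_id, "promoter", klass, rec.position,
            match_offset=None if fwd is None else fwd.s_start,
            site_offset_delta=delta,
        ))
    return out


def classify_terminator_regions(
    tep_a: Sequence[TEPRecord],
    tep_b: Sequence[TEPRecord],
    annotation_a: AnnotationSet,
    annotation_b: AnnotationSet,
    genome_a: GenomeSet,
    genome_b: GenomeSet,
    pairs: Sequence[OrthologPair],
    region_up: int = 40,
    region_down: int = 20,
    search_len: int = 520,
    site_tolerance: int = 5,
    min_len: int = 25,
    min_identity: float = 0.7,
) -> List[RegionComparisonRecord]:
    """Four-class conservation of terminator regions (TEP-40..TEP+20 vs the
    520 nt downstream of the ortholog's stop codon)."""
    pair_by_a = {p.gene_a: p for p in pairs}
    b_tep_by_gene: Dict[str, List[TEPRecord]] = {}
    for rec in tep_b:
        if rec.category in ("P", "S") and rec.associated_gene:
            b_tep_by_gene.setdefault(rec.associated_gene, []).append(rec)

    out: List[RegionComparisonRecord] = []
    for rec in tep_a:
        if rec.category not in ("P", "S") or not rec.associated_gene:
            continue
        gene_a = annotation_a.get(rec.associated_gene)
        pair = pair_by_a.get(gene_a.gene_id)
        if pair is None:
            out.append(RegionComparisonRecord(
                gene_a.gene_id, "terminator", "specific", rec.position))
            continue
        gene_b = annotation_b.get(pair.gene_b)
        region = _terminator_region(rec.position, rec.strand, genome_a,
                                    rec.seq_id, region_up, region_down)
        window_b = _downstream_window(gene_b, genome_b, search_len)
        fwd = local_match(region, window_b, min_len, min_identity)

        b_sites = b_tep_by_gene.get(gene_b.gene_id, [])
        rev = None
        for b_rec in b_sites:
            region_b = _terminator_region(b_rec.position, b_rec.strand, genome_b,
                                          b_rec.seq_id, region_up, region_down)
            window_a = _downstream_window(gene_a, genome_a, search_len)
            rev = local_match(region_b, window_a, min_len, min_identity)
            if rev is not None:
                break

        site_ok = False
        delta = None
        if fwd is not None and b_sites:
            predicted = fwd.s_start - fwd.q_start + region_up
            for b_rec in b_sites:
                actual = _site_stop_offset(gene_b, b_rec.position) - 1
                d = abs(predicted - actual)
                if delta is None or d < delta:
                    delta = d
                if d <= site_tolerance:
                    site_ok = True
        if fwd is not None and rev is not None and site_ok:
            klass = "conserved"
        elif fwd is not None or rev is not None:
            klass = "mismatched"
        else:
            klass = "orphan"
        out.append(RegionComparisonRecord(
            gene_a.gene_id, "terminator", klass, rec.position,
            match_offset=None if fwd is None else fwd.s_start,
            site_offset_delta=delta,
        ))
    return out


# ---------------------------------------------------------------------------
# Hydropathy


def hydropathy_profile(protein: str, window: int = 9) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy, centred; termini use
    shrunken windows.  Non-standard residues contribute 0 with a warning."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(protein):
        raise ValueError("window longer than the protein")
    values = []
    for aa in protein.upper():
        if aa in _KYTE_DOOLITTLE:
            values.append(_KYTE_DOOLITTLE[aa])
        else:
            logger.warning("non-standard residue %r treated as hydropathy 0", aa)
            values.append(0.0)
    values = np.asarray(values)
    half = window // 2
    out = np.empty(len(values))
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out
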