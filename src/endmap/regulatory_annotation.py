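"""UTR annotation, RBS detection, and PWM construction/scanning.

5'-UTRs run from the primary TSS to the start codon (leaderless when
shorter than 9 nt); 3'-UTRs run from the stop codon to the primary TEP.
The Shine-Dalgarno-like RBS (AGGAG) is searched 20-1 nt upstream of start
codons of genes whose 5'-UTR is longer than 10 nt.  Position weight
matrices are built from aligned fixed windows (pseudocounted column
probabilities, log-odds in bits) and scanned with exact hit p-values
computed by dynamic programming over the discretized score distribution
under the background model.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .genome_io import AnnotationSet, Gene, GenomeSet, extract
from .tep_caller import TEPRecord
from .tss_caller import TSSRecord

logger = logging.getLogger(__name__)

_BASE_IDX = {b: i for i, b in enumerate("ACGT")}
LEADERLESS_MAX = 9  # 5'-UTRs shorter than this are leaderless


@dataclass
class UTRRecord:
    gene_id: str
    kind: str  # five_prime | three_prime
    length: int
    sequence: str
    leaderless: bool = False


@dataclass
class RBSHit:
    gene_id: str
    distance: int  # nt between motif 3' end and the start codon
    offset: int  # motif start within the search window


@dataclass
class MotifHit:
    region_id: str
    offset: int
    strand: str
    score: float  # log-odds bits
    p_value: float
    is_best: bool = False


def annotate_utrs(
    tss_records: Sequence[TSSRecord],
    tep_records: Sequence[TEPRecord],
    annotation: AnnotationSet,
    genome: GenomeSet,
) -> List[UTRRecord]:
    """Derive 5'- and 3'-UTRs from primary TSS/TEP assignments."""
    p_tss = {r.associated_gene: r for r in tss_records
             if r.category == "P" and r.associated_gene}
    p_tep = {r.associated_gene: r for r in tep_records
             if r.category == "P" and r.associated_gene}
    out: List[UTRRecord] = []
    for gene in annotation:
        tss = p_tss.get(gene.gene_id)
        if tss is not None:
            if gene.strand == "+":
                length = gene.start - tss.position
                seq = extract(genome, gene.seq_id, tss.position, gene.start, "+")
            else:
                length = tss.position - (gene.end - 1)
                seq = extract(genome, gene.seq_id, gene.end, tss.position + 1, "-")
            if length < 0:
                logger.debug("gene %s: P-TSS downstream of start codon; 5'-UTR omitted",
                             gene.gene_id)
            else:
                out.append(UTRRecord(gene.gene_id, "five_prime", length, seq,
                                     leaderless=length < LEADERLESS_MAX))
        tep = p_tep.get(gene.gene_id)
        if tep is not None:
            if gene.strand == "+":
                length = tep.position - (gene.end - 1)
                seq = extract(genome, gene.seq_id, gene.end, tep.position + 1, "+")
            else:
                length = gene.start - tep.position
                seq = extract(genome, gene.seq_id, tep.position, gene.start, "-")
            if length > 0:
                out.append(UTRRecord(gene.gene_id, "three_prime", length, seq))
    return out


def find_rbs(
    utrs: Sequence[UTRRecord],
    annotation: AnnotationSet,
    genome: GenomeSet,
    motif: str = "AGGAG",
    window: int = 20,
    min_utr: int = 10,
) -> Tuple[List[RBSHit], int]:
    """Exact-substring RBS scan in the ``window`` nt upstream of start codons.

    Only genes with a 5'-UTR strictly longer than ``min_utr`` are searched.
    Returns the hits (closest occurrence to the start codon per gene) and
    the number of genes searched (the denominator for detection rates).
    """
    searched = 0
    hits: List[RBSHit] = []
    for utr in utrs:
        if utr.kind != "five_prime" or utr.length <= min_utr:
            continue
        gene = annotation.get(utr.gene_id)
        if gene.strand == "+":
            w = extract(genome, gene.seq_id, gene.start - window, gene.start, "+")
        else:
            w = extract(genome, gene.seq_id, gene.end, gene.end + window, "-")
        searched += 1
        best: Optional[RBSHit] = None
        i = w.find(motif)
        while i != -1:
            distance = len(w) - (i + len(motif))
            if best is None or distance < best.distance:
                best = RBSHit(utr.gene_id, distance, i)
            i = w.find(motif, i + 1)
        if best is not None:
            hits.append(best)
    return hits, searched


# ---------------------------------------------------------------------------
# PWMs


@dataclass
class PWM:
    """Position weight matrix with exact DP hit p-values.

    Column probabilities are ``(count + pseudocount) / (n + 4 pc)``;
    scores are log-odds against the background in bits, discretized at
    ``resolution`` bits (the discretized scores are the scoring model, so
    DP p-values are exact for it).
    """

    probs: np.ndarray  # (4, width)
    background: np.ndarray  # (4,)
    resolution: float = 0.01
    min_logodds: float = -20.0  # floor for -inf columns (pseudocount 0)

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.width < 3:
            raise ValueError("PWM must be 4 x width with width >= 3")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @cached_property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            lo = np.log2(self.probs / self.background[:, None])
        return np.maximum(lo, self.min_logodds)

    @cached_property
    def int_scores(self) -> np.ndarray:
        return np.rint(self.log_odds / self.resolution).astype(np.int64)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.probs.argmax(axis=0))

    @cached_property
    def _score_distribution(self) -> Tuple[np.ndarray, np.ndarray]:
        """(sorted unique total int scores, survival probability P(S >= s))."""
        dist: Dict[int, float] = {0: 1.0}
        for j in range(self.width):
            new: Dict[int, float] = {}
            for s, p in dist.items():
                for b in range(4):
                    t = s + int(self.int_scores[b, j])
                    new[t] = new.get(t, 0.0) + p * self.background[b]
            dist = new
        scores = np.array(sorted(dist))
        probs = np.array([dist[int(s)] for s in scores])
        sf = probs[::-1].cumsum()[::-1]
        return scores, sf

    def score_window(self, window: str) -> Optional[int]:
        """Integer score of one width-length window; None if it contains
        a non-ACGT base."""
        total = 0
        for j, b in enumerate(window):
            i = _BASE_IDX.get(b)
            if i is None:
                return None
            total += int(self.int_scores[i, j])
        return total

    def p_value(self, int_score: int) -> float:
        scores, sf = self._score_distribution
        i = np.searchsorted(scores, int_score, side="left")
        if i >= len(scores):
            return float(sf[-1]) if int_score <= scores[-1] else 0.0
        return float(sf[i])


def build_pwm(
    sequences: Sequence[str],
    pseudocount: float = 0.5,
    background: Optional[Sequence[float]] = None,
    resolution: float = 0.01,
) -> PWM:
    """Build a PWM from equal-length aligned windows."""
    if len(sequences) < 2:
        raise ValueError("at least 2 sequences are required to build a PWM")
    width = len(sequences[0])
    if any(len(s) != width for s in sequences):
        raise ValueError("all PWM input sequences must have equal length")
    counts = np.zeros((4, width))
    for seq in sequences:
        for j, b in enumerate(seq.upper()):
            i = _BASE_IDX.get(b)
            if i is not None:
                counts[i, j] += 1
    n = len(sequences)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    # renormalize columns in case of non-ACGT characters
    probs = probs / probs.sum(axis=0, keepdims=True)
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    bg = bg / bg.sum()
    return PWM(probs=probs, background=bg, resolution=resolution)


def scan_pwm(
    pwm: PWM,
    regions: Sequence[Tuple[str, str]],
    p_max: float = 1e-4,
) -> List[MotifHit]:
    """Slide the PWM over each (region_id, sequence); report hits with
    p <= ``p_max`` and flag the best hit per region."""
    hits: List[MotifHit] = []
    for region_id, seq in regions:
        seq = seq.upper()
        if len(seq) < pwm.width:
            logger.debug("region %s shorter than PWM width; skipped", region_id)
            continue
        region_hits: List[MotifHit] = []
        for off in range(len(seq) - pwm.width + 1):
            s = pwm.score_window(seq[off : off + pwm.width])
            if s is None:
                continue
            p = pwm.p_value(s)
            if p <= p_max:
                region_hits.append(
                    MotifHit(region_id, off, "+", s * pwm.resolution, p)
                )
        if region_hits:
            best = min(region_hits, key=lambda h: (h.p_value, h.offset))
            best.is_best = True
        hits.extend(region_hits)
    return hits


def write_meme(pwm: PWM, path, name: str = "motif") -> None:
    """Serialize a PWM in MEME minimal motif format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A {:.4f} C {:.4f} G {:.4f} T {:.4f}\n\n".format(*pwm.background))
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {pwm.width}\n")
        for j in range(pwm.width):
            fh.write(" ".join(f"{pwm.probs[i, j]:.6f}" for i in range(4)) + "\n")


def tss_upstream_windows(
    tss_records: Sequence[TSSRecord],
    genome: GenomeSet,
    start_offset: int,
    end_offset: int,
    categories: Sequence[str] = ("P",),
) -> List[Tuple[str, str]]:
    """Fixed windows at ``[start_offset, end_offset)`` relative to each TSS
    (negative = upstream, transcript-oriented), e.g. (-20, 0) for the -10
    box search and (-40, -20) for the -35 box search."""
    width = end_offset - start_offset
    out: List[Tuple[str, str]] = []
    for i, rec in enumerate(tss_records):
        if rec.category not in categories:
            continue
        if rec.strand == "+":
            seq = extract(genome, rec.seq_id,
                          rec.position + start_offset, rec.position + end_offset, "+")
        else:
            seq = extract(genome, rec.seq_id,
                          rec.position - end_offset + 1, rec.position - start_offset + 1, "-")
        if len(seq) == width:
            out.append((f"{rec.seq_id}:{rec.position}{rec.strand}", seq))
    return out
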