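"""Transcription start site calling from dRNA-seq end-count tracks.

The pipeline per replicate: cluster TAP+ 5'-end positions (gap < 100 nt),
sub-cluster at positional SD < 10 keeping the deepest peak, then keep
peaks absent from TAP- or enriched more than 2-fold over TAP- at the same
position.  Across replicates a peak is kept when matched in every
replicate within +/-2 nt (restoring 1-2 nt jitter between duplicates); a
peak seen in fewer replicates survives only with clear RNA-seq support
immediately downstream.  Surviving TSSs are categorized relative to the
annotation: the deepest TSS within 500 nt upstream to 100 nt downstream of
a start codon is primary (P), others in that window secondary (S);
remaining TSSs inside a gene are internal (I), antisense to a gene (A),
else intergenic (N).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._peaks import Peak, cluster_positions, group_across_replicates, merge_group
from .genome_io import AnnotationSet, EndCountTrack, Gene, GenomeSet

logger = logging.getLogger(__name__)

PeakCandidate = Peak  # a TSS candidate is a generic peak

CATEGORIES = ("P", "S", "I", "A", "N")


@dataclass
class TSSRecord:
    seq_id: str
    position: int
    strand: str
    depth: float
    category: str
    associated_gene: Optional[str]
    tap_ratio: Optional[float]
    replicate_support: int
    utr5_length: Optional[int]


@dataclass
class TSSParams:
    max_gap: int = 100
    sd_threshold: float = 10.0
    min_fold: float = 2.0
    tolerance: int = 2
    rna_support_threshold: Optional[float] = None  # None -> data-derived
    upstream: int = 500
    downstream: int = 100
    min_internal_frac: float = 0.01


def cluster_candidates(
    track: EndCountTrack, max_gap: int = 100, sd_threshold: float = 10.0
) -> List[PeakCandidate]:
    """Cluster/sub-cluster a normalized TAP+ track into candidate peaks."""
    if not track.normalized:
        raise ValueError("cluster_candidates requires a normalized track")
    peaks: List[PeakCandidate] = []
    for strand in "+-":
        depths = track.counts(strand)
        reps = cluster_positions(track.positions(strand), depths, max_gap, sd_threshold)
        peaks.extend(
            Peak(track.seq_id, p, strand, depths[p], track.replicate_id) for p in reps
        )
    return peaks


def filter_by_tap(
    peaks: Sequence[PeakCandidate],
    tap_minus: EndCountTrack,
    min_fold: float = 2.0,
) -> List[PeakCandidate]:
    """Keep peaks absent in TAP- or with depth ratio above ``min_fold``
    at the exact same position."""
    if not tap_minus.normalized:
        raise ValueError("filter_by_tap requires a normalized TAP- track")
    kept: List[PeakCandidate] = []
    for pk in peaks:
        dm = tap_minus.depth(pk.position, pk.strand)
        if dm == 0:
            pk.tap_ratio = math.inf
            kept.append(pk)
        elif pk.depth / dm > min_fold:
            pk.tap_ratio = pk.depth / dm
            kept.append(pk)
    return kept


def _downstream_rna_mean(
    position: int, strand: str, rna_tracks: Sequence[EndCountTrack], span: int = 50
) -> float:
    vals = []
    for track in rna_tracks:
        if strand == "+":
            vals.append(track.window_mean(position, position + span, strand))
        else:
            vals.append(track.window_mean(position - span + 1, position + 1, strand))
    return float(np.mean(vals)) if vals else 0.0


def default_rna_threshold(rna_tracks: Sequence[EndCountTrack]) -> float:
    """Half the median nonzero per-position RNA coverage: the bar a lone
    peak's downstream profile must clear to count as 'clear'."""
    vals: List[float] = []
    for track in rna_tracks:
        vals.extend(track.counts_fwd.values())
        vals.extend(track.counts_rev.values())
    if not vals:
        return math.inf
    return 0.5 * float(np.median(vals))


def consensus_and_curate(
    per_replicate_peaks: Sequence[Sequence[PeakCandidate]],
    rna_tracks: Sequence[EndCountTrack],
    tolerance: int = 2,
    rna_support_threshold: Optional[float] = None,
) -> List[PeakCandidate]:
    """Replicate consensus with RNA-profile rescue of lone peaks."""
    n = len(per_replicate_peaks)
    if n < 2:
        raise ValueError("at least 2 replicate peak sets are required")
    rna_tracks = list(rna_tracks)
    if rna_support_threshold is None:
        rna_support_threshold = default_rna_threshold(rna_tracks)
    kept: List[PeakCandidate] = []
    for group in group_across_replicates(per_replicate_peaks, tolerance):
        merged = merge_group(group)
        if merged.replicate_support == n:
            kept.append(merged)
        elif (
            _downstream_rna_mean(merged.position, merged.strand, rna_tracks)
            >= rna_support_threshold
        ):
            kept.append(merged)
    return kept


def _start_offset(gene: Gene, position: int) -> int:
    """Signed offset of a position from the start codon (negative = upstream)."""
    if gene.strand == "+":
        return position - gene.start
    return (gene.end - 1) - position


def categorize_tss(
    peaks: Sequence[PeakCandidate],
    annotation: AnnotationSet,
    genome: GenomeSet,
    upstream: int = 500,
    downstream: int = 100,
    min_internal_frac: float = 0.01,
) -> List[TSSRecord]:
    """Assign P/S/I/A/N categories relative to annotated genes.

    A peak eligible for several genes' windows goes to the gene with the
    nearest start codon.  Internal peaks weaker than ``min_internal_frac``
    of their gene's primary-TSS depth are dropped (stand-in for the manual
    pruning of processed-transcript peaks in very highly expressed genes).
    """
    gene_hits: Dict[str, List[Tuple[PeakCandidate, int]]] = {}
    assigned: Dict[int, Tuple[Gene, int]] = {}
    peaks = list(peaks)
    for i, pk in enumerate(peaks):
        best: Optional[Tuple[Gene, int]] = None
        for gene in annotation.on_sequence(pk.seq_id):
            if gene.strand != pk.strand:
                continue
            off = _start_offset(gene, pk.position)
            if -upstream <= off < downstream:
                if best is None or abs(off) < abs(best[1]):
                    best = (gene, off)
        if best is not None:
            assigned[i] = best
            gene_hits.setdefault(best[0].gene_id, []).append((pk, best[1]))

    records: List[TSSRecord] = []
    primary_depth: Dict[str, float] = {}
    for gene_id, hits in gene_hits.items():
        hits.sort(key=lambda t: (-t[0].depth, t[0].position))
        for rank, (pk, off) in enumerate(hits):
            category = "P" if rank == 0 else "S"
            if rank == 0:
                primary_depth[gene_id] = pk.depth
            records.append(
                TSSRecord(
                    seq_id=pk.seq_id,
                    position=pk.position,
                    strand=pk.strand,
                    depth=pk.depth,
                    category=category,
                    associated_gene=gene_id,
                    tap_ratio=pk.tap_ratio,
                    replicate_support=pk.replicate_support,
                    utr5_length=-off if off <= 0 else None,
                )
            )

    for i, pk in enumerate(peaks):
        if i in assigned:
            continue
        sense_gene = None
        anti_gene = None
        for gene in annotation.on_sequence(pk.seq_id):
            if gene.start <= pk.position < gene.end:
                if gene.strand == pk.strand and sense_gene is None:
                    sense_gene = gene
                elif gene.strand != pk.strand and anti_gene is None:
                    anti_gene = gene
        if sense_gene is not None:
            pdepth = primary_depth.get(sense_gene.gene_id)
            if pdepth is not None and pk.depth < min_internal_frac * pdepth:
                logger.debug(
                    "dropping weak internal peak at %d (%.3g < %.3g)",
                    pk.position, pk.depth, min_internal_frac * pdepth,
                )
                continue
            category, gene_id = "I", sense_gene.gene_id
        elif anti_gene is not None:
            category, gene_id = "A", anti_gene.gene_id
        else:
            category, gene_id = "N", None
        records.append(
            TSSRecord(
                seq_id=pk.seq_id, position=pk.position, strand=pk.strand,
                depth=pk.depth, category=category, associated_gene=gene_id,
                tap_ratio=pk.tap_ratio, replicate_support=pk.replicate_support,
                utr5_length=None,
            )
        )
    records.sort(key=lambda r: (r.seq_id, r.position, r.strand))
    return records


_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def tss_sequence_stats(
    tss_records: Sequence[TSSRecord], genome: GenomeSet
) -> Dict[str, object]:
    """Base frequencies at the -1/+1 positions on the TSS strand, plus the
    purine(+1) and pyrimidine(-1) fractions."""
    if not tss_records:
        raise ValueError("no TSS records given")
    counts = {off: {b: 0 for b in "ACGT"} for off in (-1, 1)}
    n_used = n_skipped = 0
    for rec in tss_records:
        seq = genome.sequence(rec.seq_id)
        if rec.strand == "+":
            p1, m1 = rec.position, rec.position - 1
        else:
            p1, m1 = rec.position, rec.position + 1
        if m1 < 0 or m1 >= len(seq) or p1 < 0 or p1 >= len(seq):
            n_skipped += 1
            continue
        b_p1, b_m1 = seq[p1], seq[m1]
        if rec.strand == "-":
            b_p1 = b_p1.translate(_COMPLEMENT)
            b_m1 = b_m1.translate(_COMPLEMENT)
        if b_p1 not in "ACGT" or b_m1 not in "ACGT":
            n_skipped += 1
            continue
        counts[1][b_p1] += 1
        counts[-1][b_m1] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable TSS sites (all skipped)")
    freq = pd.DataFrame(
        {off: {b: counts[off][b] / n_used for b in "ACGT"} for off in (-1, 1)}
    ).T
    return {
        "frequencies": freq,
        "purine_plus1": freq.loc[1, ["A", "G"]].sum(),
        "pyrimidine_minus1": freq.loc[-1, ["C", "T"]].sum(),
        "n_sites": n_used,
        "n_skipped": n_skipped,
    }


def call_tss(
    tap_plus_tracks: Sequence[EndCountTrack],
    tap_minus_tracks: Sequence[EndCountTrack],
    rna_tracks: Sequence[EndCountTrack],
    annotation: AnnotationSet,
    genome: GenomeSet,
    params: TSSParams = TSSParams(),
) -> List[TSSRecord]:
    """End-to-end TSS calling from raw or normalized tracks."""
    from .genome_io import ensure_normalized

    if len(tap_plus_tracks) != len(tap_minus_tracks):
        raise ValueError("TAP+ and TAP- tracks must be paired per replicate")
    rna_norm = [ensure_normalized(t) for t in rna_tracks]
    per_rep: List[List[PeakCandidate]] = []
    for plus, minus in zip(tap_plus_tracks, tap_minus_tracks):
        plus_n, minus_n = ensure_normalized(plus), ensure_normalized(minus)
        peaks = cluster_candidates(plus_n, params.max_gap, params.sd_threshold)
        per_rep.append(filter_by_tap(peaks, minus_n, params.min_fold))
    merged = consensus_and_curate(
        per_rep, rna_norm, params.tolerance, params.rna_support_threshold
    )
    return categorize_tss(
        merged, annotation, genome, params.upstream, params.downstream,
        params.min_internal_frac,
    )


# ---------------------------------------------------------------------------
# Tables (positions are 1-based in files)


def write_tss_table(records: Sequence[TSSRecord], path, headers: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in headers:
            fh.write(f"# {h}\n")
        fh.write("# seq_id\tposition\tstrand\tcategory\tgene\tdepth\ttap_ratio"
                 "\treplicate_support\tutr5_length\n")
        for r in records:
            ratio = "" if r.tap_ratio is None else (
                "inf" if math.isinf(r.tap_ratio) else f"{r.tap_ratio:.4g}")
            utr = "" if r.utr5_length is None else str(r.utr5_length)
            fh.write(
                f"{r.seq_id}\t{r.position + 1}\t{r.strand}\t{r.category}\t"
                f"{r.associated_gene or ''}\t{r.depth:.6g}\t{ratio}\t"
                f"{r.replicate_support}\t{utr}\n"
            )


def read_tss_table(path) -> List[TSSRecord]:
    records: List[TSSRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                TSSRecord(
                    seq_id=f[0], position=int(f[1]) - 1, strand=f[2],
                    category=f[3], associated_gene=f[4] or None,
                    depth=float(f[5]),
                    tap_ratio=(None if f[6] == "" else float(f[6])),
                    replicate_support=int(f[7]),
                    utr5_length=(None if f[8] == "" else int(f[8])),
                )
            )
    return records
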