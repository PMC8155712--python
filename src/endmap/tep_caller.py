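"""Transcript 3'-end position (TEP) calling from Term-seq tracks.

Term-seq read 5' ends (strand-reversed at ingestion) mark transcript 3'
termini.  Candidates come from the same clustering used for TSSs; a
Z-score of each representative's depth against the nonzero depths within
+/-50 nt seeds a positive training set (Z > 6 with a falling RNA profile),
negatives are the Term-seq signal positions within +/-10 nt of each
positive, and a K-nearest-neighbour classifier over the 21 depths at
offsets -10..+10 accepts or rejects every candidate.  Calls present in at
least two of three replicates (+/-1 nt) survive; they are categorized
relative to genes (P/S/U/I/A/N), shape-classified by the uridine content
near the TEP (L-shaped >= 4 U, else I-shaped), and scored for upstream
hairpin stability.
"""
from __future__ import annotations

import logging
import math
import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._peaks import Peak, cluster_positions, group_across_replicates, merge_group
from .genome_io import AnnotationSet, EndCountTrack, Gene, GenomeSet, extract
from .tss_caller import TSSRecord, _downstream_rna_mean

logger = logging.getLogger(__name__)

CATEGORIES = ("P", "S", "U", "I", "A", "N")
FEATURE_OFFSETS = np.arange(-10, 11)


@dataclass
class TEPCandidate:
    seq_id: str
    position: int
    strand: str
    depth: float
    z_score: float
    feature_vector: np.ndarray
    replicate_id: str = ""
    replicate_support: int = 1

    def key(self) -> Tuple[str, int, str]:
        return (self.seq_id, self.position, self.strand)


@dataclass
class TEPRecord:
    seq_id: str
    position: int
    strand: str
    depth: float
    category: str
    shape: str
    associated_gene: Optional[str]
    replicate_support: int
    delta_g: float = 0.0
    u_count: int = 0
    max_u_run: int = 0


@dataclass
class TEPParams:
    max_gap: int = 100
    sd_threshold: float = 10.0
    z_window: int = 50
    z_min: float = 6.0
    drop_ratio: float = 0.5
    k: int = 5
    feature_scaling: bool = True
    tolerance: int = 1
    min_support: int = 2
    downstream: int = 500
    u_min: int = 4
    shape_window: Tuple[int, int] = (-10, 2)
    engine: str = "builtin"
    upstream_len: int = 40


def feature_vector(track: EndCountTrack, position: int, strand: str) -> np.ndarray:
    """Depths at transcript-oriented offsets -10..+10 around a position."""
    counts = track.counts(strand)
    sign = 1 if strand == "+" else -1
    return np.array(
        [counts.get(position + sign * int(o), 0.0) for o in FEATURE_OFFSETS]
    )


def candidate_teps(
    track: EndCountTrack,
    max_gap: int = 100,
    sd_threshold: float = 10.0,
    z_window: int = 50,
) -> List[TEPCandidate]:
    """Cluster a normalized TERM track and score candidates by local Z.

    The Z-score compares a representative's depth with the mean/SD (ddof=1)
    of the other nonzero depths within ``z_window`` nt on the same strand;
    degenerate neighbourhoods fall back to the whole-track nonzero depth
    distribution.
    """
    if not track.normalized:
        raise ValueError("candidate_teps requires a normalized track")
    out: List[TEPCandidate] = []
    for strand in "+-":
        depths = track.counts(strand)
        positions = track.positions(strand)
        reps = cluster_positions(positions, depths, max_gap, sd_threshold)
        all_depths = np.array([depths[p] for p in positions])
        pos_arr = np.array(positions)
        for rep in reps:
            in_win = (np.abs(pos_arr - rep) <= z_window) & (pos_arr != rep)
            neigh = all_depths[in_win]
            z = _z_score(depths[rep], neigh)
            if z is None:
                fallback = all_depths[pos_arr != rep]
                z = _z_score(depths[rep], fallback)
                if z is None:
                    z = 0.0
                logger.debug(
                    "TEP candidate %s:%d%s: degenerate +/-%d nt neighbourhood, "
                    "Z computed against whole track", track.seq_id, rep, strand, z_window,
                )
            out.append(
                TEPCandidate(
                    seq_id=track.seq_id, position=rep, strand=strand,
                    depth=depths[rep], z_score=z,
                    feature_vector=feature_vector(track, rep, strand),
                    replicate_id=track.replicate_id,
                )
            )
    return out


def _z_score(depth: float, neighbourhood: np.ndarray) -> Optional[float]:
    if len(neighbourhood) < 2:
        return None
    sd = float(np.std(neighbourhood, ddof=1))
    if sd == 0:
        return None
    return (depth - float(np.mean(neighbourhood))) / sd


def _rna_drop_ratio(
    position: int, strand: str, rna_tracks: Sequence[EndCountTrack], span: int = 50
) -> float:
    """Downstream/upstream 50-nt RNA coverage ratio, transcript-oriented."""
    if strand == "+":
        up = lambda t: t.window_mean(position - span, position, strand)
        down = lambda t: t.window_mean(position + 1, position + 1 + span, strand)
    else:
        up = lambda t: t.window_mean(position + 1, position + 1 + span, strand)
        down = lambda t: t.window_mean(position - span, position, strand)
    um = float(np.mean([up(t) for t in rna_tracks]))
    dm = float(np.mean([down(t) for t in rna_tracks]))
    if um == 0:
        return 0.0 if dm == 0 else math.inf
    return dm / um


def build_training_sets(
    candidates: Sequence[TEPCandidate],
    rna_tracks: Sequence[EndCountTrack],
    track: EndCountTrack,
    z_min: float = 6.0,
    drop_ratio: float = 0.5,
) -> Tuple[List[TEPCandidate], List[TEPCandidate]]:
    """Z-score-seeded positive set and +/-10 nt neighbour negative set.

    Positives are candidates with Z above ``z_min`` whose RNA coverage
    falls past the peak (downstream/upstream ratio at most ``drop_ratio``).
    Negatives are every other Term-seq signal position within +/-10 nt of a
    positive, with feature vectors of their own.
    """
    positives = [
        c for c in candidates
        if c.z_score > z_min
        and _rna_drop_ratio(c.position, c.strand, rna_tracks) <= drop_ratio
    ]
    if not positives:
        raise ValueError(
            "no positive training examples: lower z_min or inspect the Term-seq data"
        )
    pos_keys = {c.key() for c in positives}
    negatives: List[TEPCandidate] = []
    seen = set()
    for c in positives:
        counts = track.counts(c.strand)
        for off in range(-10, 11):
            p = c.position + off
            key = (c.seq_id, p, c.strand)
            if off == 0 or key in pos_keys or key in seen:
                continue
            if counts.get(p, 0.0) > 0:
                seen.add(key)
                negatives.append(
                    TEPCandidate(
                        seq_id=c.seq_id, position=p, strand=c.strand,
                        depth=counts[p], z_score=0.0,
                        feature_vector=feature_vector(track, p, c.strand),
                        replicate_id=track.replicate_id,
                    )
                )
    return positives, negatives


def _scale(vectors: np.ndarray) -> np.ndarray:
    mx = vectors.max(axis=1, keepdims=True)
    mx[mx == 0] = 1.0
    return vectors / mx


def knn_call(
    candidates: Sequence[TEPCandidate],
    positives: Sequence[TEPCandidate],
    negatives: Sequence[TEPCandidate],
    k: int = 5,
    feature_scaling: bool = True,
) -> List[TEPCandidate]:
    """Accept candidates voted positive by their k nearest training vectors.

    Each 21-vector is divided by its own maximum before the Euclidean
    distance (shape, not depth, should drive the vote); ties go to the
    negative class; training positives are always accepted.
    """
    if not positives or not negatives:
        raise ValueError("training sets must both be non-empty")
    X = np.vstack([c.feature_vector for c in positives]
                  + [c.feature_vector for c in negatives]).astype(float)
    y = np.array([1] * len(positives) + [0] * len(negatives))
    if feature_scaling:
        X = _scale(X)
    k_eff = min(k, len(X))
    if k_eff < k:
        logger.warning("k=%d exceeds training size %d; using k=%d", k, len(X), k_eff)
    nn = NearestNeighbors(n_neighbors=k_eff).fit(X)
    pos_keys = {c.key() for c in positives}
    accepted: List[TEPCandidate] = []
    for c in candidates:
        if c.key() in pos_keys:
            accepted.append(c)
            continue
        v = c.feature_vector.astype(float)[None, :]
        if feature_scaling:
            v = _scale(v)
        _, idx = nn.kneighbors(v)
        votes = int(y[idx[0]].sum())
        if 2 * votes > k_eff:  # strict majority; ties break negative
            accepted.append(c)
    return accepted


def consensus_teps(
    per_replicate_accepted: Sequence[Sequence[TEPCandidate]],
    tolerance: int = 1,
    min_support: int = 2,
) -> List[TEPCandidate]:
    """Keep TEPs matched within +/-``tolerance`` nt in >= ``min_support``
    of at least three replicates."""
    if len(per_replicate_accepted) < 3:
        raise ValueError("triplicate consensus requires >= 3 replicate sets")
    peak_sets = [
        [Peak(c.seq_id, c.position, c.strand, c.depth, c.replicate_id)
         for c in reps]
        for reps in per_replicate_accepted
    ]
    by_key = {
        c.key(): c for reps in per_replicate_accepted for c in reps
    }
    merged: List[TEPCandidate] = []
    for group in group_across_replicates(peak_sets, tolerance):
        pk = merge_group(group)
        if pk.replicate_support >= min_support:
            src = by_key[(pk.seq_id, pk.position, pk.strand)]
            merged.append(
                TEPCandidate(
                    seq_id=pk.seq_id, position=pk.position, strand=pk.strand,
                    depth=pk.depth, z_score=src.z_score,
                    feature_vector=src.feature_vector,
                    replicate_id=pk.replicate_id,
                    replicate_support=pk.replicate_support,
                )
            )
    return merged


def _stop_distance(gene: Gene, position: int) -> int:
    """Distance downstream of the stop codon (1 = first nt past the gene)."""
    if gene.strand == "+":
        return position - (gene.end - 1)
    return gene.start - position


def categorize_tep(
    teps: Sequence[TEPCandidate],
    annotation: AnnotationSet,
    tss_map: Dict[str, int],
    downstream: int = 500,
) -> List[TEPRecord]:
    """Assign P/S/U/I/A/N categories (precedence P/S > U > I > A > N).

    ``tss_map`` maps gene_id to its primary TSS position; a TEP between a
    gene's TSS and its start codon is a 5'-UTR (U) TEP.
    """
    teps = list(teps)
    gene_hits: Dict[str, List[Tuple[TEPCandidate, int]]] = {}
    assigned: Dict[int, str] = {}
    for i, c in enumerate(teps):
        best: Optional[Tuple[Gene, int]] = None
        for gene in annotation.on_sequence(c.seq_id):
            if gene.strand != c.strand:
                continue
            d = _stop_distance(gene, c.position)
            if 1 <= d <= downstream:
                if best is None or d < best[1]:
                    best = (gene, d)
        if best is not None:
            assigned[i] = best[0].gene_id
            gene_hits.setdefault(best[0].gene_id, []).append((c, best[1]))

    records: List[TEPRecord] = []
    for gene_id, hits in gene_hits.items():
        hits.sort(key=lambda t: (-t[0].depth, t[0].position))
        for rank, (c, _d) in enumerate(hits):
            records.append(_mk_record(c, "P" if rank == 0 else "S", gene_id))

    for i, c in enumerate(teps):
        if i in assigned:
            continue
        category, gene_id = "N", None
        utr_gene = inner_gene = anti_gene = None
        for gene in annotation.on_sequence(c.seq_id):
            if gene.strand == c.strand and gene.gene_id in tss_map:
                tss = tss_map[gene.gene_id]
                start = gene.start_codon_pos
                lo, hi = sorted((tss, start))
                if lo < c.position < hi:
                    if utr_gene is None or abs(c.position - start) < abs(
                        c.position - utr_gene.start_codon_pos
                    ):
                        utr_gene = gene
            if gene.start <= c.position < gene.end:
                if gene.strand == c.strand and inner_gene is None:
                    inner_gene = gene
                elif gene.strand != c.strand and anti_gene is None:
                    anti_gene = gene
        if utr_gene is not None:
            category, gene_id = "U", utr_gene.gene_id
        elif inner_gene is not None:
            category, gene_id = "I", inner_gene.gene_id
        elif anti_gene is not None:
            category, gene_id = "A", anti_gene.gene_id
        records.append(_mk_record(c, category, gene_id))
    records.sort(key=lambda r: (r.seq_id, r.position, r.strand))
    return records


def _mk_record(c: TEPCandidate, category: str, gene_id: Optional[str]) -> TEPRecord:
    return TEPRecord(
        seq_id=c.seq_id, position=c.position, strand=c.strand, depth=c.depth,
        category=category, shape="", associated_gene=gene_id,
        replicate_support=c.replicate_support,
    )


def classify_shape(
    position: int,
    strand: str,
    genome: GenomeSet,
    seq_id: str,
    u_min: int = 4,
    window: Tuple[int, int] = (-10, 2),
) -> Tuple[str, int, int]:
    """(shape, U count, longest U run) in the transcript-oriented window.

    U on the transcript is T on the coding strand; the window is offsets
    ``window[0]..window[1]`` inclusive around the TEP.  L-shaped needs at
    least ``u_min`` uridines, otherwise I-shaped.
    """
    lo, hi = window
    if strand == "+":
        seq = extract(genome, seq_id, position + lo, position + hi + 1, "+")
    else:
        seq = extract(genome, seq_id, position - hi, position - lo + 1, "-")
    if len(seq) < hi - lo + 1:
        logger.debug("shape window truncated at sequence bounds for %s:%d", seq_id, position)
    u_count = seq.count("T")
    max_run = run = 0
    for b in seq:
        run = run + 1 if b == "T" else 0
        max_run = max(max_run, run)
    return ("L" if u_count >= u_min else "I", u_count, max_run)


def nucleotide_enrichment(
    teps: Sequence[TEPRecord],
    genome: GenomeSet,
    annotation: AnnotationSet,
    flank: int = 50,
    n_random: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-offset base frequency around TEPs over the frequency around
    random intergenic positions (rows A/C/G/T, columns -flank..+flank)."""
    rng = np.random.default_rng(seed)
    intergenic: List[Tuple[str, int]] = []
    for rec in genome:
        covered = np.zeros(len(rec.sequence), dtype=bool)
        for gene in annotation.on_sequence(rec.id):
            covered[gene.start:gene.end] = True
        free = np.flatnonzero(~covered)
        free = free[(free >= flank) & (free < len(rec.sequence) - flank)]
        intergenic.extend((rec.id, int(p)) for p in free)
    if not intergenic:
        raise ValueError("no intergenic positions available for the null sample")
    idx = rng.integers(0, len(intergenic), size=n_random)
    strands = rng.choice(["+", "-"], size=n_random)

    def _freqs(sites: Iterable[Tuple[str, int, str]]) -> Tuple[np.ndarray, int]:
        mat = np.zeros((4, 2 * flank + 1))
        base_idx = {b: i for i, b in enumerate("ACGT")}
        n = 0
        for seq_id, pos, strand in sites:
            if strand == "+":
                win = extract(genome, seq_id, pos - flank, pos + flank + 1, "+")
            else:
                win = extract(genome, seq_id, pos - flank, pos + flank + 1, "-")
            if len(win) != 2 * flank + 1:
                continue
            n += 1
            for j, b in enumerate(win):
                if b in base_idx:
                    mat[base_idx[b], j] += 1
        return mat / max(n, 1), n

    tep_freq, n_tep = _freqs((t.seq_id, t.position, t.strand) for t in teps)
    null_freq, _ = _freqs(
        (intergenic[i][0], intergenic[i][1], s) for i, s in zip(idx, strands)
    )
    if n_tep == 0:
        raise ValueError("no TEP site had a full window")
    ratio = tep_freq / np.where(null_freq == 0, np.nan, null_freq)
    return pd.DataFrame(ratio, index=list("ACGT"), columns=range(-flank, flank + 1))


# ---------------------------------------------------------------------------
# Folding energy

_PAIR_SCORE = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "T"): 2, ("T", "A"): 2,
    ("G", "T"): 1, ("T", "G"): 1,
}
_LOOP_PENALTY = 4
_MIN_STEM = 4


def hairpin_delta_g(seq: str) -> float:
    """Simplified hairpin stability score (kcal/mol-like, <= 0 or 0).

    Exhaustive search over stems >= 4 bp with loops of 3-8 nt;
    dG = -3(GC) - 2(AU) - 1(GU) + 4, or 0 when no stem exists.
    """
    n = len(seq)
    best = 0.0
    for a in range(n):
        for b in range(a + 2 * _MIN_STEM + 2, n):
            span = b - a + 1
            max_stem = (span - 3) // 2
            score = 0
            for stem_len in range(1, max_stem + 1):
                pair = (seq[a + stem_len - 1], seq[b - stem_len + 1])
                if pair not in _PAIR_SCORE:
                    break
                score += _PAIR_SCORE[pair]
                loop = span - 2 * stem_len
                if stem_len >= _MIN_STEM and 3 <= loop <= 8:
                    best = min(best, -score + _LOOP_PENALTY)
    return best


def fold_energy(
    position: int,
    strand: str,
    genome: GenomeSet,
    seq_id: str,
    engine: str = "builtin",
    upstream_len: int = 40,
) -> float:
    """Folding energy of the ``upstream_len`` nt upstream of a TEP.

    ``builtin`` uses :func:`hairpin_delta_g`; ``external`` shells out to
    RNAfold and parses its minimum free energy.
    """
    if strand == "+":
        seq = extract(genome, seq_id, position - upstream_len, position, "+")
    else:
        seq = extract(genome, seq_id, position + 1, position + 1 + upstream_len, "-")
    if len(seq) < 10:
        logger.warning("upstream sequence shorter than 10 nt at %s:%d; dG = 0", seq_id, position)
        return 0.0
    if engine == "builtin":
        return hairpin_delta_g(seq)
    if engine == "external":
        exe = shutil.which("RNAfold")
        if exe is None:
            raise RuntimeError("external folding engine 'RNAfold' not found on PATH")
        rna = seq.replace("T", "U")
        out = subprocess.run(
            [exe, "--noPS"], input=rna + "\n", capture_output=True, text=True, check=True
        ).stdout
        last = out.strip().splitlines()[-1]
        return float(last[last.rindex("(") + 1 : last.rindex(")")].strip())
    raise ValueError(f"unknown folding engine {engine!r}")


def call_tep(
    term_tracks: Sequence[EndCountTrack],
    rna_tracks: Sequence[EndCountTrack],
    annotation: AnnotationSet,
    genome: GenomeSet,
    tss_records: Sequence[TSSRecord] = (),
    params: TEPParams = TEPParams(),
) -> List[TEPRecord]:
    """End-to-end TEP calling from raw or normalized tracks."""
    from .genome_io import ensure_normalized

    term_norm = [ensure_normalized(t) for t in term_tracks]
    rna_norm = [ensure_normalized(t) for t in rna_tracks]
    accepted: List[List[TEPCandidate]] = []
    for track in term_norm:
        cands = candidate_teps(track, params.max_gap, params.sd_threshold, params.z_window)
        pos, neg = build_training_sets(
            cands, rna_norm, track, params.z_min, params.drop_ratio
        )
        accepted.append(
            knn_call(cands, pos, neg, params.k, params.feature_scaling)
        )
    merged = consensus_teps(accepted, params.tolerance, params.min_support)
    tss_map = {
        r.associated_gene: r.position
        for r in tss_records
        if r.category == "P" and r.associated_gene
    }
    records = categorize_tep(merged, annotation, tss_map, params.downstream)
    for rec in records:
        rec.shape, rec.u_count, rec.max_u_run = classify_shape(
            rec.position, rec.strand, genome, rec.seq_id,
            params.u_min, params.shape_window,
        )
        rec.delta_g = fold_energy(
            rec.position, rec.strand, genome, rec.seq_id,
            params.engine, params.upstream_len,
        )
    return records


# ---------------------------------------------------------------------------
# Tables (positions are 1-based in files)


def write_tep_table(records: Sequence[TEPRecord], path, headers: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for h in headers:
            fh.write(f"# {h}\n")
        fh.write("# seq_id\tposition\tstrand\tcategory\tshape\tgene\tdepth"
                 "\treplicate_support\tdelta_g\tu_count\tmax_u_run\n")
        for r in records:
            fh.write(
                f"{r.seq_id}\t{r.position + 1}\t{r.strand}\t{r.category}\t{r.shape}\t"
                f"{r.associated_gene or ''}\t{r.depth:.6g}\t{r.replicate_support}\t"
                f"{r.delta_g:.3f}\t{r.u_count}\t{r.max_u_run}\n"
            )


def read_tep_table(path) -> List[TEPRecord]:
    records: List[TEPRecord] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            records.append(
                TEPRecord(
                    seq_id=f[0], position=int(f[1]) - 1, strand=f[2],
                    category=f[3], shape=f[4], associated_gene=f[5] or None,
                    depth=float(f[6]), replicate_support=int(f[7]),
                    delta_g=float(f[8]), u_count=int(f[9]), max_u_run=int(f[10]),
                )
            )
    return records
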