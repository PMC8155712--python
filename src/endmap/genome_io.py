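"""Genomes, gene annotations, and strand-specific 5'-end count tracks.

All internal coordinates are 0-based half-open intervals on the forward
strand.  GFF3 (1-based inclusive) and bedGraph (0-based half-open) are
converted at the I/O boundary only.  Windows that would wrap the origin of
a circular sequence are truncated at the sequence boundary.

An :class:`EndCountTrack` stores, per strand, the number of read 5' ends at
each genomic position for one library/replicate.  Depth normalization
multiplies every count by a size factor of one million divided by the total
number of reads in the library, so normalized counts sum to 1e6.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

LIBRARY_TYPES = ("TAP_PLUS", "TAP_MINUS", "TERM", "RNA")
_VALID_BASES = frozenset("ACGTN")
_FEATURE_TYPES = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return str(Seq(seq).reverse_complement())


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class GenomeRecord:
    id: str
    sequence: str
    circular: bool = False

    def __len__(self) -> int:
        return len(self.sequence)


class GenomeSet:
    """Ordered collection of genome sequences with unique ids."""

    def __init__(self, records: Sequence[GenomeRecord]):
        if not records:
            raise ValueError("genome set is empty")
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids in genome set")
        for rec in records:
            if len(rec.sequence) == 0:
                raise ValueError(f"record {rec.id!r} has empty sequence")
            bad = set(rec.sequence) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rec.id!r} contains non-IUPAC character(s) "
                    f"{sorted(bad)!r}; only A/C/G/T/N are allowed"
                )
        self.records: List[GenomeRecord] = list(records)
        self._by_id = {r.id: r for r in records}

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, seq_id: str) -> GenomeRecord:
        try:
            return self._by_id[seq_id]
        except KeyError:
            raise KeyError(f"sequence {seq_id!r} not in genome set") from None

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._by_id

    def sequence(self, seq_id: str) -> str:
        return self.get(seq_id).sequence


def read_genome(path) -> GenomeSet:
    """Read a FASTA file into a :class:`GenomeSet` (uppercased, validated)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(GenomeRecord(id=rec.id, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeSet(records)


def write_genome(genome: GenomeSet, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in genome:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def extract(genome: GenomeSet, seq_id: str, start: int, end: int, strand: str) -> str:
    """Sequence of [start, end) in coding orientation; truncated at bounds."""
    seq = genome.sequence(seq_id)
    s = seq[max(0, start) : max(0, min(len(seq), end))]
    return revcomp(s) if strand == "-" else s


# ---------------------------------------------------------------------------
# Annotation


@dataclass(frozen=True)
class Gene:
    gene_id: str
    seq_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    feature_type: str = "CDS"
    product: Optional[str] = None

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def start_codon_pos(self) -> int:
        """Genomic position of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def stop_end_pos(self) -> int:
        """Genomic position of the last base of the gene (stop codon end)."""
        return self.end - 1 if self.strand == "+" else self.start


class AnnotationSet:
    def __init__(self, genes: Sequence[Gene]):
        ids = [g.gene_id for g in genes]
        dupes = {i for i in ids if ids.count(i) > 1} if len(set(ids)) != len(ids) else set()
        if dupes:
            raise ValueError(f"duplicate gene_id(s): {sorted(dupes)}")
        self.genes: List[Gene] = sorted(genes, key=lambda g: (g.seq_id, g.start))
        self._by_id = {g.gene_id: g for g in self.genes}

    def __iter__(self) -> Iterator[Gene]:
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def get(self, gene_id: str) -> Gene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"gene {gene_id!r} not in annotation") from None

    def on_sequence(self, seq_id: str) -> List[Gene]:
        return [g for g in self.genes if g.seq_id == seq_id]


def read_annotation(path, genome: GenomeSet) -> AnnotationSet:
    """Read GFF3 (1-based inclusive) into 0-based half-open :class:`Gene`s.

    CDS/tRNA/rRNA features are retained; gene_id comes from the ID or
    locus_tag attribute.  Features on unknown contigs or outside sequence
    bounds are rejected.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: List[Gene] = []
    seen = set()
    for feat in db.all_features():
        ftype = _FEATURE_TYPES.get(feat.featuretype)
        if ftype is None:
            continue
        if feat.seqid not in genome:
            raise ValueError(
                f"feature on unknown contig {feat.seqid!r} (not in genome)"
            )
        if feat.end < feat.start:
            raise ValueError(
                f"feature {feat.id!r}: end {feat.end} < start {feat.start}"
            )
        gene_id = feat.attributes.get("ID", feat.attributes.get("locus_tag", [None]))[0]
        if gene_id is None:
            raise ValueError(f"feature at {feat.seqid}:{feat.start} has no ID/locus_tag")
        if gene_id in seen:
            raise ValueError(f"duplicate gene_id {gene_id!r} in annotation")
        seen.add(gene_id)
        start, end = feat.start - 1, feat.end  # to 0-based half-open
        seqlen = len(genome.get(feat.seqid))
        if start < 0 or end > seqlen:
            raise ValueError(
                f"feature {gene_id!r} [{start}, {end}) outside sequence "
                f"{feat.seqid!r} of length {seqlen}"
            )
        product = feat.attributes.get("product", [None])[0]
        genes.append(Gene(gene_id, feat.seqid, start, end, feat.strand, ftype, product))
    return AnnotationSet(genes)


def write_annotation(annotation: AnnotationSet, path, headers: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for h in headers:
            fh.write(f"# {h}\n")
        for g in annotation:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                "\t".join(
                    [g.seq_id, "endmap", g.feature_type, str(g.start + 1),
                     str(g.end), ".", g.strand, "0" if g.feature_type == "CDS" else ".",
                     attrs]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# End-count tracks


@dataclass
class EndCountTrack:
    """Per-position, per-strand counts of read 5' ends for one library."""

    seq_id: str
    library_type: str
    replicate_id: str
    counts_fwd: Dict[int, float] = field(default_factory=dict)
    counts_rev: Dict[int, float] = field(default_factory=dict)
    total_reads: float = 0.0
    size_factor: float = 0.0
    normalized: bool = False

    def __post_init__(self):
        if self.library_type not in LIBRARY_TYPES:
            raise ValueError(
                f"unknown library_type {self.library_type!r}; expected one of {LIBRARY_TYPES}"
            )

    def counts(self, strand: str) -> Dict[int, float]:
        if strand == "+":
            return self.counts_fwd
        if strand == "-":
            return self.counts_rev
        raise ValueError(f"unknown strand {strand!r}")

    def depth(self, position: int, strand: str) -> float:
        return self.counts(strand).get(position, 0.0)

    def add(self, position: int, strand: str, count: float = 1.0) -> None:
        c = self.counts(strand)
        c[position] = c.get(position, 0.0) + count

    def positions(self, strand: str) -> List[int]:
        """Sorted positions with nonzero count on a strand."""
        return sorted(p for p, v in self.counts(strand).items() if v > 0)

    def window_mean(self, start: int, end: int, strand: str) -> float:
        """Mean count over [start, end) including zero positions."""
        if end <= start:
            return 0.0
        c = self.counts(strand)
        return sum(c.get(p, 0.0) for p in range(start, end)) / (end - start)

    def total(self) -> float:
        return sum(self.counts_fwd.values()) + sum(self.counts_rev.values())


def read_end_track(path, library_type: str, replicate_id: str) -> EndCountTrack:
    """Dispatch on file name: ``*.bed`` -> BED6 reads, else bedGraph pair prefix."""
    p = str(path)
    if p.endswith(".bed"):
        return read_end_track_bed6(p, library_type, replicate_id)
    return read_end_track_bedgraph(p, library_type, replicate_id)


def read_end_track_bed6(path, library_type: str, replicate_id: str) -> EndCountTrack:
    """Count read 5' ends from a BED6 file of read alignments.

    Each read contributes +1 at its 5' end (start for + reads, end-1 for -
    reads).  For TERM libraries the recorded strand is flipped relative to
    the read strand: the read 5' end marks the transcript 3' end on the
    opposite strand.
    """
    track: Optional[EndCountTrack] = None
    n_reads = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}: line {lineno}: expected >= 6 BED columns")
            chrom, s, e, _name, _score, strand = parts[:6]
            try:
                start, end = int(s), int(e)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if strand not in ("+", "-"):
                raise ValueError(f"{path}: line {lineno}: unknown strand symbol {strand!r}")
            if end <= start:
                raise ValueError(f"{path}: line {lineno}: end <= start")
            if track is None:
                track = EndCountTrack(chrom, library_type, replicate_id)
            elif chrom != track.seq_id:
                raise ValueError(
                    f"{path}: line {lineno}: multiple contigs in one track "
                    f"({track.seq_id!r} and {chrom!r}); one track per sequence"
                )
            five_prime = start if strand == "+" else end - 1
            record_strand = strand
            if library_type == "TERM":
                record_strand = "-" if strand == "+" else "+"
            track.add(five_prime, record_strand, 1.0)
            n_reads += 1
    if track is None:
        raise ValueError(f"{path}: no reads found")
    track.total_reads = float(n_reads)
    return track


def _bedgraph_paths(prefix: str) -> Tuple[str, str]:
    if prefix.endswith(".fwd.bedgraph") or prefix.endswith(".rev.bedgraph"):
        prefix = prefix[: -len(".fwd.bedgraph")]
    return prefix + ".fwd.bedgraph", prefix + ".rev.bedgraph"


def _read_bedgraph_file(path: str, track: EndCountTrack, strand: str) -> Optional[EndCountTrack]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                if "total_reads=" in line:
                    track.total_reads = float(line.split("total_reads=")[1].split()[0])
                if "normalized=true" in line:
                    track.normalized = True
                if "size_factor=" in line:
                    track.size_factor = float(line.split("size_factor=")[1].split()[0])
                continue
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            chrom, s, e, v = parts
            try:
                start, end, value = int(s), int(e), float(v)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: malformed values") from None
            if not track.seq_id:
                track.seq_id = chrom
            elif chrom != track.seq_id:
                raise ValueError(f"{path}: line {lineno}: multiple contigs in one track")
            for pos in range(start, end):
                track.add(pos, strand, value)
    return track


def read_end_track_bedgraph(prefix, library_type: str, replicate_id: str) -> EndCountTrack:
    """Read a ``.fwd.bedgraph``/``.rev.bedgraph`` pair written by this package.

    bedGraph tracks are taken at face value: the TERM strand reversal is a
    read-level rule applied when counting from alignments, and tracks
    written by :func:`write_end_track` are already in the final convention.
    """
    fwd, rev = _bedgraph_paths(str(prefix))
    track = EndCountTrack("", library_type, replicate_id)
    _read_bedgraph_file(fwd, track, "+")
    _read_bedgraph_file(rev, track, "-")
    if not track.seq_id:
        raise ValueError(f"{prefix}: empty bedGraph pair")
    if track.total_reads == 0 and not track.normalized:
        track.total_reads = track.total()
    return track


def write_end_track(track: EndCountTrack, prefix, headers: Iterable[str] = ()) -> Tuple[str, str]:
    """Write a track as a bedGraph pair (one length-1 interval per position)."""
    fwd, rev = _bedgraph_paths(str(prefix))
    meta = (
        f"# library_type={track.library_type} replicate_id={track.replicate_id} "
        f"total_reads={track.total_reads:g} size_factor={track.size_factor:g} "
        f"normalized={'true' if track.normalized else 'false'}"
    )
    for path, strand in ((fwd, "+"), (rev, "-")):
        with open(path, "w") as fh:
            fh.write(meta + "\n")
            for h in headers:
                fh.write(f"# {h}\n")
            for pos in track.positions(strand):
                v = track.counts(strand)[pos]
                fh.write(f"{track.seq_id}\t{pos}\t{pos + 1}\t{v:g}\n")
    return fwd, rev


def normalize_track(track: EndCountTrack) -> EndCountTrack:
    """Return a depth-normalized copy (size factor = 1e6 / total reads).

    Normalizing an already-normalized track is an error: the size factor is
    defined on raw read counts only.
    """
    if track.normalized:
        raise ValueError("track is already normalized")
    if track.total_reads <= 0:
        raise ValueError("cannot normalize a track with total_reads = 0")
    sf = 1e6 / track.total_reads
    return EndCountTrack(
        seq_id=track.seq_id,
        library_type=track.library_type,
        replicate_id=track.replicate_id,
        counts_fwd={p: v * sf for p, v in track.counts_fwd.items()},
        counts_rev={p: v * sf for p, v in track.counts_rev.items()},
        total_reads=track.total_reads,
        size_factor=sf,
        normalized=True,
    )


def ensure_normalized(track: EndCountTrack) -> EndCountTrack:
    return track if track.normalized else normalize_track(track)
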