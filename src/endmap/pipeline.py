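"""End-to-end orchestration: simulate, call ends, annotate, compare, report.

``run_pipeline`` executes the stages in dependency order on a simulated
dataset and writes every artifact (FASTA, GFF3, bedGraph pairs, TSV
tables) plus a JSON summary report.  All outputs carry a provenance header
with the configuration hash and seed; runs are single-process and
deterministic.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import genome_io
from .comparative_regulome import (
    classify_promoter_regions,
    classify_terminator_regions,
    extract_proteome,
    map_orthologs,
)
from .expression import call_degs
from .regulatory_annotation import annotate_utrs, build_pwm, find_rbs, tss_upstream_windows, write_meme
from .synthetic_data import (
    DivergenceConfig,
    ExpressionSimConfig,
    SimConfig,
    generate_genome,
    generate_ortholog_pair,
    simulate_expression,
    simulate_term_libraries,
    simulate_tss_libraries,
    write_truth,
)
from .tep_caller import TEPParams, call_tep, write_tep_table
from .tss_caller import TSSParams, call_tss, write_tss_table

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; the element-calling defaults are the
    published procedure's values."""

    outdir: str = "endmap_run"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    div: DivergenceConfig = field(default_factory=DivergenceConfig)
    expr: ExpressionSimConfig = field(default_factory=lambda: ExpressionSimConfig(n_genes=500, n_deg=25))
    tss: TSSParams = field(default_factory=TSSParams)
    tep: TEPParams = field(default_factory=TEPParams)
    compare_regions: bool = True

    def __post_init__(self):
        # one seed drives every stage
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        self.expr = dataclasses.replace(self.expr, seed=self.seed)

    def config_hash(self) -> str:
        params = asdict(self)
        params.pop("outdir", None)  # hash the science, not the paths
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> Dict:
    """Run simulate -> call-tss -> call-tep -> annotate-utr -> motif ->
    compare-regions -> deg and return the summary report (also written to
    ``<outdir>/report.json``)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = [f"endmap config_hash={config.config_hash()} seed={config.seed}"]

    genome, annotation, truth = generate_genome(config.sim)
    genome_io.write_genome(genome, outdir / "genome_a.fasta")
    genome_io.write_annotation(annotation, outdir / "genome_a.gff3", headers=prov)
    write_truth(truth, outdir / "truth_a")

    drna = simulate_tss_libraries(truth, config.sim)
    tap_plus = [t for t in drna if t.library_type == "TAP_PLUS"]
    tap_minus = [t for t in drna if t.library_type == "TAP_MINUS"]
    term_tracks, rna_tracks = simulate_term_libraries(truth, config.sim)
    for track in drna + term_tracks + rna_tracks:
        genome_io.write_end_track(
            track, outdir / f"{track.library_type.lower()}_{track.replicate_id}", headers=prov
        )

    tss_records = call_tss(tap_plus, tap_minus, rna_tracks, annotation, genome, config.tss)
    write_tss_table(tss_records, outdir / "tss.tsv", headers=prov)
    tep_records = call_tep(term_tracks, rna_tracks, annotation, genome,
                           tss_records, config.tep)
    write_tep_table(tep_records, outdir / "tep.tsv", headers=prov)

    utrs = annotate_utrs(tss_records, tep_records, annotation, genome)
    five = [u for u in utrs if u.kind == "five_prime"]
    rbs_hits, rbs_searched = find_rbs(utrs, annotation, genome)
    windows = tss_upstream_windows(tss_records, genome, -20, 0)
    report: Dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_genes": len(annotation),
        "tss_counts": _count_by(tss_records, "category"),
        "tep_counts": _count_by(tep_records, "category"),
        "tep_shape_counts": _count_by([t for t in tep_records if t.category in "PS"], "shape"),
        "utr5_median_length": float(np.median([u.length for u in five])) if five else None,
        "utr5_n": len(five),
        "leaderless_n": sum(u.leaderless for u in five),
        "rbs_hits": len(rbs_hits),
        "rbs_searched": rbs_searched,
        "rbs_distance_5_10_frac": (
            sum(5 <= h.distance <= 10 for h in rbs_hits) / len(rbs_hits)
            if rbs_hits else None
        ),
    }
    if len(windows) >= 2:
        pwm = build_pwm([w for _, w in windows])
        write_meme(pwm, outdir / "minus10_pwm.meme", name="minus10")
        report["minus10_consensus"] = pwm.consensus

    if config.compare_regions:
        genome_b, annotation_b, truth_b, ortho_truth = generate_ortholog_pair(
            truth, config.sim, config.div
        )
        genome_io.write_genome(genome_b, outdir / "genome_b.fasta")
        genome_io.write_annotation(annotation_b, outdir / "genome_b.gff3", headers=prov)
        pairs = map_orthologs(
            extract_proteome(genome, annotation), extract_proteome(genome_b, annotation_b)
        )
        from .tss_caller import TSSRecord
        from .tep_caller import TEPRecord

        tss_b = [
            TSSRecord(truth_b.seq_id, t.position, t.strand, 1.0, "P",
                      t.gene_id, None, 1, None)
            for t in truth_b.tss
        ]
        tep_b = [
            TEPRecord(truth_b.seq_id, t.position, t.strand, 1.0, "P", t.klass,
                      t.gene_id, 1)
            for t in truth_b.teps
        ]
        prom = classify_promoter_regions(
            tss_records, tss_b, annotation, annotation_b, genome, genome_b, pairs
        )
        termc = classify_terminator_regions(
            tep_records, tep_b, annotation, annotation_b, genome, genome_b, pairs
        )
        report["n_ortholog_pairs"] = len(pairs)
        report["promoter_classes"] = _count_by(prom, "klass")
        report["terminator_classes"] = _count_by(termc, "klass")

    counts, deg_truth = simulate_expression(config.expr)
    group_a = [c for c in counts.columns if c.startswith("A_")]
    group_b = [c for c in counts.columns if c.startswith("B_")]
    degs = call_degs(counts, group_a, group_b)
    report["deg_n"] = int(degs["is_deg"].sum())
    report["deg_tested"] = int(len(degs))
    degs.to_csv(outdir / "deg.tsv", sep="\t")

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _count_by(records, attr: str) -> Dict[str, int]:
    out: Dict[str, int] = {}
    for r in records:
        key = getattr(r, attr) or "?"
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items()))
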