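# endmap

Genome-wide mapping of bacterial transcript ends and the regulatory
elements anchored to them.

Bacterial transcriptome architecture — where transcription starts and
stops, and what sits around those positions — is read out from two
end-enriched sequencing assays. Differential RNA-seq (dRNA-seq) compares
libraries with and without 5′-polyphosphatase (TAP) treatment: primary 5′
ends carry triphosphates and are ligatable only after treatment, so true
transcription start sites (TSSs) are TAP+-enriched while processed ends
appear in both. Term-seq ligates an adaptor to transcript 3′ ends, so
read 5′ ends (strand-reversed) mark transcript 3′-end positions (TEPs).
`endmap` implements the complete analysis for a marine cyanobacterium-
style study design — duplicate dRNA-seq, triplicate Term-seq and RNA-seq,
plus a second strain for comparison — as a tested, reusable library with
a CLI.

What it does:

- **TSS calling** — cluster TAP+ 5′-end peaks (gap < 100 nt, sub-cluster
  at positional SD < 10), keep peaks > 2-fold enriched over TAP−, apply
  replicate consensus with ±2 nt restoration and RNA-profile rescue, and
  categorize P/S/I/A/N against the annotation (P = deepest TSS within
  −500..+100 nt of a start codon).
- **TEP calling** — Z-score-seeded (Z > 6) training sets, a k-nearest-
  neighbour classifier on the 21 depths at ±10 nt around each candidate,
  triplicate ±1 nt consensus, P/S/U/I/A/N categories, L/I terminator
  shape (≥ 4 uridines near the TEP), and upstream hairpin ΔG (builtin
  scorer or RNAfold).
- **Regulatory annotation** — 5′/3′-UTRs, leaderless transcripts
  (< 9 nt), AGGAG ribosome-binding-site search at −20..−1, PWMs from
  fixed TSS-anchored windows with exact DP hit p-values.
- **Cross-strain comparison** — BLOSUM62 best-hit orthologs (E < 10⁻⁶,
  > 80% coverage), promoter (50 vs 550 nt) and terminator (−40..+20 vs
  520 nt) conservation classes conserved/mismatched/orphan/specific,
  5′-UTR length conservation, p-distance, hydropathy profiles.
- **Expression** — median-of-ratios size factors and DEG calling
  (> 2-fold, BH-adjusted p < 0.01), qPCR 2^(−ΔΔCt) fold changes.
- **Synthetic data** — a generator that plants every element (TSSs with
  TANAAT/TTGCCAA boxes, RBSs, hairpin terminators with/without U-tracts,
  processed sites, ortholog scenarios, true fold changes) and emits the
  truth set, so every stage is testable against known ground truth.

See `docs/methods.md` for the models, parameters and their rationale.

## Worked example

Simulate a 60-gene genome with all four library types and run the whole
pipeline:

```sh
endmap run-all --outdir demo --seed 7 --n-genes 60
```

which prints (abridged):

```
{
  "n_genes": 60,
  "tss_counts": {"I": 12, "P": 60, "S": 20},
  "tep_counts": {"P": 60},
  "tep_shape_counts": {"I": 17, "L": 43},
  "utr5_median_length": 40.5,
  "leaderless_n": 4,
  "rbs_hits": 56, "rbs_searched": 56,
  "rbs_distance_5_10_frac": 1.0,
  "minus10_consensus": "ACTCATGATTTACAATGATT",
  "n_ortholog_pairs": 45,
  "promoter_classes": {"conserved": 15, "mismatched": 24,
                       "orphan": 22, "specific": 19},
  "terminator_classes": {"conserved": 15, "mismatched": 15,
                         "orphan": 15, "specific": 15},
  "deg_n": 24, "deg_tested": 500
}
```

Every gene's primary TSS (`"P": 60`) and terminator (`"P": 60` TEPs) is
recovered; offsets 10–15 of the −10-box consensus read `TACAAT`, an
instance of the planted TA·AAT motif; an AGGAG RBS is found for all 56
genes whose 5′-UTR admits one, all at 5–10 nt from the start codon. The
terminator classes recover the four planted ortholog scenarios exactly
(15 genes each); the promoter classes count every called P/S TSS
independently, so they exceed the 60 per-gene scenarios. The same stages
are available piecewise (`endmap simulate`, `call-tss`, `call-tep`,
`annotate-utr`, `motif-scan`, `compare-regions`, `deg`, `qpcr`) on FASTA,
GFF3 and strand-split bedGraph inputs, and as plain library calls
(`endmap.tss_caller.call_tss`, …).

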