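# Methods

`endmap` reconstructs the genome-wide map of bacterial transcript ends —
transcription start sites (TSSs) from differential RNA-seq and transcript
3′-end positions (TEPs) from Term-seq — together with the regulatory
elements anchored to them: promoter boxes, ribosome binding sites, 5′/3′
untranslated regions, intrinsic terminators, and the conservation of
promoter and terminator regions between two related strains. This note
records the models, the parameters that matter, and the choices made where
the design was genuinely open.

## Coordinate model

Internally everything is 0-based, half-open, on the forward strand. GFF3
(1-based inclusive) and bedGraph (0-based half-open) are converted only at
I/O boundaries, and positions are written 1-based in output tables.
Circularity is recorded but windows that would wrap the origin are
truncated at the sequence boundary: origin-spanning logic is not worth the
off-by-one surface it creates, and no analysis step here depends on it.

## End-count tracks and normalization

An `EndCountTrack` stores, per strand, the number of read 5′ ends at each
position for one library/replicate. From BED6 alignments a read
contributes +1 at its 5′ end (interval start for `+` reads, `end − 1` for
`−` reads). For Term-seq libraries the recorded strand is flipped
relative to the read strand: with 3′-adaptor ligation the read 5′ end is
the transcript 3′ end on the opposite strand. Tracks are depth-normalized
by a size factor of 10⁶ divided by the library's total mapped reads, so
normalized counts sum to one million; normalizing twice is an error
because the size factor is defined on raw counts.

## TSS calling

Per TAP+ replicate:

1. **Clustering.** Nonzero positions are single-linkage clustered while
   the gap to the neighbour is < 100 nt. Within a cluster a greedy
   left-to-right sweep grows a sub-cluster while the *population* standard
   deviation of its positions stays < 10; each sub-cluster keeps its
   deepest position (ties to the smaller coordinate).
2. **TAP enrichment.** A peak survives if the TAP− library has zero depth
   at the identical position, or the TAP+/TAP− depth ratio exceeds 2.
   The comparison is exact-position (±0 nt): the enrichment rule names
   "the peak of the TAP− library" without a tolerance, and exactness is
   the literal reading.

Across replicates, a peak is kept when matched in every replicate within
±2 nt (restoring the 1–2 nt jitter seen between biological duplicates);
the surviving position is the deepest replicate's and the depth is the
mean of the matched depths. A peak seen in fewer than all replicates
survives only with a "clear RNA-seq profile", codified as: mean RNA
coverage over the 50 nt downstream ≥ half the median nonzero per-position
RNA coverage. (A multiple *above* the typical transcribed-position
coverage would reject genuine single-replicate peaks, since a transcribed
region's mean coverage *is* approximately that median; half of it is a
floor that separates transcribed from silent neighbourhoods. The
threshold is a parameter.)

Categories follow positional precedence. For each gene, TSSs on its
strand within 500 nt upstream to 100 nt downstream of the start codon are
ranked by depth: the deepest is primary (P), the rest secondary (S). A
TSS eligible for several genes goes to the nearest start codon. Remaining
TSSs inside a gene body are internal (I), antisense to a gene (A),
otherwise intergenic (N). Internal peaks weaker than 1% of their gene's
P-TSS depth are dropped — a deterministic stand-in for the manual removal
of processed-transcript peaks in very highly expressed genes.

## TEP calling

Term-seq tracks (already strand-reversed) are clustered exactly as above.
Each representative gets a Z-score against the nonzero depths within
±50 nt on the same strand (sample SD, peak excluded); degenerate
neighbourhoods (fewer than two neighbours, or zero SD) fall back to the
whole-track nonzero distribution, logged. The ±50 nt window mirrors the
observation that RNA signal decays within ~50 nt of genuine 3′ ends.

The classifier is seeded per replicate: positives are candidates with
Z > 6 *and* a falling RNA profile (downstream/upstream 50-nt coverage
ratio ≤ 0.5); negatives are every other Term-seq signal position within
±10 nt of a positive (zero-depth positions are not negatives — only
observed signal can be confused with a 3′ end). Every candidate's feature
vector is the 21 depths at offsets −10..+10 (transcript-oriented); each
vector is divided by its own maximum before the Euclidean k-nearest-
neighbour vote (k = 5 by default, configurable; scaling, switchable with
`--no-feature-scaling`, makes the vote depend on peak *shape* rather than
depth). Ties break toward rejection, and training positives are always
accepted. Calls present in ≥ 2 of ≥ 3 replicates (±1 nt) survive.

Categories: per gene, TEPs within 500 nt downstream of the stop codon are
P (deepest) or S; a TEP between a gene's P-TSS and its start codon is a
5′-UTR TEP (U); inside a gene body internal (I); antisense (A); else
intergenic (N) — precedence P/S > U > I > A > N, multi-gene eligibility
resolved by nearest stop codon.

**Shape.** A TEP is L-shaped when the transcript-oriented window
−10..+2 nt contains ≥ 4 uridines (T on the coding strand), else I-shaped.
The window brackets where the U-tract of a canonical intrinsic terminator
falls relative to the 3′ end.

**Folding energy.** The 40 nt upstream of each TEP (matching the
terminator motif search window) is scored either by RNAfold (`external`
engine) or by the builtin hairpin score: exhaustive search over stems
≥ 4 bp with loops of 3–8 nt, ΔG = −3·GC − 2·AU − 1·GU + 4 (loop penalty),
0 when no stem exists. The builtin scorer is a deliberately simple
base-pair-counting model for ranking hairpin strength, not a thermodynamic
prediction; distributional comparisons (terminators vs random intergenic
windows) are its intended use.

## UTRs, RBS, and PWMs

5′-UTRs run from the P-TSS to the start codon (leaderless when < 9 nt),
3′-UTRs from the stop codon to the P-TEP; a P-TSS downstream of the start
codon yields no UTR record. The AGGAG ribosome binding site is an exact
substring search in the 20..1 nt upstream of start codons, restricted to
genes with 5′-UTRs strictly longer than 10 nt; the reported distance is
the number of bases between the motif 3′ end and the start codon, closest
occurrence first.

PWMs are built from aligned fixed windows (e.g. −20..0 for the −10 box,
−40..−20 for the −35 box): column probabilities (count + 0.5)/(n + 2),
log-odds in bits against the background. De novo motif discovery is out
of scope — the windows are fixed and known, so discovery adds nothing
testable. Scan p-values are exact for the discretized model: log-odds
are rounded to 0.01-bit integers once, and the null score distribution is
the exact dynamic-programming convolution of the per-column integer
scores under the background, so `P(S ≥ s)` agrees with brute-force
enumeration of all words to machine precision.

## Cross-strain comparison

Orthologs are best protein-level hits: Smith–Waterman with BLOSUM62 (gap
open 11/extend 1), an approximate Karlin–Altschul E-value (λ = 0.267,
K = 0.041) below 10⁻⁶, and > 80% query CDS coverage. An external `blastp`
path is available and preferred for real data; the builtin aligner keeps
the package self-contained.

Promoter regions are the 50 nt upstream of each CDS-associated TSS,
searched within the 550 nt upstream of the ortholog's start codon;
terminator regions are TEP−40..TEP+20, searched within the 520 nt
downstream of the ortholog's stop codon. The builtin matcher accepts a
local alignment (match 1/mismatch −1/gap −2) of ≥ 25 aligned columns at
≥ 70% identity, *and* requires a shared exact 11-mer word to seed it —
the same property that makes a BLASTN hit between unrelated sequences
rare. Without the word requirement, random 50–60-mers reach the
25-column/70% bar against a 500-nt window often enough to blur the class
boundaries. All three thresholds are parameters.

Classes: **conserved** = matched in both directions and the partner
strain has a TSS/TEP whose projected offset through the match is within
±5 nt (separating drifted sites from jitter); **mismatched** = matched
but the corresponding site is absent or displaced; **orphan** = no match
either way; **specific** = no ortholog. Every CDS-associated TSS/TEP is
classified independently.

5′-UTR length conservation uses length differences: < 2 nt conserved,
> 10 nt degenerated, and the gap in between is reported explicitly as
*intermediate* so the partition is complete. Sequence divergence is the
p-distance (differing sites over gap-free columns, pairwise deletion) on
a global alignment (match 1/mismatch −1/gap −2). Hydropathy profiles are
centred sliding-window means of Kyte–Doolittle values with shrunken
windows at the termini.

## Expression comparison

Gene counts are sums of raw RNA-seq 5′-end counts in the gene body.
Size factors are median-of-ratios (reference = per-gene geometric mean
over samples, genes with any zero excluded). Fold change is
log2((mean_A + 0.5)/(mean_B + 0.5)). The default test pools the
log2-scale variance across genes and tests each gene's difference of
means with a z-statistic — a common-dispersion simplification standing in
for a full negative-binomial model, which is deliberately not
re-implemented. With three replicates per group, a per-gene Welch test
(available as `method="welch"`) cannot reach an adjusted p < 0.01 at any
realistic effect size; sharing the dispersion across genes is what makes
small-replicate designs testable, exactly as shared-dispersion NB models
do. P-values are Benjamini–Hochberg adjusted; a DEG needs |log2 FC| > 1
and adjusted p < 0.01. qPCR fold changes are 2^(−ΔΔCt) against a
reference gene.

## The simulator as study conditions

The generator builds gene cassettes in coding orientation and splices
them onto alternating strands with 100–250 nt spacers. Each gene gets:
a 5′-UTR drawn lognormally around a 42 nt median (10% leaderless,
< 9 nt); TANAAT and TTGCCAA boxes written at −10/−35 from the TSS; a
purine at the TSS and pyrimidine at −1; AGGAG 5–10 nt upstream of the
start codon when the UTR allows; a CDS of 120–300 nt without internal
stops; and an intrinsic terminator — an 8-bp G/C stem, 4-nt loop, and
either a ≥ 4-nt U-tract (L-shaped, 70%) or none (I-shaped) — with the TEP
planted at the tract end. GC content is 0.47 (cyanobacterial-like,
fixed).

Libraries: peak counts are negative binomial (dispersion 0.1) around
means of 100 (TAP+, Term-seq) scaled by a per-gene lognormal expression
level; reads jitter ±1 nt with probability 0.1 (exercising the
restoration rule); planted TSS signal leaks into TAP− at ratio 0.2
(safely below the 2-fold rule); processed sites appear in both dRNA
libraries and are boosted in TAP− so the two library totals match in
expectation — untreated libraries are dominated by processed/degradation
ends in practice, and without comparable totals size-factor normalization
would distort the TAP ratio. Term-seq gets small satellite signals
within ±10 nt of each TEP (stochastic termination; these feed the
negative training set). RNA-seq covers each unit uniformly (Poisson,
mean 2/nt × level) and drops 10-fold for 100 nt past the TEP. Poisson
background (5×10⁻⁴/nt/strand) is scattered genome-wide. Everything is
reproducible bit-for-bit from (config, seed).

The ortholog generator applies one of four scenarios per gene with
deterministic largest-remainder counts: copy the promoter/terminator
region with the matching site offset (conserved); copy it and delete the
site (mismatched); randomize the region (orphan); delete the gene
(specific). One scenario governs both of a gene's regions, which keeps
scenario counts exact for both comparisons. CDSs take point mutations at
2% by default (start/stop preserved).

What the simulator does **not** emulate: sequencing error, mappability
and multi-mapping artifacts, operonic genes sharing promoters/
terminators, rho-dependent termination, condition-dependent expression,
and real promoter degeneracy (planted motifs are near-exact). Recovery
rates on simulated data therefore bound the method's behaviour under its
own assumptions; they do not certify performance on real libraries.

## Problem sizes and numeric choices

The recovery benchmarks use a 200-gene genome (~170 kb) for end calling,
40 genes for conservation scenarios, and 2,000 genes (100 true 4-fold
DEGs, 3 replicates/group) for expression — sizes at which every planted
feature class is represented many times over while a full run stays in
seconds. Degenerate inputs are contracts, not surprises: empty TSS lists,
zero-SD Z neighbourhoods, regions shorter than a PWM, undefined
p-distances and missing Ct values each have a stated fallback or error.
Ties break deterministically everywhere (smaller coordinate, negative KNN
class), so shuffled inputs give identical outputs.
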