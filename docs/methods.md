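# Methods

`mirdup` reimplements, end to end, a small-RNA-seq microRNA
discovery-and-duplication analysis: adapter-trimmed reads are mapped
exactly to a genome, read stacks seed candidate precursor hairpins, folded
candidates are filtered on stability and Dicer-like geometry, retained
loci are filtered on read support, 5'-end precision and genomic
uniqueness, and the resulting miRNA complement is analyzed for family copy
numbers across genomes, genomic cluster duplication, and 5p/3p arm-usage
divergence between species. A synthetic-data generator plants all of these
signals with known truth so that every stage can be scored exactly.

## Read preprocessing and mapping

Adapter trimming is error-free suffix matching: the leftmost position
where the read's remainder is a prefix of the 3' adapter (>= 3 nt) ends
the insert. Trimmed reads of >= 18 nt are retained (reads longer than
17 bp). Mapping is exact (0 mismatches by default) with a bowtie1-style
best-stratum contract: every placement in the best stratum is reported,
and a read whose best stratum exceeds 5 placements is discarded as a
multimapper. Reporting all placements up to that cap lets reads from
paralogous copies count at every copy; a palindromic read matching both
orientations of one locus counts once, on the forward strand. The mapper
anchors on a 12-mer index (2-bit-encoded, sorted-array lookup) with a
pigeonhole seed per permitted mismatch, and falls back to a full scan for
reads shorter than the seed. On small genomes it is verified base-by-base
against an exhaustive scan of every offset on both strands.

## Candidate hairpins and folding

Hits within 30 nt on one scaffold+strand merge into read stacks. Each
stack (>= 10 reads; smaller stacks cannot pass the later read-support
criterion) is excised into up to three windows: stack plus 70 nt of 3'
flank, 70 nt of 5' flank plus stack, and — when the stack already spans
both arms — the bare stack span.

Folding is a Nussinov-style dynamic program over nested structures with
hairpin loops >= 3 nt, Watson–Crick plus GU pairs, and N never pairing,
under one of two deliberately simplified energy models:

* `pair_count` — maximize the number of pairs; energy is −1 kcal/mol per
  pair.
* `stacking` — minimize a sum of stack energies (GC −3, AU −2, GU
  −1 kcal/mol; a pair contributes only when stacked directly on the next
  pair inward), the default for discovery because it resolves the
  pair-maximization model's highly degenerate optima toward contiguous
  helices.

These are not the Turner thermodynamic model; they are exactly testable
optima (the test suite checks the DP against exhaustive structure
enumeration) with the same *filtering contract* as a thermodynamic
folder: a candidate is retained when its energy per nucleotide is at or
below −0.2 kcal/mol/nt. Under both simplified models random sequence
folds well enough that this threshold is permissive; the discriminative
power of the pipeline comes from read support and duplex geometry, and
the threshold is kept for contract fidelity.

Qualification asks whether the stack's modal read interval (the putative
mature) sits in a Dicer-like duplex. Windows are folded with
mature-internal pairs forbidden (a constrained fold: the question is
whether a duplex geometry exists, not what the global optimum looks
like); in the unconstrained API more than 4 self-paired mature bases
reject the candidate as loop-spanning. At least 14 mature bases must be
paired; the star is the densest same-side run of partner positions (stray
pairs into the flank are ignored) extended by the 2-nt 3' Dicer overhang;
star and mature must be disjoint and separated by a loop of 3–35 nt
(pre-miRNA loops run ~3–25 nt; beyond 35 the geometry is not a Dicer
substrate). Every window is evaluated under both energy models, and the
winning window per stack is chosen by (i) the number of reads its
mature+star geometry explains, (ii) the stacking energy of the
mature–star duplex itself — a genuine stem is a contiguous helix and far
more stable than a chance flank pairing — and (iii) energy per
nucleotide.

**Known limitation.** When a stack carries reads on only one arm and is
additionally polluted by multimapped reads from a paralog, both flanking
windows occasionally misfold and a flank helix within Dicer reach can win
the star position, flipping the call's 5p/3p labels. In ensemble runs
this affects roughly one locus in several hundred; its visible symptom is
a single spurious arm-switch call or an imprecise precursor boundary.

## Annotation criteria

A qualified candidate becomes a miRNA call only if it passes, with all
three criteria always evaluated and recorded:

1. >= 10 reads at the locus (discard at 9);
2. >= 50% of the dominant mature's reads sharing the modal 5' end
   (exactly 50% passes; the criterion discards only below it);
3. <= 10 genomic loci matching the dominant mature at <= 2 substitutions
   (11 discards), counted by a seeded exhaustive scan of both strands
   with adjacent matches collapsed.

Overlapping calls on one scaffold merge regardless of strand (the two
arms of a duplex are near reverse complements, so one arm's reads can
seed a mirror-image call), keeping the best-supported call. Each arm's
product records its read count, 5'-end homogeneity, and a genome-wide
uniqueness flag (exactly one 0-mismatch locus) that gates the arm-usage
analysis.

## Homology, families and copy numbers

Paralog/ortholog search is seed-and-extend: exact 11-mer anchors (the
4-mer word size of the scoring scheme would anchor every ~256 bp and
degenerate into a full-genome alignment; 11-mers are exact for the
divergences of interest), extension by affine-gap Smith–Waterman
(+2/−3, gap 5 + 2/nt) on a padded window, gates at 70% alignment identity
and E <= 0.1 from Karlin–Altschul statistics (lambda solved from the
scoring scheme by bisection; K = 0.71 is a configured heuristic).
Queries are trimmed to the precursor proper (mature-to-star span): the
candidate window's flanks have no counterpart in another genome and only
dilute coverage.

A hit is confirmed as an ortholog when the alignment (a) spans >= 75% of
the precursor query — orthology is judged on the whole hairpin, and a
short chance island of high identity over one arm is not an ortholog —
and (b) covers >= 90% of at least one mature arm at >= 70% identity
within that arm. Confirmed hits pooled across queries collapse when they
overlap by half the shorter interval *or* by >= 16 nt: two precursor
detections sharing a mature-sized stretch are one locus found with
different boundaries, never two paralogs.

Families are single-linkage clusters over mature-arm similarity at the
70% gate, computed *ungapped* (best match fraction over all relative
offsets): family members differ by substitutions and small 5'-end
offsets, never by internal indels, whereas a gapped aligner can stitch
chance fragments of unrelated matures into deceptive identity. The
family × species copy-number matrix counts confirmed loci per family per
species, classified absent / single / multicopy (>= 2).

## Clusters and duplications

Loci within 50 kb on one scaffold chain into clusters (the only cluster
span stated for the tandem mir-3791 expansion, exposed as config); runs
of >= 2 same-family loci form tandem arrays, with interleaved families
tolerated (the mir-71/mir-2 arrangement). Two clusters group as putative
cluster paralogs when the Jaccard similarity of their family *sets* is
>= 0.5 — sets, not multisets, because duplicated clusters routinely
diverge in copy count (3 vs 6 copies of one family must still group) —
and grouping is transitive. Clusters within 10 kb of a scaffold end are
flagged as possible fragments of larger clusters.

## Arm usage and switching

Per miRNA, usage is the 5p fraction f5 = c5/(c5+c3) and the pseudocounted
log-ratio log10((c5+0.5)/(c3+0.5)); dominance uses raw counts, the
pseudocount only keeps zero arms finite. Records non-unique on both arms
are excluded from species comparisons; one-unique records carry a
reliability flag. For multicopy families, `family_average` implements the
mean of per-member fractions — the right procedure for per-mature count
tables (miRBase-style input), where counts cannot be double-counted. The
synthetic study instead pools *distinct read ids* per family arm: with
full counting of multimapped reads at every locus, per-locus counts
double-count matures shared between copies, and distinct-read pooling
undoes exactly that.

Between two species, a shared family has *switched* arms when its
dominant arm differs; a same-dominance difference above 10-fold in usage
ratio is a within-band shift; otherwise conserved. Distribution-level
comparisons use the two-sample Kolmogorov–Smirnov statistic — D as the
supremum of |ECDF difference| over pooled sample points (verified against
dense-grid evaluation to 1e-12) with the asymptotic p-value
Q(lambda) = 2 Σ (−1)^{k−1} e^{−2k²λ²},
λ = (√n_e + 0.12 + 0.11/√n_e)·D, n_e = n1·n2/(n1+n2), series truncated at
1e-12. No exact small-sample enumeration is provided; at the ~tens of
families per comparison the asymptotic form is adequate, and p-values for
very small samples should be read qualitatively.

## The synthetic study

The generator emulates the features the pipeline must resolve, and its
defaults are the study conditions: 5 scaffolds × 300 kb per species at
35% GC; 10 families of 1–6 copies (families with >= 3 copies planted as
tandem arrays with 2 kb gaps, 2-copy families dispersed); one two-family
cluster (1 + 3 copies, the single-copy member flanked) planted twice on
different scaffolds; 5% per-base divergence per copy; 22-nt matures on
hairpins with 15-nt loops and two stem bulges; log-normal read depth
(µ = 4.0, σ = 0.4 on the log scale, median ≈ 55 reads); 5p-arm bias 0.25
(the observed 3'-arm preference) with three families planted at 10:1
opposing biases between the two species; 20% ±1-nt 5'-end jitter; 30%
29-nt background reads at uniform genome positions; TruSeq small-RNA 3'
adapter with read-through padded to 100 nt.

Generator design choices that matter for interpretation:

* **Stem bulges (2 per hairpin).** A perfect-palindrome precursor lets
  one arm's reads map antisense onto the other arm, an artifact real
  pre-miRNAs (which always carry duplex imperfections) do not produce.
* **Family separability.** Consensus arms are resampled until every
  cross-family arm pair stays <= 0.55 similarity under both the
  clustering measure and plain positional identity — exact family
  recovery is only a meaningful target when planted families are
  separable in principle (copy divergence and 5'-jitter can add roughly
  3/22 to an arm pair's apparent similarity, hence the margin below the
  0.70 gate).
* **Unit spacing (>= 60 kb).** Independently planted units must not chain
  into spurious 50 kb clusters; loci of one genuine cluster or array sit
  2 kb apart.
* Two species share ancestral family sequences (drawn from the seed
  without the species tag); backgrounds, placements, divergences and
  reads are species-specific.

What the generator does *not* emulate: sequencing errors beyond 5'
jitter, quality-score structure (qualities are constant 'I'; the pipeline
never uses them after trimming), realistic piRNA biogenesis (the 29-nt
background is uniform), isomiR 3'-end variation, indel divergence between
paralogs, and minus-strand loci by default (supported and tested, off in
the study). Passing the ensemble tests therefore demonstrates that the
algorithms recover the planted signal classes under realistic noise
levels, not that the pipeline's thresholds are optimal for any particular
real library.

Scoring against truth matches detected intervals to planted loci by
coverage of at least half the planted hairpin or half of either planted
mature — the mature is the functional unit that defines a locus, and
detected precursor boundaries may legitimately lean into the flank on the
star side.

## Numerical and reproducibility choices

* All randomness flows from NumPy `SeedSequence(seed, stream)` streams;
  identical (seed, config) gives byte-identical FASTA/FASTQ/truth files
  and pipeline outputs. Derived seeds stay below 2^31.
* DP tracebacks break ties deterministically (pairing over bifurcation,
  smaller split index; diagonal over gaps, earliest end cell).
* Stacking-model tracebacks compare recomputed branch values within
  1e-9 of the stored optimum.
* Coordinates are 0-based half-open everywhere internally; BED stays
  native, GFF3 converts to 1-based inclusive at the writer and nowhere
  else.
* Problem sizes: the ensemble tests and the acceptance script run 20
  two-species studies (≈ 64 planted loci, ≈ 5,800 reads each) in a few
  minutes; these sizes were chosen as the smallest study that keeps
  cluster/tandem geometry and chance-hit statistics meaningful.
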