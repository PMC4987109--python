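# mirdup

MicroRNA discovery, duplication and arm-usage analysis from small RNA-seq
— a compact, fully tested reimplementation of an embryonic miRNA
annotation workflow, aimed at people who study miRNA repertoire evolution
(paralog expansions, cluster duplications, 5p/3p arm switching) in
non-model genomes.

From raw reads and genome FASTA files the pipeline produces:

1. **miRNA calls** — reads are adapter-trimmed (inserts > 17 bp
   retained), mapped exactly with a bowtie1-style best-stratum contract
   (all placements reported, discarded above 5 loci), stacked, excised
   into candidate precursors and folded with a Nussinov-style dynamic
   program. A candidate survives if it has at least 0.2 kcal/mol of
   predicted stability per nucleotide (MFE/nt ≤ −0.2), Dicer-like
   mature/star duplex geometry, ≥ 10 supporting reads, ≥ 50% of the
   dominant mature's reads sharing one 5′ end, and ≤ 10 genomic loci
   matching the mature at ≤ 2 substitutions.
2. **Family copy numbers across species** — affine Smith–Waterman
   ortholog search (+2/−3 match/mismatch, gaps 5 + 2/nt, 70% identity,
   Karlin–Altschul E ≤ 0.1), confirmation on the mature arms, and
   single-linkage family clustering into a family × species matrix with
   absent/single/multicopy classes.
3. **Cluster duplication** — genomic clusters chained within 50 kb,
   tandem arrays, duplicated clusters grouped by family-set Jaccard
   similarity, and scaffold-end fragment flags.
4. **Arm usage and switching** — per-miRNA 5p fraction
   f5 = c5/(c5 + c3) and log10 usage ratio, family averages, arm-switch
   calls between species (dominant arm flips; > 10-fold same-dominance
   shifts reported separately), and two-sample Kolmogorov–Smirnov
   comparisons of usage distributions.

A first-class synthetic-data generator plants miRNA families, tandem
arrays, duplicated clusters, arm biases and a 29-nt background population
into simulated genomes, so every stage is scored against known truth.
`docs/methods.md` describes the models, defaults and limitations.

## Worked example

Run the bundled two-species synthetic study end to end:

```bash
mirdup run-all --seed 1 --out results/study
```

which prints the run report:

```json
{
  "calls": 64,
  "clusters": 12,
  "config_digest": "82db3392ae84",
  "families": 10,
  "retained_reads": 5756,
  "seed": 1,
  "stacks": 1729,
  "switched": 3,
  "total_reads": 5756
}
```

Reading it: the simulator planted 10 miRNA families (32 loci per
species, copy numbers 1–6, one two-family cluster duplicated onto two
scaffolds) and ~5,800 reads; the pipeline retained 64 calls across both
species, grouped them into exactly the 10 planted families, found 12
genomic clusters (the duplicated cluster plus the tandem arrays in each
species), and called arm switching for precisely the 3 families planted
with opposing 10-fold arm biases. `results/study/` contains per-species
GFF3/BED annotations, the copy-number matrix, cluster and arm-usage
tables, and a KS summary; every file header echoes the seed and config
digest, and reruns are byte-identical.

Individual stages are available both as library functions
(`mirdup.preprocess`, `mirdup.mapping`, `mirdup.hairpin`,
`mirdup.annotation`, `mirdup.homology`, `mirdup.clusters`, `mirdup.arms`,
`mirdup.synthetic`) and as CLI subcommands
(`simulate`, `preprocess`, `map`, `annotate`, `homology`, `clusters`,
`arms`) operating on standard FASTA/FASTQ/TSV files.

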