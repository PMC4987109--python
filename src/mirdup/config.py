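"""Configuration types for every pipeline stage.

All stages take a small frozen-ish dataclass so that thresholds (read-depth
cut-off, 5'-homogeneity, per-nucleotide folding energy, identity gates,
cluster gap) are visible and versioned in one place.  Validation happens in
``__post_init__``; invalid values raise ``ValueError`` immediately.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


# Illumina TruSeq small-RNA 3' adapter
TRUSEQ_SMALLRNA_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass
class SimConfig:
    """Parameters of the synthetic study: genome, planted loci and reads.

    The defaults describe the simulated study conditions: a multi-scaffold
    genome carrying ten miRNA families with one to six copies each, tandem
    arrays for the larger families, one two-family cluster duplicated onto
    two scaffolds, a 22-nt mature read population with a 3'-arm bias plus a
    29-nt background population at 30% of reads, per-copy sequence
    divergence of 5% and a 20% chance of a +/-1 nt 5'-end offset per read.
    """

    seed: int = 0
    species: str = "simA"
    n_scaffolds: int = 5
    scaffold_length: int = 300_000
    gc_fraction: float = 0.35
    n_families: int = 10
    copies_per_family: list[int] = field(
        default_factory=lambda: [1, 3, 1, 2, 2, 3, 4, 5, 6, 1]
    )
    tandem_gap: int = 2_000
    n_duplicated_clusters: int = 1
    # family label -> copies per cluster instance; each duplicated cluster is
    # planted twice, so a family listed here has 2x this many copies in total
    cluster_composition: dict[str, int] = field(
        default_factory=lambda: {"fam1": 1, "fam2": 3}
    )
    divergence_rate: float = 0.05
    mature_length: int = 22
    loop_length: int = 15
    # stem imperfections per planted hairpin: real pre-miRNA duplexes are
    # never perfect palindromes, and a perfect stem would let one arm's
    # reads map antisense onto the other arm
    stem_bulges: int = 2
    # minimum spacing between planted units, so independent loci do not
    # chain into spurious genomic clusters (loci of one genuine cluster or
    # tandem array sit tandem_gap apart instead)
    unit_spacing: int = 60_000
    reads_mu: float = 4.0
    reads_sigma: float = 0.4
    arm_bias_5p: float = 0.25
    arm_bias_per_family: dict[str, float] = field(default_factory=dict)
    jitter_prob: float = 0.2
    background_fraction: float = 0.30
    adapter: str = TRUSEQ_SMALLRNA_ADAPTER
    raw_read_length: int = 100
    minus_strand_prob: float = 0.0

    def __post_init__(self) -> None:
        for name in ("gc_fraction", "divergence_rate", "arm_bias_5p",
                     "jitter_prob", "background_fraction", "minus_strand_prob"):
            v = getattr(self, name)
            _check(0.0 <= v <= 1.0, f"{name} must be in [0,1], got {v}")
        for name in ("n_scaffolds", "scaffold_length", "n_families",
                     "tandem_gap", "mature_length", "raw_read_length"):
            _check(getattr(self, name) > 0, f"{name} must be positive")
        _check(self.loop_length >= 3, "loop_length must be >= 3")
        _check(len(self.copies_per_family) == self.n_families,
               "copies_per_family must have n_families entries")
        _check(all(c >= 1 for c in self.copies_per_family),
               "copies_per_family entries must be >= 1")
        _check(self.n_duplicated_clusters >= 0, "n_duplicated_clusters >= 0")
        fams = {f"fam{i + 1}" for i in range(self.n_families)}
        for lab, cnt in self.cluster_composition.items():
            _check(lab in fams, f"cluster family {lab!r} not among families")
            _check(cnt >= 1, "cluster composition counts must be >= 1")
        _check(self.adapter != "", "adapter must be non-empty")


@dataclass
class TrimConfig:
    """Adapter trimming and length retention.

    ``min_length`` defaults to 18 because the study retains reads longer
    than 17 bp.
    """

    adapter: str = TRUSEQ_SMALLRNA_ADAPTER
    min_overlap: int = 3
    min_length: int = 18
    max_length: int | None = None

    def __post_init__(self) -> None:
        _check(self.min_length >= 1, "min_length must be >= 1")
        _check(len(self.adapter) > 0, "adapter must be non-empty")
        _check(self.min_overlap >= 1, "min_overlap must be >= 1")


@dataclass
class MapConfig:
    """Exact-match, best-stratum, multi-locus mapping contract.

    ``max_mismatches`` and ``max_loci`` mirror bowtie's -n and -m: reads
    whose best stratum contains more than ``max_loci`` placements are
    discarded as multimappers; all placements in the best stratum are
    reported otherwise.
    """

    max_mismatches: int = 0
    max_loci: int = 5
    k: int = 12
    merge_gap: int = 30

    def __post_init__(self) -> None:
        _check(self.max_mismatches >= 0, "max_mismatches must be >= 0")
        _check(self.max_loci >= 1, "max_loci must be >= 1")
        _check(self.k >= 4, "index word length k must be >= 4")
        _check(self.merge_gap >= 0, "merge_gap must be >= 0")


# stacking energies (kcal/mol) per closing-pair class; a deliberately
# simplified model: every stacked pair contributes by the stronger of the
# two pair types involved
DEFAULT_STACK_ENERGY = {"GC": -3.0, "AU": -2.0, "GU": -1.0}


@dataclass
class FoldConfig:
    """Secondary-structure prediction and hairpin retention rules.

    ``mfe_per_nt_max`` is the per-nucleotide folding-energy retention
    threshold (kcal/mol/nt): a candidate is kept when its energy divided by
    its length is at or below -0.2, i.e. at least 0.2 kcal/mol of predicted
    stability per nucleotide.
    """

    min_loop: int = 3
    energy_model: str = "pair_count"  # or "stacking"
    pair_energy: float = -1.0
    stack_energy: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STACK_ENERGY)
    )
    mfe_per_nt_max: float = -0.2
    min_mature_paired: int = 14
    # maximal unpaired span between mature and star: pre-miRNA loops run
    # ~3-25 nt, so a putative star further away is not a Dicer duplex
    max_duplex_gap: int = 35
    flank: int = 70

    def __post_init__(self) -> None:
        _check(self.min_loop >= 3, "min_loop must be >= 3")
        _check(self.mfe_per_nt_max < 0, "mfe_per_nt_max must be negative")
        _check(self.energy_model in ("pair_count", "stacking"),
               f"unknown energy model {self.energy_model!r}")
        _check(self.pair_energy < 0, "pair_energy must be negative")
        _check(self.min_mature_paired >= 0, "min_mature_paired must be >= 0")


@dataclass
class FilterConfig:
    """The three annotation retention criteria.

    A candidate is discarded when it has fewer than ``min_reads`` reads,
    when less than ``min_homogeneity`` of the dominant mature's reads share
    the modal 5' end, or when the dominant mature matches more than
    ``max_cross_loci`` genomic loci at up to ``cross_mismatch``
    substitutions.
    """

    min_reads: int = 10
    min_homogeneity: float = 0.5
    max_cross_loci: int = 10
    cross_mismatch: int = 2

    def __post_init__(self) -> None:
        _check(self.min_reads >= 1, "min_reads must be >= 1")
        _check(0.0 < self.min_homogeneity <= 1.0,
               "min_homogeneity must be in (0,1]")
        _check(self.max_cross_loci >= 1, "max_cross_loci must be >= 1")
        _check(self.cross_mismatch >= 0, "cross_mismatch must be >= 0")


@dataclass
class AlignParams:
    """Local-alignment scoring and homology-search gates.

    Match/mismatch (+2/-3), word size 4 and the 70% identity gate follow
    standard short-nucleotide BLASTN settings; gap open/extend (5/2) are the
    classical companions of that scheme.  ``seed_length`` is the exact-word
    length used to anchor genome scans (word_size 4 is the scoring/reference
    comparison setting and is far too unselective to enumerate anchors in a
    genome); E-value gating via Karlin-Altschul statistics is optional and
    ``ka_K`` is a documented heuristic, not ground truth.
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 4
    min_identity: float = 0.70
    evalue_max: float | None = 0.1
    ka_K: float = 0.71
    seed_length: int = 11
    extend_window: int = 200
    arm_coverage_min: float = 0.90
    # orthologs are judged on the full precursor alignment, not a short
    # high-identity island: the alignment must span most of the query
    precursor_coverage_min: float = 0.75

    def __post_init__(self) -> None:
        _check(self.match > 0 > self.mismatch, "need match > 0 > mismatch")
        _check(0.0 < self.min_identity <= 1.0, "min_identity must be in (0,1]")
        _check(self.gap_open >= 0 and self.gap_extend >= 0,
               "gap penalties must be non-negative")
        _check(self.seed_length >= self.word_size, "seed_length >= word_size")


@dataclass
class ClusterConfig:
    """Genomic clustering of miRNA loci.

    ``max_gap`` (50 kb) is the only cluster span reported for the spider's
    tandem mir-3791 expansion and doubles as the chaining distance;
    ``end_flag_distance`` marks clusters that sit close enough to a scaffold
    end to be possible assembly fragments.
    """

    max_gap: int = 50_000
    min_members: int = 2
    end_flag_distance: int = 10_000
    composition_jaccard_min: float = 0.5

    def __post_init__(self) -> None:
        _check(self.max_gap > 0, "max_gap must be positive")
        _check(self.min_members >= 1, "min_members must be >= 1")
        _check(0.0 < self.composition_jaccard_min <= 1.0,
               "composition_jaccard_min must be in (0,1]")
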