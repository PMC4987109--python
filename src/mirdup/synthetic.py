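"""Synthetic genomes and small-RNA reads with known miRNA ground truth.

The generator plants hairpin loci organized in families, tandem arrays and
duplicated two-region clusters into random-background scaffolds, then
simulates a small-RNA library over them: 22-nt mature reads with a per-locus
5p/3p arm bias and occasional +/-1 nt 5'-end offsets, adapter read-through
padded to the raw read length, and a 29-nt background population emulating
the piRNA-sized fraction of an embryonic library.  Everything is a pure
function of (seed, config), so identical inputs give byte-identical FASTA,
FASTQ and truth files.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from mirdup.config import SimConfig
from mirdup.seqio import BedInterval, FastqRecord, revcomp, write_bed6, write_fasta, write_fastq

BASES = np.array(list("ACGT"))


class CapacityError(ValueError):
    """Planted loci do not fit in the configured scaffolds."""


def _rng(seed: int, *streams: str) -> np.random.Generator:
    ids = [seed] + [zlib.crc32(s.encode()) & 0x7FFFFFFF for s in streams]
    return np.random.default_rng(np.random.SeedSequence(ids))


@dataclass
class PlantedLocus:
    """Ground truth for one planted hairpin copy.

    ``start``/``end`` are 0-based half-open genomic coordinates of the full
    hairpin; mature sequences are given in the sense of the transcript
    (reverse-complemented relative to the + strand when ``strand`` is '-').
    """

    family: str
    copy_id: int
    scaffold: str
    start: int
    end: int
    strand: str
    mature5p_seq: str
    mature3p_seq: str
    arm_bias_5p: float
    expected_reads: int

    def mature_interval(self, arm: str) -> tuple[int, int]:
        """Genomic interval of the 5p or 3p mature product."""
        m = len(self.mature5p_seq if arm == "5p" else self.mature3p_seq)
        if (arm == "5p") == (self.strand == "+"):
            return self.start, self.start + m
        return self.end - m, self.end


@dataclass
class FamilySeq:
    name: str
    mature5p: str
    hairpin: str


def _random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def make_hairpin(mature5p: str, loop_length: int, bulges: int = 0,
                 rng: np.random.Generator | None = None) -> str:
    """Construct a precursor: mature + loop + reverse complement of mature.

    ``bulges`` random unpaired bases are inserted into the 3p arm, so the
    stem still supports at least ``len(mature5p) - bulges`` base pairs.
    """
    if loop_length < 3:
        raise ValueError(f"loop_length must be >= 3, got {loop_length}")
    if len(mature5p) < 18:
        raise ValueError("mature arm must be >= 18 nt")
    rng = rng if rng is not None else np.random.default_rng(0)
    loop = _random_seq(rng, loop_length)
    arm3 = list(revcomp(mature5p))
    for _ in range(bulges):
        pos = int(rng.integers(1, len(arm3)))
        arm3.insert(pos, str(rng.choice(BASES)))
    return mature5p + loop + "".join(arm3)


def _hamming_identity(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(x == y for x, y in zip(a[:n], b[:n])) / n


def family_set(config: SimConfig) -> dict[str, FamilySeq]:
    """Family consensus hairpins, a function of the seed only.

    Derived from the seed without the species tag so that two species
    configs sharing a seed share ancestral family sequences — the premise
    of any cross-species homology comparison.  Families are resampled
    until every pair of mature arms (5p and 3p, across families) stays
    below 60% alignment similarity: planted families must be separable
    under the same mature-similarity measure the analysis clusters with,
    with margin to spare for per-copy divergence.
    """
    from mirdup.homology import mature_similarity

    rng = _rng(config.seed, "families")
    fams: dict[str, FamilySeq] = {}
    arms: list[str] = []
    m = config.mature_length
    for i in range(config.n_families):
        name = f"fam{i + 1}"
        for _ in range(200):
            mature = _random_seq(rng, m)
            hairpin = make_hairpin(mature, config.loop_length,
                                   bulges=config.stem_bulges, rng=rng)
            candidate_arms = (mature, hairpin[-m:])
            # bound both the gapped-alignment similarity and the plain
            # positional identity; the margin below the 70% clustering
            # gate must absorb the extra matches that per-copy divergence
            # and 5'-end jitter can contribute (roughly 3 of 22 positions)
            if all(mature_similarity(a, b) <= 0.55
                   and _hamming_identity(a, b) <= 0.55
                   for a in candidate_arms for b in arms):
                break
        else:  # pragma: no cover - would need absurd family counts
            raise CapacityError("cannot sample sufficiently distinct families")
        arms.extend(candidate_arms)
        fams[name] = FamilySeq(name, mature, hairpin)
    return fams


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        cur = arr[i].decode()
        others = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(others).encode()
    return arr.tobytes().decode()


def _plant_units(config: SimConfig, families: dict[str, FamilySeq]) -> list[list[str]]:
    """Groups of family labels planted together (tandem units / clusters)."""
    units: list[list[str]] = []
    cluster_fams = set(config.cluster_composition)
    for _ in range(config.n_duplicated_clusters):
        # one duplicated cluster = two instances of the same composition;
        # the least-copied family is placed internally, flanked by the rest
        members: list[str] = []
        items = sorted(config.cluster_composition.items(),
                       key=lambda kv: (-kv[1], kv[0]))
        for fam, cnt in items:
            members.extend([fam] * cnt)
        if len(members) > 2:
            members[1], members[-1] = members[-1], members[1]
        units.append(list(members))
        units.append(list(members))
    for i, fam in enumerate(families):
        if fam in cluster_fams:
            continue
        copies = config.copies_per_family[i]
        if copies >= 3:
            units.append([fam] * copies)  # tandem array
        else:
            units.extend([[fam]] * copies)  # dispersed singles
    return units


def generate_genome(config: SimConfig,
                    families: dict[str, FamilySeq] | None = None
                    ) -> tuple[dict[str, str], list[PlantedLocus]]:
    """Simulate scaffolds with planted, diverged hairpin copies.

    Returns the genome (scaffold name -> sequence) and the truth list,
    sorted by (scaffold, start).  Each copy carries independent per-base
    substitutions at ``divergence_rate``; duplicated clusters appear as two
    regions with the same family composition on different scaffolds when
    possible.
    """
    families = families if families is not None else family_set(config)
    rng = _rng(config.seed, "genome", config.species)
    scafs = {
        f"{config.species}_scaf{i + 1}": np.frombuffer(
            _random_seq(rng, config.scaffold_length, config.gc_fraction).encode(),
            dtype="S1").copy()
        for i in range(config.n_scaffolds)
    }
    names = list(scafs)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in names}
    units = _plant_units(config, families)

    hp_len = {f: len(families[f].hairpin) for f in families}
    truth: list[PlantedLocus] = []
    copy_counter = {f: 0 for f in families}

    def place(unit: list[str], scaf_hint: int) -> None:
        length = sum(hp_len[f] for f in unit) + config.tandem_gap * (len(unit) - 1)
        order = [(scaf_hint + j) % len(names) for j in range(len(names))]
        # each unit's reserved span is padded by half the spacing, so two
        # units end up at least unit_spacing apart
        margin = config.unit_spacing // 2
        for tries in range(2000):
            scaf = names[order[tries % len(names)]]
            limit = config.scaffold_length - length - 100
            if limit <= 100:
                continue
            start = int(rng.integers(100, limit))
            span = (start - margin, start + length + margin)
            if any(not (span[1] <= a or span[0] >= b) for a, b in occupied[scaf]):
                continue
            occupied[scaf].append(span)
            pos = start
            for fam in unit:
                hp = _mutate(families[fam].hairpin, config.divergence_rate, rng)
                strand = "-" if rng.random() < config.minus_strand_prob else "+"
                genomic = revcomp(hp) if strand == "-" else hp
                arr = scafs[scaf]
                arr[pos:pos + len(hp)] = np.frombuffer(genomic.encode(), dtype="S1")
                m = config.mature_length
                bias = config.arm_bias_per_family.get(fam, config.arm_bias_5p)
                n_reads = max(1, round(float(rng.lognormal(config.reads_mu,
                                                           config.reads_sigma))))
                copy_counter[fam] += 1
                truth.append(PlantedLocus(
                    family=fam, copy_id=copy_counter[fam], scaffold=scaf,
                    start=pos, end=pos + len(hp), strand=strand,
                    mature5p_seq=hp[:m], mature3p_seq=hp[-m:],
                    arm_bias_5p=bias, expected_reads=n_reads))
                pos += len(hp) + config.tandem_gap
            return
        raise CapacityError(
            f"could not place unit of {len(unit)} loci ({length} nt) "
            f"in {config.n_scaffolds} x {config.scaffold_length} nt scaffolds")

    # spread cluster instances over distinct scaffolds via the hint
    for i, unit in enumerate(units):
        place(unit, i)

    genome = {n: arr.tobytes().decode() for n, arr in scafs.items()}
    truth.sort(key=lambda t: (t.scaffold, t.start))
    return genome, truth


def simulate_reads(genome: dict[str, str], truth: list[PlantedLocus],
                   config: SimConfig) -> list[FastqRecord]:
    """Simulate raw small-RNA reads over the planted loci.

    Per locus, exactly ``expected_reads`` mature reads are emitted; each
    derives from the 5p arm with probability ``arm_bias_5p`` (else 3p) and
    its 5' end is offset by +/-1 nt with probability ``jitter_prob``.  The
    3' adapter is appended and the read padded with random sequence to
    ``raw_read_length``.  ``background_fraction`` of all reads are 29-nt
    slices at uniform genome positions.  Read ids encode the source locus.
    """
    if not truth:
        raise ValueError("truth must contain at least one planted locus")
    rng = _rng(config.seed, "reads", config.species)
    reads: list[FastqRecord] = []

    def emit(rid: str, insert: str) -> None:
        raw = insert + config.adapter
        if len(raw) < config.raw_read_length:
            raw += _random_seq(rng, config.raw_read_length - len(raw))
        raw = raw[:config.raw_read_length]
        reads.append(FastqRecord(rid, raw, "I" * len(raw)))

    n_mirna = 0
    for loc in truth:
        m = config.mature_length
        for i in range(loc.expected_reads):
            arm = "5p" if rng.random() < loc.arm_bias_5p else "3p"
            s, e = loc.mature_interval(arm)
            if rng.random() < config.jitter_prob:
                off = 1 if rng.random() < 0.5 else -1
                # a 5'-end offset moves the genomic window against the
                # transcript orientation on the - strand
                off = off if loc.strand == "+" else -off
                s, e = s + off, e + off
            s = max(0, min(s, len(genome[loc.scaffold]) - m))
            insert = genome[loc.scaffold][s:s + m]
            if loc.strand == "-":
                insert = revcomp(insert)
            emit(f"mi|{loc.family}|{loc.copy_id}|{arm}|{i}", insert)
            n_mirna += 1

    if config.background_fraction > 0:
        frac = config.background_fraction
        n_bg = round(n_mirna * frac / (1.0 - frac))
        names = list(genome)
        for i in range(n_bg):
            scaf = names[int(rng.integers(len(names)))]
            pos = int(rng.integers(0, len(genome[scaf]) - 29))
            emit(f"bg|{i}", genome[scaf][pos:pos + 29])
    return reads


def write_truth(truth: list[PlantedLocus], out_dir: str | Path,
                prefix: str = "truth") -> None:
    """Write the ground truth as a TSV sidecar plus a BED6 of planted loci."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cols = ("family\tcopy_id\tscaffold\tstart\tend\tstrand\tmature5p_seq"
            "\tmature3p_seq\tarm_bias_5p\texpected_reads")
    with open(out_dir / f"{prefix}.tsv", "w") as fh:
        fh.write(cols + "\n")
        for t in truth:
            fh.write(f"{t.family}\t{t.copy_id}\t{t.scaffold}\t{t.start}\t{t.end}"
                     f"\t{t.strand}\t{t.mature5p_seq}\t{t.mature3p_seq}"
                     f"\t{t.arm_bias_5p:g}\t{t.expected_reads}\n")
    write_bed6(
        [BedInterval(t.scaffold, t.start, t.end, f"{t.family}.{t.copy_id}",
                     t.expected_reads, t.strand) for t in truth],
        out_dir / f"{prefix}.bed")


def simulate_to_dir(config: SimConfig, out_dir: str | Path) -> tuple[dict[str, str], list[PlantedLocus]]:
    """Run the full simulation and write genome.fa, reads.fq and truth files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genome, truth = generate_genome(config)
    reads = simulate_reads(genome, truth, config)
    write_fasta(genome, out_dir / "genome.fa")
    write_fastq(reads, out_dir / "reads.fq")
    write_truth(truth, out_dir)
    return genome, truth


def species_pair(config: SimConfig, species: tuple[str, str] = ("A", "B"),
                 switch_families: tuple[str, ...] = (),
                 switch_bias: float = 10 / 11) -> tuple[SimConfig, SimConfig]:
    """Two species configs sharing ancestral families.

    ``switch_families`` are planted with opposing arm bias in the two
    species (``switch_bias`` 5p in the first, ``1 - switch_bias`` in the
    second — a >10-fold usage flip at the default), every other family
    keeps the shared default bias.
    """
    bias_a = {f: switch_bias for f in switch_families}
    bias_b = {f: 1.0 - switch_bias for f in switch_families}
    return (replace(config, species=species[0], arm_bias_per_family=bias_a),
            replace(config, species=species[1], arm_bias_per_family=bias_b))
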