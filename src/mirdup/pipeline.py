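"""End-to-end orchestration: simulate -> preprocess -> map -> discover ->
annotate -> homology -> clusters -> arms.

`run_species` is the per-species read pipeline (usable on real FASTQ +
FASTA inputs); `run_study` runs the full two-species synthetic study the
package is tested against, returning every intermediate needed for
scoring.  All outputs are deterministic given (seed, config); file headers
echo both.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from mirdup import annotation, arms, clusters, evaluate, hairpin, homology, mapping, preprocess
from mirdup.config import (AlignParams, ClusterConfig, FilterConfig,
                           FoldConfig, MapConfig, SimConfig, TrimConfig)
from mirdup.seqio import BedInterval, FastqRecord, Gff3Feature, write_bed6, write_gff3
from mirdup.synthetic import (PlantedLocus, generate_genome, simulate_reads,
                              species_pair)


@dataclass
class StudyConfig:
    """One config for the whole synthetic study."""

    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)
    trim: TrimConfig | None = None
    map: MapConfig = field(default_factory=MapConfig)
    # stacking energies resolve the max-pairing model's degenerate optima
    # toward the contiguous duplex helix, so discovery uses that model
    fold: FoldConfig = field(
        default_factory=lambda: FoldConfig(energy_model="stacking"))
    filters: FilterConfig = field(default_factory=FilterConfig)
    align: AlignParams = field(default_factory=AlignParams)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    switch_families: tuple[str, ...] = ("fam3", "fam5", "fam10")

    def __post_init__(self) -> None:
        import dataclasses
        self.sim = dataclasses.replace(self.sim, seed=self.seed)
        if self.trim is None:
            self.trim = TrimConfig(adapter=self.sim.adapter)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class SpeciesResult:
    species: str
    genome: dict[str, str]
    truth: list[PlantedLocus]
    stats: preprocess.PreprocessStats
    length_histogram: dict[int, int]
    length_modes: list[int]
    stacks: list[mapping.ReadStack]
    calls: list[annotation.MiRNACall]
    rejections: list[annotation.Rejection]


def run_species(genome: dict[str, str], reads: list[FastqRecord],
                cfg: StudyConfig, species: str,
                truth: list[PlantedLocus] | None = None) -> SpeciesResult:
    """Reads-to-calls pipeline for one species."""
    retained, stats = preprocess.preprocess(reads, cfg.trim)
    index = mapping.GenomeIndex(genome, cfg.map.k)
    results = mapping.map_reads(retained, index, cfg.map)
    hits = [h for r in results if r.status == "mapped" for h in r.hits]
    hist, modes = mapping.mapped_length_histogram(hits)
    stacks = mapping.build_stacks(hits, cfg.map.merge_gap)
    qualified, _rej_cands = hairpin.discover(
        stacks, genome, cfg.fold, min_stack_reads=cfg.filters.min_reads)
    calls, rejections = annotation.annotate(qualified, genome, cfg.filters)
    return SpeciesResult(species, genome, truth or [], stats, hist, modes,
                         stacks, calls, rejections)


def _assign_families(results: list[SpeciesResult],
                     params: AlignParams) -> dict[str, list[homology.FamilyLocus]]:
    """Cluster calls of all species into families and label the calls."""
    loci = []
    call_of: dict[str, annotation.MiRNACall] = {}
    for res in results:
        for i, call in enumerate(res.calls):
            matures = [m.sequence for m in (call.mature5p, call.mature3p) if m]
            lid = f"{res.species}:{call.scaffold}:{call.start}:{call.hairpin.strand}:{i}"
            call_of[lid] = call
            loci.append(homology.FamilyLocus(
                lid, res.species, call.scaffold, call.start, call.end,
                call.hairpin.strand, matures))
    families = homology.cluster_families(loci, params)
    for fam, members in families.items():
        for member in members:
            call_of[member.id].family = fam
    for res in results:
        annotation.name_calls(res.calls, prefix=res.species.lower())
    return families


def _queries_from_calls(results: list[SpeciesResult]) -> list[homology.QueryHairpin]:
    """Precursor queries for the ortholog search.

    The candidate window carries flanking sequence with no counterpart in
    another genome, so each query is trimmed to the precursor proper: the
    span from the mature to the star interval (plus a 3-nt pad).
    """
    queries = []
    for res in results:
        for call in res.calls:
            hp = call.hairpin
            mature = hp.mature_interval
            star = hp.star_interval
            lo = max(0, min(mature[0], star[0]) - 3)
            hi = min(len(hp.sequence), max(mature[1], star[1]) + 3)
            m5, m3 = (mature, star) if hp.mature_arm == "5p" else (star, mature)
            queries.append(homology.QueryHairpin(
                id=f"{res.species}:{call.name}", seq=hp.sequence[lo:hi],
                mature5p=(m5[0] - lo, m5[1] - lo),
                mature3p=(m3[0] - lo, m3[1] - lo), family=call.family))
    return queries


def _family_usage_table(res: SpeciesResult) -> list[arms.ArmUsageRecord]:
    """Family-level arm usage for one species.

    Reads from paralogous copies multimap and are counted fully at every
    placement, so per-locus arm counts double-count shared matures.  At the
    family level each distinct read is counted once per arm; a family is
    usable when at least one member mature on either arm is unique in the
    genome.
    """
    by_family: dict[str, dict[str, set[str]]] = {}
    uniq: dict[str, dict[str, bool]] = {}
    for call in res.calls:
        fam = call.family or call.name
        slot = by_family.setdefault(fam, {"5p": set(), "3p": set()})
        u = uniq.setdefault(fam, {"5p": False, "3p": False})
        for arm_name, product in (("5p", call.mature5p), ("3p", call.mature3p)):
            if product is None:
                continue
            slot[arm_name].update(product.read_ids)
            u[arm_name] = u[arm_name] or product.unique_in_genome
    table = []
    for fam in sorted(by_family):
        c5, c3 = len(by_family[fam]["5p"]), len(by_family[fam]["3p"])
        if c5 + c3 == 0:
            continue
        rec = arms.arm_usage(arms.ArmCounts(
            fam, res.species, c5, c3, uniq[fam]["5p"], uniq[fam]["3p"],
            family=fam))
        if rec.reliability != "excluded":
            table.append(rec)
    return table


@dataclass
class StudyResult:
    config: StudyConfig
    species: list[SpeciesResult]
    families: dict[str, list[homology.FamilyLocus]]
    matrix: homology.CopyNumberMatrix
    hits_by_species: dict[str, list[homology.OrthologHit]]
    clusters_by_species: dict[str, list[clusters.GenomicCluster]]
    duplicated_groups: dict[str, list[list[clusters.GenomicCluster]]]
    tandem_by_species: dict[str, dict[str, list]]
    comparison: arms.SpeciesComparison | None
    report: dict[str, int | float | str]


def run_study(cfg: StudyConfig) -> StudyResult:
    """Simulate two species sharing families and run every stage."""
    cfg_a, cfg_b = species_pair(cfg.sim, species=("A", "B"),
                                switch_families=cfg.switch_families)
    results = []
    for sp_cfg in (cfg_a, cfg_b):
        genome, truth = generate_genome(sp_cfg)
        reads = simulate_reads(genome, truth, sp_cfg)
        results.append(run_species(genome, reads, cfg, sp_cfg.species, truth))

    families = _assign_families(results, cfg.align)
    queries = _queries_from_calls(results)
    genomes = {res.species: res.genome for res in results}
    matrix, hits_by_species = homology.species_copy_number(
        queries, genomes, cfg.align)

    clusters_by_species: dict[str, list[clusters.GenomicCluster]] = {}
    duplicated: dict[str, list[list[clusters.GenomicCluster]]] = {}
    tandems: dict[str, dict[str, list]] = {}
    fam_of_query = {q.id: q.family for q in queries}
    for sp, hits in hits_by_species.items():
        loci = [clusters.MiRNALocus(fam_of_query[h.query_id] or h.query_id,
                                    sp, h.scaffold, h.start, h.end, h.strand)
                for h in hits]
        found, _singles = clusters.detect_clusters(loci, cfg.cluster)
        clusters_by_species[sp] = found
        duplicated[sp] = clusters.find_duplicated_clusters(found, cfg.cluster)
        tandems[sp] = clusters.tandem_arrays(loci, cfg.cluster)

    comparison = None
    usage_tables = [_family_usage_table(res) for res in results]
    if usage_tables[0] and usage_tables[1]:
        try:
            comparison = arms.compare_species(usage_tables[0], usage_tables[1])
        except ValueError:
            comparison = None

    report = {
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "total_reads": sum(r.stats.total_reads for r in results),
        "retained_reads": sum(r.stats.retained_reads for r in results),
        "stacks": sum(len(r.stacks) for r in results),
        "calls": sum(len(r.calls) for r in results),
        "families": len(families),
        "clusters": sum(len(v) for v in clusters_by_species.values()),
        "switched": sum(s.status == "switched" for s in comparison.switches)
        if comparison else 0,
    }
    return StudyResult(cfg, results, families, matrix, hits_by_species,
                       clusters_by_species, duplicated, tandems, comparison,
                       report)


def score_study(study: StudyResult) -> dict[str, float | bool | int]:
    """Score a synthetic study against its own planted truth."""
    truth_by_species = {r.species: r.truth for r in study.species}
    per_species = [evaluate.score_calls(r.calls, r.truth) for r in study.species]
    n_planted = sum(s.n_planted for s in per_species)
    n_matched = sum(s.n_truth_matched for s in per_species)
    n_called = sum(s.n_called for s in per_species)
    n_called_matched = sum(s.n_calls_matched for s in per_species)
    cluster_fams = set(study.config.sim.cluster_composition)
    dup_ok = any(
        evaluate.cluster_recovered(groups, truth_by_species[sp], cluster_fams)
        for sp, groups in study.duplicated_groups.items())
    switch_truth = set(study.config.switch_families)
    called_switch_fams = set()
    false_switches = 0
    if study.comparison:
        fam_by_locus = {}
        for r in study.species:
            for c in r.calls:
                t = evaluate.match_call(c.scaffold, c.start, c.end, r.truth)
                if t is not None and c.family:
                    fam_by_locus[c.family] = t.family
        for call in study.comparison.switches:
            if call.status != "switched":
                continue
            planted_fam = fam_by_locus.get(call.mirna)
            if planted_fam in switch_truth:
                called_switch_fams.add(planted_fam)
            else:
                false_switches += 1
    return {
        "recall": n_matched / n_planted if n_planted else 1.0,
        "precision": n_called_matched / n_called if n_called else 1.0,
        "matrix_exact": evaluate.matrix_exact(study.hits_by_species,
                                              truth_by_species),
        "duplicated_cluster_recovered": dup_ok,
        "switches_detected": len(called_switch_fams),
        "switches_planted": len(switch_truth),
        "false_switches": false_switches,
    }


def write_outputs(study: StudyResult, out_dir: str | Path) -> None:
    """Write GFF3 + BED per species, the matrix TSV, cluster and arm TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"mirdup seed={study.config.seed} config={study.config.digest()}"
    for res in study.species:
        feats = []
        beds = []
        for call in res.calls:
            hp = call.hairpin
            feats.append(Gff3Feature(hp.scaffold, "pre_miRNA", hp.start,
                                     hp.end, hp.strand, {"ID": call.name}))
            for m in (call.mature5p, call.mature3p):
                if m and m.interval:
                    feats.append(Gff3Feature(
                        hp.scaffold, "miRNA", m.interval[0], m.interval[1],
                        hp.strand, {"ID": f"{call.name}-{m.arm}",
                                    "Parent": call.name}))
            beds.append(BedInterval(hp.scaffold, hp.start, hp.end,
                                    call.name, call.total_reads, hp.strand))
        write_gff3(feats, out / f"calls_{res.species}.gff3", header)
        write_bed6(beds, out / f"calls_{res.species}.bed", header)
        with open(out / f"length_histogram_{res.species}.tsv", "w") as fh:
            fh.write(f"#{header}\nlength\treads\n")
            for length, n in res.length_histogram.items():
                fh.write(f"{length}\t{n}\n")
    with open(out / "copy_number_matrix.tsv", "w") as fh:
        fh.write(f"#{header}\n")
        study.matrix.counts.to_csv(fh, sep="\t", index_label="family")
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(f"#{header}\nspecies\tscaffold\tstart\tend\tspan\tcomposition\n")
        for sp, cls in sorted(study.clusters_by_species.items()):
            for c in cls:
                comp = ",".join(f"{f}:{n}" for f, n in sorted(c.composition.items()))
                fh.write(f"{sp}\t{c.scaffold}\t{c.start}\t{c.end}\t{c.span}\t{comp}\n")
    if study.comparison:
        with open(out / "arm_usage_comparison.tsv", "w") as fh:
            fh.write(f"#{header}\nfamily\tlog_ratio_A\tlog_ratio_B\tstatus\n")
            for fam, la, lb, status in study.comparison.rows:
                fh.write(f"{fam}\t{la:.4f}\t{lb:.4f}\t{status}\n")
        ks = study.comparison.ks
        with open(out / "ks_summary.tsv", "w") as fh:
            fh.write(f"#{header}\nD\tp\tn1\tn2\n"
                     f"{ks.D:.6f}\t{ks.p:.3e}\t{ks.n1}\t{ks.n2}\n")
    with open(out / "run_report.json", "w") as fh:
        json.dump(study.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
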