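"""End-to-end orchestration: simulate -> map -> call -> genotype -> stats.

A run is fully specified by a :class:`RunConfig` (serializable to YAML)
and a single seed; identical config+seed gives byte-identical artifacts.
Output layout under the run directory:

* ``reads/``  — wild-type/composite FASTA, GFF3, paired FASTQ, truth JSON
* ``aln/``    — SAM alignments
* ``calls/``  — insertion VCF/TSV, deletion BED, locus genotype TSV
* ``report/`` — consolidated JSON report, segregation TSV, run log, config
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import caller as caller_mod
from . import depth as depth_mod
from .architecture import InsertionArchitecture, TruthSet, apply_architecture, build_wt_reference
from .genome import VECTOR_CONTIG, ReferenceGenome, VectorConstruct
from .mapper import MapParams, SeedIndex
from .pairs import align_pairs, class_counts, deletion_spanning_gaps, unique_records
from .samio import write_sam
from .segregation import (
    estimate_penetrance,
    packaged_colony_tables,
    segregation_report,
    test_homozygote_glaucoma,
    test_mendelian_positive,
)
from .simulate import Genotype, ReadPairs, ReadSimParams, simulate_colony, simulate_reads

logger = logging.getLogger("tglocate")


@dataclass(frozen=True)
class CallerParams:
    cluster_window: int = 1100  # ~2x insert_mean: chimeric localization uncertainty
    min_support: int = 3


@dataclass(frozen=True)
class DepthParams:
    window: int = 200
    hom_max: float = 0.2
    het_band: tuple[float, float] = (0.3, 0.7)
    min_windows: int = 3
    min_z: float = 5.0


@dataclass(frozen=True)
class ColonyParams:
    n_offspring: int = 433
    penetrance: float = 0.75


@dataclass
class RunConfig:
    """All knobs of one pipeline run."""

    seed: int = 0
    contig: str = "chr1"
    contig_length: int = 500_000
    vector_length: int = 7000
    genotype: str = "HOM"
    architecture: InsertionArchitecture = field(default_factory=InsertionArchitecture)
    sim: ReadSimParams = field(default_factory=ReadSimParams)
    mapping: MapParams = field(default_factory=MapParams)
    caller: CallerParams = field(default_factory=CallerParams)
    depth: DepthParams = field(default_factory=DepthParams)
    colony: ColonyParams = field(default_factory=ColonyParams)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("architecture", InsertionArchitecture),
            ("sim", ReadSimParams),
            ("mapping", MapParams),
            ("caller", CallerParams),
            ("depth", DepthParams),
            ("colony", ColonyParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                d = kwargs[key]
                if key == "depth" and "het_band" in d and d["het_band"] is not None:
                    d["het_band"] = tuple(d["het_band"])
                kwargs[key] = sub(**d)
        return cls(**kwargs)

    def seeds(self) -> dict[str, int]:
        """Independent child seeds derived from the top-level seed."""
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ("reference", "vector", "reads", "colony")
        return {n: int(s % (2**31)) for n, s in zip(names, state)}


@dataclass
class RunReport:
    """Everything a run computed, traceable to its output files."""

    config: RunConfig
    genotype: str
    pair_classes: dict[str, int]
    insertion_calls: list[caller_mod.InsertionCall]
    deletion_calls: list[depth_mod.DeletionCall]
    copy_number: caller_mod.CopyNumberEstimate | None
    locus_genotype: depth_mod.LocusGenotype | None
    segregation: dict
    truth_metrics: dict | None = None

    def summary(self) -> str:
        lines = [f"tglocate run (genotype {self.genotype})"]
        lines.append(f"  pair classes: {self.pair_classes}")
        lines.append(f"  insertion calls: {len(self.insertion_calls)}")
        for c in self.insertion_calls:
            lines.append(
                f"    {c.contig}:{c.breakpoint_lo}-{c.breakpoint_hi} "
                f"vector {c.vector_interval} ({c.vector_orientation}) "
                f"splits={c.n_split} pairs={c.n_pairs} [{c.resolution}]"
            )
        lines.append(f"  deletion calls: {len(self.deletion_calls)}")
        for d in self.deletion_calls:
            genes = ", ".join(f"{n} ({f:.0%})" for n, f in d.genes) or "-"
            lines.append(
                f"    {d.contig}:{d.start}-{d.end} {d.zygosity} depth={d.mean_norm_depth:.2f} genes: {genes}"
            )
        if self.copy_number is not None:
            lines.append(
                f"  transgene copies/diploid: {self.copy_number.copies_per_diploid:.2f} "
                f"(vector {self.copy_number.vector_mean_depth:.1f}x / "
                f"genome {self.copy_number.genome_mean_depth:.1f}x)"
            )
        if self.locus_genotype is not None:
            lines.append(
                f"  {self.locus_genotype.locus}: {self.locus_genotype.copies} copies "
                f"-> {self.locus_genotype.genotype}"
            )
        if self.truth_metrics:
            lines.append(f"  truth comparison: {self.truth_metrics}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "genotype": self.genotype,
            "pair_classes": self.pair_classes,
            "insertion_calls": [dataclasses.asdict(c) for c in self.insertion_calls],
            "deletion_calls": [dataclasses.asdict(d) for d in self.deletion_calls],
            "copy_number": dataclasses.asdict(self.copy_number) if self.copy_number else None,
            "locus_genotype": (
                dataclasses.asdict(self.locus_genotype) if self.locus_genotype else None
            ),
            "segregation": self.segregation,
            "truth_metrics": self.truth_metrics,
        }


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                logger.error("stage %s failed: %s", name, exc)
                raise StageError(name, exc) from exc
            logger.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapper

    return deco


def simulate_stage(
    config: RunConfig, outdir: Path | None = None
) -> tuple[ReferenceGenome, VectorConstruct, str | None, TruthSet, ReadPairs]:
    """Build references + haplotypes, simulate reads, write artifacts."""
    seeds = config.seeds()
    ref = build_wt_reference(
        config.contig_length, config.architecture, seeds["reference"], config.contig
    )
    vector = VectorConstruct.random(config.vector_length, seed=seeds["vector"])
    tg_hap, truth = apply_architecture(ref, vector, config.architecture, config.contig)
    genotype = Genotype[config.genotype]
    sim = dataclasses.replace(config.sim, seed=seeds["reads"])
    reads = simulate_reads(
        ref.contigs[config.contig],
        tg_hap if genotype is not Genotype.WT else None,
        genotype,
        sim,
        config.contig,
    )
    if outdir is not None:
        rd = outdir / "reads"
        rd.mkdir(parents=True, exist_ok=True)
        ref.to_fasta(rd / "wildtype.fa")
        ref.with_vector(vector).to_fasta(rd / "composite.fa")
        ref.to_gff3(rd / "genes.gff3")
        truth.to_json(rd / "truth.json")
        reads.write_fastq(rd / "reads_1.fastq", rd / "reads_2.fastq")
    return ref, vector, tg_hap, truth, reads


def run_all(config: RunConfig, outdir: str | Path | None = None) -> RunReport:
    """Execute every stage in order and return the consolidated report."""
    out = Path(outdir) if outdir is not None else None
    handler = None
    if out is not None:
        (out / "report").mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "report" / "config.yaml")
        handler = logging.FileHandler(out / "report" / "run.log")
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        logger.addHandler(handler)
    logger.info("effective config: %s", dataclasses.asdict(config))
    try:
        ref, vector, tg_hap, truth, reads = _stage("simulate")(simulate_stage)(config, out)

        composite = ref.with_vector(vector)
        genotype = Genotype[config.genotype]

        @_stage("map")
        def _map():
            index = SeedIndex(composite.contigs, k=config.mapping.k)
            pairs = align_pairs(reads, index, config.mapping)
            if out is not None:
                (out / "aln").mkdir(exist_ok=True)
                contigs = {n: len(s) for n, s in composite.contigs.items()}
                write_sam(pairs, contigs, out / "aln" / "alignments.sam")
            return index, pairs

        index, pairs = _map()

        @_stage("call-insertions")
        def _call():
            evidence = caller_mod.collect_evidence(pairs)
            clusters = caller_mod.cluster_evidence(evidence, config.caller.cluster_window)
            calls = caller_mod.call_insertions(clusters, config.caller.min_support)
            if out is not None:
                (out / "calls").mkdir(exist_ok=True)
                contigs = {n: len(s) for n, s in composite.contigs.items()}
                caller_mod.write_vcf(
                    calls,
                    contigs,
                    out / "calls" / "insertions.vcf",
                    config.caller.min_support,
                    config.caller.cluster_window,
                )
                caller_mod.write_insertion_tsv(calls, out / "calls" / "insertions.tsv")
            return calls

        ins_calls = _call()

        @_stage("call-cnv")
        def _cnv():
            recs = unique_records(pairs)
            flank = config.mapping.insert_mean
            mask = [
                (c.breakpoint_lo - flank, c.breakpoint_hi + flank) for c in ins_calls
            ]
            gprof = depth_mod.compute_depth(
                recs,
                config.contig,
                config.contig_length,
                window=config.depth.window,
                mask_intervals=mask,
                edge_mask=flank,
            )
            vprof = depth_mod.compute_depth(
                recs, VECTOR_CONTIG, len(vector), window=config.depth.window
            )
            dels = depth_mod.call_deletions(
                gprof,
                hom_max=config.depth.hom_max,
                het_band=config.depth.het_band,
                min_windows=config.depth.min_windows,
                min_z=config.depth.min_z,
                spanning_gaps=deletion_spanning_gaps(pairs, config.mapping),
            )
            dels = depth_mod.annotate_overlaps(dels, ref.annotations)
            cn = None
            if gprof.norm_factor > 0:
                cn = caller_mod.estimate_transgene_copies(vprof, gprof)
            locus = depth_mod.genotype_locus_copy_number(gprof, ref.gene("ak_analog"))
            if out is not None:
                (out / "calls").mkdir(exist_ok=True)
                depth_mod.write_bed(dels, out / "calls" / "deletions.bed")
                with open(out / "calls" / "locus_genotype.tsv", "w") as fh:
                    fh.write("locus\tcopies\tgenotype\tmean_norm_depth\n")
                    fh.write(
                        f"{locus.locus}\t{locus.copies}\t{locus.genotype}\t{locus.mean_norm_depth:.4f}\n"
                    )
            return gprof, vprof, dels, cn, locus

        gprof, vprof, dels, cn, locus = _cnv()

        @_stage("segregation")
        def _seg():
            tables = dict(packaged_colony_tables())
            tables["simulated"] = simulate_colony(
                config.colony.n_offspring, config.colony.penetrance, config.seeds()["colony"]
            )
            df = segregation_report(list(tables.values()))
            if out is not None:
                df.to_csv(out / "report" / "segregation.tsv", sep="\t", index=False)
            seg = {
                label: {
                    "counts": list(t.counts),
                    "p_mendelian": test_mendelian_positive(t).p_rounded,
                    "p_homozygote_glaucoma": test_homozygote_glaucoma(t).p_rounded,
                    "penetrance": estimate_penetrance(t)[0],
                    "frac_positive": t.fraction_positive,
                    "frac_glaucoma": t.fraction_glaucoma,
                }
                for label, t in tables.items()
            }
            return seg

        seg = _seg()

        report = RunReport(
            config=config,
            genotype=config.genotype,
            pair_classes=class_counts(pairs),
            insertion_calls=ins_calls,
            deletion_calls=dels,
            copy_number=cn,
            locus_genotype=locus,
            segregation=seg,
        )
        if genotype is not Genotype.WT:
            report.truth_metrics = compare_to_truth(report, truth)
        if out is not None:
            (out / "report" / "report.json").write_text(
                json.dumps(report.to_dict(), indent=1, default=str)
            )
        return report
    except StageError:
        if out is not None:
            (out / "report" / "FAILED").write_text("see run.log\n")
        raise
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def compare_to_truth(report: RunReport, truth: TruthSet) -> dict:
    """Breakpoint errors, deletion reciprocal overlaps, genotype checks."""
    for c in report.insertion_calls:
        if c.contig != truth.contig:
            raise ValueError(f"call contig {c.contig} does not match truth {truth.contig}")
    junctions = [j for j in (truth.ins1, truth.ins2) if j is not None]
    bp_errors = []
    for j in junctions:
        if report.insertion_calls:
            best = min(
                report.insertion_calls, key=lambda c: j.breakpoint_error(c.breakpoint)
            )
            bp_errors.append(j.breakpoint_error(best.breakpoint))
        else:
            bp_errors.append(None)
    overlaps = []
    for a, b in truth.deletions:
        ro = 0.0
        for d in report.deletion_calls:
            inter = min(b, d.end) - max(a, d.start)
            if inter > 0:
                ro = max(ro, min(inter / (b - a), inter / d.length))
        overlaps.append(round(ro, 4))
    expected_copies = truth.ins2.copies * (2 if report.genotype == "HOM" else 1)
    cn_error = None
    if report.copy_number is not None and report.genotype in ("HET", "HOM"):
        cn_error = round(report.copy_number.copies_per_diploid - expected_copies, 3)
    expected_locus = {"WT": 2, "HET": 1, "HOM": 0}[report.genotype]
    return {
        "n_insertion_calls": len(report.insertion_calls),
        "breakpoint_errors": bp_errors,
        "deletion_reciprocal_overlaps": overlaps,
        "copy_number_error": cn_error,
        "locus_copies_correct": (
            report.locus_genotype is not None
            and report.locus_genotype.copies == expected_locus
        ),
    }
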