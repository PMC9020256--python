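"""End-to-end pipeline: simulate → map → call → genotype-design → segregation.

``run_pipeline`` drives the whole analysis on synthetic data: it builds a
host genome carrying the two-gene test locus, integrates the transgene
cassette (deleting the locus window), simulates a TLA library from a
viewpoint inside the transgene, maps the reads in two passes, calls the
integration site, deletion, copy number and junction sequences, designs the
three-primer genotyping assay on the reconstructed alleles, and runs the
segregation-ratio tests on offspring counts. Every stage's outputs are
persisted with content checksums, and identical config + seed reproduces a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import genotyping, integration, mapping, simulate
from .genome import Genome, GenomeSpec, IntegrationEvent, build_transgenic_allele, \
    generate_genome, make_transgene
from .io import write_fasta, write_json


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass
class PipelineConfig:
    """All pipeline knobs; every field has a default and the config
    round-trips through YAML unchanged."""

    seed: int = 0
    # synthetic genome
    chromosome_names: list[str] = field(default_factory=lambda: ["chr5", "chr8"])
    chromosome_lengths: list[int] = field(default_factory=lambda: [300_000, 120_000])
    gc_fraction: float = 0.42
    window_width: int | None = None
    # integration event (None → the genome's designated deletion window)
    deletion_start: int | None = None
    deletion_end: int | None = None
    copies: int = 1
    orientation: str = "forward"
    # TLA library
    viewpoint_element: str = "cre"
    read_pairs: int = 6_000
    read_length: int = 150
    substitution_error_rate: float = 0.0
    trans_ligation_rate: float = 0.01
    distance_decay_alpha: float = 1.0
    decay_scale_d0: float = 20_000.0
    # mapping / calling
    k: int = 21
    max_mismatch_rate: float = 0.04
    covered_fraction: float = 0.8
    min_support: int = 3
    cluster_window: int = 10
    junction_slop: int = 5
    junction_flank: int = 30
    flank_window: int = 5_000
    max_internal_ratio: float = 0.2
    # offspring tallies for the segregation stage
    n_het: int = 44
    n_wt: int = 24
    n_hom: int = 0

    def validate(self) -> None:
        if len(self.chromosome_names) != len(self.chromosome_lengths):
            raise ValueError("chromosome_names and chromosome_lengths differ in length")
        if self.read_pairs < 1:
            raise ValueError("read_pairs must be >= 1")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the aggregated report dict.

    Writes per-stage outputs plus ``report.json`` and a ``manifest.json``
    of content checksums under ``outdir``. A stage failure raises
    :class:`StageError` naming the stage; earlier outputs are retained.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    report: dict = {"config": config.to_dict()}

    def finish_stage(name: str, t0: float, files: list[Path]) -> None:
        manifest[name] = {
            "seconds": round(time.perf_counter() - t0, 3),
            "outputs": {f.name: _sha256(f) for f in files},
        }

    # --- simulate -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        spec = GenomeSpec(
            tuple(config.chromosome_names),
            tuple(config.chromosome_lengths),
            config.gc_fraction,
            config.seed,
            config.window_width,
        )
        host = generate_genome(spec)
        construct = make_transgene(seed=config.seed + 1)
        window = next(host.features(kind="region"))
        event = IntegrationEvent(
            chromosome=window.chromosome,
            deletion_start=(
                config.deletion_start if config.deletion_start is not None else window.start
            ),
            deletion_end=(
                config.deletion_end if config.deletion_end is not None else window.end
            ),
            copies=config.copies,
            orientation=config.orientation,
        )
        allele, truth = build_transgenic_allele(host, construct, event)
        primers = simulate.default_viewpoint_primers(allele, config.viewpoint_element)
        params = simulate.TLAParams(
            viewpoint_primers=primers,
            distance_decay_alpha=config.distance_decay_alpha,
            decay_scale_d0=config.decay_scale_d0,
            read_length=config.read_length,
            read_pairs=config.read_pairs,
            substitution_error_rate=config.substitution_error_rate,
            trans_ligation_rate=config.trans_ligation_rate,
            seed=config.seed + 2,
        )
        readset = simulate.simulate_tla_reads(allele, params)
        write_fasta(host.sequences, out / "host.fa")
        write_fasta({"transgene": construct.sequence}, out / "transgene.fa")
        write_fasta(allele.sequences, out / "allele.fa")
        simulate.write_fastq(readset, out / "reads_R1.fastq", out / "reads_R2.fastq")
        simulate.write_truth(readset, out / "truth.tsv")
        gene_models = integration.gene_models_from_genome(host)
        integration.write_gff3_genes(gene_models, out / "genes.gff3")
        report["simulate"] = {
            "event": dataclasses.asdict(event),
            "allele_length": allele.total_length(),
            "n_reads": len(readset.reads),
            "keep_prob_used": readset.keep_prob_used,
            "viewpoint": [readset.viewpoint_ref, *readset.viewpoint_interval],
        }
        finish_stage("simulate", t0, [
            out / f for f in ("host.fa", "transgene.fa", "allele.fa",
                              "reads_R1.fastq", "reads_R2.fastq", "truth.tsv",
                              "genes.gff3")
        ])
    except Exception as exc:                 # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # --- map ----------------------------------------------------------
    t0 = time.perf_counter()
    try:
        host_index = mapping.build_seed_index(host, config.k)
        tg_index = mapping.build_seed_index(
            Genome({"transgene": construct.sequence}), config.k
        )
        two_step = mapping.TwoStepParams(
            k=config.k,
            max_mismatch_rate=config.max_mismatch_rate,
            covered_fraction=config.covered_fraction,
        )
        reads = [(f"{r.read_id}/{r.mate}", r.sequence) for r in readset.reads]
        segments = mapping.tla_two_step_map(reads, host_index, tg_index, two_step)
        refs = {name: len(seq) for name, seq in host.sequences.items()}
        refs["transgene"] = len(construct.sequence)
        mapping.write_sam(segments, refs, dict(reads), out / "aln.sam")
        report["map"] = {
            "n_segments": len(segments),
            "n_split_pass": sum(1 for s in segments if s.pass_label == "split_pass"),
        }
        finish_stage("map", t0, [out / "aln.sam"])
    except Exception as exc:                 # noqa: BLE001
        raise StageError("map", exc) from exc

    # --- call ---------------------------------------------------------
    t0 = time.perf_counter()
    try:
        evidence = integration.collect_fusion_evidence(
            segments, len(construct.sequence), config.junction_slop
        )
        call = integration.call_integration_site(
            evidence, config.min_support, config.cluster_window
        )
        coverage = integration.coverage_from_segments(
            segments, call.chromosome, len(host.sequences[call.chromosome])
        )
        integration.call_deletion(
            call, coverage, config.flank_window, config.max_internal_ratio
        )
        integration.estimate_tandem_copy_number(evidence, call, config.cluster_window)
        read_seqs = dict(reads)
        integration.reconstruct_junctions(
            read_seqs, evidence, call, config.junction_flank, config.cluster_window
        )
        impacts = integration.annotate_gene_disruption(call, gene_models)
        write_json(call.to_dict(), out / "integration.json")
        with open(out / "junctions.fa", "w") as fh:
            for j in call.junctions:
                fh.write(f">{j.kind} supporting_reads={j.supporting_reads}\n")
                fh.write(j.consensus + "\n")
        with open(out / "gene_impacts.tsv", "w") as fh:
            fh.write("gene\timpact\tdetail\n")
            for gi in impacts:
                fh.write(f"{gi.gene_name}\t{gi.impact}\t{gi.detail}\n")
        report["call"] = call.to_dict()
        report["call"]["gene_impacts"] = [dataclasses.asdict(g) for g in impacts]
        report["call"]["truth"] = {
            "deletion_start": event.deletion_start,
            "deletion_end": event.deletion_end,
            "copies": event.copies,
        }
        finish_stage("call", t0, [
            out / "integration.json", out / "junctions.fa", out / "gene_impacts.tsv"
        ])
    except Exception as exc:                 # noqa: BLE001
        raise StageError("call", exc) from exc

    # --- genotype-design ----------------------------------------------
    t0 = time.perf_counter()
    try:
        wt_seq = host.sequences[call.chromosome]
        tg_seq = allele.sequences[f"{call.chromosome}_tg"]
        assay = genotyping.design_three_primer_assay(wt_seq, tg_seq, call)
        write_json(assay.to_dict(), out / "assay.json")
        genotypes = {
            "WT/WT": genotyping.genotype_allele_pair((wt_seq, wt_seq), assay),
            "WT/TG": genotyping.genotype_allele_pair((wt_seq, tg_seq), assay),
            "TG/TG": genotyping.genotype_allele_pair((tg_seq, tg_seq), assay),
        }
        report["genotype_design"] = {**assay.to_dict(), "in_silico_calls": genotypes}
        finish_stage("genotype-design", t0, [out / "assay.json"])
    except Exception as exc:                 # noqa: BLE001
        raise StageError("genotype-design", exc) from exc

    # --- segregation-test ---------------------------------------------
    t0 = time.perf_counter()
    try:
        counts = genotyping.CrossCounts(
            config.n_het + config.n_wt + config.n_hom,
            config.n_het, config.n_wt, config.n_hom,
        )
        ratio = genotyping.segregation_tests(counts)
        write_json(ratio.to_dict(), out / "segregation.json")
        report["segregation"] = ratio.to_dict()
        finish_stage("segregation-test", t0, [out / "segregation.json"])
    except Exception as exc:                 # noqa: BLE001
        raise StageError("segregation-test", exc) from exc

    write_json(manifest, out / "manifest.json")
    report_no_time = json.loads(json.dumps(report))
    write_json(report_no_time, out / "report.json")
    return report
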