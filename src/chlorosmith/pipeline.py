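"""End-to-end orchestration: simulate (optional) -> QC -> bait ->
assemble -> refine -> rescue -> gap-fill -> quadripartite resolution ->
variant calling -> densities, with a manifest of outputs and the
resolved configuration written beside the results."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import assembler, kmer_bait, quadripartite, simdata, variants
from .errors import MissingInput, NoLinkedPeaks
from .seqs import read_fasta, read_fastq_pairs, write_fasta, write_fastq_pairs

log = logging.getLogger("chlorosmith")


@dataclass
class RunConfig:
    """Resolved run configuration; serializable to YAML so every run
    can be reproduced from the copy written beside its outputs."""

    outdir: str = "chlorosmith_out"
    seed: int = 1
    # simulation (ignored when reads are supplied)
    simulate: bool = True
    lsc_len: int = 8000
    ssc_len: int = 2000
    ir_len: int = 3000
    gc_fraction: float = simdata.DEFAULT_GC
    n_accessions: int = 1
    snv_rates: dict = field(default_factory=lambda: dict(simdata.DEFAULT_SNV_RATES))
    indel_rates: dict = field(default_factory=lambda: dict(simdata.DEFAULT_INDEL_RATES))
    chloro_coverage: float = 100.0
    nuclear_coverage: float = 1.0
    nuclear_len: int = 1_000_000
    read_len: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    error_rate: float = 0.01
    # real inputs (used when simulate=False)
    reads_1: str | None = None
    reads_2: str | None = None
    reference: str | None = None
    annotation: str | None = None
    # stage parameters
    min_mean_q: float = 20.0
    k: int = kmer_bait.DEFAULT_K
    k_spread: tuple = assembler.DEFAULT_K_SPREAD
    ratio_tol: float = 0.15
    expected_size: int | None = None
    max_iter: int = 5
    min_ir_len: int = 1000
    window: int = 500

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.k_spread = tuple(cfg.k_spread)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def assemble_plastome(reads, cfg: RunConfig):
    """QC, bait, assemble across the k spread, refine, rescue, gap-fill
    and resolve the quadripartite circle.  Returns (genome, stage log)."""
    stages = []
    qc_reads, qc_stats = kmer_bait.qc_filter(reads, cfg.min_mean_q)
    log.info("qc: kept %d / dropped %d pairs", qc_stats["kept"], qc_stats["dropped"])
    hist = kmer_bait.build_histogram(qc_reads, cfg.k)
    peaks = kmer_bait.detect_linked_peaks(hist, cfg.ratio_tol)
    log.info("peaks: N=%.1f 2N=%.1f band=[%d,%d]", peaks.n_single, peaks.n_ir, peaks.band_low, peaks.band_high)
    baits = kmer_bait.select_bait_kmers(qc_reads, hist, peaks)
    baited = kmer_bait.bait_reads(qc_reads, baits)
    log.info("baited %d / %d pairs", len(baited), len(qc_reads))

    asm = assembler.assemble_spread(baited, cfg.k_spread, cfg.expected_size)
    stages.append(asm)
    asm = assembler.refine_iteratively(asm, qc_reads, cfg.max_iter, cfg.expected_size)
    stages.append(asm)
    asm = assembler.rescue_scaffold_ends(asm, qc_reads)
    stages.append(asm)
    asm = assembler.fill_gaps(asm, qc_reads)
    stages.append(asm)

    final_contigs = _scaffolds_as_contigs(stages)
    genome = quadripartite.resolve_collapsed(final_contigs, asm.k, cfg.min_ir_len)
    return genome, stages, hist, peaks


def _scaffolds_as_contigs(stages):
    """Carry per-scaffold coverages forward from the last stage that
    recorded them (the rescue/gap-fill stages reuse refined coverage)."""
    final = stages[-1]
    covs = final.coverages
    if not covs:
        for st in reversed(stages):
            if st.coverages and len(st.coverages) == len(final.scaffolds):
                covs = st.coverages
                break
    if not covs:
        covs = [1.0] * len(final.scaffolds)
    return list(zip(final.scaffolds, covs))


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline per the configuration; returns the
    manifest (also written to ``<outdir>/manifest.json``)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest: dict = {"stages": {}, "outputs": {}}

    def record(stage: str, path: Path):
        manifest["stages"].setdefault(stage, []).append(path.name)
        manifest["outputs"][path.name] = _sha256(path)

    if cfg.simulate:
        truth = simdata.simulate_genome(
            cfg.lsc_len, cfg.ssc_len, cfg.ir_len, cfg.gc_fraction, seed=cfg.seed
        )
        reference_seq = truth.sequence
        write_fasta({"truth": truth.sequence}, out / "truth.fasta")
        quadripartite.write_region_map_tsv(truth.region_map, out / "truth_regions.tsv", "truth")
        record("simulate", out / "truth.fasta")
        record("simulate", out / "truth_regions.tsv")
        accession_reads = {}
        for i in range(cfg.n_accessions):
            name = f"acc{i + 1}"
            seq, mlog = simdata.mutate_genome(
                truth, cfg.snv_rates, cfg.indel_rates, accession=name, seed=cfg.seed + 1000 + i
            )
            simdata.write_mutation_log(mlog, out / f"{name}_mutations.tsv")
            record("simulate", out / f"{name}_mutations.tsv")
            reads, labels = simdata.simulate_reads(
                seq,
                nuclear_len=cfg.nuclear_len,
                chloro_coverage=cfg.chloro_coverage,
                nuclear_coverage=cfg.nuclear_coverage,
                read_len=cfg.read_len,
                insert_mean=cfg.insert_mean,
                insert_sd=cfg.insert_sd,
                error_rate=cfg.error_rate,
                seed=cfg.seed + 2000 + i,
            )
            write_fastq_pairs(reads, out / f"{name}_1.fastq", out / f"{name}_2.fastq")
            simdata.write_labels(labels, out / f"{name}_labels.tsv")
            record("simulate", out / f"{name}_1.fastq")
            record("simulate", out / f"{name}_2.fastq")
            accession_reads[name] = reads
    else:
        if not cfg.reads_1 or not cfg.reads_2:
            raise MissingInput("reads_1/reads_2 required when simulation is disabled")
        if not cfg.reference:
            raise MissingInput("a reference genome is required when simulation is disabled")
        accession_reads = {"sample1": read_fastq_pairs(cfg.reads_1, cfg.reads_2)}
        reference_seq = next(iter(read_fasta(cfg.reference).values()))

    per_sample: dict[str, list] = {}
    for name, reads in accession_reads.items():
        genome, stages, hist, _peaks = assemble_plastome(reads, cfg)
        hist.to_tsv(out / f"{name}_kmer_histogram.tsv")
        record("bait", out / f"{name}_kmer_histogram.tsv")
        assembler.write_assembly_report(stages, out / f"{name}_assembly_report.tsv")
        record("assemble", out / f"{name}_assembly_report.tsv")
        write_fasta({f"{name}_plastome": genome.sequence}, out / f"{name}_plastome.fasta")
        quadripartite.write_region_map_tsv(genome.region_map, out / f"{name}_regions.tsv", name)
        record("partition", out / f"{name}_plastome.fasta")
        record("partition", out / f"{name}_regions.tsv")
        sample_canonical = genome.sequence
        # reference coordinates: canonicalize the reference the same way
        ref_map = quadripartite.find_inverted_repeat(reference_seq, cfg.min_ir_len)
        ref_canon = quadripartite.canonicalize(reference_seq, ref_map, "reference")
        calls = variants.call_variants(sample_canonical, ref_canon.sequence)
        per_sample[name] = calls

    table = variants.merge_samples(per_sample, "reference", len(reference_seq))
    variants.write_vcf(table, out / "variants.vcf")
    record("callvars", out / "variants.vcf")

    partition = None
    if cfg.annotation:
        partition = variants.build_feature_partition(
            variants.load_annotation(cfg.annotation), len(reference_seq)
        )
    report = variants.density_report(table, ref_canon.region_map, partition)
    report.to_csv(out / "density_report.tsv", sep="\t", index=False)
    record("density", out / "density_report.tsv")
    track = variants.window_density(table, cfg.window)
    track.to_tsv(out / "window_track.tsv")
    record("density", out / "window_track.tsv")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
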