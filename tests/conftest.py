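"""Shared fixtures: scaled simulated studies reused across test modules.

The scaled study uses a 16 kb quadripartite genome (LSC 8,000 / SSC
2,000 / IR 3,000 bp) sequenced at 100x chloroplast and 1x nuclear (1 Mb
background) coverage with 1% base errors and a 400 bp insert — the same
shape as a real plastome resequencing experiment, at desk scale.
"""

from __future__ import annotations

import warnings

import pytest

from chlorosmith import assembler, kmer_bait, quadripartite, simdata

SCALED = dict(lsc_len=8000, ssc_len=2000, ir_len=3000, gc_fraction=0.36)
EXPECTED_SIZE = 16000
READ_LEN = 150
K = 31


def simulate_study(seed: int):
    """One scaled accession study: truth genome, mutated accession,
    reads with origin labels."""
    truth = simdata.simulate_genome(**SCALED, seed=seed)
    accession, log = simdata.mutate_genome(truth, seed=seed + 100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reads, labels = simdata.simulate_reads(
            accession,
            nuclear_len=1_000_000,
            chloro_coverage=100.0,
            nuclear_coverage=1.0,
            read_len=READ_LEN,
            insert_mean=400.0,
            insert_sd=40.0,
            error_rate=0.01,
            seed=seed + 200,
        )
    return {
        "truth": truth,
        "accession": accession,
        "mutation_log": log,
        "reads": reads,
        "labels": labels,
        "seed": seed,
    }


def run_scaled_pipeline(seed: int):
    """Full pipeline on one scaled study; returns intermediate results
    for scoring against the simulation ground truth."""
    study = simulate_study(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        qc, _ = kmer_bait.qc_filter(study["reads"])
        hist = kmer_bait.build_histogram(qc, K)
        peaks = kmer_bait.detect_linked_peaks(hist)
        baits = kmer_bait.select_bait_kmers(qc, hist, peaks)
        baited = kmer_bait.bait_reads(qc, baits)
        asm = assembler.assemble_spread(baited, expected_size=EXPECTED_SIZE)
        asm = assembler.refine_iteratively(asm, qc, expected_size=EXPECTED_SIZE)
        asm = assembler.rescue_scaffold_ends(asm, qc)
        asm = assembler.fill_gaps(asm, qc)
        genome = quadripartite.resolve_collapsed(
            list(zip(asm.scaffolds, asm.coverages)), asm.k
        )
        truth_map = quadripartite.find_inverted_repeat(study["accession"])
        truth_canon = quadripartite.canonicalize(
            study["accession"], truth_map, "simulated"
        )
        equal, summary = quadripartite.genomes_equivalent(genome, truth_canon)
    return {
        **study,
        "peaks": peaks,
        "baited": baited,
        "assembly": asm,
        "genome": genome,
        "truth_canonical": truth_canon,
        "equivalent": equal,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def scaled_study():
    return simulate_study(1)


@pytest.fixture(scope="session")
def full_size_genome():
    """Default-size simulated plastome (153,482 bp)."""
    return simdata.simulate_genome(seed=7)


@pytest.fixture(scope="session")
def pipeline_runs():
    """The scaled pipeline across ten seeds (shared by the recovery
    and peak-detection acceptance checks)."""
    return [run_scaled_pipeline(seed) for seed in range(1, 11)]
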