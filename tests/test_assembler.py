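"""De Bruijn assembly, k-spread scoring, refinement, rescue, gap fill."""

import numpy as np
import pytest

from chlorosmith import assembler
from chlorosmith.errors import EmptyInput, InvalidParameter
from chlorosmith.seqs import ReadPair, revcomp

RNG = np.random.default_rng(20240901)


def random_seq(length, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=length))


def tile_pairs(seq, read_len=150, insert=400, step=10, circular=False):
    """Deterministic error-free paired reads tiling a sequence."""
    pairs = []
    source = seq + seq if circular else seq
    limit = len(seq) if circular else len(seq) - insert + 1
    starts = list(range(0, max(limit, 1), step))
    if not circular:
        # extra fragments pinning both ends so terminal k-mers stay solid
        starts = [0, 0, len(seq) - insert, len(seq) - insert] + starts
    for i, start in enumerate(starts):
        frag = source[start : start + insert]
        if len(frag) < insert:
            continue
        pairs.append(
            ReadPair(
                f"t{i}",
                frag[:read_len],
                "I" * read_len,
                revcomp(frag[-read_len:]),
                "I" * read_len,
            )
        )
    return pairs


class TestAssembleOnce:
    def test_unique_sequence_yields_single_exact_contig(self):
        truth = random_seq(5000)
        contigs = assembler.assemble_once(tile_pairs(truth), k=31, min_count=1)
        assert len(contigs) == 1
        seq = contigs[0].sequence
        assert seq == truth or seq == revcomp(truth)

    def test_circular_genome_recovered_up_to_rotation(self):
        truth = random_seq(3000)
        contigs = assembler.assemble_once(
            tile_pairs(truth, circular=True), k=31, min_count=1
        )
        assert len(contigs) == 1
        c = contigs[0]
        assert c.circular
        assert len(c.sequence) == len(truth)
        assert c.sequence in truth + truth or revcomp(c.sequence) in truth + truth

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInput):
            assembler.assemble_once([], k=31)

    def test_k_larger_than_reads_rejected(self):
        with pytest.raises(InvalidParameter):
            assembler.assemble_once(tile_pairs(random_seq(1000), read_len=50, insert=120), k=63)

    def test_deterministic(self):
        truth = random_seq(2000)
        pairs = tile_pairs(truth)
        a = assembler.assemble_once(pairs, k=31, min_count=1)
        b = assembler.assemble_once(pairs, k=31, min_count=1)
        assert [(c.id, c.sequence) for c in a] == [(c.id, c.sequence) for c in b]

    def test_substitution_bubble_resolved_to_majority(self):
        truth = random_seq(2000)
        variant = truth[:1000] + ("A" if truth[1000] != "A" else "C") + truth[1001:]
        pairs = tile_pairs(truth) * 3 + tile_pairs(variant)
        contigs = assembler.assemble_once(pairs, k=31, min_count=1)
        assert len(contigs) == 1
        assert contigs[0].sequence in (truth, revcomp(truth))


class TestAssembleSpread:
    def test_scoring_prefers_fewer_scaffolds_then_expected_size(self):
        one_good = assembler.Assembly(["A" * 16000], 51, "initial")
        fragmented = assembler.Assembly(["A" * 8000, "A" * 5000, "A" * 3000], 31, "initial")
        short = assembler.Assembly(["A" * 3000], 31, "initial")
        score = lambda a: assembler.score_assembly(a, expected_size=16000)
        assert score(one_good) < score(fragmented)
        assert score(one_good) < score(short)

    def test_single_k_returned_unchanged(self):
        truth = random_seq(2000)
        asm = assembler.assemble_spread(tile_pairs(truth), (31,), min_count=1)
        assert asm.k == 31
        assert len(asm.scaffolds) == 1

    def test_all_k_too_large_rejected(self):
        with pytest.raises(InvalidParameter):
            assembler.assemble_spread(
                tile_pairs(random_seq(1000), read_len=40, insert=100), (63,)
            )


class TestRefineIteratively:
    def test_zero_iterations_is_identity(self):
        asm = assembler.Assembly(["ACGT" * 100], 31, "initial")
        assert assembler.refine_iteratively(asm, [], max_iter=0) is asm

    def test_complete_assembly_is_a_fixed_point(self):
        truth = random_seq(3000)
        pairs = tile_pairs(truth)
        asm = assembler.assemble_spread(pairs, (31,), min_count=1)
        refined = assembler.refine_iteratively(asm, pairs, min_count=1)
        assert refined.total_length == asm.total_length
        assert refined.converged

    def test_refinement_recovers_unbaited_region(self):
        truth = random_seq(4000)
        pairs = tile_pairs(truth)
        # seed assembly deliberately missing the final kilobase
        partial = assembler.Assembly([truth[:3000]], 31, "initial")
        refined = assembler.refine_iteratively(partial, pairs, min_count=1)
        assert refined.total_length >= 3990


class TestRescueAndGapFill:
    def test_truncated_scaffold_extended_to_truth_end(self):
        truth = random_seq(4000)
        pairs = tile_pairs(truth)
        asm = assembler.Assembly([truth[:3700]], 31, "rescue-input")
        rescued = assembler.rescue_scaffold_ends(asm, pairs)
        assert len(rescued.scaffolds) == 1
        s = rescued.scaffolds[0]
        assert len(s) >= 3990
        assert s.startswith(truth[:3700])
        assert truth.startswith(s[: len(truth)])

    def test_unextendable_end_left_intact(self):
        truth = random_seq(2000)
        asm = assembler.Assembly([truth], 31, "rescue-input")
        rescued = assembler.rescue_scaffold_ends(asm, [])
        assert rescued.scaffolds == [truth]

    def test_abutting_scaffolds_with_bridging_pairs_merged(self):
        truth = random_seq(4000)
        pairs = tile_pairs(truth)
        asm = assembler.Assembly([truth[:1900], truth[1900:]], 31, "rescue-input")
        rescued = assembler.rescue_scaffold_ends(asm, pairs)
        assert len(rescued.scaffolds) == 1
        merged = rescued.scaffolds[0]
        assert truth in merged or revcomp(truth) in merged

    def test_gap_replaced_by_true_sequence(self):
        truth = random_seq(4000)
        pairs = tile_pairs(truth)
        gapped = truth[:2000] + "N" * 200 + truth[2200:]
        asm = assembler.Assembly([gapped], 31, "gap-input")
        filled = assembler.fill_gaps(asm, pairs)
        assert filled.scaffolds[0] == truth

    def test_gap_free_scaffold_unchanged(self):
        truth = random_seq(1500)
        asm = assembler.Assembly([truth], 31, "gap-input")
        assert assembler.fill_gaps(asm, []).scaffolds == [truth]

    def test_uncovered_gap_keeps_its_n_run(self):
        truth = random_seq(4000)
        # reads cover only the flanks, never the gap interior
        pairs = tile_pairs(truth[:2000]) + tile_pairs(truth[2200:])
        gapped = truth[:2000] + "N" * 200 + truth[2200:]
        asm = assembler.Assembly([gapped], 31, "gap-input")
        filled = assembler.fill_gaps(asm, pairs)
        assert "N" in filled.scaffolds[0]


class TestCollapsedPlastomeStructure:
    def test_spread_emits_two_arcs_and_collapsed_ir(self, scaled_study):
        from chlorosmith import kmer_bait

        qc, _ = kmer_bait.qc_filter(scaled_study["reads"])
        hist = kmer_bait.build_histogram(qc, 31)
        peaks = kmer_bait.detect_linked_peaks(hist)
        baits = kmer_bait.select_bait_kmers(qc, hist, peaks)
        baited = kmer_bait.bait_reads(qc, baits)
        asm = assembler.assemble_spread(baited, expected_size=16000)
        assert len(asm.scaffolds) == 3
        lengths = sorted(len(s) for s in asm.scaffolds)
        assert abs(lengths[2] - 8000) < 150  # LSC arc
        assert abs(lengths[1] - 3000) < 150  # collapsed IR
        assert abs(lengths[0] - 2000) < 150  # SSC arc
        # the IR path carries ~2x single-copy coverage
        cov_by_len = sorted(zip(asm.scaffolds, asm.coverages), key=lambda t: len(t[0]))
        ir_cov = cov_by_len[1][1]
        single = (cov_by_len[0][1] + cov_by_len[2][1]) / 2
        assert 1.7 < ir_cov / single < 2.3
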