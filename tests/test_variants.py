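"""Variant calling, normalization, merging, densities and windows."""

import numpy as np
import pytest

from chlorosmith import simdata, variants
from chlorosmith.errors import (
    InvalidAnnotation,
    InvalidVariant,
    NotCollinear,
    RefMismatch,
    ReferenceMismatch,
)
from chlorosmith.quadripartite import RegionMap
from chlorosmith.variants import Variant

RNG = np.random.default_rng(7)


def random_seq(length, rng=RNG):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestClassifySnv:
    @pytest.mark.parametrize("ref,alt", [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")])
    def test_transitions(self, ref, alt):
        assert variants.classify_snv(ref, alt) == "transition"

    @pytest.mark.parametrize(
        "ref,alt",
        [("A", "C"), ("A", "T"), ("C", "G"), ("G", "T"), ("C", "A"), ("T", "G")],
    )
    def test_transversions(self, ref, alt):
        assert variants.classify_snv(ref, alt) == "transversion"

    def test_identical_alleles_rejected(self):
        with pytest.raises(InvalidVariant):
            variants.classify_snv("A", "A")


class TestNormalizeVariant:
    def test_deletion_left_aligned_through_homopolymer(self):
        reference = "CAAAT"
        # one A deleted, represented at the third A
        raw = Variant(3, "AA", "A", "DEL")
        norm = variants.normalize_variant(raw, reference)
        assert (norm.pos, norm.ref, norm.alt) == (1, "CA", "C")

    def test_snv_unchanged(self):
        reference = "ACGTACGT"
        v = Variant(4, "T", "C", "SNV")
        assert variants.normalize_variant(v, reference) == v

    def test_ref_mismatch_rejected(self):
        with pytest.raises(RefMismatch):
            variants.normalize_variant(Variant(2, "G", "T", "SNV"), "AAAA")

    @pytest.mark.parametrize("seed", range(5))
    def test_idempotent_on_repetitive_context(self, seed):
        rng = np.random.default_rng(seed)
        # highly repetitive reference maximizes shifting opportunity
        reference = "".join(rng.choice(["A", "AT", "C", "CAG", "T"], size=400))
        for _ in range(200):
            pos = int(rng.integers(10, len(reference) - 45))
            length = int(rng.integers(1, 10))
            anchor = reference[pos - 1]
            if rng.random() < 0.5:
                v = Variant(pos, anchor, anchor + random_seq(length, rng), "INS")
            else:
                v = Variant(pos, reference[pos - 1 : pos + length], anchor, "DEL")
            once = variants.normalize_variant(v, reference)
            twice = variants.normalize_variant(once, reference)
            assert once == twice


class TestCallVariants:
    def test_identical_sequences_no_variants(self):
        seq = random_seq(10_000)
        assert variants.call_variants(seq, seq) == []

    def test_single_substitution_called_exactly(self):
        ref = random_seq(10_000)
        pos = 5000
        alt_base = "G" if ref[pos - 1] == "A" else "A"
        sample = ref[: pos - 1] + alt_base + ref[pos:]
        calls = variants.call_variants(sample, ref)
        assert calls == [Variant(pos, ref[pos - 1], alt_base, "SNV")]
        assert variants.classify_snv(ref[pos - 1], alt_base) in (
            "transition",
            "transversion",
        )

    def test_planted_mutations_recovered_exactly(self):
        genome = simdata.simulate_genome(seed=11)
        accession, log = simdata.plant_mutations(genome, 50, 10, seed=12)
        calls = variants.call_variants(accession, genome.sequence)
        truth = {
            (m.pos, m.ref, m.alt, m.vclass)
            for m in (
                variants.normalize_variant(
                    Variant(m.pos, m.ref, m.alt, m.vclass), genome.sequence
                )
                for m in log.mutations
            )
        }
        called = {(v.pos, v.ref, v.alt, v.vclass) for v in calls}
        assert called == truth

    def test_mirrored_ir_mutations_recovered(self):
        genome = simdata.simulate_genome(8000, 2000, 3000, seed=2)
        accession, log = simdata.mutate_genome(genome, seed=5)
        calls = variants.call_variants(accession, genome.sequence, min_chain_cover=0.8)
        truth = {
            (m.pos, m.ref, m.alt, m.vclass)
            for m in (
                variants.normalize_variant(
                    Variant(m.pos, m.ref, m.alt, m.vclass), genome.sequence
                )
                for m in log.mutations
            )
        }
        called = {(v.pos, v.ref, v.alt, v.vclass) for v in calls}
        assert called == truth

    def test_unrelated_sequences_not_collinear(self):
        with pytest.raises(NotCollinear):
            variants.call_variants(random_seq(5000), random_seq(5000))


class TestMergeSamples:
    def test_disagreeing_alts_flag_triallelic(self):
        table = variants.merge_samples(
            {
                "s1": [Variant(100, "A", "G", "SNV")],
                "s2": [Variant(100, "A", "T", "SNV")],
            },
            "ref",
            1000,
        )
        rec = table.records[(100, "SNV")]
        assert rec.triallelic
        assert table.triallelic_count == 1
        assert rec.sample_allele == {"s1": 0, "s2": 1}

    def test_shared_alt_not_triallelic(self):
        table = variants.merge_samples(
            {
                "s1": [Variant(100, "A", "G", "SNV")],
                "s2": [Variant(100, "A", "G", "SNV")],
            },
            "ref",
            1000,
        )
        assert not table.records[(100, "SNV")].triallelic

    def test_position_outside_reference_rejected(self):
        with pytest.raises(ReferenceMismatch):
            variants.merge_samples({"s1": [Variant(2000, "A", "G", "SNV")]}, "ref", 1000)

    def test_pooled_truth_counts_from_simulated_cohort(self):
        genome = simdata.simulate_genome(8000, 2000, 3000, seed=4)
        per_sample = {}
        pooled = set()
        for i in range(5):
            acc, log = simdata.mutate_genome(genome, accession=f"a{i}", seed=40 + i)
            calls = [
                variants.normalize_variant(
                    Variant(m.pos, m.ref, m.alt, m.vclass), genome.sequence
                )
                for m in log.mutations
            ]
            per_sample[f"a{i}"] = calls
            pooled.update((v.pos, v.vclass) for v in calls)
        table = variants.merge_samples(per_sample, "truth", len(genome.sequence))
        assert len(table) == len(pooled)


class TestFeaturePartition:
    def test_worked_example(self):
        part = variants.build_feature_partition(
            [("g1", 101, 400, [(101, 200), (301, 400)])], 1000
        )
        assert part.span("exon") == 200
        assert part.span("intron") == 100
        assert part.span("intergenic") == 700
        assert part.category_of(150) == "exon"
        assert part.category_of(250) == "intron"
        assert part.category_of(500) == "intergenic"

    def test_no_genes_all_intergenic(self):
        part = variants.build_feature_partition([], 500)
        assert part.span("intergenic") == 500

    def test_exon_outside_gene_rejected(self):
        with pytest.raises(InvalidAnnotation):
            variants.build_feature_partition([("g1", 100, 200, [(150, 250)])], 1000)

    @pytest.mark.parametrize("fmt", ["gff3", "tsv"])
    def test_annotation_loaders_agree(self, tmp_path, fmt):
        if fmt == "gff3":
            path = tmp_path / "ann.gff3"
            path.write_text(
                "##gff-version 3\n"
                "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=g1\n"
                "chr1\tsrc\texon\t101\t200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
                "chr1\tsrc\texon\t301\t400\t.\t+\t.\tID=g1.e2;Parent=g1\n"
            )
        else:
            path = tmp_path / "ann.txt"
            path.write_text(
                "# seqid\ttype\tstart\tend\tgene_id\n"
                "chr1\tgene\t101\t400\tg1\n"
                "chr1\texon\t101\t200\tg1\n"
                "chr1\texon\t301\t400\tg1\n"
            )
        genes = variants.load_annotation(path)
        assert genes == [("g1", 101, 400, [(101, 200), (301, 400)])]

    def test_partition_sums_to_reference_length(self):
        genes = [("g1", 50, 400, [(50, 120), (200, 400)]), ("g2", 600, 800, [(600, 800)])]
        part = variants.build_feature_partition(genes, 1000)
        assert part.span("exon") + part.span("intron") + part.span("intergenic") == 1000


def small_region_map():
    return RegionMap((1, 8000), (8001, 11000), (11001, 13000), (13001, 16000), 16000)


class TestDensityReport:
    def test_counts_conserved_across_scopes(self):
        rng = np.random.default_rng(3)
        per_sample = {
            "s1": [
                Variant(int(p), "A", "G", "SNV")
                for p in rng.choice(np.arange(1, 16001), size=120, replace=False)
            ]
        }
        table = variants.merge_samples(per_sample, "ref", 16000)
        part = variants.build_feature_partition(
            [("g1", 1001, 4000, [(1001, 2000), (3001, 4000)])], 16000
        )
        report = variants.density_report(table, small_region_map(), part)
        snv = report[report.vclass == "SNV"]
        whole = int(snv[snv.scope == "whole"]["count"].iloc[0])
        regions = snv[snv.scope.isin(["LSC", "SSC", "IR"])]["count"].sum()
        features = snv[snv.scope.isin(["exon", "intron", "intergenic"])]["count"].sum()
        assert whole == regions == features == 120

    def test_density_formula_inverts_to_count(self):
        rng = np.random.default_rng(9)
        per_sample = {
            "s1": [
                Variant(int(p), "A", "G", "SNV")
                for p in rng.choice(np.arange(1, 16001), size=77, replace=False)
            ]
        }
        table = variants.merge_samples(per_sample, "ref", 16000)
        report = variants.density_report(table, small_region_map())
        for _, row in report.iterrows():
            assert abs(row.density_per_kb * row.span_bp / 1000 - row["count"]) < 0.5

    def test_zero_variants_zero_density(self):
        table = variants.merge_samples({"s1": []}, "ref", 16000)
        report = variants.density_report(table, small_region_map())
        assert (report.density_per_kb == 0).all()

    def test_display_rounding_styles(self):
        assert variants.display_density(variants.per_kb_density(2646, 153_482)) == "17.2"
        assert variants.display_density(variants.per_kb_density(6, 153_482)) == "0.04"


class TestWindowTrack:
    def test_window_binning_example(self):
        per_sample = {"s1": [Variant(p, "A", "G", "SNV") for p in (100, 600, 620)]}
        table = variants.merge_samples(per_sample, "ref", 1500)
        track = variants.window_density(table, 500)
        assert list(track.counts) == [1, 2, 0]
        assert track.spans() == [(1, 500), (501, 1000), (1001, 1500)]

    def test_counts_conserved(self):
        rng = np.random.default_rng(5)
        per_sample = {
            "s1": [
                Variant(int(p), "A", "G", "SNV")
                for p in rng.choice(np.arange(1, 16001), size=200, replace=False)
            ]
        }
        table = variants.merge_samples(per_sample, "ref", 16000)
        track = variants.window_density(table)
        assert track.counts.sum() == len(table)

    def test_hotspot_windows_recover_planted_cluster(self):
        rng = np.random.default_rng(8)
        background = rng.choice(np.arange(5001, 16001), size=30, replace=False)
        cluster = np.arange(1010, 1490, 16)  # dense 500 bp hotspot
        per_sample = {
            "s1": [Variant(int(p), "A", "G", "SNV") for p in np.concatenate([background, cluster])]
        }
        table = variants.merge_samples(per_sample, "ref", 16000)
        hot = variants.window_density(table, 500).hotspots(95)
        assert any(start <= 1010 and end >= 1489 for start, end, _ in hot)


class TestVcfRoundTrip:
    def test_write_then_read_preserves_table(self, tmp_path):
        genome = simdata.simulate_genome(8000, 2000, 3000, seed=6)
        per_sample = {}
        for i in range(3):
            _, log = simdata.mutate_genome(genome, accession=f"a{i}", seed=60 + i)
            per_sample[f"a{i}"] = [
                variants.normalize_variant(
                    Variant(m.pos, m.ref, m.alt, m.vclass), genome.sequence
                )
                for m in log.mutations
            ]
        table = variants.merge_samples(per_sample, "plastome", len(genome.sequence))
        path = tmp_path / "calls.vcf"
        variants.write_vcf(table, path)
        loaded = variants.read_vcf(path)
        assert loaded.reference_id == "plastome"
        assert set(loaded.records) == set(table.records)
        for key, rec in table.records.items():
            assert loaded.records[key].sample_allele.keys() == rec.sample_allele.keys()
        assert loaded.triallelic_count == table.triallelic_count

    def test_multiallelic_record_marks_triallelic(self, tmp_path):
        vcf = tmp_path / "multi.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "ref\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t1\t2\n"
        )
        table = variants.read_vcf(vcf)
        assert table.records[(100, "SNV")].triallelic

    def test_symbolic_allele_skipped_with_warning(self, tmp_path):
        vcf = tmp_path / "sym.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##contig=<ID=ref,length=1000>\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "ref\t100\t.\tA\t<DEL>\t.\tPASS\t.\tGT\t1\n"
            "ref\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1\n"
        )
        with pytest.warns(UserWarning):
            table = variants.read_vcf(vcf)
        assert set(table.records) == {(200, "SNV")}
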