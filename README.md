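# chlorosmith

De novo chloroplast genome assembly from whole-genome shotgun reads,
and variant-landscape analysis of the resulting plastomes.

## What it does

Leaf-tissue shotgun libraries are dominated by chloroplast DNA, whose
k-mers form a distinctive high-coverage band in the k-mer spectrum:
a single-copy peak at multiplicity N and a linked peak at 2N from the
two inverted-repeat (IR) copies of the quadripartite plastome
(LSC–IRa–SSC–IRb). chlorosmith turns that signal into finished circular
genomes with a five-stage pipeline:

1. k-mer spectrum extraction and detection of the linked (N, 2N) peak
   pair; selection of bait k-mers from the band [max(valley+1, N/2), 3N];
2. extraction of reads carrying bait k-mers and initial de Bruijn
   assembly over a k spread (31, 41, 51, 63);
3. iterative re-selection of reads from the raw data against the
   current assembly, and reassembly to convergence;
4. local reassembly near scaffold ends to extend or merge scaffolds;
5. gap filling by local assembly of pairs anchored to gap flanks.

The two IR copies collapse into one path at ~2N coverage; the
quadripartite resolver restores the circle LSC·IRa·SSC·IRb from the
three scaffolds using their (k−1)-bp junction overlaps and the coverage
signal, and emits a canonical form (LSC first, lexicographically
smaller strand) so genomes can be compared by string identity — up to
rotation, strand, and SSC orientation, which are all representations of
the same molecule.

Downstream, assemblies are compared to a reference by chaining exact
unique-k-mer anchors and aligning inter-anchor segments with affine gap
costs, producing left-normalized SNVs and InDels
(transition = A↔G/C↔T). Multi-sample tables (with triallelic flagging),
per-region and per-feature densities

    density = count × 1000 / span   [variants per kb]

and 500 bp window tracks for hotspot scanning complete the analysis.
Externally produced VCFs can be ingested instead of the built-in
caller.

A full synthetic-data generator (quadripartite genome, mutated
accessions with replayable mutation logs, paired-end reads with origin
labels and nuclear background) makes every stage testable against exact
ground truth. See `docs/methods.md` for the model details.

## Worked example

```python
from chlorosmith import simdata, pipeline, quadripartite

# a 16 kb plastome study: truth genome, one mutated accession,
# 100x chloroplast / 1x nuclear paired-end reads with 1% errors
truth = simdata.simulate_genome(8000, 2000, 3000, seed=1)
accession, log = simdata.mutate_genome(truth, seed=101)
reads, labels = simdata.simulate_reads(accession, seed=201)

cfg = pipeline.RunConfig(seed=1, expected_size=16_000)
genome, stages, hist, peaks = pipeline.assemble_plastome(reads, cfg)
print(f"N={peaks.n_single:.1f} 2N={peaks.n_ir:.1f}")
print([genome.region_map.length(r) for r in ("LSC", "IRa", "SSC", "IRb")])

truth_canon = quadripartite.canonicalize(
    accession, quadripartite.find_inverted_repeat(accession), "simulated")
print(quadripartite.genomes_equivalent(genome, truth_canon)[0])
```

prints (seed 1):

```
N=58.3 2N=115.3
[7995, 3004, 1994, 3004]
True
```

i.e. the detected single-copy k-mer coverage is ≈ 58 (100× base
coverage scaled by k-mers-per-read and the error-free-31-mer
probability) with the IR band at twice that, and the assembled circle
is the accession's genome exactly — its regions differ by a few bp
from the planted 8,000/3,000/2,000 because the accession carries
InDels relative to the truth genome.

The same flow is available from the shell:

```
chlorosmith simulate --outdir sim --seed 1
chlorosmith bait sim/acc1_1.fastq sim/acc1_2.fastq
chlorosmith assemble baited_1.fastq baited_2.fastq --expected-size 153000
chlorosmith partition scaffolds.fasta
chlorosmith callvars ref.fasta sample1.fasta sample2.fasta
chlorosmith density variants.vcf --reference ref.fasta --window 500
chlorosmith pipeline --seed 1 --outdir run1
```

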