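# Methods

## The problem

Leaf-tissue whole-genome shotgun libraries contain chloroplast DNA at
very high copy number relative to the nuclear genome. chlorosmith
exploits that over-representation to assemble finished circular
plastomes directly from unfiltered paired-end reads, and then measures
the variant landscape of a set of such assemblies against a reference:
SNV/InDel classification, per-region and per-feature densities in
variants per kb, and fixed-width window tracks for hotspot scanning.

An angiosperm plastome is quadripartite: a large single-copy arc (LSC)
and a small single-copy arc (SSC) separated by two identical inverted
repeats (IRa/IRb). The IRs are present at twice the copy number of
single-copy sequence, which is both the central obstacle (a de Bruijn
assembler collapses them) and the central signal (the k-mer spectrum
shows two linked coverage peaks at N and 2N).

## Read baiting (stages 1–2 front end)

Reads are first filtered by mean Phred quality per mate (default
threshold 20, pairs dropped when either mate fails — the conventional
"Q ≤ 20" raw-data filter; a fraction-of-bases interpretation would be
an alternative, mean was chosen for simplicity and is exposed as a
parameter).

Canonical k-mers (lexicographic minimum of a k-mer and its reverse
complement, k = 31 by default, always odd so no k-mer is its own
reverse complement) are counted exactly over all reads and binned into
a multiplicity spectrum. Peak detection smooths the dense spectrum with
a width-5 moving average, collects local maxima above a minimum
multiplicity (5), and refines each candidate to the mass centroid of
its ±25% window — raw local maxima wander by several bins under
Poisson sampling noise, the centroid does not. Among candidate pairs
whose ratio lies within 2 ± 0.15 the pair carrying the largest total
k-mer mass wins; the lower centroid is the single-copy coverage N, the
upper the IR coverage ≈ 2N. The bait band is
[max(valley + 1, N/2), 3N], where the valley is the spectrum minimum
between the error/nuclear signal and the single-copy peak. Reads are
kept pair-wise when either mate carries at least one bait k-mer, so
insert information survives into assembly.

Under the default simulated conditions the expected single-copy
*k-mer* coverage is the base coverage scaled by the k-mers-per-read
ratio and the error-free-k-mer probability:
N ≈ C·(L−k+1)/L·(1−e)^k (≈ 58.6 for C = 100×, L = 150, k = 31,
e = 1%); recovery is assessed against this quantity.

## Assembly (stages 2–5)

The assembler is a self-contained canonical-k-mer de Bruijn graph.
Both orientations of every solid k-mer are inserted as edges over
(k−1)-mer nodes; maximal non-branching paths are emitted as unitigs and
reverse-complement duplicates merged. Solidity is automatic: a tenth of
the mass-weighted median multiplicity, floored at 2 (and disabled
entirely when the median is below 8, so sparse clean data is kept
whole). Graph cleaning iterates up to five rounds of:

* tip clipping — dead-ended paths shorter than 2k with coverage below
  0.1× the length-weighted median are removed;
* bubble popping — two unitigs sharing both branch-node endpoints with
  lengths within 3 bp keep only the higher-coverage arm. One subtlety:
  in a double-stranded graph a unitig and its own reverse complement
  share endpoints and would self-annihilate; arms with identical
  canonical k-mer content are therefore exempt.

The initial assembly runs over a k spread (31, 41, 51, 63) and keeps
the candidate scoring best by: fewest scaffolds, then total length
within 0.8–1.2× the expected genome size (largest such), then N50.
Stage 3 iteratively re-selects reads from the full QC-passed data that
share an exact k-mer with the current assembly and reassembles,
stopping when total length changes by < 0.1% (max 5 iterations), never
accepting a worse-scoring assembly. Stage 4 locally reassembles read
pairs anchored within 500 bp of each scaffold end and extends an end
when a local contig overlaps it by ≥ k bp at ≤ 1 mismatch per 100 bp.
Ends whose extension re-enters sequence already present in the assembly
are IR junctions, not broken ends, and are left intact — unless the
extension bridges uniquely into the start of another single-copy
scaffold, in which case the two are merged (the abutting-scaffolds
case). Scaffolds at ≥ 1.5× the median coverage are collapsed repeats
and are never extended or consumed. Stage 5 selects pairs anchored to
the flanks of each N-run, assembles them locally, and splices in a
contig that contains exact k-length copies of both flank ends;
unfillable gaps keep their N-runs.

On a plastome the cleaned graph resolves to exactly three unitigs: the
two single-copy arcs at coverage ≈ N and the collapsed IR at ≈ 2N, with
(k−1)-bp junction overlaps. The quadripartite resolver enumerates the
orientation assignments of the circle A·R·B·rc(R) over the three
scaffolds, requires all four junction overlaps to match exactly,
requires the IR candidate to carry ≥ 1.5× the single-copy coverage,
and returns the reconstructed circle in canonical form.

## Canonical form and equivalence

A circular quadripartite genome has many string representations
(rotation, strand, and SSC orientation — both SSC isomers coexist in
plastid preparations). The canonical form starts at LSC base 1 in order
LSC, IRa, SSC, IRb, on whichever strand yields the lexicographically
smaller string; IRa is always the IR copy following the LSC. Two
genomes are equivalent iff their canonical forms are identical,
optionally also testing the SSC-flipped isomer (on by default, flag to
disable). Inverted repeats are located by seeding shared 21-mers
between the sequence and its reverse complement, grouping seeds by
anti-diagonal, extending contiguous runs maximally, and keeping the
longest disjoint pair; the longer inter-IR arc becomes the LSC.

## Variant calling and densities

Calling is assembly-vs-reference rather than read-mapping based: exact
maximal matches seeded at 21-mers unique on the forward strand of both
genomes are chained by a weighted longest-increasing-subsequence
(forward-strand uniqueness matters: a k-mer inside one IR copy is
forward-unique even though its reverse complement occurs in the other
copy, so the IRs stay anchored). If anchors cover < 90% of the
reference the genomes are declared non-collinear. Inter-anchor segments
are globally aligned with affine gap costs (match +1, mismatch −2, gap
open −4, gap extend −1, via Biopython's PairwiseAligner) and alignment
columns become variants: substitution columns are SNVs (transition =
A↔G/C↔T), gap runs become anchored InDels. All InDels are left-aligned
through repeat context to the VCF convention; normalization is
idempotent.

Multi-sample merging groups normalized variants by (position, class);
a position is triallelic when samples disagree on the alternate
allele. Densities are count × 1000 / span, reported per region (LSC,
SSC, IR — the IR denominator is the combined length of both copies;
one-copy accounting would double the reported IR densities and is
configurable by passing a modified span) and per feature (exon =
union of exon spans, intron = gene minus exon, intergenic =
complement; the three categories partition the reference exactly).
Variants are assigned by the region/feature containing their
normalized anchor position. Display rounding is one decimal at
≥ 0.1/kb and two below; machine output keeps full precision. Window
tracks tile non-overlapping windows (default 500 bp) from position 1,
the last partial window keeping its true span; hotspots are windows
above the 95th percentile of counts (a convention — no standard
threshold exists).

## The simulator

The generator emulates the study design: a random quadripartite circle
(defaults LSC 83,282 / SSC 17,776 / IR 26,212 bp, GC 0.36), accessions
derived by per-bp Bernoulli mutation at region-specific rates, and
400-bp-insert paired 150 bp reads with uniform substitution errors at
high chloroplast:nuclear coverage ratio (default 100:1 — the ratio is a
choice; real libraries are only described as strongly
chloroplast-enriched). Default per-accession mutation rates (SNV
2.2/3.3/0.45 per kb and InDel 0.8/0.7/0.07 per kb for LSC/SSC/IR)
follow the observed pattern that IRs mutate ~5–7× more slowly than
single-copy regions, at within-species magnitude. InDel lengths are
geometric (p = 0.5) truncated at 38 bp, matching the observed 1–38 bp
range with single-base dominance. Mutations drawn in IRa are mirrored
into IRb so accessions keep the exact IR mirror; proposals within 31 bp
of an accepted mutation or within (31 + 38) bp of a region boundary are
rejected and counted, keeping truth-to-call matching unambiguous. The
planted IR is forced to be maximal (junction-flanking bases must not
extend the mirror by chance). Fragments are sampled uniformly on the
circle, so pairs span the origin; the nuclear background is an i.i.d.
linear 1 Mb sequence at 1× with no repeat structure — enough to
exercise baiting specificity, but it does not model nuclear plastid
insertions (NUPTs), GC skew, coverage bias, indel sequencing errors or
quality-dependent errors, so passing tests demonstrate algorithmic
correctness under the stated noise model, not robustness to every
artefact of real libraries.

Every simulation output carries ground truth: region map, mutation log
(replayable — applying the log to the parent reproduces the accession
exactly), and per-read origin labels.

## Scaled study conditions

End-to-end checks run a 16 kb genome (LSC 8,000 / SSC 2,000 / IR
3,000 bp) at 100× chloroplast / 1× nuclear (1 Mb) coverage with 1%
errors — the full-size geometry shrunk ~10× so a complete
simulate→bait→assemble→resolve→compare cycle takes ~15 s; assembly
recovery and peak detection are scored over ten independent seeds, and
caller exactness (50 SNVs + 10 InDels, error-free) over the full-size
genome.

## Known limitations

* Exact k-mer matching everywhere (baiting, re-selection, anchoring):
  deterministic and fast at plastome scale, but a diverged region with
  no 31-mer in common with the bait band relies on the stage-3/4
  re-selection to be recovered.
* The assembler resolves exactly one collapsed repeat (the IR pair) by
  coverage; it is not a general repeat-resolving assembler.
* The caller requires collinear genomes (it aborts rather than guess
  across rearrangements) and reports no genotype likelihoods or
  heteroplasmy.
* Ties in the anchor-chain LIS and in assembly scoring are broken
  deterministically (input order / smaller k), not probabilistically.
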