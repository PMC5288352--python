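"""Variant landscape of chloroplast genomes: assembly-vs-reference
calling, normalization, multi-sample merging, region/feature per-kb
densities and fixed-width window tracks.

Calling is collinear and alignment-based: exact unique anchors are
chained between the sample and the reference (the quadripartite module)
and the short inter-anchor segments are globally aligned with affine
gap costs, which yields exactly the same SNVs and InDels a mapping
pipeline would report on error-free data while staying deterministic.
Externally produced VCFs can be ingested instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio import Align

from .errors import (
    EmptyChain,
    InvalidAnnotation,
    InvalidVariant,
    NotCollinear,
    ParseError,
    RefMismatch,
    ReferenceMismatch,
)
from .quadripartite import RegionMap, build_anchor_chain, region_of_position

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class Variant:
    """A left-normalized variant on 1-based reference coordinates.

    InDels use the VCF anchor-base convention: ``ref`` and ``alt``
    share their first base, and ``pos`` is the anchor position."""

    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | INS | DEL

    @property
    def is_transition(self) -> bool:
        if self.vclass != "SNV":
            raise InvalidVariant("transition/transversion applies to SNVs only")
        return (self.ref, self.alt) in TRANSITIONS

    @property
    def indel_length(self) -> int:
        """Signed length: positive insertions, negative deletions."""
        return len(self.alt) - len(self.ref)


def classify_snv(ref_base: str, alt_base: str) -> str:
    """'transition' for A<->G / C<->T, 'transversion' otherwise."""
    if ref_base == alt_base:
        raise InvalidVariant("ref and alt alleles are identical")
    if ref_base not in "ACGT" or alt_base not in "ACGT":
        raise InvalidVariant(f"non-ACGT allele {ref_base!r}/{alt_base!r}")
    return "transition" if (ref_base, alt_base) in TRANSITIONS else "transversion"


def normalize_variant(variant: Variant, reference: str) -> Variant:
    """Shift an InDel left through repeat context to its minimal
    position (anchor-base convention); SNVs pass through unchanged.
    Idempotent."""
    pos, ref, alt = variant.pos, variant.ref, variant.alt
    if reference[pos - 1 : pos - 1 + len(ref)] != ref:
        raise RefMismatch(f"reference disagrees with ref allele at {pos}")
    if variant.vclass == "SNV":
        return variant
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        elif (len(ref) == 1 or len(alt) == 1) and ref[-1] == alt[-1] and pos > 1:
            prev = reference[pos - 2]
            ref, alt = prev + ref[:-1], prev + alt[:-1]
            pos -= 1
        else:
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return replace(variant, pos=pos, ref=ref, alt=alt)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -4
    aligner.extend_gap_score = -1
    return aligner


def _segment_variants(tseg: str, qseg: str, anchor_pos: int, reference: str) -> list[Variant]:
    """Variants from one inter-anchor segment.  ``anchor_pos`` is the
    1-based reference position of the base immediately left of tseg."""
    out: list[Variant] = []
    if tseg == qseg:
        return out
    if not tseg or not qseg:
        if anchor_pos < 1:
            warnings.warn("indel at the very start of the reference skipped")
            return out
        anchor = reference[anchor_pos - 1]
        if not qseg:  # deletion of tseg
            out.append(Variant(anchor_pos, anchor + tseg, anchor, "DEL"))
        else:  # insertion of qseg
            out.append(Variant(anchor_pos, anchor, anchor + qseg, "INS"))
        return [normalize_variant(v, reference) for v in out]

    alignment = _aligner().align(tseg, qseg)[0]
    t_aln, q_aln = str(alignment[0]), str(alignment[1])
    ref_pos = anchor_pos  # last consumed reference position
    i = 0
    while i < len(t_aln):
        tb, qb = t_aln[i], q_aln[i]
        if tb != "-" and qb != "-":
            ref_pos += 1
            if tb != qb:
                out.append(Variant(ref_pos, tb, qb, "SNV"))
            i += 1
        elif qb == "-":  # deletion run
            j = i
            while j < len(t_aln) and q_aln[j] == "-":
                j += 1
            deleted = t_aln[i:j].replace("-", "")
            anchor = reference[ref_pos - 1] if ref_pos >= 1 else None
            if anchor is not None:
                out.append(Variant(ref_pos, anchor + deleted, anchor, "DEL"))
            ref_pos += len(deleted)
            i = j
        else:  # insertion run
            j = i
            while j < len(t_aln) and t_aln[j] == "-":
                j += 1
            inserted = q_aln[i:j].replace("-", "")
            anchor = reference[ref_pos - 1] if ref_pos >= 1 else None
            if anchor is not None:
                out.append(Variant(ref_pos, anchor, anchor + inserted, "INS"))
            i = j
    return [normalize_variant(v, reference) for v in out]


def call_variants(
    sample_genome: str,
    reference_genome: str,
    anchor_k: int = 21,
    min_chain_cover: float = 0.9,
) -> list[Variant]:
    """Call SNVs and InDels from a sample assembly against a reference.

    Requires the two genomes to be collinear (same rotation and
    strand): unique-k-mer anchors must cover at least
    ``min_chain_cover`` of the reference, otherwise
    :class:`NotCollinear` is raised.  Inter-anchor segments are
    globally aligned (match +1, mismatch -2, gap open -4, gap extend
    -1) and the alignment columns converted to left-normalized
    variants."""
    if sample_genome == reference_genome:
        return []
    try:
        chain = build_anchor_chain(sample_genome, reference_genome, anchor_k)
    except EmptyChain as exc:
        raise NotCollinear(f"no shared anchors: {exc}", coverage=0.0) from exc
    fwd = [a for a in chain.anchors if a.strand == "+"]
    cover = sum(a.length for a in fwd) / len(reference_genome)
    if cover < min_chain_cover:
        raise NotCollinear(
            f"anchor chain covers {cover:.1%} of the reference", coverage=cover
        )
    variants: list[Variant] = []
    prev_q, prev_t = 0, 0  # 1-based end of previous anchor
    for a in fwd + [None]:
        if a is None:
            qseg = sample_genome[prev_q:]
            tseg = reference_genome[prev_t:]
        else:
            qseg = sample_genome[prev_q : a.qstart - 1]
            tseg = reference_genome[prev_t : a.tstart - 1]
        if qseg or tseg:
            variants.extend(_segment_variants(tseg, qseg, prev_t, reference_genome))
        if a is not None:
            prev_q, prev_t = a.qend, a.tend
    variants.sort(key=lambda v: (v.pos, v.vclass))
    return variants


@dataclass
class VariantRecord:
    """All alleles observed at one (position, class) across samples."""

    pos: int
    vclass: str
    alleles: list[tuple[str, str]] = field(default_factory=list)  # (ref, alt)
    sample_allele: dict[str, int] = field(default_factory=dict)  # sample -> allele idx

    @property
    def triallelic(self) -> bool:
        return len(self.alleles) >= 2


@dataclass
class VariantTable:
    """Merged multi-sample variant set against one reference."""

    reference_id: str
    reference_length: int
    samples: list[str] = field(default_factory=list)
    records: dict[tuple[int, str], VariantRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def triallelic_count(self) -> int:
        return sum(1 for r in self.records.values() if r.triallelic)

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records.values():
            cls = "SNV" if rec.vclass == "SNV" else "InDel"
            out[cls] = out.get(cls, 0) + 1
        return out

    def positions(self, vclass: str | None = None) -> list[int]:
        if vclass == "InDel":
            wanted = {"INS", "DEL"}
        elif vclass is None:
            wanted = {"SNV", "INS", "DEL"}
        else:
            wanted = {vclass}
        return sorted(r.pos for r in self.records.values() if r.vclass in wanted)


def merge_samples(
    per_sample: dict[str, list[Variant]],
    reference_id: str,
    reference_length: int,
) -> VariantTable:
    """Merge normalized per-sample variant lists into a
    :class:`VariantTable`, grouping by (position, class).  A position
    becomes triallelic when samples disagree on the alternate allele.
    INS and DEL are kept as distinct classes at the same position."""
    table = VariantTable(reference_id, reference_length, samples=sorted(per_sample))
    for sample in table.samples:
        for v in per_sample[sample]:
            if not 1 <= v.pos <= reference_length:
                raise ReferenceMismatch(
                    f"variant at {v.pos} outside reference of {reference_length} bp"
                )
            rec = table.records.setdefault(
                (v.pos, v.vclass), VariantRecord(v.pos, v.vclass)
            )
            allele = (v.ref, v.alt)
            if allele not in rec.alleles:
                rec.alleles.append(allele)
            rec.sample_allele[sample] = rec.alleles.index(allele)
    return table


@dataclass
class FeaturePartition:
    """Exon / intron / intergenic partition of the reference."""

    reference_length: int
    exon_mask: np.ndarray  # boolean, index 0 = position 1
    intron_mask: np.ndarray
    intergenic_mask: np.ndarray

    def span(self, category: str) -> int:
        return int(
            {"exon": self.exon_mask, "intron": self.intron_mask, "intergenic": self.intergenic_mask}[
                category
            ].sum()
        )

    def category_of(self, pos: int) -> str:
        i = pos - 1
        if self.exon_mask[i]:
            return "exon"
        if self.intron_mask[i]:
            return "intron"
        return "intergenic"


def build_feature_partition(
    genes: list[tuple[str, int, int, list[tuple[int, int]]]],
    reference_length: int,
) -> FeaturePartition:
    """Partition the reference into exon, intron and intergenic space.

    ``genes`` is a list of ``(gene_id, start, end, [(exon_start,
    exon_end), ...])`` with 1-based inclusive coordinates.  Exon space
    is the union of exon spans, intron space is gene space minus exon
    space, intergenic the complement; the three categories partition
    the reference exactly."""
    gene_mask = np.zeros(reference_length, dtype=bool)
    exon_mask = np.zeros(reference_length, dtype=bool)
    for gene_id, gstart, gend, exons in genes:
        if not 1 <= gstart <= gend <= reference_length:
            raise InvalidAnnotation(f"gene {gene_id} span outside reference")
        gene_mask[gstart - 1 : gend] = True
        for es, ee in exons:
            if not gstart <= es <= ee <= gend:
                raise InvalidAnnotation(f"exon {es}-{ee} outside gene {gene_id}")
            exon_mask[es - 1 : ee] = True
    intron_mask = gene_mask & ~exon_mask
    intergenic_mask = ~gene_mask
    return FeaturePartition(reference_length, exon_mask, intron_mask, intergenic_mask)


def load_annotation(path) -> list[tuple[str, int, int, list[tuple[int, int]]]]:
    """Load gene/exon spans from GFF3 or a simple TSV
    (seqid, type, start, end, gene_id)."""
    path = str(path)
    if path.endswith((".gff", ".gff3")):
        return _load_gff3(path)
    genes: dict[str, list] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ParseError(f"expected 5 TSV columns, got {len(parts)}", record_index=ln)
            _seqid, ftype, start, end, gene_id = parts
            entry = genes.setdefault(gene_id, [None, []])
            if ftype == "gene":
                entry[0] = (int(start), int(end))
            elif ftype == "exon":
                entry[1].append((int(start), int(end)))
    out = []
    for gene_id, (span, exons) in genes.items():
        if span is None:
            raise ParseError(f"exons without a gene record for {gene_id}")
        out.append((gene_id, span[0], span[1], sorted(exons)))
    return out


def _load_gff3(path):
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    out = []
    for gene in db.features_of_type("gene"):
        exons = [
            (e.start, e.end)
            for e in db.children(gene, featuretype="exon", order_by="start")
        ]
        out.append((gene.id, gene.start, gene.end, exons))
    return out


def per_kb_density(count: int, span_bp: int) -> float:
    """Variants per kilobase: count * 1000 / span."""
    return count * 1000.0 / span_bp if span_bp else 0.0


def display_density(density: float) -> str:
    """Report-style rounding: one decimal at >= 0.1 per kb, two below
    (so 17.24 prints as 17.2 and 0.039 as 0.04)."""
    return f"{density:.1f}" if density >= 0.1 else f"{density:.2f}"


def density_report(
    table: VariantTable,
    region_map: RegionMap | None = None,
    feature_partition: FeaturePartition | None = None,
    classes: tuple[str, ...] = ("SNV", "InDel"),
) -> pd.DataFrame:
    """Per-region and per-feature variant densities.

    Each variant is assigned to the region/feature containing its
    normalized 1-based position (the anchor base for InDels).  The IR
    scope pools both copies over their combined span.  Returns a
    DataFrame with columns scope, vclass, count, span_bp,
    density_per_kb (full precision) and display (report rounding)."""
    rows = []
    n = table.reference_length
    scopes: list[tuple[str, int, set[int] | None]] = [("whole", n, None)]
    if region_map is not None:
        for scope, labels in (("LSC", {"LSC"}), ("SSC", {"SSC"}), ("IR", {"IRa", "IRb"})):
            span = sum(region_map.length(lab) for lab in labels)
            scopes.append((scope, span, labels))
    for vclass in classes:
        positions = table.positions(vclass)
        for scope, span, labels in scopes:
            if labels is None:
                count = len(positions)
            else:
                count = sum(
                    1 for p in positions if region_of_position(region_map, p) in labels
                )
            dens = per_kb_density(count, span)
            rows.append((scope, vclass, count, span, dens, display_density(dens)))
        if feature_partition is not None:
            for category in ("exon", "intron", "intergenic"):
                span = feature_partition.span(category)
                count = sum(
                    1 for p in positions if feature_partition.category_of(p) == category
                )
                dens = per_kb_density(count, span)
                rows.append((category, vclass, count, span, dens, display_density(dens)))
    return pd.DataFrame(
        rows, columns=["scope", "vclass", "count", "span_bp", "density_per_kb", "display"]
    )


@dataclass
class WindowTrack:
    """Non-overlapping fixed-width window counts from position 1; the
    last partial window keeps its true span."""

    window: int
    counts: np.ndarray
    reference_length: int

    def spans(self) -> list[tuple[int, int]]:
        out = []
        for i in range(len(self.counts)):
            start = i * self.window + 1
            out.append((start, min(start + self.window - 1, self.reference_length)))
        return out

    def hotspots(self, percentile: float = 95.0) -> list[tuple[int, int, int]]:
        """Windows whose count exceeds the given percentile of all
        window counts: (start, end, count)."""
        if len(self.counts) == 0:
            return []
        threshold = np.percentile(self.counts, percentile)
        return [
            (s, e, int(c))
            for (s, e), c in zip(self.spans(), self.counts)
            if c > threshold
        ]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# start\tend\tcount (1-based inclusive spans)\n")
            for (s, e), c in zip(self.spans(), self.counts):
                fh.write(f"{s}\t{e}\t{int(c)}\n")


def window_density(table: VariantTable, window: int = 500) -> WindowTrack:
    """Count variants (all classes) in consecutive ``window``-bp bins
    over the reference, by normalized position."""
    if window < 1:
        raise InvalidVariant("window must be >= 1")
    n_windows = -(-table.reference_length // window)
    counts = np.zeros(n_windows, dtype=int)
    for pos in table.positions():
        counts[(pos - 1) // window] += 1
    return WindowTrack(window, counts, table.reference_length)


def write_vcf(table: VariantTable, path) -> None:
    """Write a VCF 4.2 file with haploid per-sample GT presence."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line("##source=chlorosmith")
    header.contigs.add(table.reference_id, length=table.reference_length)
    header.formats.add("GT", 1, "String", "Genotype")
    for sample in table.samples:
        header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for (pos, _vclass), rec in sorted(table.records.items()):
            ref, alts = _pad_alleles(rec.alleles)
            r = out.new_record(
                contig=table.reference_id, start=pos - 1, alleles=(ref, *alts)
            )
            r.stop = pos - 1 + len(ref)
            for sample in table.samples:
                idx = rec.sample_allele.get(sample)
                r.samples[sample]["GT"] = (None,) if idx is None else (idx + 1,)
            out.write(r)


def _pad_alleles(alleles: list[tuple[str, str]]) -> tuple[str, list[str]]:
    """Rewrite (ref, alt) pairs sharing a position onto one common ref."""
    ref = max((r for r, _ in alleles), key=len)
    alts = []
    for r, a in alleles:
        alts.append(a + ref[len(r) :])
    return ref, alts


def read_vcf(path) -> VariantTable:
    """Ingest a VCF 4.2 file (e.g. from an external mapping pipeline)
    into a :class:`VariantTable`; symbolic alleles are skipped with a
    warning."""
    import pysam

    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ParseError(f"cannot parse VCF: {exc}") from exc
    contig = next(iter(vf.header.contigs.values()), None)
    ref_id = contig.name if contig is not None else "reference"
    ref_len = contig.length if contig is not None and contig.length else 0
    samples = list(vf.header.samples)
    per_sample: dict[str, list[Variant]] = {s: [] for s in samples or ["sample1"]}
    for rec in vf:
        if rec.alts is None:
            continue
        for ai, alt in enumerate(rec.alts, start=1):
            if alt.startswith("<") or "[" in alt or "]" in alt:
                warnings.warn(f"skipping symbolic allele {alt} at {rec.pos}")
                continue
            v = _variant_from_alleles(rec.pos, rec.ref, alt)
            if samples:
                for s in samples:
                    gt = rec.samples[s].get("GT")
                    if gt and any(g == ai for g in gt if g is not None):
                        per_sample[s].append(v)
            else:
                per_sample["sample1"].append(v)
        ref_len = max(ref_len, rec.stop)
    return merge_samples(per_sample, ref_id, ref_len or 1)


def _variant_from_alleles(pos: int, ref: str, alt: str) -> Variant:
    # trim shared trailing context so the class is read off the lengths
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    if len(ref) == len(alt) == 1:
        return Variant(pos, ref, alt, "SNV")
    if len(alt) > len(ref):
        return Variant(pos, ref, alt, "INS")
    return Variant(pos, ref, alt, "DEL")
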