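"""Synthetic plastome study generator.

Emulates the data this toolkit is built for: a circular quadripartite
chloroplast genome (default region sizes LSC 83,282 / SSC 17,776 /
IR 26,212 bp per copy), accession genomes derived from it by
region-specific SNV and InDel mutation, and 400-bp-insert paired-end
shotgun reads in which the chloroplast is vastly over-represented
relative to a nuclear background.  Every output carries full ground
truth (region map, mutation log, per-read origin labels) so the
assembly, baiting and variant-calling stages can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameter
from .quadripartite import RegionMap, region_of_position
from .seqs import ReadPair, revcomp

DEFAULT_LSC = 83_282
DEFAULT_SSC = 17_776
DEFAULT_IR = 26_212
DEFAULT_GC = 0.36

# Per-bp mutation probabilities for one accession.  Region ratios follow
# the strong IR suppression of plastome substitution rates (single-copy
# regions mutate roughly 5-7x faster than the IRs); magnitudes are at
# the within-species scale of a few variants per kb.
DEFAULT_SNV_RATES = {"LSC": 0.0022, "SSC": 0.0033, "IR": 0.00045}
DEFAULT_INDEL_RATES = {"LSC": 0.0008, "SSC": 0.0007, "IR": 0.00007}

MAX_INDEL_LEN = 38
_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimulatedGenome:
    """Ground-truth circular quadripartite genome."""

    sequence: str
    region_map: RegionMap
    seed: int


@dataclass(frozen=True)
class Mutation:
    """One applied mutation in VCF-style anchored representation on
    1-based parent coordinates (for INS/DEL, ref and alt share the
    anchor base at ``pos``)."""

    pos: int
    ref: str
    alt: str
    vclass: str  # SNV | INS | DEL


@dataclass
class MutationLog:
    """Every mutation applied to derive one accession from its parent."""

    accession: str
    mutations: list[Mutation] = field(default_factory=list)
    rejected: int = 0  # proposals dropped by the spacing/boundary guard

    def __len__(self) -> int:
        return len(self.mutations)


@dataclass(frozen=True)
class ReadOrigin:
    origin: str  # chloroplast | nuclear
    source: str
    frag_start: int  # 1-based on the source sequence
    frag_end: int


def _random_dna(rng: np.random.Generator, length: int, gc_fraction: float) -> str:
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    arr = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    return arr.tobytes().decode()


def _break_junction_symmetry(arc: str, rng: np.random.Generator) -> str:
    """If an arc's terminal base complements its first base, the
    adjacent IR pair would extend past its planted boundary; replace the
    terminal base so the planted IR is exactly maximal."""
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    if arc[-1] != comp[arc[0]]:
        return arc
    choices = [b for b in "ACGT" if b != comp[arc[0]]]
    return arc[:-1] + str(rng.choice(choices))


def simulate_genome(
    lsc_len: int = DEFAULT_LSC,
    ssc_len: int = DEFAULT_SSC,
    ir_len: int = DEFAULT_IR,
    gc_fraction: float = DEFAULT_GC,
    seed: int = 0,
) -> SimulatedGenome:
    """Draw a random circular quadripartite genome.

    The sequence is laid out LSC, IRa, SSC, IRb with IRb the exact
    reverse complement of IRa, so its total length is
    ``lsc_len + ssc_len + 2*ir_len``.  Deterministic in ``seed``.
    """
    for name, val in (("lsc_len", lsc_len), ("ssc_len", ssc_len), ("ir_len", ir_len)):
        if val <= 0:
            raise InvalidParameter(f"{name} must be positive, got {val}")
    if lsc_len <= ssc_len:
        raise InvalidParameter("LSC must be longer than SSC")
    if not 0.0 < gc_fraction < 1.0:
        raise InvalidParameter(f"gc_fraction must be in (0,1), got {gc_fraction}")
    if min(lsc_len, ssc_len, ir_len) < 124:
        warnings.warn("region shorter than 4x a typical k-mer size; assembly may be degenerate")
    rng = np.random.default_rng(seed)
    lsc = _random_dna(rng, lsc_len, gc_fraction)
    ira = _random_dna(rng, ir_len, gc_fraction)
    ssc = _random_dna(rng, ssc_len, gc_fraction)
    # keep the planted IR maximal: the bases flanking each junction must
    # not accidentally extend the mirror symmetry by chance
    lsc = _break_junction_symmetry(lsc, rng)
    ssc = _break_junction_symmetry(ssc, rng)
    seq = lsc + ira + ssc + revcomp(ira)
    total = len(seq)
    rm = RegionMap(
        lsc=(1, lsc_len),
        ira=(lsc_len + 1, lsc_len + ir_len),
        ssc=(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len + 1, total),
        total=total,
    )
    rm.validate()
    return SimulatedGenome(seq, rm, seed)


def apply_mutation_log(parent: str, log: MutationLog) -> str:
    """Rebuild the accession sequence by splicing the logged mutations
    into the parent; the exact inverse bookkeeping of mutation."""
    out = []
    cursor = 0  # 0-based position in parent
    for mut in sorted(log.mutations, key=lambda m: m.pos):
        start = mut.pos - 1
        if start < cursor:
            raise InvalidParameter(f"overlapping mutations at position {mut.pos}")
        if parent[start : start + len(mut.ref)] != mut.ref:
            raise InvalidParameter(f"log ref mismatch at position {mut.pos}")
        out.append(parent[cursor:start])
        out.append(mut.alt)
        cursor = start + len(mut.ref)
    out.append(parent[cursor:])
    return "".join(out)


def _mirror_mutation(mut: Mutation, parent: str, ira: tuple[int, int], irb: tuple[int, int]) -> Mutation:
    """Project a mutation in IRa onto the corresponding IRb position so
    the inverted-repeat mirror identity survives mutation."""
    a1, _ = ira
    b1, b2 = irb
    t = mut.pos - a1  # 0-based offset within IRa
    if mut.vclass == "SNV":
        p = b2 - t
        return Mutation(p, revcomp(mut.ref), revcomp(mut.alt), "SNV")
    if mut.vclass == "DEL":
        ell = len(mut.ref) - 1  # deleted bases sit at IRa offsets t+1 .. t+ell
        p = b2 - t - ell - 1  # anchor just left of the mirrored run
        ref = parent[p - 1 : p - 1 + ell + 1]
        return Mutation(p, ref, ref[0], "DEL")
    # INS: inserted bases sit between IRa offsets t and t+1; the mirror
    # inserts revcomp(bases) after IRb offset (irlen-1-t-1).
    ins = mut.alt[1:]
    p = b2 - t - 1
    anchor = parent[p - 1]
    return Mutation(p, anchor, anchor + revcomp(ins), "INS")


def _indel_alleles(
    parent: str, pos: int, rng: np.random.Generator, max_indel_len: int, gc_fraction: float
) -> Mutation:
    """Draw an insertion or deletion anchored at ``pos`` with length
    from a geometric law (p=0.5) truncated at ``max_indel_len`` —
    single-base InDels dominate, as observed in plastomes."""
    length = min(int(rng.geometric(0.5)), max_indel_len)
    anchor = parent[pos - 1]
    if rng.random() < 0.5:
        ins = _random_dna(rng, length, gc_fraction)
        return Mutation(pos, anchor, anchor + ins, "INS")
    ref = parent[pos - 1 : pos - 1 + length + 1]
    return Mutation(pos, ref, anchor, "DEL")


def mutate_genome(
    genome: SimulatedGenome,
    snv_rate_by_region: dict[str, float] | None = None,
    indel_rate_by_region: dict[str, float] | None = None,
    max_indel_len: int = MAX_INDEL_LEN,
    min_separation: int = 31,
    accession: str = "acc1",
    seed: int = 0,
    gc_fraction: float = DEFAULT_GC,
) -> tuple[str, MutationLog]:
    """Derive an accession genome by per-bp Bernoulli mutation.

    Rates are given per region class (keys LSC, SSC, IR); mutations
    drawn in IRa are mirrored into IRb so the accession keeps the exact
    IR mirror identity.  Proposals closer than ``min_separation`` bp to
    an accepted mutation, or within ``min_separation + max_indel_len``
    bp of a region boundary, are rejected (counted in the log) so that
    truth-to-call matching stays unambiguous.
    """
    snv_rates = dict(DEFAULT_SNV_RATES if snv_rate_by_region is None else snv_rate_by_region)
    indel_rates = dict(DEFAULT_INDEL_RATES if indel_rate_by_region is None else indel_rate_by_region)
    for rates in (snv_rates, indel_rates):
        for key, rate in rates.items():
            if rate < 0:
                raise InvalidParameter(f"negative mutation rate for {key}")
            if rate > 0.5:
                raise InvalidParameter(f"rate {rate} for {key} would make alignment meaningless")

    rng = np.random.default_rng(seed)
    parent = genome.sequence
    rm = genome.region_map
    margin = min_separation + max_indel_len
    log = MutationLog(accession)
    accepted: list[int] = []

    # Only LSC, IRa, SSC are drawn from; IRb is filled in by mirroring.
    for region in ("LSC", "IRa", "SSC"):
        rate_key = "IR" if region.startswith("IR") else region
        s, e = rm.span(region)
        length = rm.length(region)
        snv_hits = np.nonzero(rng.random(length) < snv_rates.get(rate_key, 0.0))[0]
        indel_hits = np.nonzero(rng.random(length) < indel_rates.get(rate_key, 0.0))[0]
        proposals = sorted(
            [(int(off), "SNV") for off in snv_hits] + [(int(off), "INDEL") for off in indel_hits]
        )
        for off, kind in proposals:
            if off < margin or off >= length - margin:
                log.rejected += 1
                continue
            pos = s + off  # spans here never wrap (simulated layout)
            if accepted and any(abs(pos - p) < min_separation for p in accepted[-4:]):
                log.rejected += 1
                continue
            if kind == "SNV":
                ref = parent[pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                mut = Mutation(pos, ref, alt, "SNV")
            else:
                mut = _indel_alleles(parent, pos, rng, max_indel_len, gc_fraction)
            log.mutations.append(mut)
            accepted.append(pos)
            if region == "IRa":
                log.mutations.append(_mirror_mutation(mut, parent, rm.span("IRa"), rm.span("IRb")))

    log.mutations.sort(key=lambda m: m.pos)
    return apply_mutation_log(parent, log), log


def plant_mutations(
    genome: SimulatedGenome,
    n_snv: int,
    n_indel: int,
    max_indel_len: int = MAX_INDEL_LEN,
    min_separation: int = 60,
    accession: str = "acc1",
    seed: int = 0,
) -> tuple[str, MutationLog]:
    """Plant exact mutation counts (SNVs then InDels) at well-separated
    single-copy positions — the controlled input for caller-exactness
    checks.  Positions are uniform over LSC and SSC interiors."""
    rng = np.random.default_rng(seed)
    rm = genome.region_map
    parent = genome.sequence
    margin = min_separation + max_indel_len
    candidates: list[int] = []
    for region in ("LSC", "SSC"):
        s, _ = rm.span(region)
        length = rm.length(region)
        candidates.extend(range(s + margin, s + length - margin))
    rng.shuffle(candidates)
    chosen: list[int] = []
    for pos in candidates:
        if len(chosen) == n_snv + n_indel:
            break
        if all(abs(pos - p) >= min_separation for p in chosen):
            chosen.append(pos)
    if len(chosen) < n_snv + n_indel:
        raise InvalidParameter("genome too small for the requested mutation count")
    log = MutationLog(accession)
    for i, pos in enumerate(chosen):
        if i < n_snv:
            ref = parent[pos - 1]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            log.mutations.append(Mutation(pos, ref, alt, "SNV"))
        else:
            log.mutations.append(_indel_alleles(parent, pos, rng, max_indel_len, DEFAULT_GC))
    log.mutations.sort(key=lambda m: m.pos)
    return apply_mutation_log(parent, log), log


def _phred_profile(read_len: int, profile: str) -> str:
    if profile == "constant":
        return chr(33 + 35) * read_len
    if profile == "decay":  # Q40 at the 5' end decaying linearly to Q20
        return "".join(chr(33 + int(round(40 - 20 * i / max(read_len - 1, 1)))) for i in range(read_len))
    raise InvalidParameter(f"unknown quality profile {profile!r}")


def simulate_reads(
    genomes: SimulatedGenome | str | list[tuple[str, str, float]],
    nuclear_len: int = 1_000_000,
    chloro_coverage: float = 100.0,
    nuclear_coverage: float = 1.0,
    read_len: int = 150,
    insert_mean: float = 400.0,
    insert_sd: float = 40.0,
    error_rate: float = 0.01,
    quality_profile: str = "constant",
    seed: int = 0,
) -> tuple[list[ReadPair], dict[str, ReadOrigin]]:
    """Simulate paired-end shotgun reads with a nuclear background.

    ``genomes`` is a circular chloroplast genome (or a list of
    ``(name, sequence, copy_number)`` for a multi-accession pool); each
    receives ``round(copy_number * chloro_coverage * len / (2*read_len))``
    pairs with fragment starts uniform on the circle, so some pairs span
    the origin.  The nuclear background is an i.i.d. random linear
    sequence of ``nuclear_len`` bp sampled at ``nuclear_coverage``.
    Substitution errors are uniform at ``error_rate`` per base.
    """
    if chloro_coverage <= 0:
        raise InvalidParameter("chloro_coverage must be positive")
    if read_len > insert_mean:
        raise InvalidParameter(f"read_len {read_len} exceeds insert_mean {insert_mean}")
    if insert_mean < 2 * read_len:
        warnings.warn("insert_mean below 2x read length: mates will overlap")

    if isinstance(genomes, SimulatedGenome):
        pool = [("chloroplast", genomes.sequence, 1.0)]
    elif isinstance(genomes, str):
        pool = [("chloroplast", genomes, 1.0)]
    else:
        pool = list(genomes)

    rng = np.random.default_rng(seed)
    pairs: list[ReadPair] = []
    labels: dict[str, ReadOrigin] = {}
    qual = _phred_profile(read_len, quality_profile)

    def emit(source_name, source_seq, circular, n_pairs, origin, tag):
        slen = len(source_seq)
        doubled = source_seq + source_seq if circular else source_seq
        inserts = np.maximum(
            read_len, np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int)
        )
        inserts = np.minimum(inserts, slen)
        if circular:
            starts = rng.integers(0, slen, n_pairs)
        else:
            starts = np.array([rng.integers(0, slen - ins + 1) for ins in inserts])
        flips = rng.random(n_pairs) < 0.5
        for idx in range(n_pairs):
            ins = int(inserts[idx])
            start = int(starts[idx])
            frag = doubled[start : start + ins]
            if flips[idx]:
                frag = revcomp(frag)
            s1 = _with_errors(frag[:read_len], rng, error_rate)
            s2 = _with_errors(revcomp(frag[-read_len:]), rng, error_rate)
            rid = f"{tag}_{idx:07d}"
            pairs.append(ReadPair(rid, s1, qual, s2, qual))
            labels[rid] = ReadOrigin(origin, source_name, start + 1, start + ins)

    for name, seq, copies in pool:
        n_pairs = int(round(copies * chloro_coverage * len(seq) / (2 * read_len)))
        emit(name, seq, True, n_pairs, "chloroplast", f"chl_{name}")
    if nuclear_coverage > 0 and nuclear_len > 0:
        nuclear = _random_dna(rng, nuclear_len, 0.5)
        n_pairs = int(round(nuclear_coverage * nuclear_len / (2 * read_len)))
        emit("nuclear", nuclear, False, n_pairs, "nuclear", "nuc")
    return pairs, labels


def _with_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    mask = np.nonzero(rng.random(len(seq)) < error_rate)[0]
    if mask.size == 0:
        return seq
    out = list(seq)
    for i in mask:
        out[i] = str(rng.choice([b for b in "ACGT" if b != out[i]]))
    return "".join(out)


def write_mutation_log(log: MutationLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("# accession\tpos\tref\talt\tclass (1-based parent coordinates)\n")
        for m in log.mutations:
            fh.write(f"{log.accession}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.vclass}\n")


def write_labels(labels: dict[str, ReadOrigin], path) -> None:
    with open(path, "w") as fh:
        fh.write("# read_id\torigin\tsource\tfrag_start\tfrag_end\n")
        for rid, lab in labels.items():
            fh.write(f"{rid}\t{lab.origin}\t{lab.source}\t{lab.frag_start}\t{lab.frag_end}\n")


def genome_region_of(genome: SimulatedGenome, pos: int) -> str:
    """Region label (LSC/IRa/SSC/IRb) of a 1-based genome position."""
    return region_of_position(genome.region_map, pos)
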