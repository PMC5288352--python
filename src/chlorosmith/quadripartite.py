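"""Quadripartite plastome structure: inverted-repeat detection, canonical
rotation/orientation, genome equivalence, anchor chains, region slicing.

Angiosperm chloroplast genomes are circular with four parts — a large
single-copy (LSC) arc and a small single-copy (SSC) arc separated by two
identical inverted-repeat (IR) copies.  Because the molecule is circular
and the SSC occurs in both orientations in vivo, a genome has many string
representations; this module defines one canonical form (LSC first, order
LSC–IRa–SSC–IRb, lexicographically smaller strand) so genomes can be
compared by string identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EmptyChain, InvalidRegionMap, NoIRFound
from .seqs import iter_kmers, revcomp

REGION_ORDER = ("LSC", "IRa", "SSC", "IRb")


@dataclass(frozen=True)
class RegionMap:
    """Labelled quadripartite spans, 1-based inclusive, on a circular
    coordinate system of ``total`` bp.

    Spans are stored in canonical order LSC, IRa, SSC, IRb; a span may
    wrap past the origin (start > end).
    """

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    total: int

    def span(self, name: str) -> tuple[int, int]:
        return getattr(self, {"LSC": "lsc", "IRa": "ira", "SSC": "ssc", "IRb": "irb"}[name])

    def length(self, name: str) -> int:
        s, e = self.span(name)
        if e >= s:
            return e - s + 1
        return self.total - s + 1 + e  # wraps the origin

    def validate(self) -> None:
        lengths = {n: self.length(n) for n in REGION_ORDER}
        if any(v <= 0 for v in lengths.values()):
            raise InvalidRegionMap("all four regions must be non-empty")
        if sum(lengths.values()) != self.total:
            raise InvalidRegionMap(
                f"region lengths sum to {sum(lengths.values())}, total is {self.total}"
            )
        if lengths["IRa"] != lengths["IRb"]:
            raise InvalidRegionMap("IR copies differ in length")
        if lengths["LSC"] <= lengths["SSC"]:
            raise InvalidRegionMap("LSC must be longer than SSC")
        # circular order must be LSC -> IRa -> SSC -> IRb -> (LSC)
        for cur, nxt in zip(REGION_ORDER, REGION_ORDER[1:] + REGION_ORDER[:1]):
            if self.span(cur)[1] % self.total + 1 != self.span(nxt)[0]:
                raise InvalidRegionMap(f"{nxt} does not follow {cur} on the circle")
        covered = set()
        for n in REGION_ORDER:
            s, e = self.span(n)
            pos = s
            for _ in range(self.length(n)):
                if pos in covered:
                    raise InvalidRegionMap("region spans overlap")
                covered.add(pos)
                pos = pos % self.total + 1
        if len(covered) != self.total:
            raise InvalidRegionMap("region spans do not cover the circle")


@dataclass(frozen=True)
class QuadripartiteGenome:
    """A plastome in canonical form: starts at LSC base 1, region order
    LSC, IRa, SSC, IRb, on the lexicographically smaller strand."""

    sequence: str
    region_map: RegionMap
    provenance: str = "assembled"  # assembled | reference | simulated

    def __post_init__(self):
        if len(self.sequence) != self.region_map.total:
            raise InvalidRegionMap("sequence length disagrees with region map")


@dataclass(frozen=True)
class Anchor:
    """One exact unique match between query and target."""

    qstart: int  # 1-based inclusive
    qend: int
    tstart: int
    tend: int
    strand: str  # '+' or '-'

    @property
    def length(self) -> int:
        return self.qend - self.qstart + 1


@dataclass
class AnchorChain:
    """A strictly collinear subset of anchors (increasing in both query
    and target coordinates), as used for dot plots and variant calling."""

    anchors: list[Anchor] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.anchors)

    def anchored_fraction(self, target_length: int) -> float:
        return sum(a.length for a in self.anchors) / target_length if target_length else 0.0

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# qstart\tqend\ttstart\ttend\tstrand (1-based inclusive)\n")
            for a in self.anchors:
                fh.write(f"{a.qstart}\t{a.qend}\t{a.tstart}\t{a.tend}\t{a.strand}\n")


def _rotate(seq: str, offset: int) -> str:
    """Rotate so that 0-based position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def _circular_slice(seq: str, start: int, end: int) -> str:
    """1-based inclusive slice that may wrap past the origin."""
    if end >= start:
        return seq[start - 1 : end]
    return seq[start - 1 :] + seq[:end]


def find_inverted_repeat(sequence: str, min_ir_len: int = 1000, seed_k: int = 21) -> RegionMap:
    """Locate the longest pair of disjoint, exactly reverse-complementary
    spans on a circular sequence and label the quadripartite regions.

    Matching spans are seeded by ``seed_k``-mers shared between the
    sequence and its reverse complement and extended maximally.  The
    longer arc between the two IR copies becomes the LSC, the shorter
    the SSC.  Raises :class:`NoIRFound` when no repeat of at least
    ``min_ir_len`` exists.
    """
    n = len(sequence)
    if n < 2 * min_ir_len:
        raise NoIRFound(f"sequence of {n} bp cannot hold two {min_ir_len} bp IR copies")
    doubled = sequence + sequence  # circular search space

    # Index forward k-mers of the original sequence by packed code.
    index: dict[int, list[int]] = {}
    for pos, fwd, _ in iter_kmers(sequence, seed_k):
        index.setdefault(fwd, []).append(pos)

    # A seed is (i, j): sequence[i:i+k] == revcomp(sequence[j:j+k]).
    # All positions of one inverted-repeat pair share the anti-diagonal
    # i + j + k == const, so group seeds by that sum.
    diagonals: dict[int, list[int]] = {}
    for pos, _, rc_code in iter_kmers(doubled, seed_k):
        if pos >= n:
            break
        for j in index.get(rc_code, ()):
            if j == pos:
                continue
            diagonals.setdefault(pos + j, []).append(pos)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    best: tuple[int, int, int] | None = None  # (length, start_a, start_b)
    for s, starts in diagonals.items():
        starts.sort()
        # Split into strictly contiguous runs; within one inverted-repeat
        # pair every consecutive position seeds, so runs are exact matches.
        runs = []
        run_start = prev = starts[0]
        for p in starts[1:]:
            if p != prev + 1:
                runs.append((run_start, prev))
                run_start = p
            prev = p
        runs.append((run_start, prev))
        for a0, a1 in runs:
            # A = sequence[i : i+length] (in doubled coordinates),
            # B = sequence[j : j+length], with A == revcomp(B) and
            # invariant s == i + j + length - seed_k.
            i, j = a0, s - a1
            length = a1 - a0 + seed_k
            if j < 0 or j + length > n:
                continue
            # extend A left / B right
            while i > 0 and j + length < n and doubled[i - 1] == comp.get(sequence[j + length]):
                i -= 1
                length += 1
            # extend A right / B left
            while i + length < 2 * n and j > 0 and doubled[i + length] == comp.get(sequence[j - 1]):
                length += 1
                j -= 1
            if length < min_ir_len or length * 2 >= n:
                continue
            a_span = (i % n, length)
            b_span = (j % n, length)
            if _spans_disjoint(a_span, b_span, n):
                cand = (length, *sorted((a_span[0], b_span[0])))
                if best is None or cand > best:
                    best = cand
    if best is None:
        raise NoIRFound(f"no inverted repeat of >= {min_ir_len} bp found")
    length, start_a, start_b = best
    return _region_map_from_ir(n, start_a, start_b, length)


def _spans_disjoint(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """Disjointness of two (start0, length) spans on a circle of size n."""
    return (b[0] - a[0]) % n >= a[1] and (a[0] - b[0]) % n >= b[1]


def _region_map_from_ir(n: int, start_a: int, start_b: int, ir_len: int) -> RegionMap:
    """Build a RegionMap from the two IR start offsets (0-based)."""
    end_a = (start_a + ir_len - 1) % n
    end_b = (start_b + ir_len - 1) % n
    # Arc from end of first IR copy to start of the second, and vice versa.
    arc1_start = (end_a + 1) % n
    arc1_len = (start_b - arc1_start) % n
    arc2_start = (end_b + 1) % n
    arc2_len = (start_a - arc2_start) % n
    if arc1_len == 0 or arc2_len == 0:
        raise NoIRFound("IR copies are adjacent; no quadripartite structure")
    if arc1_len >= arc2_len:
        lsc = (arc1_start, arc1_len)
        ssc = (arc2_start, arc2_len)
        ira_start, irb_start = start_b, start_a
    else:
        lsc = (arc2_start, arc2_len)
        ssc = (arc1_start, arc1_len)
        ira_start, irb_start = start_a, start_b
    # IRa is the copy immediately following the LSC.
    def span(start0: int, length: int) -> tuple[int, int]:
        return (start0 + 1, (start0 + length - 1) % n + 1)

    rm = RegionMap(
        lsc=span(*lsc),
        ira=span((lsc[0] + lsc[1]) % n, ir_len),
        ssc=span(*ssc),
        irb=span((ssc[0] + ssc[1]) % n, ir_len),
        total=n,
    )
    rm.validate()
    return rm


def resolve_collapsed(
    contigs: list,
    k: int,
    min_ir_len: int = 1000,
    min_cov_ratio: float = 1.5,
) -> QuadripartiteGenome:
    """Rebuild the quadripartite circle from a collapsed assembly.

    A de Bruijn assembly of a plastome collapses the two IR copies into
    one path at ~2x single-copy coverage, leaving three scaffolds (the
    two single-copy arcs and the collapsed IR) whose ends overlap by
    k-1 bp at the four junctions.  ``contigs`` are objects with
    ``sequence`` and ``coverage`` attributes (or ``(sequence,
    coverage)`` tuples).  The IR candidate must carry at least
    ``min_cov_ratio`` times the mean single-copy coverage.  The
    reconstructed circle is returned canonicalized.
    """
    items = [
        (c[0], c[1]) if isinstance(c, tuple) else (c.sequence, c.coverage) for c in contigs
    ]
    items = [it for it in items if len(it[0]) >= k]
    if not items:
        raise NoIRFound("no usable contigs")
    items.sort(key=lambda it: -len(it[0]))
    if len(items) == 1:
        # Already a full circle (IR below k, or supplied pre-resolved).
        genome = items[0][0]
        rm = find_inverted_repeat(genome, min_ir_len)
        return canonicalize(genome, rm, "assembled")
    items = items[:3]
    if len(items) < 3:
        raise NoIRFound("collapsed plastome needs three scaffolds (two arcs + IR)")

    ov = k - 1
    best = None  # (cov_ratio, canonical genome)
    for r_idx in range(3):
        r_seq, r_cov = items[r_idx]
        rest = [items[i] for i in range(3) if i != r_idx]
        single_cov = (rest[0][1] + rest[1][1]) / 2.0
        if single_cov > 0 and r_cov / single_cov < min_cov_ratio:
            continue
        arrangements = [(rest[0][0], rest[1][0]), (rest[1][0], rest[0][0])]
        for a_raw, b_raw in arrangements:
            for a_seq in (a_raw, revcomp(a_raw)):
                for r_or in (r_seq, revcomp(r_seq)):
                    for b_seq in (b_raw, revcomp(b_raw)):
                        rc_r = revcomp(r_or)
                        if not (
                            a_seq[-ov:] == r_or[:ov]
                            and r_or[-ov:] == b_seq[:ov]
                            and b_seq[-ov:] == rc_r[:ov]
                            and rc_r[-ov:] == a_seq[:ov]
                        ):
                            continue
                        circle = a_seq + r_or[ov:] + b_seq[ov:] + rc_r[ov:]
                        circle = circle[: len(circle) - ov]
                        try:
                            rm = find_inverted_repeat(circle, min_ir_len)
                            genome = canonicalize(circle, rm, "assembled")
                        except (NoIRFound, InvalidRegionMap):
                            continue
                        ratio = r_cov / single_cov if single_cov > 0 else float("inf")
                        if best is None or ratio > best[0]:
                            if best is None or best[1].sequence != genome.sequence:
                                best = (ratio, genome)
    if best is None:
        raise NoIRFound("no consistent quadripartite reconstruction from the scaffolds")
    return best[1]


def canonicalize(sequence: str, region_map: RegionMap, provenance: str = "assembled") -> QuadripartiteGenome:
    """Rotate/reflect a quadripartite circle into canonical form.

    The output starts at LSC base 1 with region order LSC, IRa, SSC,
    IRb.  Of the two strand choices the lexicographically smaller
    canonical sequence wins; IRa is always the IR copy following the
    LSC in the chosen orientation.
    """
    region_map.validate()
    if len(sequence) != region_map.total:
        raise InvalidRegionMap("sequence length disagrees with region map")
    n = region_map.total

    fwd = _rotate(sequence, region_map.lsc[0] - 1)
    rev = revcomp(fwd)
    # On the reverse strand the rotated sequence ends with rc(LSC);
    # rotate so LSC leads again.  rc maps order LSC,IRa,SSC,IRb to
    # rc(IRb),rc(SSC),rc(IRa),rc(LSC); bringing rc(LSC) to the front
    # gives order LSC', IR, SSC', IR with the IR labels swapped.
    lsc_len = region_map.length("LSC")
    rev = _rotate(rev, n - lsc_len)
    chosen = min(fwd, rev)

    ir_len = region_map.length("IRa")
    ssc_len = region_map.length("SSC")
    canon_map = RegionMap(
        lsc=(1, lsc_len),
        ira=(lsc_len + 1, lsc_len + ir_len),
        ssc=(lsc_len + ir_len + 1, lsc_len + ir_len + ssc_len),
        irb=(lsc_len + ir_len + ssc_len + 1, n),
        total=n,
    )
    canon_map.validate()
    genome = QuadripartiteGenome(chosen, canon_map, provenance)
    _check_ir_mirror(genome)
    return genome


def _check_ir_mirror(genome: QuadripartiteGenome) -> None:
    ira = slice_regions(genome)["IRa"]
    irb = slice_regions(genome)["IRb"]
    if ira != revcomp(irb):
        raise InvalidRegionMap("IRa is not the exact reverse complement of IRb")


def flip_ssc(genome: QuadripartiteGenome) -> QuadripartiteGenome:
    """Return the SSC-orientation isomer (SSC reverse-complemented in
    place); both isomers coexist in plastid preparations."""
    parts = slice_regions(genome)
    seq = parts["LSC"] + parts["IRa"] + revcomp(parts["SSC"]) + parts["IRb"]
    return canonicalize(seq, genome.region_map, genome.provenance)


def genomes_equivalent(
    a: QuadripartiteGenome | tuple[str, RegionMap],
    b: QuadripartiteGenome | tuple[str, RegionMap],
    allow_ssc_flip: bool = True,
) -> tuple[bool, dict]:
    """Test whether two plastomes are the same molecule up to rotation,
    strand, and (optionally) SSC orientation.

    Returns ``(equal, summary)``; the summary holds the matching mode
    and, for unequal same-length genomes, the mismatch count.
    """
    ga = a if isinstance(a, QuadripartiteGenome) else canonicalize(*a)
    gb = b if isinstance(b, QuadripartiteGenome) else canonicalize(*b)
    ga = canonicalize(ga.sequence, ga.region_map, ga.provenance)
    gb = canonicalize(gb.sequence, gb.region_map, gb.provenance)
    if ga.sequence == gb.sequence:
        return True, {"mode": "exact", "mismatches": 0}
    if allow_ssc_flip and flip_ssc(gb).sequence == ga.sequence:
        return True, {"mode": "ssc_flip", "mismatches": 0}
    summary: dict = {"mode": None, "length_a": len(ga.sequence), "length_b": len(gb.sequence)}
    if len(ga.sequence) == len(gb.sequence):
        candidates = [gb.sequence]
        if allow_ssc_flip:
            candidates.append(flip_ssc(gb).sequence)
        summary["mismatches"] = min(
            sum(x != y for x, y in zip(ga.sequence, cand)) for cand in candidates
        )
    return False, summary


def build_anchor_chain(query: str, target: str, anchor_k: int = 21) -> AnchorChain:
    """Chain maximal exact unique matches between two sequences.

    Anchors are seeded at ``anchor_k``-mers that occur exactly once on
    the forward strand of both sequences (forward matches take
    precedence; a k-mer unique in the query but matching the target only
    in reverse orientation seeds a '-' anchor, which is how inversions
    surface).  The chain is the highest-coverage strictly collinear
    subset: a weighted longest-increasing-subsequence over target
    position with non-overlapping spans.
    """
    if not query or not target:
        raise EmptyChain("empty sequence")

    def fwd_index(seq: str) -> dict[int, int | None]:
        idx: dict[int, int | None] = {}
        for pos, fwd, _ in iter_kmers(seq, anchor_k):
            idx[fwd] = None if fwd in idx else pos
        return idx

    qidx = fwd_index(query)
    tidx = fwd_index(target)
    trc = revcomp(target)
    trc_idx = fwd_index(trc)

    seeds: list[tuple[int, int, str]] = []  # (qpos0, tpos0, strand)
    for code, qpos in qidx.items():
        if qpos is None:
            continue
        tpos = tidx.get(code)
        if tpos is not None:
            seeds.append((qpos, tpos, "+"))
            continue
        if code in tidx:  # present but repeated forward: ambiguous
            continue
        rpos = trc_idx.get(code)
        if rpos is not None:
            seeds.append((qpos, rpos, "-"))

    if not seeds:
        raise EmptyChain("no unique shared anchors")

    # Extend seeds maximally.  Seeds on one diagonal that fall inside an
    # already-extended match belong to that match, so each maximal
    # match is extended exactly once.
    n_t = len(target)
    anchors: dict[tuple[int, int, str], int] = {}
    by_diagonal: dict[tuple[str, int], list[tuple[int, int]]] = {}
    for qpos, tpos, strand in seeds:
        by_diagonal.setdefault((strand, qpos - tpos), []).append((qpos, tpos))
    for (strand, _d), group in by_diagonal.items():
        tseq = target if strand == "+" else trc
        group.sort()
        covered_until = -1
        for qpos, tpos in group:
            if qpos < covered_until:
                continue
            qs, ts, length = qpos, tpos, anchor_k
            while qs > 0 and ts > 0 and query[qs - 1] == tseq[ts - 1]:
                qs -= 1
                ts -= 1
                length += 1
            while qs + length < len(query) and ts + length < len(tseq) and query[qs + length] == tseq[ts + length]:
                length += 1
            anchors[(qs, ts, strand)] = length
            covered_until = qs + length

    raw: list[Anchor] = []
    for (qs, ts, strand), length in anchors.items():
        if strand == "+":
            raw.append(Anchor(qs + 1, qs + length, ts + 1, ts + length, "+"))
        else:
            # Map the match on revcomp(target) back to target coordinates.
            t_end0 = n_t - ts - 1
            t_start0 = t_end0 - length + 1
            raw.append(Anchor(qs + 1, qs + length, t_start0 + 1, t_end0 + 1, "-"))

    # Weighted LIS over (qstart, tstart), spans non-overlapping.
    raw.sort(key=lambda a: (a.tstart, a.qstart))
    best_len = [a.length for a in raw]
    prev = [-1] * len(raw)
    for i, a in enumerate(raw):
        for j in range(i):
            b = raw[j]
            if b.tend < a.tstart and b.qend < a.qstart:
                cand = best_len[j] + a.length
                if cand > best_len[i]:
                    best_len[i] = cand
                    prev[i] = j
    end = max(range(len(raw)), key=lambda i: best_len[i])
    chain = []
    while end != -1:
        chain.append(raw[end])
        end = prev[end]
    chain.reverse()
    return AnchorChain(chain)


def slice_regions(genome: QuadripartiteGenome) -> dict[str, str]:
    """Per-region sequences of a canonical genome, plus the LSC+SSC
    concatenation and the whole sequence."""
    seq = genome.sequence
    rm = genome.region_map
    parts = {name: _circular_slice(seq, *rm.span(name)) for name in REGION_ORDER}
    parts["LSC+SSC"] = parts["LSC"] + parts["SSC"]
    parts["whole"] = seq
    return parts


def region_of_position(region_map: RegionMap, pos: int) -> str:
    """Region label containing a 1-based position."""
    for name in REGION_ORDER:
        s, e = region_map.span(name)
        if e >= s:
            if s <= pos <= e:
                return name
        elif pos >= s or pos <= e:
            return name
    raise InvalidRegionMap(f"position {pos} outside circle of {region_map.total}")


def write_region_map_tsv(region_map: RegionMap, path, name: str = "genome") -> None:
    with open(path, "w") as fh:
        fh.write("# name\tstart\tend\tlabel (1-based inclusive; end<start wraps origin)\n")
        for label in REGION_ORDER:
            s, e = region_map.span(label)
            fh.write(f"{name}\t{s}\t{e}\t{label}\n")
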