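"""Stages 2-5 of the assembly pipeline: initial de Bruijn assembly over
a k spread, iterative read re-selection, scaffold-end rescue, and gap
filling.

The assembler is deliberately small: a canonical-k-mer de Bruijn graph
with tip clipping and bubble popping, emitting maximal non-branching
paths.  The two inverted-repeat copies of a plastome collapse into one
high-coverage path; restoring the quadripartite circle from the
collapsed path is the job of the quadripartite module, signalled by the
IR path's ~2x coverage.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import EmptyInput, InvalidParameter
from .seqs import ReadPair, decode_kmer, iter_kmers, revcomp

DEFAULT_K_SPREAD = (31, 41, 51, 63)
_GAP_RE = re.compile(r"N+")


@dataclass(frozen=True)
class Contig:
    id: str
    sequence: str
    coverage: float  # mean k-mer multiplicity along the contig
    circular: bool = False


@dataclass
class Assembly:
    """Ordered scaffolds; N-runs mark unfilled gaps with their estimated
    sizes.  ``stage`` records the last pipeline stage applied."""

    scaffolds: list[str]
    k: int
    stage: str  # initial | refined | rescued | gapfilled
    coverages: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    @property
    def non_gap_length(self) -> int:
        return sum(len(s) - s.count("N") for s in self.scaffolds)

    def n50(self) -> int:
        lengths = sorted((len(s) for s in self.scaffolds), reverse=True)
        half = sum(lengths) / 2
        acc = 0
        for ln in lengths:
            acc += ln
            if acc >= half:
                return ln
        return 0

    def gaps(self) -> list[tuple[int, int, int]]:
        """(scaffold index, 0-based gap start, gap length) for every N-run."""
        out = []
        for i, s in enumerate(self.scaffolds):
            for m in _GAP_RE.finditer(s):
                out.append((i, m.start(), m.end() - m.start()))
        return out


def _rc_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def _solid_kmers(pairs: list[ReadPair], k: int, min_count: int | None) -> dict[int, int]:
    from .kmer_bait import count_kmers

    counts = count_kmers(pairs, k)
    if min_count is None:
        min_count = _auto_min_count(counts)
    return {c: n for c, n in counts.items() if n >= min_count}


def _auto_min_count(counts: dict[int, int]) -> int:
    """Solidity threshold: a tenth of the mass-weighted median
    multiplicity among non-singleton k-mers, floored at 2.  At high
    coverage this removes nearly all error k-mers before graph
    cleaning; at low coverage it degrades to keeping everything."""
    mults = np.array([n for n in counts.values() if n >= 2])
    if mults.size == 0:
        return 1
    order = np.sort(mults)
    cum = np.cumsum(order)
    med = int(order[np.searchsorted(cum, cum[-1] / 2)])
    if med < 8:
        return 1
    return max(2, int(round(0.1 * med)))


class _Graph:
    """Directed de Bruijn graph over (k-1)-mer nodes; both orientations
    of every canonical k-mer are present as edges."""

    def __init__(self, solid: dict[int, int], k: int):
        self.k = k
        self.mask = (1 << (2 * (k - 1))) - 1
        self.succ: dict[int, dict[int, int]] = {}
        self.pred: dict[int, dict[int, int]] = {}
        for code, count in solid.items():
            for oriented in {code, _rc_code(code, k)}:
                u = oriented >> 2
                v = oriented & self.mask
                self.succ.setdefault(u, {})[v] = count
                self.pred.setdefault(v, {})[u] = count
                self.succ.setdefault(v, {})
                self.pred.setdefault(u, {})

    def simple(self, node: int) -> bool:
        return len(self.succ[node]) == 1 and len(self.pred[node]) == 1

    def unitigs(self) -> list[tuple[list[int], list[int], bool]]:
        """Maximal non-branching paths as (node path, edge counts,
        circular); endpoints are branch nodes or dead ends.  A purely
        circular non-branching component is returned once, starting at
        its smallest node."""
        out = []
        visited: set[tuple[int, int]] = set()
        for u in self.succ:
            if self.simple(u):
                continue
            for v in self.succ[u]:
                if (u, v) in visited:
                    continue
                path, covs = [u, v], [self.succ[u][v]]
                visited.add((u, v))
                while self.simple(path[-1]):
                    w = next(iter(self.succ[path[-1]]))
                    if (path[-1], w) in visited:
                        break
                    visited.add((path[-1], w))
                    covs.append(self.succ[path[-1]][w])
                    path.append(w)
                out.append((path, covs, False))
        # remaining edges belong to fully circular simple components
        for u in sorted(self.succ):
            for v in self.succ[u]:
                if (u, v) in visited:
                    continue
                path, covs = [u, v], [self.succ[u][v]]
                visited.add((u, v))
                while True:
                    w = next(iter(self.succ[path[-1]]))
                    if (path[-1], w) in visited:
                        break
                    visited.add((path[-1], w))
                    covs.append(self.succ[path[-1]][w])
                    path.append(w)
                out.append((path, covs, True))
        return out

    def path_seq(self, path: list[int]) -> str:
        return decode_kmer(path[0], self.k - 1) + "".join(
            "ACGT"[v & 3] for v in path[1:]
        )

    def path_kmers(self, path: list[int]) -> list[int]:
        """Canonical k-mer codes of the edges along a path."""
        k = self.k
        out = []
        for u, v in zip(path, path[1:]):
            code = (u << 2) | (v & 3)
            rc = _rc_code(code, k)
            out.append(code if code <= rc else rc)
        return out


def _clean_graph(solid: dict[int, int], k: int, max_rounds: int = 5) -> dict[int, int]:
    """Iteratively clip tips and pop bubbles on the solid k-mer set."""
    for _ in range(max_rounds):
        graph = _Graph(solid, k)
        unitigs = graph.unitigs()
        if not unitigs:
            break
        covs = np.array([float(np.mean(c)) for _, c, _ in unitigs])
        lens = np.array([len(p) for p, _, _ in unitigs], dtype=float)
        order = np.argsort(covs)
        cum = np.cumsum(lens[order])
        median_cov = float(covs[order[np.searchsorted(cum, cum[-1] / 2)]])
        to_remove: set[int] = set()

        # Tips: dead-ended short low-coverage paths.
        for path, ecovs, circular in unitigs:
            if circular:
                continue
            dead_start = len(graph.pred[path[0]]) == 0
            dead_end = len(graph.succ[path[-1]]) == 0
            if not (dead_start or dead_end):
                continue
            seq_len = len(path) + k - 2
            if seq_len < 2 * k and float(np.mean(ecovs)) < 0.1 * median_cov:
                to_remove.update(graph.path_kmers(path))

        # Bubbles: two unitigs sharing both endpoints whose lengths
        # differ by <= 3 bp; keep the higher-coverage arm.
        arms: dict[tuple[int, int], list[tuple[list[int], float]]] = {}
        for path, ecovs, circular in unitigs:
            if not circular:
                arms.setdefault((path[0], path[-1]), []).append(
                    (path, float(np.mean(ecovs)))
                )
        for (u, v), group in arms.items():
            if len(group) < 2:
                continue
            group.sort(key=lambda item: (-item[1], len(item[0])))
            keep_path = group[0][0]
            keep_kmers = set(graph.path_kmers(keep_path))
            for path, _cov in group[1:]:
                arm_kmers = set(graph.path_kmers(path))
                # a path and its reverse complement share endpoints in
                # this graph but are one molecule, not a bubble
                if arm_kmers == keep_kmers:
                    continue
                if abs(len(path) - len(keep_path)) <= 3:
                    to_remove.update(arm_kmers)

        if not to_remove:
            break
        for code in to_remove:
            solid.pop(code, None)
    return solid


def assemble_once(pairs: list[ReadPair], k: int, min_count: int | None = None) -> list[Contig]:
    """Single de Bruijn assembly at one k: build the graph on canonical
    k-mers, clean tips and bubbles, and emit maximal non-branching paths
    as contigs (reverse-complement duplicates merged)."""
    if not pairs:
        raise EmptyInput("no reads to assemble")
    if k % 2 == 0 or k < 3:
        raise InvalidParameter(f"k must be odd and >= 3, got {k}")
    max_read = max(max(len(p.seq1), len(p.seq2)) for p in pairs)
    if k > max_read:
        raise InvalidParameter(f"k={k} exceeds the longest read ({max_read} bp)")

    solid = _solid_kmers(pairs, k, min_count)
    if not solid:
        raise EmptyInput("no k-mers above the solidity threshold")
    solid = _clean_graph(solid, k)
    graph = _Graph(solid, k)

    seen: dict[str, Contig] = {}
    idx = 0
    for path, ecovs, circular in graph.unitigs():
        seq = graph.path_seq(path)
        if circular:
            seq = seq[: len(path) - 1]  # drop the wrapped (k-1)-overlap
        if len(seq) < k:
            continue
        key = min(seq, revcomp(seq)) if not circular else _circular_key(seq)
        if key in seen:
            continue
        idx += 1
        seen[key] = Contig(f"contig_{idx}", seq, float(np.mean(ecovs)), circular)
    contigs = sorted(seen.values(), key=lambda c: (-len(c.sequence), c.sequence))
    return [replace(c, id=f"contig_{i + 1}") for i, c in enumerate(contigs)]


def _circular_key(seq: str) -> str:
    """Rotation/strand-invariant key for a circular sequence."""
    best = None
    for s in (seq, revcomp(seq)):
        doubled = s + s
        cand = min(doubled[i : i + len(s)] for i in range(len(s)))
        best = cand if best is None else min(best, cand)
    return best


def score_assembly(assembly: Assembly, expected_size: int | None = None) -> tuple:
    """Ranking key (smaller is better): fewest scaffolds, then total
    length within 0.8-1.2x the expected size (largest such), then N50."""
    n = len(assembly.scaffolds)
    total = assembly.total_length
    if expected_size is not None:
        in_band = 0 if 0.8 * expected_size <= total <= 1.2 * expected_size else 1
    else:
        in_band = 0
    return (n, in_band, -total, -assembly.n50())


def assemble_spread(
    pairs: list[ReadPair],
    k_values: tuple[int, ...] = DEFAULT_K_SPREAD,
    expected_size: int | None = None,
    min_count: int | None = None,
) -> Assembly:
    """Run the initial assembly across a spread of k values and keep the
    best-scoring candidate (its k is recorded for the later stages)."""
    if not pairs:
        raise EmptyInput("no reads to assemble")
    max_read = max(max(len(p.seq1), len(p.seq2)) for p in pairs)
    usable = [k for k in k_values if k <= max_read]
    if not usable:
        raise InvalidParameter(f"all k values exceed the read length ({max_read} bp)")
    best: Assembly | None = None
    for k in usable:
        contigs = assemble_once(pairs, k, min_count)
        cand = Assembly(
            [c.sequence for c in contigs], k, "initial", [c.coverage for c in contigs]
        )
        if best is None or score_assembly(cand, expected_size) < score_assembly(best, expected_size):
            best = cand
    return best


def _assembly_kmer_set(assembly: Assembly) -> set[int]:
    k = assembly.k
    kmers: set[int] = set()
    for s in assembly.scaffolds:
        for _, f, r in iter_kmers(s, k):
            kmers.add(f if f <= r else r)
    return kmers


def select_reads_by_kmers(pairs: list[ReadPair], kmers: set[int], k: int) -> list[ReadPair]:
    """Read pairs where either mate shares >= 1 exact canonical k-mer
    with the given set."""
    out = []
    for p in pairs:
        hit = False
        for seq in (p.seq1, p.seq2):
            for _, f, r in iter_kmers(seq, k):
                if (f if f <= r else r) in kmers:
                    hit = True
                    break
            if hit:
                break
        if hit:
            out.append(p)
    return out


def refine_iteratively(
    assembly: Assembly,
    all_reads: list[ReadPair],
    max_iter: int = 5,
    expected_size: int | None = None,
    min_count: int | None = None,
) -> Assembly:
    """Stage 3: re-select reads from the full QC-passed data that share
    a k-mer with the current assembly, reassemble, and iterate until the
    total length moves by < 0.1%.  Never returns a worse-scoring
    assembly than its input."""
    if max_iter <= 0:
        return assembly
    current = assembly
    converged = False
    for _ in range(max_iter):
        selected = select_reads_by_kmers(all_reads, _assembly_kmer_set(current), current.k)
        if not selected:
            break
        contigs = assemble_once(selected, current.k, min_count)
        cand = Assembly(
            [c.sequence for c in contigs],
            current.k,
            "refined",
            [c.coverage for c in contigs],
        )
        if abs(cand.total_length - current.total_length) < 0.001 * max(current.total_length, 1):
            if score_assembly(cand, expected_size) <= score_assembly(current, expected_size):
                current = cand
            converged = True
            break
        if score_assembly(cand, expected_size) <= score_assembly(current, expected_size):
            current = cand
    if not converged:
        warnings.warn("refinement did not converge within max_iter")
    out = replace(current, stage="refined")
    out.converged = converged
    return out


def _overlap_length(left: str, right: str, min_overlap: int) -> int:
    """Longest o >= min_overlap with left[-o:] matching right[:o] at
    <= 1 mismatch per 100 bp; 0 when none."""
    for o in range(min(len(left), len(right)), min_overlap - 1, -1):
        allowed = o // 100
        mism = 0
        ok = True
        for a, b in zip(left[-o:], right[:o]):
            if a != b:
                mism += 1
                if mism > allowed:
                    ok = False
                    break
        if ok:
            return o
    return 0


def _repeat_flags(coverages: list[float], lengths: list[int], ratio: float = 1.5) -> list[bool]:
    """Scaffolds at >= ratio times the length-weighted median coverage
    are collapsed repeats (in a plastome, the merged IR path); they are
    never extended through or merged away."""
    if not coverages or len(coverages) != len(lengths):
        return [False] * len(lengths)
    order = np.argsort(coverages)
    cum = np.cumsum(np.asarray(lengths, dtype=float)[order])
    median = coverages[int(order[np.searchsorted(cum, cum[-1] / 2)])]
    return [median > 0 and c / median >= ratio for c in coverages]


def _kmer_set(seqs, k: int) -> set[int]:
    out: set[int] = set()
    for s in seqs:
        for _, f, r in iter_kmers(s, k):
            out.add(f if f <= r else r)
    return out


def _novel_fraction(seq: str, known: set[int], k: int) -> float:
    total = novel = 0
    for _, f, r in iter_kmers(seq, k):
        total += 1
        if (f if f <= r else r) not in known:
            novel += 1
    return novel / total if total else 1.0


def rescue_scaffold_ends(
    assembly: Assembly,
    all_reads: list[ReadPair],
    end_window: int = 500,
    min_count: int | None = None,
) -> Assembly:
    """Stage 4: collect read pairs anchored near each scaffold end,
    assemble them locally, and extend or merge scaffolds when a local
    contig overlaps the end by >= k bp (<= 1 mismatch / 100 bp).

    Ends that would extend into sequence already present elsewhere in
    the assembly are junctions (e.g. the flanks of the collapsed IR),
    not broken ends, and are left intact — unless the extension
    bridges cleanly into the start of exactly one other single-copy
    scaffold, in which case the two scaffolds are merged."""
    k = assembly.k
    scaffolds = list(assembly.scaffolds)
    covs = list(assembly.coverages) if len(assembly.coverages) == len(scaffolds) else [1.0] * len(scaffolds)
    repeat = _repeat_flags(covs, [len(s) for s in scaffolds])

    i = 0
    while i < len(scaffolds):
        if repeat[i]:
            i += 1
            continue
        for side in ("start", "end"):
            s = scaffolds[i]
            window = s[:end_window] if side == "start" else s[-end_window:]
            wk = _kmer_set([window], k)
            local = select_reads_by_kmers(all_reads, wk, k)
            if not local:
                continue
            try:
                contigs = assemble_once(local, k, min_count)
            except (EmptyInput, InvalidParameter):
                continue
            best_ext = None  # (gain, extension segment)
            for c in contigs:
                for cand in (c.sequence, revcomp(c.sequence)):
                    if side == "end":
                        o = _overlap_length(s, cand, k)
                        ext = cand[o:] if o else ""
                    else:
                        o = _overlap_length(cand, s, k)
                        ext = cand[: len(cand) - o] if o else ""
                    if ext and (best_ext is None or len(ext) > best_ext[0]):
                        best_ext = (len(ext), ext)
            if best_ext is None:
                continue
            ext = best_ext[1]
            others = _kmer_set(
                [x for j, x in enumerate(scaffolds) if j != i] + [s], k
            )
            # judge novelty on the junction-spanning sequence so short
            # extensions still contribute k-mers
            spanning = s[-(k - 1) :] + ext if side == "end" else ext + s[: k - 1]
            if _novel_fraction(spanning, others, k) >= 0.5:
                scaffolds[i] = s + ext if side == "end" else ext + s
                continue
            # extension re-enters known sequence: try a unique bridge
            # into another single-copy scaffold, else leave the end.
            extended = s + ext if side == "end" else ext + s
            bridges = []
            for j in range(len(scaffolds)):
                if j == i or repeat[j]:
                    continue
                for b in (scaffolds[j], revcomp(scaffolds[j])):
                    if side == "end":
                        o = _overlap_length(extended, b, k)
                        if o >= k and o < len(b):
                            bridges.append((j, extended + b[o:]))
                    else:
                        o = _overlap_length(b, extended, k)
                        if o >= k and o < len(b):
                            bridges.append((j, b[: len(b) - o] + extended))
            if len(bridges) == 1:
                j, merged = bridges[0]
                scaffolds[i] = merged
                del scaffolds[j]
                del covs[j]
                del repeat[j]
                if j < i:
                    i -= 1
        i += 1
    return Assembly(scaffolds, k, "rescued", covs, assembly.converged)


def fill_gaps(
    assembly: Assembly,
    all_reads: list[ReadPair],
    flank_window: int = 800,
    min_count: int | None = None,
) -> Assembly:
    """Stage 5: for each N-run, select pairs anchored to the gap flanks,
    assemble locally, and splice in a contig that overlaps both flanks
    by >= k bp; gaps with no spanning contig keep their N-run."""
    k = assembly.k
    scaffolds = list(assembly.scaffolds)
    for idx in range(len(scaffolds)):
        search_from = 0
        while True:
            s = scaffolds[idx]
            m = _GAP_RE.search(s, search_from)
            if m is None:
                break
            gs, ge = m.start(), m.end()
            left = s[max(0, gs - flank_window) : gs]
            right = s[ge : ge + flank_window]
            if len(left) < k or len(right) < k:
                search_from = ge
                continue
            fk = {
                (f if f <= r else r)
                for part in (left, right)
                for _, f, r in iter_kmers(part, k)
            }
            local = select_reads_by_kmers(all_reads, fk, k)
            filler = None
            if local:
                try:
                    contigs = assemble_once(local, k, min_count)
                except EmptyInput:
                    contigs = []
                lkey = left[-k:]
                rkey = right[:k]
                for c in contigs:
                    for cand in (c.sequence, revcomp(c.sequence)):
                        p1 = cand.find(lkey)
                        p2 = cand.find(rkey)
                        if p1 != -1 and p2 != -1 and p2 >= p1 + k:
                            filler = cand[p1 + k : p2]
                            break
                    if filler is not None:
                        break
            if filler is not None:
                scaffolds[idx] = s[:gs] + filler + s[ge:]
                search_from = gs + len(filler)
            else:
                search_from = ge  # unfillable: keep the N-run, move on
    covs = assembly.coverages if len(assembly.coverages) == len(scaffolds) else []
    return Assembly(scaffolds, k, "gapfilled", list(covs), assembly.converged)


def write_assembly_report(assemblies: list[Assembly], path) -> None:
    with open(path, "w") as fh:
        fh.write("stage\tscaffolds\ttotal_length\tn50\tk\n")
        for a in assemblies:
            fh.write(f"{a.stage}\t{len(a.scaffolds)}\t{a.total_length}\t{a.n50()}\t{a.k}\n")
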