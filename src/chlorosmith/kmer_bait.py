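"""Stage 1-2 front end: read QC, k-mer spectrum, linked-peak detection,
bait k-mer selection and chloroplast read extraction.

In whole-genome shotgun data from leaf tissue the chloroplast is present
at far higher copy number than the nuclear genome, so its k-mers form a
high-multiplicity band in the k-mer spectrum: a peak at the single-copy
multiplicity N and a linked companion at 2N contributed by the two
inverted-repeat copies.  Reads carrying k-mers from that band are almost
exclusively chloroplast-derived and form the input of the assembler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .errors import EmptyBaitSet, InvalidParameter, NoLinkedPeaks
from .seqs import ReadPair, canonical_kmer_counts, iter_kmers

DEFAULT_K = 31


@dataclass
class KmerHistogram:
    """Multiplicity spectrum: distinct canonical k-mer counts per
    multiplicity."""

    k: int
    table: dict[int, int]  # multiplicity -> number of distinct k-mers

    def total_instances(self) -> int:
        return sum(m * c for m, c in self.table.items())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# multiplicity\tdistinct_kmers\n")
            for m in sorted(self.table):
                fh.write(f"{m}\t{self.table[m]}\n")

    @classmethod
    def from_tsv(cls, path, k: int) -> "KmerHistogram":
        table = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                m, c = line.split()
                table[int(m)] = int(c)
        return cls(k, table)


@dataclass(frozen=True)
class PeakModel:
    """The linked (N, 2N) peak pair and the bait multiplicity band."""

    n_single: float
    n_ir: float
    band_low: int
    band_high: int
    valley: int

    def __post_init__(self):
        if not (self.band_low < self.n_single < self.n_ir < self.band_high):
            raise InvalidParameter("band must bracket both peaks")


@dataclass
class BaitSet:
    """Canonical k-mers (packed codes) selected from the coverage band."""

    k: int
    kmers: set[int]

    def __len__(self) -> int:
        return len(self.kmers)


def qc_filter(pairs: list[ReadPair], min_mean_q: float = 20.0) -> tuple[list[ReadPair], dict]:
    """Drop read pairs in which either mate has mean Phred <= threshold.

    Mirrors the common 'Q-value <= 20' raw-data filter, interpreted as a
    per-mate mean-quality rule.  Returns the kept pairs and
    ``{"kept": n, "dropped": n}``.
    """
    kept = [
        p for p in pairs if p.mean_quality(1) > min_mean_q and p.mean_quality(2) > min_mean_q
    ]
    return kept, {"kept": len(kept), "dropped": len(pairs) - len(kept)}


def build_histogram(pairs: list[ReadPair], k: int = DEFAULT_K) -> KmerHistogram:
    """Count canonical k-mers across both mates of every pair and bin
    them by multiplicity.  Non-ACGT symbols break the k-mer window."""
    counts = count_kmers(pairs, k)
    table: dict[int, int] = {}
    for c in counts.values():
        table[c] = table.get(c, 0) + 1
    return KmerHistogram(k, table)


def count_kmers(pairs: list[ReadPair], k: int) -> dict[int, int]:
    """Canonical k-mer -> multiplicity over all mates."""
    if k % 2 == 0:
        raise InvalidParameter(f"k must be odd, got {k}")
    if k < 1:
        raise InvalidParameter("k must be positive")

    def seqs():
        for p in pairs:
            yield p.seq1
            yield p.seq2

    return canonical_kmer_counts(seqs(), k)


def detect_linked_peaks(
    hist: KmerHistogram,
    ratio_tol: float = 0.15,
    min_peak_multiplicity: int = 5,
    smooth_width: int = 5,
) -> PeakModel:
    """Find the single-copy/IR peak pair (N, ~2N) in the spectrum.

    The spectrum is smoothed with a moving average, local maxima above
    the error/nuclear valley are collected, and among all candidate
    pairs whose multiplicity ratio lies within ``2 +/- ratio_tol`` the
    one carrying the largest total k-mer mass wins.  The bait band is
    then set to ``[max(valley+1, N/2), 3N]``.
    """
    if not hist.table:
        raise NoLinkedPeaks("empty histogram")
    max_mult = max(hist.table)
    # trailing zero-padding so a peak at the highest multiplicity is
    # still a local maximum after smoothing
    dense = np.zeros(max_mult + smooth_width + 2)
    for m, c in hist.table.items():
        dense[m] = c
    kernel = np.ones(smooth_width) / smooth_width
    smooth = np.convolve(dense, kernel, mode="same")

    lo = max(min_peak_multiplicity, 1)
    peaks, _ = find_peaks(smooth[lo:])
    peaks = peaks + lo
    # Delta-function spectra (all mass at isolated multiplicities) have
    # no smooth local maxima wider than the kernel; fall back to raw bins.
    if peaks.size == 0:
        peaks = np.array(
            [m for m in sorted(hist.table) if m >= lo and hist.table[m] > 0], dtype=int
        )
    if peaks.size == 0:
        raise NoLinkedPeaks("no candidate peaks above the minimum multiplicity")

    # Poisson sampling noise shifts raw local maxima by several bins, so
    # refine each candidate to the mass centroid of its +/-25% window
    # before testing the 2:1 ratio.
    def centroid_and_mass(m: int) -> tuple[float, float]:
        a = max(1, int(round(m * 0.75)))
        b = min(int(round(m * 1.25)) + 1, len(dense))
        window = dense[a:b]
        total = float(window.sum())
        if total == 0:
            return float(m), 0.0
        return float(np.arange(a, b) @ window / total), total

    refined: list[tuple[float, float]] = []
    for m in peaks:
        c, mass = centroid_and_mass(int(m))
        if mass > 0 and all(abs(c - c0) > 0.05 * c0 for c0, _ in refined):
            refined.append((c, mass))

    best = None
    for i, (c1, mass1) in enumerate(refined):
        for c2, mass2 in refined[i + 1 :]:
            if abs(c2 / c1 - 2.0) <= ratio_tol:
                if best is None or mass1 + mass2 > best[0]:
                    best = (mass1 + mass2, c1, c2)
    if best is None:
        raise NoLinkedPeaks("no peak pair with multiplicity ratio near 2")
    _, n_single, n_ir = best

    # Valley: minimum of the smoothed spectrum between the low-multiplicity
    # error/nuclear signal and the single-copy peak.
    valley_lo = 1
    valley_hi = max(int(round(n_single)) - 1, 2)
    valley = int(np.argmin(smooth[valley_lo : valley_hi + 1]) + valley_lo)

    band_low = max(valley + 1, int(round(0.5 * n_single)))
    band_high = int(round(3.0 * n_single))
    return PeakModel(float(n_single), float(n_ir), band_low, band_high, valley)


def select_bait_kmers(
    pairs: list[ReadPair], hist: KmerHistogram, peaks: PeakModel
) -> BaitSet:
    """Bait set = canonical k-mers whose multiplicity falls inside the
    peak band [band_low, band_high]."""
    counts = count_kmers(pairs, hist.k)
    kmers = {km for km, c in counts.items() if peaks.band_low <= c <= peaks.band_high}
    if not kmers:
        raise EmptyBaitSet("no k-mers in the bait band")
    return BaitSet(hist.k, kmers)


def bait_reads(pairs: list[ReadPair], baits: BaitSet, min_hits: int = 1) -> list[ReadPair]:
    """Keep read pairs where either mate contains >= min_hits bait
    k-mers; pair-preserving so insert information survives."""
    if not baits.kmers:
        raise EmptyBaitSet("bait set is empty")
    k = baits.k
    bait = baits.kmers
    out = []
    for p in pairs:
        hits = 0
        for seq in (p.seq1, p.seq2):
            for _, f, r in iter_kmers(seq, k):
                if (f if f <= r else r) in bait:
                    hits += 1
                    if hits >= min_hits:
                        break
            if hits >= min_hits:
                break
        if hits >= min_hits:
            out.append(p)
    return out


def write_bait_set(baits: BaitSet, path) -> None:
    from .seqs import decode_kmer

    with open(path, "w") as fh:
        fh.write(f"# canonical {baits.k}-mers\n")
        for code in sorted(baits.kmers):
            fh.write(decode_kmer(code, baits.k) + "\n")
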