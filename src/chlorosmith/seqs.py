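"""Low-level sequence utilities: reverse complement, canonical k-mer
iteration over 2-bit integer encodings, and light FASTA/FASTQ I/O.

K-mers are packed into Python integers (2 bits per base, A=0 C=1 G=2 T=3)
so that k up to 63 works uniformly; the canonical form of a k-mer is the
smaller of the packed forward and reverse-complement encodings.  Bases
outside ACGT interrupt the rolling window: no k-mer spanning them is
emitted.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (ACGTN, case preserved)."""
    return seq.translate(_COMP)[::-1]


def encode_kmer(kmer: str) -> int:
    """Pack an ACGT string into its 2-bit integer encoding."""
    v = 0
    for ch in kmer:
        v = (v << 2) | _CODE[ch]
    return v


def decode_kmer(code: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    out = []
    for i in range(k - 1, -1, -1):
        out.append(_BASE[(code >> (2 * i)) & 3])
    return "".join(out)


def iter_kmers(seq: str, k: int) -> Iterator[tuple[int, int, int]]:
    """Yield ``(position, forward_code, rc_code)`` for every ACGT-only
    k-mer of ``seq``; position is the 0-based start of the k-mer."""
    mask = (1 << (2 * k)) - 1
    shift = 2 * (k - 1)
    fwd = rev = 0
    run = 0
    code = _CODE
    for i, ch in enumerate(seq):
        c = code.get(ch)
        if c is None:
            run = 0
            fwd = rev = 0
            continue
        fwd = ((fwd << 2) | c) & mask
        rev = (rev >> 2) | ((3 - c) << shift)
        run += 1
        if run >= k:
            yield i - k + 1, fwd, rev


def iter_canonical(seq: str, k: int) -> Iterator[int]:
    """Yield canonical (strand-symmetric) k-mer codes of ``seq``."""
    for _, f, r in iter_kmers(seq, k):
        yield f if f <= r else r


def canonical_kmer_counts(seqs: Iterable[str], k: int) -> dict[int, int]:
    """Count canonical k-mers over an iterable of sequences."""
    counts: dict[int, int] = {}
    get = counts.get
    for seq in seqs:
        for _, f, r in iter_kmers(seq, k):
            c = f if f <= r else r
            counts[c] = get(c, 0) + 1
    return counts


@dataclass(frozen=True)
class ReadPair:
    """A paired-end read with Phred+33 quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def mean_quality(self, mate: int) -> float:
        q = self.qual1 if mate == 1 else self.qual2
        if not q:
            return 0.0
        return sum(ord(ch) - 33 for ch in q) / len(q)


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(path1, path2) -> list[ReadPair]:
    """Load a paired FASTQ file pair (optionally gzipped).

    Mates are matched by record order; a length mismatch between the two
    files raises :class:`ParseError`.
    """
    pairs: list[ReadPair] = []
    with _open_text(path1) as h1, _open_text(path2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        idx = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                raise ParseError(
                    "paired FASTQ files differ in record count", record_index=idx
                )
            name = r1[0].split()[0]
            for suffix in ("/1", "/2"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
            pairs.append(ReadPair(name, r1[1].upper(), r1[2], r2[1].upper(), r2[2]))
            idx += 1
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], path1, path2) -> None:
    with _open_text(path1, "wt") as h1, _open_text(path2, "wt") as h2:
        for p in pairs:
            h1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            h2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` dict."""
    from Bio import SeqIO

    with _open_text(path) as handle:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}


def write_fasta(records: dict[str, str], path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in records.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
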