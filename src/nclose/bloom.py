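"""Multiplicity-thresholded Bloom filter over canonical k-mers.

The filter is *cascading*: it holds ``num_levels`` plain Bloom levels and an
occurrence of a k-mer is inserted into level ``i+1`` only if the k-mer is
already present in levels ``1..i``.  A k-mer is **solid** when present in
all levels, i.e. observed at least ``num_levels`` times (the multiplicity
threshold, default 2).  This keeps singleton k-mers — overwhelmingly
sequencing errors at reasonable coverage — out of the graph while storing
only bits, never counts.

Errors are one-sided: a k-mer inserted at or above the threshold always
queries solid (no false negatives); a never-inserted k-mer may query solid
with probability about ``fill_ratio ** num_hashes`` per level.
"""

from __future__ import annotations

import struct
import warnings
from typing import Iterable

import numpy as np

from . import hashing

_MAGIC = b"NCBF1\n"
_U64 = np.uint64

DEFAULT_NUM_HASHES = 4
DEFAULT_THRESHOLD = 2


def parse_size_bytes(text: str | int) -> int:
    """Parse a byte-size argument like ``"500M"`` (K/M/G suffixes) to bytes."""
    if isinstance(text, int):
        return text
    s = text.strip().upper().replace(" ", "")
    mult = 1
    if s and s[-1] in "KMG":
        mult = {"K": 1 << 10, "M": 1 << 20, "G": 1 << 30}[s[-1]]
        s = s[:-1]
    try:
        return int(float(s) * mult)
    except ValueError:
        raise ValueError(f"cannot parse Bloom filter size {text!r}") from None


class KmerBloom:
    """Cascading Bloom filter holding canonical k-mers of one fixed ``k``.

    Parameters
    ----------
    k:
        K-mer length in bp.
    size_bits:
        Bit capacity of **each** level.
    num_levels:
        Multiplicity threshold; a k-mer is solid after ``num_levels``
        insertions.
    num_hashes:
        Hash functions per level (double hashing, ``h1 + i*h2``).
    hash_seed:
        Seed mixed into the hash; recorded so runs are reproducible.
    """

    def __init__(
        self,
        k: int,
        size_bits: int,
        num_levels: int = DEFAULT_THRESHOLD,
        num_hashes: int = DEFAULT_NUM_HASHES,
        hash_seed: int = 0,
    ) -> None:
        if num_levels < 1:
            raise ValueError("num_levels must be >= 1")
        if num_hashes < 1:
            raise ValueError("num_hashes must be >= 1")
        if size_bits < 8 * num_hashes:
            raise ValueError("size_bits must be at least 8 * num_hashes")
        self.k = k
        self.size_bits = int(size_bits)
        self.num_levels = num_levels
        self.num_hashes = num_hashes
        self.hash_seed = int(hash_seed)
        nbytes = (self.size_bits + 7) // 8
        self.levels = [np.zeros(nbytes, dtype=np.uint8) for _ in range(num_levels)]
        self.inserted_distinct = 0  # approximate count of distinct solid k-mers

    # -- bit plumbing -----------------------------------------------------

    def _bit_indices(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        """(m, num_hashes) bit positions from the double-hashing pair."""
        i = np.arange(self.num_hashes, dtype=np.uint64)
        with np.errstate(over="ignore"):
            return (h1[:, None] + i[None, :] * h2[:, None]) % _U64(self.size_bits)

    def _contains(self, level: np.ndarray, idx: np.ndarray) -> np.ndarray:
        bits = (level[(idx >> _U64(3)).astype(np.int64)]
                >> (idx & _U64(7)).astype(np.uint8)) & 1
        return bits.all(axis=1)

    @staticmethod
    def _set_bits(level: np.ndarray, idx: np.ndarray) -> None:
        flat = idx.ravel()
        byte = (flat >> _U64(3)).astype(np.int64)
        mask = (np.uint8(1) << (flat & _U64(7)).astype(np.uint8))
        np.bitwise_or.at(level, byte, mask)

    # -- insertion --------------------------------------------------------

    def insert_hashes(self, h1: np.ndarray, h2: np.ndarray) -> None:
        """Insert a batch of k-mer occurrences given their hash pairs.

        Duplicates within the batch count as separate occurrences.  The
        cascade is applied exactly: a k-mer currently present in the first
        ``c`` levels with ``m`` occurrences in the batch ends up present in
        the first ``min(num_levels, c + m)`` levels — the same final state
        as inserting the occurrences one at a time.
        """
        if h1.shape[0] == 0:
            return
        pair = np.stack([h1, h2], axis=1)
        uniq, counts = np.unique(pair, axis=0, return_counts=True)
        idx = self._bit_indices(uniq[:, 0], uniq[:, 1])
        cur = np.zeros(uniq.shape[0], dtype=np.int64)
        alive = np.ones(uniq.shape[0], dtype=bool)
        for level in self.levels:
            alive = alive & self._contains(level, idx)
            cur += alive
        target = np.minimum(self.num_levels, cur + counts)
        for li, level in enumerate(self.levels):
            sel = (cur <= li) & (target > li)
            if sel.any():
                self._set_bits(level, idx[sel])
                if li == self.num_levels - 1:
                    self.inserted_distinct += int(sel.sum())

    def add_sequences(
        self, seqs: Iterable[str], chunk_bases: int = 1 << 20
    ) -> None:
        """Insert every clean k-mer occurrence of each sequence.

        Sequences are concatenated (with separators) into chunks of about
        *chunk_bases* bases so hashing stays vectorized.
        """
        buf: list[str] = []
        size = 0
        for s in seqs:
            buf.append(s)
            size += len(s) + 1
            if size >= chunk_bases:
                self._insert_chunk(buf)
                buf, size = [], 0
        if buf:
            self._insert_chunk(buf)

    def _insert_chunk(self, seqs: list[str]) -> None:
        codes = hashing.encode("N".join(seqs).upper())
        _, h1, h2 = hashing.window_hash_pairs(codes, self.k, self.hash_seed)
        self.insert_hashes(h1, h2)

    # -- queries ----------------------------------------------------------

    def solid_hashes(self, h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        """Boolean array: solid (present in all levels) per hash pair."""
        if h1.shape[0] == 0:
            return np.zeros(0, dtype=bool)
        idx = self._bit_indices(h1, h2)
        out = np.ones(h1.shape[0], dtype=bool)
        for level in self.levels:
            out &= self._contains(level, idx)
        return out

    def solid(self, kmer: str) -> bool:
        """True iff the canonical form of *kmer* is present in all levels."""
        if len(kmer) != self.k:
            raise ValueError(
                f"k-mer length {len(kmer)} does not match filter k={self.k}"
            )
        h1, h2 = hashing.hash_kmers([kmer], self.k, self.hash_seed)
        return bool(self.solid_hashes(h1, h2)[0])

    def solid_many(self, kmers: list[str]) -> np.ndarray:
        """Vectorized :meth:`solid` over same-length k-mer strings."""
        h1, h2 = hashing.hash_kmers(kmers, self.k, self.hash_seed)
        return self.solid_hashes(h1, h2)

    # -- occupancy --------------------------------------------------------

    def fill_ratios(self) -> list[float]:
        """Fraction of set bits per level."""
        out = []
        for level in self.levels:
            ones = int(np.bitwise_count(level).sum())
            out.append(ones / self.size_bits)
        return out

    def fpr_estimates(self) -> list[float]:
        """Analytic false-positive rate per level: fill_ratio ** num_hashes."""
        return [r**self.num_hashes for r in self.fill_ratios()]

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Write the filter to a flat binary file (bit-exact round trip)."""
        header = struct.pack(
            "<6s5Q",
            _MAGIC,
            self.k,
            self.num_levels,
            self.size_bits,
            self.num_hashes,
            self.hash_seed & 0xFFFFFFFFFFFFFFFF,
        )
        with open(path, "wb") as fh:
            fh.write(header)
            for level in self.levels:
                fh.write(level.tobytes())

    @classmethod
    def load(cls, path: str) -> "KmerBloom":
        with open(path, "rb") as fh:
            header = fh.read(struct.calcsize("<6s5Q"))
            magic, k, num_levels, size_bits, num_hashes, seed = struct.unpack(
                "<6s5Q", header
            )
            if magic != _MAGIC:
                raise ValueError(f"{path}: not a k-mer Bloom filter file")
            filt = cls(int(k), int(size_bits), int(num_levels), int(num_hashes),
                       int(seed))
            nbytes = (int(size_bits) + 7) // 8
            for li in range(int(num_levels)):
                data = fh.read(nbytes)
                if len(data) != nbytes:
                    raise ValueError(f"{path}: truncated Bloom filter file")
                filt.levels[li] = np.frombuffer(data, dtype=np.uint8).copy()
        return filt


def build_from_reads(
    reads: Iterable[str],
    k: int,
    threshold: int = DEFAULT_THRESHOLD,
    size_bits: int = 1 << 25,
    num_hashes: int = DEFAULT_NUM_HASHES,
    hash_seed: int = 0,
) -> KmerBloom:
    """Build a multiplicity-thresholded filter from a stream of reads.

    ``size_bits`` is the capacity of each level.  Emits a warning when the
    estimated false-positive rate of the top (threshold) level exceeds 5 %,
    which means the filter is undersized for the read set.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    filt = KmerBloom(k, size_bits, num_levels=threshold,
                     num_hashes=num_hashes, hash_seed=hash_seed)
    filt.add_sequences(reads)
    top_fpr = filt.fpr_estimates()[-1]
    if top_fpr > 0.05:
        warnings.warn(
            f"Bloom filter overloaded: top-level false-positive rate "
            f"estimate {top_fpr:.3f} exceeds 5% (size_bits={size_bits}); "
            f"spurious graph edges are likely",
            RuntimeWarning,
            stacklevel=2,
        )
    return filt
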