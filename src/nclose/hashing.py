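"""Strand-neutral k-mer hashing.

A k-mer and its reverse complement must hash identically so that the Bloom
filter sees double-stranded data as one set of canonical k-mers.  Each
strand of every window gets a 64-bit polynomial rolling hash (computed for
all windows of a sequence at once with prefix sums in wrapping uint64
arithmetic); the two strand hashes are symmetrized with ``min`` and pushed
through a murmur-style finalizer keyed by the filter's seed.  Two
independent base constants give the (h1, h2) pair used for double hashing:
bit index ``i`` is ``h1 + i*h2``.

Collisions of the 64-bit hash are indistinguishable from Bloom false
positives and are covered by the same one-sided error contract.
"""

from __future__ import annotations

import numpy as np

_U64 = np.uint64
_MOD = 1 << 64

# Odd bases so they are invertible mod 2^64.
_BASE1 = 0x9E3779B97F4A7C15
_BASE2 = 0xC2B2AE3D27D4EB4F
_BASE1_INV = pow(_BASE1, -1, _MOD)
_BASE2_INV = pow(_BASE2, -1, _MOD)

_MIX1 = _U64(0xFF51AFD7ED558CCD)
_MIX2 = _U64(0xC4CEB9FE1A85EC53)
_S33 = _U64(33)

# ASCII -> 2-bit code; anything but A/C/G/T maps to 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a sequence into uint8 codes (A=0, C=1, G=2, T=3, other=255)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def _fmix64(z: np.ndarray) -> np.ndarray:
    z = z ^ (z >> _S33)
    z = z * _MIX1
    z = z ^ (z >> _S33)
    z = z * _MIX2
    return z ^ (z >> _S33)


def _strand_min_hashes(
    codes: np.ndarray, k: int, base: int, base_inv: int
) -> np.ndarray:
    """min(forward, reverse-complement) polynomial hash of every window.

    Returns one uint64 per window position (values at windows containing an
    invalid code are garbage; callers mask them with :func:`valid_windows`).
    """
    n = codes.shape[0]
    nwin = n - k + 1
    c = codes.astype(np.uint64)
    comp = (_U64(3) - (c & _U64(3)))

    bpow = np.empty(n, dtype=np.uint64)
    bpow[0] = 1
    if n > 1:
        np.cumprod(np.full(n - 1, base, dtype=np.uint64), out=bpow[1:])
    binv_pow = np.empty(n, dtype=np.uint64)
    binv_pow[0] = 1
    if n > 1:
        np.cumprod(np.full(n - 1, base_inv, dtype=np.uint64), out=binv_pow[1:])

    # Exclusive prefix sums (wrapping) of c[j]*B^-j and comp[j]*B^j.
    q = np.zeros(n + 1, dtype=np.uint64)
    np.cumsum(c * binv_pow, out=q[1:])
    p = np.zeros(n + 1, dtype=np.uint64)
    np.cumsum(comp * bpow, out=p[1:])

    idx = np.arange(nwin)
    # forward hash of window i: sum_t c[i+t] * B^(k-1-t)
    fwd = (q[idx + k] - q[idx]) * bpow[idx + k - 1]
    # reverse-complement hash: sum_t comp(c[i+t]) * B^t
    rc = (p[idx + k] - p[idx]) * binv_pow[idx]
    return np.minimum(fwd, rc)


def valid_windows(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over window start positions: True iff ACGT-only."""
    n = codes.shape[0]
    if n < k:
        return np.zeros(0, dtype=bool)
    bad = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(codes > 3, out=bad[1:])
    idx = np.arange(n - k + 1)
    return bad[idx + k] == bad[idx]


def window_hash_pairs(
    codes: np.ndarray, k: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(positions, h1, h2) for every clean k-window of an encoded sequence.

    ``positions`` are window start offsets into *codes*; h1/h2 are the
    strand-neutral hash pair at each kept position.
    """
    if codes.shape[0] < k:
        e = np.empty(0, dtype=np.uint64)
        return np.empty(0, dtype=np.int64), e, e
    mask = valid_windows(codes, k)
    with np.errstate(over="ignore"):
        g1 = _strand_min_hashes(codes, k, _BASE1, _BASE1_INV)
        g2 = _strand_min_hashes(codes, k, _BASE2, _BASE2_INV)
        s = _U64(seed & (_MOD - 1))
        h1 = _fmix64(g1 ^ s)
        h2 = _fmix64(g2 ^ (s * _MIX2 + _U64(1))) | _U64(1)
    pos = np.nonzero(mask)[0]
    return pos, h1[pos], h2[pos]


def hash_kmers(kmers: list[str], k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Hash pair for each of several same-length ACGT k-mer strings.

    The k-mers are concatenated with a separator so a single vectorized
    pass covers them all; exactly one clean window per k-mer results.
    """
    if not kmers:
        e = np.empty(0, dtype=np.uint64)
        return e, e
    codes = encode("N".join(kmers))
    pos, h1, h2 = window_hash_pairs(codes, k, seed)
    if pos.shape[0] != len(kmers):
        raise ValueError("k-mers must be ACGT-only strings of length k")
    return h1, h2


def hash_kmer(kmer: str, seed: int) -> tuple[int, int]:
    """Hash pair of one ACGT k-mer string."""
    h1, h2 = hash_kmers([kmer], len(kmer), seed)
    return int(h1[0]), int(h2[0])
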