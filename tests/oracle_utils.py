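"""Independent reference implementations used only for cross-checking.

The exact counter and the exhaustive depth-first path enumeration below
deliberately share no code with the package's Bloom filter or
bidirectional search: they hold canonical k-mer strings in a plain dict
and walk the graph recursively, so agreement between the two routes is
evidence, not tautology.
"""

from __future__ import annotations

from collections import Counter

_COMP = str.maketrans("ACGT", "TGCA")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _canon(s: str) -> str:
    r = _rc(s)
    return s if s <= r else r


def exact_kmer_counts(reads: list[str], k: int) -> Counter:
    """Exact multiplicities of canonical k-mers over all clean windows."""
    counts: Counter = Counter()
    acgt = frozenset("ACGT")
    for read in reads:
        good = 0
        for i, c in enumerate(read):
            if c not in acgt:
                good = i + 1
            elif i - good + 1 >= k:
                counts[_canon(read[i - k + 1 : i + 1])] += 1
    return counts


def exact_solid_set(reads: list[str], k: int, threshold: int) -> set[str]:
    return {km for km, n in exact_kmer_counts(reads, k).items() if n >= threshold}


def oracle_find_anchor(flank: str, side: str, solid: set[str], k: int):
    """Scan inward from the gap edge for the first k-mer in the solid set."""
    n = len(flank)
    if n < k:
        return None
    for off in range(n - k + 1):
        if side == "left":
            kmer = flank[n - k - off : n - off]
        else:
            kmer = flank[off : off + k]
        if _canon(kmer) in solid:
            return kmer, off
    return None


def random_kmers_absent_from(
    reads: list[str], k: int, n: int, rng
) -> list[str]:
    """*n* random k-mers whose canonical form never occurs in *reads*."""
    present = set(exact_kmer_counts(reads, k))
    out: list[str] = []
    while len(out) < n:
        km = "".join(rng.choice("ACGT") for _ in range(k))
        if _canon(km) not in present:
            out.append(km)
    return out


def dfs_paths(solid: set[str], start: str, goal: str, max_interior: int) -> list[str]:
    """Every spelled path from start to goal by exhaustive depth-first walk.

    A path may not revisit a stranded k-mer, may add at most
    ``max_interior`` bases beyond the start k-mer, and ends the moment it
    sits on the goal k-mer.
    """
    k = len(start)
    out: set[str] = set()
    stack: list[tuple[str, frozenset[str]]] = [(start, frozenset([start]))]
    while stack:
        spelled, visited = stack.pop()
        node = spelled[-k:]
        if node == goal:
            out.add(spelled)
            continue
        if len(spelled) - k >= max_interior:
            continue
        for c in "ACGT":
            nxt = node[1:] + c
            if nxt in visited:
                continue
            if _canon(nxt) in solid:
                stack.append((spelled + c, visited | {nxt}))
    return sorted(out)
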