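"""Implicit de Bruijn graph over a k-mer Bloom filter.

Nodes are stranded k-mer strings; membership is resolved strand-neutrally
by the filter.  Edges are never stored: the at-most-four successors (or
predecessors) of a node are generated on demand and kept only if solid.
"""

from __future__ import annotations

from dataclasses import dataclass

from .bloom import KmerBloom

_BASES = "ACGT"


@dataclass
class GraphParams:
    """A k value and the Bloom filter backing its implicit graph."""

    k: int
    bloom: KmerBloom

    def __post_init__(self) -> None:
        if self.bloom.k != self.k:
            raise ValueError(
                f"Bloom filter k={self.bloom.k} does not match graph k={self.k}"
            )


def neighbors(g: GraphParams, kmer: str, direction: str) -> list[tuple[str, str]]:
    """Solid extensions of *kmer* by one base.

    ``direction="right"`` proposes ``kmer[1:] + c`` and ``"left"`` proposes
    ``c + kmer[:-1]`` for c in A, C, G, T (fixed order); entries whose
    k-mer is not solid are dropped.
    """
    if direction == "right":
        core = kmer[1:]
        cands = [core + c for c in _BASES]
    elif direction == "left":
        core = kmer[:-1]
        cands = [c + core for c in _BASES]
    else:
        raise ValueError(f"direction must be 'left' or 'right', got {direction!r}")
    keep = g.bloom.solid_many(cands)
    return [(b, cand) for b, cand, ok in zip(_BASES, cands, keep) if ok]
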