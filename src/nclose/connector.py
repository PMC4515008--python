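"""Flank-pair connection through the implicit de Bruijn graph.

Given the two N-free flanks of a scaffold gap, the connector anchors a
solid k-mer on each flank, enumerates every distinct k-mer path between the
anchors with a depth-limited bidirectional breadth-first search, and emits
a single replacement sequence: the path itself when unique, or a
position-wise IUPAC consensus when several equal-length paths exist.

The search is all-or-none.  Exceeding the live-branch budget, the path
multiplicity budget, or the product length cap fails the whole gap — no
partial fills are ever reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph import GraphParams
from .seq_core import iupac_merge

# Connection statuses.
UNIQUE = "unique"
CONSENSUS = "consensus"
NO_PATH = "no_path"
TOO_MANY_PATHS = "too_many_paths"
BRANCH_LIMIT = "branch_limit"
LENGTH_LIMIT = "length_limit"
NO_ANCHOR = "no_anchor"

SUCCESS_STATUSES = frozenset({UNIQUE, CONSENSUS})

_OK = "ok"

_ACGT = frozenset("ACGT")


@dataclass
class SearchParams:
    """Limits of one flank-pair search.

    ``max_paths`` caps the number of distinct complete paths accepted for a
    consensus; ``max_branches`` caps simultaneously live partial paths
    summed over both search frontiers; ``max_frag`` caps the full length of
    the assembled replacement (kept flanks included), mirroring the maximum
    fragment length of paired-read connection; ``max_flank_scan`` bounds how
    far inward from the gap edge an anchor k-mer may be sought (``None``
    scans the whole flank).
    """

    k: int
    max_paths: int = 2
    max_branches: int = 1000
    max_frag: int = 1000
    max_flank_scan: int | None = None

    def __post_init__(self) -> None:
        if self.max_paths < 1:
            raise ValueError("max_paths must be >= 1")
        if self.max_branches < 1:
            raise ValueError("max_branches must be >= 1")
        if self.max_frag < 2 * self.k:
            raise ValueError("max_frag must be at least 2k")


@dataclass
class ConnectionResult:
    """Outcome of one flank-pair search."""

    status: str
    sequence: str | None = None
    num_paths: int = 0
    left_trim: int = 0
    right_trim: int = 0
    #: Distinct anchor-to-anchor path spellings (diagnostic; populated on
    #: success and on too_many_paths when the paths were fully enumerated).
    path_seqs: list[str] = field(default_factory=list)

    @property
    def success(self) -> bool:
        return self.status in SUCCESS_STATUSES


def find_anchor(
    flank: str, side: str, g: GraphParams, max_flank_scan: int | None = None
) -> tuple[str, int] | None:
    """First solid k-mer scanning inward from the gap edge of a flank.

    For ``side="left"`` candidates start at the flank's 3' end (the gap
    edge) and move inward; for ``side="right"`` they start at the 5' end.
    Returns ``(kmer, trim)`` where *trim* is the number of flank bases
    between the anchor and the gap edge — these bases are replaced by the
    assembled path, correcting potential micro-misassemblies at the flank
    tip.  Returns None when no solid anchor exists in the scan window.
    """
    k = g.k
    n = len(flank)
    if n < k:
        return None
    limit = n - k if max_flank_scan is None else min(max_flank_scan, n - k)
    for off in range(limit + 1):
        if side == "left":
            kmer = flank[n - k - off : n - off]
        elif side == "right":
            kmer = flank[off : off + k]
        else:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        if _ACGT.issuperset(kmer) and g.bloom.solid(kmer):
            return kmer, off
    return None


def _has_repeated_kmer(spelled: str, k: int) -> bool:
    n = len(spelled) - k + 1
    return len({spelled[i : i + k] for i in range(n)}) != n


def enumerate_paths(
    g: GraphParams,
    start: str,
    goal: str,
    max_interior: int,
    max_paths: int,
    max_branches: int,
) -> tuple[str, list[str]]:
    """All distinct k-mer paths from *start* to *goal* within the limits.

    Two breadth-first frontiers expand alternately, one level per turn:
    right-extensions from *start* and left-extensions from *goal*.  Every
    partial path is registered at its end node; whenever an expansion lands
    on a node the opposite side has reached, the two halves are joined and
    the joint spelling recorded.  A path never visits the same stranded
    k-mer twice (cycle guard; traversing a k-mer and later its reverse
    complement — an inverted repeat — is allowed).  *max_interior* caps the
    number of bases a path adds beyond the start k-mer.

    Returns ``("ok", paths)`` with the distinct spellings sorted, or a
    limit status with an empty list: ``branch_limit`` when live branches
    exceed *max_branches*, ``too_many_paths`` when distinct complete paths
    exceed *max_paths*, ``length_limit`` when every branch died at the
    depth cap without a single complete path, and ``no_path`` when both
    frontiers exhaust with no meeting.
    """
    k = g.k
    complete: set[str] = set()
    hit_depth = False

    # node -> every partial-path spelling reaching it (left: paths from
    # start ending at node; right: paths from node ending at goal).
    left_reg: dict[str, list[str]] = {start: [start]}
    right_reg: dict[str, list[str]] = {goal: [goal]}

    def join(left_spelled: str, right_spelled: str) -> None:
        combined = left_spelled + right_spelled[k:]
        if len(combined) - k > max_interior:
            return
        if _has_repeated_kmer(combined, k):
            return
        complete.add(combined)

    if start == goal:
        join(start, goal)

    # Frontier entries: (spelled, set of visited stranded k-mers).
    left_frontier: list[tuple[str, set[str]]] = [(start, {start})]
    right_frontier: list[tuple[str, set[str]]] = [(goal, {goal})]

    def batch_neighbors(nodes: list[str], direction: str) -> dict[str, list[tuple[str, str]]]:
        # One vectorized Bloom query for every candidate extension of every
        # frontier node; semantics identical to per-node `neighbors`.
        cands: list[str] = []
        for node in nodes:
            core = node[1:] if direction == "right" else node[:-1]
            if direction == "right":
                cands.extend(core + c for c in "ACGT")
            else:
                cands.extend(c + core for c in "ACGT")
        keep = g.bloom.solid_many(cands) if cands else []
        out: dict[str, list[tuple[str, str]]] = {}
        for i, node in enumerate(nodes):
            steps = [
                ("ACGT"[j], cands[4 * i + j])
                for j in range(4)
                if keep[4 * i + j]
            ]
            out[node] = steps
        return out

    def expand(side: str) -> tuple[list[tuple[str, set[str]]], str | None]:
        nonlocal hit_depth
        frontier = left_frontier if side == "left" else right_frontier
        own_reg = left_reg if side == "left" else right_reg
        other_reg = right_reg if side == "left" else left_reg
        other_live = len(right_frontier if side == "left" else left_frontier)
        direction = "right" if side == "left" else "left"
        alive = [e for e in frontier if len(e[0]) - k < max_interior]
        if len(alive) < len(frontier):
            hit_depth = True
        nodes = list(dict.fromkeys(
            (s[-k:] if side == "left" else s[:k]) for s, _ in alive))
        nbr = batch_neighbors(nodes, direction)
        new_frontier: list[tuple[str, set[str]]] = []
        for spelled, visited in alive:
            steps = nbr[spelled[-k:] if side == "left" else spelled[:k]]
            for base, nxt in steps:
                if nxt in visited:
                    continue
                ns = spelled + base if side == "left" else base + spelled
                own_reg.setdefault(nxt, []).append(ns)
                for other in other_reg.get(nxt, ()):
                    if side == "left":
                        join(ns, other)
                    else:
                        join(other, ns)
                    if len(complete) > max_paths:
                        return [], TOO_MANY_PATHS
                new_frontier.append((ns, visited | {nxt}))
                if len(new_frontier) + other_live > max_branches:
                    return [], BRANCH_LIMIT
        return new_frontier, None

    while left_frontier or right_frontier:
        for side in ("left", "right"):
            frontier = left_frontier if side == "left" else right_frontier
            if not frontier:
                continue
            new_frontier, abort = expand(side)
            if abort is not None:
                return abort, []
            if side == "left":
                left_frontier = new_frontier
            else:
                right_frontier = new_frontier

    if complete:
        return _OK, sorted(complete)
    if hit_depth:
        return LENGTH_LIMIT, []
    return NO_PATH, []


def consensus_paths(paths: list[str]) -> str | None:
    """Single sequence summarizing one or more path spellings.

    One path is returned verbatim.  Several paths of equal length merge
    position-wise, columns that disagree getting the IUPAC code of the
    observed bases.  Paths of unequal length cannot be merged column-wise
    and yield None (the gap stays open).
    """
    if not paths:
        raise ValueError("consensus of an empty path list")
    if len(paths) == 1:
        return paths[0]
    length = len(paths[0])
    if any(len(p) != length for p in paths[1:]):
        return None
    cols = []
    for column in zip(*paths):
        bases = set(column)
        cols.append(column[0] if len(bases) == 1 else iupac_merge(bases))
    return "".join(cols)


def connect(
    left_flank: str, right_flank: str, g: GraphParams, p: SearchParams
) -> ConnectionResult:
    """Assemble the sequence spanning a gap from its two flanks.

    On success the returned sequence is the full replacement product —
    kept left flank through the interior to the kept right flank — whose
    length never exceeds ``p.max_frag``.
    """
    k = g.k
    left = find_anchor(left_flank, "left", g, p.max_flank_scan)
    right = find_anchor(right_flank, "right", g, p.max_flank_scan)
    if left is None or right is None:
        return ConnectionResult(NO_ANCHOR)
    start, left_trim = left
    goal, right_trim = right
    left_kept = left_flank[: len(left_flank) - left_trim]
    right_kept = right_flank[right_trim:]

    max_interior = p.max_frag - len(left_kept) - len(right_kept) + k
    if max_interior < 0:
        return ConnectionResult(LENGTH_LIMIT, left_trim=left_trim,
                                right_trim=right_trim)

    status, paths = enumerate_paths(
        g, start, goal, max_interior, p.max_paths, p.max_branches
    )
    if status != _OK:
        return ConnectionResult(status, left_trim=left_trim,
                                right_trim=right_trim)

    merged = consensus_paths(paths)
    if merged is None:
        # Alternate paths of different lengths: ambiguity beyond what a
        # column-wise consensus can express, so the gap stays open.
        return ConnectionResult(TOO_MANY_PATHS, num_paths=len(paths),
                                left_trim=left_trim, right_trim=right_trim,
                                path_seqs=paths)
    sequence = left_kept[:-k] + merged + right_kept[k:]
    return ConnectionResult(
        UNIQUE if len(paths) == 1 else CONSENSUS,
        sequence=sequence,
        num_paths=len(paths),
        left_trim=left_trim,
        right_trim=right_trim,
        path_seqs=paths,
    )
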