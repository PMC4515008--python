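"""End-to-end gap closing: discovery, subtractive k-sweep, scaffold update.

The pipeline finds every qualifying N-run in the input scaffolds, then for
each k in the configured sweep builds one multiplicity-thresholded Bloom
filter from the reads, attempts to connect the flanks of every still-open
gap, and removes successful closures from the working set before the next
k (the subtractive sweep: a gap closed once is never re-attempted, and
only one filter is resident at a time).  Finally the closures are spliced
into the scaffolds right-most first, so earlier coordinates stay valid as
replacement lengths differ from the N-run lengths they displace.

All coordinates are 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from . import bloom as bloom_mod
from . import connector
from .graph import GraphParams
from .io import write_fasta

logger = logging.getLogger(__name__)

_N_RUN = re.compile(r"N+")
_ACGT = frozenset("ACGT")

Scaffold = tuple[str, str]  # (id, sequence)


@dataclass
class GapRecord:
    """One N-run and its two clean flanks — the unit of work."""

    scaffold_id: str
    start: int
    end: int
    left_flank: str
    right_flank: str

    @property
    def gap_len(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple[str, int, int]:
        return (self.scaffold_id, self.start, self.end)


@dataclass
class Closure:
    """A successful gap closure ready to be spliced into its scaffold."""

    gap: GapRecord
    replacement: str
    left_trim: int
    right_trim: int
    k_used: int
    status: str
    num_paths: int = 1

    @property
    def window_start(self) -> int:
        """Start of the replaced window: the gap minus its full left flank."""
        return self.gap.start - len(self.gap.left_flank)

    @property
    def window_end(self) -> int:
        return self.gap.end + len(self.gap.right_flank)


@dataclass
class RunConfig:
    """Configuration of one gap-closing run.

    ``k_list`` is attempted in the given order; descending k first is the
    recommended default since large k-mers resolve repeats better and the
    first k typically closes the most gaps.  ``bloom_bytes`` is the total
    memory of one filter, split equally over its ``threshold`` levels.
    """

    k_list: Sequence[int]
    min_flank: int = 100
    threshold: int = 2
    max_paths: int = 2
    max_branches: int = 1000
    max_frag: int = 1000
    max_flank_scan: int | None = None
    bloom_bytes: int = 32 << 20
    num_hashes: int = bloom_mod.DEFAULT_NUM_HASHES
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.k_list:
            raise ValueError("k_list must not be empty")
        bad = [k for k in self.k_list if k > self.min_flank]
        if bad:
            raise ValueError(
                f"k values {bad} exceed the flank length {self.min_flank}; "
                f"anchors could never be found"
            )

    def search_params(self, k: int) -> connector.SearchParams:
        return connector.SearchParams(
            k=k,
            max_paths=self.max_paths,
            max_branches=self.max_branches,
            max_frag=self.max_frag,
            max_flank_scan=self.max_flank_scan,
        )

    @property
    def level_bits(self) -> int:
        return max(64, (self.bloom_bytes * 8) // self.threshold)


def find_gaps(scaffolds: Iterable[Scaffold], min_flank: int) -> list[GapRecord]:
    """One record per maximal N-run with ``min_flank`` clean bases each side.

    A qualifying gap has at least *min_flank* consecutive bases adjacent on
    BOTH sides that are plain A/C/G/T (N or ambiguity codes disqualify —
    they are not solid sequence).  Gaps at scaffold termini or crowded by a
    neighbouring N-run are skipped.  The *min_flank* bases nearest the gap
    become the flanks.  Records come back sorted by (scaffold_id, start).
    """
    if min_flank < 1:
        raise ValueError("min_flank must be >= 1")
    records: list[GapRecord] = []
    for name, seq in scaffolds:
        for m in _N_RUN.finditer(seq):
            start, end = m.span()
            if start < min_flank or end + min_flank > len(seq):
                continue
            left = seq[start - min_flank : start]
            right = seq[end : end + min_flank]
            if _ACGT.issuperset(left) and _ACGT.issuperset(right):
                records.append(GapRecord(name, start, end, left, right))
    records.sort(key=lambda r: (r.scaffold_id, r.start))
    return records


def _read_stream(reads) -> Iterable[str]:
    """Reads may be a re-iterable sequence or a zero-arg factory."""
    if callable(reads):
        return reads()
    return reads


def run_sweep(
    scaffolds: Iterable[Scaffold],
    reads: Iterable[str] | Callable[[], Iterable[str]],
    cfg: RunConfig,
    gaps: list[GapRecord] | None = None,
) -> tuple[list[Closure], list[dict]]:
    """Attempt every gap at each k in turn, subtracting successes.

    *reads* must be re-iterable (a list, or a callable returning a fresh
    iterator) because one Bloom filter is built per k; filters are released
    between iterations so only one is in memory at a time.

    Returns the closures plus a log: one ``type=sweep`` row per k with
    attempted/closed/status counts, and one ``type=gap`` row per attempt.
    """
    scaffolds = list(scaffolds)
    if gaps is None:
        gaps = find_gaps(scaffolds, cfg.min_flank)
    open_gaps = list(gaps)
    closures: list[Closure] = []
    log: list[dict] = []

    for k in cfg.k_list:
        filt = bloom_mod.build_from_reads(
            _read_stream(reads),
            k,
            threshold=cfg.threshold,
            size_bits=cfg.level_bits,
            num_hashes=cfg.num_hashes,
            hash_seed=cfg.seed,
        )
        g = GraphParams(k=k, bloom=filt)
        params = cfg.search_params(k)
        status_counts: dict[str, int] = {}
        still_open: list[GapRecord] = []
        closed_here = 0
        for gap in open_gaps:
            res = connector.connect(gap.left_flank, gap.right_flank, g, params)
            status_counts[res.status] = status_counts.get(res.status, 0) + 1
            log.append({
                "type": "gap",
                "k": k,
                "scaffold_id": gap.scaffold_id,
                "start": gap.start,
                "end": gap.end,
                "status": res.status,
                "num_paths": res.num_paths,
                "replacement_len": len(res.sequence) if res.sequence else 0,
            })
            if res.success:
                assert res.sequence is not None
                closures.append(Closure(
                    gap=gap,
                    replacement=res.sequence,
                    left_trim=res.left_trim,
                    right_trim=res.right_trim,
                    k_used=k,
                    status=res.status,
                    num_paths=res.num_paths,
                ))
                closed_here += 1
            else:
                still_open.append(gap)
        log.append({
            "type": "sweep",
            "k": k,
            "attempted": len(open_gaps),
            "closed": closed_here,
            "open_after": len(still_open),
            **{f"n_{s}": c for s, c in sorted(status_counts.items())},
        })
        logger.info("k=%d: attempted %d gaps, closed %d, %d remain open",
                    k, len(open_gaps), closed_here, len(still_open))
        open_gaps = still_open
        del filt, g  # only one Bloom filter resident at a time

    return closures, log


def apply_closures(
    scaffolds: Iterable[Scaffold], closures: list[Closure]
) -> tuple[list[Scaffold], list[Closure]]:
    """Splice closures into their scaffolds, right-most gap first.

    Replacement windows span the gap plus both full flanks (the flank tips
    may have been corrected during assembly).  Applying from 3' to 5' keeps
    every remaining closure's original coordinates valid even though
    replacement lengths differ from the N-runs they displace.  When two
    windows overlap the right-most closure wins and the other is dropped
    (returned separately and logged).
    """
    by_scaffold: dict[str, list[Closure]] = {}
    for c in closures:
        by_scaffold.setdefault(c.gap.scaffold_id, []).append(c)

    dropped: list[Closure] = []
    out: list[Scaffold] = []
    for name, seq in scaffolds:
        todo = sorted(by_scaffold.get(name, []),
                      key=lambda c: c.gap.start, reverse=True)
        applied_min_start = len(seq) + 1
        for c in todo:
            if c.window_end > applied_min_start:
                logger.warning(
                    "dropping closure of %s:[%d,%d): window overlaps an "
                    "already-applied closure", name, c.gap.start, c.gap.end)
                dropped.append(c)
                continue
            seq = seq[: c.window_start] + c.replacement + seq[c.window_end :]
            applied_min_start = c.window_start
        out.append((name, seq))
    return out, dropped


def write_outputs(
    filled_scaffolds: list[Scaffold],
    closures: list[Closure],
    log: list[dict],
    out_prefix: str | Path,
    gaps: list[GapRecord] | None = None,
    print_flanks: bool = False,
) -> dict[str, Path]:
    """Write the gap-filled scaffolds, merged sequences, TSV log and
    (optionally) the flank pairs.

    Returns a name->path map of everything written.  Merged-sequence
    headers are ``<scaffold_id>_<gap_start>_<gap_end> k=<k> status=<s>``
    with 0-based half-open coordinates from the *input* scaffolds.
    """
    prefix = Path(out_prefix)
    check_writable(prefix)
    files: dict[str, Path] = {}

    files["scaffolds"] = Path(f"{prefix}_scaffolds.fa")
    write_fasta(files["scaffolds"], filled_scaffolds)

    files["merged"] = Path(f"{prefix}_merged.fa")
    write_fasta(files["merged"], [
        (f"{c.gap.scaffold_id}_{c.gap.start}_{c.gap.end} "
         f"k={c.k_used} status={c.status}", c.replacement)
        for c in closures
    ])

    files["log"] = Path(f"{prefix}_log.tsv")
    _write_log_tsv(files["log"], log)

    if print_flanks:
        if gaps is None:
            raise ValueError("print_flanks requires the gap records")
        pairs: list[tuple[str, str]] = []
        for gap in gaps:
            stem = f"{gap.scaffold_id}_{gap.start}_{gap.end}"
            pairs.append((f"{stem}/1", gap.left_flank))
            pairs.append((f"{stem}/2", gap.right_flank))
        files["flanks"] = Path(f"{prefix}_flanks.fa")
        write_fasta(files["flanks"], pairs)

    return files


_LOG_COLUMNS = [
    "type", "k", "scaffold_id", "start", "end", "status", "num_paths",
    "replacement_len", "attempted", "closed", "open_after",
    "n_unique", "n_consensus", "n_no_path", "n_too_many_paths",
    "n_branch_limit", "n_length_limit", "n_no_anchor",
]


def _write_log_tsv(path: Path, log: list[dict]) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open\n")
        fh.write("\t".join(_LOG_COLUMNS) + "\n")
        for row in log:
            fh.write("\t".join(str(row.get(c, "")) for c in _LOG_COLUMNS) + "\n")


def check_writable(out_prefix: str | Path) -> None:
    """Fail before any computation if the output location is unusable."""
    prefix = Path(out_prefix)
    parent = prefix.parent if prefix.parent != Path("") else Path(".")
    if not parent.is_dir():
        raise FileNotFoundError(f"output directory {parent} does not exist")
    probe = parent / f".{prefix.name}.write_probe"
    try:
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise PermissionError(f"output directory {parent} is not writable") from exc


def seal(
    scaffolds: Iterable[Scaffold],
    reads: Iterable[str] | Callable[[], Iterable[str]],
    cfg: RunConfig,
) -> dict:
    """Run discovery, sweep and splice; return everything in one bundle."""
    scaffolds = list(scaffolds)
    gaps = find_gaps(scaffolds, cfg.min_flank)
    closures, log = run_sweep(scaffolds, reads, cfg, gaps=gaps)
    filled, dropped = apply_closures(scaffolds, closures)
    applied = [c for c in closures if c not in dropped]
    return {
        "gaps": gaps,
        "closures": closures,
        "applied": applied,
        "dropped": dropped,
        "filled": filled,
        "log": log,
    }
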