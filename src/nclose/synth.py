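"""Synthetic fixtures: reference genome, paired-end reads, gapped draft.

These generators emulate the data a whole-genome shotgun gap-closing run
consumes: an i.i.d. reference (optionally with planted exact repeats),
paired-end reads with Gaussian fragment lengths and i.i.d. substitution
errors, and a draft whose chosen windows are masked by N-runs whose
written length may deliberately misstate the true masked length — gap
sizes in real drafts are estimates from fragment-library distributions,
not measurements.

Every operation draws from its own RNG stream seeded by (seed, operation
tag), so each output is individually reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seq_core import reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Per-operation RNG stream tags.
_TAG_GENOME = 1
_TAG_READS = 2
_TAG_DRAFT = 3


@dataclass
class SimConfig:
    """Parameters of one synthetic dataset.

    ``gap_size_error`` is the signed fraction by which the written N-run
    length misstates the true masked length: a float applies uniformly
    (0.5 writes 150 Ns over 100 masked bases), a (low, high) pair draws a
    fraction per gap.
    """

    genome_len: int = 100_000
    gc: float = 0.5
    repeat_spec: Sequence[tuple[int, int]] = ()
    read_len: int = 100
    frag_len_mean: float = 400.0
    frag_len_sd: float = 40.0
    coverage: float = 50.0
    sub_error_rate: float = 0.0
    n_gaps: int = 20
    gap_len_range: tuple[int, int] = (50, 500)
    gap_size_error: float | tuple[float, float] = 0.0
    min_flank: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.genome_len <= 0 or self.read_len <= 0 or self.min_flank <= 0:
            raise ValueError("all lengths must be positive")
        if self.gap_len_range[0] < 1 or self.gap_len_range[1] < self.gap_len_range[0]:
            raise ValueError("invalid gap_len_range")


@dataclass
class TruthEntry:
    """Ground truth for one planted gap, in draft coordinates."""

    scaffold_id: str
    start: int  # N-run start in the draft (0-based half-open)
    end: int
    true_sequence: str

    @property
    def true_len(self) -> int:
        return len(self.true_sequence)


def _rng(cfg: SimConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, tag])


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_genome(cfg: SimConfig) -> str:
    """I.i.d. genome at the configured GC fraction with planted repeats."""
    return simulate_genome_with_repeats(cfg)[0]


def simulate_genome_with_repeats(
    cfg: SimConfig,
) -> tuple[str, list[tuple[int, int]]]:
    """As :func:`simulate_genome`, also returning the repeat intervals.

    Each ``(unit_len, copies)`` entry of ``repeat_spec`` picks one source
    window and copies it verbatim to ``copies - 1`` additional positions,
    creating exact duplications that tangle the k-mer graph for k below
    the unit length.  The returned intervals cover every copy (source
    included), 0-based half-open.
    """
    rng = _rng(cfg, _TAG_GENOME)
    at = (1.0 - cfg.gc) / 2.0
    gcp = cfg.gc / 2.0
    codes = rng.choice(4, size=cfg.genome_len, p=[at, gcp, gcp, at]).astype(np.uint8)
    intervals: list[tuple[int, int]] = []
    for unit_len, copies in cfg.repeat_spec:
        if unit_len > cfg.genome_len:
            raise ValueError(
                f"repeat unit of {unit_len} bp exceeds genome length")
        src = int(rng.integers(0, cfg.genome_len - unit_len + 1))
        unit = codes[src : src + unit_len].copy()
        intervals.append((src, src + unit_len))
        for _ in range(copies - 1):
            dst = int(rng.integers(0, cfg.genome_len - unit_len + 1))
            codes[dst : dst + unit_len] = unit
            intervals.append((dst, dst + unit_len))
    return _codes_to_str(codes), sorted(intervals)


def num_pairs(cfg: SimConfig) -> int:
    """Read pairs needed for the configured coverage."""
    return math.ceil(cfg.coverage * cfg.genome_len / (2 * cfg.read_len))


def simulate_reads(genome: str, cfg: SimConfig) -> tuple[list[str], list[str]]:
    """Paired-end reads: fragment 5' prefix and reverse-complemented 3' suffix.

    Fragments start uniformly; lengths are Gaussian, clamped to
    [read_len, genome_len].  Substitutions hit each base independently at
    ``sub_error_rate`` and always change the base.
    """
    if len(genome) < cfg.read_len:
        raise ValueError("genome shorter than the read length")
    rng = _rng(cfg, _TAG_READS)
    n = num_pairs(cfg)
    codes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    code_of = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        code_of[b] = i
    codes = code_of[codes]
    glen = len(genome)

    frag_lens = rng.normal(cfg.frag_len_mean, cfg.frag_len_sd, size=n)
    frag_lens = np.clip(np.rint(frag_lens), cfg.read_len, glen).astype(np.int64)
    starts = (rng.random(n) * (glen - frag_lens + 1)).astype(np.int64)

    rl = cfg.read_len
    offs = np.arange(rl)
    r1 = codes[starts[:, None] + offs]                       # fragment prefix
    r2_fwd = codes[(starts + frag_lens - rl)[:, None] + offs]  # fragment suffix

    if cfg.sub_error_rate > 0:
        for mat in (r1, r2_fwd):
            hit = rng.random(mat.shape) < cfg.sub_error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.uint8)
            mat[hit] = (mat[hit] + shift[hit]) % 4

    reads1 = [_codes_to_str(row) for row in r1]
    reads2 = [reverse_complement(_codes_to_str(row)) for row in r2_fwd]
    return reads1, reads2


def make_gapped_draft(
    genome: str,
    cfg: SimConfig,
    scaffold_id: str = "scaffold1",
    max_tries: int = 10_000,
    avoid_intervals: Sequence[tuple[int, int]] = (),
    force_in_intervals: Sequence[tuple[int, int]] | None = None,
) -> tuple[list[tuple[str, str]], list[TruthEntry]]:
    """Mask ``n_gaps`` windows of the genome with N-runs; keep the truth.

    Windows are at least ``min_flank`` from the scaffold ends and pairwise
    separated by at least ``2 * min_flank`` so every gap keeps clean
    flanks.  The written N-run length is ``round(true_len * (1 + e))``
    (minimum 1) with ``e`` the configured size error.  Truth coordinates
    are the N-run positions *in the draft*.

    ``avoid_intervals`` (e.g. planted repeat regions) are never overlapped
    by a gap window; ``force_in_intervals`` instead requires every window
    to overlap one of the given intervals, which plants gaps inside
    repeats to exercise large-k repeat resolution.
    """
    rng = _rng(cfg, _TAG_DRAFT)
    glen = len(genome)
    lo, hi = cfg.gap_len_range

    def acceptable(start: int, end: int) -> bool:
        if any(start < e and s < end for s, e in avoid_intervals):
            return False
        if force_in_intervals is not None and not any(
                start < e and s < end for s, e in force_in_intervals):
            return False
        return True

    windows: list[tuple[int, int]] = []
    tries = 0
    while len(windows) < cfg.n_gaps:
        if tries >= max_tries:
            raise ValueError(
                f"could only place {len(windows)} of {cfg.n_gaps} gap "
                f"windows after {max_tries} tries")
        tries += 1
        length = int(rng.integers(lo, hi + 1))
        if glen < length + 2 * cfg.min_flank:
            continue
        start = int(rng.integers(cfg.min_flank, glen - length - cfg.min_flank + 1))
        end = start + length
        if not acceptable(start, end):
            continue
        if all(start - e >= 2 * cfg.min_flank or s - end >= 2 * cfg.min_flank
               for s, e in windows):
            windows.append((start, end))
    windows.sort()

    if isinstance(cfg.gap_size_error, tuple):
        lo_e, hi_e = cfg.gap_size_error
        errors = rng.uniform(lo_e, hi_e, size=len(windows))
    else:
        errors = np.full(len(windows), float(cfg.gap_size_error))

    pieces: list[str] = []
    truth: list[TruthEntry] = []
    cursor = 0       # position in the genome
    out_pos = 0      # position in the draft being built
    for (start, end), err in zip(windows, errors):
        pieces.append(genome[cursor:start])
        out_pos += start - cursor
        true_seq = genome[start:end]
        n_len = max(1, round(len(true_seq) * (1.0 + float(err))))
        pieces.append("N" * n_len)
        truth.append(TruthEntry(scaffold_id, out_pos, out_pos + n_len, true_seq))
        out_pos += n_len
        cursor = end
    pieces.append(genome[cursor:])
    draft = "".join(pieces)
    return [(scaffold_id, draft)], truth


def write_truth_tsv(path, truth: list[TruthEntry]) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates are 0-based half-open in the draft\n")
        fh.write("scaffold_id\tstart\tend\ttrue_len\ttrue_sequence\n")
        for t in truth:
            fh.write(f"{t.scaffold_id}\t{t.start}\t{t.end}\t{t.true_len}\t"
                     f"{t.true_sequence}\n")


def read_truth_tsv(path) -> list[TruthEntry]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("scaffold_id"):
                continue
            sid, start, end, _tl, seq = line.rstrip("\n").split("\t")
            truth.append(TruthEntry(sid, int(start), int(end), seq))
    return truth
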