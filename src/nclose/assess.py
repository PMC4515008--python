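"""Evaluation of gap-filled assemblies.

A gap is one or a contiguous group of N bases.  Closure is assessed by
re-locating each original gap's flanks in the filled assembly and pulling
out whatever now sits between them; when ground truth is available the
inserted sequence is scored by global alignment with an ambiguity-aware
match definition — an IUPAC code in the query counts as a match against
any base in its set, since a consensus code records a genuine alternate
path rather than an error.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seq_core import IUPAC_SETS

_N_RUN = re.compile(r"N+")

Scaffold = tuple[str, str]

_ALPHABET = "ACGTRYSWKMBDHVN"


def _make_aligner() -> Align.PairwiseAligner:
    # Unit scoring: +1 for a compatible pair (IUPAC sets intersect), 0 for
    # mismatch and gaps.  The optimal score is then exactly the maximum
    # number of matching bases over all global alignments.
    m = substitution_matrices.Array(_ALPHABET, dims=2)
    for a in _ALPHABET:
        for b in _ALPHABET:
            m[a, b] = 1.0 if IUPAC_SETS[a] & IUPAC_SETS[b] else 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = m
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


@dataclass
class GapCount:
    """Number of maximal N-runs, per scaffold and total."""

    per_scaffold: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.per_scaffold.values())


def count_gaps(scaffolds: list[Scaffold]) -> GapCount:
    """Count maximal runs of N per scaffold (terminal runs included).

    Ambiguity codes are not N: an R or Y from a consensus does not count
    as unknown sequence.
    """
    if not scaffolds:
        warnings.warn("counting gaps in an empty assembly", stacklevel=2)
    counts = {name: len(_N_RUN.findall(seq)) for name, seq in scaffolds}
    return GapCount(counts)


@dataclass
class InsertedSeq:
    """Bases found between one original gap's flanks in the filled assembly."""

    scaffold_id: str
    start: int  # original N-run coordinates in the draft
    end: int
    sequence: str | None  # None when the flanks could not be anchored
    assessable: bool


def extract_inserted(
    draft: list[Scaffold], filled: list[Scaffold], flank_len: int = 100
) -> list[InsertedSeq]:
    """Per original gap, the bases now between its two flanks.

    For each N-run in the draft, the ``flank_len`` bases on each side are
    located in the corresponding filled scaffold — first near the expected
    (shift-corrected) coordinate, then scaffold-wide — and the sequence
    strictly between them is reported.  Gaps whose flanks are too short,
    missing, or ambiguous to anchor are marked unassessable.
    """
    filled_by_id = dict(filled)
    out: list[InsertedSeq] = []
    for name, seq in draft:
        target = filled_by_id.get(name)
        cursor = 0  # search cursor in the filled scaffold; gaps are in order
        for m in _N_RUN.finditer(seq):
            start, end = m.span()
            if target is None or start < flank_len or end + flank_len > len(seq):
                out.append(InsertedSeq(name, start, end, None, False))
                continue
            left = seq[start - flank_len : start]
            right = seq[end : end + flank_len]
            if "N" in left or "N" in right:
                out.append(InsertedSeq(name, start, end, None, False))
                continue
            lpos = target.find(left, cursor)
            if lpos < 0:
                lpos = target.find(left)  # scaffold-wide fallback
            if lpos < 0:
                out.append(InsertedSeq(name, start, end, None, False))
                continue
            rpos = target.find(right, lpos + flank_len)
            if rpos < 0:
                out.append(InsertedSeq(name, start, end, None, False))
                continue
            inserted = target[lpos + flank_len : rpos]
            out.append(InsertedSeq(name, start, end, inserted, True))
            cursor = rpos + flank_len
    return out


def similarity(query: str, truth: str) -> float:
    """Percent of query bases matched in an optimal global alignment.

    Unit scoring (match 1, mismatch/indel contribute nothing) and IUPAC
    codes in either sequence match any base of their set, so consensus
    ambiguity codes are not penalized.  Returns 100 * matches / len(query).
    """
    if not query or not truth:
        raise ValueError("similarity of an empty sequence is undefined")
    score = _ALIGNER.score(query, truth)
    return 100.0 * score / len(query)


def ambiguity_equal(query: str, truth: str) -> bool:
    """True if some IUPAC-consistent resolution of *query* equals *truth*."""
    if len(query) != len(truth):
        return False
    return all(t in IUPAC_SETS[q] for q, t in zip(query, truth))


@dataclass
class GapEvalRow:
    scaffold_id: str
    start: int
    end: int
    closed: bool
    assessable: bool
    inserted: str | None = None
    truth: str | None = None
    percent_similarity: float | None = None
    exact_match: bool | None = None


@dataclass
class EvalReport:
    rows: list[GapEvalRow]
    total_gaps: int
    closed: int
    percent_success: float
    mean_similarity: float | None
    exact_match_fraction: float | None
    #: (n at or above the similarity threshold, n scored), when requested.
    above_threshold: tuple[int, int] | None = None

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# coordinates are 0-based half-open in the draft\n")
            fh.write("scaffold_id\tstart\tend\tclosed\tassessable\t"
                     "percent_similarity\texact_match\n")
            for r in self.rows:
                sim = f"{r.percent_similarity:.2f}" if r.percent_similarity is not None else ""
                exact = "" if r.exact_match is None else str(r.exact_match)
                fh.write(f"{r.scaffold_id}\t{r.start}\t{r.end}\t{r.closed}\t"
                         f"{r.assessable}\t{sim}\t{exact}\n")

    def summary_line(self) -> str:
        sim = (f"{self.mean_similarity:.2f}"
               if self.mean_similarity is not None else "NA")
        exact = (f"{self.exact_match_fraction:.3f}"
                 if self.exact_match_fraction is not None else "NA")
        return (f"gaps={self.total_gaps} closed={self.closed} "
                f"success={self.percent_success:.1f}% "
                f"mean_similarity={sim} exact_match_fraction={exact}")


def evaluate(
    draft: list[Scaffold],
    filled: list[Scaffold],
    truth: list | None = None,
    flank_len: int = 100,
    similarity_threshold: float | None = None,
) -> EvalReport:
    """Closure and accuracy report for a filled assembly.

    A gap counts as closed when its flanks anchor in the filled assembly
    and the sequence between them is N-free.  With *truth* entries
    (matched by draft coordinates) each closed insertion is scored by
    :func:`similarity` and for exact match under ambiguity expansion.
    ``similarity_threshold`` (e.g. 95.0) only annotates the summary
    counts; it never filters rows.
    """
    draft_ids = {name for name, _ in draft}
    filled_ids = {name for name, _ in filled}
    missing = sorted(draft_ids - filled_ids)
    if missing:
        raise ValueError(f"scaffolds missing from the filled assembly: {missing}")

    truth_by_key: dict[tuple[str, int, int], str] = {}
    if truth:
        for t in truth:
            truth_by_key[(t.scaffold_id, t.start, t.end)] = t.true_sequence

    rows: list[GapEvalRow] = []
    sims: list[float] = []
    exacts: list[bool] = []
    closed = 0
    for ins in extract_inserted(draft, filled, flank_len):
        row = GapEvalRow(ins.scaffold_id, ins.start, ins.end,
                         closed=False, assessable=ins.assessable,
                         inserted=ins.sequence)
        if ins.assessable and ins.sequence is not None and "N" not in ins.sequence:
            row.closed = True
            closed += 1
            key = (ins.scaffold_id, ins.start, ins.end)
            t = truth_by_key.get(key)
            if t is not None:
                row.truth = t
                if ins.sequence:
                    row.percent_similarity = similarity(ins.sequence, t)
                else:  # gap legitimately closed to zero interior bases
                    row.percent_similarity = 100.0 if not t else 0.0
                row.exact_match = ambiguity_equal(ins.sequence, t)
                sims.append(row.percent_similarity)
                exacts.append(row.exact_match)
        rows.append(row)

    total = len(rows)
    report = EvalReport(
        rows=rows,
        total_gaps=total,
        closed=closed,
        percent_success=100.0 * closed / total if total else 0.0,
        mean_similarity=sum(sims) / len(sims) if sims else None,
        exact_match_fraction=sum(exacts) / len(exacts) if exacts else None,
    )
    if similarity_threshold is not None and sims:
        n_pass = sum(s >= similarity_threshold for s in sims)
        report.above_threshold = (n_pass, len(sims))
    return report
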