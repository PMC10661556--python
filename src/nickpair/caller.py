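"""Amplicon read alignment and indel calling.

Each read is globally aligned to its amplicon reference (end-anchored,
affine gap penalties), gaps are converted to deletion intervals and
insertion events, and every indel is left-aligned so that all
shift-equivalent placements inside a repeat map to one canonical
representative.  Substitution-only reads are reported as unedited:
the read-out of interest is indels at repair junctions, and isolated
mismatches are indistinguishable from sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Optional, Sequence

from Bio import Align

from .geometry import InputError

__all__ = [
    "EDIT_CLASSES",
    "AlignmentScoring",
    "IndelCall",
    "EditingStats",
    "align_and_call",
    "call_edits",
    "canonicalize_call",
    "left_align_deletion",
    "left_align_insertion",
]

EDIT_CLASSES = ("unedited", "deletion", "insertion", "deletion_plus_insertion",
                "complex", "low_quality")


@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring; gap of length L costs open + (L-1)*extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -6
    gap_extend: int = -1

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_open >= 0:
            raise InputError("need match > 0 and mismatch, gap_open < 0")

    def build_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = self.match
        aligner.mismatch_score = self.mismatch
        aligner.open_gap_score = self.gap_open
        aligner.extend_gap_score = self.gap_extend
        return aligner


@dataclass(frozen=True)
class IndelCall:
    """Per-read edit description with canonical (left-aligned) intervals."""

    read_id: str
    edit_class: str
    deletions: tuple[tuple[int, int], ...] = ()
    insertion_seq: str = ""
    insertion_point: Optional[int] = None

    def __post_init__(self) -> None:
        if self.edit_class not in EDIT_CLASSES:
            raise InputError(f"unknown edit_class {self.edit_class!r}")
        if self.edit_class in ("unedited", "low_quality"):
            assert not self.deletions and not self.insertion_seq

    @property
    def total_deleted_nt(self) -> int:
        return sum(e - s for s, e in self.deletions)

    def is_edited(self, window: Optional[tuple[int, int]] = None,
                  min_indel_nt: int = 1) -> bool:
        """Does this read carry a qualifying indel inside ``window``?"""
        if self.edit_class in ("unedited", "low_quality"):
            return False
        lo, hi = window if window is not None else (float("-inf"), float("inf"))
        for s, e in self.deletions:
            if e - s >= min_indel_nt and s < hi and e > lo:
                return True
        if (len(self.insertion_seq) >= min_indel_nt
                and self.insertion_point is not None
                and lo <= self.insertion_point <= hi):
            return True
        return False


@dataclass(frozen=True)
class EditingStats:
    total_reads: int
    edited_reads: int
    transfection_efficiency: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.transfection_efficiency <= 1):
            raise InputError("transfection_efficiency must be in (0, 1]")
        if self.edited_reads > self.total_reads:
            raise InputError("edited_reads cannot exceed total_reads")

    @property
    def indel_frequency(self) -> float:
        """(edited/total)/transfection_efficiency, capped at 1."""
        if self.total_reads == 0:
            return 0.0
        return min(1.0, (self.edited_reads / self.total_reads)
                   / self.transfection_efficiency)


def left_align_deletion(reference: str, start: int, end: int) -> tuple[int, int]:
    """Shift a deletion to its lowest-coordinate shift-equivalent placement."""
    while start > 0 and reference[start - 1] == reference[end - 1]:
        start -= 1
        end -= 1
    return start, end


def left_align_insertion(reference: str, point: int, seq: str) -> tuple[int, str]:
    """Shift an insertion leftward through flanking repeats (rotating it)."""
    while point > 0 and seq and reference[point - 1] == seq[-1]:
        seq = reference[point - 1] + seq[:-1]
        point -= 1
    return point, seq


def _merge_deletions(dels: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    dels = sorted(dels)
    merged: list[tuple[int, int]] = []
    for s, e in dels:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return tuple(merged)


def canonicalize_call(call: IndelCall, reference: str) -> IndelCall:
    """Left-align all indels; idempotent.

    Deletions are shifted independently and merged if they collide;
    the insertion (if any) is rotated leftward through repeats.
    """
    if call.edit_class in ("unedited", "low_quality"):
        return call
    dels = [left_align_deletion(reference, s, e) for s, e in call.deletions]
    point, seq = call.insertion_point, call.insertion_seq
    if seq and point is not None:
        point, seq = left_align_insertion(reference, point, seq)
    return replace(call, deletions=_merge_deletions(dels),
                   insertion_seq=seq, insertion_point=point)


def _classify(deletions: Sequence[tuple[int, int]],
              insertions: Sequence[tuple[int, str]]) -> str:
    if not deletions and not insertions:
        return "unedited"
    if deletions and not insertions:
        return "deletion"
    if not deletions and len(insertions) == 1:
        return "insertion"
    if deletions and len(insertions) == 1:
        return "deletion_plus_insertion"
    return "complex"


def _gaps_from_alignment(alignment, read: str) -> tuple[list, list]:
    """Deletion intervals and insertion events from an aligned-blocks pair."""
    t_blocks, q_blocks = alignment.aligned
    deletions: list[tuple[int, int]] = []
    insertions: list[tuple[int, str]] = []
    ref_len = len(alignment.target)
    if len(t_blocks) == 0:  # degenerate: nothing aligned
        return [(0, ref_len)] if ref_len else [], \
            [(0, read)] if read else []
    # leading end gaps
    t0, q0 = t_blocks[0][0], q_blocks[0][0]
    if t0 > 0:
        deletions.append((0, int(t0)))
    if q0 > 0:
        insertions.append((0, read[:int(q0)]))
    for i in range(1, len(t_blocks)):
        t_prev, q_prev = int(t_blocks[i - 1][1]), int(q_blocks[i - 1][1])
        t_next, q_next = int(t_blocks[i][0]), int(q_blocks[i][0])
        if t_next > t_prev:
            deletions.append((t_prev, t_next))
        if q_next > q_prev:
            insertions.append((t_prev, read[q_prev:q_next]))
    # trailing end gaps
    t_end, q_end = int(t_blocks[-1][1]), int(q_blocks[-1][1])
    if t_end < ref_len:
        deletions.append((t_end, ref_len))
    if q_end < len(read):
        insertions.append((t_end, read[q_end:]))
    return deletions, insertions


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def align_and_call(read: str, reference: str,
                   qualities: Optional[Sequence[int]] = None,
                   scoring: AlignmentScoring = AlignmentScoring(),
                   read_id: str = "read",
                   min_read_len: int = 30,
                   min_mean_quality: float = 20.0) -> IndelCall:
    """Align one read end-to-end against the amplicon and call its indels.

    Reads below the length floor or the mean-Phred threshold are classed
    ``low_quality`` and never count as edited.  Equal-length reads with at
    most two mismatches are provably substitution-only under the default
    scoring (an indel detour can never score higher), so they short-circuit
    the dynamic programme.
    """
    read = str(read).upper()
    reference = str(reference).upper()
    if not reference:
        raise InputError("empty reference")
    if len(read) < min_read_len:
        return IndelCall(read_id, "low_quality")
    if qualities is not None and len(qualities) > 0:
        if sum(qualities) / len(qualities) < min_mean_quality:
            return IndelCall(read_id, "low_quality")
    if len(read) == len(reference) and _hamming(read, reference) <= 2:
        return IndelCall(read_id, "unedited")
    aligner = scoring.build_aligner()
    alignment = aligner.align(reference, read)[0]
    deletions, insertions = _gaps_from_alignment(alignment, read)
    edit_class = _classify(deletions, insertions)
    if edit_class in ("insertion", "deletion_plus_insertion"):
        point, seq = insertions[0]
    elif edit_class == "complex":
        # keep the first insertion as representative; full detail would
        # need a richer record than the per-read table provides
        point, seq = insertions[0] if insertions else (None, "")
    else:
        point, seq = None, ""
    call = IndelCall(read_id, edit_class, tuple(deletions), seq, point)
    return canonicalize_call(call, reference)


def call_edits(reads: Iterable[tuple[str, str, Optional[Sequence[int]]]],
               reference: str,
               window: Optional[tuple[int, int]] = None,
               min_indel_nt: int = 1,
               transfection_efficiency: float = 1.0,
               scoring: AlignmentScoring = AlignmentScoring(),
               min_read_len: int = 30,
               min_mean_quality: float = 20.0,
               ) -> tuple[EditingStats, list[IndelCall]]:
    """Call every read in a stream and tally editing statistics.

    ``reads`` yields (read_id, sequence, phred_qualities-or-None) tuples,
    e.g. from :func:`nickpair.io.read_fastq`.  A read counts as edited iff
    it carries an indel of at least ``min_indel_nt`` intersecting
    ``window`` (default: the whole reference).  Deterministic and
    order-independent in its statistics.
    """
    if window is not None:
        lo, hi = window
        if not (0 <= lo < hi <= len(reference)):
            raise InputError("window must lie inside the reference")
    calls: list[IndelCall] = []
    edited = 0
    for read_id, seq, quals in reads:
        call = align_and_call(seq, reference, quals, scoring, read_id,
                              min_read_len, min_mean_quality)
        calls.append(call)
        if call.is_edited(window, min_indel_nt):
            edited += 1
    stats = EditingStats(len(calls), edited, transfection_efficiency)
    return stats, calls
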